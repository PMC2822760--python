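"""Genomic probe grid and interval primitives shared across the package.

All genomic intervals are 0-based, half-open ``[start, end)`` — on disk and
in memory; no other convention appears anywhere in the package. Probe
adjacency (the unit of the recurrence screen) is defined only between
consecutive probes of the same chromosome, in genome order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRID_COLUMNS = ("chrom", "start", "end", "probe_id", "gene")

DEFAULT_SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


class GridError(ValueError):
    """Raised for malformed probe grids or grid-aligned inputs."""


@dataclass(frozen=True)
class ProbeGrid:
    """Ordered genomic probe coordinates defining adjacency.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``chrom, start, end, probe_id`` and optional ``gene``.
        Rows are sorted into genome order (chromosome in first-appearance
        order, then start) on construction.

    Notes
    -----
    Invariants enforced at construction: unique probe ids, ``end > start``
    for every probe, strictly increasing starts within each chromosome.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        missing = {"chrom", "start", "end", "probe_id"} - set(df.columns)
        if missing:
            raise GridError(f"probe table lacks columns: {sorted(missing)}")
        if "gene" not in df.columns:
            df = df.assign(gene=None)
        df = df.loc[:, list(GRID_COLUMNS)].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df.index[df["end"] <= df["start"]]
        if len(bad):
            raise GridError(f"probe interval with end <= start at row {bad[0]}")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise GridError(f"duplicate probe_id: {dup!r}")
        # genome order: chromosomes in first-appearance order, then start
        chrom_rank = {c: i for i, c in enumerate(pd.unique(df["chrom"]))}
        order = np.lexsort((df["start"].to_numpy(),
                            df["chrom"].map(chrom_rank).to_numpy()))
        df = df.iloc[order].reset_index(drop=True)
        for _, sub in df.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            if np.any(np.diff(s) <= 0):
                raise GridError(
                    f"starts not strictly increasing on {sub['chrom'].iloc[0]}")
        object.__setattr__(self, "df", df)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.df["probe_id"])

    @property
    def chroms(self) -> list[str]:
        return list(pd.unique(self.df["chrom"]))

    def chrom_bounds(self) -> dict[str, tuple[int, int]]:
        """Row-index span ``[lo, hi)`` of each chromosome."""
        out: dict[str, tuple[int, int]] = {}
        chroms = self.df["chrom"].to_numpy()
        for c in self.chroms:
            idx = np.flatnonzero(chroms == c)
            out[c] = (int(idx[0]), int(idx[-1]) + 1)
        return out

    def adjacent_pairs(self) -> np.ndarray:
        """(n_pairs, 2) row indices of genome-adjacent probe pairs.

        Pairs never span a chromosome boundary.
        """
        pairs = []
        for lo, hi in self.chrom_bounds().values():
            if hi - lo >= 2:
                i = np.arange(lo, hi - 1)
                pairs.append(np.column_stack([i, i + 1]))
        if not pairs:
            return np.empty((0, 2), dtype=np.int64)
        return np.concatenate(pairs)

    def probes_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row indices of probes overlapping ``[start, end)`` on ``chrom``."""
        sub = self.df["chrom"].to_numpy() == chrom
        s = self.df["start"].to_numpy()
        e = self.df["end"].to_numpy()
        return np.flatnonzero(sub & (s < end) & (e > start))

    def subset(self, rows: np.ndarray) -> "ProbeGrid":
        return ProbeGrid(self.df.iloc[rows].reset_index(drop=True))

    def address(self, row: int) -> str:
        """Mbp display address, e.g. ``chr14:105.41`` (report-only string)."""
        r = self.df.iloc[row]
        return f"{r['chrom']}:{r['start'] / 1e6:.2f}"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeGrid):
            return NotImplemented
        return self.df.equals(other.df)


def merge_intervals(intervals: "list[tuple[str, int, int]] | pd.DataFrame",
                    ) -> pd.DataFrame:
    """Union overlapping/abutting half-open intervals per chromosome.

    Returns a sorted DataFrame with columns ``chrom, start, end`` in which
    intervals are disjoint within each chromosome.
    """
    if isinstance(intervals, pd.DataFrame):
        df = intervals.loc[:, ["chrom", "start", "end"]].copy()
    else:
        df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["end"] <= df["start"]).any():
        raise GridError("interval with end <= start")
    out = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom"):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:          # overlap or abut -> union
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def interval_overlaps_any(chrom: str, start: int, end: int,
                          merged: pd.DataFrame) -> bool:
    """True if ``[start, end)`` overlaps (>=1 bp) a merged interval set."""
    sub = merged[merged["chrom"] == chrom]
    if sub.empty:
        return False
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    # merged and sorted: find the first interval with end > start
    i = int(np.searchsorted(ends, start, side="right"))
    return i < len(starts) and starts[i] < end
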