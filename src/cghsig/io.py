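"""Readers and writers for every on-disk artifact.

Formats are deliberately plain: BED-like TSV for probe tables and interval
masks (0-based half-open, no header), TSV matrices with a header row of
sample ids and ``probe_id`` as the first column, and Newick for dendrograms.
FR values are serialized with 6 significant digits; downstream comparisons
use numeric tolerances, never string equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import to_tree

from .grid import GridError, ProbeGrid, merge_intervals
from .vocab import SAMPLE_CLASSES, SEXES

log = logging.getLogger("cghsig")

FLOAT_FMT = "%.6g"


class ParseError(ValueError):
    """Malformed on-disk input; the message names the offending line."""


# ---------------------------------------------------------------------------
# probe tables
# ---------------------------------------------------------------------------

def read_probe_table(path) -> ProbeGrid:
    """Read a 4-5 column BED-like probe table into a :class:`ProbeGrid`.

    Columns: chrom, start, end, probe_id, optional gene. Unsorted input is
    sorted silently (logged); a line with ``end <= start`` raises
    :class:`ParseError` naming the line number (1-based).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                         comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty probe table")
    if df.shape[1] < 4:
        raise ParseError(f"{path}: probe table needs >= 4 columns")
    df = df.iloc[:, :5]
    df.columns = ["chrom", "start", "end", "probe_id", "gene"][: df.shape[1]]
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-integer coordinate ({exc})")
    bad = np.flatnonzero((df["end"] <= df["start"]).to_numpy())
    if bad.size:
        raise ParseError(f"{path}: end <= start at line {bad[0] + 1}")
    if "gene" in df.columns:
        df["gene"] = df["gene"].where(df["gene"].notna()
                                      & (df["gene"] != "."), None)
    was_sorted = (df["start"].groupby(df["chrom"], sort=False)
                  .apply(lambda s: bool(s.is_monotonic_increasing)).all())
    grid = ProbeGrid(df)            # sorts, validates uniqueness/monotonicity
    if not was_sorted:
        log.info("probe table %s was not in genome order; sorted", path)
    return grid


def write_probe_table(grid: ProbeGrid, path) -> None:
    df = grid.df.copy()
    df["gene"] = df["gene"].fillna(".")
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FR matrix
# ---------------------------------------------------------------------------

def read_fr_matrix(path, grid: ProbeGrid) -> pd.DataFrame:
    """Read a probes x samples ratio matrix aligned to ``grid`` order.

    The file has a header row of unique sample ids and ``probe_id`` as its
    first column. Probes present in the matrix but absent from the grid are
    an error; grid probes absent from the matrix become all-missing rows
    (logged). Empty cells are missing (NaN), never zero.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise ParseError(f"{path}: duplicate sample ids in header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = df.index.difference(grid.probe_ids)
    if len(unknown):
        raise ParseError(
            f"{path}: probe {unknown[0]!r} absent from the probe grid")
    aligned = df.reindex(grid.probe_ids)
    n_absent = len(grid) - df.index.nunique()
    if n_absent:
        log.info("%s: %d grid probes missing from matrix; rows set missing",
                 path, n_absent)
    aligned.index.name = "probe_id"
    return aligned.astype(float)


def write_fr_matrix(fr: pd.DataFrame, path) -> None:
    fr.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="probe_id")


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "class", "sex"} - set(df.columns)
    if need:
        raise ParseError(f"{path}: sample sheet lacks columns {sorted(need)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    bad = set(df["class"]) - set(SAMPLE_CLASSES)
    if bad:
        raise ParseError(f"{path}: unknown class {sorted(bad)[0]!r} "
                         f"(allowed: {SAMPLE_CLASSES})")
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise ParseError(f"{path}: unknown sex {sorted(bad_sex)[0]!r}")
    return df.loc[:, ["sample_id", "class", "sex"]]


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.loc[:, ["sample_id", "class", "sex"]].to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CNV mask
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNVMask:
    """Known copy-number-variable regions, merged per chromosome."""

    intervals: pd.DataFrame = field(repr=False)  # chrom, start, end (merged)
    merged: bool = True

    @classmethod
    def from_intervals(cls, intervals) -> "CNVMask":
        return cls(intervals=merge_intervals(intervals), merged=True)

    def __len__(self) -> int:
        return len(self.intervals)


def load_cnv_mask(path) -> CNVMask:
    """Load a BED(3+) file of CNV regions; overlaps are unioned."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {i}: fewer than 3 columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}: line {i}: non-integer coordinate")
            if e <= s:
                raise ParseError(f"{path}: line {i}: end <= start")
            rows.append((parts[0], s, e))
    return CNVMask.from_intervals(rows)


def write_cnv_mask(mask: "CNVMask | pd.DataFrame", path) -> None:
    df = mask.intervals if isinstance(mask, CNVMask) else mask
    df.loc[:, ["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# call matrices and truth sets
# ---------------------------------------------------------------------------

def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index_label="probe_id")


def read_calls(path, grid: ProbeGrid) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = df.index.difference(grid.probe_ids)
    if len(unknown):
        raise ParseError(
            f"{path}: probe {unknown[0]!r} absent from the probe grid")
    return df.reindex(grid.probe_ids).astype(int)


def write_truth(truth, path) -> None:
    truth.events_frame().to_csv(path, sep="\t", index=False,
                                float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Newick serialization of a merge tree
# ---------------------------------------------------------------------------

_NEWICK_UNSAFE = set("(),:;'\"[]\t\n ")


def write_newick(linkage_matrix: "np.ndarray | None",
                 labels: "list[str]") -> str:
    """Serialize an agglomerative merge tree as Newick text.

    Branch lengths are differences of merge heights (an ultrametric tree:
    every leaf sits at depth equal to the root merge height). Two leaves
    merged at height 1.0 give ``(A:1,B:1);``. A single leaf (no merges)
    serializes as ``A;``.
    """
    if len(set(labels)) != len(labels):
        raise GridError("duplicate leaf labels in tree")
    for lab in labels:
        if _NEWICK_UNSAFE & set(lab):
            raise GridError(f"leaf label {lab!r} contains Newick syntax "
                            "characters")
    if len(labels) == 1:
        return f"{labels[0]};"
    root = to_tree(np.asarray(linkage_matrix, dtype=float))

    def render(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        inner = ",".join(render(c, node.dist) for c in
                         (node.left, node.right))
        return f"({inner}):{parent_height - node.dist:.6g}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"


def save_newick(linkage_matrix, labels, path) -> None:
    Path(path).write_text(write_newick(linkage_matrix, labels) + "\n")


# ---------------------------------------------------------------------------
# dataset validation (backs the CLI `validate` subcommand)
# ---------------------------------------------------------------------------

def validate_dataset(directory) -> list[dict]:
    """Check a dataset directory; return a machine-readable error list.

    Expects ``probes.bed``, ``fr_matrix.tsv``, ``samples.tsv`` and
    optionally ``cnv_mask.bed``. Each error is a dict with ``file`` and
    ``error`` keys; an empty list means the dataset loads cleanly.
    """
    directory = Path(directory)
    errors: list[dict] = []
    grid = None
    for fname, reader in (("probes.bed", read_probe_table),
                          ("samples.tsv", read_sample_sheet)):
        fpath = directory / fname
        if not fpath.exists():
            errors.append({"file": fname, "error": "missing file"})
            continue
        try:
            obj = reader(fpath)
            if fname == "probes.bed":
                grid = obj
        except (ParseError, GridError) as exc:
            errors.append({"file": fname, "error": str(exc)})
    fpath = directory / "fr_matrix.tsv"
    if not fpath.exists():
        errors.append({"file": "fr_matrix.tsv", "error": "missing file"})
    elif grid is not None:
        try:
            read_fr_matrix(fpath, grid)
        except (ParseError, GridError) as exc:
            errors.append({"file": "fr_matrix.tsv", "error": str(exc)})
    fpath = directory / "cnv_mask.bed"
    if fpath.exists():
        try:
            load_cnv_mask(fpath)
        except ParseError as exc:
            errors.append({"file": "cnv_mask.bed", "error": str(exc)})
    return errors
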