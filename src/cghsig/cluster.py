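"""Hierarchical clustering of call profiles and region-level signatures.

Samples are clustered on a selected probe subset (typically the top probes
of the two-class analysis) with average-linkage agglomerative clustering on
Euclidean distance. Region-level deletion flags summarise ternary calls
over named genomic regions (IGH, TCRG, TCRA/D, IKZF1 and the broader 7p/9p
segments); a sample shows the "concomitant" 7p/9p loss when every
secondary-role region is deleted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .grid import ProbeGrid
from .simulate import ConfigError

log = logging.getLogger("cghsig")

DELETED, NOT_DELETED, NO_DATA = "deleted", "not_deleted", "no_data"


@dataclass(frozen=True)
class RegionDef:
    """A named genomic region with a signature role.

    ``role`` is ``"primary"`` (loci nearly always deleted in lymphoid blast
    crisis: IGH, TCR, IKZF1) or ``"secondary"`` (the 7p/9p segments whose
    joint loss defines the concomitant pattern).
    """

    name: str
    chrom: str
    start: int
    end: int
    role: str = "primary"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigError(f"region {self.name!r}: end <= start")
        if self.role not in ("primary", "secondary"):
            raise ConfigError(f"region {self.name!r}: bad role {self.role!r}")


def regions_from_templates(templates) -> list[RegionDef]:
    """Region definitions matching a simulation's signature templates."""
    return [RegionDef(t.name, t.chrom, t.start, t.end, t.role)
            for t in templates]


def read_regions(path) -> list[RegionDef]:
    df = pd.read_csv(path, sep="\t")
    need = {"name", "chrom", "start", "end", "role"} - set(df.columns)
    if need:
        raise ConfigError(f"{path}: region table lacks columns "
                          f"{sorted(need)}")
    if df["name"].duplicated().any():
        raise ConfigError(f"{path}: duplicate region names")
    return [RegionDef(r["name"], r["chrom"], int(r["start"]), int(r["end"]),
                      r["role"]) for _, r in df.iterrows()]


def write_regions(regions, path) -> None:
    pd.DataFrame([(r.name, r.chrom, r.start, r.end, r.role) for r in regions],
                 columns=["name", "chrom", "start", "end", "role"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def hierarchical_cluster(fr_sub: pd.DataFrame, method: str = "average",
                         metric: str = "euclidean",
                         ) -> tuple[list[str], np.ndarray]:
    """Cluster samples on a selected-probes x samples matrix.

    Missing cells are imputed with the probe-wise median (logged). Returns
    the dendrogram leaf order (sample ids) and the scipy linkage matrix,
    whose heights serialise to Newick via :func:`cghsig.io.write_newick`.
    """
    if fr_sub.shape[1] < 2:
        raise ConfigError("clustering needs >= 2 samples")
    X = fr_sub.to_numpy(dtype=float).T        # samples x probes
    if np.isnan(X).all(axis=0).any():
        raise ConfigError("a probe with no data in any sample cannot be "
                          "imputed")
    if np.isnan(X).any():
        med = np.nanmedian(X, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = med[nan_c]
        log.info("imputed %d missing cells with probe-wise medians",
                 nan_r.size)
    Z = linkage(X, method=method, metric=metric)
    order = [fr_sub.columns[i] for i in leaves_list(Z)]
    return order, Z


def cut_clusters(Z: np.ndarray, n_clusters: int) -> np.ndarray:
    """Flat cluster labels for a linkage matrix at ``n_clusters``."""
    return fcluster(Z, t=n_clusters, criterion="maxclust")


# ---------------------------------------------------------------------------
# region signature calls
# ---------------------------------------------------------------------------

def region_deletion_flag(calls, grid: ProbeGrid, region: RegionDef,
                         min_fraction: float = 0.5,
                         missing=None) -> pd.Series:
    """Per-sample deletion flag for one region.

    A sample is ``deleted`` when at least ``min_fraction`` of the region's
    probes carry call -1; ``no_data`` when every region probe is missing
    for that sample (``missing`` is an optional probes x samples boolean
    matrix). A region overlapping no probe is an error naming the region.
    """
    rows = grid.probes_in(region.chrom, region.start, region.end)
    if rows.size == 0:
        raise ConfigError(f"region {region.name!r} overlaps no probe")
    calls = np.asarray(calls)
    sub = calls[rows]                           # region probes x samples
    n_probes = rows.size
    lost = (sub == -1).sum(axis=0)
    flags = np.where(lost / n_probes >= min_fraction, DELETED, NOT_DELETED)
    if missing is not None:
        miss = np.asarray(missing)[rows]
        flags = np.where(miss.all(axis=0), NO_DATA, flags)
    return pd.Series(flags, name=region.name)


def signature_flags(calls, grid: ProbeGrid, regions, sample_ids,
                    min_fraction: float = 0.5, missing=None) -> pd.DataFrame:
    """Samples x regions flag matrix (values deleted/not_deleted/no_data)."""
    names = [r.name for r in regions]
    if len(set(names)) != len(names):
        raise ConfigError("region names must be unique")
    cols = {r.name: region_deletion_flag(calls, grid, r, min_fraction,
                                         missing).to_numpy()
            for r in regions}
    return pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))


def classify_concomitant(flags: pd.DataFrame, regions) -> pd.Series:
    """True where every secondary-role region is deleted in the sample.

    Monotone by construction: deleting more regions can only turn the flag
    on, never off.
    """
    secondary = [r.name for r in regions if r.role == "secondary"]
    if not secondary:
        return pd.Series(False, index=flags.index, name="concomitant_7p9p")
    out = (flags[secondary] == DELETED).all(axis=1)
    out.name = "concomitant_7p9p"
    return out


def cohort_summary(flags: pd.DataFrame, samples: pd.DataFrame,
                   target_class) -> pd.DataFrame:
    """Per-region deletion counts and fractions over a sample class set.

    ``target_class`` is a class name or an iterable of class names (e.g.
    the lymphoid pair BCL + BCmix). An empty class yields NaN fractions.
    """
    if isinstance(target_class, str):
        target_class = [target_class]
    ids = samples.loc[samples["class"].isin(target_class), "sample_id"]
    sub = flags.loc[flags.index.intersection(ids)]
    n_class = len(sub)
    rows = []
    for region in flags.columns:
        n_del = int((sub[region] == DELETED).sum())
        frac = n_del / n_class if n_class else np.nan
        rows.append((region, n_del, n_class, frac))
    return pd.DataFrame(rows, columns=["region", "n_deleted", "n_class",
                                       "fraction"])
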