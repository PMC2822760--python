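"""Per-sample noise estimation, ternary calling and the recurrence screen.

The noise model is per sample: each hybridisation has its own fluorescence
ratio scatter, summarised by an iterative outlier-resistant standard
deviation (sigma clipping about the running median). Probes are called
gained (+1) or lost (-1) when their ratio leaves a ``center +- k*SD`` band
— k = 4 for the genome-wide aberration screen, k = 3 for per-region call
displays. The preliminary screen keeps loci where at least ``min_adjacent``
genome-adjacent probes are called in the same direction within a sample,
and at least ``min_samples`` samples support the same probe pair; known
copy-number-variant regions are then masked out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .grid import DEFAULT_SEX_CHROMS, ProbeGrid, interval_overlaps_any
from .simulate import ConfigError


class DegenerateSampleWarning(UserWarning):
    """A sample whose retained values are all identical (SD = 0)."""


class RobustStats(NamedTuple):
    sd: float
    center: float
    n_iter: int
    n_excluded: int


def robust_sd(values, k_reject: float = 3.0, tol: float = 1e-6,
              max_iter: int = 50) -> RobustStats:
    """Iterative outlier-resistant scale estimate (sigma clipping).

    Starting from all non-missing values, repeat: center = median of the
    retained set, sd = sample standard deviation of the retained set,
    reject retained points with ``|x - center| > k_reject * sd``. Stop when
    the retained set is unchanged, ``|delta sd| < tol``, or ``max_iter`` is
    reached.

    Notes
    -----
    The retained-set SD is reported as-is (no truncation-bias correction),
    so on clean Gaussian data the estimate sits ~1.5% below the true sigma
    — the fixed point of a +-3 sigma clip. This keeps the invariant
    ``robust_sd <= plain SD``.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError("robust_sd needs >= 3 non-missing values")
    retained = x
    sd = float(np.std(retained, ddof=1))
    center = float(np.median(retained))
    n_iter = 0
    while n_iter < max_iter:
        n_iter += 1
        center = float(np.median(retained))
        sd = float(np.std(retained, ddof=1))
        if sd == 0.0:
            warnings.warn("all retained values identical; SD = 0",
                          DegenerateSampleWarning, stacklevel=2)
            break
        keep = np.abs(retained - center) <= k_reject * sd
        if keep.all():
            break
        new = retained[keep]
        new_sd = float(np.std(new, ddof=1)) if new.size > 1 else 0.0
        converged = abs(new_sd - sd) < tol
        retained = new
        center = float(np.median(retained))
        sd = new_sd
        if sd == 0.0:
            warnings.warn("all retained values identical; SD = 0",
                          DegenerateSampleWarning, stacklevel=2)
            break
        if converged:
            break
    return RobustStats(sd=sd, center=center, n_iter=n_iter,
                       n_excluded=int(x.size - retained.size))


def sample_qc(fr: pd.DataFrame, **kw) -> pd.DataFrame:
    """Per-sample robust noise statistics for a probes x samples matrix."""
    rows = [robust_sd(fr[c].to_numpy(), **kw) for c in fr.columns]
    return pd.DataFrame(rows, index=pd.Index(fr.columns, name="sample_id"),
                        columns=["robust_sd", "center", "n_iter",
                                 "n_excluded"])


def call_matrix(fr, center, sd, k: float = 4.0) -> np.ndarray:
    """Ternary gain/normal/loss calls at per-sample ``center +- k*sd``.

    Parameters
    ----------
    fr : array-like, shape (n_probes, n_samples)
        Simple fluorescence ratios; NaN cells are never calls.
    center, sd : array-like, shape (n_samples,)
        Per-sample robust location and scale (e.g. from :func:`sample_qc`).
    k : float
        SD multiplier; 4 for the aberration screen, 3 for call displays.

    Returns
    -------
    ndarray of int8, shape (n_probes, n_samples)
        +1 where ``fr > center + k*sd``, -1 where ``fr < center - k*sd``,
        0 otherwise. Samples with ``sd == 0`` yield all-zero calls (with a
        warning).
    """
    if k <= 0:
        raise ConfigError("k must be > 0")
    x = np.asarray(fr, dtype=float)
    center = np.asarray(center, dtype=float)[np.newaxis, :]
    sd = np.asarray(sd, dtype=float)[np.newaxis, :]
    if (sd == 0).any():
        warnings.warn("sample(s) with SD = 0: their calls are all 0",
                      DegenerateSampleWarning, stacklevel=2)
    hi = center + k * sd
    lo = center - k * sd
    calls = np.zeros(x.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        ok = ~np.isnan(x) & (sd > 0)
        calls[ok & (x > hi)] = 1
        calls[ok & (x < lo)] = -1
    return calls


class TernaryCaller(BaseEstimator, TransformerMixin):
    """Robust-SD ternary caller, sklearn style.

    ``fit(X)`` estimates a robust center and SD per sample (rows of ``X``);
    ``transform(X)`` returns ternary calls. ``X`` follows the sklearn
    orientation, shape (n_samples, n_probes); NaN entries are allowed and
    never become calls.

    Parameters
    ----------
    k : float, default 4.0
        Call threshold in robust-SD units.
    k_reject, tol, max_iter :
        Sigma-clipping parameters of :func:`robust_sd`.

    Attributes
    ----------
    center_, sd_ : ndarray of shape (n_samples,)
    n_iter_, n_excluded_ : ndarray of shape (n_samples,)
    """

    def __init__(self, k: float = 4.0, k_reject: float = 3.0,
                 tol: float = 1e-6, max_iter: int = 50):
        self.k = k
        self.k_reject = k_reject
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_probes)")
        stats = [robust_sd(row, k_reject=self.k_reject, tol=self.tol,
                           max_iter=self.max_iter) for row in X]
        self.center_ = np.array([s.center for s in stats])
        self.sd_ = np.array([s.sd for s in stats])
        self.n_iter_ = np.array([s.n_iter for s in stats])
        self.n_excluded_ = np.array([s.n_excluded for s in stats])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        # call_matrix is probes x samples; X is samples x probes
        return call_matrix(X.T, self.center_, self.sd_, k=self.k).T


# ---------------------------------------------------------------------------
# adjacency / recurrence screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    chrom: str
    first_probe: int         # grid row index of the first probe
    last_probe: int          # grid row index of the last probe (inclusive)
    start: int               # bp footprint start (first probe start)
    end: int                 # bp footprint end (last probe end)
    direction: int           # -1 loss, +1 gain
    samples: tuple[str, ...]
    n_pairs: int


@dataclass(frozen=True)
class RecurrentLocusSet:
    loci: tuple[Locus, ...]
    min_adjacent: int
    min_samples: int
    k: float

    def __len__(self) -> int:
        return len(self.loci)

    def to_frame(self) -> pd.DataFrame:
        rows = [(l.chrom, l.start, l.end, l.direction, l.n_pairs,
                 len(l.samples), ",".join(l.samples)) for l in self.loci]
        return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "direction", "n_pairs",
                                           "n_samples", "samples"])


def _run_covered(called: np.ndarray, min_adjacent: int) -> np.ndarray:
    """Mark cells belonging to a run of >= min_adjacent consecutive True.

    ``called`` has shape (n_probes_in_chrom, n_samples); runs are along
    axis 0.
    """
    p, s = called.shape
    m = min_adjacent
    if p < m:
        return np.zeros_like(called)
    c = called.astype(np.int32)
    cs = np.zeros((p + 1, s), dtype=np.int32)
    np.cumsum(c, axis=0, out=cs[1:])
    window_full = (cs[m:] - cs[:-m]) == m          # window starting at w
    covered = np.zeros_like(called)
    for off in range(m):
        covered[off:off + window_full.shape[0]] |= window_full
    return covered


def recurrent_adjacent_loci(calls, grid: ProbeGrid, min_adjacent: int = 2,
                            min_samples: int = 3,
                            sample_ids=None, k: float = 4.0,
                            ) -> RecurrentLocusSet:
    """Find recurrently aberrant loci from adjacent same-direction calls.

    A sample supports an adjacent probe pair when both probes lie in a
    within-chromosome run of >= ``min_adjacent`` consecutive calls of the
    same direction in that sample. Pairs supported by >= ``min_samples``
    samples are kept and merged (per direction) into maximal loci. Runs and
    pairs never span chromosome boundaries; missing cells are not calls and
    break runs.

    Parameters
    ----------
    calls : array-like of int, shape (n_probes, n_samples)
        Ternary call matrix aligned to ``grid`` row order.
    """
    if min_adjacent < 2:
        raise ConfigError("min_adjacent must be >= 2")
    calls = np.asarray(calls)
    if calls.shape[0] != len(grid):
        raise ValueError("calls not aligned to grid")
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(calls.shape[1])]
    sample_ids = list(sample_ids)
    loci: list[Locus] = []
    bounds = grid.chrom_bounds()
    starts = grid.df["start"].to_numpy()
    ends = grid.df["end"].to_numpy()
    for chrom, (lo, hi) in bounds.items():
        block = calls[lo:hi]
        for direction in (-1, 1):
            covered = _run_covered(block == direction, min_adjacent)
            if not covered.any():
                continue
            pair_support = covered[:-1] & covered[1:]   # (n-1, s)
            support_n = pair_support.sum(axis=1)
            good = support_n >= min_samples             # qualifying pairs
            if not good.any():
                continue
            # merge consecutive qualifying pairs into maximal loci
            idx = np.flatnonzero(good)
            breaks = np.flatnonzero(np.diff(idx) > 1)
            groups = np.split(idx, breaks + 1)
            for g in groups:
                first, last = int(g[0]), int(g[-1]) + 1   # probe rows in block
                supp_mask = pair_support[g].any(axis=0)
                loci.append(Locus(
                    chrom=chrom, first_probe=lo + first, last_probe=lo + last,
                    start=int(starts[lo + first]), end=int(ends[lo + last]),
                    direction=direction,
                    samples=tuple(sorted(np.array(sample_ids)[supp_mask])),
                    n_pairs=len(g)))
    loci.sort(key=lambda l: (l.first_probe, l.direction))
    return RecurrentLocusSet(tuple(loci), min_adjacent=min_adjacent,
                             min_samples=min_samples, k=k)


def apply_cnv_mask(loci: RecurrentLocusSet, mask, grid: ProbeGrid,
                   ) -> RecurrentLocusSet:
    """Drop loci whose bp footprint overlaps (>= 1 bp) a CNV mask interval.

    ``mask`` is a :class:`~cghsig.io.CNVMask` or a merged chrom/start/end
    DataFrame. An empty mask is the identity.
    """
    intervals = getattr(mask, "intervals", mask)
    if intervals is None or len(intervals) == 0:
        return loci
    kept = tuple(l for l in loci.loci
                 if not interval_overlaps_any(l.chrom, l.start, l.end,
                                              intervals))
    return RecurrentLocusSet(kept, loci.min_adjacent, loci.min_samples,
                             loci.k)


def drop_sex_chromosomes(fr: pd.DataFrame, grid: ProbeGrid,
                         sex_chroms=DEFAULT_SEX_CHROMS,
                         ) -> tuple[pd.DataFrame, ProbeGrid]:
    """Restrict an FR matrix and its grid to autosomal probes.

    Row order and (probe, sample) values are preserved for retained probes.
    """
    keep = ~grid.df["chrom"].isin(sex_chroms).to_numpy()
    if keep.all():
        return fr, grid
    return fr.iloc[keep].copy(), grid.subset(np.flatnonzero(keep))
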