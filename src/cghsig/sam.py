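"""Two-class unpaired significance analysis with permutation FDR (SAM).

For each probe *i*, the relative difference between two sample classes is

    d_i = (xbar_2i - xbar_1i) / (s_i + s0)

where ``s_i`` is the pooled-variance standard error of the mean difference
and ``s0`` (the "fudge factor") is a small constant stabilising
low-variance probes. The null distribution of the ordered d values is
estimated by permuting class labels: the expected relative difference
``dbar_E(r)`` at rank *r* is the mean of the r-th order statistic over
permutations. Probes are selected either by a delta threshold on the
observed-vs-expected gap (with asymmetric cutpoints and a permutation FDR
estimate) or as the top-k probes by gap magnitude.

FDR convention: for a delta threshold, the number of falsely called probes
is the number of permuted d values beyond the cutpoints, aggregated over
permutations by the MEAN (default). With the mean, an estimated FDR of 0
requires the cutpoints to beat every permutation, which keeps the
pure-noise rate of non-empty FDR=0 calls near 2/(B+1); the classical
median aggregation (and a 90th-percentile variant) remain available via
``false_stat`` but make "FDR = 0" an extremely weak statement — under the
null the observed extreme d beats the median of permuted extremes about
half the time.
"""

from __future__ import annotations

import itertools
import logging
from math import comb

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

log = logging.getLogger("cghsig")

_FALSE_STATS = ("mean", "median", "q90")


class SamError(ValueError):
    pass


# ---------------------------------------------------------------------------
# core statistic
# ---------------------------------------------------------------------------

def _group_stats(X: np.ndarray, Z: np.ndarray):
    """Pooled two-class statistics for many label arrangements at once.

    Parameters
    ----------
    X : (n_samples, n_probes) float array, NaN = missing.
    Z : (B, n_samples) bool array; True marks membership of class 2.

    Returns
    -------
    numer : (B, n_probes) mean(class2) - mean(class1)
    s : (B, n_probes) pooled-variance scatter
    valid : (B, n_probes) bool, False where either class has < 2 values
    """
    V = ~np.isnan(X)
    Xz = np.where(V, X, 0.0)
    Zf = Z.astype(float)
    sum_all = Xz.sum(axis=0)
    sumsq_all = (Xz * Xz).sum(axis=0)
    n_all = V.sum(axis=0).astype(float)
    S2 = Zf @ Xz
    N2 = Zf @ V.astype(float)
    S1 = sum_all - S2
    N1 = n_all - N2
    valid = (N1 >= 2) & (N2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = S1 / N1
        m2 = S2 / N2
        ssw = sumsq_all - S2 * m2 - S1 * m1
        ssw = np.clip(ssw, 0.0, None)
        dof = N1 + N2 - 2.0
        s = np.sqrt((1.0 / N1 + 1.0 / N2) * ssw / dof)
        numer = m2 - m1
    return numer, s, valid


def _as_two_class(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise SamError(f"need exactly two classes, got {classes.size}")
    z = y == classes[1]
    if (~z).sum() < 2 or z.sum() < 2:
        raise SamError("both classes need >= 2 samples")
    return classes, z


def d_statistic(X, y, s0: float):
    """Observed SAM relative difference per probe.

    Parameters
    ----------
    X : array-like (n_samples, n_probes)
        Ratio matrix, samples in rows; NaN cells are excluded per probe
        with class sizes recomputed.
    y : array-like (n_samples,)
        Two-class labels; ``d > 0`` means the second class (sorted label
        order) has the larger mean.
    s0 : float
        Fudge factor added to the denominator.

    Returns
    -------
    d, s : ndarray (n_probes,)
        ``d`` is NaN for probes with < 2 values in either class (flagged,
        excluded from ranking downstream).
    """
    X = np.asarray(X, dtype=float)
    _, z = _as_two_class(y)
    numer, s, valid = _group_stats(X, z[np.newaxis, :])
    numer, s, valid = numer[0], s[0], valid[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = numer / (s + s0)
    d[~valid] = np.nan
    if s0 == 0:
        d[valid & (s == 0)] = np.nan      # 0-denominator probes are flagged
    return d, s


# ---------------------------------------------------------------------------
# fudge factor
# ---------------------------------------------------------------------------

def choose_s0(s, numer, n_windows: int = 100) -> float:
    """Fudge factor by the percentile-CV-minimisation rule.

    Candidates are the 0th-100th percentiles of ``s`` in steps of 5. For
    each candidate the probes are split into ``n_windows`` equal-rank
    windows of ``s``, the median absolute deviation of ``d = numer /
    (s + s0)`` is computed per window, and the candidate minimising the
    coefficient of variation of those MADs wins (smallest percentile on
    ties). Deterministic.
    """
    s = np.asarray(s, dtype=float)
    numer = np.asarray(numer, dtype=float)
    ok = np.isfinite(s) & np.isfinite(numer)
    s, numer = s[ok], numer[ok]
    if s.size < 20:
        raise SamError("choose_s0 needs >= 20 probes")
    if np.ptp(s) == 0:
        return float(s[0])        # degenerate: every percentile is the same
    order = np.argsort(s, kind="stable")
    n_windows = min(n_windows, max(2, s.size // 5))
    windows = np.array_split(order, n_windows)
    pcts = np.arange(0, 101, 5)
    candidates = np.percentile(s, pcts)
    best = (np.inf, 0.0)
    for alpha, s0 in zip(pcts, candidates):
        with np.errstate(divide="ignore", invalid="ignore"):
            d = numer / (s + s0)
        mads = np.array([np.median(np.abs(d[w] - np.median(d[w])))
                         for w in windows]) * 1.4826
        mu = mads.mean()
        cv = mads.std(ddof=1) / mu if mu > 0 else np.inf
        if cv < best[0]:
            best = (cv, float(s0))
    return best[1]


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _arrangements(n: int, n2: int, B: int, rng: np.random.Generator,
                  exhaustive_if_feasible: bool, exhaustive_limit: int,
                  ) -> tuple[np.ndarray, bool]:
    """Label arrangements as a (B', n) boolean class-2 membership matrix.

    Enumerates all C(n, n2) arrangements (classes kept distinct, so a full
    class swap counts as a different arrangement) when feasible, otherwise
    samples B arrangements uniformly.
    """
    total = comb(n, n2)
    if total <= 1:
        raise SamError("only one distinct label arrangement; "
                       "classes degenerate")
    if exhaustive_if_feasible and total <= exhaustive_limit:
        Z = np.zeros((total, n), dtype=bool)
        for i, pos in enumerate(itertools.combinations(range(n), n2)):
            Z[i, list(pos)] = True
        return Z, True
    if B < 100:
        raise SamError("n_permutations must be >= 100 when sampling")
    U = rng.random((B, n))
    idx = np.argsort(U, axis=1)[:, :n2]
    Z = np.zeros((B, n), dtype=bool)
    np.put_along_axis(Z, idx, True, axis=1)
    return Z, False


def permutation_null(X, y, s0: float, n_permutations: int = 1000,
                     seed: int = 0, exhaustive_if_feasible: bool = True,
                     exhaustive_limit: int = 10_000,
                     chunk_cells: int = 20_000_000,
                     ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Expected order statistics of d under label permutation.

    Returns
    -------
    dbar_expected : (n_valid,) ascending expected d at each rank.
    d_perm_sorted : (B', n_valid) each row one permutation's sorted d.
    exhaustive : bool, whether all arrangements were enumerated.

    Notes
    -----
    Probes invalid under the observed labelling (< 2 values per class) are
    excluded; a probe that degenerates under a particular permutation
    (possible only with missing cells) contributes d = 0 there.
    """
    X = np.asarray(X, dtype=float)
    _, z = _as_two_class(y)
    n = X.shape[0]
    n2 = int(z.sum())
    rng = np.random.default_rng(seed)
    Z, exhaustive = _arrangements(n, n2, n_permutations, rng,
                                  exhaustive_if_feasible, exhaustive_limit)
    _, _, valid = _group_stats(X, z[np.newaxis, :])
    cols = np.flatnonzero(valid[0])
    Xv = X[:, cols]
    m = cols.size
    chunk = max(1, chunk_cells // max(m, 1))
    rows = []
    for b0 in range(0, Z.shape[0], chunk):
        numer, s, v = _group_stats(Xv, Z[b0:b0 + chunk])
        with np.errstate(divide="ignore", invalid="ignore"):
            d = numer / (s + s0)
        d[~v] = 0.0
        d[~np.isfinite(d)] = 0.0
        rows.append(np.sort(d, axis=1))
    d_perm_sorted = np.concatenate(rows, axis=0)
    dbar_expected = d_perm_sorted.mean(axis=0)
    return dbar_expected, d_perm_sorted, exhaustive


# ---------------------------------------------------------------------------
# delta table / selection
# ---------------------------------------------------------------------------

def _cutpoints(d_sorted: np.ndarray, dbar: np.ndarray, delta: float,
               ) -> tuple[float, float]:
    """Asymmetric SAM cutpoints for one delta.

    cut_up is the smallest observed d among ranks whose gap exceeds +delta;
    cut_low the largest observed d among ranks whose gap falls below
    -delta. Probes are called when d >= cut_up or d <= cut_low.
    """
    gap = d_sorted - dbar
    up = d_sorted[gap >= delta]
    low = d_sorted[gap <= -delta]
    cut_up = float(up.min()) if up.size else np.inf
    cut_low = float(low.max()) if low.size else -np.inf
    return cut_low, cut_up


def fdr_table(d, dbar_expected, d_perm_sorted, delta_grid,
              false_stat: str = "mean") -> pd.DataFrame:
    """Delta table: calls, estimated false calls and FDR per delta.

    For each delta, probes beyond the asymmetric cutpoints are called; the
    false-call estimate is the ``false_stat`` (mean / median / q90) over
    permutations of the number of permuted d beyond the same cutpoints;
    FDR = false / called, capped at 1. Rows with 0 called report FDR 0
    with the ``n_called`` column flagging the emptiness.
    """
    delta_grid = np.atleast_1d(np.asarray(delta_grid, dtype=float))
    if delta_grid.size == 0:
        raise SamError("empty delta grid")
    if false_stat not in _FALSE_STATS:
        raise SamError(f"false_stat must be one of {_FALSE_STATS}")
    d = np.asarray(d, dtype=float)
    dv = np.sort(d[np.isfinite(d)])
    rows = []
    for delta in delta_grid:
        cut_low, cut_up = _cutpoints(dv, dbar_expected, delta)
        called = int(((dv >= cut_up) | (dv <= cut_low)).sum())
        counts = ((d_perm_sorted >= cut_up).sum(axis=1)
                  + (d_perm_sorted <= cut_low).sum(axis=1))
        if false_stat == "mean":
            false = float(counts.mean())
        elif false_stat == "median":
            false = float(np.median(counts))
        else:
            false = float(np.percentile(counts, 90))
        fdr = min(1.0, false / called) if called > 0 else 0.0
        rows.append((float(delta), called, false, fdr, cut_low, cut_up))
    return pd.DataFrame(rows, columns=["delta", "n_called", "false_calls",
                                       "fdr", "cut_low", "cut_up"])


def select_fdr_zero(delta_table: pd.DataFrame, d) -> np.ndarray:
    """Probe indices called at the smallest delta with estimated FDR = 0.

    The smallest such delta yields the largest FDR-0 set. Returns an empty
    array (with a log notice) when no delta with at least one call reaches
    FDR 0.
    """
    d = np.asarray(d, dtype=float)
    tab = delta_table[(delta_table["fdr"] == 0.0)
                      & (delta_table["n_called"] > 0)]
    if tab.empty:
        log.info("no delta reaches FDR = 0; empty selection")
        return np.array([], dtype=np.int64)
    row = tab.loc[tab["delta"].idxmin()]
    with np.errstate(invalid="ignore"):
        mask = (d >= row["cut_up"]) | (d <= row["cut_low"])
    mask &= np.isfinite(d)
    return np.flatnonzero(mask)


def top_by_delta_gap(d, gap, k: int) -> np.ndarray:
    """Top-k probe indices ranked by |observed - expected| gap.

    Descending |gap|; ties broken by |d| (descending) then by probe index,
    i.e. genome address, since matrices are kept in grid order. NaN d
    (excluded probes) never rank.
    """
    if k <= 0:
        raise SamError("k must be positive")
    d = np.asarray(d, dtype=float)
    gap = np.asarray(gap, dtype=float)
    ok = np.isfinite(gap) & np.isfinite(d)
    idx = np.flatnonzero(ok)
    if k > idx.size:
        raise SamError(f"k={k} exceeds the {idx.size} rankable probes")
    order = np.lexsort((idx, -np.abs(d[idx]), -np.abs(gap[idx])))
    return idx[order[:k]]


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class SAMTwoClass(BaseEstimator):
    """Two-class unpaired SAM as a scikit-learn style estimator.

    ``fit(X, y)`` computes the observed d statistics, the fudge factor,
    the permutation expected order statistics, the delta/FDR table and the
    FDR-0 selection. ``X`` has samples in rows and probes in columns
    (NaN = missing); ``y`` holds exactly two label values.

    Parameters
    ----------
    n_permutations : int
        Label arrangements to sample when exhaustive enumeration is not
        feasible; must be >= 100.
    s0_mode : {"percentile_cv_min", "fixed"}
        Fudge-factor rule; "fixed" uses ``s0_fixed``.
    false_stat : {"mean", "median", "q90"}
        Aggregation of permuted false-call counts (see module docstring).
    delta_grid : array-like or None
        Deltas for the FDR table; None builds ``n_delta`` evenly spaced
        values spanning [0, max |gap|].
    random_state : int
        Seed for permutation sampling.

    Attributes
    ----------
    d_, s_, gap_, expected_d_ : ndarray (n_probes,)
        Observed statistic, scatter, observed-minus-expected gap at the
        probe's rank, and the expected d at that rank; NaN for probes with
        < 2 values in a class.
    s0_ : float
    dbar_expected_ : ndarray, ascending expected order statistics.
    delta_table_ : DataFrame
    significant_fdr0_ : ndarray of probe indices (FDR = 0 selection).
    n_arrangements_ : int, exhaustive_ : bool
    """

    def __init__(self, n_permutations: int = 1000,
                 s0_mode: str = "percentile_cv_min",
                 s0_fixed: "float | None" = None,
                 exhaustive_if_feasible: bool = True,
                 exhaustive_limit: int = 10_000,
                 false_stat: str = "mean",
                 delta_grid=None, n_delta: int = 64,
                 random_state: int = 0):
        self.n_permutations = n_permutations
        self.s0_mode = s0_mode
        self.s0_fixed = s0_fixed
        self.exhaustive_if_feasible = exhaustive_if_feasible
        self.exhaustive_limit = exhaustive_limit
        self.false_stat = false_stat
        self.delta_grid = delta_grid
        self.n_delta = n_delta
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise SamError("X must be 2-D (n_samples, n_probes)")
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise SamError("y length must match the number of samples")
        self.classes_, z = _as_two_class(y)

        numer, s, valid = _group_stats(X, z[np.newaxis, :])
        numer, s, valid = numer[0], s[0], valid[0]
        n_excluded = int((~valid).sum())
        if n_excluded:
            log.info("SAM: %d probes excluded (<2 values in a class)",
                     n_excluded)
        if self.s0_mode == "fixed":
            if self.s0_fixed is None or self.s0_fixed < 0:
                raise SamError("s0_mode='fixed' needs a non-negative "
                               "s0_fixed")
            self.s0_ = float(self.s0_fixed)
        elif self.s0_mode == "percentile_cv_min":
            self.s0_ = choose_s0(s[valid], numer[valid])
        else:
            raise SamError(f"unknown s0_mode {self.s0_mode!r}")

        d, s = d_statistic(X, y, self.s0_)
        self.d_, self.s_ = d, s
        self.dbar_expected_, d_perm, self.exhaustive_ = permutation_null(
            X, y, self.s0_, n_permutations=self.n_permutations,
            seed=self.random_state,
            exhaustive_if_feasible=self.exhaustive_if_feasible,
            exhaustive_limit=self.exhaustive_limit)
        self.n_arrangements_ = d_perm.shape[0]

        # per-probe expected value and gap at the probe's rank
        ok = np.isfinite(d)
        order = np.argsort(d[ok], kind="stable")
        expected = np.full_like(d, np.nan)
        idx_ok = np.flatnonzero(ok)
        expected[idx_ok[order]] = self.dbar_expected_
        self.expected_d_ = expected
        self.gap_ = d - expected

        if self.delta_grid is not None:
            grid = np.asarray(self.delta_grid, dtype=float)
        else:
            gmax = np.nanmax(np.abs(self.gap_)) if ok.any() else 0.0
            grid = np.linspace(0.0, gmax, self.n_delta)
        self.delta_table_ = fdr_table(d, self.dbar_expected_, d_perm, grid,
                                      false_stat=self.false_stat)
        self.significant_fdr0_ = select_fdr_zero(self.delta_table_, d)
        self.n_features_in_ = X.shape[1]
        return self

    # -- selection helpers -------------------------------------------------
    def top_by_delta_gap(self, k: int = 22) -> np.ndarray:
        """Indices of the k probes with the largest observed-expected gap."""
        return top_by_delta_gap(self.d_, self.gap_, k)

    def get_support(self, indices: bool = False):
        """Boolean mask (or indices) of the FDR = 0 probe selection."""
        if indices:
            return self.significant_fdr0_
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.significant_fdr0_] = True
        return mask

    def results_frame(self, probe_ids=None) -> pd.DataFrame:
        """Per-probe results table (d, scatter, expected d, gap, rank)."""
        d = self.d_
        rank = np.full(d.shape, -1, dtype=int)
        ok = np.isfinite(d)
        rank[np.flatnonzero(ok)[np.argsort(d[ok], kind="stable")]] = (
            np.arange(ok.sum()))
        df = pd.DataFrame({
            "d": d, "s": self.s_, "expected_d": self.expected_d_,
            "gap": self.gap_, "rank": rank,
            "fdr0": self.get_support()})
        if probe_ids is not None:
            df.insert(0, "probe_id", np.asarray(probe_ids))
        return df
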