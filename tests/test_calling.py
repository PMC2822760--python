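"""Robust SD, ternary calling, adjacency screen, CNV masking, sex drop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cghsig import io
from cghsig.calling import (DegenerateSampleWarning, TernaryCaller,
                            apply_cnv_mask, call_matrix,
                            drop_sex_chromosomes, recurrent_adjacent_loci,
                            robust_sd, sample_qc)
from cghsig.grid import ProbeGrid
from cghsig.simulate import ConfigError
from conftest import make_grid


class TestRobustSD:
    def test_constant_vector(self):
        with pytest.warns(DegenerateSampleWarning):
            res = robust_sd(np.ones(100))
        assert res.sd == 0.0
        assert res.center == 1.0
        assert res.n_iter == 1

    def test_clean_gaussian_within_three_percent(self, rng):
        x = rng.normal(1.0, 0.09, size=10_000)
        res = robust_sd(x)
        assert res.sd == pytest.approx(0.09, rel=0.03)
        assert res.center == pytest.approx(1.0, abs=0.005)

    def test_contamination_resistance(self, rng):
        x = rng.normal(1.0, 0.09, size=10_000)
        x[:500] = 0.5                       # 5% outliers
        res = robust_sd(x)
        plain = float(np.std(x, ddof=1))
        # oracle: plain SD of the uncontaminated points
        clean_sd = float(np.std(x[500:], ddof=1))
        assert res.sd == pytest.approx(0.09, rel=0.05)
        assert abs(res.sd - clean_sd) < 0.05 * clean_sd
        assert plain > 1.3 * 0.09           # plain SD is badly inflated
        assert res.n_excluded >= 500

    def test_robust_never_exceeds_plain_sd(self, rng):
        for _ in range(10):
            x = rng.normal(1, 0.1, 300) + rng.choice(
                [0, 1], 300, p=[0.95, 0.05]) * rng.normal(0, 0.5, 300)
            assert robust_sd(x).sd <= np.std(x, ddof=1) + 1e-12

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            robust_sd([1.0, 2.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100),
           seed=st.integers(0, 10))
    def test_scale_equivariant_shift_invariant(self, a, b, seed):
        x = np.random.default_rng(seed).normal(0, 1, 400)
        base = robust_sd(x)
        scaled = robust_sd(a * x + b)
        assert scaled.sd == pytest.approx(a * base.sd, rel=1e-9)
        assert scaled.center == pytest.approx(a * base.center + b,
                                              rel=1e-6, abs=1e-6)

    def test_missing_values_ignored(self, rng):
        x = rng.normal(1, 0.05, 1000)
        x_nan = np.concatenate([x, [np.nan] * 50])
        assert robust_sd(x_nan).sd == robust_sd(x).sd


class TestCallMatrix:
    def test_at_center_no_calls(self):
        fr = np.ones((10, 3))
        calls = call_matrix(fr, center=np.ones(3), sd=np.full(3, 0.1), k=4)
        assert (calls == 0).all()

    def test_single_low_cell_called_loss(self):
        fr = np.ones((10, 3))
        fr[4, 1] = 1 - 5 * 0.1
        calls = call_matrix(fr, np.ones(3), np.full(3, 0.1), k=4)
        assert calls[4, 1] == -1
        assert (np.delete(calls.ravel(), 4 * 3 + 1) == 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_elementwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fr = rng.normal(1, 0.2, size=(50, 8))
        fr[rng.random(fr.shape) < 0.05] = np.nan
        center = rng.normal(1, 0.01, 8)
        sd = rng.uniform(0.05, 0.2, 8)
        calls = call_matrix(fr, center, sd, k=4)
        for i in range(50):                 # brute-force per-cell oracle
            for j in range(8):
                v = fr[i, j]
                if np.isnan(v):
                    want = 0
                elif v > center[j] + 4 * sd[j]:
                    want = 1
                elif v < center[j] - 4 * sd[j]:
                    want = -1
                else:
                    want = 0
                assert calls[i, j] == want

    def test_zero_sd_sample_all_zero_with_warning(self):
        fr = np.full((5, 2), 2.0)
        with pytest.warns(DegenerateSampleWarning):
            calls = call_matrix(fr, np.array([1.0, 1.0]),
                                np.array([0.1, 0.0]), k=4)
        assert (calls[:, 1] == 0).all()
        assert (calls[:, 0] == 1).all()

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ConfigError):
            call_matrix(np.ones((2, 2)), np.ones(2), np.ones(2), k=0)


class TestTernaryCaller:
    def test_sklearn_protocol(self, rng):
        from sklearn.base import clone
        X = rng.normal(1, 0.1, size=(6, 500))
        est = TernaryCaller(k=3.5)
        assert clone(est).get_params()["k"] == 3.5
        calls = est.fit(X).transform(X)
        assert calls.shape == X.shape
        assert est.sd_.shape == (6,)
        assert set(np.unique(calls)) <= {-1, 0, 1}

    def test_fit_estimates_per_sample_noise(self, rng):
        sds = np.array([0.06, 0.12, 0.18])
        X = rng.normal(1, 1, size=(3, 20_000)) * sds[:, None] + 1
        est = TernaryCaller().fit(X)
        assert est.sd_ == pytest.approx(sds, rel=0.05)


def oracle_loci(calls, grid, min_adjacent, min_samples, sample_ids):
    """Independent re-derivation: python-loop run scan + per-pair support."""
    chroms = grid.df["chrom"].tolist()
    n_probes, n_samples = calls.shape
    support: dict[tuple[int, int], set] = {}
    for j in range(n_samples):
        i = 0
        while i < n_probes:
            d = calls[i, j]
            if d == 0:
                i += 1
                continue
            run = [i]
            while (run[-1] + 1 < n_probes
                   and chroms[run[-1] + 1] == chroms[i]
                   and calls[run[-1] + 1, j] == d):
                run.append(run[-1] + 1)
            if len(run) >= min_adjacent:
                for a in run[:-1]:
                    support.setdefault((a, d), set()).add(sample_ids[j])
            i = run[-1] + 1
    kept = {pair: s for pair, s in support.items()
            if len(s) >= min_samples}
    # merge consecutive kept pairs per direction
    loci = set()
    for d in (-1, 1):
        pairs = sorted(a for (a, dd) in kept if dd == d)
        group: list[int] = []
        for a in pairs + [None]:
            if group and (a is None or a != group[-1] + 1
                          or chroms[a] != chroms[group[-1]]):
                samples = frozenset().union(
                    *(kept[(g, d)] for g in group))
                loci.add((chroms[group[0]], group[0], group[-1] + 1, d,
                          samples))
                group = []
            if a is not None:
                group.append(a)
    return loci


def as_comparable(locus_set):
    return {(l.chrom, l.first_probe, l.last_probe, l.direction,
             frozenset(l.samples)) for l in locus_set.loci}


class TestRecurrentAdjacentLoci:
    def test_isolated_single_probe_call_yields_nothing(self, two_chrom_grid):
        calls = np.zeros((len(two_chrom_grid), 4), dtype=int)
        calls[5, 0] = -1
        loci = recurrent_adjacent_loci(calls, two_chrom_grid)
        assert len(loci) == 0

    def test_pair_in_three_samples_is_one_locus(self, two_chrom_grid):
        calls = np.zeros((len(two_chrom_grid), 4), dtype=int)
        calls[[7, 8], :3] = -1
        loci = recurrent_adjacent_loci(calls, two_chrom_grid,
                                       sample_ids=list("abcd"))
        assert len(loci) == 1
        locus = loci.loci[0]
        assert (locus.first_probe, locus.last_probe) == (7, 8)
        assert locus.direction == -1
        assert locus.samples == ("a", "b", "c")

    def test_two_samples_insufficient(self, two_chrom_grid):
        calls = np.zeros((len(two_chrom_grid), 4), dtype=int)
        calls[[7, 8], :2] = -1
        assert len(recurrent_adjacent_loci(calls, two_chrom_grid)) == 0

    def test_runs_do_not_span_chromosomes(self):
        grid = make_grid({"c1": 260, "c2": 260})   # 2 + 2 probes
        calls = np.full((4, 3), -1, dtype=int)
        loci = recurrent_adjacent_loci(calls, grid)
        spans = {(l.chrom, l.first_probe, l.last_probe) for l in loci.loci}
        assert spans == {("c1", 0, 1), ("c2", 2, 3)}

    def test_min_adjacent_below_two_rejected(self, two_chrom_grid):
        calls = np.zeros((len(two_chrom_grid), 3), dtype=int)
        with pytest.raises(ConfigError):
            recurrent_adjacent_loci(calls, two_chrom_grid, min_adjacent=1)

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("min_adjacent", [2, 3])
    def test_matches_bruteforce_enumeration(self, seed, min_adjacent):
        rng = np.random.default_rng(seed)
        grid = make_grid({"c1": 4060, "c2": 2060, "c3": 1060})
        ids = [f"s{j}" for j in range(10)]
        calls = rng.choice([-1, 0, 0, 0, 1], size=(len(grid), 10))
        got = recurrent_adjacent_loci(calls, grid,
                                      min_adjacent=min_adjacent,
                                      min_samples=3, sample_ids=ids)
        want = oracle_loci(calls, grid, min_adjacent, 3, ids)
        assert as_comparable(got) == want

    def test_invariant_to_sample_column_order(self, rng, two_chrom_grid):
        calls = rng.choice([-1, 0, 0, 1], size=(len(two_chrom_grid), 8))
        ids = [f"s{j}" for j in range(8)]
        perm = rng.permutation(8)
        a = recurrent_adjacent_loci(calls, two_chrom_grid, sample_ids=ids)
        b = recurrent_adjacent_loci(calls[:, perm], two_chrom_grid,
                                    sample_ids=[ids[p] for p in perm])
        assert as_comparable(a) == as_comparable(b)

    def test_other_chromosome_shuffle_leaves_loci_unchanged(self, rng):
        grid = make_grid({"c1": 2060, "c2": 2060})
        calls = rng.choice([-1, 0, 0, 1], size=(len(grid), 6))
        bounds = grid.chrom_bounds()
        lo, hi = bounds["c2"]
        shuffled = calls.copy()
        shuffled[lo:hi] = shuffled[rng.permutation(np.arange(lo, hi))]
        a = [l for l in recurrent_adjacent_loci(calls, grid).loci
             if l.chrom == "c1"]
        b = [l for l in recurrent_adjacent_loci(shuffled, grid).loci
             if l.chrom == "c1"]
        assert a == b


class TestApplyCNVMask:
    def test_empty_mask_identity(self, rng, two_chrom_grid):
        calls = rng.choice([-1, 0, 1], size=(len(two_chrom_grid), 6))
        loci = recurrent_adjacent_loci(calls, two_chrom_grid, min_samples=2)
        masked = apply_cnv_mask(loci, io.CNVMask.from_intervals([]),
                                two_chrom_grid)
        assert masked.loci == loci.loci

    def test_locus_inside_mask_removed(self, two_chrom_grid):
        calls = np.zeros((len(two_chrom_grid), 4), dtype=int)
        calls[[3, 4], :3] = -1
        loci = recurrent_adjacent_loci(calls, two_chrom_grid)
        footprint = loci.loci[0]
        mask = io.CNVMask.from_intervals(
            [("chr1", footprint.start - 10, footprint.end + 10)])
        assert len(apply_cnv_mask(loci, mask, two_chrom_grid)) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_per_bp_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = make_grid({"c1": 3060, "c2": 2060})
        calls = rng.choice([-1, 0, 0, 1], size=(len(grid), 8))
        loci = recurrent_adjacent_loci(calls, grid, min_samples=2)
        intervals = [("c1" if rng.random() < 0.5 else "c2",
                      int(s), int(s) + int(rng.integers(20, 400)))
                     for s in rng.integers(0, 2800, size=12)]
        mask = io.CNVMask.from_intervals(intervals)
        got = apply_cnv_mask(loci, mask, grid)
        covered = {c: np.zeros(4000, dtype=bool) for c in ("c1", "c2")}
        for c, s, e in intervals:
            covered[c][s:min(e, 4000)] = True
        want = [l for l in loci.loci if not covered[l.chrom][l.start:l.end].any()]
        assert list(got.loci) == want


class TestDropSexChromosomes:
    def test_no_sex_probes_unchanged(self, two_chrom_grid, rng):
        fr = pd.DataFrame(rng.normal(1, 0.1, (len(two_chrom_grid), 3)),
                          index=two_chrom_grid.probe_ids,
                          columns=list("abc"))
        fr2, grid2 = drop_sex_chromosomes(fr, two_chrom_grid)
        assert grid2 is two_chrom_grid and fr2 is fr

    def test_sex_probes_removed_values_aligned(self, rng):
        grid = make_grid({"chr1": 9060, "chrX": 1060})
        assert len(grid) == 100
        fr = pd.DataFrame(rng.normal(1, 0.1, (100, 4)),
                          index=grid.probe_ids, columns=list("abcd"))
        fr2, grid2 = drop_sex_chromosomes(fr, grid)
        assert len(grid2) == 90
        assert set(grid2.df["chrom"]) == {"chr1"}
        for pid in grid2.probe_ids:        # dictionary-lookup oracle
            assert (fr2.loc[pid] == fr.loc[pid]).all()


def test_sample_qc_frame_shape(rng):
    fr = pd.DataFrame(rng.normal(1, 0.1, (500, 3)), columns=list("abc"))
    qc = sample_qc(fr)
    assert list(qc.columns) == ["robust_sd", "center", "n_iter",
                                "n_excluded"]
    assert (qc["robust_sd"] > 0).all()


def test_planted_deletion_recovered_by_screen():
    """10-probe heterozygous deletion planted in 8/12 samples at SD 0.09 is
    found by the +-4 SD two-adjacent-probe screen in >= 9/10 seeds."""
    grid = make_grid({"c1": 20_060})       # 200 probes
    hits = 0
    planted_pairs = set(range(50, 59))     # pairs within probes 50..59
    for seed in range(10):
        rng = np.random.default_rng(seed)
        fr = rng.normal(1.0, 0.09, size=(200, 12))
        fr[50:60, :8] -= 0.5
        center = np.full(12, 1.0)
        sd = np.full(12, 0.09)
        calls = call_matrix(fr, center, sd, k=4)
        loci = recurrent_adjacent_loci(calls, grid, min_samples=3)
        found = set()
        for l in loci.loci:
            if l.direction == -1:
                found.update(range(l.first_probe, l.last_probe))
        if planted_pairs <= found:
            hits += 1
    assert hits >= 9
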