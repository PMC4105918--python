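"""Population-genetic statistics: allele stats, the exact HWE test, the
LD permutation test, B-Y threshold, Weir-Cockerham theta, Nei distance
and PCoA — each checked against hand computations or an independent
oracle."""

import math

import numpy as np
import pytest
from scipy import stats

from snppanel import popgen
from snppanel.datatypes import MISSING, DistanceMatrix

from conftest import toy_dataset


class TestAlleleStats:
    def test_hand_counted_frequencies(self):
        ds = toy_dataset([[0], [0], [1]], pops=["P1"] * 3)
        f = popgen.allele_stats(ds)
        assert f.p[0, 0] == pytest.approx(1 / 6)
        assert f.ho[0, 0] == pytest.approx(1 / 3)
        assert f.he[0, 0] == pytest.approx(2 * (1 / 6) * (5 / 6))

    def test_all_homozygous_population(self):
        ds = toy_dataset([[0], [0], [2], [2]], pops=["P1"] * 4)
        f = popgen.allele_stats(ds)
        assert f.p[0, 0] == pytest.approx(0.5)
        assert f.ho[0, 0] == 0.0

    def test_missing_cell_flagged(self):
        ds = toy_dataset([[0, MISSING], [1, MISSING], [2, 1], [0, 1]],
                         pops=["P1", "P1", "P2", "P2"])
        f = popgen.allele_stats(ds)
        assert ("P1", "L2") in f.missing_cells
        assert np.isnan(f.p[0, 1])

    def test_binomial_sampling_recovery(self):
        # p-hat within 3 SE of the generating p for nearly all cells
        rng = np.random.default_rng(1)
        p_true = rng.uniform(0.1, 0.9, 50)
        n = 200
        calls = rng.binomial(2, p_true, size=(n, 50)).astype(np.int8)
        ds = toy_dataset(calls, pops=["P1"] * n)
        f = popgen.allele_stats(ds)
        se = np.sqrt(p_true * (1 - p_true) / (2 * n))
        frac_ok = np.mean(np.abs(f.p[0] - p_true) <= 3 * se)
        assert frac_ok >= 0.95


class TestHweExact:
    def test_hand_enumerated_case(self):
        # one AA and one aa: conditional on 2 A and 2 a alleles in 2
        # diploids, P(het=0)=1/3, P(het=2)=2/3; observed het=0 -> p=1/3
        assert popgen.hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)

    def test_monomorphic_returns_one(self):
        assert popgen.hwe_exact_test(5, 0, 0) == 1.0
        assert popgen.hwe_exact_test(0, 0, 7) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            popgen.hwe_exact_test(-1, 2, 3)

    def test_against_monte_carlo_oracle(self):
        # MC oracle: resample heterozygote counts from the exact
        # conditional distribution by gamete shuffling
        rng = np.random.default_rng(7)
        for _ in range(8):
            n = int(rng.integers(5, 50))
            na = int(rng.integers(1, 2 * n))
            gametes = np.array([1] * na + [0] * (2 * n - na))
            draws = 100_000
            hets = np.empty(draws, dtype=int)
            for d in range(draws):
                rng.shuffle(gametes)
                hets[d] = np.sum(gametes[::2] != gametes[1::2])
            # observed table: modal het count for a well-covered case
            h_obs = int(np.bincount(hets).argmax())
            if (na - h_obs) % 2:
                h_obs += 1
            naa = (na - h_obs) // 2
            nbb = n - naa - h_obs
            p_exact = popgen.hwe_exact_test(naa, h_obs, nbb)
            # MC p: prob of counts at most as probable as observed
            probs = np.bincount(hets, minlength=2 * n + 1) / draws
            mask = probs <= probs[h_obs] + 1e-9
            p_mc = probs[mask].sum()
            se = math.sqrt(p_mc * (1 - p_mc) / draws) + 1e-4
            assert abs(p_exact - p_mc) <= 4 * se

    def test_super_uniform_under_hwe(self):
        # type-I error at alpha=0.05 must not exceed nominal
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 4000
        for _ in range(reps):
            p = rng.uniform(0.2, 0.8)
            g = rng.binomial(2, p, size=30)
            pv = popgen.hwe_exact_test(
                int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum())
            )
            rejections += pv < 0.05
        rate = rejections / reps
        assert rate <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / reps)


class TestLdPermutation:
    def test_perfect_association(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, 30)
        calls = np.column_stack([a, a])
        ds = toy_dataset(calls, pops=["P1"] * 30)
        p = popgen.ld_permutation_test(ds, "L1", "L2", "P1", n_perm=999, seed=1)
        assert p <= 0.01

    def test_constant_locus_gives_one(self):
        rng = np.random.default_rng(5)
        calls = np.column_stack([np.ones(20, dtype=int), rng.integers(0, 3, 20)])
        ds = toy_dataset(calls, pops=["P1"] * 20)
        assert popgen.ld_permutation_test(ds, "L1", "L2", "P1", n_perm=999, seed=1) == 1.0

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(300):
            calls = rng.binomial(2, 0.5, size=(25, 2)).astype(np.int8)
            ds = toy_dataset(calls, pops=["P1"] * 25)
            pvals.append(
                popgen.ld_permutation_test(ds, "L1", "L2", "P1", n_perm=199, seed=rng)
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestByFdr:
    def test_values(self):
        assert popgen.by_fdr_alpha(0.05, 1) == 0.05
        assert popgen.by_fdr_alpha(0.05, 3) == pytest.approx(0.05 / (1 + 0.5 + 1 / 3))

    def test_paper_scale_threshold(self):
        assert round(popgen.by_fdr_alpha(0.05, 27_260), 4) == 0.0046

    def test_strictly_decreasing_in_m(self):
        vals = [popgen.by_fdr_alpha(0.05, m) for m in range(1, 200)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            popgen.by_fdr_alpha(0.05, 0)


def _wc_theta_literal(counts_by_pop):
    """Independent literal transcription of the 1984 variance components
    for one biallelic locus; counts_by_pop: list of (nAA, nAa, naa)."""
    r = len(counts_by_pop)
    n = [sum(c) for c in counts_by_pop]
    p = [(2 * c[0] + c[1]) / (2 * ni) for c, ni in zip(counts_by_pop, n)]
    h = [c[1] / ni for c, ni in zip(counts_by_pop, n)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


class TestWcTheta:
    def test_fixed_difference_gives_one(self):
        calls = np.array([[0]] * 10 + [[2]] * 10)
        ds = toy_dataset(calls, pops=["P1"] * 10 + ["P2"] * 10)
        res = popgen.wc_theta(ds)
        assert res.theta_locus[0] == pytest.approx(1.0)

    def test_null_simulation_centers_on_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.2, 0.8, 100)
        calls = rng.binomial(2, p, size=(1000, 100)).astype(np.int8)
        ds = toy_dataset(calls, pops=["P1"] * 500 + ["P2"] * 500)
        res = popgen.wc_theta(ds)
        assert abs(res.theta_multilocus) < 0.005

    def test_matches_literal_formula_transcription(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            counts = [tuple(rng.integers(1, 10, 3)) for _ in range(3)]
            calls, pops = [], []
            for k, (naa2, nab, nbb) in enumerate(counts):
                for g, cnt in ((2, naa2), (1, nab), (0, nbb)):
                    calls += [[g]] * cnt
                    pops += [f"P{k}"] * cnt
            ds = toy_dataset(np.array(calls), pops=pops)
            res = popgen.wc_theta(ds)
            assert res.theta_locus[0] == pytest.approx(
                _wc_theta_literal(counts), abs=1e-10
            )

    def test_monomorphic_locus_excluded(self):
        calls = np.column_stack(
            [np.zeros(20, dtype=int), np.repeat([0, 2], 10)]
        )
        ds = toy_dataset(calls, pops=["P1"] * 10 + ["P2"] * 10)
        res = popgen.wc_theta(ds)
        assert res.excluded_loci == ["L1"]
        assert np.isnan(res.theta_locus[0])

    def test_duplicating_everyone_barely_moves_theta(self):
        # consistency in the n -> infinity direction: the finite-sample
        # corrections scale as 1/n, so at a few hundred individuals per
        # population doubling everyone moves multilocus theta by < 1e-3
        from snppanel.simulate import (
            SimulationConfig,
            simulate_environment,
            simulate_genotypes,
        )

        cfg = SimulationConfig(
            n_regions=2, pops_per_region=2, inds_per_pop=300, n_loci=50,
            n_candidates=0, missing_rate=0.0, seed=8,
        )
        ds, _ = simulate_genotypes(cfg, simulate_environment(cfg))
        res1 = popgen.wc_theta(ds)
        doubled = ds.subset_individuals(np.repeat(np.arange(ds.n_individuals), 2))
        res2 = popgen.wc_theta(doubled)
        assert abs(res1.theta_multilocus - res2.theta_multilocus) < 1e-3


class TestNeiDistance:
    def _freqs(self, pmat, pops):
        from snppanel.popgen import PopulationFrequencies

        p = np.asarray(pmat, float)
        return PopulationFrequencies(
            populations=pops,
            locus_ids=[f"L{j}" for j in range(p.shape[1])],
            p=p,
            ho=np.zeros_like(p),
            he=2 * p * (1 - p),
            n=np.full(p.shape, 10),
            panel_maf=p.mean(axis=0),
        )

    def test_identical_frequencies_give_zero(self):
        f = self._freqs([[0.3, 0.7], [0.3, 0.7]], ["A", "B"])
        d = popgen.nei_distance(f)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_single_locus(self):
        f = self._freqs([[0.9], [0.1]], ["A", "B"])
        d = popgen.nei_distance(f)
        assert d.values[0, 1] == pytest.approx(-math.log(0.18 / 0.82), abs=1e-4)

    def test_monotone_in_frequency_separation(self):
        base = 0.5
        last = -1.0
        for delta in (0.05, 0.15, 0.25, 0.35, 0.45):
            f = self._freqs([[base - delta], [base + delta]], ["A", "B"])
            d = popgen.nei_distance(f).values[0, 1]
            assert d > last
            last = d

    def test_symmetry_and_zero_diagonal_random(self):
        rng = np.random.default_rng(4)
        f = self._freqs(rng.uniform(0.05, 0.95, (5, 30)), [f"P{i}" for i in range(5)])
        d = popgen.nei_distance(f)
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)


class TestPcoa:
    def test_collinear_points_recovered_on_axis_one(self):
        pos = np.array([0.0, 1.0, 3.0])
        d = np.abs(pos[:, None] - pos[None, :])
        res = popgen.pcoa(DistanceMatrix(["a", "b", "c"], d), n_axes=1)
        rec = res.coordinates[:, 0]
        rec = rec - rec[0]
        if rec[-1] < 0:
            rec = -rec
        np.testing.assert_allclose(rec, pos, atol=1e-9)
        assert res.pct_variance[0] == pytest.approx(100.0)

    def test_planted_2d_configuration_procrustes(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = popgen.pcoa(DistanceMatrix([f"p{i}" for i in range(12)], d), n_axes=2)
        x = res.coordinates - res.coordinates.mean(axis=0)
        y = pts - pts.mean(axis=0)
        u, _, vt = np.linalg.svd(x.T @ y)
        rot = u @ vt
        assert np.sqrt(np.mean((x @ rot - y) ** 2)) < 1e-8

    def test_equidistant_simplex_has_equal_eigenvalues(self):
        d = np.ones((4, 4)) - np.eye(4)
        res = popgen.pcoa(DistanceMatrix(list("abcd"), d), n_axes=3)
        assert np.allclose(res.eigenvalues, res.eigenvalues[0])

    def test_axes_truncated_with_warning(self):
        pos = np.array([0.0, 1.0, 3.0])
        d = np.abs(pos[:, None] - pos[None, :])
        with pytest.warns(UserWarning, match="positive"):
            popgen.pcoa(DistanceMatrix(["a", "b", "c"], d), n_axes=3)

    def test_against_skbio(self, small_dataset):
        skbio = pytest.importorskip("skbio")
        dm = popgen.pairwise_theta_distance(small_dataset)
        res = popgen.pcoa(dm, n_axes=3)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, ids=dm.labels)
        )
        ref_coords = ref.samples.to_numpy()[:, :3]
        for j in range(3):
            r = np.corrcoef(res.coordinates[:, j], ref_coords[:, j])[0, 1]
            assert abs(r) > 1 - 1e-6
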