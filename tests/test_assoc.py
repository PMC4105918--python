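"""Seasonal aggregation, the univariate frequency-environment scan with
its exclusion-robustness rerun, Mantel tests and environmental
distances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snppanel import assoc
from snppanel.datatypes import MONTHS, DistanceMatrix, EnvironmentTable
from snppanel.popgen import PopulationFrequencies


def flat_env(n_pops=6, precip=10.0, tmax_by_month=None):
    data = {"population": [f"P{i}" for i in range(n_pops)],
            "latitude": np.linspace(45, 47, n_pops),
            "longitude": np.linspace(-123, -120, n_pops),
            "elevation": np.linspace(100, 900, n_pops),
            "migration_distance": np.linspace(10, 500, n_pops)}
    for k, m in enumerate(MONTHS):
        t = tmax_by_month[k] if tmax_by_month is not None else 15.0
        data[f"tmax_{m}"] = np.full(n_pops, float(t))
        data[f"tmin_{m}"] = np.full(n_pops, float(t) - 10)
        data[f"precip_{m}"] = np.full(n_pops, precip)
    return EnvironmentTable(pd.DataFrame(data))


def freqs_from(pmat, pops):
    p = np.asarray(pmat, float)
    return PopulationFrequencies(
        populations=list(pops),
        locus_ids=[f"L{j}" for j in range(p.shape[1])],
        p=p, ho=np.zeros_like(p), he=2 * p * (1 - p),
        n=np.full(p.shape, 20), panel_maf=np.minimum(p.mean(0), 1 - p.mean(0)),
    )


class TestSeasonalAggregate:
    def test_constant_precip_sums(self):
        env = assoc.seasonal_aggregate(flat_env(precip=10.0))
        assert (env.table["precip_spring"] == 30.0).all()
        assert (env.table["precip_annual"] == 120.0).all()

    def test_summer_tmax_mean(self):
        env = assoc.seasonal_aggregate(flat_env(tmax_by_month=list(range(1, 13))))
        assert (env.table["tmax_summer"] == 8.0).all()  # mean of Jul-Sep = (7+8+9)/3

    def test_seasonal_precip_conserves_annual(self, small_env):
        t = small_env.table
        seasonal = t[[f"precip_{s}" for s in ("winter", "spring", "summer", "fall")]]
        np.testing.assert_allclose(seasonal.sum(axis=1), t["precip_annual"], rtol=1e-12)


class TestUnivariateScan:
    def test_exact_linear_relationship_flagged(self):
        n = 20
        x = np.linspace(0, 1, n)
        env = assoc.seasonal_aggregate(flat_env(n_pops=n))
        env.table["elevation"] = 100 + 800 * x
        f = freqs_from(np.column_stack([0.2 + 0.5 * x]), env.populations)
        res = assoc.univariate_scan(f, env, variables=["elevation"])
        assert res.p[0, 0] < 1e-12
        assert res.significant[0, 0]

    def test_constant_frequency_not_flagged(self):
        env = assoc.seasonal_aggregate(flat_env(n_pops=10))
        f = freqs_from(np.full((10, 1), 0.4), env.populations)
        res = assoc.univariate_scan(f, env, variables=["elevation"])
        assert res.slope[0, 0] == 0.0
        assert not res.significant[0, 0]

    def test_zero_variance_variable_skipped(self):
        env = assoc.seasonal_aggregate(flat_env(n_pops=8))
        f = freqs_from(np.random.default_rng(0).uniform(0.2, 0.8, (8, 2)), env.populations)
        with pytest.warns(UserWarning, match="zero variance"):
            res = assoc.univariate_scan(f, env, variables=["tmax_annual", "elevation"])
        assert res.variables == ["elevation"]

    def test_permuted_variable_false_positive_rates(self):
        # pre-correction rate ~ alpha; post-Bonferroni familywise <= alpha
        rng = np.random.default_rng(12)
        n_pops, n_loci, reps = 20, 60, 50
        env = assoc.seasonal_aggregate(flat_env(n_pops=n_pops))
        raw_hits, fw_hits, total = 0, 0, 0
        for _ in range(reps):
            env.table["elevation"] = rng.permutation(env.table["elevation"].to_numpy())
            f = freqs_from(rng.uniform(0.2, 0.8, (n_pops, n_loci)), env.populations)
            res = assoc.univariate_scan(f, env, variables=["elevation"])
            raw_hits += (res.p < 0.05).sum()
            fw_hits += res.significant.any()
            total += n_loci
        raw_rate = raw_hits / total
        assert 0.02 < raw_rate < 0.09
        assert fw_hits / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)


class TestRobustnessExclusion:
    def _setup(self, cline_in_excluded_only):
        rng = np.random.default_rng(3)
        n = 24
        env = assoc.seasonal_aggregate(flat_env(n_pops=n))
        x = env.variable("elevation").to_numpy()
        x = (x - x.mean()) / x.std()
        p = np.full(n, 0.5) + rng.normal(0, 0.01, n)
        excluded = [f"P{i}" for i in range(16, 24)]
        if cline_in_excluded_only:
            # association driven entirely by the excluded group
            p[16:] += 0.35 * (x[16:] - x[16:].mean()) / max(1e-9, x[16:].std())
            p[16:] += 0.25  # group offset, Clearwater-style
        else:
            p += 0.2 * x
        f = freqs_from(np.clip(p, 0.01, 0.99)[:, None], env.populations)
        return f, env, excluded

    def test_confined_association_not_robust(self):
        f, env, excl = self._setup(cline_in_excluded_only=True)
        res = assoc.robustness_exclusion(f, env, ["elevation"], exclude_populations=excl)
        assert res.significant[0, 0]
        assert not res.robust[0, 0]

    def test_global_cline_is_robust(self):
        f, env, excl = self._setup(cline_in_excluded_only=False)
        res = assoc.robustness_exclusion(f, env, ["elevation"], exclude_populations=excl)
        assert res.significant[0, 0]
        assert res.robust[0, 0]

    def test_empty_exclusion_is_identity(self):
        f, env, _ = self._setup(False)
        res = assoc.robustness_exclusion(f, env, ["elevation"], exclude_populations=[])
        np.testing.assert_array_equal(res.robust, res.significant)

    def test_exclusion_must_be_strict_subset(self):
        f, env, _ = self._setup(False)
        with pytest.raises(ValueError):
            assoc.robustness_exclusion(
                f, env, ["elevation"], exclude_populations=list(f.populations)
            )


class TestMantel:
    def test_proportional_matrices_give_r_one(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d1 = DistanceMatrix([f"p{i}" for i in range(8)], d)
        d2 = DistanceMatrix([f"p{i}" for i in range(8)], 2 * d)
        r, p = assoc.mantel(d1, d2, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_exact_enumeration_on_four_labels(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(1, 5, (4, 4)); a = np.triu(a, 1); a = a + a.T
        b = rng.uniform(1, 5, (4, 4)); b = np.triu(b, 1); b = b + b.T
        d1 = DistanceMatrix(list("wxyz"), a)
        d2 = DistanceMatrix(list("wxyz"), b)
        iu = np.triu_indices(4, 1)

        def corr(m):
            x, y = a[iu], m[iu]
            return np.corrcoef(x, y)[0, 1]

        r_obs = corr(b)
        count = sum(
            corr(b[np.ix_(perm, perm)]) >= r_obs - 1e-12
            for perm in itertools.permutations(range(4))
        )
        exact_p = count / 24
        r, p = assoc.mantel(d1, d2, n_perm=9999, seed=3)
        assert r == pytest.approx(r_obs)
        assert p == pytest.approx(exact_p, abs=0.02)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(200):
            pts1 = rng.normal(size=(7, 2)); pts2 = rng.normal(size=(7, 2))
            d1 = np.linalg.norm(pts1[:, None] - pts1[None, :], axis=2)
            d2 = np.linalg.norm(pts2[:, None] - pts2[None, :], axis=2)
            labels = [f"p{i}" for i in range(7)]
            _, p = assoc.mantel(DistanceMatrix(labels, d1), DistanceMatrix(labels, d2),
                                n_perm=199, seed=rng)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_matrix_rejected(self):
        labels = list("abc")
        d1 = DistanceMatrix(labels, np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValueError, match="constant"):
            assoc.mantel(d1, d1, n_perm=9)


class TestIsolationByDistance:
    def _theta_matrix(self, pmat, n_ind=40, seed=0):
        rng = np.random.default_rng(seed)
        from snppanel.popgen import pairwise_theta_distance
        from conftest import toy_dataset

        pops, calls = [], []
        for i, p in enumerate(pmat):
            calls.append(rng.binomial(2, p, size=(n_ind, len(p))))
            pops += [f"P{i:02d}"] * n_ind
        ds = toy_dataset(np.vstack(calls).astype(np.int8), pops=pops)
        return pairwise_theta_distance(ds)

    def test_stepping_stone_shows_ibd_island_does_not(self):
        # frequencies drifting as a spatial random walk produce a
        # positive Mantel correlation with line distance; exchangeable
        # island-model drift at the same scale does not
        rng = np.random.default_rng(42)
        n_pops, n_loci = 15, 80
        positions = np.arange(n_pops, dtype=float)
        geo = DistanceMatrix(
            [f"P{i:02d}" for i in range(n_pops)],
            np.abs(positions[:, None] - positions[None, :]),
        )
        # stepping stone: random walk along the line
        p = np.full(n_loci, 0.5)
        stepping = []
        for _ in range(n_pops):
            p = np.clip(p + rng.normal(0, 0.035, n_loci), 0.02, 0.98)
            stepping.append(p.copy())
        dm_ss = self._theta_matrix(stepping, seed=1)
        r_ss, p_ss = assoc.mantel(dm_ss, geo, n_perm=999, seed=2)
        assert r_ss > 0 and p_ss < 0.01
        # island model: independent drift around a common ancestor
        island = [
            np.clip(0.5 + rng.normal(0, 0.07, n_loci), 0.02, 0.98)
            for _ in range(n_pops)
        ]
        dm_is = self._theta_matrix(island, seed=3)
        _, p_is = assoc.mantel(dm_is, geo, n_perm=999, seed=4)
        assert p_is > 0.05


class TestEnvDistance:
    def test_hand_values(self):
        env = assoc.seasonal_aggregate(flat_env(n_pops=3))
        env.table["elevation"] = [0.0, 1.0, 3.0]
        d = assoc.env_distance(env, "elevation")
        assert sorted(d.condensed()) == [1.0, 2.0, 3.0]
        assert d.kind == "env_abs_diff"

    def test_constant_variable_zero_matrix(self):
        env = assoc.seasonal_aggregate(flat_env(n_pops=4))
        env.table["elevation"] = 5.0
        d = assoc.env_distance(env, "elevation")
        assert np.all(d.values == 0)

    def test_triangle_inequality(self, small_env):
        d = assoc.env_distance(small_env, "precip_summer").values
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9
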