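"""Environmental association: seasonal climate variables, univariate
MAF-on-environment regression with Bonferroni adjustment and a
group-exclusion robustness rerun, Mantel tests and environmental distance
matrices.

Frequencies entering the regressions are of the panel-minor allele,
unfolded, so that cline direction is preserved across populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DistanceMatrix, EnvironmentTable
from .popgen import PopulationFrequencies

SEASONS = {
    "winter": ["01", "02", "03"],
    "spring": ["04", "05", "06"],
    "summer": ["07", "08", "09"],
    "fall": ["10", "11", "12"],
}

#: the five physical variables of the climate-ranking and association work
DEFAULT_VARIABLES = [
    "tmax_winter", "tmax_spring", "tmax_summer", "tmax_fall", "tmax_annual",
    "tmin_winter", "tmin_spring", "tmin_summer", "tmin_fall", "tmin_annual",
    "precip_winter", "precip_spring", "precip_summer", "precip_fall", "precip_annual",
    "elevation", "latitude", "longitude", "migration_distance",
]

VARIABLE_SETS = {
    "temperature": [v for v in DEFAULT_VARIABLES if v.startswith(("tmax", "tmin"))],
    "precipitation": [v for v in DEFAULT_VARIABLES if v.startswith("precip")],
    "geography": ["elevation", "latitude", "longitude", "migration_distance"],
}


def seasonal_aggregate(env: EnvironmentTable) -> EnvironmentTable:
    """Add seasonal and annual climate fields.

    Seasonal temperature is the mean of the season's monthly means;
    seasonal precipitation is the sum of the season's monthly totals
    (winter Jan–Mar, spring Apr–Jun, summer Jul–Sep, fall Oct–Dec).
    Annual temperature is the mean of all twelve months, annual
    precipitation their sum.
    """
    df = env.table.copy()
    for kind in ("tmax", "tmin"):
        monthly = env.monthly(kind)
        for season, months in SEASONS.items():
            df[f"{kind}_{season}"] = monthly[[f"{kind}_{m}" for m in months]].mean(axis=1)
        df[f"{kind}_annual"] = monthly.mean(axis=1)
    monthly = env.monthly("precip")
    for season, months in SEASONS.items():
        df[f"precip_{season}"] = monthly[[f"precip_{m}" for m in months]].sum(axis=1)
    df["precip_annual"] = monthly.sum(axis=1)
    return EnvironmentTable(df)


@dataclass
class AssociationResult:
    """Per locus x variable slope, r-squared and slope p-value, with
    significance at the Bonferroni-adjusted threshold and (after an
    exclusion rerun) a robustness flag."""

    locus_ids: list[str]
    variables: list[str]
    slope: np.ndarray  # (n_loci, n_vars)
    r2: np.ndarray
    p: np.ndarray
    adjusted_alpha: float
    significant: np.ndarray  # bool (n_loci, n_vars)
    robust: np.ndarray | None = None  # set by robustness_exclusion

    def significant_loci(self, require_robust: bool = False) -> list[str]:
        flags = self.robust if (require_robust and self.robust is not None) else self.significant
        return [l for j, l in enumerate(self.locus_ids) if flags[j].any()]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for j, locus in enumerate(self.locus_ids):
            for k, var in enumerate(self.variables):
                recs.append(
                    (locus, var, self.slope[j, k], self.r2[j, k], self.p[j, k],
                     bool(self.significant[j, k]),
                     bool(self.robust[j, k]) if self.robust is not None else None)
                )
        return pd.DataFrame(
            recs,
            columns=["locus", "variable", "slope", "r2", "p", "significant", "robust"],
        )


def univariate_scan(
    freqs: PopulationFrequencies,
    env: EnvironmentTable,
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> AssociationResult:
    """OLS of per-population locus frequency on each physical variable.

    Significance uses a Bonferroni threshold of alpha divided by the
    number of loci tested (one adjusted threshold shared by all
    variables).  Zero-variance variables are skipped with a warning.
    """
    if variables is None:
        variables = [v for v in DEFAULT_VARIABLES if v in env.table.columns]
    pops = [p for p in freqs.populations if p in set(env.populations)]
    if len(pops) < 4:
        raise ValueError("univariate scan needs >=4 populations")
    env = env.subset(pops)
    pop_idx = [freqs.populations.index(p) for p in pops]
    pmat = freqs.p[pop_idx, :]  # (n_pops, n_loci)

    keep_vars = []
    for v in variables:
        x = env.variable(v).to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"variable {v!r} has zero variance; skipped", stacklevel=2)
            continue
        keep_vars.append(v)
    variables = keep_vars

    n_loci, n_vars = pmat.shape[1], len(variables)
    slope = np.full((n_loci, n_vars), np.nan)
    r2 = np.full((n_loci, n_vars), np.nan)
    pval = np.ones((n_loci, n_vars))
    for k, v in enumerate(variables):
        x = env.variable(v).to_numpy(dtype=float)
        for j in range(n_loci):
            y = pmat[:, j]
            ok = np.isfinite(y)
            if ok.sum() < 4 or np.std(y[ok]) == 0:
                slope[j, k], r2[j, k], pval[j, k] = 0.0, 0.0, 1.0
                continue
            res = stats.linregress(x[ok], y[ok])
            slope[j, k] = res.slope
            r2[j, k] = res.rvalue**2
            pval[j, k] = res.pvalue
    adj = alpha / n_loci
    return AssociationResult(
        locus_ids=list(freqs.locus_ids),
        variables=variables,
        slope=slope,
        r2=r2,
        p=pval,
        adjusted_alpha=adj,
        significant=pval < adj,
    )


def robustness_exclusion(
    freqs: PopulationFrequencies,
    env: EnvironmentTable,
    variables: list[str] | None = None,
    exclude_populations: list[str] | tuple[str, ...] = (),
    alpha: float = 0.05,
) -> AssociationResult:
    """Guard against a single geographically coherent group driving an
    association: rerun the scan without the excluded populations and flag
    as robust only associations significant in both runs."""
    full = univariate_scan(freqs, env, variables, alpha)
    excl = set(exclude_populations)
    if not excl:
        full.robust = full.significant.copy()
        return full
    if not excl < set(freqs.populations):
        raise ValueError("excluded set must be a strict subset of populations")
    keep = [p for p in freqs.populations if p not in excl]
    if len(keep) < 4:
        raise ValueError("exclusion leaves fewer than 4 populations")
    keep_idx = [freqs.populations.index(p) for p in keep]
    reduced_freqs = PopulationFrequencies(
        populations=keep,
        locus_ids=freqs.locus_ids,
        p=freqs.p[keep_idx],
        ho=freqs.ho[keep_idx],
        he=freqs.he[keep_idx],
        n=freqs.n[keep_idx],
        panel_maf=freqs.panel_maf,
    )
    reduced = univariate_scan(reduced_freqs, env.subset(keep), full.variables, alpha)
    full.robust = full.significant & reduced.significant
    return full


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """One-tailed Mantel test of positive association between two distance
    matrices: Pearson r over off-diagonal entries, p from joint
    row/column permutations of the second matrix,
    p = (#{r_perm >= r_obs} + 1)/(n_perm + 1)."""
    if d1.labels != d2.labels:
        d2 = d2.reorder(d1.labels)
    rng = np.random.default_rng(seed)
    n = d1.n
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    if np.std(x) == 0 or np.std(d2.values[iu]) == 0:
        raise ValueError("Mantel test undefined for a constant matrix")
    xc = (x - x.mean()) / x.std()

    def corr(mat):
        y = mat[iu]
        return float(np.mean(xc * (y - y.mean()) / y.std()))

    r_obs = corr(d2.values)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        count += corr(d2.values[np.ix_(perm, perm)]) >= r_obs - 1e-12
    return r_obs, (count + 1) / (n_perm + 1)


def linearize_fst(dm: DistanceMatrix) -> DistanceMatrix:
    """FST/(1-FST) transform sometimes used for isolation-by-distance
    regressions; off by default throughout the pipeline (raw FST is the
    default response)."""
    vals = dm.values / (1 - dm.values)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(dm.labels, vals, kind=dm.kind)


def env_distance(env: EnvironmentTable, variable: str) -> DistanceMatrix:
    """Absolute pairwise difference in a physical variable."""
    v = env.variable(variable).to_numpy(dtype=float)
    return DistanceMatrix(
        env.populations, np.abs(v[:, None] - v[None, :]), kind="env_abs_diff"
    )
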