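"""Synthetic genotype + environment datasets with known ground truth.

The generator emulates the study system the pipeline is built for: a
riverscape of populations in regional groups with hierarchical drift,
spatially structured climate covariates, and a subset of loci whose
allele frequencies follow logistic clines in one environmental variable.
Drift uses the F-model (Balding–Nichols Beta-binomial hierarchy), which
has closed-form FST expectations used to calibrate the outlier-scan null.
QC defects (missing data, interspecific hybrids, duplicated loci,
heterozygote-excess loci) are planted on request and recorded in a truth
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import MISSING, MONTHS, EnvironmentTable, GenotypeDataset

# monthly mean-max temperature baseline (degC) and winter-heavy monthly
# precipitation profile (fractions of the annual total), Pacific-Northwest
# style seasonality
_TMAX_BASE = np.array([8.0, 10.0, 13.0, 17.0, 21.0, 25.0, 29.0, 28.0, 24.0, 18.0, 11.0, 8.0])
_PRECIP_PROFILE = np.array(
    [0.14, 0.12, 0.11, 0.09, 0.07, 0.05, 0.02, 0.02, 0.04, 0.08, 0.12, 0.14]
)


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic riverscape.

    Defaults describe a desk-scale single lineage: 50 populations in five
    regional groups of ten, 30 individuals each, 200 biallelic loci of
    which ten carry environmental clines of one logit unit per SD of the
    cline variable, and drift intensities giving a multilocus theta near
    0.05 — the within-lineage differentiation scale of the steelhead
    system this pipeline targets.
    """

    n_regions: int = 5
    pops_per_region: int = 10
    inds_per_pop: int = 30
    n_loci: int = 200
    n_candidates: int = 10
    f_region: float = 0.02
    f_pop: float = 0.03
    cline_beta: float = 1.0  # logit units per SD of the cline variable
    cline_variable: str = "precip_summer"
    # environment model
    elev_gradient: float = 1500.0  # m over the west-east transect
    env_noise_sd: float = 150.0  # elevation spatial-noise SD, m
    temp_precip_rho: float = -0.6  # corr(summer tmax, annual precip)
    # planted QC defects
    missing_rate: float = 0.01
    n_high_missing: int = 0  # individuals with ~15% missing calls
    hybrid_frac: float = 0.0
    n_diagnostic: int = 0  # species-diagnostic loci appended to the panel
    n_duplicate_pairs: int = 0
    n_hwe_loci: int = 0  # heterozygote-excess loci
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_candidates > self.n_loci:
            raise ValueError("n_candidates cannot exceed n_loci")
        for name in ("f_region", "f_pop"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("missing_rate", "hybrid_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def n_pops(self) -> int:
        return self.n_regions * self.pops_per_region

    def population_names(self) -> list[str]:
        return [
            f"R{r + 1}P{p + 1:02d}"
            for r in range(self.n_regions)
            for p in range(self.pops_per_region)
        ]

    def region_of(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_regions), self.pops_per_region)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """Ground truth emitted alongside each synthetic dataset."""

    locus_status: dict[str, str]  # locus -> neutral | candidate | diagnostic | duplicate | hwe_excess
    candidate_effects: dict[str, tuple[str, float]]  # locus -> (variable, beta)
    individual_status: dict[str, str]  # individual -> clean | hybrid | high_missing
    linked_groups: list[set[str]] = field(default_factory=list)
    diagnostic_loci: list[str] = field(default_factory=list)

    def candidates(self) -> list[str]:
        return [l for l, s in self.locus_status.items() if s == "candidate"]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for locus, status in self.locus_status.items():
            var, beta = self.candidate_effects.get(locus, ("", np.nan))
            recs.append((locus, status, var, beta))
        return pd.DataFrame(recs, columns=["locus", "status", "cline_variable", "beta"])


def simulate_environment(config: SimulationConfig, seed: int | None = None) -> EnvironmentTable:
    """Spatially structured climate table for the configured populations.

    Populations sit on a 2-D lattice along a west-to-east transect (x) with
    a within-region cross axis (y).  Elevation is a gradient in x plus
    Gaussian noise; monthly temperatures fall with elevation and latitude;
    precipitation is negatively correlated with summer maximum temperature
    at the configured rho; migration distance is the lattice path length
    from the downstream origin.  Seasonal/annual aggregates are included.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pops = config.population_names()
    region = config.region_of()
    within = np.tile(np.arange(config.pops_per_region), config.n_regions)
    x = (region + (within + 0.5) / config.pops_per_region) / config.n_regions
    y = within / max(1, config.pops_per_region - 1)

    latitude = 45.0 + 1.5 * x
    longitude = -123.0 + 6.0 * x
    elevation = 100.0 + config.elev_gradient * x + rng.normal(
        0, config.env_noise_sd, config.n_pops
    )
    migration = 600.0 * x + 150.0 * y  # km of river path from the origin

    # lapse rate 6.5 degC/km; 0.8 degC per degree of latitude northing;
    # each month also carries independent station-level noise so the
    # monthly normals are correlated but not rank-deficient
    offset = -6.5 * elevation / 1000.0 - 0.8 * (latitude - 45.0)
    month_sd = config.env_noise_sd / 500.0
    tmax = (
        _TMAX_BASE[None, :]
        + offset[:, None]
        + rng.normal(0, month_sd, (config.n_pops, 12))
    )
    tmin = tmax - 10.0 + rng.normal(0, month_sd, (config.n_pops, 12))

    summer = tmax[:, 6:9].mean(axis=1)
    sd = summer.std()
    z = (summer - summer.mean()) / sd if sd > 0 else np.zeros_like(summer)
    rho = config.temp_precip_rho
    w = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(0, 1, config.n_pops)
    annual_precip = np.clip(900.0 + 300.0 * w, 50.0, None)
    profile = _PRECIP_PROFILE[None, :] * np.exp(
        rng.normal(0, 0.15, (config.n_pops, 12))
    )
    profile /= profile.sum(axis=1, keepdims=True)
    precip = annual_precip[:, None] * profile

    data = {"population": pops, "latitude": latitude, "longitude": longitude,
            "elevation": elevation, "migration_distance": migration}
    for k, m in enumerate(MONTHS):
        data[f"tmax_{m}"] = tmax[:, k]
    for k, m in enumerate(MONTHS):
        data[f"tmin_{m}"] = tmin[:, k]
    for k, m in enumerate(MONTHS):
        data[f"precip_{m}"] = precip[:, k]
    env = EnvironmentTable(pd.DataFrame(data))
    from .assoc import seasonal_aggregate

    return seasonal_aggregate(env)


def _beta_draw(rng, mean: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols draw: Beta with the given mean and variance
    f * mean * (1 - mean)."""
    if f <= 0:
        return mean.copy()
    a = mean * (1 - f) / f
    b = (1 - mean) * (1 - f) / f
    return rng.beta(np.maximum(a, 1e-6), np.maximum(b, 1e-6))


def simulate_genotypes(
    config: SimulationConfig, env: EnvironmentTable, seed: int | None = None
) -> tuple[GenotypeDataset, TruthTable]:
    """Hierarchical F-model genotypes with planted clines and QC defects.

    Ancestral frequencies are Uniform(0.1, 0.9); regional and population
    frequencies are Beta-distributed around their parent with variances
    f_region and f_pop times p(1-p).  Candidate loci get a logit-scale
    shift of cline_beta per SD of the cline variable applied to the
    population frequency.  Genotypes are Binomial(2, p).  Calls are then
    oriented to the panel-wide minor allele.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pops = config.population_names()
    if env.populations != pops:
        raise ValueError("environment table does not match the configured layout")
    region = config.region_of()
    n_pops, n_loci = config.n_pops, config.n_loci

    locus_ids = [f"SNP{j + 1:04d}" for j in range(n_loci)]
    p_anc = rng.uniform(0.1, 0.9, n_loci)
    p_reg = np.vstack([_beta_draw(rng, p_anc, config.f_region) for _ in range(config.n_regions)])
    p_pop = np.vstack([_beta_draw(rng, p_reg[region[i]], config.f_pop) for i in range(n_pops)])

    candidate_idx = rng.choice(n_loci, size=config.n_candidates, replace=False)
    zvar = env.variable(config.cline_variable).to_numpy(dtype=float)
    zvar = (zvar - zvar.mean()) / zvar.std()
    clipped = 0
    for j in candidate_idx:
        logit = np.log(p_pop[:, j] / (1 - p_pop[:, j])) + config.cline_beta * zvar
        pj = 1 / (1 + np.exp(-logit))
        clipped += int(((pj < 0.001) | (pj > 0.999)).sum())
        p_pop[:, j] = np.clip(pj, 0.001, 0.999)

    n_ind = n_pops * config.inds_per_pop
    pop_of_ind = np.repeat(np.arange(n_pops), config.inds_per_pop)
    calls = rng.binomial(2, p_pop[pop_of_ind, :]).astype(np.int8)

    locus_status = {l: "neutral" for l in locus_ids}
    candidate_effects = {}
    for j in candidate_idx:
        locus_status[locus_ids[j]] = "candidate"
        candidate_effects[locus_ids[j]] = (config.cline_variable, config.cline_beta)

    # heterozygote-excess loci (scoring-artifact analogue): overwrite a
    # few neutral loci so that most genotyped individuals are heterozygous
    neutral_pool = [j for j in range(n_loci) if j not in set(candidate_idx)]
    hwe_idx = rng.choice(neutral_pool, size=config.n_hwe_loci, replace=False) if config.n_hwe_loci else []
    for j in hwe_idx:
        calls[:, j] = rng.choice([0, 1, 2], size=n_ind, p=[0.05, 0.9, 0.05])
        locus_status[locus_ids[j]] = "hwe_excess"

    # duplicated loci: an exact copy appended to the panel
    linked_groups = []
    dup_pool = [j for j in neutral_pool if j not in set(hwe_idx)]
    dup_src = rng.choice(dup_pool, size=config.n_duplicate_pairs, replace=False) if config.n_duplicate_pairs else []
    dup_cols, dup_ids = [], []
    for j in dup_src:
        dup_id = f"{locus_ids[j]}dup"
        dup_ids.append(dup_id)
        dup_cols.append(calls[:, j].copy())
        linked_groups.append({locus_ids[j], dup_id})
        locus_status[dup_id] = "duplicate"

    # species-diagnostic loci: natives are homozygous for the native
    # allele (call 0); hybrids carry the alien allele
    diag_ids = [f"DIAG{k + 1}" for k in range(config.n_diagnostic)]
    diag_cols = [np.zeros(n_ind, dtype=np.int8) for _ in diag_ids]
    individual_ids = [
        f"{pops[pop_of_ind[i]]}_i{i % config.inds_per_pop + 1:02d}" for i in range(n_ind)
    ]
    individual_status = {iid: "clean" for iid in individual_ids}
    if config.hybrid_frac > 0 and config.n_diagnostic > 0:
        n_hyb = int(round(config.hybrid_frac * n_ind))
        hyb = rng.choice(n_ind, size=n_hyb, replace=False)
        for i in hyb:
            for col in diag_cols:
                col[i] = rng.choice([1, 2])
            individual_status[individual_ids[i]] = "hybrid"
    for did, col in zip(diag_ids, diag_cols):
        locus_status[did] = "diagnostic"

    all_ids = locus_ids + dup_ids + diag_ids
    all_calls = np.column_stack([calls] + dup_cols + diag_cols) if (dup_cols or diag_cols) else calls

    # random missingness, plus planted high-missingness individuals
    if config.missing_rate > 0:
        mask = rng.random(all_calls.shape) < config.missing_rate
        all_calls[mask] = MISSING
    if config.n_high_missing > 0:
        clean = [i for i in range(n_ind) if individual_status[individual_ids[i]] == "clean"]
        hm = rng.choice(clean, size=config.n_high_missing, replace=False)
        for i in hm:
            mask = rng.random(all_calls.shape[1]) < 0.15
            while mask.mean() < 0.10:  # guarantee the removal threshold is crossed
                mask |= rng.random(all_calls.shape[1]) < 0.05
            all_calls[i, mask] = MISSING
            individual_status[individual_ids[i]] = "high_missing"

    # orient every call column to the panel-wide minor allele
    valid = all_calls != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(valid, all_calls, 0).sum(axis=0) / (2 * valid.sum(axis=0))
    flip = freq > 0.5
    flipped = all_calls.copy()
    flipped[:, flip] = np.where(
        all_calls[:, flip] == MISSING, MISSING, 2 - all_calls[:, flip]
    ).astype(np.int8)

    dataset = GenotypeDataset(
        individual_ids=individual_ids,
        population_labels=[pops[r] for r in pop_of_ind],
        locus_ids=all_ids,
        calls=flipped,
        metadata={
            "config": config.to_dict(),
            "diagnostic_loci": diag_ids,
            "n_cline_clipped": clipped,
        },
    )
    truth = TruthTable(
        locus_status=locus_status,
        candidate_effects=candidate_effects,
        individual_status=individual_status,
        linked_groups=linked_groups,
        diagnostic_loci=diag_ids,
    )
    return dataset, truth


def expected_fst(config: SimulationConfig) -> dict[str, float]:
    """Closed-form F-model drift expectations used to calibrate outlier
    nulls: within-region pairs differentiate at f_pop; between-region
    pairs at the composite f_region + (1 - f_region) * f_pop."""
    within = config.f_pop
    between = config.f_region + (1 - config.f_region) * config.f_pop
    return {"within_region": within, "between_region": between}
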