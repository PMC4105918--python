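"""Planted-candidate recovery study: the generator's default study
conditions (50 populations in five regional groups, 30 individuals each,
200 loci of which ten carry clines of one logit unit per SD of summer
precipitation) run through the full pipeline repeatedly, scoring the
candidate panel against the planted truth.

The exclusion group for the regression-robustness rerun is chosen the
way the source analysis chose its own: the regional group sitting at the
wet extreme of the cline variable, whose shared drift could masquerade
as an association.
"""

from __future__ import annotations

import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import PipelineConfig, run_pipeline
from .simulate import SimulationConfig, simulate_environment


def wettest_region_populations(sim_cfg: SimulationConfig, seed: int) -> list[str]:
    """Populations of the regional group with the highest mean of the
    cline variable (the robustness-exclusion group)."""
    env = simulate_environment(sim_cfg, seed=seed)
    v = env.variable(sim_cfg.cline_variable)
    pops = np.asarray(sim_cfg.population_names())
    region = sim_cfg.region_of()
    means = [v[pops[region == r]].mean() for r in range(sim_cfg.n_regions)]
    return list(pops[region == int(np.argmax(means))])


def study_config(seed: int, cline_beta: float = 1.0, fast: bool = True) -> PipelineConfig:
    """Pipeline configuration for one recovery replicate.

    `fast` trims simulation sizes that do not change the decision rule
    (null size, permutation counts, EM restarts) to desk scale.
    """
    sim = dict(
        n_regions=5, pops_per_region=10, inds_per_pop=30,
        n_loci=200, n_candidates=10, cline_beta=cline_beta,
    )
    sim_cfg = SimulationConfig(**sim, seed=seed)
    exclude = wettest_region_populations(sim_cfg, seed)
    kwargs = dict(
        synthetic=sim,
        exclude_populations=exclude,
        comparisons=False,
        seed=seed,
    )
    if fast:
        kwargs.update(
            n_null_loci=4000, n_pilot_loci=400, outlier_window_k=1000,
            em_restarts=2, em_max_iter=300, em_tol=1e-4,
            distlm_n_perm=99, ld_n_perm=499,
        )
    return PipelineConfig(**kwargs)


def run_replicate(seed: int, outdir: str | Path | None = None, **cfg_kwargs) -> dict:
    """One end-to-end replicate; returns recovery counts vs truth."""
    cfg = study_config(seed, **cfg_kwargs)
    with tempfile.TemporaryDirectory() as tmp:
        out = Path(outdir) if outdir else Path(tmp) / "run"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_pipeline(cfg, out)
        truth = pd.read_csv(out / "truth.tsv", sep="\t")
        planted = set(truth.loc[truth["status"] == "candidate", "locus"])
        candidates = set((out / "all" / "panel_candidate.txt").read_text().split())
        post_qc = set(pd.read_csv(out / "all" / "classification.tsv", sep="\t")["locus"])
    neutral_truth = post_qc - planted
    return {
        "seed": seed,
        "n_planted": len(planted & post_qc),
        "n_recovered": len(planted & candidates),
        "n_false": len(candidates - planted),
        "n_neutral": len(neutral_truth),
        "n_candidates": len(candidates),
    }


def recovery_study(n_replicates: int = 20, seed: int = 1, **cfg_kwargs) -> dict:
    """Replicate the study and aggregate sensitivity and the
    false-candidate rate (truly neutral loci wrongly classified
    candidate, per neutral locus)."""
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(1, 2**31 - 1, size=n_replicates)
    reps = [run_replicate(int(s), **cfg_kwargs) for s in rep_seeds]
    n_rec = sum(r["n_recovered"] for r in reps)
    n_planted = sum(r["n_planted"] for r in reps)
    n_false = sum(r["n_false"] for r in reps)
    n_neutral = sum(r["n_neutral"] for r in reps)
    return {
        "replicates": reps,
        "sensitivity": n_rec / n_planted,
        "false_candidate_rate": n_false / n_neutral,
        "mean_candidates": np.mean([r["n_candidates"] for r in reps]),
    }
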