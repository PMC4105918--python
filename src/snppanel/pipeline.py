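"""End-to-end orchestration: QC -> lineage split -> per-lineage outlier
scan, neutral controls, environmental association, DISTLM ranking,
classification, and the neutral-vs-candidate comparisons (trees, Mantel
tests, climate ranking).  Every stage writes TSV artifacts into a run
directory and registers them in a JSON manifest carrying the config hash
and seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as io_mod
from .admixture import assign_lineage, build_controls
from .assoc import (
    DEFAULT_VARIABLES,
    env_distance,
    mantel,
    robustness_exclusion,
    seasonal_aggregate,
)
from .classify import build_panels, classify_all, flag_loci
from .datatypes import EnvironmentTable, GenotypeDataset
from .distlm import per_locus_distlm
from .outliers import calibrate_migration, default_sample_spec, outlier_test, simulate_null
from .popgen import allele_stats, pairwise_theta_distance, wc_theta
from .qc import run_qc
from .simulate import SimulationConfig, simulate_environment, simulate_genotypes
from .trees import bootstrap_consensus, climate_rank, compare_trees


@dataclass
class PipelineConfig:
    # inputs: file paths, or a synthetic config when genotype_path is None
    genotype_path: str | None = None
    genotype_format: str = "tsv"  # tsv | genepop
    env_path: str | None = None
    precedence_path: str | None = None
    diagnostic_loci: list[str] = field(default_factory=list)
    synthetic: dict = field(default_factory=dict)
    # lineage handling
    lineage: str = "none"  # auto | none
    min_lineage_pops: int = 8
    # QC
    max_missing_frac: float = 0.10
    hwe_max_departure_frac: float = 0.08
    ld_min_pop_frac: float = 0.10
    ld_n_perm: int = 999
    # outlier scan
    n_demes: int = 100
    n_null_loci: int = 50_000
    n_pilot_loci: int = 2000
    outlier_window_k: int = 2000
    outlier_quantiles: tuple[float, float] = (0.01, 0.99)
    calibration_tol: float = 0.005
    # neutral controls
    control_k: int = 6
    em_restarts: int = 3
    em_max_iter: int = 500
    em_tol: float = 1e-4
    # association
    variables: list[str] | None = None
    exclude_populations: list[str] = field(default_factory=list)
    # DISTLM
    distlm_mode: str = "sets"
    distlm_n_perm: int = 199
    # classification
    linreg_only_failures_ambiguous: bool = False
    # comparisons (trees, Mantel, climate ranking); can be disabled for
    # recovery studies that only need the classification
    comparisons: bool = True
    bootstrap_reps: int = 200
    mantel_n_perm: int = 9999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_inputs(
    config: PipelineConfig, seed: int | None = None
) -> tuple[GenotypeDataset, EnvironmentTable, "object"]:
    """Read the configured genotype/environment files, or simulate them."""
    truth = None
    if config.genotype_path is None:
        sim_cfg = SimulationConfig(**{**config.synthetic, "seed": config.seed if seed is None else seed})
        env = simulate_environment(sim_cfg)
        dataset, truth = simulate_genotypes(sim_cfg, env)
    else:
        if config.genotype_format == "genepop":
            dataset = io_mod.read_genepop(config.genotype_path)
        else:
            dataset = io_mod.read_genotype_table(config.genotype_path)
        if config.env_path is None:
            raise ValueError("env_path is required with real genotype input")
        env = io_mod.read_environment_table(config.env_path, dataset)
        env = seasonal_aggregate(env)
    return dataset, env, truth


def _read_precedence(config: PipelineConfig) -> list[str]:
    if not config.precedence_path:
        return []
    return [
        line.strip()
        for line in Path(config.precedence_path).read_text().splitlines()
        if line.strip()
    ]


def analyze_lineage(
    dataset: GenotypeDataset,
    env: EnvironmentTable,
    config: PipelineConfig,
    seed: int,
    outdir: Path,
    lineage_name: str = "all",
    precedence: list[str] | None = None,
    manifest: dict | None = None,
) -> dict:
    """Per-lineage analysis chain; returns summary statistics and writes
    one TSV per stage under outdir."""
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = manifest if manifest is not None else {}
    rng = np.random.default_rng(seed)
    precedence = precedence or []
    env = env.subset(dataset.populations)

    def save(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest[f"{lineage_name}/{name}"] = str(path)

    # descriptive statistics
    freqs = allele_stats(dataset)
    fst = wc_theta(dataset)
    save("locus_stats", freqs.to_frame())
    per_locus = pd.DataFrame(
        {"locus": fst.locus_ids, "theta": fst.theta_locus,
         "he_mean": np.nanmean(freqs.he, axis=0)}
    )
    save("locus_theta", per_locus)
    pw = pairwise_theta_distance(dataset)
    pw.to_frame().to_csv(outdir / "pairwise_fst.tsv", sep="\t")
    manifest[f"{lineage_name}/pairwise_fst"] = str(outdir / "pairwise_fst.tsv")

    # outlier scan against the calibrated island-model null
    sizes = [len(ix) for ix in dataset.population_indices().values()]
    spec = default_sample_spec(
        len(dataset.populations), int(np.median(sizes)), config.n_demes
    )
    target = fst.theta_multilocus
    migration = calibrate_migration(
        target, config.n_demes, spec, seed=int(rng.integers(2**31 - 1)),
        tol=config.calibration_tol, n_pilot=config.n_pilot_loci,
    )
    null = simulate_null(
        migration, config.n_demes, spec, n_loci=config.n_null_loci,
        seed=int(rng.integers(2**31 - 1)), target_fst=target,
    )
    lo, hi = config.outlier_quantiles
    outl = outlier_test(
        fst.locus_ids, np.nanmean(freqs.he, axis=0), fst.theta_locus, null,
        window_k=config.outlier_window_k, lower_q=lo, upper_q=hi,
    )
    save("outliers", outl.to_frame())

    # neutral-structure controls from the non-outlier panel
    neutral_for_controls = [
        l for l in dataset.locus_ids if l not in set(outl.directional_loci())
    ]
    k = min(config.control_k, len(dataset.populations))
    controls = build_controls(
        dataset, neutral_for_controls, k=k, seed=int(rng.integers(2**31 - 1)),
        restarts=config.em_restarts, max_iter=config.em_max_iter, tol=config.em_tol,
    )
    save("controls", controls.to_frame())

    # univariate association with the exclusion-robustness rerun
    excl = [p for p in config.exclude_populations if p in set(dataset.populations)]
    assoc = robustness_exclusion(
        freqs, env, config.variables, exclude_populations=excl
    )
    save("association", assoc.to_frame())

    # criteria 1-3 flags, then DISTLM (criterion 4) for flagged loci
    flags = flag_loci(outl, precedence, assoc, require_robust=bool(excl))
    distlm_results = {}
    for locus in sorted(l for l, f in flags.items() if f):
        distlm_results[locus] = per_locus_distlm(
            dataset, locus, env, controls, mode=config.distlm_mode,
            n_perm=config.distlm_n_perm, seed=int(rng.integers(2**31 - 1)),
            variables=config.variables,
        )
    if distlm_results:
        save(
            "distlm",
            pd.concat([r.to_frame() for r in distlm_results.values() if r.steps],
                      ignore_index=True) if any(r.steps for r in distlm_results.values())
            else pd.DataFrame(),
        )

    classifications = classify_all(
        flags, distlm_results,
        linreg_only_failures_ambiguous=config.linreg_only_failures_ambiguous,
    )
    panels = build_panels(classifications)
    save("classification", panels.summary)
    for name, loci in (("neutral", panels.neutral), ("candidate", panels.candidate),
                       ("ambiguous", panels.ambiguous)):
        path = outdir / f"panel_{name}.txt"
        path.write_text("\n".join(loci) + ("\n" if loci else ""))
        manifest[f"{lineage_name}/panel_{name}"] = str(path)

    # neutral vs candidate comparisons
    comparisons = {}
    trees = {}
    if not config.comparisons:
        return _summary(lineage_name, dataset, fst, migration, null, outl, flags, panels, comparisons)
    for name, loci in (("neutral", panels.neutral), ("candidate", panels.candidate)):
        if len(loci) >= 2 and len(dataset.populations) >= 3:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                trees[name] = bootstrap_consensus(
                    freqs, loci, n_reps=config.bootstrap_reps,
                    seed=int(rng.integers(2**31 - 1)),
                )
            io_mod.write_newick(trees[name], outdir / f"tree_{name}.nwk")
            manifest[f"{lineage_name}/tree_{name}"] = str(outdir / f"tree_{name}.nwk")
    if len(trees) == 2:
        comp = compare_trees(trees["neutral"], trees["candidate"])
        comparisons["rf_distance"] = comp.rf_distance

    # Mantel: isolation by distance, and by each climate variable
    mantel_rows = []
    stream = env_distance(env, "migration_distance")
    for name, loci in (("neutral", panels.neutral), ("candidate", panels.candidate)):
        if len(loci) < 2:
            continue
        dm = pairwise_theta_distance(dataset, loci_subset=loci).reorder(env.populations)
        r, p = mantel(dm, stream, n_perm=config.mantel_n_perm,
                      seed=int(rng.integers(2**31 - 1)))
        mantel_rows.append((name, "migration_distance", r, r**2, p))
        for var in ("precip_spring", "precip_summer", "tmax_summer"):
            r, p = mantel(dm, env_distance(env, var), n_perm=config.mantel_n_perm,
                          seed=int(rng.integers(2**31 - 1)))
            mantel_rows.append((name, var, r, r**2, p))
    save(
        "mantel",
        pd.DataFrame(mantel_rows, columns=["panel", "variable", "r", "r2", "p"]),
    )
    save("climate_rank", climate_rank(env))

    return _summary(lineage_name, dataset, fst, migration, null, outl, flags, panels, comparisons)


def _summary(lineage_name, dataset, fst, migration, null, outl, flags, panels, comparisons):
    return {
        "lineage": lineage_name,
        "n_populations": len(dataset.populations),
        "n_loci": dataset.n_loci,
        "multilocus_theta": fst.theta_multilocus,
        "migration_calibrated": migration,
        "null_mean_fst": null.mean_fst,
        "n_outliers_directional": len(outl.directional_loci()),
        "n_flagged": sum(bool(f) for f in flags.values()),
        "panel_sizes": {p: len(getattr(panels, p)) for p in ("neutral", "candidate", "ambiguous")},
        "comparisons": comparisons,
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis; returns the manifest dict (also written
    to manifest.json in outdir)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "artifacts": {},
    }
    art = manifest["artifacts"]
    stage = "load"
    try:
        dataset, env, truth = load_inputs(config)
        io_mod.write_genotype_table(dataset, outdir / "genotypes.tsv")
        io_mod.write_environment_table(env, outdir / "environment.tsv")
        art["genotypes"] = str(outdir / "genotypes.tsv")
        art["environment"] = str(outdir / "environment.tsv")
        if truth is not None:
            truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
            art["truth"] = str(outdir / "truth.tsv")
        precedence = _read_precedence(config)

        stage = "qc"
        diagnostics = config.diagnostic_loci or dataset.metadata.get("diagnostic_loci", [])
        pared, report = run_qc(
            dataset,
            diagnostic_loci=diagnostics,
            max_missing_frac=config.max_missing_frac,
            max_departure_frac=config.hwe_max_departure_frac,
            ld_min_pop_frac=config.ld_min_pop_frac,
            ld_n_perm=config.ld_n_perm,
            seed=config.seed,
        )
        report.to_frame().to_csv(outdir / "paring.tsv", sep="\t", index=False)
        art["paring"] = str(outdir / "paring.tsv")

        stage = "lineage"
        groups: dict[str, GenotypeDataset] = {}
        if config.lineage == "auto":
            assign = assign_lineage(pared, seed=config.seed)
            assign.to_csv(outdir / "lineage.tsv", sep="\t", index=False)
            art["lineage"] = str(outdir / "lineage.tsv")
            for lin in ("lineage1", "lineage2"):
                pops = assign.loc[assign["lineage"] == lin, "population"].tolist()
                if len(pops) >= config.min_lineage_pops:
                    groups[lin] = pared.subset_populations(pops)
            if not groups:
                groups["all"] = pared
        else:
            groups["all"] = pared

        summaries = []
        for lin, ds in groups.items():
            stage = f"analyze:{lin}"
            summaries.append(
                analyze_lineage(
                    ds, env, config, seed=config.seed, outdir=outdir / lin,
                    lineage_name=lin, precedence=precedence, manifest=art,
                )
            )
        manifest["summaries"] = summaries
    except Exception as exc:  # persist partial outputs, then re-raise
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise StageFailure(stage, exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    _write_report(outdir, config, manifest)
    return manifest


def _write_report(outdir: Path, config: PipelineConfig, manifest: dict) -> None:
    lines = [
        "snppanel run report",
        f"config hash: {manifest['config_hash']}  seed: {manifest['seed']}",
        "",
    ]
    for s in manifest.get("summaries", []):
        lines += [
            f"[{s['lineage']}] {s['n_populations']} populations, {s['n_loci']} loci",
            f"  multilocus theta = {s['multilocus_theta']:.4f} "
            f"(null calibrated to mean FST {s['null_mean_fst']:.4f}, M = {s['migration_calibrated']:.3g})",
            f"  directional outliers: {s['n_outliers_directional']}; "
            f"flagged by criteria 1-3: {s['n_flagged']}",
            "  panels: " + ", ".join(f"{k}={v}" for k, v in s["panel_sizes"].items()),
            "",
        ]
    (outdir / "report.txt").write_text("\n".join(lines))
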