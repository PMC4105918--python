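"""Sample and locus paring: missingness, interspecific-hybrid screen,
Hardy–Weinberg-based and linkage-based locus removal.

The pipeline order is fixed and logged: missingness -> hybrid screen ->
HWE paring -> LD paring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset
from .popgen import allele_stats, by_fdr_alpha, hwe_exact_test, ld_permutation_test


@dataclass
class ParingReport:
    removed_individuals: list[tuple[str, str, float]] = field(default_factory=list)  # (id, reason, statistic)
    removed_loci: list[tuple[str, str, float]] = field(default_factory=list)  # (id, reason, statistic)
    linkage_groups: list[dict] = field(default_factory=list)  # {members, retained}
    thresholds: dict = field(default_factory=dict)

    def merge(self, other: "ParingReport") -> "ParingReport":
        return ParingReport(
            removed_individuals=self.removed_individuals + other.removed_individuals,
            removed_loci=self.removed_loci + other.removed_loci,
            linkage_groups=self.linkage_groups + other.linkage_groups,
            thresholds={**self.thresholds, **other.thresholds},
        )

    def to_frame(self) -> pd.DataFrame:
        recs = [("individual", i, r, s) for i, r, s in self.removed_individuals]
        recs += [("locus", l, r, s) for l, r, s in self.removed_loci]
        return pd.DataFrame(recs, columns=["unit", "id", "reason", "statistic"])


def filter_missingness(
    dataset: GenotypeDataset, max_missing_frac: float = 0.10
) -> tuple[GenotypeDataset, ParingReport]:
    """Drop individuals whose fraction of missing calls reaches
    max_missing_frac (strict: kept iff fraction < threshold)."""
    frac = dataset.missing_fraction()
    drop = frac >= max_missing_frac
    if drop.all():
        raise ValueError("missingness filter would remove every individual")
    report = ParingReport(
        removed_individuals=[
            (dataset.individual_ids[i], "missingness", float(frac[i]))
            for i in np.flatnonzero(drop)
        ],
        thresholds={"max_missing_frac": max_missing_frac},
    )
    return dataset.subset_individuals(~drop), report


def screen_diagnostic(
    dataset: GenotypeDataset,
    diagnostic_loci: list[str],
    max_alien_alleles: int = 1,
) -> tuple[GenotypeDataset, ParingReport]:
    """Remove putative interspecific hybrids, then drop the diagnostic
    loci from the panel.

    Each diagnostic locus is scored for the 'alien' (non-native) allele —
    the panel-minor allele of that locus, since natives are expected to
    be (near-)fixed for the native allele.  An individual carrying alien
    alleles at more than max_alien_alleles diagnostic loci is removed.
    """
    absent = [l for l in diagnostic_loci if l not in dataset.locus_ids]
    if absent:
        raise ValueError(f"diagnostic loci absent from panel: {absent}")
    pos = [dataset.locus_ids.index(l) for l in diagnostic_loci]
    diag = dataset.calls[:, pos]
    loci_with_alien = ((diag != MISSING) & (diag > 0)).sum(axis=1)
    drop = loci_with_alien > max_alien_alleles
    report = ParingReport(
        removed_individuals=[
            (dataset.individual_ids[i], "hybrid", float(loci_with_alien[i]))
            for i in np.flatnonzero(drop)
        ],
        thresholds={"max_alien_alleles": max_alien_alleles},
    )
    kept = dataset.subset_individuals(~drop)
    remaining = [l for l in kept.locus_ids if l not in set(diagnostic_loci)]
    return kept.subset_loci(remaining), report


def hwe_pvalue_table(dataset: GenotypeDataset) -> pd.DataFrame:
    """Exact HWE p-values per locus x population (rows: loci)."""
    idx = dataset.population_indices()
    out = {}
    for pop, rows in idx.items():
        calls = dataset.calls[rows, :]
        pvals = np.empty(dataset.n_loci)
        for j in range(dataset.n_loci):
            c = calls[:, j]
            c = c[c != MISSING]
            pvals[j] = hwe_exact_test(
                int((c == 2).sum()), int((c == 1).sum()), int((c == 0).sum())
            )
        out[pop] = pvals
    return pd.DataFrame(out, index=dataset.locus_ids)


def pare_hwe(
    dataset: GenotypeDataset,
    alpha: float = 0.05,
    max_departure_frac: float = 0.08,
    pvalues: pd.DataFrame | None = None,
) -> tuple[GenotypeDataset, ParingReport]:
    """Remove loci departing from Hardy–Weinberg proportions in more than
    max_departure_frac of populations, at the Benjamini–Yekutieli
    threshold adjusted for loci x populations simultaneous tests."""
    if pvalues is None:
        pvalues = hwe_pvalue_table(dataset)
    n_pops = pvalues.shape[1]
    threshold = by_fdr_alpha(alpha, dataset.n_loci * n_pops)
    frac = (pvalues < threshold).sum(axis=1) / n_pops
    drop = frac[frac > max_departure_frac]
    report = ParingReport(
        removed_loci=[(l, "hwe", float(f)) for l, f in drop.items()],
        thresholds={
            "hwe_alpha": threshold,
            "hwe_n_tests": dataset.n_loci * n_pops,
            "max_departure_frac": max_departure_frac,
        },
    )
    keep = [l for l in dataset.locus_ids if l not in set(drop.index)]
    return dataset.subset_loci(keep), report


def ld_pvalue_pairs(
    dataset: GenotypeDataset,
    n_perm: int = 999,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-pair, per-population LD permutation p-values (long format)."""
    rng = np.random.default_rng(seed)
    loci = dataset.locus_ids
    if pairs is None:
        pairs = [(loci[i], loci[j]) for i in range(len(loci)) for j in range(i + 1, len(loci))]
    recs = []
    for a, b in pairs:
        for pop in dataset.populations:
            p = ld_permutation_test(dataset, a, b, pop, n_perm=n_perm, seed=rng)
            recs.append((a, b, pop, p))
    return pd.DataFrame(recs, columns=["locus_a", "locus_b", "population", "p"])


def candidate_linked_pairs(dataset: GenotypeDataset, screen_r: float = 0.3) -> list[tuple[str, str]]:
    """Cheap screen for the permutation LD test: locus pairs whose
    genotype correlation across all individuals reaches screen_r in
    absolute value.  Background structure at the differentiation scales
    this pipeline targets induces correlations an order of magnitude
    smaller, so genuinely linked (or duplicated) loci dominate the
    screened set."""
    calls = dataset.calls.astype(float)
    calls[calls == MISSING] = np.nan
    col_mean = np.nanmean(calls, axis=0)
    filled = np.where(np.isnan(calls), col_mean, calls)
    sd = filled.std(axis=0)
    ok = sd > 0
    z = (filled[:, ok] - filled[:, ok].mean(axis=0)) / sd[ok]
    corr = z.T @ z / z.shape[0]
    ids = [l for l, o in zip(dataset.locus_ids, ok) if o]
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(corr[i, j]) >= screen_r:
                out.append((ids[i], ids[j]))
    return out


def flag_linked_pairs(
    ld_pvalues: pd.DataFrame,
    n_populations: int,
    pair_alpha: float,
    min_pop_frac: float = 0.10,
) -> list[tuple[str, str]]:
    """Pairs significant in at least min_pop_frac of populations."""
    sig = ld_pvalues[ld_pvalues["p"] < pair_alpha]
    counts = sig.groupby(["locus_a", "locus_b"]).size()
    return [
        pair for pair, k in counts.items() if k / n_populations >= min_pop_frac
    ]


def pare_linkage(
    dataset: GenotypeDataset,
    ld_pvalues: pd.DataFrame | None = None,
    pair_alpha: float | None = None,
    min_pop_frac: float = 0.10,
    flagged_pairs: list[tuple[str, str]] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[GenotypeDataset, ParingReport]:
    """Resolve linked locus groups, keeping one locus per group.

    Flagged pairs (from p-values, or supplied directly) are merged into
    connected components, so a locus linked to two others forms a trio;
    within each component only the highest-panel-MAF locus is retained,
    ties broken lexicographically by locus id.  The default pair_alpha is
    the B-Y threshold for n_pairs x n_pops simultaneous tests.
    """
    n_pops = len(dataset.populations)
    if flagged_pairs is None:
        if ld_pvalues is None:
            ld_pvalues = ld_pvalue_pairs(dataset, n_perm=n_perm, seed=seed)
        if pair_alpha is None:
            n_pairs = dataset.n_loci * (dataset.n_loci - 1) // 2
            pair_alpha = by_fdr_alpha(0.05, n_pairs * n_pops)
        flagged_pairs = flag_linked_pairs(ld_pvalues, n_pops, pair_alpha, min_pop_frac)

    graph = nx.Graph()
    graph.add_edges_from(flagged_pairs)
    maf = dict(zip(dataset.locus_ids, allele_stats(dataset).panel_maf))
    removed, groups = [], []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        # highest panel MAF retained; tie -> lexicographically smaller id
        best = max(maf.get(l, -1.0) for l in members)
        tied = sorted(l for l in members if maf.get(l, -1.0) == best)
        retained = tied[0]
        groups.append({"members": members, "retained": retained})
        removed += [(l, "linkage", float(maf.get(l, np.nan))) for l in members if l != retained]
    report = ParingReport(
        removed_loci=removed,
        linkage_groups=groups,
        thresholds={"pair_alpha": pair_alpha, "min_pop_frac": min_pop_frac},
    )
    keep = [l for l in dataset.locus_ids if l not in {r[0] for r in removed}]
    return dataset.subset_loci(keep), report


def run_qc(
    dataset: GenotypeDataset,
    diagnostic_loci: list[str] | None = None,
    max_missing_frac: float = 0.10,
    max_alien_alleles: int = 1,
    hwe_alpha: float = 0.05,
    max_departure_frac: float = 0.08,
    ld_pair_alpha: float | None = None,
    ld_min_pop_frac: float = 0.10,
    ld_n_perm: int = 999,
    seed: int = 0,
) -> tuple[GenotypeDataset, ParingReport]:
    """Full paring pipeline in the fixed order: missingness -> hybrid
    screen -> HWE paring -> LD paring."""
    ds, report = filter_missingness(dataset, max_missing_frac)
    if diagnostic_loci:
        ds, rep2 = screen_diagnostic(ds, diagnostic_loci, max_alien_alleles)
        report = report.merge(rep2)
    ds, rep3 = pare_hwe(ds, alpha=hwe_alpha, max_departure_frac=max_departure_frac)
    report = report.merge(rep3)
    screened = candidate_linked_pairs(ds)
    ld_p = ld_pvalue_pairs(ds, n_perm=ld_n_perm, seed=seed, pairs=screened)
    if ld_pair_alpha is None:
        n_pairs = ds.n_loci * (ds.n_loci - 1) // 2
        ld_pair_alpha = by_fdr_alpha(0.05, n_pairs * len(ds.populations))
    # permutation p-values cannot fall below 1/(n_perm+1); flag at that
    # floor when the adjusted threshold is finer than the permutation
    # resolution
    eff_alpha = max(ld_pair_alpha, 1.0 / (ld_n_perm + 1) + 1e-12)
    ds, rep4 = pare_linkage(
        ds,
        ld_pvalues=ld_p,
        pair_alpha=eff_alpha,
        min_pop_frac=ld_min_pop_frac,
    )
    return ds, report.merge(rep4)
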