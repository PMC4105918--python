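"""Descriptive and inferential population-genetic statistics.

Implements per-population allele statistics, an exact Hardy–Weinberg test
(full enumeration of the conditional heterozygote-count distribution), a
permutation test for linkage disequilibrium, the Benjamini–Yekutieli FDR
threshold adjustment, the Weir–Cockerham variance-components FST
estimator (theta), Nei's standard genetic distance, and principal
coordinates analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, DistanceMatrix, GenotypeDataset

# Cap applied when Nei's D is infinite (no shared alleles at any locus);
# keeps neighbor-joining runnable while preserving the ordering of all
# finite distances.
NEI_CAP = 50.0


# ---------------------------------------------------------------------------
# allele statistics


@dataclass
class PopulationFrequencies:
    """Per population x locus allele frequency of the panel-minor allele
    (p), observed heterozygosity (Ho), expected heterozygosity
    He = 2p(1-p) and genotyped count n.  Cells with no genotyped
    individuals are NaN and listed in ``missing_cells``."""

    populations: list[str]
    locus_ids: list[str]
    p: np.ndarray  # (n_pops, n_loci)
    ho: np.ndarray
    he: np.ndarray
    n: np.ndarray
    panel_maf: np.ndarray  # per locus, folded to [0, 0.5]
    monomorphic_missing: list[str] = field(default_factory=list)
    missing_cells: list[tuple[str, str]] = field(default_factory=list)

    def subset_loci(self, loci: list[str]) -> "PopulationFrequencies":
        pos = {l: j for j, l in enumerate(self.locus_ids)}
        idx = np.array([pos[l] for l in loci], dtype=int)
        return PopulationFrequencies(
            populations=self.populations,
            locus_ids=list(loci),
            p=self.p[:, idx],
            ho=self.ho[:, idx],
            he=self.he[:, idx],
            n=self.n[:, idx],
            panel_maf=self.panel_maf[idx],
            monomorphic_missing=[l for l in self.monomorphic_missing if l in set(loci)],
            missing_cells=[c for c in self.missing_cells if c[1] in set(loci)],
        )

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, pop in enumerate(self.populations):
            for j, locus in enumerate(self.locus_ids):
                recs.append(
                    (pop, locus, self.p[i, j], self.ho[i, j], self.he[i, j],
                     int(self.n[i, j]))
                )
        return pd.DataFrame(recs, columns=["population", "locus", "p", "ho", "he", "n"])


def allele_stats(dataset: GenotypeDataset) -> PopulationFrequencies:
    """Frequency of the panel-minor allele, Ho, He and genotyped count per
    population x locus, plus the panel-wide MAF per locus."""
    pops = dataset.populations
    idx = dataset.population_indices()
    n_pops, n_loci = len(pops), dataset.n_loci
    p = np.full((n_pops, n_loci), np.nan)
    ho = np.full((n_pops, n_loci), np.nan)
    nmat = np.zeros((n_pops, n_loci), dtype=int)
    for i, pop in enumerate(pops):
        calls = dataset.calls[idx[pop], :].astype(float)
        calls[calls == MISSING] = np.nan
        n = np.sum(~np.isnan(calls), axis=0)
        nmat[i] = n
        with np.errstate(invalid="ignore"):
            p[i] = np.nansum(calls, axis=0) / (2 * n)
            ho[i] = np.nansum(calls == 1, axis=0) / n
        p[i, n == 0] = np.nan
        ho[i, n == 0] = np.nan
    he = 2 * p * (1 - p)

    total_n = nmat.sum(axis=0)
    with np.errstate(invalid="ignore"):
        overall_p = np.nansum(np.where(np.isnan(p), 0, p) * nmat, axis=0) / np.where(
            total_n > 0, total_n, 1
        )
    panel_maf = np.minimum(overall_p, 1 - overall_p)
    panel_maf[total_n == 0] = np.nan

    mono_missing = [dataset.locus_ids[j] for j in np.flatnonzero(total_n == 0)]
    cells = [
        (pops[i], dataset.locus_ids[j]) for i, j in np.argwhere(nmat == 0)
    ]
    return PopulationFrequencies(
        populations=pops,
        locus_ids=list(dataset.locus_ids),
        p=p,
        ho=ho,
        he=he,
        n=nmat,
        panel_maf=panel_maf,
        monomorphic_missing=mono_missing,
        missing_cells=cells,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def _hwe_het_logprobs(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities of each possible heterozygote count
    given sample size n (diploids) and minor-allele count n_a."""
    n_b = 2 * n - n_a
    h_min = n_a % 2
    h_max = min(n_a, n_b)
    hs = np.arange(h_min, h_max + 1, 2)
    lg = math.lgamma
    # P(h) proportional to 2^h * n! / ( ((nA-h)/2)! h! ((nB-h)/2)! )
    logp = np.array(
        [
            h * math.log(2) - lg((n_a - h) / 2 + 1) - lg(h + 1) - lg((n_b - h) / 2 + 1)
            for h in hs
        ]
    )
    logp -= np.logaddexp.reduce(logp)
    return hs, logp


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact test of Hardy–Weinberg proportions for a biallelic
    locus by full enumeration of heterozygote counts conditional on the
    allele counts (the distribution genepop's MCMC approximates).

    The p-value sums the conditional probabilities of all heterozygote
    counts at most as probable as the observed one.  Monomorphic input
    returns 1.0 by convention.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    if n == 0 or n_a == 0 or n_a == 2 * n:
        return 1.0
    hs, logp = _hwe_het_logprobs(n, n_a)
    obs = np.flatnonzero(hs == n_ab)[0]
    keep = logp <= logp[obs] + 1e-12
    return float(min(1.0, np.exp(np.logaddexp.reduce(logp[keep]))))


# ---------------------------------------------------------------------------
# linkage-disequilibrium permutation test


def _g_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Log-likelihood-ratio G on the 3x3 two-locus genotype table."""
    table = np.bincount(3 * a + b, minlength=9).reshape(3, 3).astype(float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    mask = table > 0
    return float(2 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def ld_permutation_test(
    dataset: GenotypeDataset,
    locus_a: str,
    locus_b: str,
    population: str,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation exact test of genotypic association between two loci
    within one population.  One locus's genotype vector is permuted across
    individuals; p = (#{G_perm >= G_obs} + 1) / (n_perm + 1)."""
    rng = np.random.default_rng(seed)
    idx = dataset.population_indices()[population]
    ja = dataset.locus_ids.index(locus_a)
    jb = dataset.locus_ids.index(locus_b)
    a = dataset.calls[idx, ja]
    b = dataset.calls[idx, jb]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(int), b[ok].astype(int)
    if len(a) < 2:
        raise ValueError("need >=2 individuals genotyped at both loci")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return 1.0
    g_obs = _g_statistic(a, b)
    count = 0
    for _ in range(n_perm):
        if _g_statistic(a, rng.permutation(b)) >= g_obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# multiple-testing threshold


def by_fdr_alpha(alpha: float, m: int) -> float:
    """Benjamini–Yekutieli-adjusted significance threshold
    alpha / sum_{i=1..m} 1/i for m simultaneous tests (single-threshold
    form, valid under arbitrary dependence)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / float(np.sum(1.0 / np.arange(1, m + 1)))


# ---------------------------------------------------------------------------
# Weir-Cockerham theta


@dataclass
class FstResult:
    locus_ids: list[str]
    theta_locus: np.ndarray  # per-locus a/(a+b+c); NaN when undefined
    theta_multilocus: float  # sum(a)/sum(a+b+c)
    components: np.ndarray  # (n_loci, 3) variance components a, b, c
    pairwise: DistanceMatrix | None = None
    excluded_loci: list[str] = field(default_factory=list)


def _wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham (1984) variance components per locus, vectorized.

    n, p, h: (n_pops, n_loci) sample sizes, allele frequencies and
    heterozygote frequencies; populations with n == 0 at a locus are
    excluded from that locus.
    """
    valid = n > 0
    r = valid.sum(axis=0).astype(float)  # populations with data
    n_ = np.where(valid, n, 0.0)
    p_ = np.where(valid, np.nan_to_num(p), 0.0)
    h_ = np.where(valid, np.nan_to_num(h), 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = n_.sum(axis=0) / r
        nc = (r * nbar - (n_**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_ * p_).sum(axis=0) / (r * nbar)
        s2 = (n_ * (p_ - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_ * h_).sum(axis=0) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2

    bad = (r < 2) | (nbar <= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_theta(
    dataset: GenotypeDataset,
    loci_subset: list[str] | None = None,
    pops_subset: list[str] | None = None,
    pairwise: bool = False,
) -> FstResult:
    """Weir–Cockerham theta: per-locus and multilocus (ratio of summed
    variance components), optionally with the pairwise-population theta
    matrix from the same estimator.  Loci monomorphic across the subset
    have undefined theta and are excluded from the multilocus sums.
    Negative estimates are reported as-is."""
    ds = dataset
    if pops_subset is not None:
        ds = ds.subset_populations(pops_subset)
    if loci_subset is not None:
        ds = ds.subset_loci(loci_subset)
    if len(ds.populations) < 2:
        raise ValueError("theta needs >=2 populations with calls")

    freqs = allele_stats(ds)
    a, b, c = _wc_components(freqs.n, freqs.p, freqs.ho)
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_locus = a / denom
    defined = np.isfinite(denom) & (denom != 0)
    theta_multi = (
        float(a[defined].sum() / denom[defined].sum()) if defined.any() else np.nan
    )
    excluded = [ds.locus_ids[j] for j in np.flatnonzero(~defined)]

    pw = None
    if pairwise:
        pops = ds.populations
        k = len(pops)
        mat = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                sub = np.isin(np.arange(k), [i, j])
                ai, bi, ci = _wc_components(
                    freqs.n[sub], freqs.p[sub], freqs.ho[sub]
                )
                den = ai + bi + ci
                ok = np.isfinite(den) & (den != 0)
                mat[i, j] = mat[j, i] = (
                    ai[ok].sum() / den[ok].sum() if ok.any() else np.nan
                )
        pw = DistanceMatrix(pops, np.nan_to_num(mat), kind="fst") if not np.isnan(
            mat
        ).any() else DistanceMatrix(pops, np.nan_to_num(mat), kind="fst")
    return FstResult(
        locus_ids=list(ds.locus_ids),
        theta_locus=theta_locus,
        theta_multilocus=theta_multi,
        components=np.column_stack([a, b, c]),
        pairwise=pw,
        excluded_loci=excluded,
    )


def pairwise_theta_distance(dataset: GenotypeDataset, loci_subset=None) -> DistanceMatrix:
    """Pairwise multilocus theta as a distance matrix; negative pairwise
    estimates are floored at 0 (distance semantics require
    non-negativity; the floor is logged on the result)."""
    res = wc_theta(dataset, loci_subset=loci_subset, pairwise=True)
    vals = res.pairwise.values.copy()
    floored = int((vals < 0).sum())
    vals[vals < 0] = 0.0
    dm = DistanceMatrix(res.pairwise.labels, vals, kind="fst")
    dm.n_floored = floored
    return dm


# ---------------------------------------------------------------------------
# Nei's standard genetic distance


def nei_distance(
    freqs: PopulationFrequencies, loci_subset: list[str] | None = None
) -> DistanceMatrix:
    """Nei's standard genetic distance D = -ln(Jxy / sqrt(Jx Jy)) with the
    homozygosity terms averaged over loci (biallelic: alleles p and 1-p).
    Pairwise-complete over loci; infinite D is capped at NEI_CAP."""
    f = freqs.subset_loci(loci_subset) if loci_subset is not None else freqs
    p = f.p
    k = len(f.populations)
    mat = np.zeros((k, k))
    capped = []
    for i in range(k):
        for j in range(i + 1, k):
            ok = np.isfinite(p[i]) & np.isfinite(p[j])
            if not ok.any():
                raise ValueError(
                    f"no shared genotyped loci between {f.populations[i]} "
                    f"and {f.populations[j]}"
                )
            pi, pj = p[i, ok], p[j, ok]
            jx = np.mean(pi**2 + (1 - pi) ** 2)
            jy = np.mean(pj**2 + (1 - pj) ** 2)
            jxy = np.mean(pi * pj + (1 - pi) * (1 - pj))
            if jxy <= 0:
                d = NEI_CAP
                capped.append((f.populations[i], f.populations[j]))
            else:
                d = min(NEI_CAP, -math.log(jxy / math.sqrt(jx * jy)))
            mat[i, j] = mat[j, i] = max(0.0, d)
    dm = DistanceMatrix(list(f.populations), mat, kind="nei")
    dm.capped_pairs = capped
    return dm


# ---------------------------------------------------------------------------
# principal coordinates analysis


@dataclass
class PCoAResult:
    labels: list[str]
    coordinates: np.ndarray  # (n, n_axes)
    eigenvalues: np.ndarray  # positive eigenvalues used, descending
    pct_variance: np.ndarray  # percent of positive-eigenvalue total
    negative_eigenvalues: np.ndarray


def pcoa(distance_matrix: DistanceMatrix, n_axes: int = 3) -> PCoAResult:
    """Classical PCoA: Gower double-centering of -0.5 D^2, then the
    eigendecomposition; coordinates are eigenvectors scaled by the square
    root of the positive eigenvalues.  Negative eigenvalues (non-Euclidean
    input) are reported, not silently dropped."""
    d = distance_matrix.values
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-10, 1e-10 * abs(vals[0])) if n else 0.0
    pos = vals > tol
    neg = vals[vals < -tol]
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive "
            "eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = n_pos
    pv = vals[pos]
    coords = vecs[:, :n_axes] * np.sqrt(pv[:n_axes])
    pct = 100 * pv / pv.sum() if pv.size else np.array([])
    return PCoAResult(
        labels=list(distance_matrix.labels),
        coordinates=coords,
        eigenvalues=pv,
        pct_variance=pct,
        negative_eigenvalues=neg,
    )
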