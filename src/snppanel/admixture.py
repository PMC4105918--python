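"""Neutral-structure controls: a maximum-likelihood admixture model
fitted by EM, Evanno delta-K model choice over restarts, label-switching
alignment of replicate Q matrices, the coastal/inland-style lineage
split, and assembly of the Q + eigenvector control variables used in the
association tests.

The admixture model is the standard one: individual i draws each of its
two gene copies at locus l from cluster k with probability q_ik, and the
copy is the counted allele with probability f_kl, so the genotype is
Binomial(2, sum_k q_ik f_kl).  The Bayesian MCMC engines commonly used to
fit this model are replaced here by EM with random restarts — same model
family, deterministic given a seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset
from .popgen import pairwise_theta_distance, pcoa

_EPS = 1e-9


@dataclass
class QMatrix:
    unit: str  # "individual" or "population"
    labels: list[str]
    q: np.ndarray  # (n_units, K), rows sum to 1
    k: int
    replicate: int = 0
    loglik: float = np.nan
    converged: bool = True
    loglik_trace: np.ndarray | None = None
    allele_freqs: np.ndarray | None = None  # (K, n_loci)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")
        if self.q.min() < -1e-12 or self.q.max() > 1 + 1e-12:
            raise ValueError("Q entries must lie in [0, 1]")

    def population_means(self, population_labels: list[str]) -> "QMatrix":
        pops = list(dict.fromkeys(population_labels))
        labels = np.asarray(population_labels)
        rows = np.vstack([self.q[labels == p].mean(axis=0) for p in pops])
        rows /= rows.sum(axis=1, keepdims=True)
        return QMatrix("population", pops, rows, self.k, self.replicate, self.loglik)


def _em_once(
    g: np.ndarray, mask: np.ndarray, k: int, rng: np.random.Generator,
    max_iter: int, tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    n, L = g.shape
    g0 = np.where(mask, g, 0.0)
    g2 = np.where(mask, 2.0 - g, 0.0)
    l_i = mask.sum(axis=1).astype(float)
    # log C(2, g) constant of the binomial likelihood
    const = float(np.sum(np.where(mask & (g == 1), np.log(2.0), 0.0)))

    q = rng.dirichlet(np.ones(k), size=n)
    pooled = g0.sum(axis=0) / np.maximum(1.0, 2 * mask.sum(axis=0))
    f = np.clip(pooled[None, :] + rng.normal(0, 0.1, (k, L)), 0.05, 0.95)

    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        w = np.clip(q @ f, _EPS, 1 - _EPS)
        ll = const + float(np.sum(g0 * np.log(w) + g2 * np.log1p(-w)))
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
        r1 = g0 / w  # weight of "counted allele" copies
        r0 = g2 / (1 - w)
        a = q * (r1 @ f.T)  # (n, k) expected counted-allele copies per cluster
        b = q * (r0 @ (1 - f).T)
        q = (a + b) / (2 * l_i)[:, None]
        q = np.clip(q, _EPS, None)
        q /= q.sum(axis=1, keepdims=True)
        num = f * (q.T @ r1)
        den = num + (1 - f) * (q.T @ r0)
        f = np.clip(num / np.maximum(den, _EPS), _EPS, 1 - _EPS)
    return q, f, np.asarray(trace), converged


def admixture_em(
    dataset: GenotypeDataset,
    k: int,
    seed: int | np.random.Generator = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    restarts: int = 5,
) -> QMatrix:
    """Maximum-likelihood admixture fit, best of `restarts` random EM
    starts.  The log-likelihood is non-decreasing within each run (EM
    guarantee); non-convergence within max_iter is flagged, not fatal."""
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > len(dataset.populations):
        warnings.warn(
            f"K={k} exceeds the number of populations ({len(dataset.populations)})",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    g = dataset.calls.astype(float)
    mask = dataset.calls != MISSING
    g[~mask] = 0.0

    best = None
    for rep in range(restarts):
        q, f, trace, conv = _em_once(g, mask, k, rng, max_iter, tol)
        if best is None or trace[-1] > best.loglik:
            best = QMatrix(
                "individual", list(dataset.individual_ids), q, k,
                replicate=rep, loglik=float(trace[-1]), converged=conv,
                loglik_trace=trace, allele_freqs=f,
            )
    return best


def select_k(
    runs: dict[int, list[float]], k_range: list[int] | None = None
) -> tuple[pd.DataFrame, int | None]:
    """Evanno delta-K over replicate log-likelihoods.

    L'(K) = mean L(K) - mean L(K-1); |L''(K)| = |L'(K+1) - L'(K)|;
    delta-K = |L''(K)| / sd(L(K)), defined for interior K only.  Returns
    the table and the arg-max K (None when every delta-K is ~0, i.e. the
    likelihood surface is flat and K is indeterminate).
    """
    ks = sorted(k_range or runs)
    if len(ks) < 3:
        raise ValueError("need a contiguous K range of at least 3 values")
    for k in ks:
        if len(runs[k]) < 1:
            raise ValueError(f"no replicates for K={k}")
    mean = {k: float(np.mean(runs[k])) for k in ks}
    sd = {k: float(np.std(runs[k], ddof=1)) if len(runs[k]) > 1 else 0.0 for k in ks}
    rows = []
    for i, k in enumerate(ks[1:-1], start=1):
        lp = mean[ks[i]] - mean[ks[i - 1]]
        lp_next = mean[ks[i + 1]] - mean[ks[i]]
        l2 = abs(lp_next - lp)
        dk = np.inf if sd[k] == 0 else l2 / sd[k]
        rows.append({"K": k, "mean_loglik": mean[k], "sd_loglik": sd[k],
                     "abs_l2": l2, "delta_k": dk})
    table = pd.DataFrame(rows)
    finite = table.replace(np.inf, np.nan)
    if np.nanmax(np.abs(finite["abs_l2"])) < 1e-9:
        return table, None
    chosen = int(table.loc[table["delta_k"].idxmax(), "K"])
    return table, chosen


def align_replicates(q_list: list[QMatrix]) -> tuple[list[QMatrix], QMatrix]:
    """Resolve label switching across replicate Q matrices.

    Each replicate is aligned to the first by the column permutation
    maximizing the similarity G = sum of elementwise products (exact
    search over K! permutations; K > 8 falls back to a greedy match with
    a warning).  Returns the aligned replicates and their mean Q.
    """
    if not q_list:
        raise ValueError("no replicates")
    k = q_list[0].k
    ref = q_list[0]
    aligned = [ref]
    for rep in q_list[1:]:
        if rep.k != k or rep.labels != ref.labels:
            raise ValueError("replicates must share unit set and K")
        if k <= 8:
            best_perm, best_g = None, -np.inf
            for perm in itertools.permutations(range(k)):
                gsim = float(np.sum(ref.q * rep.q[:, perm]))
                if gsim > best_g:
                    best_g, best_perm = gsim, perm
        else:
            warnings.warn("K > 8: greedy column matching instead of exact search", stacklevel=2)
            sim = ref.q.T @ rep.q
            best_perm, used = [], set()
            for i in range(k):
                j = max((j for j in range(k) if j not in used), key=lambda j: sim[i, j])
                best_perm.append(j)
                used.add(j)
            best_perm = tuple(best_perm)
        aligned.append(
            QMatrix(rep.unit, rep.labels, rep.q[:, best_perm], k, rep.replicate, rep.loglik)
        )
    mean_q = np.mean([a.q for a in aligned], axis=0)
    mean_q /= mean_q.sum(axis=1, keepdims=True)
    return aligned, QMatrix(ref.unit, ref.labels, mean_q, k)


def assign_lineage(
    dataset: GenotypeDataset, seed: int | np.random.Generator = 0,
    admixed_threshold: float = 0.7, restarts: int = 3,
) -> pd.DataFrame:
    """K=2 admixture split of populations into two lineages.

    Each population goes to the cluster holding the majority of its mean
    ancestry; populations whose maximum mean Q falls below
    admixed_threshold are flagged admixed (transition-zone populations).
    """
    if len(dataset.populations) < 2:
        raise ValueError("lineage assignment needs >=2 populations")
    fit = admixture_em(dataset, k=2, seed=seed, restarts=restarts)
    pop_q = fit.population_means(dataset.population_labels)
    lineage = np.where(pop_q.q[:, 0] > 0.5, "lineage1", "lineage2")
    max_q = pop_q.q.max(axis=1)
    return pd.DataFrame(
        {
            "population": pop_q.labels,
            "lineage": lineage,
            "max_mean_q": max_q,
            "admixed": max_q < admixed_threshold,
        }
    )


@dataclass
class ControlVariables:
    """Per-population neutral-structure covariates: mean admixture
    proportions for the chosen K and the first three PCoA eigenvectors of
    the neutral-locus pairwise-FST matrix."""

    populations: list[str]
    q: np.ndarray  # (n_pops, K)
    ev: np.ndarray  # (n_pops, <=3)
    k: int
    ev_pct_variance: np.ndarray = field(default_factory=lambda: np.array([]))

    def _rows(self, pops: list[str]) -> np.ndarray:
        pos = {p: i for i, p in enumerate(self.populations)}
        return np.array([pos[p] for p in pops], dtype=int)

    def q_matrix(self, pops: list[str]) -> np.ndarray:
        """Q columns as covariates: the last column is dropped because Q
        rows sum to one (perfect collinearity)."""
        return self.q[self._rows(pops), : max(1, self.k - 1)]

    def ev_matrix(self, pops: list[str]) -> np.ndarray:
        return self.ev[self._rows(pops), :]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"population": self.populations})
        for j in range(self.q.shape[1]):
            df[f"Q{j + 1}"] = self.q[:, j]
        for j in range(self.ev.shape[1]):
            df[f"EV{j + 1}"] = self.ev[:, j]
        return df


def build_controls(
    dataset: GenotypeDataset,
    neutral_loci: list[str],
    k: int,
    seed: int | np.random.Generator = 0,
    restarts: int = 3,
    n_ev: int = 3,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> ControlVariables:
    """Assemble the neutral-structure control variables from the
    putatively neutral locus panel: population-mean Q at the chosen K and
    EV1–EV3 of PCoA on pairwise multilocus theta."""
    ds = dataset.subset_loci(neutral_loci)
    fit = admixture_em(ds, k=k, seed=seed, restarts=restarts, max_iter=max_iter, tol=tol)
    pop_q = fit.population_means(ds.population_labels)
    dm = pairwise_theta_distance(ds)
    dm = dm.reorder(pop_q.labels)
    n_axes = min(n_ev, dm.n - 1)
    res = pcoa(dm, n_axes=n_axes)
    return ControlVariables(
        populations=pop_q.labels,
        q=pop_q.q,
        ev=res.coordinates,
        k=k,
        ev_pct_variance=res.pct_variance[: res.coordinates.shape[1]],
    )
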