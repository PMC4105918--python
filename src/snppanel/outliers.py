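"""FDIST-style FST-outlier detection.

A finite island model (symmetric migration among n_demes demes) is
simulated with the structured coalescent to build a null distribution of
(He, FST) pairs for neutral biallelic loci; the migration parameter is
calibrated by bisection so the simulated mean FST matches the observed
multilocus theta.  Each observed locus gets a conditional p-value from
the FST distribution of the He-nearest null loci, and loci beyond the
1% / 99% quantiles are flagged as putatively under balancing or
directional selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .popgen import _wc_components

_DEME_SIZE = 1000.0  # diploid deme size; only the product with m matters


@dataclass
class NullDistribution:
    he: np.ndarray
    fst: np.ndarray
    n_demes: int
    migration: float  # M = 4*N*m, total scaled immigration per deme
    sample_spec: list[tuple[int, int]]  # (deme index, diploids sampled)
    target_fst: float
    mean_fst: float
    seed: int
    n_requested: int = 0

    @property
    def n_loci(self) -> int:
        return len(self.he)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"he": self.he, "fst": self.fst})

    def save(self, path) -> None:
        """Cache as TSV with the island-model parameters in the header."""
        import json

        meta = {
            "n_demes": self.n_demes, "migration": self.migration,
            "sample_spec": self.sample_spec, "target_fst": self.target_fst,
            "mean_fst": self.mean_fst, "seed": self.seed,
            "n_requested": self.n_requested,
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(meta) + "\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "NullDistribution":
        import json

        with open(path) as fh:
            meta = json.loads(fh.readline().lstrip("# "))
            df = pd.read_csv(fh, sep="\t")
        return cls(
            he=df["he"].to_numpy(), fst=df["fst"].to_numpy(),
            sample_spec=[tuple(s) for s in meta.pop("sample_spec")], **meta,
        )


def default_sample_spec(n_populations: int, median_n: int, n_demes: int = 100) -> list[tuple[int, int]]:
    """Sampled demes mirror the observed design: one deme per observed
    population (capped at n_demes), each sampled at the observed median
    population size."""
    k = min(n_populations, n_demes)
    return [(i, median_n) for i in range(k)]


def _island_demography(n_demes: int, migration: float) -> msprime.Demography:
    dem = msprime.Demography.island_model(
        initial_size=[_DEME_SIZE] * n_demes,
        migration_rate=migration / (4 * _DEME_SIZE * (n_demes - 1)),
    )
    return dem


def _pairs_from_calls(
    calls: np.ndarray, sizes: np.ndarray, pop_of: np.ndarray
) -> tuple[float, float]:
    """(He, theta) for one simulated locus from per-diploid derived counts."""
    n_pops = len(sizes)
    p = np.zeros(n_pops)
    h = np.zeros(n_pops)
    for k in range(n_pops):
        c = calls[pop_of == k]
        p[k] = c.sum() / (2 * len(c))
        h[k] = np.mean(c == 1)
    he = float(np.mean(2 * p * (1 - p)))
    a, b, cc = _wc_components(sizes[:, None].astype(float), p[:, None], h[:, None])
    denom = float(a[0] + b[0] + cc[0])
    fst = float(a[0]) / denom if denom != 0 else np.nan
    return he, fst


def _simulate_pairs(
    migration: float,
    n_demes: int,
    sample_spec: list[tuple[int, int]],
    n_loci: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(He, theta) for n_loci independent neutral loci.

    Each locus is one island-model coalescent genealogy; a single
    mutation is placed uniformly along the total branch length
    (infinite-sites, conditioned on polymorphism in the sample),
    genotypes are read off the two gene copies of each sampled diploid,
    and theta comes from the same Weir–Cockerham components as the
    observed data.  He is the mean within-deme expected heterozygosity.
    """
    from .islandcoal import simulate_locus

    sizes = np.array([n for _, n in sample_spec])
    pop_of = np.repeat(np.arange(len(sample_spec)), sizes)
    copy_deme = np.repeat(
        np.array([d for d, _ in sample_spec]), 2 * sizes
    ).astype(np.int64)
    rng = np.random.default_rng(seed)
    locus_seeds = rng.integers(1, 2**31 - 1, size=n_loci)
    he_out = np.empty(n_loci)
    fst_out = np.empty(n_loci)
    for i in range(n_loci):
        state = simulate_locus(copy_deme, n_demes, migration, int(locus_seeds[i]))
        calls = state.reshape(-1, 2).sum(axis=1)
        he_out[i], fst_out[i] = _pairs_from_calls(calls, sizes, pop_of)
    ok = np.isfinite(fst_out) & (he_out > 0)
    return he_out[ok], fst_out[ok]


def _simulate_pairs_msprime(
    migration: float,
    n_demes: int,
    sample_spec: list[tuple[int, int]],
    n_loci: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference implementation of the same null via msprime's general
    structured coalescent; far slower, kept as an independent
    cross-check of the island-model engine."""
    dem = _island_demography(n_demes, migration)
    samples = [
        msprime.SampleSet(n, population=f"pop_{d}", ploidy=2) for d, n in sample_spec
    ]
    rng = np.random.default_rng(seed)
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=1,
        num_replicates=n_loci,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    sizes = np.array([n for _, n in sample_spec])
    pop_of = np.repeat(np.arange(len(sample_spec)), sizes)
    he_out = np.empty(n_loci)
    fst_out = np.empty(n_loci)
    for i, ts in enumerate(reps):
        tree = ts.first()
        nodes, lengths = [], []
        for u in tree.nodes():
            bl = tree.branch_length(u)
            if bl > 0:
                nodes.append(u)
                lengths.append(bl)
        lengths = np.asarray(lengths)
        u = nodes[rng.choice(len(nodes), p=lengths / lengths.sum())]
        below = set(tree.samples(u))
        carries = np.fromiter((s in below for s in ts.samples()), dtype=int)
        calls = carries.reshape(-1, 2).sum(axis=1)
        he_out[i], fst_out[i] = _pairs_from_calls(calls, sizes, pop_of)
    ok = np.isfinite(fst_out) & (he_out > 0)
    return he_out[ok], fst_out[ok]


def _mean_fst(he: np.ndarray, fst: np.ndarray) -> float:
    return float(np.mean(fst))


def calibrate_migration(
    target_fst: float,
    n_demes: int,
    sample_spec: list[tuple[int, int]],
    seed: int = 0,
    tol: float = 0.005,
    n_pilot: int = 2000,
    max_iter: int = 40,
) -> float:
    """Bisection on the scaled migration parameter M = 4*N*m until the
    simulated mean FST of a pilot batch is within tol of target_fst."""
    if not 0 < target_fst < 0.9:
        raise ValueError("target_fst must be in (0, 0.9)")
    # island-model expectation FST ~ 1/(1 + M (d/(d-1))^2) brackets the search
    ratio = (n_demes / (n_demes - 1)) ** 2

    def simulate_mean(m: float, it: int) -> float:
        he, fst = _simulate_pairs(m, n_demes, sample_spec, n_pilot, seed + 1000 * it)
        return _mean_fst(he, fst)

    m_lo = max(1e-3, (1 / target_fst - 1) / ratio / 10)  # higher FST side
    m_hi = (1 / target_fst - 1) / ratio * 10
    f_lo = simulate_mean(m_lo, 0)
    f_hi = simulate_mean(m_hi, 1)
    if not (f_hi < target_fst < f_lo):
        raise RuntimeError(
            f"target FST {target_fst} not bracketed: "
            f"FST(M={m_lo:.3g})={f_lo:.4f}, FST(M={m_hi:.3g})={f_hi:.4f}"
        )
    for it in range(2, max_iter + 2):
        m_mid = np.sqrt(m_lo * m_hi)  # bisect in log space
        f_mid = simulate_mean(m_mid, it)
        if abs(f_mid - target_fst) <= tol:
            return float(m_mid)
        if f_mid > target_fst:
            m_lo = m_mid
        else:
            m_hi = m_mid
    raise RuntimeError(
        f"calibration did not converge in {max_iter} iterations "
        f"(last bracket M in [{m_lo:.4g}, {m_hi:.4g}])"
    )


def simulate_null(
    migration: float,
    n_demes: int = 100,
    sample_spec: list[tuple[int, int]] | None = None,
    n_loci: int = 50_000,
    seed: int = 0,
    target_fst: float = np.nan,
) -> NullDistribution:
    """Island-model null distribution of (He, FST) pairs."""
    if sample_spec is None:
        sample_spec = default_sample_spec(n_demes, 10, n_demes)
    he, fst = _simulate_pairs(migration, n_demes, sample_spec, n_loci, seed)
    return NullDistribution(
        he=he,
        fst=fst,
        n_demes=n_demes,
        migration=migration,
        sample_spec=list(sample_spec),
        target_fst=target_fst,
        mean_fst=_mean_fst(he, fst),
        seed=seed,
        n_requested=n_loci,
    )


@dataclass
class OutlierResult:
    locus_ids: list[str]
    he: np.ndarray
    fst: np.ndarray
    p: np.ndarray  # P(null FST >= observed | He window)
    flags: list[str]  # directional | balancing | none
    excluded: list[tuple[str, str]] = field(default_factory=list)
    window_k: int = 2000

    def directional_loci(self) -> list[str]:
        return [l for l, f in zip(self.locus_ids, self.flags) if f == "directional"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"locus": self.locus_ids, "he": self.he, "fst": self.fst,
             "p": self.p, "flag": self.flags}
        )


def outlier_test(
    locus_ids: list[str],
    observed_he: np.ndarray,
    observed_fst: np.ndarray,
    null: NullDistribution,
    window_k: int = 2000,
    lower_q: float = 0.01,
    upper_q: float = 0.99,
) -> OutlierResult:
    """Conditional outlier p-values against the island-model null.

    For each observed locus the window_k null loci nearest in He form the
    conditional distribution; p is the fraction of those with FST at
    least the observed value.  p <= lower_q flags directional selection,
    p >= upper_q flags balancing selection.  Monomorphic observed loci
    (He = 0 or undefined FST) are excluded and reported.
    """
    observed_he = np.asarray(observed_he, dtype=float)
    observed_fst = np.asarray(observed_fst, dtype=float)
    k = min(window_k, null.n_loci)
    order = np.argsort(null.he)
    he_sorted = null.he[order]
    fst_sorted = null.fst[order]

    ids, he_o, fst_o, pvals, flags, excluded = [], [], [], [], [], []
    for locus, he, fst in zip(locus_ids, observed_he, observed_fst):
        if not np.isfinite(fst) or not np.isfinite(he) or he <= 0:
            excluded.append((locus, "monomorphic"))
            continue
        # nearest-k window by |He difference| over the He-sorted null
        j = np.searchsorted(he_sorted, he)
        lo = max(0, j - k)
        hi = min(null.n_loci, j + k)
        window = np.arange(lo, hi)
        d = np.abs(he_sorted[window] - he)
        nearest = window[np.argsort(d, kind="stable")[:k]]
        p = float(np.mean(fst_sorted[nearest] >= fst - 1e-12))
        ids.append(locus)
        he_o.append(he)
        fst_o.append(fst)
        pvals.append(p)
        if p <= lower_q:
            flags.append("directional")
        elif p >= upper_q:
            flags.append("balancing")
        else:
            flags.append("none")
    return OutlierResult(
        locus_ids=ids,
        he=np.asarray(he_o),
        fst=np.asarray(fst_o),
        p=np.asarray(pvals),
        flags=flags,
        excluded=excluded,
        window_k=k,
    )
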