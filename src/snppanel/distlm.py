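"""Distance-based multivariate multiple regression (DISTLM) with forward
selection and permutation of residuals under a reduced model.

The response is a Gower-centered inner-product matrix G built from a
(per-locus pairwise-FST) distance matrix; predictors are per-population
variable values entered individually or in declared sets.  The pseudo-F
statistic is the McArdle–Anderson trace ratio, and conditional p-values
come from Freedman–Lane permutation of the reduced-model residual matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DistanceMatrix


def gower_center(d: np.ndarray | DistanceMatrix) -> np.ndarray:
    """G = (I - 11'/n) (-0.5 d_ij^2) (I - 11'/n)."""
    if isinstance(d, DistanceMatrix):
        d = d.values
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def lingoes_correct(g: np.ndarray) -> np.ndarray:
    """Correction for negative eigenvalues of a Gower-centered matrix
    from a non-Euclidean distance (e.g. pairwise FST): adding a constant
    to the squared off-diagonal distances shifts every nontrivial
    eigenvalue of G up by that constant, making G positive
    semi-definite so that the trace partition behaves (explained
    proportions in [0, 1], residual trace non-negative).  Euclidean
    input passes through unchanged."""
    vals = np.linalg.eigvalsh((g + g.T) / 2)
    lam_min = vals[0]
    if lam_min >= -1e-12 * max(1.0, abs(vals[-1])):
        return g
    n = g.shape[0]
    jc = np.eye(n) - np.ones((n, n)) / n
    return g + (-lam_min) * jc


def _center(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    return x - x.mean(axis=0)


def _drop_collinear(x: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Keep a maximal independent column subset (QR with pivoting)."""
    if x.size == 0:
        return x
    # greedy rank-revealing accumulation; n is small so this is cheap
    keep: list[int] = []
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(x).max())) > len(keep):
            keep.append(j)
    return x[:, keep]


def _hat(x: np.ndarray) -> np.ndarray:
    if x.size == 0:
        n = x.shape[0]
        return np.zeros((n, n))
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def pseudo_f(
    g: np.ndarray,
    x_candidate: np.ndarray,
    x_covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """McArdle–Anderson pseudo-F of the candidate columns given the
    covariates, and the proportion of trace(G) the full fit explains.

    F = [tr((H - Hr) G (H - Hr)) / q] / [tr((I - H) G (I - H)) / (n - m - 1)]
    with H the hat matrix of [covariates, candidate], Hr of the
    covariates alone, q the candidate column count and m the total fitted
    column count.  Collinear columns are dropped with a warning-free QR
    screen (the caller logs).
    """
    n = g.shape[0]
    xc = _center(x_candidate)
    cov = _center(x_covariates) if x_covariates is not None and np.size(x_covariates) else np.empty((n, 0))
    cov = _drop_collinear(cov)
    full = _drop_collinear(np.column_stack([cov, xc]) if cov.size else xc)
    q = full.shape[1] - cov.shape[1]
    if q == 0:
        return 0.0, 0.0
    h = _hat(full)
    hr = _hat(cov)
    m = full.shape[1]
    diff = h - hr
    resid = np.eye(n) - h
    num = np.trace(diff @ g @ diff) / q
    den = np.trace(resid @ g @ resid) / (n - m - 1)
    tr_g = np.trace(g)
    prop = tr_g and np.trace(h @ g @ h) / tr_g
    # a perfect fit leaves a numerically-zero residual trace
    tol = 1e-12 * max(1.0, abs(tr_g))
    if den <= tol:
        return (np.inf if num > tol else 0.0), float(prop)
    return float(num / den), float(prop)


def permutation_p(
    g: np.ndarray,
    x_candidate: np.ndarray,
    x_covariates: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> float:
    """Freedman–Lane conditional permutation p-value.

    The reduced-model residual matrix R = (I - Hr) G (I - Hr) is permuted
    jointly in rows and columns and recombined with the fitted part
    Hr G Hr; p = (#{F* >= F} + 1) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    n = g.shape[0]
    cov = _center(x_covariates) if x_covariates is not None and np.size(x_covariates) else np.empty((n, 0))
    cov = _drop_collinear(cov)
    hr = _hat(cov)
    ir = np.eye(n) - hr
    fitted = hr @ g @ hr
    resid = ir @ g @ ir
    f_obs, _ = pseudo_f(g, x_candidate, cov if cov.size else None)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        g_star = fitted + resid[np.ix_(perm, perm)]
        f_star, _ = pseudo_f(g_star, x_candidate, cov if cov.size else None)
        if f_star >= f_obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


@dataclass
class DistlmResult:
    """Forward-selection trace for one response matrix."""

    locus: str
    steps: list[dict] = field(default_factory=list)  # name, pseudo_f, p, cum_prop
    top_variable: str | None = None  # first selection with p < 0.05
    top_is_control: bool = False
    skipped_reason: str | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.steps)
        if not df.empty:
            df.insert(0, "locus", self.locus)
        return df


def forward_select(
    g: np.ndarray,
    variable_sets: dict[str, np.ndarray],
    control_sets: set[str] | None = None,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    max_steps: int | None = None,
    alpha: float = 0.05,
    locus: str = "",
    force_controls_first: bool = False,
) -> DistlmResult:
    """Stepwise forward selection over named variables/sets.

    At each step the most informative candidate enters: the one whose
    addition gives the model the largest adjusted R-squared
    (1 - (1 - R2)(n - 1)/(n - m - 1), the selection criterion
    recommended for forward selection over sets of unequal size, since
    raw explained variation is biased toward larger sets).  The entering
    candidate's conditional pseudo-F and permutation p are recorded, and
    selection stops when its p >= alpha or max_steps is reached.  Ties
    break by declaration order.
    The first selected candidate with p < alpha is the top-ranked
    variable; top_is_control records whether it belongs to control_sets.
    With force_controls_first the control sets are entered as covariates
    before any free competition.
    """
    if not variable_sets:
        raise ValueError("empty candidate list")
    rng = np.random.default_rng(seed)
    control_sets = control_sets or set()
    names = list(variable_sets)
    mats = {k: _center(v) for k, v in variable_sets.items()}
    n = g.shape[0]
    selected: list[str] = []
    cov = np.empty((n, 0))
    result = DistlmResult(locus=locus)
    if force_controls_first:
        for name in names:
            if name in control_sets:
                cov = np.column_stack([cov, mats[name]]) if cov.size else mats[name]
                selected.append(name)
        names = [k for k in names if k not in control_sets]
    max_steps = max_steps or len(names)
    for _ in range(max_steps):
        remaining = [k for k in names if k not in selected]
        if not remaining:
            break
        best_name, best_adj, best_prop = None, -np.inf, np.nan
        for k in remaining:
            trial = np.column_stack([cov, mats[k]]) if cov.size else mats[k]
            trial = _drop_collinear(trial)
            m = trial.shape[1]
            if n - m - 1 < 1:
                continue
            _, prop = pseudo_f(g, trial)
            adj = 1 - (1 - prop) * (n - 1) / (n - m - 1)
            if adj > best_adj + 1e-12:  # ties keep the earlier declaration
                best_adj = adj
                best_name = k
                best_prop = prop
        if best_name is None:
            break
        best_f, _ = pseudo_f(g, mats[best_name], cov if cov.size else None)
        p = permutation_p(g, mats[best_name], cov if cov.size else None, n_perm=n_perm, seed=rng)
        new_cov = np.column_stack([cov, mats[best_name]]) if cov.size else mats[best_name]
        cum_prop = best_prop
        result.steps.append(
            {"name": best_name, "pseudo_f": best_f, "p": p, "cum_prop": cum_prop}
        )
        if p >= alpha:
            break
        if result.top_variable is None:
            result.top_variable = best_name
            result.top_is_control = best_name in control_sets
        selected.append(best_name)
        cov = new_cov
    return result


def per_locus_distlm(
    dataset,
    locus: str,
    env,
    controls,
    mode: str = "sets",
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    variables: list[str] | None = None,
) -> DistlmResult:
    """Forward DISTLM on one locus's pairwise-FST response matrix.

    mode='sets' enters temperature, precipitation, geography and the Q
    and EV control blocks as sets; mode='individual' enters every
    variable singly (Q and EV columns remain their own candidates).
    Loci polymorphic in fewer than 4 populations are skipped.
    """
    from .assoc import DEFAULT_VARIABLES, VARIABLE_SETS
    from .popgen import pairwise_theta_distance

    ds = dataset.subset_loci([locus])
    freqs_p = []
    for pop, idx in ds.population_indices().items():
        c = ds.calls[idx, 0]
        c = c[c != -1]
        freqs_p.append((pop, len(np.unique(c)) > 1))
    n_poly = sum(poly for _, poly in freqs_p)
    if n_poly < 4:
        return DistlmResult(locus=locus, skipped_reason=f"polymorphic in {n_poly} populations")

    dm = pairwise_theta_distance(dataset, loci_subset=[locus])
    pops = dm.labels
    g = lingoes_correct(gower_center(dm))

    env = env.subset(pops)
    q_cols = controls.q_matrix(pops)  # (n_pops, K-1): last column dropped
    ev_cols = controls.ev_matrix(pops)
    variables = variables or [v for v in DEFAULT_VARIABLES if v in env.table.columns]

    sets: dict[str, np.ndarray] = {}
    controls_names: set[str] = set()
    if mode == "sets":
        for set_name, members in VARIABLE_SETS.items():
            cols = [v for v in members if v in variables]
            if cols:
                sets[set_name] = np.column_stack(
                    [env.variable(v).to_numpy(dtype=float) for v in cols]
                )
        sets["Q"] = q_cols
        sets["EV"] = ev_cols
        controls_names = {"Q", "EV"}
    elif mode == "individual":
        for v in variables:
            sets[v] = env.variable(v).to_numpy(dtype=float)[:, None]
        for k in range(q_cols.shape[1]):
            sets[f"Q{k + 1}"] = q_cols[:, [k]]
            controls_names.add(f"Q{k + 1}")
        for k in range(ev_cols.shape[1]):
            sets[f"EV{k + 1}"] = ev_cols[:, [k]]
            controls_names.add(f"EV{k + 1}")
    else:
        raise ValueError("mode must be 'individual' or 'sets'")

    return forward_select(
        g, sets, control_sets=controls_names, n_perm=n_perm, seed=seed, locus=locus
    )
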