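"""Tree building and climate ranking for the neutral-vs-candidate
comparison: Nei-distance neighbor-joining, locus-bootstrap majority-rule
consensus with supports, the five-variable climate ranking, and tree
congruence reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .datatypes import DistanceMatrix
from .popgen import PopulationFrequencies, nei_distance


def neighbor_joining(
    dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Saitou–Nei agglomeration with the Studier–Keppler Q criterion.

    Negative branch lengths are clamped to zero with the deficit added to
    the sibling edge; the number of clamps is recorded on the returned
    tree as ``clamp_count``.  The result is unrooted (trifurcating seed
    node).
    """
    labels = list(dm.labels)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate labels")
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs >=3 labels")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("distances must be finite")

    tns = taxon_namespace or dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        leaf = dendropy.Node()
        leaf.taxon = tns.get_taxon(lab) or tns.new_taxon(lab)
        nodes.append(leaf)

    d = dm.values.astype(float).copy()
    active = list(range(n))
    clamp_count = 0

    def attach(parent, child_i, child_j, li, lj):
        nonlocal clamp_count
        # clamp negatives, moving the deficit onto the sibling edge
        if li < 0:
            lj += li  # may itself go negative; re-clamped below
            li = 0.0
            clamp_count += 1
        if lj < 0:
            li = max(0.0, li + lj)
            lj = 0.0
            clamp_count += 1
        parent.add_child(nodes[child_i])
        nodes[child_i].edge.length = li
        parent.add_child(nodes[child_j])
        nodes[child_j].edge.length = lj

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        q = (r - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        gi, gj = active[i_loc], active[j_loc]
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (sums[i_loc] - sums[j_loc]) / (2 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        attach(parent, gi, gj, li, lj)
        # distances from the new node to the remaining taxa
        new_idx = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k_loc, gk in enumerate(active):
            if gk in (gi, gj):
                continue
            duk = 0.5 * (d[gi, gk] + d[gj, gk] - dij)
            d[new_idx, gk] = d[gk, new_idx] = duk
        active = [g for g in active if g not in (gi, gj)] + [new_idx]

    # closing star: three remaining nodes joined at the seed
    gi, gj, gk = active
    li = 0.5 * (d[gi, gj] + d[gi, gk] - d[gj, gk])
    lj = 0.5 * (d[gi, gj] + d[gj, gk] - d[gi, gk])
    lk = 0.5 * (d[gi, gk] + d[gj, gk] - d[gi, gj])
    seed = dendropy.Node()
    for g, ln in ((gi, li), (gj, lj), (gk, lk)):
        if ln < 0:
            clamp_count += 1
            ln = 0.0
        seed.add_child(nodes[g])
        nodes[g].edge.length = ln

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    tree.clamp_count = clamp_count
    return tree


def _split_counts(trees: list[dendropy.Tree]) -> tuple[dict[int, int], int]:
    counts: dict[int, int] = {}
    full = 0
    for t in trees:
        t.encode_bipartitions()
        full = t.taxon_namespace.all_taxa_bitmask()
        for bip in t.bipartition_encoding:
            mask = bip.split_bitmask
            if bip.is_trivial():
                continue
            counts[mask] = counts.get(mask, 0) + 1
    return counts, full


def _compatible(mask: int, chosen: list[int], full: int) -> bool:
    for m in chosen:
        inter = mask & m
        if inter != 0 and inter != mask and inter != m and (mask | m) != full:
            return False
    return True


def bootstrap_consensus(
    freqs: PopulationFrequencies,
    loci_panel: list[str],
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    extended: bool = True,
) -> dendropy.Tree:
    """Locus-bootstrap majority-rule consensus NJ tree with supports.

    Loci are resampled with replacement per replicate; each replicate
    yields a Nei-distance NJ tree.  Bipartitions above 50% replicate
    frequency form the consensus; with ``extended`` the remaining
    bipartitions are added greedily in frequency order where compatible.
    Supports are replicate percentages on internal nodes; branch lengths
    are copied from the full-data NJ tree where the edge occurs there.
    """
    if len(loci_panel) < 10:
        warnings.warn(
            f"bootstrapping over only {len(loci_panel)} loci; supports will "
            "be coarse",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace(freqs.populations)
    reps = []
    for _ in range(n_reps):
        sample = [loci_panel[i] for i in rng.integers(0, len(loci_panel), len(loci_panel))]
        reps.append(neighbor_joining(nei_distance(freqs, sample), taxon_namespace=tns))
    counts, full = _split_counts(reps)

    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    chosen: list[int] = []
    support: dict[int, float] = {}
    for mask, c in ordered:
        freq = 100.0 * c / n_reps
        if freq > 50.0 or (extended and _compatible(mask, chosen, full)):
            if _compatible(mask, chosen, full):
                chosen.append(mask)
                support[mask] = freq

    full_tree = neighbor_joining(nei_distance(freqs, loci_panel), taxon_namespace=tns)
    full_tree.encode_bipartitions()
    full_lengths = {
        bip.split_bitmask: edge.length
        for bip, edge in full_tree.bipartition_edge_map.items()
    }

    cons = dendropy.Tree.from_split_bitmasks(chosen, tns)
    cons.is_rooted = False
    cons.encode_bipartitions()
    for node in cons.postorder_node_iter():
        bip = node.edge.bipartition
        mask = bip.split_bitmask
        if node.is_leaf():
            node.edge.length = full_lengths.get(mask)
        elif node.parent_node is not None and not bip.is_trivial():
            node.label = str(int(round(support.get(mask, 100.0))))
            node.edge.length = full_lengths.get(mask)
    return cons


# ---------------------------------------------------------------------------
# climate ranking

RANK_VARIABLES = {
    # variable -> ascending? (True: smallest value gets rank 1)
    "tmax_spring": False,  # warmest first
    "tmax_summer": False,
    "elevation": True,  # lowest elevation ~ warmest
    "precip_spring": True,  # driest first
    "precip_summer": True,
}


def climate_rank(env) -> pd.DataFrame:
    """Rank populations from most hot-and-dry to most cold-and-wet.

    Five component ranks (spring/summer maximum temperature descending,
    elevation ascending, spring/summer precipitation ascending) are
    averaged; ties get the average rank.  The table is ordered by the
    mean rank, hot/dry first.
    """
    df = pd.DataFrame({"population": env.populations})
    for var, ascending in RANK_VARIABLES.items():
        df[f"rank_{var}"] = (
            env.variable(var).reset_index(drop=True).rank(ascending=ascending, method="average")
        )
    df["mean_rank"] = df[[c for c in df.columns if c.startswith("rank_")]].mean(axis=1)
    return df.sort_values("mean_rank", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# congruence


@dataclass
class TreeComparison:
    rf_distance: int
    shared_bipartitions: list[frozenset]
    n_bipartitions: tuple[int, int]
    purity: pd.DataFrame = field(default_factory=pd.DataFrame)


def _nontrivial_splits(tree: dendropy.Tree) -> dict[int, frozenset]:
    tree.encode_bipartitions()
    out = {}
    taxa = list(tree.taxon_namespace)
    for bip in tree.bipartition_encoding:
        if bip.is_trivial():
            continue
        mask = bip.split_bitmask
        side = frozenset(t.label for i, t in enumerate(taxa) if mask >> i & 1)
        out[mask] = side
    return out


def compare_trees(
    tree_a: dendropy.Tree,
    tree_b: dendropy.Tree,
    group_labels: dict[str, str] | None = None,
) -> TreeComparison:
    """Robinson–Foulds distance, shared bipartitions, and (optionally)
    per-group cluster purity of each tree.

    Purity of a group is the best Jaccard overlap between the group's
    members and any bipartition side of the tree — 1.0 when the group is
    exactly a clade.
    """
    if set(t.label for t in tree_a.taxon_namespace) != set(
        t.label for t in tree_b.taxon_namespace
    ):
        raise ValueError("trees must share a leaf set")
    sa = _nontrivial_splits(tree_a)
    sb = _nontrivial_splits(tree_b)
    if tree_a.taxon_namespace is tree_b.taxon_namespace:
        shared_masks = set(sa) & set(sb)
        shared = [sa[m] for m in shared_masks]
        rf = len(set(sa) - set(sb)) + len(set(sb) - set(sa))
    else:  # compare by label sets (each split counted by its smaller side too)
        all_labels = frozenset(t.label for t in tree_a.taxon_namespace)
        norm_a = {min(s, all_labels - s, key=sorted) for s in sa.values()}
        norm_b = {min(s, all_labels - s, key=sorted) for s in sb.values()}
        shared = sorted(norm_a & norm_b, key=sorted)
        rf = len(norm_a - norm_b) + len(norm_b - norm_a)

    purity = pd.DataFrame()
    if group_labels:
        all_labels = frozenset(group_labels)
        rows = []
        for group in sorted(set(group_labels.values())):
            members = {p for p, g in group_labels.items() if g == group}
            rows.append(
                {
                    "group": group,
                    "purity_a": _best_jaccard(members, sa.values(), all_labels),
                    "purity_b": _best_jaccard(members, sb.values(), all_labels),
                }
            )
        purity = pd.DataFrame(rows)
    return TreeComparison(
        rf_distance=rf,
        shared_bipartitions=list(shared),
        n_bipartitions=(len(sa), len(sb)),
        purity=purity,
    )


def _best_jaccard(members: set, sides, all_labels: frozenset) -> float:
    best = 0.0
    for side in sides:
        for s in (set(side) & set(all_labels), set(all_labels) - set(side)):
            if not s:
                continue
            j = len(s & members) / len(s | members)
            best = max(best, j)
    return best
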