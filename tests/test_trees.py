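"""Neighbor joining, locus-bootstrap consensus, climate ranking and tree
congruence."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from snppanel.datatypes import DistanceMatrix, EnvironmentTable, MONTHS
from snppanel.popgen import allele_stats, nei_distance
from snppanel.simulate import SimulationConfig, simulate_environment, simulate_genotypes
from snppanel.trees import bootstrap_consensus, climate_rank, compare_trees, neighbor_joining


def random_additive_tree(n_leaves, rng):
    """Random binary tree built by sequential joining, returned as its
    path-length distance matrix (an independent construction that never
    touches the NJ code)."""
    labels = [f"t{i}" for i in range(n_leaves)]
    d = np.zeros((n_leaves, n_leaves))
    # each active cluster: {leaf index: distance from cluster root}
    clusters = [{i: 0.0} for i in range(n_leaves)]
    while len(clusters) > 1:
        i, j = rng.choice(len(clusters), size=2, replace=False)
        a, b = clusters[int(i)], clusters[int(j)]
        ea, eb = rng.uniform(0.1, 2.0, size=2)
        for la, da in a.items():
            for lb, db in b.items():
                d[la, lb] = d[lb, la] = da + ea + db + eb
        merged = {l: dd + ea for l, dd in a.items()}
        merged.update({l: dd + eb for l, dd in b.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (int(i), int(j))]
        clusters.append(merged)
    return None, DistanceMatrix(labels, d)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_exact(self):
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d[i, j], abs=1e-10)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("ABC"), d))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx((4 + 6 - 8) / 2)
        assert lengths["B"] == pytest.approx((4 + 8 - 6) / 2)
        assert lengths["C"] == pytest.approx((6 + 8 - 4) / 2)

    def test_consistency_on_random_additive_matrices(self):
        # additive input implies exact recovery of topology and path lengths
        rng = np.random.default_rng(0)
        for rep in range(100):
            n = int(rng.integers(4, 10))
            _, dm = random_additive_tree(n, rng)
            tree = neighbor_joining(dm)
            pdm = tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.taxon_namespace}
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = dm.labels[i], dm.labels[j]
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        dm.values[i, j], abs=1e-8
                    )

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate|unique"):
            neighbor_joining(DistanceMatrix(["A", "A", "B"], np.zeros((3, 3))))


class TestBootstrapConsensus:
    @pytest.fixture(scope="class")
    def grouped_freqs(self):
        cfg = SimulationConfig(
            n_regions=3, pops_per_region=3, inds_per_pop=25, n_loci=80,
            n_candidates=0, f_region=0.2, f_pop=0.01, missing_rate=0.0, seed=33,
        )
        ds, _ = simulate_genotypes(cfg, simulate_environment(cfg))
        return allele_stats(ds), ds.locus_ids

    def test_strong_groups_get_high_support(self, grouped_freqs):
        freqs, loci = grouped_freqs
        tree = bootstrap_consensus(freqs, loci, n_reps=100, seed=1)
        # the three regional clades must appear with >= 95% support
        by_region = {}
        for pop in freqs.populations:
            by_region.setdefault(pop[:2], set()).add(pop)
        taxa = list(tree.taxon_namespace)
        tree.encode_bipartitions()
        found = {}
        for bip in tree.bipartition_encoding:
            mask = bip.split_bitmask
            side = frozenset(t.label for i, t in enumerate(taxa) if mask >> i & 1)
            other = frozenset(t.label for t in taxa) - side
            for region, members in by_region.items():
                if side == members or other == members:
                    node = tree.bipartition_edge_map[bip].head_node
                    found[region] = int(node.label) if node.label else 100
        assert len(found) >= 2  # one regional split is the root trifurcation
        assert all(v >= 95 for v in found.values())

    def test_single_locus_panel_warns(self, grouped_freqs):
        freqs, loci = grouped_freqs
        with pytest.warns(UserWarning, match="loci"):
            bootstrap_consensus(freqs, loci[:1], n_reps=10, seed=0)

    def test_deterministic_given_seed(self, grouped_freqs):
        freqs, loci = grouped_freqs
        t1 = bootstrap_consensus(freqs, loci[:30], n_reps=30, seed=9)
        t2 = bootstrap_consensus(freqs, loci[:30], n_reps=30, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_supports_in_range_and_compatible(self, grouped_freqs):
        freqs, loci = grouped_freqs
        tree = bootstrap_consensus(freqs, loci, n_reps=50, seed=2)
        supports = [
            int(n.label) for n in tree.internal_nodes() if n.label and n.label.isdigit()
        ]
        assert supports and all(0 <= s <= 100 for s in supports)


def rank_env(values):
    n = len(values["elevation"])
    data = {"population": [f"P{i}" for i in range(n)],
            "latitude": [45.0] * n, "longitude": [-120.0] * n,
            "migration_distance": [1.0] * n}
    for k, m in enumerate(MONTHS):
        data[f"tmax_{m}"] = [0.0] * n
        data[f"tmin_{m}"] = [0.0] * n
        data[f"precip_{m}"] = [0.0] * n
    data["elevation"] = values["elevation"]
    env = EnvironmentTable(pd.DataFrame(data))
    df = env.table
    for var, vals in values.items():
        df[var] = vals
    for var in ("tmax_spring", "tmax_summer", "precip_spring", "precip_summer"):
        if var not in values:
            df[var] = 0.0
    return EnvironmentTable(df)


class TestClimateRank:
    def test_three_population_hand_ranking(self):
        env = rank_env({
            "tmax_spring": [20.0, 15.0, 10.0],  # P0 warmest
            "tmax_summer": [30.0, 25.0, 20.0],
            "elevation": [100.0, 500.0, 900.0],  # P0 lowest
            "precip_spring": [50.0, 100.0, 150.0],  # P0 driest
            "precip_summer": [10.0, 20.0, 30.0],
        })
        table = climate_rank(env)
        assert table["population"].tolist() == ["P0", "P1", "P2"]
        assert table["mean_rank"].tolist() == [1.0, 2.0, 3.0]

    def test_identical_populations_all_tie(self):
        env = rank_env({"tmax_spring": [1.0] * 4, "tmax_summer": [1.0] * 4,
                        "elevation": [5.0] * 4, "precip_spring": [2.0] * 4,
                        "precip_summer": [2.0] * 4})
        table = climate_rank(env)
        assert (table["mean_rank"] == 2.5).all()  # (n+1)/2

    def test_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(1)
        vals = {v: rng.uniform(0, 100, 8).tolist() for v in
                ("tmax_spring", "tmax_summer", "elevation", "precip_spring", "precip_summer")}
        t1 = climate_rank(rank_env(vals))
        vals2 = dict(vals)
        vals2["elevation"] = (np.exp(np.asarray(vals["elevation"]) / 50)).tolist()
        t2 = climate_rank(rank_env(vals2))
        assert t1["population"].tolist() == t2["population"].tolist()


class TestCompareTrees:
    def test_identical_trees_rf_zero(self):
        rng = np.random.default_rng(2)
        _, dm = random_additive_tree(8, rng)
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(dm)
        comp = compare_trees(t1, t2)
        assert comp.rf_distance == 0
        assert len(comp.shared_bipartitions) == comp.n_bipartitions[0]

    def test_rf_matches_exhaustive_bipartition_comparison(self):
        rng = np.random.default_rng(3)
        _, dm1 = random_additive_tree(8, rng)
        _, dm2 = random_additive_tree(8, rng)
        dm2 = DistanceMatrix(dm1.labels, dm2.values)  # same leaf set
        t1, t2 = neighbor_joining(dm1), neighbor_joining(dm2)

        def splits(tree):
            taxa = frozenset(t.label for t in tree.taxon_namespace)
            tree.encode_bipartitions()
            out = set()
            for bip in tree.bipartition_encoding:
                if bip.is_trivial():
                    continue
                side = frozenset(
                    t.label for i, t in enumerate(tree.taxon_namespace)
                    if bip.split_bitmask >> i & 1
                )
                out.add(min(side, taxa - side, key=sorted))
            return out

        s1, s2 = splits(t1), splits(t2)
        expected = len(s1 - s2) + len(s2 - s1)
        assert compare_trees(t1, t2).rf_distance == expected

    def test_leaf_set_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        _, dm1 = random_additive_tree(5, rng)
        _, dm2 = random_additive_tree(6, rng)
        with pytest.raises(ValueError, match="leaf set"):
            compare_trees(neighbor_joining(dm1), neighbor_joining(dm2))

    def test_group_purity_detects_clades(self):
        cfg = SimulationConfig(
            n_regions=3, pops_per_region=3, inds_per_pop=25, n_loci=60,
            n_candidates=0, f_region=0.25, f_pop=0.01, missing_rate=0.0, seed=44,
        )
        ds, _ = simulate_genotypes(cfg, simulate_environment(cfg))
        freqs = allele_stats(ds)
        tree = neighbor_joining(nei_distance(freqs))
        groups = {p: p[:2] for p in freqs.populations}
        comp = compare_trees(tree, tree, group_labels=groups)
        assert (comp.purity["purity_a"] >= 0.99).all()
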