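"""Structured coalescent for the symmetric finite island model.

This is the simulation engine behind the FST-outlier null: d demes of
equal size exchanging migrants symmetrically, with gene copies sampled
from a subset of demes.  Time is measured in units of 2N generations:
two lineages in the same deme coalesce at rate 1 per pair, and each
lineage migrates at rate M/2 (M = 4Nm, the scaled number of immigrant
gene copies per deme per generation), choosing a destination uniformly
among the other demes.

A general-purpose coalescent simulator spends most of its time shuffling
lineages between demes; exploiting the island model's symmetry with a
flat Gillespie loop compiled by numba brings the per-locus cost from
seconds to well under a millisecond at the scales this pipeline uses.
One biallelic mutation per locus is placed uniformly along the total
branch length (infinite sites, conditioned on polymorphism in the
sample, which uniform placement on a sample-spanning genealogy
guarantees).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sim_tree(deme_of_sample, n_demes, migration, seed):
    """One island-model genealogy.

    Returns (parent, time) arrays over 2n-1 nodes: nodes 0..n-1 are the
    sampled gene copies (leaves, time 0), coalescences append internal
    nodes; the root's parent is -1.
    """
    np.random.seed(seed)
    n = deme_of_sample.shape[0]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)

    # active lineage bookkeeping
    active = np.arange(n)  # node ids of active lineages
    deme = deme_of_sample.copy()  # deme of each active lineage (parallel)
    n_active = n
    # per-deme member lists (ragged, swap-remove)
    members = np.full((n_demes, n), -1, dtype=np.int64)  # indices into active
    count = np.zeros(n_demes, dtype=np.int64)
    slot = np.empty(n, dtype=np.int64)  # lineage index -> slot in its deme list
    for i in range(n):
        d = deme[i]
        members[d, count[d]] = i
        slot[i] = count[d]
        count[d] += 1

    coal_rate = np.zeros(n_demes)
    for d in range(n_demes):
        coal_rate[d] = count[d] * (count[d] - 1) / 2.0
    total_coal = coal_rate.sum()

    t = 0.0
    next_node = n
    mig_per_lineage = migration / 2.0
    while n_active > 1:
        total_mig = n_active * mig_per_lineage
        total = total_coal + total_mig
        t += np.random.exponential(1.0 / total)
        if np.random.random() * total < total_coal:
            # coalescence: pick deme proportional to its pair count
            u = np.random.random() * total_coal
            acc = 0.0
            d = 0
            for dd in range(n_demes):
                acc += coal_rate[dd]
                if u < acc:
                    d = dd
                    break
            # two distinct lineages within deme d
            i1 = np.random.randint(count[d])
            i2 = np.random.randint(count[d] - 1)
            if i2 >= i1:
                i2 += 1
            a_idx = members[d, i1]
            b_idx = members[d, i2]
            node_a = active[a_idx]
            node_b = active[b_idx]
            new = next_node
            next_node += 1
            parent[node_a] = new
            parent[node_b] = new
            time[new] = t
            # replace lineage a by the new node; remove lineage b
            active[a_idx] = new
            # remove b from deme list (swap with last)
            last = count[d] - 1
            moved = members[d, last]
            members[d, i2] = moved
            slot_of_b = i2
            if moved >= 0:
                slot[moved] = slot_of_b
            count[d] = last
            # remove b from the active array (swap with last active)
            last_active = n_active - 1
            if b_idx != last_active:
                moved_node = active[last_active]
                active[b_idx] = moved_node
                deme[b_idx] = deme[last_active]
                # fix the members entry pointing at last_active
                dd = deme[b_idx]
                members[dd, slot[last_active]] = b_idx
                slot[b_idx] = slot[last_active]
            n_active = last_active
            old = coal_rate[d]
            coal_rate[d] = count[d] * (count[d] - 1) / 2.0
            total_coal += coal_rate[d] - old
        else:
            # migration: uniform lineage, uniform destination deme
            i = np.random.randint(n_active)
            src = deme[i]
            dst = np.random.randint(n_demes - 1)
            if dst >= src:
                dst += 1
            # remove from src list
            s = slot[i]
            last = count[src] - 1
            moved = members[src, last]
            members[src, s] = moved
            if moved >= 0 and moved != i:
                slot[moved] = s
            count[src] = last
            # add to dst list
            members[dst, count[dst]] = i
            slot[i] = count[dst]
            count[dst] += 1
            deme[i] = dst
            old = coal_rate[src] + coal_rate[dst]
            coal_rate[src] = count[src] * (count[src] - 1) / 2.0
            coal_rate[dst] = count[dst] * (count[dst] - 1) / 2.0
            total_coal += coal_rate[src] + coal_rate[dst] - old
    return parent, time


@njit(cache=True)
def _drop_mutation(parent, time, n_leaves, seed):
    """Place one mutation uniformly on the branches; return the 0/1
    derived state of each leaf."""
    np.random.seed(seed)
    n_nodes = parent.shape[0]
    total = 0.0
    for v in range(n_nodes):
        if parent[v] >= 0:
            total += time[parent[v]] - time[v]
    u = np.random.random() * total
    acc = 0.0
    chosen = -1
    for v in range(n_nodes):
        if parent[v] >= 0:
            acc += time[parent[v]] - time[v]
            if u < acc:
                chosen = v
                break
    state = np.zeros(n_leaves, dtype=np.int64)
    for leaf in range(n_leaves):
        v = leaf
        while v >= 0:
            if v == chosen:
                state[leaf] = 1
                break
            v = parent[v]
    return state


def simulate_locus(
    deme_of_sample: np.ndarray, n_demes: int, migration: float, seed: int
) -> np.ndarray:
    """Derived-allele state (0/1) of each sampled gene copy for one
    neutral locus."""
    parent, time = _sim_tree(
        np.asarray(deme_of_sample, dtype=np.int64), n_demes, migration, seed
    )
    return _drop_mutation(parent, time, len(deme_of_sample), (seed * 7919 + 1) % 2**31)
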