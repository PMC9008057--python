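"""Multispecies-coalescent genealogy simulation with one hybrid edge.

A single locus is simulated backwards in time.  Sampled haploid lineages
start in their own populations (C, D, O, A) and coalesce within each
population at rate ``1 / size`` per pair per coalescent unit.  At the
hybrid-origin time ``t_h`` every lineage still inside D is routed,
independently, to the O-side ancestral population with probability
``gamma`` and to the C-side population otherwise (population-admixture
semantics).  C and O merge at ``t_co``; the outgroup joins at ``t_root``.

Genealogies are stored as flat parent/time arrays (leaves first, internal
nodes in coalescence order, so a parent's index always exceeds its
children's); this keeps per-locus cost low enough for the replicated
calibration studies downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

from .network import GROUPS, ParameterError, SampleDesign, SpeciesNetwork

__all__ = [
    "Genealogy",
    "sim_genealogy",
    "topology_probabilities",
    "genealogy_to_newick",
]


@dataclass
class Genealogy:
    """A rooted coalescent tree in parent-array form.

    ``parent[i]`` is the parent node of ``i`` (-1 for the root) and
    ``time[i]`` its age; leaves occupy indices ``0 .. n_leaves-1`` grouped
    contiguously per lineage as recorded in ``group_slices``.
    """

    parent: np.ndarray
    time: np.ndarray
    n_leaves: int
    group_slices: Dict[str, slice]

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        blen = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        blen[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return blen

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def node_group_counts(self) -> np.ndarray:
        """(n_nodes, 4) matrix of descendant-leaf counts per group (C, D, O, A)."""
        counts = np.zeros((self.n_nodes, len(GROUPS)), dtype=np.int32)
        for k, g in enumerate(GROUPS):
            counts[self.group_slices[g], k] = 1
        parent = self.parent
        for i in range(self.n_nodes - 1):  # parents always have larger indices
            counts[parent[i]] += counts[i]
        return counts

    def descendant_matrix(self) -> np.ndarray:
        """(n_nodes, n_leaves) boolean matrix of leaf sets per node."""
        desc = np.zeros((self.n_nodes, self.n_leaves), dtype=bool)
        desc[np.arange(self.n_leaves), np.arange(self.n_leaves)] = True
        parent = self.parent
        for i in range(self.n_nodes - 1):
            desc[parent[i]] |= desc[i]
        return desc


def _coalesce_until(
    pools: Sequence[list],
    sizes: Sequence[float],
    t: float,
    t_end: float,
    parent: np.ndarray,
    times: np.ndarray,
    next_id: int,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Run Kingman coalescence in parallel populations until ``t_end``."""
    while True:
        rates = [len(p) * (len(p) - 1) / (2.0 * s) for p, s in zip(pools, sizes)]
        total = sum(rates)
        if total == 0.0:
            return t_end, next_id
        t_next = t + rng.exponential(1.0 / total)
        if t_next >= t_end:
            return t_end, next_id
        t = t_next
        u = rng.random() * total
        for pool, rate in zip(pools, rates):
            if u < rate:
                break
            u -= rate
        k = len(pool)
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = pool[i], pool[j]
        parent[a] = next_id
        parent[b] = next_id
        times[next_id] = t
        # O(1) removal: overwrite the two slots, shrink by one.
        hi, lo = (i, j) if i > j else (j, i)
        pool[hi] = pool[-1]
        pool.pop()
        if lo < len(pool):
            pool[lo] = next_id
        else:
            pool.append(next_id)
        next_id += 1


def sim_genealogy(
    network: SpeciesNetwork, design: SampleDesign, rng: np.random.Generator
) -> Genealogy:
    """Simulate one locus genealogy under the network (coalescent units)."""
    n_per = [design.n_haploids(g) for g in GROUPS]
    n = sum(n_per)
    offsets = np.concatenate([[0], np.cumsum(n_per)])
    slices = {g: slice(int(offsets[k]), int(offsets[k + 1])) for k, g in enumerate(GROUPS)}

    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    times = np.zeros(n_nodes)
    pools = {g: list(range(slices[g].start, slices[g].stop)) for g in GROUPS}
    next_id = n

    # Phase 1: four separate populations until the hybrid-origin time.
    t, next_id = _coalesce_until(
        [pools[g] for g in GROUPS],
        [network.size(g) for g in GROUPS],
        0.0,
        network.t_h,
        parent,
        times,
        next_id,
        rng,
    )
    # Hybrid node: each surviving D lineage picks a parental population.
    d_lineages = pools.pop("D")
    if d_lineages:
        to_o = rng.random(len(d_lineages)) < network.gamma
        for lid, flag in zip(d_lineages, to_o):
            pools["O" if flag else "C"].append(lid)

    # Phase 2: C, O, A until the C/O ancestor merge.
    t, next_id = _coalesce_until(
        [pools["C"], pools["O"], pools["A"]],
        [network.size("C"), network.size("O"), network.size("A")],
        t,
        network.t_co,
        parent,
        times,
        next_id,
        rng,
    )
    co_pool = pools["C"] + pools["O"]

    # Phase 3: CO ancestor and the outgroup until the root.
    t, next_id = _coalesce_until(
        [co_pool, pools["A"]],
        [network.size("CO"), network.size("A")],
        t,
        network.t_root,
        parent,
        times,
        next_id,
        rng,
    )

    # Phase 4: single ancestral population until the grand MRCA.
    root_pool = co_pool + pools["A"]
    t, next_id = _coalesce_until(
        [root_pool],
        [network.size("ROOT")],
        t,
        math.inf,
        parent,
        times,
        next_id,
        rng,
    )
    assert next_id == n_nodes
    return Genealogy(parent=parent, time=times, n_leaves=n, group_slices=slices)


def topology_probabilities(network: SpeciesNetwork) -> tuple[float, float, float]:
    """Exact rooted-topology probabilities for one sampled lineage per group.

    Topology I groups C with D, II groups D with O, III groups C with O.
    With probability ``1 - gamma`` the single D lineage enters the C-side
    parent branch and coalesces there before ``t_co`` with probability
    ``1 - exp(-T / size_C)`` (topology I); symmetrically for the O side.
    Conditional on reaching the common C/O ancestor uncoalesced, all three
    ingroup lineages are exchangeable and each topology is equally likely.
    """
    T = network.internal_branch
    g = network.gamma
    e_c = math.exp(-T / network.size("C"))
    e_o = math.exp(-T / network.size("O"))
    residual = (1.0 - g) * e_c + g * e_o  # P(D still unresolved at t_co)
    p1 = (1.0 - g) * (1.0 - e_c) + residual / 3.0
    p2 = g * (1.0 - e_o) + residual / 3.0
    p3 = residual / 3.0
    return p1, p2, p3


def genealogy_to_newick(g: Genealogy, labels: Sequence[str]) -> str:
    """Render a genealogy as a rooted newick string with branch lengths."""
    if len(labels) != g.n_leaves:
        raise ParameterError(f"expected {g.n_leaves} labels, got {len(labels)}")
    children: list[list[int]] = [[] for _ in range(g.n_nodes)]
    root = -1
    for i, p in enumerate(g.parent):
        if p >= 0:
            children[p].append(i)
        else:
            root = i
    blen = g.branch_lengths()

    def render(i: int) -> str:
        if i < g.n_leaves:
            return f"{labels[i]}:{blen[i]:.6g}"
        inner = ",".join(render(c) for c in children[i])
        if g.parent[i] < 0:
            return f"({inner})"
        return f"({inner}):{blen[i]:.6g}"

    return render(root) + ";"
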