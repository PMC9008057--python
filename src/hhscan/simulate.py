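"""Synthetic data generation under the coalescent-with-hybridization model.

Three generators share one genealogy engine (:mod:`hhscan.coalescent`):

* :func:`simulate_gene_trees` -- per-locus rooted genealogies (dendropy
  trees) for the topology census and its ILS null;
* :func:`simulate_variants` / :func:`simulate_frequency_table` -- biallelic
  SNP/indel markers with diploid genotypes (or, on the fast path, group
  allele frequencies directly) for the D-statistic, hybrid-invariant and
  PIV analyses;
* :func:`simulate_gene_alignments` -- per-gene codon alignments with
  optional planted parent-of-origin selection signals for the
  positive-selection scan.

Mutations follow an infinite-sites model: every mutation creates a new
biallelic marker, so long indels are homoplasy-free by construction.
Markers are anchored on eight synthetic chromosomes (mirroring the
karyotype of the study system); the markers of one locus occupy
consecutive positions around the locus anchor, so genomic contiguity
reflects genealogical linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .coalescent import Genealogy, genealogy_to_newick, sim_genealogy, topology_probabilities
from .io import (
    FIXED_ALT,
    FIXED_REF,
    POLYMORPHIC,
    GeneAlignment,
    GroupAlleleSummary,
    GroupMap,
    InputError,
    VariantTable,
    _polarize,
)
from .network import GROUPS, MutationModel, ParameterError, SampleDesign, SpeciesNetwork
from .trees import GeneTreeSet

logger = logging.getLogger(__name__)

N_CHROMOSOMES = 8
CHROM_LENGTH = 46_000_000  # ~372 Mb genome over 8 chromosomes

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def design_group_map(design: SampleDesign) -> GroupMap:
    """Group map over the diploid individuals implied by a sample design."""
    assignment = {}
    for g in GROUPS:
        for ind in design.individuals(g):
            assignment[ind] = g
    return GroupMap(assignment)


def _tip_labels(design: SampleDesign) -> List[str]:
    labels: List[str] = []
    for g in GROUPS:
        labels.extend(design.haplotype_names(g))
    return labels


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------

def _random_anchors(n: int, rng: np.random.Generator, span: int = 0) -> List[Tuple[str, int]]:
    chroms = rng.integers(1, N_CHROMOSOMES + 1, size=n)
    pos = rng.integers(1, CHROM_LENGTH - span - 1, size=n)
    return [(f"chr{c}", int(p)) for c, p in zip(chroms, pos)]


def simulate_gene_trees(
    network: SpeciesNetwork,
    design: SampleDesign,
    n_loci: int,
    seed: int,
    anchored: bool = True,
) -> GeneTreeSet:
    """Simulate ``n_loci`` independent gene trees under the network.

    Each D lineage is routed through the hybrid edge independently per
    locus; branch lengths are in coalescent units.  Deterministic given
    ``seed``.
    """
    if n_loci < 1:
        raise ParameterError(f"n_loci must be positive, got {n_loci}")
    rng = np.random.default_rng(seed)
    labels = _tip_labels(design)
    trees = []
    for _ in range(n_loci):
        g = sim_genealogy(network, design, rng)
        nwk = genealogy_to_newick(g, labels)
        trees.append(
            dendropy.Tree.get(
                data=nwk,
                schema="newick",
                suppress_internal_node_taxa=True,
                rooting="default-rooted",
                preserve_underscores=True,
            )
        )
    anchors = _random_anchors(n_loci, rng) if anchored else None
    return GeneTreeSet(trees=trees, anchors=anchors)


def _single_tip_topology(g: Genealogy) -> int:
    """Topology label (1, 2, 3) for a one-tip-per-group genealogy.

    Leaves are ordered C=0, D=1, O=2, A=3; the ingroup pair whose members
    share the shallowest common ancestor is the sister pair.
    """
    pairs = ((0, 1), (1, 2), (0, 2))  # I: C+D, II: D+O, III: C+O
    # MRCA time of each pair by climbing; small trees so this is cheap.
    def mrca_time(a: int, b: int) -> float:
        anc = set()
        while a >= 0:
            anc.add(a)
            a = g.parent[a]
        while b not in anc:
            b = g.parent[b]
        return g.time[b]

    times = [mrca_time(a, b) for a, b in pairs]
    return int(np.argmin(times)) + 1


def sample_topology_counts(
    network: SpeciesNetwork,
    n_loci: int,
    rng: np.random.Generator,
    method: str = "multinomial",
    design: Optional[SampleDesign] = None,
) -> Tuple[int, int, int]:
    """Sample per-dataset topology counts for one lineage per group.

    ``method='multinomial'`` draws from the exact single-tip topology
    probabilities of the network (distributionally identical to simulating
    and classifying the genealogies, but fast enough for the 10,000
    replicates of the ILS null); ``method='genealogy'`` runs the full
    coalescent per locus.
    """
    if n_loci < 1:
        raise ParameterError(f"n_loci must be positive, got {n_loci}")
    if method == "multinomial":
        probs = topology_probabilities(network)
        n1, n2, n3 = rng.multinomial(n_loci, probs)
        return int(n1), int(n2), int(n3)
    if method == "genealogy":
        design = design or SampleDesign({g: 1 for g in GROUPS})
        counts = [0, 0, 0]
        for _ in range(n_loci):
            counts[_single_tip_topology(sim_genealogy(network, design, rng)) - 1] += 1
        return tuple(counts)  # type: ignore[return-value]
    raise ParameterError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def _marker_classes(
    n: int, model: MutationModel, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Sample marker classes and indel lengths for ``n`` new mutations."""
    is_indel = rng.random(n) < model.indel_fraction
    lengths = np.zeros(n, dtype=np.int64)
    k = int(is_indel.sum())
    if k:
        lengths[is_indel] = model.min_indel_len - 1 + rng.geometric(model.indel_geom_p, size=k)
    return is_indel, lengths


def _alleles_for(
    is_indel: np.ndarray, lengths: np.ndarray, rng: np.random.Generator
) -> Tuple[List[str], List[str]]:
    """Synthetic REF/ALT strings: SNP substitutions and 50/50 ins/del indels."""
    refs: List[str] = []
    alts: List[str] = []
    for ind, ln in zip(is_indel, lengths):
        if not ind:
            i = int(rng.integers(4))
            j = (i + 1 + int(rng.integers(3))) % 4
            refs.append(chr(_BASES[i]))
            alts.append(chr(_BASES[j]))
        else:
            anchor = chr(_BASES[int(rng.integers(4))])
            extra = "".join(chr(_BASES[b]) for b in rng.integers(0, 4, size=int(ln)))
            if rng.random() < 0.5:
                refs.append(anchor + extra)
                alts.append(anchor)
            else:
                refs.append(anchor)
                alts.append(anchor + extra)
    return refs, alts


def _mutation_nodes(
    g: Genealogy, theta: float, rng: np.random.Generator
) -> np.ndarray:
    blen = g.branch_lengths()
    total = blen.sum()
    n_mut = rng.poisson(theta * total)
    if n_mut == 0:
        return np.empty(0, dtype=np.int64)
    cum = np.cumsum(blen)
    return np.minimum(
        np.searchsorted(cum, rng.random(n_mut) * total, side="right"), g.n_nodes - 2
    )


def simulate_variants(trees: GeneTreeSet, model: MutationModel, seed: int) -> VariantTable:
    """Drop infinite-sites mutations on gene trees and emit diploid genotypes.

    Each mutation becomes one biallelic marker (SNP or indel per the
    model); REF is the ancestral (root-side) allele except that markers
    fixed derived in the outgroup are emitted with alleles swapped so that
    REF always matches the outgroup-side allele.  Diploid genotypes pair
    the two haplotypes ``<ind>_1`` / ``<ind>_2`` of each individual.
    """
    rng = np.random.default_rng(seed)
    if not len(trees):
        raise InputError("empty gene-tree set")

    # Haplotype ordering from the first tree; all trees must agree.
    labels = sorted(t.taxon.label for t in trees.trees[0].leaf_node_iter())
    label_idx = {lab: i for i, lab in enumerate(labels)}
    individuals: List[str] = []
    hap_of_ind: Dict[str, List[int]] = {}
    for lab in labels:
        ind = lab.rsplit("_", 1)[0] if "_" in lab else lab
        if ind not in hap_of_ind:
            hap_of_ind[ind] = []
            individuals.append(ind)
        hap_of_ind[ind].append(label_idx[lab])

    anchors = trees.anchors or _random_anchors(len(trees), rng)
    a_indices = [label_idx[l] for l in labels if l.startswith("A")]

    chroms: List[str] = []
    positions: List[int] = []
    carrier_rows: List[np.ndarray] = []
    class_rows: List[np.ndarray] = []
    len_rows: List[np.ndarray] = []
    for tree, (chrom, anchor) in zip(trees.trees, anchors):
        nodes = list(tree.postorder_node_iter())
        n_nodes = len(nodes)
        masks = np.zeros((n_nodes, len(labels)), dtype=bool)
        blen = np.zeros(n_nodes)
        for k, nd in enumerate(nodes):
            nd._sim_index = k
            if nd.is_leaf():
                masks[k, label_idx[nd.taxon.label]] = True
            else:
                for ch in nd.child_nodes():
                    masks[k] |= masks[ch._sim_index]
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise InputError("gene tree lacks branch lengths")
                blen[k] = nd.edge.length
        total = blen.sum()
        n_mut = rng.poisson(model.theta * total)
        if n_mut == 0:
            continue
        cum = np.cumsum(blen)
        hit = np.minimum(
            np.searchsorted(cum, rng.random(n_mut) * total, side="right"), n_nodes - 1
        )
        carriers = masks[hit]
        is_indel, lengths = _marker_classes(n_mut, model, rng)
        chroms.extend([chrom] * n_mut)
        positions.extend(range(anchor, anchor + n_mut))
        carrier_rows.append(carriers)
        class_rows.append(is_indel)
        len_rows.append(lengths)

    if not carrier_rows:
        sites = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "vclass", "indel_len"]
        )
        return VariantTable(
            sites=sites,
            genotypes=np.zeros((0, len(individuals)), dtype=np.int8),
            samples=individuals,
        )

    carriers = np.vstack(carrier_rows)
    is_indel = np.concatenate(class_rows)
    lengths = np.concatenate(len_rows)

    # Swap alleles where the outgroup is fixed for the derived state, so
    # REF is the outgroup-side allele.
    if a_indices:
        swap = carriers[:, a_indices].all(axis=1)
        carriers[swap] = ~carriers[swap]

    geno = np.zeros((carriers.shape[0], len(individuals)), dtype=np.int8)
    for j, ind in enumerate(individuals):
        cols = hap_of_ind[ind]
        if len(cols) == 2:
            geno[:, j] = carriers[:, cols[0]].astype(np.int8) + carriers[:, cols[1]]
        else:  # single sampled haplotype: emitted as a homozygote
            geno[:, j] = 2 * carriers[:, cols[0]].astype(np.int8)

    refs, alts = _alleles_for(is_indel, lengths, rng)
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "vclass": np.where(is_indel, "indel", "snp"),
            "indel_len": lengths,
        }
    )
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    return VariantTable(sites=sites, genotypes=geno[order], samples=individuals)


def simulate_frequency_table(
    network: SpeciesNetwork,
    design: SampleDesign,
    model: MutationModel,
    n_loci: int,
    seed: int | np.random.Generator,
) -> GroupAlleleSummary:
    """Fast path: simulate markers and return group allele summaries directly.

    Equivalent to ``simulate_gene_trees -> simulate_variants ->
    summarize_groups`` for fully called genotypes, but skips tree objects
    and genotype matrices; used by the replicated calibration and power
    studies.  The derived allele is always the alt allele here.
    """
    if n_loci < 1:
        raise ParameterError(f"n_loci must be positive, got {n_loci}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_per = np.array([design.n_haploids(g) for g in GROUPS])

    dc_rows: List[np.ndarray] = []
    chrom_rows: List[np.ndarray] = []
    pos_rows: List[np.ndarray] = []
    indel_rows: List[np.ndarray] = []
    len_rows: List[np.ndarray] = []
    for _ in range(n_loci):
        g = sim_genealogy(network, design, rng)
        nodes = _mutation_nodes(g, model.theta, rng)
        if nodes.size == 0:
            continue
        dc_rows.append(g.node_group_counts()[nodes])
        is_indel, lengths = _marker_classes(nodes.size, model, rng)
        chrom = int(rng.integers(1, N_CHROMOSOMES + 1))
        anchor = int(rng.integers(1, CHROM_LENGTH - nodes.size - 1))
        chrom_rows.append(np.full(nodes.size, chrom))
        pos_rows.append(np.arange(anchor, anchor + nodes.size))
        indel_rows.append(is_indel)
        len_rows.append(lengths)

    if not dc_rows:
        empty = np.empty(0)
        sites = pd.DataFrame(columns=["chrom", "pos", "vclass", "indel_len"])
        summary = GroupAlleleSummary(
            sites=sites,
            groups=list(GROUPS),
            alt_freq={g: empty.copy() for g in GROUPS},
            call_rate={g: empty.copy() for g in GROUPS},
            fixed={g: np.empty(0, dtype=np.int8) for g in GROUPS},
        )
        _polarize(summary)
        return summary

    dc = np.vstack(dc_rows)
    chrom = np.concatenate(chrom_rows)
    pos = np.concatenate(pos_rows)
    is_indel = np.concatenate(indel_rows)
    lengths = np.concatenate(len_rows)
    order = np.lexsort((pos, chrom))
    dc, chrom, pos = dc[order], chrom[order], pos[order]
    is_indel, lengths = is_indel[order], lengths[order]

    sites = pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in chrom],
            "pos": pos,
            "vclass": np.where(is_indel, "indel", "snp"),
            "indel_len": lengths,
        }
    )
    alt_freq: Dict[str, np.ndarray] = {}
    call_rate: Dict[str, np.ndarray] = {}
    fixed: Dict[str, np.ndarray] = {}
    for k, g in enumerate(GROUPS):
        n = n_per[k]
        freq = dc[:, k] / n
        code = np.full(len(freq), POLYMORPHIC, dtype=np.int8)
        code[dc[:, k] == 0] = FIXED_REF
        code[dc[:, k] == n] = FIXED_ALT
        alt_freq[g] = freq
        call_rate[g] = np.ones(len(freq))
        fixed[g] = code
    summary = GroupAlleleSummary(
        sites=sites, groups=list(GROUPS), alt_freq=alt_freq, call_rate=call_rate, fixed=fixed
    )
    _polarize(summary)
    return summary


# ---------------------------------------------------------------------------
# Codon alignments with planted selection signals
# ---------------------------------------------------------------------------

_STOP_CODONS = {"TAA", "TAG", "TGA"}
# A fixed nonsynonymous codon pair differing at one site (Glu vs Asp).
_PLANT_PAIR = ("GAA", "GAT")
_ALT_PAIR = ("AAA", "GAA")  # Lys vs Glu, first-position difference


@dataclass(frozen=True)
class PlantedGene:
    """Specification of one planted selection signal.

    ``origin`` forces the gene's D haplotypes to descend from that parent
    (C or O); ``n_fixed_nonsyn`` nonsynonymous differences are fixed
    between the D+parent pair and the contrast lineage.  ``alternating``
    plants ``k1`` amino-acid states matching C-fixed residues and ``k2``
    matching O-fixed residues inside the same gene (a recombinant gene);
    such genes have no single parent of origin.  ``sweep_retention`` thins
    polymorphism within the swept (D+parent) side.
    """

    index: int
    origin: Optional[str] = None  # 'C' or 'O'; None for alternating-only genes
    n_fixed_nonsyn: int = 20
    alternating: Optional[Tuple[int, int]] = None
    sweep_retention: float = 0.5

    def __post_init__(self) -> None:
        if self.origin not in (None, "C", "O"):
            raise ParameterError(f"origin must be 'C', 'O' or None, got {self.origin!r}")
        if self.origin is None and self.alternating is None:
            raise ParameterError("planted gene needs an origin or an alternating pattern")


def _ancestral_codons(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """Random non-stop codons as a flat uint8 base array of length 3*n."""
    seq = np.empty(3 * n_codons, dtype=np.uint8)
    for i in range(n_codons):
        while True:
            cod = _BASES[rng.integers(0, 4, size=3)]
            if cod.tobytes().decode() not in _STOP_CODONS:
                seq[3 * i : 3 * i + 3] = cod
                break
    return seq


def _side_masks(design: SampleDesign) -> Dict[str, np.ndarray]:
    n_per = [design.n_haploids(g) for g in GROUPS]
    offsets = np.concatenate([[0], np.cumsum(n_per)])
    masks = {}
    for k, g in enumerate(GROUPS):
        m = np.zeros(int(offsets[-1]), dtype=bool)
        m[int(offsets[k]) : int(offsets[k + 1])] = True
        masks[g] = m
    return masks


def simulate_gene_alignments(
    network: SpeciesNetwork,
    design: SampleDesign,
    n_genes: int,
    planted: Sequence[PlantedGene] = (),
    seed: int = 0,
    n_codons: int = 150,
    theta_site: float = 0.002,
    omega: float = 0.25,
) -> Tuple[List[GeneAlignment], List[PlantedGene]]:
    """Simulate per-gene codon alignments; planted genes carry their signal exactly.

    Unplanted genes evolve under purifying selection on genealogies drawn
    from the network: a mutation that changes the encoded amino acid is
    retained with probability ``omega`` (the dN/dS ratio of the
    background), synonymous changes always.  Planted genes are simulated
    with the hybrid edge forced toward their origin parent (all D lineages
    routed there), carry ``n_fixed_nonsyn`` planted fixed nonsynonymous
    differences between the D+parent pair and the contrast parent, and
    have within-pair polymorphism thinned by ``sweep_retention``.
    Alignments never contain internal stop codons.
    """
    if n_genes < 1:
        raise ParameterError(f"n_genes must be positive, got {n_genes}")
    by_index: Dict[int, PlantedGene] = {}
    for p in planted:
        if not (0 <= p.index < n_genes):
            raise ParameterError(f"planted index {p.index} outside 0..{n_genes - 1}")
        n_cols = p.n_fixed_nonsyn + sum(p.alternating or (0, 0))
        if n_cols > n_codons:
            raise ParameterError(
                f"planted gene {p.index}: {n_cols} planted codons exceed gene length {n_codons}"
            )
        by_index[p.index] = p

    rng = np.random.default_rng(seed)
    labels = _tip_labels(design)
    masks = _side_masks(design)
    n_hap = len(labels)
    L = 3 * n_codons
    width = len(str(n_genes))
    alignments: List[GeneAlignment] = []

    for gi in range(n_genes):
        plant = by_index.get(gi)
        net = network
        if plant is not None and plant.origin is not None:
            forced_gamma = 0.0 if plant.origin == "C" else 1.0
            net = SpeciesNetwork(
                t_h=network.t_h,
                t_co=network.t_co,
                t_root=network.t_root,
                gamma=forced_gamma,
                pop_sizes=network.pop_sizes,
            )
        g = sim_genealogy(net, design, rng)
        seq = np.tile(_ancestral_codons(n_codons, rng), (n_hap, 1))

        # Reserve planted codon columns before placing neutral mutations.
        n_reserved = 0
        if plant is not None:
            n_reserved = plant.n_fixed_nonsyn + sum(plant.alternating or (0, 0))
        codon_perm = rng.permutation(n_codons)
        reserved_codons = codon_perm[:n_reserved]
        free_sites = np.setdiff1d(
            np.arange(L), np.concatenate([3 * reserved_codons + o for o in range(3)])
            if n_reserved else np.empty(0, dtype=np.int64),
        )

        nodes = _mutation_nodes(g, theta_site * len(free_sites), rng)
        if plant is not None and plant.sweep_retention < 1.0 and plant.origin is not None:
            side = masks["D"] | masks[plant.origin]
            desc = g.descendant_matrix()
            hits = desc[nodes]
            inside = (hits & ~side).sum(axis=1) == 0
            strict = inside & (hits.sum(axis=1) < side.sum())
            keep = ~strict | (rng.random(nodes.size) < plant.sweep_retention)
            nodes = nodes[keep]
        if nodes.size:
            from .psg import _AA_OF_CODON, _BASE_INDEX  # shared translation tables

            desc = g.descendant_matrix()
            if nodes.size <= len(free_sites):
                cols = rng.choice(free_sites, size=nodes.size, replace=False)
            else:
                cols = rng.choice(free_sites, size=nodes.size, replace=True)
            for node, col in zip(nodes, cols):
                codon_start = 3 * (col // 3)
                context = seq[0, codon_start : codon_start + 3].copy()
                current = seq[0, col]
                b = _BASES[(int(_BASE_INDEX[current]) + 1 + int(rng.integers(3))) % 4]
                old_idx = (
                    16 * _BASE_INDEX[context[0]]
                    + 4 * _BASE_INDEX[context[1]]
                    + _BASE_INDEX[context[2]]
                )
                context[col % 3] = b
                new_idx = (
                    16 * _BASE_INDEX[context[0]]
                    + 4 * _BASE_INDEX[context[1]]
                    + _BASE_INDEX[context[2]]
                )
                new_aa = _AA_OF_CODON[new_idx]
                if new_aa == "*":
                    continue  # premature stop: lethal, mutation lost
                if new_aa != _AA_OF_CODON[old_idx] and rng.random() >= omega:
                    continue  # purifying selection removes the replacement
                seq[desc[node], col] = b

        if plant is not None:
            x = np.frombuffer(_PLANT_PAIR[0].encode(), dtype=np.uint8)
            y = np.frombuffer(_PLANT_PAIR[1].encode(), dtype=np.uint8)
            cursor = 0
            if plant.origin is not None and plant.n_fixed_nonsyn:
                side1 = masks["D"] | masks[plant.origin]
                side2 = masks["O" if plant.origin == "C" else "C"]
                for c in reserved_codons[cursor : cursor + plant.n_fixed_nonsyn]:
                    s = 3 * c
                    seq[side1, s : s + 3] = x
                    seq[side2, s : s + 3] = y
                    seq[masks["A"], s : s + 3] = y
                cursor += plant.n_fixed_nonsyn
            if plant.alternating is not None:
                k1, k2 = plant.alternating
                for j, c in enumerate(reserved_codons[cursor : cursor + k1 + k2]):
                    s = 3 * c
                    seq[masks["C"], s : s + 3] = x
                    seq[masks["O"], s : s + 3] = y
                    seq[masks["A"], s : s + 3] = x
                    seq[masks["D"], s : s + 3] = x if j < k1 else y

        # Multi-hit codons can still assemble a stop; revert those haplotypes.
        n_fixed_stops = _scrub_stops(seq, n_codons)
        if n_fixed_stops:
            logger.debug("gene %d: reverted %d stop codon(s)", gi, n_fixed_stops)

        alignments.append(
            GeneAlignment(gene_id=f"gene{gi:0{width}d}", names=list(labels), seqs=seq)
        )
    return alignments, list(by_index.values())


def _scrub_stops(seq: np.ndarray, n_codons: int) -> int:
    """Replace any internal stop codon by the row-0 codon (count returned)."""
    stops = [np.frombuffer(s.encode(), dtype=np.uint8) for s in _STOP_CODONS]
    n_fixed = 0
    codons = seq.reshape(seq.shape[0], n_codons, 3)
    for stop in stops:
        bad = (codons == stop).all(axis=2)
        if bad.any():
            rows, cols = np.nonzero(bad)
            for r, c in zip(rows, cols):
                if r == 0:
                    # ancestral row itself never starts as a stop; pick a safe codon
                    codons[:, c][(codons[:, c] == stop).all(axis=1)] = np.frombuffer(
                        b"GAA", dtype=np.uint8
                    )
                else:
                    codons[r, c] = codons[0, c]
                n_fixed += 1
    return n_fixed
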