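"""Positive-selection scan on the hybrid lineage and hybrid-signal genes.

A gene is called positively selected (PSG) in the hybrid lineage D when
three criteria hold:

1. a significant HKA-style contrast (p <= 0.01) of within-pair
   polymorphism S against between-side divergence K, realized as a
   gene-versus-genome 2x2 chi-square;
2. its count of fixed nonsynonymous differences ranks in the top 2.5% of
   all genes tested (ties at the cutoff included);
3. an unambiguous parental origin: at least 80% of D haplotypes cluster
   with one parent on a neighbor-joining tree of unique haplotypes
   (p-distance).

Two groupings are scanned: D pooled with C against O (``DC_vs_O``) and D
pooled with O against C (``DO_vs_C``).  A gene passing the first two
criteria under BOTH groupings -- regardless of phylogeny -- carries a
hybrid signal: each parental allele class contributes divergence, as
happens after hybrid recombination inside a gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io import GeneAlignment, GroupMap, InputError
from .network import ParameterError
from .stats import chi2_2x2

logger = logging.getLogger(__name__)

GROUPINGS = ("DC_vs_O", "DO_vs_C")
#: combined-pair groups and contrast group per grouping tag
_GROUPING_SIDES = {"DC_vs_O": (("D", "C"), "O"), "DO_vs_C": (("D", "O"), "C")}

_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

# 64-entry codon -> amino acid table (stop = '*'), standard code.
_AA_OF_CODON = np.empty(64, dtype="U1")
_table = CodonTable.unambiguous_dna_by_id[1]
for _i0, _b0 in enumerate("ACGT"):
    for _i1, _b1 in enumerate("ACGT"):
        for _i2, _b2 in enumerate("ACGT"):
            codon = _b0 + _b1 + _b2
            idx = 16 * _i0 + 4 * _i1 + _i2
            _AA_OF_CODON[idx] = "*" if codon in _table.stop_codons else _table.forward_table[codon]


def haplotype_group(name: str, groups: GroupMap) -> Optional[str]:
    """Group of a haplotype name (individual name plus ``_1``/``_2`` suffix)."""
    assignment = dict(groups.assignment)
    if name in assignment:
        return assignment[name]
    stem = name.rsplit("_", 1)[0]
    return assignment.get(stem)


def _group_rows(aln: GeneAlignment, groups: GroupMap) -> Dict[str, np.ndarray]:
    cache = getattr(aln, "_group_rows_cache", None)
    if cache is None:
        cache = {}
        aln._group_rows_cache = cache  # type: ignore[attr-defined]
    key = id(groups)
    if key in cache:
        return cache[key]
    rows: Dict[str, List[int]] = {}
    for i, name in enumerate(aln.names):
        g = haplotype_group(name, groups)
        if g is not None:
            rows.setdefault(g, []).append(i)
    out = {g: np.array(r, dtype=np.int64) for g, r in rows.items()}
    cache[key] = out
    return out


def _sides(aln: GeneAlignment, groups: GroupMap, grouping: str) -> Tuple[np.ndarray, np.ndarray]:
    if grouping not in _GROUPING_SIDES:
        raise ParameterError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    pair, contrast = _GROUPING_SIDES[grouping]
    rows = _group_rows(aln, groups)
    side1 = np.concatenate([rows.get(g, np.empty(0, dtype=np.int64)) for g in pair])
    side2 = rows.get(contrast, np.empty(0, dtype=np.int64))
    if side1.size == 0 or side2.size == 0:
        raise InputError(
            f"gene {aln.gene_id}: grouping {grouping} has an empty side "
            f"(pair {pair}, contrast {contrast!r})"
        )
    return side1, side2


class PolymorphismDivergence(NamedTuple):
    S: int  # segregating sites within the combined pair
    K: int  # fixed differences between the pair and the contrast lineage
    n_excluded: int  # columns skipped for gaps/ambiguity


def polymorphism_divergence(
    aln: GeneAlignment, groups: GroupMap, grouping: str
) -> PolymorphismDivergence:
    """Count segregating (S) and fixed-divergent (K) nucleotide columns."""
    side1, side2 = _sides(aln, groups, grouping)
    used = np.concatenate([side1, side2])
    sub = aln.seqs[used]
    valid = (_BASE_INDEX[sub] >= 0).all(axis=0)
    s1 = aln.seqs[side1]
    s2 = aln.seqs[side2]
    fixed1 = (s1 == s1[0]).all(axis=0)
    fixed2 = (s2 == s2[0]).all(axis=0)
    S = int((valid & ~fixed1).sum())
    K = int((valid & fixed1 & fixed2 & (s1[0] != s2[0])).sum())
    return PolymorphismDivergence(S=S, K=K, n_excluded=int((~valid).sum()))


def hka_test(S_gene: int, K_gene: int, S_genome: int, K_genome: int) -> Tuple[float, float]:
    """Gene-versus-genome 2x2 chi-square contrast of polymorphism and divergence.

    Table: [[S_gene, K_gene], [S_genome - S_gene, K_genome - K_gene]],
    1 df, no continuity correction.  Genome totals include the focal gene.
    """
    if S_genome < S_gene or K_genome < K_gene:
        raise ParameterError("genome totals must be at least the gene counts")
    if S_genome + K_genome == 0:
        raise ParameterError("genome totals must be positive")
    return chi2_2x2(S_gene, K_gene, S_genome - S_gene, K_genome - K_gene)


def _codon_indices(seqs: np.ndarray) -> np.ndarray:
    """(n_hap, n_codons) codon indices in 0..63, or -1 where ambiguous."""
    n_hap, L = seqs.shape
    if L % 3:
        raise InputError(f"alignment length {L} not divisible by 3")
    b = _BASE_INDEX[seqs].reshape(n_hap, L // 3, 3).astype(np.int64)
    idx = 16 * b[:, :, 0] + 4 * b[:, :, 1] + b[:, :, 2]
    idx[(b < 0).any(axis=2)] = -1
    return idx


def count_fixed_nonsynonymous(aln: GeneAlignment, groups: GroupMap, grouping: str) -> int:
    """Fixed nonsynonymous codon differences between the two sides.

    A codon column counts when both sides are fixed for different codons
    encoding different amino acids; columns with any gap/ambiguity are
    skipped, as are (with a warning) consensus stop codons.
    """
    side1, side2 = _sides(aln, groups, grouping)
    cod = _codon_indices(aln.seqs)
    c1 = cod[side1]
    c2 = cod[side2]
    valid = (c1 >= 0).all(axis=0) & (c2 >= 0).all(axis=0)
    fixed1 = (c1 == c1[0]).all(axis=0)
    fixed2 = (c2 == c2[0]).all(axis=0)
    cand = valid & fixed1 & fixed2 & (c1[0] != c2[0])
    if not cand.any():
        return 0
    aa1 = _AA_OF_CODON[c1[0][cand]]
    aa2 = _AA_OF_CODON[c2[0][cand]]
    stops = (aa1 == "*") | (aa2 == "*")
    if stops.any():
        logger.warning(
            "gene %s: %d consensus stop codon(s) skipped", aln.gene_id, int(stops.sum())
        )
    return int(((aa1 != aa2) & ~stops).sum())


def rank_top_fraction(values: Sequence[float], fraction: float = 0.025) -> np.ndarray:
    """Boolean mask of values in the top ``fraction``; cutoff ties included."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.zeros(0, dtype=bool)
    if not (0 < fraction < 1):
        raise ParameterError(f"fraction must lie in (0, 1), got {fraction}")
    threshold = np.quantile(values, 1.0 - fraction, method="higher")
    if np.all(values == values[0]):
        logger.info("rank_top_fraction: all values equal; every gene passes")
    return values >= threshold


def _p_distance_matrix(seqs: np.ndarray) -> np.ndarray:
    n = seqs.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = (seqs[i + 1 :] != seqs[i]).mean(axis=1)
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return d


def assign_origin(
    aln: GeneAlignment, groups: GroupMap, threshold: float = 0.8
) -> str:
    """Parental origin of the D haplotypes: 'parentC', 'parentO' or 'ambiguous'.

    Unique haplotypes of C, D and O are placed on a neighbor-joining tree
    built from p-distances; each D haplotype is assigned to the parent
    whose nearest haplotype (patristic distance) is closer.  The call is
    made when at least ``threshold`` of D haplotypes agree.
    """
    rows = _group_rows(aln, groups)
    for g in ("C", "D", "O"):
        if g not in rows:
            raise InputError(f"gene {aln.gene_id}: no haplotypes for group {g!r}")
    used = np.concatenate([rows["C"], rows["D"], rows["O"]])
    seqs = aln.seqs[used]
    labels = np.array(
        ["C"] * rows["C"].size + ["D"] * rows["D"].size + ["O"] * rows["O"].size
    )
    uniq, inverse = np.unique(seqs, axis=0, return_inverse=True)
    n_uniq = uniq.shape[0]
    if n_uniq < 2:
        logger.info("gene %s: fewer than two unique haplotypes", aln.gene_id)
        return "ambiguous"
    # Which groups does each unique haplotype carry?
    has = {g: np.zeros(n_uniq, dtype=bool) for g in ("C", "D", "O")}
    for k in range(len(used)):
        has[labels[k]][inverse[k]] = True

    pdist = _p_distance_matrix(uniq)
    if n_uniq >= 4:
        from skbio import DistanceMatrix
        from skbio.tree import nj

        ids = [f"h{k}" for k in range(n_uniq)]
        tree = nj(DistanceMatrix(pdist, ids))
        td = tree.tip_tip_distances(ids)
        dist = np.asarray(td.data)
    else:
        dist = pdist

    votes = {"C": 0, "O": 0}
    n_d = 0
    for k in range(n_uniq):
        if not has["D"][k]:
            continue
        weight = int(((inverse == k) & (labels == "D")).sum())
        d_c = 0.0 if has["C"][k] else min(
            (dist[k, j] for j in range(n_uniq) if has["C"][j]), default=np.inf
        )
        d_o = 0.0 if has["O"][k] else min(
            (dist[k, j] for j in range(n_uniq) if has["O"][j]), default=np.inf
        )
        n_d += weight
        if d_c < d_o:
            votes["C"] += weight
        elif d_o < d_c:
            votes["O"] += weight
    if n_d == 0:
        return "ambiguous"
    if votes["C"] >= threshold * n_d:
        return "parentC"
    if votes["O"] >= threshold * n_d:
        return "parentO"
    return "ambiguous"


def alternating_fixed_aa(aln: GeneAlignment, groups: GroupMap) -> Tuple[int, int]:
    """Counts of D-fixed residues matching C-fixed vs O-fixed states.

    Over amino-acid positions where C and O are fixed for different
    residues and D is fixed: (positions where D matches C, positions where
    D matches O).
    """
    rows = _group_rows(aln, groups)
    cod = _codon_indices(aln.seqs)
    aa_fixed: Dict[str, np.ndarray] = {}
    aa_state: Dict[str, np.ndarray] = {}
    for g in ("C", "D", "O"):
        if g not in rows or rows[g].size == 0:
            raise InputError(f"gene {aln.gene_id}: no haplotypes for group {g!r}")
        sub = cod[rows[g]]
        valid = (sub >= 0).all(axis=0)
        aa = np.where(sub >= 0, _AA_OF_CODON[np.maximum(sub, 0)], "?")
        fixed = valid & (aa == aa[0]).all(axis=0) & (aa[0] != "*")
        aa_fixed[g] = fixed
        aa_state[g] = aa[0]
    informative = (
        aa_fixed["C"] & aa_fixed["O"] & aa_fixed["D"] & (aa_state["C"] != aa_state["O"])
    )
    k_from_c = int((informative & (aa_state["D"] == aa_state["C"])).sum())
    k_from_o = int((informative & (aa_state["D"] == aa_state["O"])).sum())
    return k_from_c, k_from_o


@dataclass
class PsgCallSet:
    """Final PSG and hybrid-signal calls."""

    psg_from_c: List[str] = field(default_factory=list)
    psg_from_o: List[str] = field(default_factory=list)
    hybrid_signal: List[str] = field(default_factory=list)
    origin: Dict[str, str] = field(default_factory=dict)
    alternating: Dict[str, Tuple[int, int]] = field(default_factory=dict)


def _gene_record(aln: GeneAlignment, groups: GroupMap, grouping: str) -> tuple:
    """One gene x grouping record, sharing the codon-index computation."""
    side1, side2 = _sides(aln, groups, grouping)
    used = np.concatenate([side1, side2])
    valid = (_BASE_INDEX[aln.seqs[used]] >= 0).all(axis=0)
    s1 = aln.seqs[side1]
    s2 = aln.seqs[side2]
    fixed1 = (s1 == s1[0]).all(axis=0)
    fixed2 = (s2 == s2[0]).all(axis=0)
    S = int((valid & ~fixed1).sum())
    K = int((valid & fixed1 & fixed2 & (s1[0] != s2[0])).sum())

    cod = _codon_cache(aln)
    c1 = cod[side1]
    c2 = cod[side2]
    cvalid = (c1 >= 0).all(axis=0)
    cand = cvalid & (c1 == c1[0]).all(axis=0) & (c2 == c2[0]).all(axis=0) & (c1[0] != c2[0])
    n_fix = 0
    if cand.any():
        aa1 = _AA_OF_CODON[c1[0][cand]]
        aa2 = _AA_OF_CODON[c2[0][cand]]
        n_fix = int(((aa1 != aa2) & (aa1 != "*") & (aa2 != "*")).sum())
    return (aln.gene_id, grouping, S, K, n_fix, int((~valid).sum()))


def _codon_cache(aln: GeneAlignment) -> np.ndarray:
    cached = getattr(aln, "_codon_idx", None)
    if cached is None:
        cached = _codon_indices(aln.seqs)
        aln._codon_idx = cached  # type: ignore[attr-defined]
    return cached


def gene_stats(
    alignments: Iterable[GeneAlignment], groups: GroupMap
) -> pd.DataFrame:
    """Per-gene, per-grouping S/K/N_fix with gene-vs-genome HKA p values."""
    records = []
    for aln in alignments:
        for grouping in GROUPINGS:
            records.append(_gene_record(aln, groups, grouping))
    df = pd.DataFrame(
        records, columns=["gene", "grouping", "S", "K", "N_fix", "n_excluded"]
    )
    if df.empty:
        raise InputError("no genes to scan")
    parts = []
    for grouping, sub in df.groupby("grouping", sort=False):
        sub = sub.copy()
        S_tot = int(sub["S"].sum())
        K_tot = int(sub["K"].sum())
        chi2_p = [hka_test(s, k, S_tot, K_tot) for s, k in zip(sub["S"], sub["K"])]
        sub["hka_chi2"] = [c for c, _ in chi2_p]
        sub["hka_p"] = [p for _, p in chi2_p]
        sub["top_nfix"] = rank_top_fraction(sub["N_fix"].to_numpy())
        sub["nfix_percentile"] = 100.0 * sub["N_fix"].rank(pct=True, method="max")
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def call_psgs(
    stats: pd.DataFrame,
    alignments: Mapping[str, GeneAlignment],
    groups: GroupMap,
    hka_alpha: float = 0.01,
    origin_threshold: float = 0.8,
) -> PsgCallSet:
    """Apply the three PSG criteria and the two-criterion hybrid-signal rule.

    A gene is a PSG from parent X when, under the grouping pooling D with
    X, its HKA p is at most ``hka_alpha`` and its N_fix ranks in the top
    fraction, and its haplotype tree assigns D to X.  A gene passing the
    first two criteria under both groupings is a hybrid-signal gene.
    """
    calls = PsgCallSet()
    passing: Dict[str, set] = {}
    for _, row in stats.iterrows():
        ok = (row["hka_p"] == row["hka_p"]) and row["hka_p"] <= hka_alpha and row["top_nfix"]
        if ok:
            passing.setdefault(row["gene"], set()).add(row["grouping"])
    for gene in sorted(passing):
        groupings = passing[gene]
        if len(groupings) == 2:
            calls.hybrid_signal.append(gene)
            calls.alternating[gene] = alternating_fixed_aa(alignments[gene], groups)
        origin = assign_origin(alignments[gene], groups, origin_threshold)
        calls.origin[gene] = origin
        if origin == "parentC" and "DC_vs_O" in groupings:
            calls.psg_from_c.append(gene)
        elif origin == "parentO" and "DO_vs_C" in groupings:
            calls.psg_from_o.append(gene)
    return calls


def call_hybrid_signal(stats: pd.DataFrame, hka_alpha: float = 0.01) -> List[str]:
    """Genes passing the HKA and N_fix criteria under both groupings."""
    ok = stats[(stats["hka_p"].notna()) & (stats["hka_p"] <= hka_alpha) & stats["top_nfix"]]
    by_gene = ok.groupby("gene")["grouping"].nunique()
    return sorted(by_gene[by_gene == 2].index.tolist())


def scan_genes(
    alignments: Iterable[GeneAlignment],
    groups: GroupMap,
    hka_alpha: float = 0.01,
    origin_threshold: float = 0.8,
) -> Tuple[pd.DataFrame, PsgCallSet]:
    """Full scan: per-gene statistics plus PSG/hybrid-signal calls."""
    alns = {a.gene_id: a for a in alignments}
    stats = gene_stats(alns.values(), groups)
    calls = call_psgs(stats, alns, groups, hka_alpha, origin_threshold)
    return stats, calls
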