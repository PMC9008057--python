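"""Input/output and shared per-group allele summaries.

Reads the standard inputs of the pipeline -- a biallelic VCF, a
sample-to-lineage map (TSV with columns ``sample`` and ``group``), newick
gene-tree sets and per-gene FASTA alignments -- applies the long-indel
filter, and computes the per-group allele-frequency/fixedness summaries
that the site-pattern and indel tests consume.

Coordinate conventions: VCF positions are 1-based (as in the format);
internal window/BED arithmetic is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .network import GROUPS, ParameterError

logger = logging.getLogger(__name__)

# Fixedness codes used throughout.
FIXED_REF, FIXED_ALT, POLYMORPHIC, INSUFFICIENT = 0, 1, 2, 3
FIXED_CODES = {0: "fixed-ref", 1: "fixed-alt", 2: "polymorphic", 3: "insufficient-data"}


class InputError(ValueError):
    """Raised for malformed or inconsistent input data."""


class ConfigurationError(ValueError):
    """Raised when inputs disagree with each other (e.g. unmapped samples)."""


@dataclass(frozen=True)
class GroupMap:
    """Mapping from individual identifiers to lineage group labels."""

    assignment: Mapping[str, str]
    display_names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, group in dict(self.assignment).items():
            if group not in GROUPS:
                raise ConfigurationError(
                    f"sample {sample!r} assigned to unknown group {group!r}; expected one of {GROUPS}"
                )

    def group_of(self, sample: str) -> str:
        try:
            return dict(self.assignment)[sample]
        except KeyError:
            raise ConfigurationError(f"sample {sample!r} is not present in the group map")

    def samples_in(self, group: str) -> List[str]:
        return [s for s, g in dict(self.assignment).items() if g == group]

    @property
    def groups(self) -> List[str]:
        return [g for g in GROUPS if self.samples_in(g)]


def read_group_map(path: str | Path) -> GroupMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(df.columns):
        raise InputError(f"group map {path} must have columns 'sample' and 'group'")
    dup = df["sample"][df["sample"].duplicated()]
    if len(dup):
        raise ConfigurationError(f"duplicate sample(s) in group map: {sorted(set(dup))}")
    return GroupMap(dict(zip(df["sample"], df["group"])))


def write_group_map(groups: GroupMap, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(groups.assignment), "group": list(groups.assignment.values())}
    ).to_csv(path, sep="\t", index=False)


@dataclass
class VariantTable:
    """Biallelic markers with per-individual diploid genotypes.

    ``sites`` columns: chrom, pos (1-based), ref, alt, vclass ('snp' or
    'indel'), indel_len (0 for SNPs).  ``genotypes`` holds alt-allele
    dosages 0/1/2 with -1 for missing, shape (n_sites, n_samples).
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: List[str]

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise InputError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            sites=self.sites.loc[np.asarray(mask)].reset_index(drop=True),
            genotypes=self.genotypes[np.asarray(mask)],
            samples=list(self.samples),
        )


_GT_TYPE_MAP = np.array([0, 1, -1, 2], dtype=np.int8)  # cyvcf2 gt_types order


def read_variants(
    vcf_path: str | Path, group_map_path: str | Path
) -> tuple[VariantTable, GroupMap]:
    """Read a biallelic VCF and its group map.

    Multi-allelic records are skipped (the count is logged); marker class
    and indel length are derived from REF/ALT lengths.
    """
    from cyvcf2 import VCF  # deferred: htslib import is relatively heavy

    groups = read_group_map(group_map_path)
    try:
        vcf = VCF(str(vcf_path), gts012=False)
    except Exception as exc:  # pragma: no cover - htslib error text varies
        raise InputError(f"cannot parse VCF {vcf_path}: {exc}") from exc
    samples = list(vcf.samples)
    for s in samples:
        groups.group_of(s)  # raises ConfigurationError naming the sample

    rows = []
    gts = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        ref, alt = v.REF, v.ALT[0]
        indel_len = abs(len(ref) - len(alt))
        rows.append(
            (
                v.CHROM,
                v.POS,
                ref,
                alt,
                "indel" if indel_len > 0 else "snp",
                indel_len,
            )
        )
        gts.append(_GT_TYPE_MAP[np.asarray(v.gt_types)])
    if n_skipped:
        logger.info("skipped %d multi-allelic record(s) in %s", n_skipped, vcf_path)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vclass", "indel_len"])
    genotypes = (
        np.vstack(gts) if gts else np.zeros((0, len(samples)), dtype=np.int8)
    )
    table = VariantTable(sites=sites, genotypes=genotypes, samples=samples)
    table.n_multiallelic_skipped = n_skipped  # type: ignore[attr-defined]
    return table, groups


def write_vcf(table: VariantTable, path: str | Path, contig_length: int = 50_000_000) -> None:
    """Write the table as an uncompressed VCF 4.2 with GT-only genotypes."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(table.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom},length={contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        sites = table.sites
        for i in range(table.n_sites):
            row = sites.iloc[i]
            calls = "\t".join(gt_str[int(g)] for g in table.genotypes[i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def filter_long_indels(table: VariantTable, min_len: int = 5) -> VariantTable:
    """Retain indels of length >= ``min_len`` (row order preserved)."""
    if min_len < 1:
        raise ParameterError(f"min_len must be >= 1, got {min_len}")
    mask = (table.sites["vclass"] == "indel") & (table.sites["indel_len"] >= min_len)
    return table.subset(mask.to_numpy())


@dataclass
class GroupAlleleSummary:
    """Per-marker, per-group allele summaries.

    ``alt_freq`` is the alt-allele frequency among called genotypes (NaN if
    none), ``fixed`` the fixedness code, ``derived_freq`` the
    outgroup-polarized derived-allele frequency (NaN where the outgroup A
    is not fixed, i.e. the marker is unpolarizable).
    """

    sites: pd.DataFrame
    groups: List[str]
    alt_freq: Dict[str, np.ndarray]
    call_rate: Dict[str, np.ndarray]
    fixed: Dict[str, np.ndarray]
    derived_freq: Dict[str, np.ndarray] = field(default_factory=dict)
    polarizable: Optional[np.ndarray] = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset(self, mask: np.ndarray) -> "GroupAlleleSummary":
        mask = np.asarray(mask)
        return GroupAlleleSummary(
            sites=self.sites.loc[mask].reset_index(drop=True),
            groups=list(self.groups),
            alt_freq={g: a[mask] for g, a in self.alt_freq.items()},
            call_rate={g: a[mask] for g, a in self.call_rate.items()},
            fixed={g: a[mask] for g, a in self.fixed.items()},
            derived_freq={g: a[mask] for g, a in self.derived_freq.items()},
            polarizable=None if self.polarizable is None else self.polarizable[mask],
        )


def _polarize(summary: GroupAlleleSummary) -> None:
    """Fill derived-allele frequencies using the outgroup's fixed state."""
    if "A" not in summary.groups:
        summary.polarizable = np.zeros(summary.n_sites, dtype=bool)
        return
    a_fixed = summary.fixed["A"]
    polarizable = (a_fixed == FIXED_REF) | (a_fixed == FIXED_ALT)
    flip = a_fixed == FIXED_ALT
    for g in summary.groups:
        f = summary.alt_freq[g].copy()
        f[flip] = 1.0 - f[flip]
        f[~polarizable] = np.nan
        summary.derived_freq[g] = f
    summary.polarizable = polarizable
    n_un = int((~polarizable).sum())
    if n_un:
        logger.info("%d marker(s) unpolarizable by the outgroup", n_un)


def summarize_groups(
    table: VariantTable, groups: GroupMap, min_call_rate: float = 0.7
) -> GroupAlleleSummary:
    """Per-group allele frequencies, call rates and fixedness states.

    A group is called fixed at a marker iff its call rate is at least
    ``min_call_rate`` and every called genotype is the same homozygote;
    groups below the call-rate floor are 'insufficient-data'.
    """
    present = groups.groups
    sample_idx = {s: k for k, s in enumerate(table.samples)}
    alt_freq: Dict[str, np.ndarray] = {}
    call_rate: Dict[str, np.ndarray] = {}
    fixed: Dict[str, np.ndarray] = {}
    for g in present:
        cols = [sample_idx[s] for s in groups.samples_in(g) if s in sample_idx]
        if not cols:
            alt_freq[g] = np.full(table.n_sites, np.nan)
            call_rate[g] = np.zeros(table.n_sites)
            fixed[g] = np.full(table.n_sites, INSUFFICIENT, dtype=np.int8)
            continue
        sub = table.genotypes[:, cols]
        called = sub >= 0
        n_called = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(called, sub, 0).sum(axis=1) / (2.0 * n_called)
        freq[n_called == 0] = np.nan
        rate = n_called / sub.shape[1]
        all_ref = np.all((sub == 0) | ~called, axis=1) & (n_called > 0)
        all_alt = np.all((sub == 2) | ~called, axis=1) & (n_called > 0)
        code = np.full(table.n_sites, POLYMORPHIC, dtype=np.int8)
        code[all_ref] = FIXED_REF
        code[all_alt] = FIXED_ALT
        code[rate < min_call_rate] = INSUFFICIENT
        alt_freq[g], call_rate[g], fixed[g] = freq, rate, code
    summary = GroupAlleleSummary(
        sites=table.sites.copy(),
        groups=present,
        alt_freq=alt_freq,
        call_rate=call_rate,
        fixed=fixed,
    )
    _polarize(summary)
    return summary


@dataclass
class GeneAlignment:
    """One gene's haplotype alignment as a byte matrix (rows = haplotypes)."""

    gene_id: str
    names: List[str]
    seqs: np.ndarray  # uint8 matrix of ASCII codes, shape (n_haplotypes, length)

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    def sequence(self, i: int) -> str:
        return self.seqs[i].tobytes().decode("ascii")


def alignment_from_strings(gene_id: str, named_seqs: Sequence[tuple[str, str]]) -> GeneAlignment:
    names = [n for n, _ in named_seqs]
    lengths = {len(s) for _, s in named_seqs}
    if len(lengths) > 1:
        raise InputError(f"gene {gene_id}: unequal sequence lengths {sorted(lengths)}")
    seqs = np.frombuffer(
        "".join(s.upper() for _, s in named_seqs).encode("ascii"), dtype=np.uint8
    ).reshape(len(names), -1) if names else np.zeros((0, 0), dtype=np.uint8)
    return GeneAlignment(gene_id=gene_id, names=names, seqs=seqs.copy())


def read_alignments(directory: str | Path, codon_mode: bool = True) -> Dict[str, GeneAlignment]:
    """Read per-gene FASTA alignments (``*.fa`` / ``*.fasta``) from a directory."""
    directory = Path(directory)
    out: Dict[str, GeneAlignment] = {}
    for path in sorted(list(directory.glob("*.fa")) + list(directory.glob("*.fasta"))):
        gene_id = path.stem
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        aln = alignment_from_strings(gene_id, records)
        if codon_mode and aln.length % 3:
            raise InputError(f"gene {gene_id}: length {aln.length} not divisible by 3")
        out[gene_id] = aln
    return out


def write_alignments(alignments: Iterable[GeneAlignment], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for aln in alignments:
        with open(directory / f"{aln.gene_id}.fa", "w") as fh:
            for i, name in enumerate(aln.names):
                fh.write(f">{name}\n{aln.sequence(i)}\n")
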