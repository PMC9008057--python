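"""Long-indel PIV/AV classification and the hybrid-signal chi-square tests.

Long indels (>= 5 bp) are treated as homoplasy-free markers.  A marker
that is fixed within each of the four lineages and variable between them
is classified by which two ingroups share an allele:

* PIV classes CD, OD, CO -- the shared allele is absent from the outgroup
  A, so the sharing arose between the first and last lineage splits and is
  phylogenetically informative;
* AV classes CDA, ODA, COA -- the shared allele is also carried by A, so
  the pattern reflects ancestral variation (or a lineage-specific change).

Observing significant PIV signal simultaneously for CD and for OD is the
population-level signature of a hybrid origin of D: no single placement
of D on a tree can make both sharing classes exceed the C-O reference.
The reference column of each 2x2 test is (CO, COA), because C-O sharing
cannot be clade signal wherever D is placed, making it the natural
lineage-sorting-plus-noise baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .io import FIXED_ALT, FIXED_REF, GroupAlleleSummary, GroupMap, InputError, VariantTable, filter_long_indels, summarize_groups
from .network import GROUPS, ParameterError
from .stats import UndefinedResult, chi2_homogeneity, yates_chi2

SHARING_CLASSES = ("CD", "OD", "CO", "CDA", "ODA", "COA")
UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class PivCounts:
    """Counts of the six fixed-indel sharing classes."""

    CD: int = 0
    OD: int = 0
    CO: int = 0
    CDA: int = 0
    ODA: int = 0
    COA: int = 0
    n_fixed: int = 0  # inter-group fixed indels entering classification
    n_unclassifiable: int = 0

    def __post_init__(self) -> None:
        values = [getattr(self, c) for c in SHARING_CLASSES]
        if min(values + [self.n_fixed, self.n_unclassifiable]) < 0:
            raise ParameterError("counts must be non-negative")
        if self.n_fixed and sum(values) + self.n_unclassifiable > self.n_fixed:
            raise ParameterError("class counts exceed the fixed-indel total")

    def as_dict(self) -> Dict[str, int]:
        return {c: int(getattr(self, c)) for c in SHARING_CLASSES}


def fixed_intergroup_mask(summary: GroupAlleleSummary) -> np.ndarray:
    """Markers where all four groups are fixed but not all for one allele."""
    fixed_states = []
    for g in GROUPS:
        if g not in summary.fixed:
            raise InputError(f"group {g!r} absent from summary")
        fixed_states.append(summary.fixed[g])
    f = np.stack(fixed_states, axis=1)
    all_fixed = np.all((f == FIXED_REF) | (f == FIXED_ALT), axis=1)
    invariant = np.all(f == f[:, :1], axis=1)
    return all_fixed & ~invariant


def fixed_intergroup_indels(summary: GroupAlleleSummary) -> GroupAlleleSummary:
    """Subset of the (long-indel) summary that is fixed between groups."""
    return summary.subset(fixed_intergroup_mask(summary))


def classify_sharing(xC: int, xD: int, xO: int, xA: int) -> str:
    """Classify one fixed-state pattern into a PIV/AV sharing class.

    Inputs are fixedness codes (fixed-ref or fixed-alt per group).  PIV
    classes pair two ingroups on the allele absent from A; AV classes pair
    an ingroup pair (including A's allele) against the remaining lineage.
    """
    states = (xC, xD, xO, xA)
    for s in states:
        if s not in (FIXED_REF, FIXED_ALT):
            raise ParameterError(f"classify_sharing requires fixed states, got {states}")
    if xC == xD != xA and xO == xA:
        return "CD"
    if xO == xD != xA and xC == xA:
        return "OD"
    if xC == xO != xA and xD == xA:
        return "CO"
    if xC == xD == xA != xO:
        return "CDA"
    if xO == xD == xA != xC:
        return "ODA"
    if xC == xO == xA != xD:
        return "COA"
    return UNCLASSIFIABLE


def _classify_vector(f: np.ndarray) -> np.ndarray:
    """Vectorized sharing classification; f is (n, 4) of fixed codes."""
    lut = np.full(16, -1, dtype=np.int8)
    for idx in range(16):
        bits = [(idx >> k) & 1 for k in (3, 2, 1, 0)]
        label = classify_sharing(*bits)
        if label in SHARING_CLASSES:
            lut[idx] = SHARING_CLASSES.index(label)
    code = (f[:, 0] << 3) | (f[:, 1] << 2) | (f[:, 2] << 1) | f[:, 3]
    return lut[code]


def piv_census(
    table: VariantTable,
    groups: GroupMap,
    min_indel_len: int = 5,
    min_call_rate: float = 0.7,
) -> Tuple[PivCounts, pd.DataFrame]:
    """Count PIV/AV sharing classes among inter-group fixed long indels.

    Returns the counts plus a per-marker table (chrom, pos, class) of the
    classified markers for genome mapping.
    """
    long_indels = filter_long_indels(table, min_indel_len)
    summary = summarize_groups(long_indels, groups, min_call_rate)
    return piv_census_from_summary(summary)


def piv_census_from_summary(summary: GroupAlleleSummary) -> Tuple[PivCounts, pd.DataFrame]:
    mask = fixed_intergroup_mask(summary)
    sub = summary.subset(mask)
    if sub.n_sites == 0:
        return PivCounts(), pd.DataFrame(columns=["chrom", "pos", "sharing"])
    f = np.stack([sub.fixed[g] for g in GROUPS], axis=1)
    cls = _classify_vector(f)
    counts = {c: int((cls == k).sum()) for k, c in enumerate(SHARING_CLASSES)}
    n_uncl = int((cls < 0).sum())
    classified = pd.DataFrame(
        {
            "chrom": sub.sites["chrom"].to_numpy(),
            "pos": sub.sites["pos"].to_numpy(),
            "sharing": [SHARING_CLASSES[k] if k >= 0 else UNCLASSIFIABLE for k in cls],
        }
    )
    return (
        PivCounts(n_fixed=int(mask.sum()), n_unclassifiable=n_uncl, **counts),
        classified,
    )


@dataclass
class PivSignalResult:
    """Yates-corrected chi-square tests of the two PIV sharing groups.

    Each 2x2 contrasts a focal (PIV, AV) pair against the (CO, COA)
    reference: table_cd = [[CD, CDA], [CO, COA]], table_od likewise.
    """

    table_cd: Tuple[Tuple[int, int], Tuple[int, int]]
    table_od: Tuple[Tuple[int, int], Tuple[int, int]]
    chi2_cd: float
    p_cd: float
    chi2_od: float
    p_od: float
    signal_cd: bool
    signal_od: bool
    alpha: float = 0.05


def piv_signal_test(counts: PivCounts, alpha: float = 0.05) -> PivSignalResult:
    """Test PIV enrichment of CD and of OD against the C-O reference."""
    t_cd = ((counts.CD, counts.CDA), (counts.CO, counts.COA))
    t_od = ((counts.OD, counts.ODA), (counts.CO, counts.COA))
    if sum(t_cd[0]) + sum(t_cd[1]) == 0 or sum(t_od[0]) + sum(t_od[1]) == 0:
        raise UndefinedResult("PIV signal test undefined: an empty 2x2 table")
    chi2_cd, p_cd = yates_chi2(*t_cd[0], *t_cd[1])
    chi2_od, p_od = yates_chi2(*t_od[0], *t_od[1])
    return PivSignalResult(
        table_cd=t_cd,
        table_od=t_od,
        chi2_cd=chi2_cd,
        p_cd=p_cd,
        chi2_od=chi2_od,
        p_od=p_od,
        signal_cd=bool(p_cd == p_cd and p_cd <= alpha),
        signal_od=bool(p_od == p_od and p_od <= alpha),
        alpha=alpha,
    )


def piv_genome_map(
    classified: pd.DataFrame, window_size: int = 1_000_000
) -> Tuple[pd.DataFrame, float]:
    """Per-window CD/OD counts (BED-style, 0-based half-open) + homogeneity p."""
    sub = classified[classified["sharing"].isin(["CD", "OD"])]
    if sub.empty:
        return (
            pd.DataFrame(columns=["chrom", "start", "end", "n_CD", "n_OD"]),
            float("nan"),
        )
    start = ((sub["pos"].astype(int) - 1) // window_size) * window_size
    df = pd.DataFrame(
        {"chrom": sub["chrom"].to_numpy(), "start": start.to_numpy(), "sharing": sub["sharing"].to_numpy()}
    )
    table = (
        df.groupby(["chrom", "start", "sharing"]).size().unstack(fill_value=0)
        .reindex(columns=["CD", "OD"], fill_value=0)
        .reset_index()
        .rename(columns={"CD": "n_CD", "OD": "n_OD"})
    )
    table["end"] = table["start"] + window_size
    table = table[["chrom", "start", "end", "n_CD", "n_OD"]].sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)
    p = chi2_homogeneity(table["n_CD"].to_numpy(), table["n_OD"].to_numpy())
    return table, p
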