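"""Gene-tree topology census and the ILS-only simulation null.

Rooted by the outgroup A, a gene tree for the three ingroups falls into
topology I (C and D sister), II (D and O sister) or III (C and O sister).
Under lineage sorting alone the two minor topologies are equally
frequent, so an excess of II over III is the census-level signature of
gene flow between D and O.  The ILS null simulates topology counts under
a gamma-free network and compares the replicate III/II ratios with the
observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps

from .coalescent import topology_probabilities
from .io import GroupMap, InputError
from .network import GROUPS, ParameterError, SpeciesNetwork
from .simulate import sample_topology_counts
from .stats import UndefinedResult, chi2_homogeneity
from .trees import GeneTreeSet

PAIR_OF_LABEL = {"I": ("C", "D"), "II": ("D", "O"), "III": ("C", "O")}
DISCARDED = "discarded"


@dataclass(frozen=True)
class TopologyCounts:
    """Counts of the three rooted ingroup topologies among classified trees."""

    n_I: int
    n_II: int
    n_III: int
    n_discarded: int = 0

    def __post_init__(self) -> None:
        if min(self.n_I, self.n_II, self.n_III, self.n_discarded) < 0:
            raise ParameterError("topology counts must be non-negative")

    @property
    def total_classified(self) -> int:
        return self.n_I + self.n_II + self.n_III


def _leaf_group(label: str, groups: GroupMap) -> str:
    """Group of a tip label, accepting either individual or haplotype names."""
    assignment = dict(groups.assignment)
    if label in assignment:
        return assignment[label]
    stem = label.rsplit("_", 1)[0]
    if stem in assignment:
        return assignment[stem]
    raise InputError(f"tip {label!r} cannot be mapped to a group")


def _support_value(node: dendropy.Node) -> Optional[float]:
    label = node.label
    if label is None:
        return None
    try:
        return float(label)
    except ValueError:
        return None


def classify_topology(
    tree: dendropy.Tree, groups: GroupMap, support_min: float = 50
) -> str:
    """Classify one rooted gene tree as 'I', 'II', 'III' or 'discarded'.

    The tree is read as rooted on the outgroup A side.  A tree is
    discarded when any ingroup is non-monophyletic, when no ingroup pair
    forms a clade to the exclusion of A, or when the pair node carries a
    support value below ``support_min``.
    """
    leaf_groups: Dict[int, int] = {}
    totals = np.zeros(4, dtype=np.int64)
    gidx = {g: k for k, g in enumerate(GROUPS)}
    for leaf in tree.leaf_node_iter():
        k = gidx[_leaf_group(leaf.taxon.label, groups)]
        leaf_groups[id(leaf)] = k
        totals[k] += 1
    for g in GROUPS:
        if totals[gidx[g]] == 0:
            raise InputError(f"tree has no tips from group {g!r}")

    counts: Dict[int, np.ndarray] = {}
    by_pattern: Dict[tuple, dendropy.Node] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            c = np.zeros(4, dtype=np.int64)
            c[leaf_groups[id(node)]] = 1
        else:
            c = np.zeros(4, dtype=np.int64)
            for ch in node.child_nodes():
                c += counts[id(ch)]
        counts[id(node)] = c
        by_pattern.setdefault(tuple(c), node)

    def _pure(members: Sequence[str]) -> tuple:
        return tuple(totals[gidx[g]] if g in members else 0 for g in GROUPS)

    def _find(members: Sequence[str]) -> Tuple[bool, Optional[dendropy.Node]]:
        """Is the leaf set of ``members`` one side of some edge? Return its node."""
        want = _pure(members)
        if want in by_pattern:
            return True, by_pattern[want]
        comp = tuple(t - w for t, w in zip(totals, want))
        if comp in by_pattern:
            return True, by_pattern[comp]
        return False, None

    for g in ("C", "D", "O"):
        if totals[gidx[g]] > 1 and not _find((g,))[0]:
            return DISCARDED

    hits = []
    for label, pair in PAIR_OF_LABEL.items():
        found, node = _find(pair)
        if found:
            hits.append((label, node))
    if len(hits) != 1:
        return DISCARDED
    label, node = hits[0]
    support = _support_value(node) if node is not None else None
    if support is not None and support < support_min:
        return DISCARDED
    return label


def classify_all(
    trees: GeneTreeSet, groups: GroupMap, support_min: float = 50
) -> List[str]:
    return [classify_topology(t, groups, support_min) for t in trees]


def census(trees: GeneTreeSet, groups: GroupMap, support_min: float = 50) -> TopologyCounts:
    """Count topologies I/II/III (and discarded trees) over a gene-tree set."""
    if not len(trees):
        raise InputError("empty gene-tree set")
    labels = classify_all(trees, groups, support_min)
    return TopologyCounts(
        n_I=labels.count("I"),
        n_II=labels.count("II"),
        n_III=labels.count("III"),
        n_discarded=labels.count(DISCARDED),
    )


def minor_topology_binomial_test(counts: TopologyCounts) -> float:
    """Exact two-tailed binomial test of N_II vs N_III at p = 0.5.

    Two-tailed mass is the sum of outcome probabilities no larger than
    that of the observed count.
    """
    n = counts.n_II + counts.n_III
    if n == 0:
        raise UndefinedResult("binomial test undefined: no minor-topology trees")
    return float(sps.binomtest(counts.n_II, n, 0.5, alternative="two-sided").pvalue)


def calibrate_internal_branch(counts: TopologyCounts) -> float:
    """Internal branch length T for which an ILS-only null matches P(I).

    Under gamma = 0 and one lineage per group, P(I) = 1 - (2/3)e^{-T}, so
    T = -ln(1.5 (1 - P(I))).  Requires the observed topology-I fraction to
    exceed 1/3.
    """
    total = counts.total_classified
    if total == 0:
        raise UndefinedResult("no classified trees")
    p1 = counts.n_I / total
    if p1 <= 1.0 / 3.0:
        raise ParameterError(
            f"observed topology-I fraction {p1:.3f} <= 1/3; no ILS-only branch length fits"
        )
    return -math.log(1.5 * (1.0 - p1))


def null_network_from_counts(
    counts: TopologyCounts, t_h: float = 5.0, outgroup_extra: float = 3.0
) -> SpeciesNetwork:
    """Gamma-free network whose expected P(I) matches the observed census."""
    T = calibrate_internal_branch(counts)
    return SpeciesNetwork(t_h=t_h, t_co=t_h + T, t_root=t_h + T + outgroup_extra, gamma=0.0)


@dataclass
class RatioTestResult:
    """Observed vs simulated minor-topology ratio under the ILS null."""

    r_obs: float
    replicate_ratios: np.ndarray
    p_empirical: float
    t_stat: float
    p_t: float
    n_reps: int
    loci_per_rep: int
    seed: int
    n_redrawn: int = 0
    calibration: Optional[str] = None


def ils_null_ratio_test(
    counts: TopologyCounts,
    network: SpeciesNetwork,
    loci_per_rep: Optional[int] = None,
    n_reps: int = 10_000,
    seed: int = 0,
    method: str = "multinomial",
) -> RatioTestResult:
    """Compare the observed III/II ratio with its ILS-only null distribution.

    Each replicate simulates ``loci_per_rep`` gene-tree topologies under
    the gamma-free network (default: the observed census size) and records
    r = N_III / N_II.  Replicates with N_II = 0 are redrawn (bounded) and
    counted.  The empirical two-sided p is floored at 1/n_reps; the
    one-sample two-tailed t test of the replicate ratios against the
    observed ratio is reported alongside.
    """
    if network.gamma != 0.0:
        raise ParameterError("the ILS null requires a network with gamma = 0")
    if counts.n_II == 0:
        raise UndefinedResult("observed N_II is zero; ratio undefined")
    loci = loci_per_rep if loci_per_rep is not None else counts.total_classified
    if loci < 1:
        raise ParameterError("loci_per_rep must be >= 1")
    r_obs = counts.n_III / counts.n_II
    rng = np.random.default_rng(seed)

    if method == "multinomial":
        probs = list(topology_probabilities(network))
        draws = rng.multinomial(loci, probs, size=n_reps)
        n_redrawn = 0
        for _ in range(100):
            bad = draws[:, 1] == 0
            if not bad.any():
                break
            n_redrawn += int(bad.sum())
            draws[bad] = rng.multinomial(loci, probs, size=int(bad.sum()))
        else:
            raise UndefinedResult("could not draw replicates with N_II > 0")
        ratios = draws[:, 2] / draws[:, 1]
    elif method == "genealogy":
        ratios_list = []
        n_redrawn = 0
        for _ in range(n_reps):
            for _retry in range(100):
                n1, n2, n3 = sample_topology_counts(network, loci, rng, method="genealogy")
                if n2 > 0:
                    ratios_list.append(n3 / n2)
                    break
                n_redrawn += 1
            else:
                raise UndefinedResult("could not draw a replicate with N_II > 0")
        ratios = np.array(ratios_list)
    else:
        raise ParameterError(f"unknown method {method!r}")

    n_low = int((ratios <= r_obs).sum())
    n_high = int((ratios >= r_obs).sum())
    p_emp = 2.0 * min(n_low, n_high) / n_reps
    p_emp = min(1.0, max(p_emp, 1.0 / n_reps))
    t_stat, p_t = sps.ttest_1samp(ratios, r_obs)
    return RatioTestResult(
        r_obs=r_obs,
        replicate_ratios=ratios,
        p_empirical=float(p_emp),
        t_stat=float(t_stat),
        p_t=float(p_t),
        n_reps=n_reps,
        loci_per_rep=loci,
        seed=seed,
        n_redrawn=n_redrawn,
        calibration=f"T={network.internal_branch:.4f} (gamma=0)",
    )


def windowed_distribution(
    anchors: Sequence[Tuple[str, int]],
    labels: Sequence[str],
    window_size: int = 1_000_000,
) -> Tuple[pd.DataFrame, float]:
    """Per-window counts of topologies I and II plus a homogeneity test.

    Windows are 0-based half-open.  The chi-square homogeneity test of the
    II/(I+II) fraction across windows pools consecutive windows until all
    expected counts reach 5; p is NaN when fewer than two pooled windows
    remain.
    """
    if anchors is None:
        raise InputError("windowed distribution requires genomic anchors")
    if len(anchors) != len(labels):
        raise InputError(f"{len(anchors)} anchors for {len(labels)} labels")
    rows = []
    for (chrom, pos), lab in zip(anchors, labels):
        if lab in ("I", "II"):
            start = ((int(pos) - 1) // window_size) * window_size
            rows.append((chrom, start, lab))
    if not rows:
        return (
            pd.DataFrame(columns=["chrom", "start", "end", "n_I", "n_II"]),
            float("nan"),
        )
    df = pd.DataFrame(rows, columns=["chrom", "start", "label"])
    table = (
        df.groupby(["chrom", "start", "label"]).size().unstack(fill_value=0)
        .reindex(columns=["I", "II"], fill_value=0)
        .reset_index()
        .rename(columns={"I": "n_I", "II": "n_II"})
    )
    table["end"] = table["start"] + window_size
    table = table[["chrom", "start", "end", "n_I", "n_II"]].sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)
    p = chi2_homogeneity(
        table["n_I"].to_numpy(), table["n_II"].to_numpy(), min_expected=5.0
    )
    return table, p
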