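"""Parameter objects for the four-lineage species network and mutation process.

The system modelled throughout this package is a rooted four-lineage
phylogeny: two parental lineages C and O, a putative hybrid lineage D that
originates at time ``t_h`` from the ancestors of C and O with mixing
proportion ``gamma`` (fraction of D's ancestry drawn from the O-side
parent), and an outgroup A.  With ``gamma = 0`` the network collapses to
the species tree (((C, D), O), A).

All times are measured backwards from the present in coalescent units
(one unit = the expected time for a pair of lineages to coalesce in a
reference-size population).  Conversion to calendar time is deliberately
out of scope; only the ordering ``t_h < t_co < t_root`` matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

GROUPS = ("C", "D", "O", "A")

#: Branch identifiers used for per-branch relative population sizes.
BRANCHES = ("C", "D", "O", "A", "CO", "ROOT")


class ParameterError(ValueError):
    """Raised for invalid model parameters."""


@dataclass(frozen=True)
class SpeciesNetwork:
    """Four-lineage species network with one optional hybrid edge.

    Parameters
    ----------
    t_h:
        Hybrid origin of D (also the divergence of D from its parents),
        in coalescent units before present.
    t_co:
        Split of the C- and O-ancestors.  The internal branch relevant to
        lineage sorting has length ``T = t_co - t_h``.
    t_root:
        Ingroup/outgroup (A) split.
    gamma:
        Probability that a D lineage traces its ancestry to the O-side
        parent at ``t_h``; ``1 - gamma`` to the C-side parent.
    pop_sizes:
        Optional per-branch relative population sizes (default 1 for every
        branch); coalescence within a branch proceeds at rate
        ``1 / size`` per pair per coalescent unit.
    """

    t_h: float = 5.0
    t_co: float = 6.0
    t_root: float = 9.0
    gamma: float = 0.11
    pop_sizes: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = (self.t_h, self.t_co, self.t_root)
        if not all(math.isfinite(t) and t > 0 for t in times):
            raise ParameterError("all split times must be strictly positive and finite")
        if not (self.t_h < self.t_co < self.t_root):
            raise ParameterError(
                f"require 0 < t_h < t_co < t_root, got {self.t_h}, {self.t_co}, {self.t_root}"
            )
        if not (0.0 <= self.gamma <= 1.0):
            raise ParameterError(f"gamma must lie in [0, 1], got {self.gamma}")
        for branch, size in dict(self.pop_sizes).items():
            if branch not in BRANCHES:
                raise ParameterError(f"unknown branch {branch!r}; expected one of {BRANCHES}")
            if not (math.isfinite(size) and size > 0):
                raise ParameterError(f"population size for {branch!r} must be positive")

    @property
    def internal_branch(self) -> float:
        """Length ``T = t_co - t_h`` of the internal branch, in coalescent units."""
        return self.t_co - self.t_h

    def size(self, branch: str) -> float:
        return float(dict(self.pop_sizes).get(branch, 1.0))


@dataclass(frozen=True)
class SampleDesign:
    """Number of sampled haploid lineages per group.

    Diploid genotypes are emitted by pairing consecutive haplotypes of the
    same individual, so haploid counts must be even whenever genotypes are
    requested.  The default mirrors the resequencing census of the study
    system (10 C, 27 D, 7 O and 3 A diploid individuals).
    """

    haploids: Mapping[str, int] = field(
        default_factory=lambda: {"C": 20, "D": 54, "O": 14, "A": 6}
    )

    def __post_init__(self) -> None:
        counts = dict(self.haploids)
        for g in GROUPS:
            n = counts.get(g, 0)
            if n < 1:
                raise ParameterError(f"group {g!r} needs at least one sampled lineage")

    @classmethod
    def from_individuals(cls, C: int, D: int, O: int, A: int) -> "SampleDesign":
        """Build a design from diploid individual counts."""
        return cls({"C": 2 * C, "D": 2 * D, "O": 2 * O, "A": 2 * A})

    def n_haploids(self, group: str) -> int:
        return int(dict(self.haploids)[group])

    @property
    def total_haploids(self) -> int:
        return sum(self.n_haploids(g) for g in GROUPS)

    def individuals(self, group: str) -> list[str]:
        """Individual identifiers; haploid counts must be even."""
        n = self.n_haploids(group)
        if n % 2:
            raise ParameterError(
                f"group {group!r} has an odd haploid count ({n}); cannot pair into diploids"
            )
        return [f"{group}{i}" for i in range(1, n // 2 + 1)]

    def haplotype_names(self, group: str) -> list[str]:
        """Haplotype labels ``<ind>_1`` / ``<ind>_2`` (or ``<group><i>_1`` singles)."""
        n = self.n_haploids(group)
        if n % 2 == 0:
            return [f"{group}{(k // 2) + 1}_{(k % 2) + 1}" for k in range(n)]
        return [f"{group}{k + 1}_1" for k in range(n)]


@dataclass(frozen=True)
class MutationModel:
    """Infinite-sites mutation process layered on simulated genealogies.

    ``theta`` is the expected number of mutations per unit of total branch
    length at one locus.  A fraction ``indel_fraction`` of mutations are
    emitted as indels whose lengths follow ``min_indel_len + Geometric(p)``
    (support starting at 0), the rest as SNPs.
    """

    theta: float = 5.0
    indel_fraction: float = 0.066
    min_indel_len: int = 5
    indel_geom_p: float = 0.5
    infinite_sites: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.theta) and self.theta >= 0):
            raise ParameterError("theta must be finite and >= 0")
        if not (0.0 <= self.indel_fraction <= 1.0):
            raise ParameterError("indel_fraction must lie in [0, 1]")
        if self.min_indel_len < 1:
            raise ParameterError("min_indel_len must be >= 1")
        if not (0.0 < self.indel_geom_p <= 1.0):
            raise ParameterError("indel_geom_p must lie in (0, 1]")
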