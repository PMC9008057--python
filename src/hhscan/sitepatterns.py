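"""Population-level site-pattern tests: ABBA-BABA D and a hybrid invariant.

Both statistics are computed from per-group allele frequencies (all
individuals of a lineage pooled) and use a delete-one block jackknife
over contiguous marker blocks for standard errors.

For the four-taxon ordering (P1, P2, P3, Out) and frequencies
(p1, p2, p3, p4):

    ABBA = (1 - p1) p2 p3 (1 - p4),   BABA = p1 (1 - p2) p3 (1 - p4)
    D = sum(ABBA - BABA) / sum(ABBA + BABA)

Positive D indicates excess derived-allele sharing between P2 and P3.

The hybrid test works on outgroup-polarized derived frequencies for the
quartet (Out, P1, Hybrid, P2).  Writing f_ABBA, f_AABB and f_ABAB for the
frequency-weighted pattern sums in which respectively P1+Hybrid, Hybrid+P2
and P1+P2 share the derived allele, f_ABAB is the lineage-sorting
baseline: both pattern excesses f_ABBA - f_ABAB and f_AABB - f_ABAB have
zero expectation without hybridization, and under admixture their sizes
are proportional to the two parental contributions, giving

    gamma_hat = (f_AABB - f_ABAB) / ((f_ABBA - f_ABAB) + (f_AABB - f_ABAB))

as the estimated fraction of the hybrid's ancestry drawn from P2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .io import GroupAlleleSummary
from .network import ParameterError
from .stats import UndefinedResult, block_jackknife_ratio

__all__ = ["DResult", "HydeResult", "dstat", "hybrid_invariant_test", "z_to_one_tailed_p"]


def z_to_one_tailed_p(z: float) -> float:
    """Upper-tail standard-normal probability at ``z``."""
    if not math.isfinite(z):
        raise ParameterError(f"z must be finite, got {z}")
    return float(sps.norm.sf(z))


@dataclass
class DResult:
    """ABBA-BABA D with block-jackknife standard error."""

    D: float
    se: float
    Z: float
    p: float  # two-tailed, Student-t reference with n_blocks - 1 df
    n_markers: int
    n_blocks: int
    block_size: int
    order: Tuple[str, str, str, str]
    block_loo: np.ndarray  # leave-one-out D values


@dataclass
class HydeResult:
    """Invariant-based hybrid test with admixture-proportion estimate."""

    gamma: float  # clamped to [0, 1]
    gamma_raw: Optional[float]
    Z: float
    p: float  # one-tailed, Student-t reference with n_blocks - 1 df
    f_abba: float
    f_aabb: float
    f_abab: float
    n_markers: int
    n_blocks: int
    block_size: int
    quartet: Tuple[str, str, str, str]


def _frequencies(
    summary: GroupAlleleSummary, labels: Sequence[str], polarized: bool
) -> Tuple[np.ndarray, ...]:
    source = summary.derived_freq if polarized else summary.alt_freq
    for g in labels:
        if g not in source:
            raise ParameterError(f"group {g!r} absent from summary")
    return tuple(np.asarray(source[g], dtype=float) for g in labels)


def dstat(
    summary: GroupAlleleSummary,
    order: Tuple[str, str, str, str] = ("C", "D", "O", "A"),
    block_size: int = 500,
) -> DResult:
    """Patterson's D from pooled group allele frequencies.

    Markers lacking a frequency in any of the four groups are dropped; no
    outgroup polarization is required because the outgroup frequency
    enters the pattern weights directly.
    """
    p1, p2, p3, p4 = _frequencies(summary, order, polarized=False)
    keep = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(p4))
    p1, p2, p3, p4 = p1[keep], p2[keep], p3[keep], p4[keep]
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    if (abba + baba).sum() == 0:
        raise UndefinedResult("D undefined: no ABBA or BABA signal at retained markers")
    d, se, n_blocks, loo = block_jackknife_ratio(abba - baba, abba + baba, block_size)
    # degenerate toy inputs can have zero jackknife variance; Z is then undefined
    z = d / se if se > 0 else float("nan")
    # jackknife inference is Student-t with n_blocks - 1 df; indistinguishable
    # from normal at genome scale but properly calibrated for few blocks
    return DResult(
        D=d,
        se=se,
        Z=z,
        p=float(2 * sps.t.sf(abs(z), df=n_blocks - 1)) if se > 0 else float("nan"),
        n_markers=int(p1.size),
        n_blocks=n_blocks,
        block_size=block_size,
        order=tuple(order),
        block_loo=loo,
    )


def hybrid_invariant_test(
    summary: GroupAlleleSummary,
    quartet: Tuple[str, str, str, str] = ("A", "C", "D", "O"),
    block_size: int = 500,
) -> HydeResult:
    """Hybrid-origin test and admixture proportion from site-pattern sums.

    ``quartet`` is (outgroup, parent1, hybrid, parent2).  Only markers
    polarizable by the outgroup contribute.  The Z statistic tests
    H0: f_AABB - f_ABAB = 0 against the one-sided excess (> 0, i.e. some
    ancestry from parent2) using a block-jackknife SE of the normalized
    excess; gamma_hat is reported clamped to [0, 1] alongside the raw value.
    """
    out, par1, hyb, par2 = quartet
    p1, ph, p2 = _frequencies(summary, (par1, hyb, par2), polarized=True)
    keep = ~(np.isnan(p1) | np.isnan(ph) | np.isnan(p2))
    p1, ph, p2 = p1[keep], ph[keep], p2[keep]

    w_abba = p1 * ph * (1 - p2)  # P1 + hybrid share the derived allele
    w_aabb = (1 - p1) * ph * p2  # hybrid + P2
    w_abab = p1 * (1 - ph) * p2  # P1 + P2 (lineage-sorting baseline)
    f_abba = float(w_abba.sum())
    f_aabb = float(w_aabb.sum())
    f_abab = float(w_abab.sum())

    num = w_aabb - w_abab
    den = w_aabb + w_abab
    if den.sum() == 0:
        raise UndefinedResult("hybrid test undefined: no AABB/ABAB signal")
    r, se, n_blocks, _ = block_jackknife_ratio(num, den, block_size)
    z = r / se if se > 0 else float("nan")
    p_one_tailed = float(sps.t.sf(z, df=n_blocks - 1)) if se > 0 else float("nan")

    denom = (f_abba - f_abab) + (f_aabb - f_abab)
    if denom == 0:
        gamma_raw: Optional[float] = None
        gamma = float("nan")
    else:
        gamma_raw = (f_aabb - f_abab) / denom
        gamma = min(1.0, max(0.0, gamma_raw))
    return HydeResult(
        gamma=gamma,
        gamma_raw=gamma_raw,
        Z=float(z),
        p=p_one_tailed,
        f_abba=f_abba,
        f_aabb=f_aabb,
        f_abab=f_abab,
        n_markers=int(p1.size),
        n_blocks=n_blocks,
        block_size=block_size,
        quartet=tuple(quartet),
    )
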