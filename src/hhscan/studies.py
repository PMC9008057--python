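"""Desk-scale replication studies.

Each function runs one of the package's standing simulation studies --
type-I calibration of the site-pattern and PIV tests, admixture-proportion
recovery, the qualitative echo of the hybrid-speciation pattern, the
closed-form lineage-sorting check, and end-to-end recovery of planted
selection signals -- under frozen study conditions, returning plain
dictionaries of summary numbers.

The study conditions (networks, sample designs, mutation densities, locus
counts) are part of the package's experimental design; docs/methods.md
explains each choice.  Every study takes a single integer seed and is
fully reproducible.
"""

from __future__ import annotations

import math
from typing import Dict, Sequence

import numpy as np
from scipy import stats as sps

from .network import MutationModel, SampleDesign, SpeciesNetwork
from .piv import piv_census_from_summary, piv_signal_test
from .psg import scan_genes
from .simulate import (
    PlantedGene,
    design_group_map,
    simulate_frequency_table,
    simulate_gene_alignments,
    simulate_gene_trees,
)
from .sitepatterns import dstat, hybrid_invariant_test
from .topology import census

# ---------------------------------------------------------------------------
# Frozen study conditions
# ---------------------------------------------------------------------------

#: Sample design for marker-level studies: 2 diploids per ingroup, 1 outgroup.
MARKER_DESIGN = SampleDesign.from_individuals(2, 2, 2, 1)

#: Deep-divergence network (long internal branch, little lineage sorting)
#: used for the site-pattern null; gamma-free.
DEEP_NULL_NETWORK = SpeciesNetwork(t_h=5.0, t_co=7.0, t_root=10.0, gamma=0.0)

#: Shallow network with substantial lineage sorting; used where the PIV
#: and AV classes must have comparable mass.
SHALLOW_NULL_NETWORK = SpeciesNetwork(t_h=2.0, t_co=2.5, t_root=5.0, gamma=0.0)

#: Deep network carrying the study system's estimated minor contribution
#: gamma = 0.11: within-lineage variation fixes long before the splits,
#: as in the real lineages, giving clean lineage-level site patterns.
DEEP_HYBRID_NETWORK = SpeciesNetwork(t_h=5.0, t_co=7.0, t_root=10.0, gamma=0.11)

#: Marker densities (indel-only, mirroring the paper's use of long indels
#: for the population-level tests).  Sparse density for the calibration
#: studies keeps markers near-independent within loci.
SPARSE_INDELS = MutationModel(theta=0.15, indel_fraction=1.0)
VERY_SPARSE_INDELS = MutationModel(theta=0.04, indel_fraction=1.0)
ECHO_INDELS = MutationModel(theta=0.5, indel_fraction=1.0)

#: PSG-scan study: deep splits, fast within-branch coalescence (population
#: sizes 0.2) and purifying selection keep the gene-vs-genome HKA contrast
#: calibrated; the background is tree-like, planted genes force origins.
PSG_SIZES = {b: 0.2 for b in ("C", "D", "O", "A", "CO", "ROOT")}
PSG_NETWORK = SpeciesNetwork(t_h=5.0, t_co=8.0, t_root=10.5, gamma=0.0, pop_sizes=PSG_SIZES)
PSG_DESIGN = SampleDesign.from_individuals(2, 3, 2, 1)
PSG_N_GENES = 1000
PSG_N_CODONS = 450
PSG_THETA_SITE = 0.0066
PSG_OMEGA = 0.05
PSG_PLANTED = tuple(
    [PlantedGene(index=i, origin="C", n_fixed_nonsyn=25) for i in range(15)]
    + [PlantedGene(index=i, origin="O", n_fixed_nonsyn=25) for i in range(15, 25)]
)


def _subseeds(seed: int, n: int) -> np.ndarray:
    """Independent 31-bit child seeds from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


# ---------------------------------------------------------------------------
# Studies
# ---------------------------------------------------------------------------

def topology_closed_form_study(seed: int, n_loci: int = 10_000) -> Dict[str, float]:
    """Topology-I frequency under gamma=0, T=1, versus 1 - (2/3)e^{-1}.

    Simulates ``n_loci`` one-tip-per-group gene trees through the full
    coalescent and the census classifier.
    """
    network = SpeciesNetwork(t_h=5.0, t_co=6.0, t_root=9.0, gamma=0.0)
    design = SampleDesign({"C": 1, "D": 1, "O": 1, "A": 1})
    trees = simulate_gene_trees(network, design, n_loci, seed=int(seed))
    groups = design_group_map(SampleDesign.from_individuals(1, 1, 1, 1))
    counts = census(trees, groups)
    expected = 1.0 - (2.0 / 3.0) * math.exp(-1.0)
    freq = counts.n_I / counts.total_classified
    mc_se = math.sqrt(expected * (1 - expected) / n_loci)
    return {
        "freq_topology_I": freq,
        "expected": expected,
        "mc_se": mc_se,
        "n_loci": n_loci,
        "abs_error_in_se": abs(freq - expected) / mc_se,
    }


def sitepattern_type1_study(
    seed: int, n_reps: int = 500, n_loci: int = 3000, alpha: float = 0.05
) -> Dict[str, float]:
    """Rejection rates of D and the hybrid test under the gamma-free null.

    Each replicate simulates ~20k long-indel markers (sparse density, so
    markers within a locus are nearly independent) and rejects when the
    test's own p value falls below ``alpha`` (two-sided for D, one-sided
    for the hybrid test, both on their jackknife-t reference).
    """
    seeds = _subseeds(seed, n_reps)
    n_rej_d = n_rej_h = 0
    markers = 0
    for s in seeds:
        summary = simulate_frequency_table(
            DEEP_NULL_NETWORK, MARKER_DESIGN, SPARSE_INDELS, n_loci, int(s)
        )
        markers += summary.n_sites
        if dstat(summary).p <= alpha:
            n_rej_d += 1
        if hybrid_invariant_test(summary).p <= alpha:
            n_rej_h += 1
    return {
        "dstat_rejection_rate": n_rej_d / n_reps,
        "hyde_rejection_rate": n_rej_h / n_reps,
        "n_reps": n_reps,
        "mean_markers": markers / n_reps,
    }


def piv_type1_study(
    seed: int, n_reps: int = 200, n_loci: int = 4000, alpha: float = 0.05
) -> Dict[str, float]:
    """Rate of the OD-group PIV verdict under the gamma-free shallow null."""
    seeds = _subseeds(seed, n_reps)
    n_sig = 0
    for s in seeds:
        summary = simulate_frequency_table(
            SHALLOW_NULL_NETWORK, MARKER_DESIGN, VERY_SPARSE_INDELS, n_loci, int(s)
        )
        counts, _ = piv_census_from_summary(summary)
        if piv_signal_test(counts, alpha=alpha).signal_od:
            n_sig += 1
    return {"od_rejection_rate": n_sig / n_reps, "n_reps": n_reps}


#: Moderate density for the recovery study: ~10 markers per locus keeps
#: the ratio estimator's denominator noise (and hence its small-sample
#: bias) low at a fixed marker total.
RECOVERY_INDELS = MutationModel(theta=0.5, indel_fraction=1.0)


def gamma_recovery_study(
    seed: int,
    gammas: Sequence[float] = (0.0, 0.1, 0.25, 0.5),
    n_reps: int = 4,
    n_loci_recovery: int = 2400,
    n_loci_grid: int = 1200,
) -> Dict[str, object]:
    """Admixture-proportion recovery and monotonicity of gamma_hat.

    Uses the deep-divergence network, where within-lineage coalescence
    completes well before the hybridization time and the invariant
    estimator is unbiased.  Reports gamma_hat at simulated gamma = 0.3
    (~50k markers) and the mean gamma_hat over a gamma grid (~25k markers
    per replicate), with the Spearman rank correlation of grid means
    against truth.
    """
    seeds = _subseeds(seed, 1 + len(gammas) * n_reps)
    net03 = SpeciesNetwork(t_h=5.0, t_co=7.0, t_root=10.0, gamma=0.3)
    summary = simulate_frequency_table(
        net03, MARKER_DESIGN, RECOVERY_INDELS, n_loci_recovery, int(seeds[0])
    )
    gamma_hat_03 = hybrid_invariant_test(summary).gamma
    n_markers_03 = summary.n_sites

    means = []
    k = 1
    for g in gammas:
        net = SpeciesNetwork(t_h=5.0, t_co=7.0, t_root=10.0, gamma=g)
        vals = []
        for _ in range(n_reps):
            s = simulate_frequency_table(
                net, MARKER_DESIGN, RECOVERY_INDELS, n_loci_grid, int(seeds[k])
            )
            k += 1
            vals.append(hybrid_invariant_test(s).gamma)
        means.append(float(np.mean(vals)))
    rho = sps.spearmanr(list(gammas), means).statistic
    return {
        "gamma_hat_at_0.3": float(gamma_hat_03),
        "n_markers_at_0.3": int(n_markers_03),
        "grid_gammas": list(gammas),
        "grid_means": means,
        "rank_correlation": float(rho),
    }


def hybrid_echo_study(seed: int, n_reps: int = 20, n_loci: int = 4600) -> Dict[str, object]:
    """Qualitative echo of the hybrid-origin pattern at gamma = 0.11.

    Each replicate (~1e5 long-indel markers on the deep hybrid network)
    succeeds when D > 0 with Z > 3, the hybrid test recovers gamma within
    0.05 of 0.11, PIV counts order CD >> OD > CO (CD at least twice OD),
    and both PIV verdicts are significant at alpha = 0.05.
    """
    seeds = _subseeds(seed, n_reps)
    n_success = 0
    ds, zs, gammas_hat = [], [], []
    cd = od = co = 0
    for s in seeds:
        summary = simulate_frequency_table(
            DEEP_HYBRID_NETWORK, MARKER_DESIGN, ECHO_INDELS, n_loci, int(s)
        )
        d = dstat(summary)
        h = hybrid_invariant_test(summary)
        counts, _ = piv_census_from_summary(summary)
        sig = piv_signal_test(counts, alpha=0.05)
        ds.append(d.D)
        zs.append(d.Z)
        gammas_hat.append(h.gamma)
        cd += counts.CD
        od += counts.OD
        co += counts.CO
        ok = (
            d.D > 0
            and d.Z > 3
            and abs(h.gamma - 0.11) <= 0.05
            and counts.CD > 2 * counts.OD
            and counts.OD > counts.CO
            and sig.signal_cd
            and sig.signal_od
        )
        n_success += ok
    return {
        "success_rate": n_success / n_reps,
        "n_reps": n_reps,
        "mean_D": float(np.mean(ds)),
        "mean_Z": float(np.mean(zs)),
        "mean_gamma_hat": float(np.mean(gammas_hat)),
        "total_CD": cd,
        "total_OD": od,
        "total_CO": co,
    }


def psg_recovery_study(seed: int, n_runs: int = 50) -> Dict[str, object]:
    """End-to-end recovery of planted selection signals.

    Each run simulates 1000 genes with 25 planted PSGs (15 from C, 10 from
    O) and succeeds when the called from-C/from-O split matches planting
    within two genes per class.
    """
    seeds = _subseeds(seed, n_runs)
    groups = design_group_map(PSG_DESIGN)
    n_success = 0
    from_c, from_o, correct = [], [], []
    planted_c = {f"gene{i:04d}" for i in range(15)}
    planted_o = {f"gene{i:04d}" for i in range(15, 25)}
    for s in seeds:
        alignments, _ = simulate_gene_alignments(
            PSG_NETWORK,
            PSG_DESIGN,
            PSG_N_GENES,
            PSG_PLANTED,
            seed=int(s),
            n_codons=PSG_N_CODONS,
            theta_site=PSG_THETA_SITE,
            omega=PSG_OMEGA,
        )
        _, calls = scan_genes(alignments, groups)
        nc, no = len(calls.psg_from_c), len(calls.psg_from_o)
        from_c.append(nc)
        from_o.append(no)
        correct.append(
            len(planted_c & set(calls.psg_from_c)) + len(planted_o & set(calls.psg_from_o))
        )
        if abs(nc - 15) <= 2 and abs(no - 10) <= 2:
            n_success += 1
    return {
        "success_rate": n_success / n_runs,
        "n_runs": n_runs,
        "mean_from_c": float(np.mean(from_c)),
        "mean_from_o": float(np.mean(from_o)),
        "mean_correct_of_25": float(np.mean(correct)),
    }
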