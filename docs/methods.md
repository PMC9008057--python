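# Methods

This note documents the models, statistics and numerical choices behind
`hhscan`, and the design of the standing simulation studies in
`hhscan.studies`.  Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is asserted from
external data.

## The species network and the coalescent simulator

The system is four lineages C, D, O, A with split times in coalescent
units before present: `t_h` (origin of D), `t_co` (split of the C- and
O-ancestors) and `t_root` (outgroup split), with `0 < t_h < t_co <
t_root`.  D originates at `t_h` by hybridization: tracing time backwards,
each D lineage still uncoalesced at `t_h` is routed independently to the
O-side ancestral population with probability γ and to the C-side with
probability 1−γ (population-admixture semantics).  With one D lineage per
locus this is indistinguishable from routing the whole locus, which is
the regime of the single-representative topology census; with population
samples it is the standard admixture model.  γ = 0 collapses the network
to the species tree (((C,D),O),A).

Within every branch, lineages coalesce pairwise at rate `1/size` per
coalescent unit (per-branch relative sizes, default 1).  The simulator is
a direct structured-coalescent implementation over the four epochs
(present→`t_h`→`t_co`→`t_root`→MRCA); an independent implementation
(msprime with an equivalent demography) reproduces its discordance level
in the test suite, and the single-tip topology distribution has the exact
closed form

    P(I)  = (1−γ)(1−e^(−T/s_C)) + R/3,
    P(II) = γ(1−e^(−T/s_O)) + R/3,      R = (1−γ)e^(−T/s_C) + γe^(−T/s_O),
    P(III)= R/3,

with T = `t_co − t_h`; after the C/O ancestors merge, the three ingroup
lineages are exchangeable, hence the uniform R/3 terms.  This closed form
doubles as the fast path for the 10,000-replicate ILS null: per-replicate
topology counts are multinomial draws from it, which is distributionally
identical to simulating and classifying single-tip genealogies (a
chi-square equivalence test covers this).

Mutations are infinite-sites: a Poisson(θ·L) number of mutations is
placed on the genealogy proportionally to branch length, each creating a
new biallelic marker.  Long indels are therefore homoplasy-free by
construction, which is precisely the property the PIV method assumes.  A
fraction of mutations become indels with lengths `min_len − 1 +
Geometric(p)` (default minimum 5 bp, p = 0.5; only the 5 bp floor is
substantive, the tail shape is a modelling convenience).  Loci are
anchored uniformly on eight synthetic chromosomes (the karyotype of the
study system) with a locus's markers at consecutive positions, so
coordinate order preserves genealogical linkage — this matters for the
block jackknife, whose blocks are contiguous in coordinate order.
Internally coordinates are 0-based half-open; VCF emission is 1-based.

Diploid genotypes pair consecutive haplotypes of an individual; no
missing data or genotyping error is simulated (the readers handle both
for real inputs).  The default sample design mirrors the resequencing
census of the study system (10 C / 27 D / 7 O / 3 A diploids); the
replicated studies below use smaller designs, noted per study.

## Topology census

Trees are classified by bipartition: each ingroup must be monophyletic
(with respect to rooting on A) and exactly one ingroup pair must form a
clade excluding A; trees failing either condition, or whose pair node
carries a support label below 50, are discarded and excluded from every
denominator.  The II-vs-III asymmetry test is the exact two-tailed
binomial test at p = 1/2 (two-tailed mass = sum of outcome probabilities
not exceeding the observed one's).  The ILS null simulates the III/II
ratio under γ = 0 with T calibrated so the null P(I) matches the observed
concordance fraction, T = −ln(1.5(1−P̂(I))) — the study's coalescent
branch lengths are not otherwise identifiable from a census.  Both an
empirical two-sided p (floored at 1/n_reps) and the one-sample two-tailed
t test against the observed ratio are reported; the empirical p is the
headline because a ratio of small counts is not Gaussian.

For the published census (2414/1449/906) the binomial p is ~6×10⁻³⁰.
The source analysis reports 3.11×10⁻⁷⁹ for the same comparison; that
value is not recoverable from these counts under any two-tailed binomial
convention we know, so the package reports the exact test and leaves the
discrepancy documented here rather than matched.

Window maps count topologies I/II per fixed-size window (BED-style); the
homogeneity chi-square pools consecutive windows until all expected
counts reach 5 and returns NaN when fewer than two pooled windows remain.

## Site-pattern tests

Both tests run on per-group pooled allele frequencies.  For order
(P1,P2,P3,Out) and frequencies (p1,p2,p3,p4):
ABBA = (1−p1)p2p3(1−p4), BABA = p1(1−p2)p3(1−p4),
D = Σ(ABBA−BABA)/Σ(ABBA+BABA).  D needs no outgroup polarization (p4
enters the weights); the hybrid test uses outgroup-polarized derived
frequencies and drops markers where A is not fixed.  The admixture
proportion is estimated from the two pattern excesses over the
lineage-sorting baseline f_ABAB:

    γ̂ = (f_AABB − f_ABAB) / ((f_ABBA − f_ABAB) + (f_AABB − f_ABAB)).

Because the C- and O-parent branches span the same interval, the two
excesses are proportional to (1−γ) and γ with a common factor, making γ̂
consistent; simulations confirm near-unbiasedness on the deep network
(within-lineage coalescence complete before `t_h`) and a modest shrinkage
bias (up to ~0.05) on shallow networks, which is why the recovery study
runs deep.

Uncertainty comes from a delete-one block jackknife over contiguous
blocks of 500 markers (the source study names no block scheme; 500
markers comfortably exceeds the simulated locus length, so block
boundaries respect linkage).  **p values use a Student-t reference with
`n_blocks − 1` degrees of freedom**, not the normal: with the ~40 blocks
of a desk-scale run the normal is visibly anti-conservative (the null Z
standard deviation matches the t prediction to three decimals in our
calibration runs), while at genome scale (hundreds of blocks) t and
normal coincide.  `z_to_one_tailed_p` remains the plain normal tail, as
a self-contained conversion utility.

## PIV / AV classification

Markers (after the ≥5 bp indel filter) enter classification when all
four groups are fixed — every called genotype the same homozygote and
call rate ≥ 0.7, a completeness floor the source does not specify but
which small per-group samples require — and not all four share one
allele.  The six classes are defined purely on the fixed-state pattern
(see `classify_sharing`; an exhaustive 16-pattern truth table is in the
tests).  Two patterns (a change specific to the outgroup, and sharing by
all three ingroups) fit no class and are counted as unclassifiable,
never silently dropped.

The signal test contrasts each focal pair against (CO, COA):
[[CD, CDA], [CO, COA]] and [[OD, ODA], [CO, COA]], each a Yates-corrected
chi-square with 1 df.  The source names the test and the verdicts but
not the table; C–O sharing is the natural reference because it cannot be
clade signal under any placement of D, so it measures the
lineage-sorting-plus-noise floor.  Under γ = 0 the OD row equals the CO
row in expectation (minor-topology symmetry of the MSC), which is what
the type-I study verifies.

## Positive-selection scan

Per gene and grouping (D pooled with C against O, and D pooled with O
against C): S = nucleotide columns polymorphic within the pooled pair,
K = columns fixed for different states between the sides (gap/ambiguous
columns excluded and counted), N_fix = codon columns fixed for different
codons encoding different amino acids.  The HKA criterion is the
operational gene-versus-genome 2×2 chi-square
[[S_gene, K_gene], [S_total − S_gene, K_total − K_gene]] with genome
totals over all scanned genes (including the focal one; the classical
multi-locus HKA likelihood is out of scope).  The top-2.5% rule uses the
`higher` quantile so that, with distinct values, exactly 2.5% pass; ties
at the cutoff are all included.  Origin is assigned on a neighbor-joining
tree (scikit-bio, p-distances) of unique C/D/O haplotypes: each D
haplotype votes for the parent with the smaller minimum patristic
distance, and a call needs ≥ 80% agreement — NJ rather than ML for
dependency-free determinism, a declared deviation from the source
pipeline.  PSG-from-C requires passing HKA and N_fix under the D+C
grouping *and* origin C (symmetrically for O); hybrid-signal genes pass
the two statistical criteria under both groupings, phylogeny ignored.
The alternating-residue scan counts amino-acid positions where C and O
are fixed for different residues and D is fixed for one of them.

The alignment generator evolves random non-stop codons along simulated
genealogies; a mutation that would create a stop is rejected (lethal),
and a replacement substitution is retained with probability ω (default
0.25, lowered to 0.05 in the recovery study) — ordinary purifying
selection.  Planted genes are simulated with the hybrid edge forced to
their origin parent, carry an exact number of planted fixed
nonsynonymous differences, and have within-pair polymorphism thinned
(retention 0.5) as a selective sweep would.

## The replication studies (frozen conditions)

All marker studies use 2/2/2/1 diploids and indel-only mutation (the
population-level tests in the source ran on long indels).  Two network
regimes appear: *shallow* (t_h = 2, T = 0.5, t_root = 5), where lineage
sorting is strong and the PIV and AV classes have comparable mass, and
*deep* (t_h = 5, T = 2, t_root = 10), where within-lineage variation
fixes long before the splits, as in lineages separated by tens of
millions of years.

- **Closed-form check**: γ = 0, T = 1, 10,000 single-tip loci through
  the full simulator and classifier; topology-I frequency within 3 Monte
  Carlo SE of 1 − (2/3)e⁻¹ ≈ 0.7547.
- **Site-pattern type-I**: deep null, θ = 0.15/locus, 3000 loci (~20k
  markers, ~6 markers per locus so blocks of 500 hold ~77 loci), 500
  replicates; rejection = the test's own p ≤ 0.05.  Calibrates at ~5%
  (600-replicate check: 5.3% / 5.0%).
- **PIV type-I**: shallow null, θ = 0.04, 4000 loci, 200 replicates of
  the OD verdict at α = 0.05.  The sparse density keeps fixed indels
  nearly independent; the Yates correction leaves the test slightly
  conservative (~4.5%).
- **γ recovery**: deep network, θ = 0.5; a single γ = 0.3 run at ~50k
  markers (tolerance 0.05) plus a 4-replicate grid over
  {0, 0.1, 0.25, 0.5} at ~25k markers whose means must be rank-monotone.
- **Hybrid echo**: deep network with γ = 0.11, ~10⁵ markers per
  replicate; success = D > 0 with Z > 3, |γ̂ − 0.11| ≤ 0.05, CD > 2·OD >
  2·CO ordering (CD at least twice OD and OD above CO), and both PIV
  verdicts significant at 0.05.  Note that D's magnitude (~0.7 here
  versus 0.16 in the motivating data) depends strongly on the
  marker-ascertainment and divergence regime; only its sign and
  significance are portable, which is what the study asserts.
- **PSG recovery**: 1000 genes of 450 codons (2/3/2/1 diploids,
  θ_site = 0.0066, ω = 0.05, all branch sizes 0.2), 25 planted (15 from
  C, 10 from O, 25 planted replacements each); success = called
  from-C/from-O counts within ±2 of 15/10; 50 seeded runs, ≥90% must
  succeed.  Three design choices make this discriminating and are worth
  stating plainly: (i) the background is tree-like (γ = 0) — with an
  admixed background, whole genes genuinely inherited from the minor
  parent satisfy all three criteria and are *correctly* called
  O-derived, so planted-versus-called bookkeeping would conflate real
  minor-parent ancestry with false positives; (ii) strong purifying
  selection (ω = 0.05) keeps a gene's N_fix outliers from dragging its
  total divergence K into HKA significance; (iii) small branch population
  sizes make stem lengths nearly deterministic, so the gene-vs-genome
  HKA contrast sees Poisson noise rather than coalescent depth variance.
  Under relaxed versions of these conditions the scan still recovers all
  planted genes but over-calls by ~5–15 background genes per thousand —
  a real limitation of the three-criterion pipeline on admixed
  backgrounds, not of the implementation.

## Degenerate inputs and numerical conventions

Ratio statistics with empty denominators, single jackknife blocks, or
empty 2×2 margins raise `UndefinedResult` or return NaN (documented per
function); zero jackknife variance on degenerate toys yields NaN Z rather
than an exception.  The Yates correction is floored at zero.  Replicates
of the ILS null with N_II = 0 are redrawn (bounded) and counted.  Seeds
propagate through `numpy.random.SeedSequence`; equal seeds give
bit-identical outputs everywhere.

## What the synthetic data do and do not show

The generator reproduces the statistical skeleton the tests assume —
MSC genealogies with an admixture edge, homoplasy-free biallelic
markers, lineage-level fixation, codon structure with purifying
selection — and omits recombination within loci, sequencing and
genotyping error, missing data, indel-length homoplasy, selection
outside planted genes, and any calendar-time calibration.  Passing the
studies therefore shows the estimators are correct and calibrated under
the model's assumptions, not that those assumptions hold in any given
empirical dataset; on real data the block size, call-rate floor and
support threshold are the knobs that absorb the difference.
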