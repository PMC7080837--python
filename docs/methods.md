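# Methods

`hybridscan` implements the computational core of a hybridization study in a
clade of deeply diverged species (the worked examples use seven tropical
eel species, *Anguilla* spp.): detecting contemporary hybrids from
species-diagnostic SNPs, quantifying past introgression with the D and f4
statistics, and interrogating per-locus genealogies. This note documents
the models, the defaults and why, the numerical choices, and what the
synthetic data generator does and does not emulate.

## Genotype filtering

Two filter chains mirror common RAD-seq practice. Genotype masking uses
strict inequalities — depth below 5 or above 50, or genotype quality below
30, sets a genotype to missing. The phylogenetic-grade chain then drops
sites that are monomorphic after masking, have a missing fraction at or
above 0.3, or an observed heterozygosity above 0.5. The popgen-grade chain
drops sites with mean depth above 50, minor-allele frequency below 0.02, or
significant heterozygote excess, and optionally prunes linked sites
(greedy left-to-right removal when genotype r² with a retained site within
10 kb exceeds 0.8, correlations on alternate-allele counts with
pairwise-complete observations). The heterozygote-excess test is the exact
conditional (Levene/Haldane) distribution of the heterozygote count given
the allele counts, one-sided toward excess, pooled across all samples;
whether pooling or stratifying by population is preferable is
data-dependent, and the pooled choice is recorded in the filter report.
Every filter is idempotent and the order is fixed: mask, site filters,
prune.

## Ancestry painting

For a pair of species, the diagnostic panel is the set of sites at which
all *called* core-group genotypes of one species are homozygous for one
allele and all of the other species for the other allele, with at most 20%
missing genotypes per core group. Judging fixation on called genotypes
only means panels can include sites that are not truly fixed in the
species; larger core groups shrink this contamination roughly
geometrically. A putative hybrid is painted by classifying its genotype at
every panel site (homozygous-maternal / heterozygous /
homozygous-paternal, with the maternal side set by the mitochondrial
assignment), requiring at least 20 called panel sites (a repository floor;
configurable). From the counts follow the heterozygosity H = N_het/called
and the maternal genome fraction f_m,genome = (2 N_hom_m + N_het) /
(2 called). Hybrid classes use H alone: F1 when H ≥ 0.9, backcross when
0.3 ≤ H ≤ 0.7, otherwise "ambiguous" — later-generation backcrosses are
deliberately not auto-labelled. The thresholds are qualitative; expected
values are H = 1 for F1s and H ≈ 0.5, f_m ∈ {0.25, 0.75} for first-
generation backcrosses.

## Morphology

From raw measurements TL, PA, PD, HL the derived measures are AD = PA −
PD, PDH = PD − HL, T = TL − PA, TR = PA − HL, and the seven analysis
traits are the ratios of PA, T, HL, TR, PD, PDH, AD to TL. PCA for
core-group delimitation is run on standardized ratios (correlation matrix)
because the ratio traits have variances differing by an order of
magnitude. The maternal-similarity statistic

f_m,morphology = 1 − ½ [ (PDH/TL − m̄_PDH)/(p̄_PDH − m̄_PDH)
                        + (AD/TL − m̄_AD)/(p̄_AD − m̄_AD) ]

is the hybrid's position on the axis between the maternal (m̄) and
paternal (p̄) species mean ratios; it is affine-invariant, maps the
maternal mean to 1 and the paternal mean to 0, and is *not* clamped to
[0, 1] because transgressive phenotypes are biologically meaningful.
Species means use core-group individuals only (the alternative — all
conspecifics — risks contamination by unrecognized hybrids). The
genome–morphology association is an OLS fit of f_m,morphology on
f_m,genome with a two-tailed t test on the slope.

## D and f4 statistics

For a quartet (((P1,P2),P3),O) with per-site derived-allele frequencies
p1..p4, the site weights are ABBA = (1−p1)p2p3(1−p4) and BABA =
p1(1−p2)p3(1−p4); D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA). Alleles are
polarized per site so the allele rare in the outgroup is derived; sites
with a polymorphic outgroup contribute through the (1−p4) weights rather
than being dropped, which is what produces fractional pattern counts. f4
is the mean of (p1−p2)(p3−p4) and is invariant to polarization. Quartet
enumeration yields every (P1,P2,P3,O) in which P1,P2 are sisters relative
to P3 and O is outgroup to all three under the species tree; when several
outgroups are available each is run and the largest-D orientation is
flagged as the reported row (all runs retained). No multiple-testing
correction is applied by default; a Benjamini–Hochberg column is optional.

### Simulation null for f4

Significance is assessed against a no-admixture null rather than a block
jackknife (the genome-wide f4 distribution is heavy-tailed). The null
model is per-site independent Balding–Nichols drift on the quartet tree:
six branch fixation indices F plus an ancestral-diversity parameter c0 =
E[p(1−p)] realized as a symmetric Beta(a,a) root distribution. Calibration
("burnin") has a closed-form first stage — under Balding–Nichols drift,
E(p_i−p_j)² = c0(2g_ij − g_i − g_j) with g the product of (1−F) from the
root, so minus-log products are additive and the seven parameters are
fitted to the six observed pairwise dissimilarities by bounded least
squares — followed by simulated refinement (damped multiplicative updates
on each branch) until every pair matches within 10% relative (4,000-site
check datasets, at most 30 iterations; failure to converge reports the
p-value as missing with diagnostics). The main phase simulates n_reps
(default 400) datasets of the observed size; p is the fraction of
replicates with f4 at least as extreme as observed, one-sided in the sign
of the observed f4. Such a data-directed one-sided p lives on (0, 0.5)
under the null, so calibration checks assert uniformity of 2p; an observed
f4 of exactly 0 returns p = 1. Because only second moments are matched,
the null can be mildly anticonservative when the generating process
differs from the Balding–Nichols class (measured: ~20% of p-values below
0.05 for data generated by the multi-step drift simulator); under the
fitted model class itself the p-values are well calibrated.

## Genealogy interrogation

Per-locus log-likelihoods of competing fixed topologies are computed with
a standard pruning (post-order conditional-likelihood) engine for
reversible models (JC69 and GTR with empirical base frequencies, no
among-site rate heterogeneity), with per-node rescaling and gaps/N as
missing data. Branch lengths (and GTR exchangeabilities, with GT fixed at
1 as reference) are optimized coordinate-wise by bounded Brent on
[1e-9, 5] substitutions/site, sweeping until the log-likelihood improves
by less than 1e-6 relative; for a bifurcating root one root-child branch
is pinned at 0 since the pair is confounded under reversibility. The fits
are deterministic, so replicate runs are unnecessary. A locus supports one
hypothesis over another when the log-likelihood difference exceeds a tie
tolerance of 0.01; each hypothesis pair gets a two-tailed exact binomial
test of a 50:50 split, the null expected under incomplete lineage sorting
alone. One structural caveat matters in practice: competing *rooted*
placements of a taxon are only distinguishable when the alignment includes
outgroup taxa — with the focal five species alone the three hypotheses
collapse to a single unrooted topology and all likelihoods tie. Ternary
plot coordinates place each locus at the support-weighted barycenter of
the three hypothesis vertices with ΔlnL capped at 10 log-units; this
projection is this package's convention.

## Window topology scan

Chromosome-scale 4-taxon alignments are scanned in 20-kb windows stepped
by 10 kb (0-based, half-open internally; emitted BED stays 0-based). Each
window with at least `min_sites` fully called variable sites is fit under
the three resolved quartet topologies (same engine, JC by default for
speed) and labelled by the best ingroup sister pair, with the same 0.01
tie tolerance (ties → undetermined). The summary reports counts and
percentages over resolved windows and the longest run of consecutive
windows sharing one alternative topology, measured as the genomic span
from the first window start to the last window end — a 7-window run at
these settings spans 20,000 + 6 × 10,000 = 80,000 bp. Long alternative
runs are the signature of recent hybrid ancestry.

## Popgen summaries

The p-distance between two species is the mean over jointly called sites
of p_a(1−p_b) + p_b(1−p_a); on a SNP-only matrix this is per variant site,
not per genomic bp. Watterson's Θ uses per-site sample sizes: a site with
n_s ≥ 2 called chromosomes contributes 1/a_{n_s} when segregating, divided
by the count of usable sites. Mutation-rate conversion from a pairwise
distance and a divergence time supports two conventions — "half-distance"
(default), r = (p/2)·g/(T·1e6), and "full-distance", r = p·g/(T·1e6) — and
always reports which was used; no single convention reproduces all the
published per-species rates exactly, so none is asserted. Mitochondrial
species assignment is nearest-reference by mismatch fraction over
unambiguous bases.

## Synthetic data generator

The generator is first-class, tested code and defines the study conditions
for every property test.

* **Species tree.** The default seven-tip tree uses the study clade's
  anchor ages (root 13.76 Ma, ingroup radiation 9.7 Ma, the
  marmorata/obscura split 7.2023 Ma); the remaining node ages (8.5, 4.5,
  3.5 Ma) are round within-range values chosen once for qualitative
  realism. Defaults: diploid Ne = 200,000 per branch, generation time 10
  years, mutation rate 5e-9 per site per generation — mid-range for the
  published per-species estimates.
* **Allele frequencies.** Each site draws an ancestral frequency from
  Uniform(0.05, 0.95) and drifts along each branch by a Balding–Nichols
  Beta kernel with F = 1 − exp(−t/(2Ne)) (or an explicit per-branch F);
  admixture pulses mix recipient frequencies as (1−α)·recipient +
  α·donor. The kernel matches Wright–Fisher first and second moments
  exactly but has no fixation atoms, so sample-level fixed-difference
  counts run ~15–20% below a true Wright–Fisher process at moderate
  drift — panels are therefore slightly smaller than a forward simulation
  would give, which no downstream test depends on. Sites are independent
  (the RAD-locus unlinkage assumption).
* **Genotypes.** Pure individuals are binomial draws from their species'
  frequency; F1s take one allele from each parental species; BC1s one
  allele from the backcross parent and one from an F1 gamete (fair
  per-site coin between grandparental species). Depth is Poisson (mean
  20), quality clipped-normal (mean 60, sd 15), and missingness is
  uniform at the configured rate; the mitochondrial label always equals
  the maternal species.
* **Sequences.** Per-locus gene trees come from a structured coalescent
  within the species tree (instant coalescence when a branch has Ne = 0;
  lineages switch to the donor population with probability α at admixture
  events, tracing backward in time), cross-checked against msprime in the
  test suite; sequences then evolve site-independently under JC/GTR. A
  linked-block mode concatenates tracts that share one gene tree for the
  window-scan tests (exponential tract lengths).
* **Morphology.** Species are bivariate normal clouds on the (PDH/TL,
  AD/TL) plane with a common covariance; hybrids centre on
  f·maternal + (1−f)·paternal with f ∈ {0.5, 0.75, 0.25} by pedigree. The
  default means place long-finned species high on both axes and
  short-finned species low, a qualitative rendering of the measured
  pattern. Raw TL/PA/PD/HL are reconstructed from the ratios so the
  measurement identities hold exactly.

What the generator does **not** emulate: linkage within RAD loci,
depth/quality covariance with genotype correctness, allele-frequency
spectra estimated from the real data (unpublished), sequencing error,
selection, or later-generation hybrid classes. Tests passing on this
generator therefore demonstrate correctness of the statistics under the
stated models, not robustness to every artefact of empirical RAD data.

## Problem sizes in the test and acceptance runs

The property suites run on deliberately modest sizes chosen as this
package's test conditions: cohorts of 40–64 individuals at 3,000–4,000
SNPs, f4 calibration over 40 seeds at 2,000 sites with 200 null
replicates, power checks over 20 seeds at 10,000 sites, genealogy
batteries of 90–150 loci of 500 bp on the seven-taxon tree, and window
scans over 200 kb. The acceptance script's quantities are recomputed from
the published pattern-count inputs at full scale.
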