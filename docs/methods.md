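# Methods

This note documents the models implemented in `redpcr`, the parameter
choices behind the synthetic data, the numerical details of the estimators,
and the limits of what the synthetic experiments demonstrate.

## The site model

The NsiI recognition sequence ATGCAT occupies *SMAD4* c.1494_1499
(transcript NM_005359.6), spanning codon Leu498 (last base), codon Cys499
(all three bases) and codon Ile500 (first two bases). All 18 single-base
substitutions in the window abolish exact-match recognition and are
enumerated in a fixed order (cDNA position, then alternate base A<C<G<T) so
every downstream table is bit-stable. Protein consequences come from the
standard genetic code applied to the reconstructed codons.

Two context bases are configurable because they lie outside the site: the
first two bases of codon 498 (`codon498_prefix`, default CTA = Leu) and the
third base of codon 500 (`codon500_suffix`, default A, giving ATA = Ile).
The codon-500 suffix is pinned by the observed variant spectrum (both
c.1498A>C and c.1498A>T must encode Leu, which requires the suffix A); the
codon-498 prefix is not fully determined, so consequences of c.1494A>C and
c.1494A>T are flagged `context_dependent` in output, while c.1494A>G is
synonymous under either plausible Leu codon (CTA/TTA).

Because the site is its own reverse complement, position *p* mirrors
position 7−*p*: the `reciprocal_partner` map (complement both alleles,
mirror the position) is a fixed-point-free involution that partitions the
18 substitutions into 9 pairs. Reciprocal pairs are the key to artifact
discrimination (below).

## In-silico digestion

`red_digest.digest` cuts at every exact occurrence of each recognition
6-mer, at a fixed intra-site offset (both NsiI ATGCA^T and PstI CTGCA^G cut
after position 5 on the top strand). Cut-to-cut distances are
offset-independent, which is what the assay's fragment sizes are: the
synthetic reference (`assay_sim.generate_reference`) is a random backbone
constrained so the two PstI cuts are 1,332 bp apart with the internal NsiI
cut splitting that interval 488 + 844 bp. Rejection sampling guarantees no
spurious NsiI/PstI occurrences in the wild-type, any of the 18 mutant
alleles, or the integrant allele. Size selection retains fragments of
1,264–1,371 bp (the gel window between the marker bands), so the
digestion-resistant 1,332 bp fragment survives and both wild-type
sub-fragments are discarded. Recognition is exact-match only: no ambiguity
codes, star activity or methylation sensitivity.

## The assay forward model

One technical replicate is simulated in two layers.

**Molecule layer.** A reaction receives `input_mass_ug` = 10 μg of gDNA at
`genome_mass_pg` = 3.0 pg per haploid genome, i.e. G ≈ 3.33 × 10⁶ haploid
genomes. The value 3.0 pg is the single constant that reconciles the
protocol's stated equivalences (10 μg ≈ 3.3 × 10⁶ genomes; 0.6 ng of
heterozygous spike ≈ 100 copies at 3 × 10⁻⁵; 2 ng ≈ 333 copies at 10⁻⁴).
Mutant copies for substitution *m* are Poisson(f_m · G) where f_m is the
latent allele fraction; integrant copies are Poisson(100). Wild-type
molecules must escape `n_digestion_rounds` = 3 successive digestion events
(genomic digest, post-PCR1 re-digest, final pool digest), each with escape
probability `wt_survival_per_round` = 0.01, so survivors are
Binomial(G, 10⁻⁶) ≈ 3 molecules. Neither the per-event survival nor the
final wild-type read fraction is published; both defaults are free
parameters of the simulator.

**Read layer.** Library depth is Poisson(`read_depth` = 5 × 10⁵) and is
allocated multinomially over the surviving molecule classes; a per-allele
misassignment probability `seq_error_rate` = 10⁻⁶ then moves reads into
each substitution class irrespective of origin (the post-consensus
substitution error floor). Note that because errors of this kind arise
*after* enrichment, they translate to absolute levels of ~10⁻¹⁰ — far below
the assay's nominal 10⁻⁶ limit of detection, which is therefore
conservative with respect to the simulated error floor. Pre-enrichment
molecular damage is modelled only through the explicit oxidative-damage
channel below.

**Latent truth.** In sperm (never blood — clonal expansion happens in the
testis), each selected substitution is carried at detectable levels with
probability `detect_frac + detect_age_slope·(age − 49.5)` (clipped to
[0, 1]); carriers receive log₁₀ f = intercept + slope·age + N(0, σ). The
age-dependent indicator reflects that clonal expansions accumulate with
age, raising both prevalence and level in older donors. In both tissues a
per-sample damage intensity 10^N(`damage_mean` = −5.6, `damage_sd` = 0.4)
is added to the reciprocal pair c.1496G>T/c.1497C>A, with a small
independent log-normal jitter (σ = 0.15 log₁₀) per member so the pair
correlation is strong but imperfect. Donor ages are uniform on 24–75 years.

The selection defaults are *calibrated, not derived*: the published data
constrain only cohort summaries. The frozen defaults reproduce, at truth
level over many cohorts: for c.1498A>G (p.Ile500Val) a detection prevalence
of ~0.72 above 10⁻⁶, mean level ~9.4 per million and cohort age correlation
R_S ≈ 0.5; detection prevalences of ~0.22, ~0.15 and ~0.09 with weaker age
trends for c.1499T>C, c.1498A>C and c.1498A>T. The targeted prevalence
(0.246) and mean level (0.9/million) for c.1499T>C are not jointly
attainable under a log-normal age law — the frozen compromise favours the
mean. All randomness flows from one seed through spawned per-sample
sub-streams, so cohorts are reproducible regardless of generation order.

**Reads.** `emit_reads` writes each replicate as 2 × 151 bp paired FASTQ
over a 208-bp amplicon centred on the site; integrant reads carry the 17-bp
deletion junction. `quantify.count_alleles` classifies pairs by exact match
(deletion-junction 20-mer for the integrant, otherwise the 6-bp site
window against the 19 known 6-mers), with disagreeing mates or unmatched
windows counted as "other"; the counts→FASTQ→counts round trip is exact.

What the generator does **not** emulate: PCR-cycle-resolved amplification
bias and polymerase error spectra, gel-extraction efficiency, real
base-quality structure, alignment artifacts, UMI consensus, and any
molecular background beyond the explicit damage channel. Passing tests
therefore demonstrate the *statistical machinery* — calibration,
enrichment-invariance, interval behaviour, classification logic — not
robustness to the full error structure of real libraries.

## Quantification

Technical replicates are pooled by field-wise summation before QC and
estimation. QC excludes samples with pooled depth < 1,000 reads or
integrant coverage < 250 reads (strict inequalities). The absolute level of
substitution *m* is (n_m / n_integrant) × 3 × 10⁻⁵; the spike cancels the
enrichment factor, which the tests verify by holding estimates invariant
across 100-fold changes in wild-type survival.

**Simultaneous intervals.** The 95% bounds come from Sison–Glaz
simultaneous multinomial intervals on the non-wild-type count vector (18
substitutions + integrant + other; wild-type reads are excluded because
their abundance measures digestion leakage, not mutation load). The
implementation mirrors the reference behaviour of the R routine used for
the published intervals: find the smallest integer c whose estimated joint
coverage ν(c) — a truncated-Poisson representation with an Edgeworth
correction — exceeds 1 − α, with ν(0) taken as 0; interpolate
γ = (1 − α − ν(c−1)) / (ν(c) − ν(c−1)); report
[max(0, p̂ − c/n), min(1, p̂ + c/n + 2γ/n)]. ν is monotone in c, so the
linear scan is accelerated by exponential bracketing plus bisection
(verified at the solution; results are identical to the scan). Degenerate
inputs: an all-zero vector is an error; if coverage is never reached
(pathologically small n) c falls back to n. Empirical simultaneous coverage
is ~94–98% over k ∈ {3, 6, 20}, n ∈ {10², 10³, 10⁴}, mildly conservative at
small n, and the bounds agree with an exhaustive-enumeration oracle at
k = 2, n = 100 to within 0.02.

**Transfer to the absolute scale** divides each substitution's proportion
bounds by the integrant's *point* proportion, keeping every interval
ordered around its estimate; integrant-count uncertainty is deliberately
not propagated (point-spike calibration).

**Limitation — the molecule bottleneck.** At a fraction of 10⁻⁵ only ~33
mutant and ~100 spike molecules survive digestion, yet they are sequenced
to ~5 × 10⁵ reads; read-count intervals therefore describe multinomial read
sampling (~1% relative width) while the estimate's real uncertainty is
dominated by Poisson molecule sampling (~20% CV). Read-scale intervals —
the published convention — consequently do not cover the nominal input of
a titration point at anything near 95%. `estimate_levels` offers
`spike_copy_rescale` to shrink the count vector to molecule-equivalents
(integrant ≈ 100), which widens intervals to the bottleneck scale, though
denominator uncertainty still leaves them below nominal. The default
remains the read-scale convention.

## Classification

Per substitution, the panel records sperm/blood detection prevalence
(point estimate strictly above the 10⁻⁶ limit of detection; a CI-based
variant `above_background_ci` is available), the Spearman age correlation
in sperm (average ranks for ties, t-approximation p-values), and the
Spearman correlation with the reciprocal partner's levels across matched
sperm samples. Decision rules, evaluated artifact → selected → background:

* **artifact** — present above background in both tissues *and* reciprocal
  correlation significant (p < 0.05, R_S > 0.3);
* **selected** — detected in ≥ 20% of sperm samples, in no blood sample,
  with a significantly positive age correlation (p < 0.05);
* **background** — otherwise; fewer than 10 sperm samples yields
  `insufficient_data`.

These rules and thresholds formalise a qualitative argument and are
configuration, not measured quantities. Age-correlation p-values are raw by
default (18 parallel tests; a Benjamini–Hochberg option exists but is off,
matching the convention of reporting raw correlations). A consequence of
the 20% prevalence gate is that rare selected variants (the two
p.Ile500Leu channels at ~9–15% prevalence, and marginally p.Ile500Thr at
~22%) are intentionally conservative calls: they classify as background in
most cohorts, and the label-recovery tests check the canonical labels the
rules can express (p.Ile500Val selected, the damage pair artifact, the 12
signal-free substitutions background).

## Epidemiology

The paternal-age excess for each family is the father's age at the
proband's birth minus the year-matched population mean; the test is a
one-sample, one-tailed t test for mean excess > 0 (SEM = SD/√n; a
single-family cohort has no degrees of freedom and is flagged). The
population reference is consumed as a prepared TSV of per-year means and
SDs; `synthetic_population_reference()` provides a deterministic synthetic
stand-in with the broad shape of national natality statistics (paternal
mean rising 27→33 years over 1972–2021, SD 6.3). The parent-of-origin test
reports both the Pearson chi-square against (0.8, 0.2) with df = 1 (no
continuity correction) and the exact binomial tail in the observed
direction. At a 16/0 tally these disagree (chi-square 4.0, p ≈ 0.046;
exact 0.8¹⁶ ≈ 0.028) and neither is privileged — whether a one-tailed or
corrected chi-square convention underlies any particular published figure
is not resolvable, so both numbers are surfaced.

## Problem sizes and numerical conventions

The test suite and acceptance script run at the scale the analyses use:
cohorts of 57 sperm + 5 blood samples in technical triplicate at 5 × 10⁵
reads; 100 seeded cohorts for classifier label recovery; 2,000 Monte-Carlo
replicates (k = 6, n = 1,000) for interval coverage; 500 replicates for
estimator-bias checks; 450 simulated trio cohorts for the age-excess
recovery check. Stochastic tests are seeded and deterministic. Ties in
Spearman statistics use average ranks; constant vectors are flagged
undefined rather than silently zero; integrant dropout yields NaN estimates
flagged as QC failures rather than infinities.

## Known limitations

* Read-scale confidence intervals understate molecule-level sampling noise
  (see above); replicate-to-replicate scatter is the honest dispersion
  measure at low input copies.
* The clonal-expansion law (log-linear in age, log-normal noise, linear
  age-dependent detectability) is a calibration device, not a mechanistic
  model of spermatogonial clone dynamics; it does not model per-division
  selection coefficients or clone-size distributions.
* Protein annotation covers only the six-codon window around the site and
  depends on the configured codon-498 context for two substitutions.
* The epidemiology stage performs no demographic standardisation beyond
  year matching, and the bundled population reference is synthetic.
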