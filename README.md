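# redpcr

Spike-in-calibrated quantification of ultra-rare *SMAD4* variants from
restriction-enzyme-enriched deep amplicon sequencing, with a full synthetic
assay model, artifact discrimination, germline-selection inference, and
paternal-age-effect epidemiology.

## The scientific problem

Myhre syndrome is caused by de novo missense mutations at *SMAD4* codons
Arg496/Ile500. Mutations of this kind — gain-of-function, exclusively
paternal in origin, recurring far above the background mutation rate — are
the signature of *selfish spermatogonial selection*: mutant spermatogonial
stem-cell clones expand in aging testes, so the mutant allele fraction in
sperm rises with a donor's age.

Measuring allele fractions of 10⁻⁶–10⁻⁴ directly is impossible for standard
sequencing, whose error floor sits orders of magnitude higher. The assay
modelled here (RED-PCR) exploits the NsiI restriction site ATGCAT at *SMAD4*
c.1494_1499, which spans codons Leu498–Cys499–Ile500: every one of the 18
single-nucleotide substitutions in the site destroys the recognition
sequence, so repeated NsiI digestion destroys wild-type molecules while
mutant molecules survive and are enriched before sequencing. Absolute
calibration comes from a known spike: ~100 copies of an engineered
NsiI-resistant "integrant" allele (a 17-bp deletion, c.1478_1494del) added
to the ~3.3 × 10⁶ input haploid genomes (dilution 3 × 10⁻⁵). Because spike
and mutant are enriched identically, the absolute level of substitution *m*
is

```
level_m = (n_m / n_integrant) × 3×10⁻⁵
```

independent of digestion efficiency. Simultaneous 95% confidence intervals
for the non-wild-type count vector (18 substitutions + integrant + other)
use the Sison–Glaz multinomial procedure.

Two further ideas complete the analysis:

* **Artifact discrimination.** The NsiI site is palindromic, so each
  substitution has a *reciprocal* partner (mirror position, complemented
  alleles). A strand-symmetric chemical artifact — oxidative G>T damage —
  shows up as correlated levels of the reciprocal pair c.1496G>T/c.1497C>A
  in both sperm and blood, with no age trend. True selection shows the
  opposite pattern: sperm-specific levels rising with donor age.
* **Epidemiology.** Selfish selection predicts fathers of probands are
  older than the year-matched population mean (one-tailed t test on the
  per-family age excess) and that phased mutations are paternal in origin
  more often than the ~80% baseline (chi-square and exact binomial).

The package implements every stage against synthetic data from its own
forward model of the assay (molecule-level Poisson sampling, digestion
leakage, multinomial read sampling, sequencing error, age-dependent clonal
expansion, damage artifact), down to optional paired FASTQ.

## Worked example

Run the numbered analyses (each is a thin driver over `src/redpcr/`;
outputs land in `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quantify_levels.py
python analysis/03_selection_analysis.py
python analysis/04_titration_validation.py
python analysis/05_epidemiology.py
```

The cohort run (57 sperm + 5 blood donors, technical triplicates) prints:

```
c.1498A>G (p.Ile500Val) in sperm: mean 9.37 per million, max 118.8 per million
```

and the classification stage:

```
c.1496G>T (p.Cys499Phe): artifact; sperm prevalence 72%, age R_S = 0.374 (p = 0.0042), reciprocal R_S = 0.888
c.1497C>A (p.Cys499*): artifact; sperm prevalence 70%, age R_S = 0.343 (p = 0.0091), reciprocal R_S = 0.888
c.1498A>G (p.Ile500Val): selected; sperm prevalence 75%, age R_S = 0.565 (p = 4.6e-06), reciprocal R_S = 0.235
15 substitutions classified background
```

i.e. the p.Ile500Val clone is detected in ~three quarters of sperm samples,
absent from blood, and rises with donor age (Spearman R_S = 0.57), while the
reciprocal G>T/C>A pair is flagged as a damage artifact by its cross-sample
correlation (R_S = 0.89). The titration series recovers its inputs over
1 × 10⁻⁶–1 × 10⁻⁴ with Spearman(estimate, input) = 1.000 for both spiked
variants, and the epidemiology stage reports a 4.6 ± 1.2 year paternal age
excess (6.3 injected, n = 35; one-tailed p = 2.1 × 10⁻⁴) and chi-square 4.0
for a 16/0 paternal-origin tally.

The same stages are available as a CLI (`redpcr simulate | titrate |
quantify | analyze | epi`) configured by a YAML file; see
`redpcr --help`.

## Layout

```
src/redpcr/        library: site_model, red_digest, assay_sim, quantify,
                   selection_stats, epidemiology, config, cli
analysis/          numbered narrative drivers writing results/
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    model description, parameter choices, limitations
```
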