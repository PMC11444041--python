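"""Synthetic-data generator for the NsiI RED-PCR assay.

Forward model of the whole experiment, from latent per-donor mutation
fractions down to read counts (optionally paired FASTQ):

* each reaction receives ~3.3 million haploid genomes (10 ug at 3 pg per
  haploid genome) plus ~100 copies of the heterozygous NsiI-resistant
  integrant spike (0.6 ng, dilution 3e-5);
* mutant and integrant molecule numbers are Poisson; wild-type molecules
  survive three successive NsiI digestion events with a small per-event
  escape probability;
* sequencing allocates the library depth multinomially over the surviving
  molecule classes, with a small per-allele read-misassignment error;
* in sperm (never blood), selected substitutions carry age-dependent clonal
  expansions: log10(fraction) is linear in donor age with lognormal noise,
  gated by a per-donor Bernoulli "has a detectable clone" indicator;
* an oxidative-damage artifact adds a shared per-sample intensity to the
  reciprocal G>T/C>A pair (c.1496G>T / c.1497C>A) in both tissues.

All randomness flows from a single seed through spawned per-sample
sub-streams, so cohorts are reproducible regardless of generation order.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np

from .quantify import SampleCounts, estimate_levels, substitution_labels
from .red_digest import NSII, PSTI
from .site_model import SiteModel, Substitution, enumerate_escaping_substitutions

#: reciprocal palindromic pair carrying the oxidative-damage artifact
DAMAGE_PAIR = ("c.1496G>T", "c.1497C>A")

#: codon-500 substitutions under positive (selfish) germline selection
SELECTED_SUBSTITUTIONS = ("c.1498A>G", "c.1499T>C", "c.1498A>C", "c.1498A>T")


#: reference donor age (midpoint of the default 24-75 cohort) at which
#: ``detect_frac`` applies
DETECT_AGE_REF = 49.5


@dataclass(frozen=True)
class SelectionParams:
    """Age law of one selected substitution in sperm.

    A donor carries a detectable clone with probability
    ``detect_frac + detect_age_slope * (age - 49.5)`` (clipped to [0, 1]) -
    clonal expansions accumulate with age, so both prevalence and level rise
    in older donors.  Carriers get
    log10(allele fraction) = intercept + slope_per_year * age + N(0, sigma).
    """

    intercept: float
    slope_per_year: float
    sigma: float
    detect_frac: float
    detect_age_slope: float = 0.0

    def detect_prob(self, age: float) -> float:
        return float(np.clip(self.detect_frac + self.detect_age_slope * (age - DETECT_AGE_REF), 0.0, 1.0))


# Calibrated so that, through the full pipeline, the codon-500 channels
# reproduce the reported cohort summaries: for c.1498A>G (p.Ile500Val) ~73%
# of 57 sperm samples above the 1e-6 detection limit, mean level ~9.3 per
# million and an age correlation near R_S ~ 0.49; detection prevalences of
# roughly 14/57, 8/57 and 5/57 (with weaker age correlations) for the
# p.Ile500Thr and the two p.Ile500Leu channels.
DEFAULT_SELECTION_PARAMS: dict[str, SelectionParams] = {
    "c.1498A>G": SelectionParams(-6.41, 0.022, 0.45, detect_frac=0.80, detect_age_slope=0.008),
    "c.1499T>C": SelectionParams(-6.63, 0.018, 0.40, detect_frac=0.29, detect_age_slope=0.006),
    "c.1498A>C": SelectionParams(-6.45, 0.022, 0.50, detect_frac=0.16, detect_age_slope=0.006),
    "c.1498A>T": SelectionParams(-6.45, 0.022, 0.50, detect_frac=0.10, detect_age_slope=0.004),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic assay.

    Masses follow the bench protocol: ``genome_mass_pg`` = 3.0 pg per haploid
    genome reconciles 10 ug ~ 3.3e6 haploid genomes, 0.6 ng spike ~ 100
    heterozygous copies (dilution 3e-5) and 2 ng ~ 333 copies (1e-4).
    """

    seed: int = 0
    genome_mass_pg: float = 3.0
    input_mass_ug: float = 10.0
    spike_mass_ng: float = 0.6
    spike_zygosity: float = 0.5
    n_digestion_rounds: int = 3
    wt_survival_per_round: float = 0.01
    read_depth: float = 5e5
    seq_error_rate: float = 1e-6
    n_replicates: int = 3
    damage_mean: float = -5.6  # log10 of the shared per-sample artifact level
    damage_sd: float = 0.4
    damage_pair_jitter_sd: float = 0.15
    selection_params: dict[str, SelectionParams] = field(
        default_factory=lambda: dict(DEFAULT_SELECTION_PARAMS)
    )

    def __post_init__(self) -> None:
        for name in ("spike_zygosity", "wt_survival_per_round", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("genome_mass_pg", "input_mass_ug"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spike_mass_ng < 0:
            raise ValueError("spike_mass_ng must be non-negative")

    @property
    def haploid_genomes(self) -> float:
        """Haploid genome copies per reaction (1 ug = 1e6 pg)."""
        return self.input_mass_ug * 1e6 / self.genome_mass_pg

    @property
    def spike_copies(self) -> float:
        return mutant_copies_from_mass(self.spike_mass_ng, self.spike_zygosity, self).copies

    @property
    def spike_dilution(self) -> float:
        return self.spike_copies / self.haploid_genomes


@dataclass(frozen=True)
class CopyEstimate:
    copies: float
    dilution: float


def mutant_copies_from_mass(mass_ng: float, zygosity: float, config: SimulationConfig) -> CopyEstimate:
    """Expected mutant copies (and dilution) contributed by a gDNA mass.

    copies = (mass_ng * 1e3 / genome_mass_pg) * zygosity;
    dilution = copies / haploid genomes per reaction.
    """
    if mass_ng < 0:
        raise ValueError("mass must be non-negative")
    copies = mass_ng * 1e3 / config.genome_mass_pg * zygosity
    return CopyEstimate(copies=copies, dilution=copies / config.haploid_genomes)


@dataclass
class TrueMutationState:
    """Latent per-sample truth: allele fractions and the damage intensity."""

    sample_id: str
    donor_age: float
    tissue: str  # "sperm" | "blood" | "titration"
    true_fraction: dict[str, float]
    damage_intensity: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for m, f in self.true_fraction.items():
            if not 0.0 <= f <= 0.5:
                raise ValueError(f"{self.sample_id}: fraction for {m} outside [0, 0.5]")


def simulate_cohort(
    config: SimulationConfig,
    n_sperm: int = 57,
    n_blood: int = 5,
    age_range: tuple[float, float] = (24.0, 75.0),
) -> list[TrueMutationState]:
    """Draw latent truth for a donor cohort.

    Sperm samples carry the age-dependent selected clones; blood samples
    never do (clonal expansion happens in the testis).  The damage artifact
    hits both tissues with a per-sample intensity shared across the
    reciprocal pair.
    """
    if age_range[0] >= age_range[1]:
        raise ValueError("age range must be non-empty (min < max)")
    labels = substitution_labels()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_sperm + n_blood)]
    states = []
    samples = [("sperm", i) for i in range(n_sperm)] + [("blood", i) for i in range(n_blood)]
    for (tissue, i), child in zip(samples, child_seeds):
        age = float(rng.uniform(*age_range))
        fractions = {m: 0.0 for m in labels}
        if tissue == "sperm":
            for m, par in config.selection_params.items():
                if rng.random() < par.detect_prob(age):
                    log10_f = par.intercept + par.slope_per_year * age + rng.normal(0.0, par.sigma)
                    fractions[m] = min(10.0**log10_f, 0.5)
        damage = 10.0 ** rng.normal(config.damage_mean, config.damage_sd)
        for m in DAMAGE_PAIR:
            jitter = 10.0 ** rng.normal(0.0, config.damage_pair_jitter_sd)
            fractions[m] = min(fractions[m] + damage * jitter, 0.5)
        states.append(
            TrueMutationState(
                sample_id=f"{tissue}_{i + 1:02d}",
                donor_age=age,
                tissue=tissue,
                true_fraction=fractions,
                damage_intensity=damage,
                rng_seed=child,
            )
        )
    return states


def simulate_counts(
    state: TrueMutationState,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    replicate_id: str = "r1",
) -> SampleCounts:
    """One technical replicate of the enrichment + sequencing forward model.

    Molecule layer: mutant and integrant copies are Poisson; wild-type
    survivors are binomial with per-molecule survival
    ``wt_survival_per_round ** n_digestion_rounds``.  Read layer: library
    depth is allocated multinomially over surviving molecule classes, then a
    per-allele misassignment probability ``seq_error_rate`` moves reads into
    each substitution class irrespective of origin.
    """
    if rng is None:
        rng = np.random.default_rng(state.rng_seed if state.rng_seed is not None else config.seed)
    labels = substitution_labels()
    G = config.haploid_genomes
    mutant_mols = np.array(
        [rng.poisson(state.true_fraction.get(m, 0.0) * G) for m in labels], dtype=float
    )
    integrant_mols = float(rng.poisson(config.spike_copies))
    p_survive = config.wt_survival_per_round**config.n_digestion_rounds
    wt_mols = float(rng.binomial(int(G), p_survive))
    molecules = np.concatenate([mutant_mols, [integrant_mols, wt_mols]])
    depth = int(rng.poisson(config.read_depth))
    total = molecules.sum()
    if total == 0 or depth == 0:
        reads = np.zeros(len(molecules), dtype=int)
        n_other = depth
    else:
        p = molecules / total
        e = config.seq_error_rate
        q = p * (1.0 - len(labels) * e)
        q[: len(labels)] += e
        reads = rng.multinomial(depth, q / q.sum())
        n_other = 0
    return SampleCounts(
        sample_id=state.sample_id,
        donor_age=state.donor_age,
        tissue=state.tissue,
        replicate_id=replicate_id,
        n_wt=int(reads[-1]),
        n_sub={m: int(reads[i]) for i, m in enumerate(labels)},
        n_integrant=int(reads[-2]),
        n_other=int(n_other),
    )


def simulate_sample_replicates(
    state: TrueMutationState, config: SimulationConfig, n_replicates: int | None = None
) -> list[SampleCounts]:
    """Independent technical replicates (separate 10 ug aliquots) of a sample."""
    n = n_replicates if n_replicates is not None else config.n_replicates
    rng = np.random.default_rng(state.rng_seed if state.rng_seed is not None else config.seed)
    return [simulate_counts(state, config, rng=rng, replicate_id=f"r{j + 1}") for j in range(n)]


def simulate_cohort_counts(
    config: SimulationConfig,
    states: list[TrueMutationState] | None = None,
    **cohort_kwargs,
) -> tuple[list[TrueMutationState], list[SampleCounts]]:
    """Convenience: latent truth plus replicate-level counts for a cohort."""
    if states is None:
        states = simulate_cohort(config, **cohort_kwargs)
    counts = [c for s in states for c in simulate_sample_replicates(s, config)]
    return states, counts


# ---------------------------------------------------------------------------
# titration-reconstruction series


@dataclass(frozen=True)
class TitrationDesign:
    """Two-replicate dilution series of an equimolar pair of variant gDNAs."""

    dilutions: tuple[float, ...] = (0.0, 1e-6, 3e-6, 1e-5, 3e-5, 1e-4)
    replicate_count: int = 2
    variant_pair: tuple[str, str] = ("c.1498A>G", "c.1499T>C")

    def __post_init__(self) -> None:
        nonzero = [d for d in self.dilutions if d > 0]
        if any(d < 0 for d in self.dilutions) or sorted(nonzero) != list(nonzero) or len(set(nonzero)) != len(nonzero):
            raise ValueError("dilutions must be non-negative and strictly increasing after zero")


@dataclass
class TitrationSample:
    dilution: float
    replicate: int
    counts: SampleCounts


def simulate_titration(design: TitrationDesign, config: SimulationConfig) -> list[TitrationSample]:
    """Simulate the spike-in dilution series, both variants added equimolar."""
    labels = substitution_labels()
    ss = np.random.SeedSequence(config.seed)
    children = iter(ss.spawn(len(design.dilutions) * design.replicate_count))
    out = []
    for d in design.dilutions:
        fractions = {m: 0.0 for m in labels}
        for v in design.variant_pair:
            fractions[v] = d
        state = TrueMutationState(
            sample_id=f"titration_{d:.0e}",
            donor_age=float("nan"),
            tissue="titration",
            true_fraction=fractions,
        )
        for r in range(design.replicate_count):
            rng = np.random.default_rng(next(children))
            out.append(
                TitrationSample(d, r + 1, simulate_counts(state, config, rng=rng, replicate_id=f"r{r + 1}"))
            )
    return out


def titration_report(
    samples: list[TitrationSample],
    config: SimulationConfig,
    design: TitrationDesign | None = None,
):
    """Estimated-vs-input table and per-variant Spearman over nonzero points.

    Levels are estimated per replicate and averaged within a dilution point,
    mirroring how the titration duplicates are reported.
    """
    import pandas as pd
    from scipy.stats import spearmanr

    design = design or TitrationDesign()
    rows = []
    for s in samples:
        ests = {e.substitution: e for e in estimate_levels(s.counts, config.spike_dilution)}
        for v in design.variant_pair:
            rows.append(
                {
                    "dilution": s.dilution,
                    "replicate": s.replicate,
                    "cdna_change": v,
                    "level": ests[v].level,
                    "lwr": ests[v].lwr,
                    "upr": ests[v].upr,
                }
            )
    df = pd.DataFrame(rows)
    means = df.groupby(["cdna_change", "dilution"], as_index=False)["level"].mean()
    correlations = {}
    for v in design.variant_pair:
        sub = means[(means["cdna_change"] == v) & (means["dilution"] > 0)]
        rs = spearmanr(sub["dilution"], sub["level"]).statistic
        correlations[v] = float(rs)
    return df, correlations


# ---------------------------------------------------------------------------
# synthetic reference sequence and read emission

_BASES = np.array(list("ACGT"))


@dataclass
class ReferenceLayout:
    """Synthetic locus engineered to reproduce the assay's fragment sizes.

    A random backbone carries two PstI sites 1,332 bp apart (cut-to-cut) with
    one internal NsiI site placed so wild-type digestion yields 488 + 844 bp
    sub-fragments.  The 208-bp PCR2 amplicon window is centred on the NsiI
    site; the integrant allele deletes the 17 bp ending at the first site
    base (c.1478_1494del).
    """

    sequence: str
    nsii_start: int
    psti_starts: tuple[int, int]
    amplicon_start: int
    site_offset: int = 101
    amplicon_length: int = 208
    read_length: int = 151
    deletion_length: int = 17
    model: SiteModel = field(default_factory=SiteModel)

    @property
    def amplicon(self) -> str:
        return self.sequence[self.amplicon_start : self.amplicon_start + self.amplicon_length]

    @property
    def deletion_start(self) -> int:
        """0-based reference start of the 17-bp integrant deletion; the
        deleted interval ends just after the first NsiI-site base."""
        return self.nsii_start - self.deletion_length + 1

    @property
    def integrant_sequence(self) -> str:
        s = self.deletion_start
        return self.sequence[:s] + self.sequence[s + self.deletion_length :]

    @property
    def integrant_amplicon(self) -> str:
        return self.integrant_sequence[
            self.amplicon_start : self.amplicon_start + self.amplicon_length - self.deletion_length
        ]

    @property
    def integrant_signature(self) -> str:
        """20-mer spanning the deletion junction; identifies integrant reads."""
        j = self.deletion_start - self.amplicon_start
        return self.integrant_amplicon[j - 10 : j + 10]

    @property
    def window_map(self) -> dict[str, str]:
        """Exact 6-mer at the site window -> allele label (WT or cdna_change)."""
        mapping = {self.model.site_sequence: "WT"}
        for sub in enumerate_escaping_substitutions(self.model):
            mapping[sub.mutated_site(self.model)] = sub.cdna_change
        return mapping

    def mutant_sequence(self, sub: Substitution) -> str:
        i = self.nsii_start + sub.site_position(self.model) - 1
        return self.sequence[:i] + sub.alt_base + self.sequence[i + 1 :]

    def mutant_amplicon(self, cdna_change: str) -> str:
        from .site_model import substitution_from_cdna_change

        sub = substitution_from_cdna_change(self.model, cdna_change)
        i = self.site_offset + sub.site_position(self.model) - 1
        amp = self.amplicon
        return amp[:i] + sub.alt_base + amp[i + 1 :]


def generate_reference(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    flank: int = 50,
) -> ReferenceLayout:
    """Random reference with the published digestion geometry.

    Rejection-samples the backbone until neither the wild-type, any of the 18
    single-substitution mutants, nor the integrant allele contains a spurious
    NsiI or PstI site, and the integrant junction signature is unique.
    """
    if seed is None:
        seed = (config.seed if config is not None else 0) + 104729
    rng = np.random.default_rng(seed)
    model = SiteModel()
    # cut-to-cut geometry: PstI...488...NsiI...844...PstI (offset-5 cuts)
    left_psti = flank
    left_cut = left_psti + 5
    nsii_start = left_cut + 488 - 5
    right_psti = left_cut + 1332 - 5
    total = right_psti + 6 + flank
    amplicon_start = nsii_start - 101
    fixed = {}
    for s, motif in ((left_psti, PSTI), (nsii_start, NSII), (right_psti, PSTI)):
        for k, b in enumerate(motif):
            fixed[s + k] = b
    for _ in range(1000):
        seq = rng.choice(_BASES, size=total)
        for pos, b in fixed.items():
            seq[pos] = b
        sequence = "".join(seq)
        layout = ReferenceLayout(sequence, nsii_start, (left_psti, right_psti), amplicon_start, model=model)
        if _layout_is_clean(layout):
            return layout
    raise RuntimeError("failed to sample a clean reference layout")


def _count(haystack: str, needle: str) -> int:
    return sum(1 for i in range(len(haystack) - len(needle) + 1) if haystack[i : i + len(needle)] == needle)


def _layout_is_clean(layout: ReferenceLayout) -> bool:
    seq = layout.sequence
    if _count(seq, NSII) != 1 or _count(seq, PSTI) != 2:
        return False
    integrant = layout.integrant_sequence
    if _count(integrant, NSII) != 0 or _count(integrant, PSTI) != 2:
        return False
    for sub in enumerate_escaping_substitutions(layout.model):
        if _count(layout.mutant_sequence(sub), NSII) != 0:
            return False
    sig = layout.integrant_signature
    if sig in layout.amplicon:
        return False
    return True


#: site-window 6-mer guaranteed to match no allele (>=2 mismatches from all)
_OTHER_WINDOW = "AAAAAA"


def emit_reads(counts: SampleCounts, layout: ReferenceLayout, r1_path, r2_path) -> int:
    """Write the counts as paired 151-bp FASTQ over the amplicon layout.

    Allele identity is encoded purely in the read sequences (site 6-mer, or
    the 17-bp deletion junction for integrant reads); ``n_other`` reads get a
    multiply-mismatched site window so they classify as neither allele.
    Counting the reads back with ``quantify.count_alleles`` reproduces the
    input tallies exactly.  Returns the number of read pairs written.
    """
    amp = layout.amplicon
    i0 = layout.site_offset
    other_amp = amp[:i0] + _OTHER_WINDOW + amp[i0 + 6 :]
    jobs: list[tuple[str, int]] = [(amp, counts.n_wt)]
    for m, k in sorted(counts.n_sub.items()):
        jobs.append((layout.mutant_amplicon(m), k))
    jobs.append((layout.integrant_amplicon, counts.n_integrant))
    jobs.append((other_amp, counts.n_other))
    L = layout.read_length
    written = 0

    def _open(path):
        path = str(path)
        return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")

    with _open(r1_path) as f1, _open(r2_path) as f2:
        for template, k in jobs:
            r1 = template[:L]
            r2 = _revcomp(template[-L:])
            qual = "I" * L
            for _ in range(k):
                written += 1
                name = f"{counts.sample_id}:{counts.replicate_id}:{written}"
                f1.write(f"@{name}/1\n{r1}\n+\n{qual}\n")
                f2.write(f"@{name}/2\n{r2}\n+\n{qual}\n")
    return written


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def write_reference_fasta(layout: ReferenceLayout, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(layout.sequence), id="synthetic_smad4_locus", description="synthetic RED-PCR reference")
    with open(path, "w") as fh:
        seqio_write([rec], fh, "fasta")


def write_truth_tsv(states: list[TrueMutationState], path) -> None:
    import pandas as pd

    rows = [
        {
            "sample_id": s.sample_id,
            "donor_age": s.donor_age,
            "tissue": s.tissue,
            "cdna_change": m,
            "true_fraction": f,
        }
        for s in states
        for m, f in sorted(s.true_fraction.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
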