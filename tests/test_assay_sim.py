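"""Forward model: spike arithmetic, cohort structure, counts and reads."""

import gzip

import numpy as np
import pytest

from redpcr import assay_sim as asim
from redpcr import quantify as q
from redpcr.red_digest import NSII, PSTI, digest, internal_fragments


# ---------------------------------------------------------------------------
# spike arithmetic


@pytest.mark.parametrize(
    "mass_ng, zygosity, copies, dilution",
    [
        (0.6, 0.5, 100.0, 3e-5),  # the integrant spike
        (0.02, 0.5, 10.0 / 3.0, 1e-6),  # lowest titration point
        (2.0, 0.5, 1000.0 / 3.0, 1e-4),  # highest titration point
        (0.0, 0.5, 0.0, 0.0),
    ],
)
def test_mutant_copies_from_mass(sim_config, mass_ng, zygosity, copies, dilution):
    est = asim.mutant_copies_from_mass(mass_ng, zygosity, sim_config)
    assert est.copies == pytest.approx(copies, rel=1e-9)
    assert est.dilution == pytest.approx(dilution, rel=1e-9)


def test_negative_mass_rejected(sim_config):
    with pytest.raises(ValueError):
        asim.mutant_copies_from_mass(-1.0, 0.5, sim_config)


def test_config_haploid_genomes(sim_config):
    assert sim_config.haploid_genomes == pytest.approx(10.0 / 3.0 * 1e6)
    assert sim_config.spike_copies == pytest.approx(100.0)
    assert sim_config.spike_dilution == pytest.approx(3e-5)


# ---------------------------------------------------------------------------
# cohort truth


def test_blood_samples_carry_no_selected_clones(sim_config):
    states = asim.simulate_cohort(sim_config, n_sperm=10, n_blood=8)
    for s in states:
        if s.tissue == "blood":
            for m in asim.SELECTED_SUBSTITUTIONS:
                assert s.true_fraction[m] == 0.0
        assert all(0.0 <= f <= 0.5 for f in s.true_fraction.values())


def test_degenerate_age_law_gives_identical_fractions():
    params = {"c.1498A>G": asim.SelectionParams(-5.0, 0.0, 0.0, detect_frac=1.0)}
    cfg = asim.SimulationConfig(seed=1, selection_params=params)
    states = asim.simulate_cohort(cfg, n_sperm=20, n_blood=0)
    fractions = {s.true_fraction["c.1498A>G"] for s in states}
    assert len(fractions) == 1
    assert next(iter(fractions)) == pytest.approx(1e-5)


def test_empty_age_range_rejected(sim_config):
    with pytest.raises(ValueError):
        asim.simulate_cohort(sim_config, n_sperm=5, n_blood=0, age_range=(50.0, 50.0))


def test_detection_prevalence_matches_calibration():
    """~73% of sperm donors carry c.1498A>G above the 1e-6 detection limit."""
    fracs = []
    for seed in range(12):
        cfg = asim.SimulationConfig(seed=200 + seed)
        states = asim.simulate_cohort(cfg, n_sperm=57, n_blood=0)
        levels = np.array([s.true_fraction["c.1498A>G"] for s in states])
        fracs.append((levels > 1e-6).mean())
    assert np.mean(fracs) == pytest.approx(0.73, abs=0.05)


def test_cohort_is_reproducible_under_seed(sim_config):
    a = asim.simulate_cohort(sim_config, n_sperm=6, n_blood=2)
    b = asim.simulate_cohort(sim_config, n_sperm=6, n_blood=2)
    assert [(s.sample_id, s.donor_age, s.true_fraction) for s in a] == [
        (s.sample_id, s.donor_age, s.true_fraction) for s in b
    ]


# ---------------------------------------------------------------------------
# count simulation


def _flat_state(fractions=None, tissue="sperm"):
    base = {m: 0.0 for m in q.substitution_labels()}
    base.update(fractions or {})
    return asim.TrueMutationState("s", 40.0, tissue, base, rng_seed=123)


def test_only_integrant_when_nothing_else_survives():
    cfg = asim.SimulationConfig(seed=4, seq_error_rate=0.0, wt_survival_per_round=0.0)
    counts = asim.simulate_counts(_flat_state(), cfg)
    assert counts.n_wt == 0 and counts.n_other == 0
    assert sum(counts.n_sub.values()) == 0
    assert counts.n_integrant == counts.depth > 0


def test_spike_symmetry_at_matching_dilution(sim_config):
    """A mutant at the spike dilution is read out at parity with the spike."""
    state = _flat_state({"c.1498A>G": 3e-5})
    rng = np.random.default_rng(9)
    mut, integ = [], []
    for _ in range(120):
        c = asim.simulate_counts(state, sim_config, rng=rng)
        mut.append(c.n_sub["c.1498A>G"])
        integ.append(c.n_integrant)
    assert np.mean(mut) == pytest.approx(np.mean(integ), rel=0.1)


def test_counts_reproducible_from_state_seed(sim_config):
    a = asim.simulate_counts(_flat_state({"c.1499T>C": 1e-5}), sim_config)
    b = asim.simulate_counts(_flat_state({"c.1499T>C": 1e-5}), sim_config)
    assert a.n_sub == b.n_sub and a.n_integrant == b.n_integrant and a.n_wt == b.n_wt


# ---------------------------------------------------------------------------
# titration series


def test_titration_structure_and_zero_point(sim_config):
    design = asim.TitrationDesign()
    samples = asim.simulate_titration(design, sim_config)
    assert len(samples) == len(design.dilutions) * design.replicate_count
    zero = [s for s in samples if s.dilution == 0.0]
    # no mutant molecules are injected at dilution zero; only rare
    # read-misassignment errors can appear
    for s in zero:
        for v in design.variant_pair:
            assert s.counts.n_sub[v] <= 3


def test_titration_design_validation():
    with pytest.raises(ValueError):
        asim.TitrationDesign(dilutions=(0.0, 1e-5, 1e-6))
    with pytest.raises(ValueError):
        asim.TitrationDesign(dilutions=(-1e-6, 1e-5))


# ---------------------------------------------------------------------------
# reference and reads


def test_reference_geometry(layout):
    assert layout.sequence.count(NSII) == 1
    assert layout.sequence.count(PSTI) == 2
    psti_only = internal_fragments(digest(layout.sequence, [PSTI]), len(layout.sequence))
    assert [f.length for f in psti_only] == [1332]
    assert layout.integrant_sequence.count(NSII) == 0
    assert len(layout.sequence) - len(layout.integrant_sequence) == 17


def test_reference_deterministic_per_seed():
    a = asim.generate_reference(seed=11)
    b = asim.generate_reference(seed=11)
    c = asim.generate_reference(seed=12)
    assert a.sequence == b.sequence
    assert a.sequence != c.sequence


def test_read_roundtrip_exact(layout, tmp_path, rng):
    n_sub = {m: int(rng.integers(0, 40)) for m in q.substitution_labels()}
    counts = q.SampleCounts("s1", 40.0, "sperm", "r1", n_wt=57, n_sub=n_sub, n_integrant=100, n_other=5)
    r1, r2 = tmp_path / "R1.fastq.gz", tmp_path / "R2.fastq.gz"
    written = asim.emit_reads(counts, layout, r1, r2)
    assert written == counts.depth
    back = q.count_alleles(r1, r2, layout, sample_id="s1", donor_age=40.0, tissue="sperm")
    assert back.n_wt == counts.n_wt
    assert back.n_sub == counts.n_sub
    assert back.n_integrant == counts.n_integrant
    assert back.n_other == counts.n_other


def test_integrant_reads_carry_the_deletion(layout, tmp_path):
    counts = q.SampleCounts("s2", 40.0, "sperm", "r1", n_wt=0, n_sub={}, n_integrant=100, n_other=0)
    r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
    asim.emit_reads(counts, layout, r1, r2)
    reads = [line.strip() for i, line in enumerate(open(r1)) if i % 4 == 1]
    assert len(reads) == 100
    assert all(layout.integrant_signature in r for r in reads)
    back = q.count_alleles(r1, r2, layout)
    assert back.n_integrant == 100 and back.depth == 100


def test_empty_counts_give_empty_fastq(layout, tmp_path):
    counts = q.SampleCounts("e", 0.0, "blood", "r1", n_wt=0, n_sub={}, n_integrant=0, n_other=0)
    r1, r2 = tmp_path / "R1.fastq.gz", tmp_path / "R2.fastq.gz"
    assert asim.emit_reads(counts, layout, r1, r2) == 0
    assert gzip.open(r1).read() == b""


def test_conflicting_mates_count_as_other(layout, tmp_path):
    amp_wt = layout.amplicon
    amp_mut = layout.mutant_amplicon("c.1498A>G")
    L = layout.read_length
    r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
    qual = "I" * L
    r1.write_text(f"@x/1\n{amp_mut[:L]}\n+\n{qual}\n")
    rc = amp_wt[-L:].translate(str.maketrans("ACGT", "TGCA"))[::-1]
    r2.write_text(f"@x/2\n{rc}\n+\n{qual}\n")
    back = q.count_alleles(r1, r2, layout)
    assert back.n_other == 1 and back.depth == 1


def test_malformed_fastq_names_record(layout, tmp_path):
    r1 = tmp_path / "R1.fastq"
    r2 = tmp_path / "R2.fastq"
    good = f"@a/1\n{layout.amplicon[:151]}\n+\n{'I' * 151}\n"
    r1.write_text(good + "not-a-header\nACGT\n+\nIIII\n")
    r2.write_text(good + good)
    with pytest.raises(ValueError, match=r"malformed FASTQ record \d+"):
        q.count_alleles(r1, r2, layout)
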