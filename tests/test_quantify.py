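"""Pooling, QC, Sison-Glaz intervals and spike-calibrated estimation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom

from redpcr import assay_sim as asim
from redpcr import quantify as q


def _counts(n_sub=None, n_int=100, n_wt=10, n_other=0, sample="s", rep="r1"):
    base = {m: 0 for m in q.substitution_labels()}
    base.update(n_sub or {})
    return q.SampleCounts(sample, 40.0, "sperm", rep, n_wt=n_wt, n_sub=base, n_integrant=n_int, n_other=n_other)


# ---------------------------------------------------------------------------
# pooling and QC


@given(st.lists(st.integers(0, 1000), min_size=3, max_size=3), st.permutations([0, 1, 2]))
def test_pooling_is_permutation_invariant(depths, perm):
    reps = [
        _counts({"c.1498A>G": d}, n_int=50 + d, n_wt=d, rep=f"r{i}") for i, d in enumerate(depths)
    ]
    a = q.pool_replicates(reps)
    b = q.pool_replicates([reps[i] for i in perm])
    assert (a.n_wt, a.n_sub, a.n_integrant, a.n_other) == (b.n_wt, b.n_sub, b.n_integrant, b.n_other)


def test_pooling_identity_and_depth():
    single = _counts({"c.1497C>A": 7})
    pooled = q.pool_replicates([single])
    assert pooled.n_sub == single.n_sub and pooled.depth == single.depth
    reps = [_counts(n_int=300, n_wt=700, rep=f"r{i}") for i in range(3)]
    assert q.pool_replicates(reps).depth == 3000


def test_pooling_rejects_mixed_samples():
    with pytest.raises(ValueError):
        q.pool_replicates([_counts(sample="a"), _counts(sample="b")])


@pytest.mark.parametrize(
    "depth_pad, n_int, passed, reason_part",
    [
        (0, 100, False, "integrant"),  # depth ok via pad below
        (0, 250, True, None),
        (0, 249, False, "integrant"),
    ],
)
def test_qc_integrant_threshold(depth_pad, n_int, passed, reason_part):
    counts = _counts(n_int=n_int, n_wt=2000 + depth_pad)
    res = q.qc_filter(counts)
    assert res.passed is passed
    if reason_part:
        assert any(reason_part in r for r in res.reasons)


def test_qc_depth_threshold_is_strict():
    fail = q.qc_filter(_counts(n_int=500, n_wt=499, n_other=0))  # depth 999
    assert not fail.passed and any("depth" in r for r in fail.reasons)
    edge = q.qc_filter(_counts(n_int=250, n_wt=750))  # depth 1000, integrant 250
    assert edge.passed
    big = q.qc_filter(_counts(n_int=249, n_wt=10**6))
    assert not big.passed


# ---------------------------------------------------------------------------
# Sison-Glaz intervals


def test_ci_matches_exact_enumeration_oracle():
    """k=2, (50,50): compare to the same construction with *exact* joint
    coverage computed by full enumeration of the binomial outcome space."""
    n = 100
    x = np.array([50, 50])

    def exact_nu(c):
        return binom.cdf(50 + c, n, 0.5) - binom.cdf(50 - c - 1, n, 0.5)

    nu_prev, c_star = 0.0, None
    for c in range(1, n + 1):
        nu = exact_nu(c)
        if nu > 0.95:
            c_star = c
            break
        nu_prev = nu
    gamma = (0.95 - nu_prev) / (nu - nu_prev)
    oracle_lwr = 0.5 - c_star / n
    oracle_upr = 0.5 + c_star / n + 2 * gamma / n
    ci = q.multinomial_ci(x)
    assert ci[0, 0] == pytest.approx(oracle_lwr, abs=0.02)
    assert ci[0, 1] == pytest.approx(oracle_upr, abs=0.02)


def test_ci_symmetry_equal_widths():
    ci = q.multinomial_ci([10, 10, 10, 10])
    widths = ci[:, 1] - ci[:, 0]
    assert np.allclose(widths, widths[0])


def test_ci_single_category_clipped():
    ci = q.multinomial_ci([20, 0, 0])
    assert ci[0, 1] == 1.0  # upper bound capped at 1
    assert ci[0, 0] > 0.8
    assert ci[1, 0] == 0.0


def test_ci_rejects_degenerate_input():
    with pytest.raises(ValueError):
        q.multinomial_ci([0, 0, 0])
    with pytest.raises(ValueError):
        q.multinomial_ci([5])
    with pytest.raises(ValueError):
        q.multinomial_ci([1.5, 2.5])


def test_ci_widths_shrink_with_n():
    base = np.array([30, 30, 40])
    widths = []
    for scale in (1, 10, 100):
        ci = q.multinomial_ci(base * scale)
        widths.append((ci[:, 1] - ci[:, 0]).mean())
    assert widths[0] > widths[1] > widths[2]


@pytest.mark.parametrize("k", [3, 6, 20])
@pytest.mark.parametrize("n", [100, 1000, 10000])
def test_ci_empirical_coverage_near_nominal(k, n):
    """Simultaneous coverage stays near 95% (mildly conservative at small n)."""
    rng = np.random.default_rng(42)
    cov = q.simulate_ci_coverage(k, n, 300, rng=rng)
    assert 0.92 <= cov <= 0.99


# ---------------------------------------------------------------------------
# estimation


def test_estimate_closed_forms():
    counts = _counts({"c.1498A>G": 100, "c.1499T>C": 30}, n_int=100)
    est = {e.substitution: e for e in q.estimate_levels(counts)}
    assert est["c.1498A>G"].level == pytest.approx(3e-5)
    assert est["c.1499T>C"].level == pytest.approx(9e-6)  # 9 per million
    assert est["c.1499T>C"].per_million == pytest.approx(9.0)
    zero = est["c.1494A>C"]
    assert zero.level == 0.0 and zero.lwr == 0.0


def test_estimate_interval_ordering():
    rng = np.random.default_rng(3)
    counts = _counts({m: int(rng.integers(0, 200)) for m in q.substitution_labels()}, n_int=500, n_wt=100)
    for e in q.estimate_levels(counts):
        assert 0.0 <= e.lwr <= e.level <= e.upr


def test_integrant_dropout_is_flagged_not_infinite():
    counts = _counts({"c.1498A>G": 10}, n_int=0)
    ests = q.estimate_levels(counts)
    assert all(math.isnan(e.level) and not e.qc_pass for e in ests)


def test_estimator_consistency():
    """Relative bias < 10% for fractions >= 1e-5 at high depth."""
    cfg = asim.SimulationConfig(seed=5)
    for truth in (1e-5, 5e-5):
        state = asim.TrueMutationState(
            "s", 40.0, "sperm", {m: 0.0 for m in q.substitution_labels()} | {"c.1498A>G": truth}
        )
        rng = np.random.default_rng(17)
        levels = []
        for _ in range(500):
            c = asim.simulate_counts(state, cfg, rng=rng)
            e = {x.substitution: x for x in q.estimate_levels(c, cfg.spike_dilution)}
            levels.append(e["c.1498A>G"].level)
        assert abs(np.mean(levels) / truth - 1.0) < 0.10


def test_enrichment_strength_does_not_shift_estimates():
    """The spike cancels digestion efficiency: estimates agree across
    100-fold changes in wild-type survival."""
    truth = 3e-5
    state = asim.TrueMutationState(
        "s", 40.0, "sperm", {m: 0.0 for m in q.substitution_labels()} | {"c.1498A>G": truth}
    )
    means = []
    for survival in (1e-1, 1e-2, 1e-3):
        cfg = asim.SimulationConfig(seed=5, wt_survival_per_round=survival)
        rng = np.random.default_rng(23)
        levels = [
            {x.substitution: x for x in q.estimate_levels(asim.simulate_counts(state, cfg, rng=rng), cfg.spike_dilution)}[
                "c.1498A>G"
            ].level
            for _ in range(80)
        ]
        means.append(np.mean(levels))
    grand = np.mean(means)
    assert all(abs(m / grand - 1.0) < 0.10 for m in means)


# ---------------------------------------------------------------------------
# TSV round trip


def test_counts_tsv_roundtrip(tmp_path, rng):
    counts = [
        _counts({m: int(rng.integers(0, 50)) for m in q.substitution_labels()}, rep=f"r{i}")
        for i in range(3)
    ]
    path = tmp_path / "counts.tsv"
    q.write_counts_tsv(counts, path)
    back = q.read_counts_tsv(path)
    assert len(back) == 3
    for a, b in zip(sorted(counts, key=lambda c: c.replicate_id), back):
        assert (a.n_wt, a.n_sub, a.n_integrant, a.n_other) == (b.n_wt, b.n_sub, b.n_integrant, b.n_other)


def test_counts_tsv_schema_errors(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("sample_id\treads\nx\t1\n")
    with pytest.raises(ValueError, match="missing required column"):
        q.read_counts_tsv(bad)
    empty = tmp_path / "empty.tsv"
    empty.write_text("sample_id\tdonor_age\ttissue\treplicate_id\tallele\treads\n")
    with pytest.raises(ValueError, match="empty"):
        q.read_counts_tsv(empty)
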