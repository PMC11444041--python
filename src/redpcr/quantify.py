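"""From raw read tallies to spike-calibrated absolute mutation levels.

The assay destroys wild-type molecules by repeated NsiI digestion, so raw
read fractions are meaningless in absolute terms.  Calibration relies on a
known-copy-number spike: an engineered NsiI-resistant "integrant" allele
(a 17-bp deletion, c.1478_1494del) added at ~100 copies per reaction,
i.e. a dilution of 3x10^-5 of the ~3.3x10^6 input haploid genomes.  Because
spike and mutant molecules are enriched identically, the absolute mutant
allele fraction is

    level_m = (n_m / n_integrant) * spike_dilution

independent of digestion efficiency.  Simultaneous 95% confidence intervals
for the non-wild-type read-count vector (18 substitutions + integrant +
other) come from the Sison-Glaz multinomial procedure and are transferred to
the absolute scale through the integrant's point proportion.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .site_model import SiteModel, annotate_consequence, enumerate_escaping_substitutions

WT_LABEL = "WT"
INTEGRANT_LABEL = "INTEGRANT"
OTHER_LABEL = "OTHER"

DEFAULT_SPIKE_DILUTION = 3e-5


def substitution_labels(model: SiteModel | None = None) -> list[str]:
    """The 18 cdna_change labels in canonical (position, alt) order."""
    return [s.cdna_change for s in enumerate_escaping_substitutions(model or SiteModel())]


# ---------------------------------------------------------------------------
# sample counts


@dataclass
class SampleCounts:
    """Per-replicate read tallies over the NsiI-site allele classes.

    ``n_sub`` maps each of the 18 escaping substitutions (cdna_change label)
    to its read count; the integrant deletion is tallied separately and reads
    matching no known allele fall into ``n_other``.
    """

    sample_id: str
    donor_age: float
    tissue: str  # "sperm" | "blood" | "titration"
    replicate_id: str
    n_wt: int
    n_sub: dict[str, int] = field(default_factory=dict)
    n_integrant: int = 0
    n_other: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_wt, self.n_integrant, self.n_other, *self.n_sub.values()]
        if any(c < 0 for c in counts):
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.n_wt + sum(self.n_sub.values()) + self.n_integrant + self.n_other


def pool_replicates(counts: list[SampleCounts]) -> SampleCounts:
    """Field-wise sum of technical replicates of one sample."""
    if not counts:
        raise ValueError("nothing to pool")
    sample_ids = {c.sample_id for c in counts}
    if len(sample_ids) != 1:
        raise ValueError(f"cannot pool counts from different samples: {sorted(sample_ids)}")
    labels = sorted({k for c in counts for k in c.n_sub})
    pooled_sub = {m: sum(c.n_sub.get(m, 0) for c in counts) for m in labels}
    first = counts[0]
    return SampleCounts(
        sample_id=first.sample_id,
        donor_age=first.donor_age,
        tissue=first.tissue,
        replicate_id="pooled",
        n_wt=sum(c.n_wt for c in counts),
        n_sub=pooled_sub,
        n_integrant=sum(c.n_integrant for c in counts),
        n_other=sum(c.n_other for c in counts),
    )


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple[str, ...] = ()


def qc_filter(counts: SampleCounts, min_depth: int = 1000, min_integrant: int = 250) -> QCResult:
    """Exclude samples with read depth < 1000 or integrant coverage < 250.

    Both thresholds are strict: a sample at exactly the threshold passes.
    """
    reasons = []
    if counts.depth < min_depth:
        reasons.append(f"depth {counts.depth} < {min_depth}")
    if counts.n_integrant < min_integrant:
        reasons.append(f"integrant coverage {counts.n_integrant} < {min_integrant}")
    return QCResult(passed=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# Sison-Glaz simultaneous multinomial confidence intervals


def _truncated_poisson_moments(c: int, lam: np.ndarray):
    """First four central moments (and normalising mass) of Poisson(lam)
    truncated to [lam - c, lam + c], via factorial moments.

    Vectorised over the category means ``lam`` (the observed counts).
    """
    lam = np.asarray(lam, dtype=float)
    a = lam + c
    b = np.maximum(lam - c, 0.0)
    # cdf evaluated in two batched calls; cdf(j < 0) = 0 subsumes the edge cases
    shift = np.arange(5)[:, None]
    cdf_a = poisson.cdf(a[None, :] - shift, lam[None, :])
    cdf_b = poisson.cdf(b[None, :] - 1 - shift, lam[None, :])
    den = cdf_a[0] - cdf_b[0]
    mu = {}
    for r in (1, 2, 3, 4):
        pois_a = cdf_a[0] - cdf_a[r]
        pois_b = cdf_b[0] - cdf_b[r]
        with np.errstate(invalid="ignore", divide="ignore"):
            mu[r] = lam**r * (1.0 - (pois_a - pois_b) / den)
    m1 = mu[1]
    m2 = mu[2] + mu[1] - mu[1] ** 2
    m3 = mu[3] + mu[2] * (3 - 3 * mu[1]) + (mu[1] - 3 * mu[1] ** 2 + 2 * mu[1] ** 3)
    m4 = (
        mu[4]
        + mu[3] * (6 - 4 * mu[1])
        + mu[2] * (7 - 12 * mu[1] + 6 * mu[1] ** 2)
        + mu[1]
        - 4 * mu[1] ** 2
        + 6 * mu[1] ** 3
        - 3 * mu[1] ** 4
    )
    return m1, m2, m3, m4, den


def _truncpoi_coverage(c: int, x: np.ndarray, n: int) -> float:
    """Edgeworth-corrected estimate of P(all |X_i - x_i| <= c) for a
    multinomial(n, x/n) vector, via the conditioned truncated-Poisson
    representation."""
    m1, m2, m3, m4, den = _truncated_poisson_moments(c, x)
    m4c = m4 - 3 * m2**2
    s1, s2, s3, s4 = m1.sum(), m2.sum(), m3.sum(), m4c.sum()
    if s2 <= 0:
        return 1.0
    probn = 1.0 / (poisson.cdf(n, n) - poisson.cdf(n - 1, n))
    z = (n - s1) / math.sqrt(s2)
    g1 = s3 / s2**1.5
    g2 = s4 / s2**2
    poly = (
        1.0
        + g1 * (z**3 - 3 * z) / 6.0
        + g2 * (z**4 - 6 * z**2 + 3) / 24.0
        + g1**2 * (z**6 - 15 * z**4 + 45 * z**2 - 15) / 72.0
    )
    f = poly * math.exp(-(z**2) / 2.0) / math.sqrt(2 * math.pi)
    return float(probn * np.prod(den) * f / math.sqrt(s2))


def _find_sison_glaz_c(x: np.ndarray, n: int, alpha: float) -> tuple[int, float, float]:
    """Smallest integer half-width c with estimated coverage nu(c) > 1-alpha.

    Returns (c, nu(c-1), nu(c)); nu(0) is conventionally taken as 0, matching
    the reference linear scan.  The scan is accelerated by exponential
    bracketing plus bisection (nu is monotone in c), with the bracketing
    verified at the solution.
    """
    target = 1.0 - alpha
    nu_cache: dict[int, float] = {0: 0.0}

    def nu(c: int) -> float:
        if c not in nu_cache:
            nu_cache[c] = _truncpoi_coverage(c, x, n)
        return nu_cache[c]

    hi = 1
    while hi < n and nu(hi) <= target:
        hi = min(2 * hi, n)
    if nu(hi) <= target:  # coverage never reached; degenerate tiny-n case
        return hi, nu(hi - 1) if hi > 1 else 0.0, nu(hi)
    lo = hi // 2 if hi > 1 else 0
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if nu(mid) > target:
            hi = mid
        else:
            lo = mid
    return hi, nu(hi - 1) if hi > 1 else 0.0, nu(hi)


def multinomial_ci(count_vector, alpha: float = 0.05) -> np.ndarray:
    """Sison-Glaz simultaneous confidence intervals for multinomial
    proportions.

    Finds the smallest integer c whose estimated joint coverage
    nu(c) = P(all counts within +/- c of observation) exceeds 1 - alpha
    (truncated-Poisson / Edgeworth approximation), then interpolates a
    continuity correction 2*gamma/n on the upper bounds:

        [max(0, p_i - c/n), min(1, p_i + c/n + 2*gamma/n)]

    with gamma = ((1-alpha) - nu(c-1)) / (nu(c) - nu(c-1)).  This mirrors the
    MultinomCI reference behaviour used for the published intervals.

    Returns an (k, 2) array of (lower, upper) proportion bounds.
    """
    x = np.asarray(count_vector, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("count_vector must be 1-D with at least two categories")
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("counts must be non-negative integers")
    n = int(x.sum())
    if n == 0:
        raise ValueError("count vector must contain at least one observation")
    c, nu_prev, nu_c = _find_sison_glaz_c(x, n, alpha)
    if nu_c > nu_prev:
        gamma = ((1.0 - alpha) - nu_prev) / (nu_c - nu_prev)
    else:
        gamma = 0.0
    p = x / n
    lwr = np.maximum(0.0, p - c / n)
    upr = np.minimum(1.0, p + c / n + 2.0 * gamma / n)
    return np.column_stack([lwr, upr])


def simulate_ci_coverage(
    k: int,
    n: int,
    reps: int,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    p: np.ndarray | None = None,
) -> float:
    """Empirical simultaneous coverage of `multinomial_ci` by Monte-Carlo.

    Draws ``reps`` multinomial(n, p) vectors (equiprobable categories by
    default) and reports the fraction of draws in which every true proportion
    lies inside its interval.
    """
    rng = rng or np.random.default_rng()
    if p is None:
        p = np.full(k, 1.0 / k)
    draws = rng.multinomial(n, p, size=reps)
    hits = 0
    for x in draws:
        ci = multinomial_ci(x, alpha=alpha)
        if np.all((ci[:, 0] <= p) & (p <= ci[:, 1])):
            hits += 1
    return hits / reps


# ---------------------------------------------------------------------------
# absolute mutation-level estimates


@dataclass(frozen=True)
class MutationLevelEstimate:
    """Absolute mutant allele fraction with simultaneous 95% bounds.

    ``level`` is dimensionless (multiply by 1e6 for "per million"); an
    undefined estimate (integrant dropout) carries NaN and qc_pass=False.
    """

    substitution: str
    level: float
    lwr: float
    upr: float
    qc_pass: bool = True

    @property
    def per_million(self) -> float:
        return self.level * 1e6


def estimate_levels(
    counts: SampleCounts,
    spike_dilution: float = DEFAULT_SPIKE_DILUTION,
    alpha: float = 0.05,
    qc_pass: bool = True,
    model: SiteModel | None = None,
    spike_copy_rescale: float | None = None,
) -> list[MutationLevelEstimate]:
    """Spike-calibrated absolute levels for the 18 site substitutions.

    The multinomial category set is the 18 substitutions plus integrant plus
    "other" - wild-type reads are excluded, since their abundance reflects
    digestion leakage, not mutation load.  Proportion bounds are divided by
    the integrant's *point* proportion (spike-count uncertainty is not
    propagated), keeping each interval ordered around its estimate.

    ``spike_copy_rescale``: optionally rescale the count vector so the
    integrant category equals this many counts (e.g. the ~100 spiked
    molecules) before computing intervals.  Read counts vastly oversample the
    few hundred molecules that survive digestion, so read-scale intervals
    understate molecule-sampling noise; the rescaled intervals approximate
    uncertainty at the molecule bottleneck.  Off by default, matching the
    published read-count intervals.
    """
    labels = substitution_labels(model)
    if counts.n_integrant == 0:
        return [
            MutationLevelEstimate(m, float("nan"), float("nan"), float("nan"), qc_pass=False)
            for m in labels
        ]
    x = np.array([counts.n_sub.get(m, 0) for m in labels] + [counts.n_integrant, counts.n_other], dtype=float)
    if spike_copy_rescale is not None:
        x = np.floor(x * spike_copy_rescale / counts.n_integrant)
        x[len(labels)] = max(x[len(labels)], 1)
    n = x.sum()
    ci = multinomial_ci(x.astype(int), alpha=alpha)
    p = x / n
    p_int = p[len(labels)]
    estimates = []
    for i, m in enumerate(labels):
        level = (p[i] / p_int) * spike_dilution
        lwr = (ci[i, 0] / p_int) * spike_dilution
        upr = (ci[i, 1] / p_int) * spike_dilution
        estimates.append(MutationLevelEstimate(m, level, lwr, upr, qc_pass=qc_pass))
    return estimates


def estimates_table(
    counts: SampleCounts,
    estimates: list[MutationLevelEstimate],
    model: SiteModel | None = None,
) -> pd.DataFrame:
    """Long-format estimates table for one sample (one row per substitution)."""
    from .site_model import substitution_from_cdna_change

    model = model or SiteModel()
    rows = []
    for est in estimates:
        sub = substitution_from_cdna_change(model, est.substitution)
        cons = annotate_consequence(model, sub)
        rows.append(
            {
                "sample_id": counts.sample_id,
                "donor_age": counts.donor_age,
                "tissue": counts.tissue,
                "cdna_change": est.substitution,
                "hgvs_p": cons.hgvs_p,
                "level": est.level,
                "level_per_million": est.per_million,
                "lwr_per_million": est.lwr * 1e6,
                "upr_per_million": est.upr * 1e6,
                "qc_pass": est.qc_pass,
            }
        )
    return pd.DataFrame(rows)


def quantify_samples(
    counts: list[SampleCounts],
    min_depth: int = 1000,
    min_integrant: int = 250,
    spike_dilution: float = DEFAULT_SPIKE_DILUTION,
    alpha: float = 0.05,
    model: SiteModel | None = None,
    spike_copy_rescale: float | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, tuple[str, ...]]]]:
    """Replicate counts -> pooled, QC-filtered estimates table.

    Technical replicates of each sample are pooled read-wise, the pooled
    tallies are QC-filtered, and levels are estimated for passing samples.
    Returns the long-format estimates table plus the exclusion list
    (sample_id, reasons) for QC failures.
    """
    by_sample: dict[str, list[SampleCounts]] = {}
    for c in counts:
        by_sample.setdefault(c.sample_id, []).append(c)
    frames = []
    exclusions = []
    for sample_id in sorted(by_sample):
        pooled = pool_replicates(by_sample[sample_id])
        qc = qc_filter(pooled, min_depth=min_depth, min_integrant=min_integrant)
        if not qc.passed:
            exclusions.append((sample_id, qc.reasons))
            continue
        ests = estimate_levels(
            pooled,
            spike_dilution=spike_dilution,
            alpha=alpha,
            model=model,
            spike_copy_rescale=spike_copy_rescale,
        )
        frames.append(estimates_table(pooled, ests, model=model))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return table, exclusions


# ---------------------------------------------------------------------------
# read-level counting (synthetic FASTQ)


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_fastq(path):
    """Streaming FASTQ iterator yielding (name, sequence).

    Wraps Bio.SeqIO so malformed input raises a ValueError naming the
    1-based record index.
    """
    from Bio import SeqIO

    with _open_maybe_gzip(path) as fh:
        records = SeqIO.parse(fh, "fastq")
        index = 0
        while True:
            try:
                rec = next(records)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {index + 1} in {path}: {exc}") from exc
            index += 1
            yield rec.id, str(rec.seq)


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def count_alleles(
    fastq_r1,
    fastq_r2,
    layout,
    sample_id: str = "sample",
    donor_age: float = float("nan"),
    tissue: str = "",
    replicate_id: str = "r1",
) -> SampleCounts:
    """Classify read pairs over the known amplicon layout by exact matching.

    Each mate votes: the integrant is recognised by its deletion-junction
    signature, otherwise the 6-bp site window is compared exactly against the
    wild-type 6-mer and the 18 single-substitution 6-mers.  Pairs whose mates
    disagree, or whose window matches nothing (e.g. two mismatches), count as
    "other".
    """
    window_map = layout.window_map
    signature = layout.integrant_signature
    amplicon_len = len(layout.amplicon)
    read_len = layout.read_length
    site_off_r1 = layout.site_offset
    site_off_r2 = layout.site_offset - (amplicon_len - read_len)
    tallies: dict[str, int] = {m: 0 for m in window_map.values() if m != WT_LABEL}
    n_wt = n_int = n_other = 0
    for (_, r1), (_, r2) in zip(_parse_fastq(fastq_r1), _parse_fastq(fastq_r2), strict=True):
        seg2 = _revcomp(r2)
        sig1 = signature in r1
        sig2 = signature in seg2
        if sig1 and sig2:
            n_int += 1
            continue
        if sig1 != sig2:
            n_other += 1
            continue
        w1 = r1[site_off_r1 : site_off_r1 + 6]
        w2 = seg2[site_off_r2 : site_off_r2 + 6]
        if w1 != w2 or w1 not in window_map:
            n_other += 1
            continue
        label = window_map[w1]
        if label == WT_LABEL:
            n_wt += 1
        else:
            tallies[label] += 1
    return SampleCounts(
        sample_id=sample_id,
        donor_age=donor_age,
        tissue=tissue,
        replicate_id=replicate_id,
        n_wt=n_wt,
        n_sub=tallies,
        n_integrant=n_int,
        n_other=n_other,
    )


# ---------------------------------------------------------------------------
# TSV interchange

_COUNTS_COLUMNS = ["sample_id", "donor_age", "tissue", "replicate_id", "allele", "reads"]


def write_counts_tsv(counts: list[SampleCounts], path) -> None:
    """Long-format counts TSV: one row per sample x replicate x allele."""
    rows = []
    for c in counts:
        base = dict(sample_id=c.sample_id, donor_age=c.donor_age, tissue=c.tissue, replicate_id=c.replicate_id)
        rows.append({**base, "allele": WT_LABEL, "reads": c.n_wt})
        for m in sorted(c.n_sub):
            rows.append({**base, "allele": m, "reads": c.n_sub[m]})
        rows.append({**base, "allele": INTEGRANT_LABEL, "reads": c.n_integrant})
        rows.append({**base, "allele": OTHER_LABEL, "reads": c.n_other})
    pd.DataFrame(rows, columns=_COUNTS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> list[SampleCounts]:
    """Read a long-format counts TSV back into per-replicate SampleCounts."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: counts table is empty")
    out = []
    for (sample_id, replicate_id), grp in df.groupby(["sample_id", "replicate_id"], sort=True):
        alleles = dict(zip(grp["allele"], grp["reads"]))
        n_sub = {a: int(v) for a, v in alleles.items() if a not in (WT_LABEL, INTEGRANT_LABEL, OTHER_LABEL)}
        out.append(
            SampleCounts(
                sample_id=str(sample_id),
                donor_age=float(grp["donor_age"].iloc[0]),
                tissue=str(grp["tissue"].iloc[0]),
                replicate_id=str(replicate_id),
                n_wt=int(alleles.get(WT_LABEL, 0)),
                n_sub=n_sub,
                n_integrant=int(alleles.get(INTEGRANT_LABEL, 0)),
                n_other=int(alleles.get(OTHER_LABEL, 0)),
            )
        )
    return out
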