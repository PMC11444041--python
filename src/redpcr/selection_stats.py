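"""Cross-sample inference: selection vs artifact vs background.

A substitution under positive germline selection shows a characteristic
signature: detectable levels in a substantial fraction of sperm samples,
absence from blood, and levels that rise with donor age.  A strand-symmetric
technical artifact (oxidative G>T/C>A damage) instead appears in both
tissues, ignores age, and - because damage hits both strands of the
palindromic site - produces correlated levels across a reciprocal
substitution pair.  These qualitative contrasts are formalised here as an
explicit, configurable decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import MutationLevelEstimate
from .site_model import (
    SiteModel,
    reciprocal_partner,
    substitution_from_cdna_change,
)

CLASS_SELECTED = "selected"
CLASS_ARTIFACT = "artifact"
CLASS_BACKGROUND = "background"
CLASS_INSUFFICIENT = "insufficient_data"

DEFAULT_LOD = 1e-6


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with its two-sided p-value.

    ``undefined`` marks degenerate inputs (a constant vector has no rank
    ordering, so the correlation does not exist).
    """

    rs: float
    p_value: float
    n: int
    undefined: bool = False

    def significant(self, alpha: float = 0.05) -> bool:
        return (not self.undefined) and self.p_value < alpha


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties; p-value from
    the large-sample t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), len(x), undefined=True)
    res = stats.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x))


def above_background(estimate: MutationLevelEstimate | float, lod: float = DEFAULT_LOD) -> bool:
    """True iff the point estimate strictly exceeds the limit of detection."""
    level = estimate.level if isinstance(estimate, MutationLevelEstimate) else float(estimate)
    return level > lod


def above_background_ci(estimate: MutationLevelEstimate, lod: float = DEFAULT_LOD) -> bool:
    """Conservative variant: the whole confidence interval sits above the LOD."""
    return estimate.lwr > lod


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision-rule configuration (formalisation, not a measured quantity)."""

    lod: float = DEFAULT_LOD
    alpha: float = 0.05
    artifact_min_rs: float = 0.3
    selected_min_frac_sperm: float = 0.2
    min_sperm_samples: int = 10
    bh_correct: bool = False  # Benjamini-Hochberg across the 18 age tests


@dataclass
class SubstitutionPanel:
    """Per-substitution cross-sample summary used for classification."""

    substitution: str
    sperm_levels: np.ndarray
    sperm_ages: np.ndarray
    blood_levels: np.ndarray
    reciprocal_substitution: str
    spearman_age: CorrelationResult
    reciprocal: CorrelationResult
    frac_sperm_above_bg: float
    frac_blood_above_bg: float
    classification: str | None = None


def reciprocal_correlation(levels_a, levels_b) -> CorrelationResult:
    """Spearman correlation of a reciprocal pair's levels across matched
    samples (strongly positive for a strand-symmetric artifact)."""
    return spearman(levels_a, levels_b)


def classify_substitution(
    panel: SubstitutionPanel,
    thresholds: ClassifierThresholds | None = None,
    age_p_value: float | None = None,
) -> str:
    """Apply the decision rules in order artifact -> selected -> background.

    artifact: present above background in both tissues and significantly
    correlated with its reciprocal partner; selected: present in >= 20% of
    sperm, absent from blood, and positively age-correlated; otherwise
    background.  ``age_p_value`` may substitute a multiplicity-adjusted
    p-value for the raw age-correlation test.
    """
    t = thresholds or ClassifierThresholds()
    if len(panel.sperm_levels) < t.min_sperm_samples:
        return CLASS_INSUFFICIENT
    if (
        panel.frac_sperm_above_bg > 0
        and panel.frac_blood_above_bg > 0
        and panel.reciprocal.significant(t.alpha)
        and panel.reciprocal.rs > t.artifact_min_rs
    ):
        return CLASS_ARTIFACT
    p_age = age_p_value if age_p_value is not None else panel.spearman_age.p_value
    if (
        panel.frac_sperm_above_bg >= t.selected_min_frac_sperm
        and panel.frac_blood_above_bg == 0
        and not panel.spearman_age.undefined
        and panel.spearman_age.rs > 0
        and p_age < t.alpha
    ):
        return CLASS_SELECTED
    return CLASS_BACKGROUND


def build_panels(
    estimates: pd.DataFrame,
    model: SiteModel | None = None,
    thresholds: ClassifierThresholds | None = None,
) -> list[SubstitutionPanel]:
    """Build and classify per-substitution panels from a long-format
    estimates table (one row per QC-passing sample x substitution).

    Required columns: sample_id, donor_age, tissue, cdna_change, level,
    qc_pass.  Sample order does not affect the result.
    """
    model = model or SiteModel()
    t = thresholds or ClassifierThresholds()
    df = estimates[estimates["qc_pass"]].copy()
    df = df.sort_values(["cdna_change", "sample_id"], kind="stable")
    sperm = df[df["tissue"] == "sperm"]
    blood = df[df["tissue"] == "blood"]
    sperm_wide = sperm.pivot(index="sample_id", columns="cdna_change", values="level")
    ages = sperm.drop_duplicates("sample_id").set_index("sample_id")["donor_age"]
    ages = ages.loc[sperm_wide.index]
    panels = []
    for sub_label in sorted(df["cdna_change"].unique()):
        sub = substitution_from_cdna_change(model, sub_label)
        partner = reciprocal_partner(model, sub).cdna_change
        sperm_levels = sperm_wide[sub_label].to_numpy()
        blood_levels = blood[blood["cdna_change"] == sub_label]["level"].to_numpy()
        if len(sperm_levels) >= 3:
            age_corr = spearman(ages.to_numpy(), sperm_levels)
        else:
            age_corr = CorrelationResult(float("nan"), float("nan"), len(sperm_levels), undefined=True)
        if partner in sperm_wide.columns and len(sperm_levels) >= 3:
            recip = reciprocal_correlation(sperm_levels, sperm_wide[partner].to_numpy())
        else:
            recip = CorrelationResult(float("nan"), float("nan"), 0, undefined=True)
        panels.append(
            SubstitutionPanel(
                substitution=sub_label,
                sperm_levels=sperm_levels,
                sperm_ages=ages.to_numpy(),
                blood_levels=blood_levels,
                reciprocal_substitution=partner,
                spearman_age=age_corr,
                reciprocal=recip,
                frac_sperm_above_bg=float(np.mean(sperm_levels > t.lod)) if len(sperm_levels) else 0.0,
                frac_blood_above_bg=float(np.mean(blood_levels > t.lod)) if len(blood_levels) else 0.0,
            )
        )
    age_p = {p.substitution: p.spearman_age.p_value for p in panels}
    if t.bh_correct:
        labels = [p.substitution for p in panels if not p.spearman_age.undefined]
        raw = [age_p[m] for m in labels]
        if raw:
            adj = stats.false_discovery_control(raw, method="bh")
            age_p.update(dict(zip(labels, adj)))
    for p in panels:
        p.classification = classify_substitution(p, t, age_p_value=age_p[p.substitution])
    return panels


def panels_table(panels: list[SubstitutionPanel], model: SiteModel | None = None) -> pd.DataFrame:
    """Panel summary TSV: correlations, prevalences and classification."""
    from .site_model import annotate_consequence

    model = model or SiteModel()
    rows = []
    for p in panels:
        sub = substitution_from_cdna_change(model, p.substitution)
        cons = annotate_consequence(model, sub)
        rows.append(
            {
                "cdna_change": p.substitution,
                "hgvs_p": cons.hgvs_p,
                "n_sperm": len(p.sperm_levels),
                "n_blood": len(p.blood_levels),
                "frac_sperm_above_bg": p.frac_sperm_above_bg,
                "frac_blood_above_bg": p.frac_blood_above_bg,
                "spearman_age_rs": p.spearman_age.rs,
                "spearman_age_p": p.spearman_age.p_value,
                "reciprocal_partner": p.reciprocal_substitution,
                "reciprocal_rs": p.reciprocal.rs,
                "reciprocal_p": p.reciprocal.p_value,
                "classification": p.classification,
            }
        )
    return pd.DataFrame(rows)


def plot_table(estimates: pd.DataFrame, lod: float = DEFAULT_LOD) -> pd.DataFrame:
    """Plot-ready long table: level per million vs donor age on a log10
    scale, with sub-LOD levels floored at LOD/10 for display."""
    df = estimates.copy()
    df["level_per_million"] = df["level"] * 1e6
    floored = np.maximum(df["level"].to_numpy(), lod / 10.0)
    df["log10_level"] = np.log10(floored)
    df["above_lod"] = df["level"] > lod
    return df[
        ["sample_id", "donor_age", "tissue", "cdna_change", "level_per_million", "log10_level", "above_lod"]
    ]
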