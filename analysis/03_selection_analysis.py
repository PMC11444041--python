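"""Classify the 18 site substitutions: selected vs artifact vs background.

Builds per-substitution panels (sperm/blood detection prevalence, Spearman
age correlation, reciprocal-pair correlation) and applies the decision rules.
The expected picture mirrors the assay's biology: c.1498A>G (p.Ile500Val)
selected, the reciprocal c.1496G>T / c.1497C>A pair flagged as a
strand-symmetric damage artifact, everything else background.

Reads results/estimates.tsv; writes results/panel.tsv and
results/levels_by_age.tsv.
"""

from pathlib import Path

import pandas as pd

from redpcr import selection_stats
from redpcr.config import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    est_path = RESULTS / "estimates.tsv"
    if not est_path.exists():
        raise SystemExit("run analysis/02_quantify_levels.py first (results/estimates.tsv missing)")
    cfg = PipelineConfig()
    estimates = pd.read_csv(est_path, sep="\t")
    panels = selection_stats.build_panels(estimates, thresholds=cfg.thresholds)
    table = selection_stats.panels_table(panels)
    table.to_csv(RESULTS / "panel.tsv", sep="\t", index=False)
    selection_stats.plot_table(estimates, lod=cfg.thresholds.lod).to_csv(
        RESULTS / "levels_by_age.tsv", sep="\t", index=False
    )
    for _, row in table.iterrows():
        if row["classification"] != selection_stats.CLASS_BACKGROUND:
            print(
                f"{row['cdna_change']} ({row['hgvs_p']}): {row['classification']}; "
                f"sperm prevalence {row['frac_sperm_above_bg']:.0%}, "
                f"age R_S = {row['spearman_age_rs']:.3f} (p = {row['spearman_age_p']:.2g}), "
                f"reciprocal R_S = {row['reciprocal_rs']:.3f}"
            )
    n_bg = (table["classification"] == selection_stats.CLASS_BACKGROUND).sum()
    print(f"{n_bg} substitutions classified background")
    print(f"wrote {RESULTS / 'panel.tsv'}, {RESULTS / 'levels_by_age.tsv'}")


if __name__ == "__main__":
    main()
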