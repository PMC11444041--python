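"""Titration-reconstruction validation of the absolute quantification.

Simulates the two-replicate dilution series (0, 1e-6, 3e-6, 1e-5, 3e-5,
1e-4) of the equimolar c.1498A>G + c.1499T>C gDNA mix against the 3e-5
integrant spike, runs each replicate through estimation, and reports the
Spearman correlation of estimated vs input levels over the nonzero points.

Writes results/titration.tsv.
"""

from pathlib import Path

from redpcr import assay_sim
from redpcr.config import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = PipelineConfig().with_seed(SEED)
    design = assay_sim.TitrationDesign()
    samples = assay_sim.simulate_titration(design, cfg.simulation)
    df, correlations = assay_sim.titration_report(samples, cfg.simulation, design)
    df.to_csv(RESULTS / "titration.tsv", sep="\t", index=False)
    print("estimated vs input levels (means of 2 replicates):")
    means = df.groupby(["cdna_change", "dilution"], as_index=False)["level"].mean()
    for _, row in means.iterrows():
        print(f"  {row['cdna_change']} input {row['dilution']:.0e} -> estimate {row['level']:.2e}")
    for variant, rs in correlations.items():
        print(f"{variant}: Spearman(estimate, input) = {rs:.3f} over nonzero dilutions")
    print(f"wrote {RESULTS / 'titration.tsv'}")


if __name__ == "__main__":
    main()
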