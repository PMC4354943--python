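"""Stage 1 — factor screening with a Plackett-Burman design.

Builds the 12-run PB design (+3 center points) over the five instrument
factors, simulates the four assay responses with the synthetic
chromatogram generator, fits main-effects models, and ranks the
standardized effects against the 5% critical t.  Writes the design,
responses and Pareto table to results/screening/.
"""

from pathlib import Path

import pandas as pd

from chromdoe import chromsim, designs, pipeline, rsm

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "screening"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    specs = pipeline.DEFAULT_FACTOR_SPECS
    names = [s.name for s in specs]

    design = designs.generate_pb(len(specs), 12, 3, factor_names=names)
    actual = designs.coded_to_actual(design, specs)
    responses = chromsim.simulate_responses(actual, names, seed=SEED)

    design.to_csv(OUT / "pb_design_coded.csv")
    pd.DataFrame(actual, columns=names).to_csv(OUT / "pb_design_actual.csv", index=False)
    responses.to_csv(OUT / "pb_responses.csv", index=False)

    rows = []
    for resp in ("Y1", "Y2", "Y3", "Y4"):
        model = rsm.fit_model(design, responses[resp].to_numpy(), rsm.MAIN_EFFECTS)
        tcrit = rsm.t_critical(0.05, model.residual_df)
        for term, abs_t, sig, sign in rsm.pareto_effects(model):
            rows.append(
                {"response": resp, "factor": term, "abs_t": abs_t,
                 "sign": sign, "t_critical": tcrit, "significant": sig}
            )
    pareto = pd.DataFrame(rows)
    pareto.to_csv(OUT / "pareto_effects.csv", index=False)

    sig = pareto[pareto.significant]
    print("Significant screening effects (|t| > t_crit at alpha = 0.05):")
    for _, r in sig.iterrows():
        direction = "+" if r.sign > 0 else "-"
        print(f"  {r.response}: {r.factor} ({direction}), |t| = {r.abs_t:.1f}")
    carried = sorted(sig.factor.unique())
    print(f"\nFactors carried into the response-surface stage: {carried}")
    print(f"Tables written to {OUT}")


if __name__ == "__main__":
    main()
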