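"""Stage 2 — response-surface optimization with a Box-Behnken design.

Runs the pipeline through the Box-Behnken stage: full quadratic models
for the four responses on the three carried factors, the desirability
optimum over the coded cube, and a checkpoint analysis comparing model
predictions with fresh simulated observations at the optimum and at two
off-optimum settings.  Writes models, the optimum and the checkpoint
table to results/optimization/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from chromdoe import chromsim, designs, desirability, pipeline

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "optimization"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = pipeline.PipelineConfig(seed=SEED, dr_runs=2000, lhs_points=25,
                                  runs_per_point=400)
    result = pipeline.run_pipeline(cfg)

    result.bb_design.to_csv(OUT / "bb_design_coded.csv")
    result.bb_responses.to_csv(OUT / "bb_responses.csv", index=False)
    (OUT / "bb_models.json").write_text(
        json.dumps({r: m.to_dict() for r, m in result.bb_models.items()}, indent=2)
    )

    carry = result.carryover
    print(f"Carried factors: {carry}")
    print("Desirability optimum (actual units):")
    for name, value in zip(carry, result.optimum_actual):
        print(f"  {name} = {value:.2f}")
    print(f"Overall desirability d = {result.optimum_desirability:.3f}")

    # Checkpoint analysis: model prediction vs fresh simulated observation.
    bb_specs = [s for s in pipeline.DEFAULT_FACTOR_SPECS if s.name in carry]
    names = [s.name for s in pipeline.DEFAULT_FACTOR_SPECS]
    checkpoints = [result.optimum_coded,
                   np.array([-0.5, 0.6, 0.0]), np.array([0.5, -0.4, 0.5])]
    rows = []
    for i, coded in enumerate(checkpoints):
        d = designs.DesignMatrix("custom", coded.reshape(1, -1), carry)
        actual3 = designs.coded_to_actual(d, bb_specs)[0]
        full = {s.name: cfg.preferred_levels.get(s.name, s.mid)
                for s in pipeline.DEFAULT_FACTOR_SPECS}
        full.update(dict(zip(carry, actual3)))
        observed = chromsim.simulate_responses(
            np.array([[full[n] for n in names]]), names, seed=SEED + 100 + i,
        ).iloc[0]
        for resp, model in result.bb_models.items():
            pred = float(model.predict(coded))
            rows.append(
                {"checkpoint": i, "response": resp, "predicted": pred,
                 "observed": float(observed[resp]),
                 "pct_error": desirability.checkpoint_error(pred, float(observed[resp]))}
            )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "checkpoint_analysis.csv", index=False)
    worst = table.pct_error.max()
    print(f"\nCheckpoint analysis: worst |prediction error| = {worst:.1f}%"
          f" over {len(checkpoints)} settings x 4 responses")
    print(f"Tables written to {OUT}")


if __name__ == "__main__":
    main()
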