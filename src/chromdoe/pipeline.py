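"""End-to-end assay-development pipeline.

Runs the whole workflow from one seeded configuration: synthesize
screening responses on a Plackett-Burman design, carry the significant
factors into a Box-Behnken design, fit full quadratic response-surface
models, find the desirability optimum, estimate its Monte Carlo defect
rate, then minimize the defect rate with the Latin-hypercube + Gaussian
process simulation experiment and round the winning setpoint to
practical instrument increments.  All intermediate tables are written to
the output directory as CSV/JSON so a run is fully inspectable and
reproducible from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromsim, defectsim, desirability, designs, rsm, surrogate
from .errors import ConfigurationError

RESPONSES = ("Y1", "Y2", "Y3", "Y4")

#: Screening factors of the fixture assay, coded -1/0/+1 anchors in actual
#: units, with the run-to-run SDs assumed by the defect simulator (the
#: robustness perturbations +-0.1 mL/min flow, +-2 nm, +-2 % v/v read as
#: +-3 sigma; injection volume at typical autosampler repeatability).
DEFAULT_FACTOR_SPECS = [
    designs.FactorSpec("flow", "mL/min", 0.6, 0.8, 1.0, sim_sd=0.1 / 3),
    designs.FactorSpec("volume", "uL", 10.0, 15.0, 20.0, sim_sd=0.5),
    designs.FactorSpec("wavelength", "nm", 265.0, 270.0, 275.0, sim_sd=2.0 / 3),
    designs.FactorSpec("organic_init", "% v/v", 60.0, 70.0, 80.0, sim_sd=2.0 / 3),
    designs.FactorSpec("organic_late", "% v/v", 85.0, 90.0, 95.0, sim_sd=2.0 / 3),
]

#: Levels at which non-carried factors are clamped after screening.
DEFAULT_PREFERRED_LEVELS = {"wavelength": 270.0, "organic_late": 95.0}

#: Fixture spec limits: lower limits on the two peak areas (AU*min) chosen
#: for the synthetic generator's response scale, upper limit 1.5 on both
#: tailing factors.
DEFAULT_SPEC_LIMITS = {
    "Y1": (0.12, None),
    "Y2": (0.15, None),
    "Y3": (None, 1.5),
    "Y4": (None, 1.5),
}

#: Practical rounding increments of the instrument settings.
DEFAULT_INCREMENTS = {"flow": 0.1, "volume": 1.0, "wavelength": 1.0,
                      "organic_init": 1.0, "organic_late": 1.0}


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, seedable and serializable."""

    factor_specs: list = field(default_factory=lambda: list(DEFAULT_FACTOR_SPECS))
    preferred_levels: dict = field(default_factory=lambda: dict(DEFAULT_PREFERRED_LEVELS))
    spec_limits: dict = field(default_factory=lambda: dict(DEFAULT_SPEC_LIMITS))
    increments: dict = field(default_factory=lambda: dict(DEFAULT_INCREMENTS))
    pb_base_runs: int = 12
    pb_center: int = 3
    bb_center: int = 3
    n_carryover: int = 3
    alpha: float = 0.05
    # Desirability ramps for tailing target the pharmacopeial acceptance
    # criterion (T < 2); the defect simulation applies the stricter 1.5
    # specification limit, so the desirability optimum can still carry a
    # nonzero defect rate for the surrogate stage to minimize.
    tailing_anchor_low: float = 1.0
    tailing_anchor_high: float = 2.0
    dr_runs: int = 15000
    lhs_points: int = 80
    runs_per_point: int = 2000
    noise_sd: float = chromsim.DEFAULT_NOISE_SD
    injection_cv: float = chromsim.DEFAULT_INJECTION_CV
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "factor_specs" in raw:
            raw["factor_specs"] = [designs.FactorSpec(**d) for d in raw["factor_specs"]]
        if "spec_limits" in raw:
            raw["spec_limits"] = {
                k: (v[0], v[1]) for k, v in raw["spec_limits"].items()
            }
        return cls(**raw)


def round_to_practical(setpoint, increments) -> np.ndarray:
    """Round each coordinate half-away-from-zero to its practical increment."""
    x = np.asarray(setpoint, dtype=float)
    inc = np.asarray(increments, dtype=float)
    if np.any(inc <= 0):
        raise ConfigurationError("increments must be positive")
    # tiny epsilon so exact halves (e.g. 0.65 / 0.1) survive binary rounding
    return np.sign(x) * np.floor(np.abs(x) / inc + 0.5 + 1e-9) * inc


def _fit_responses(design: designs.DesignMatrix, responses: pd.DataFrame, form: str):
    return {name: rsm.fit_model(design, responses[name].to_numpy(), form)
            for name in RESPONSES}


def _area_anchors(model: rsm.FittedModel, resolution: int = 9):
    """Desirability anchors for a maximize goal: predicted min/max over the cube."""
    axes = [np.linspace(-1, 1, resolution)] * model.n_factors
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, model.n_factors)
    preds = model.predict(grid)
    lo, hi = float(preds.min()), float(preds.max())
    if hi <= lo:  # flat response; widen trivially so the ramp is well formed
        lo, hi = lo - 1.0, hi + 1.0
    return lo, hi


@dataclass
class PipelineResult:
    """Report bundle of one pipeline run (also written to ``outdir``)."""

    screening_design: designs.DesignMatrix
    screening_responses: pd.DataFrame
    screening_models: dict
    screening_pareto: dict
    carryover: list[str]
    bb_design: designs.DesignMatrix
    bb_responses: pd.DataFrame
    bb_models: dict
    optimum_coded: np.ndarray
    optimum_actual: np.ndarray
    optimum_desirability: float
    predicted_at_optimum: dict
    dr_initial: defectsim.DefectReport
    sim_experiment: surrogate.SimExperiment
    dr_final: defectsim.DefectReport
    final_setpoint: np.ndarray
    final_setpoint_practical: np.ndarray

    def summary(self) -> dict:
        return {
            "carryover_factors": self.carryover,
            "desirability_optimum_actual": self.optimum_actual.tolist(),
            "overall_desirability": self.optimum_desirability,
            "dr_initial": self.dr_initial.overall_dr,
            "dpm_initial": self.dr_initial.dpm,
            "dr_initial_per_response": self.dr_initial.per_response_dr,
            "surrogate_jackknife_r2": self.sim_experiment.jackknife_r2,
            "surrogate_predicted_min_dr": self.sim_experiment.predicted_min_dr,
            "final_setpoint_actual": self.final_setpoint.tolist(),
            "final_setpoint_practical": self.final_setpoint_practical.tolist(),
            "dr_final": self.dr_final.overall_dr,
            "dpm_final": self.dr_final.dpm,
        }


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute screening -> optimization -> defect-rate minimization."""
    specs = config.factor_specs
    names = [s.name for s in specs]
    seed = config.seed

    # --- Stage 1: Plackett-Burman screening on all factors -----------------
    pb = designs.generate_pb(len(specs), config.pb_base_runs, config.pb_center,
                             factor_names=names)
    pb_actual = designs.coded_to_actual(pb, specs)
    pb_resp = chromsim.simulate_responses(
        pb_actual, names, noise_sd=config.noise_sd,
        injection_cv=config.injection_cv, seed=seed,
    )
    screen_models = _fit_responses(pb, pb_resp, rsm.MAIN_EFFECTS)
    pareto = {r: rsm.pareto_effects(m, config.alpha) for r, m in screen_models.items()}

    # Carryover: factors significant for any response advance; top up (or trim)
    # by the largest |t| across responses to the Box-Behnken factor count.
    max_abs_t = {n: 0.0 for n in names}
    significant = set()
    for rows in pareto.values():
        for term, abs_t, sig, _ in rows:
            max_abs_t[term] = max(max_abs_t[term], abs_t)
            if sig:
                significant.add(term)
    ranked = sorted(names, key=lambda n: -max_abs_t[n])
    carryover = [n for n in ranked if n in significant][: config.n_carryover]
    for n in ranked:
        if len(carryover) >= config.n_carryover:
            break
        if n not in carryover:
            carryover.append(n)
    carryover = [n for n in names if n in carryover]  # canonical order

    fixed_levels = {}
    for s in specs:
        if s.name not in carryover:
            fixed_levels[s.name] = config.preferred_levels.get(s.name, s.mid)

    # --- Stage 2: Box-Behnken response surface on the carried factors ------
    bb_specs = [s for s in specs if s.name in carryover]
    bb = designs.generate_bb(len(bb_specs), config.bb_center,
                             factor_names=[s.name for s in bb_specs])
    bb_actual = designs.coded_to_actual(bb, bb_specs)
    full_actual = np.column_stack(
        [bb_actual[:, carryover.index(n)] if n in carryover
         else np.full(bb.n_runs, fixed_levels[n]) for n in names]
    )
    bb_resp = chromsim.simulate_responses(
        full_actual, names, noise_sd=config.noise_sd,
        injection_cv=config.injection_cv, seed=seed + 1,
    )
    bb_models = _fit_responses(bb, bb_resp, rsm.FULL_QUADRATIC)

    # --- Stage 3: desirability optimum --------------------------------------
    goals = []
    for area_resp in ("Y1", "Y2"):
        lo, hi = _area_anchors(bb_models[area_resp])
        goals.append(desirability.ResponseGoal(area_resp, desirability.MAXIMIZE,
                                               lower=lo, upper=hi))
    for tail_resp in ("Y3", "Y4"):
        goals.append(desirability.ResponseGoal(
            tail_resp, desirability.MINIMIZE,
            lower=config.tailing_anchor_low, upper=config.tailing_anchor_high,
        ))
    opt_coded, preds, d_opt, degenerate = desirability.optimize_profile(
        bb_models, goals, seed=seed,
    )
    if degenerate:
        raise ConfigurationError(
            "desirability optimum is degenerate (0 everywhere); check the goals"
        )
    opt_design = designs.DesignMatrix("custom", opt_coded.reshape(1, -1),
                                      [s.name for s in bb_specs])
    opt_actual = designs.coded_to_actual(opt_design, bb_specs)[0]

    # --- Stage 4: Monte Carlo defect rate at the desirability optimum ------
    dspec = defectsim.DefectSpec(
        factor_specs=bb_specs,
        setpoint=opt_actual,
        spec_limits=config.spec_limits,
        n_runs=config.dr_runs,
        seed=seed + 2,
    )
    dr_initial = defectsim.simulate_defect_rate(bb_models, dspec)

    # --- Stage 5: LHS + GP surrogate minimization of the defect rate -------
    sim = surrogate.run_simulation_experiment(
        bb_models, dspec, n_points=config.lhs_points,
        runs_per_point=config.runs_per_point, seed=seed + 3,
    )
    final_spec = dspec.with_setpoint(sim.optimum_actual)
    final_spec.seed = seed + 4
    dr_final = defectsim.simulate_defect_rate(bb_models, final_spec)
    inc = np.array([config.increments.get(s.name, 1.0) for s in bb_specs])
    practical = round_to_practical(sim.optimum_actual, inc)

    result = PipelineResult(
        screening_design=pb,
        screening_responses=pb_resp,
        screening_models=screen_models,
        screening_pareto=pareto,
        carryover=carryover,
        bb_design=bb,
        bb_responses=bb_resp,
        bb_models=bb_models,
        optimum_coded=opt_coded,
        optimum_actual=opt_actual,
        optimum_desirability=d_opt,
        predicted_at_optimum=preds,
        dr_initial=dr_initial,
        sim_experiment=sim,
        dr_final=dr_final,
        final_setpoint=sim.optimum_actual,
        final_setpoint_practical=practical,
    )
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.screening_design.to_csv(outdir / "pb_design_coded.csv")
    result.screening_responses.to_csv(outdir / "pb_responses.csv", index=False)
    result.bb_design.to_csv(outdir / "bb_design_coded.csv")
    result.bb_responses.to_csv(outdir / "bb_responses.csv", index=False)
    models = {r: m.to_dict() for r, m in result.bb_models.items()}
    (outdir / "bb_models.json").write_text(json.dumps(models, indent=2))
    pareto = {
        r: [{"term": t, "abs_t": a, "significant": s, "sign": g} for t, a, s, g in rows]
        for r, rows in result.screening_pareto.items()
    }
    (outdir / "screening_pareto.json").write_text(json.dumps(pareto, indent=2))
    exp = result.sim_experiment
    pd.DataFrame(
        {
            **{f"x_{i}": exp.actual_points[:, i] for i in range(exp.actual_points.shape[1])},
            "dr": exp.dr,
            "log10_dr": exp.log10_dr,
            "jackknife_pred": exp.jackknife,
        }
    ).to_csv(outdir / "simulation_experiment.csv", index=False)
    (outdir / "summary.json").write_text(json.dumps(result.summary(), indent=2))
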