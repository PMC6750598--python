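"""End-to-end orchestration: cohort -> trials -> cost tables and figures.

A run generates (or loads) gait and pulmonary data for every subject and
(speed, incline) condition, performs inverse dynamics and muscle-state
estimation once per trial, evaluates every requested metabolic energy
model on the solved states, computes the measured cost by indirect
calorimetry, and compares the two with per-condition RMS errors and the
repeated-measures correlation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from gaitmet import calorimetry, energy, stats
from gaitmet.energy import ALL_MODELS
from gaitmet.estimation import SolverFailure, build_problem, solve
from gaitmet.inverse_dynamics import process_trial
from gaitmet.muscle import MuscleParams, SPECIFIC_TENSION, default_muscles
from gaitmet.synthetic import (
    INCLINES,
    SPEEDS,
    NoiseConfig,
    SubjectMeta,
    generate_cohort,
    generate_gait_trial,
    generate_pulmonary,
)

log = logging.getLogger("gaitmet")

FMAX_MODES = ("nominal", "plus10", "minus10", "mass_personalized", "double_stress")


def reference_cost(speed: float, incline: float) -> float:
    """Nominal measured cost of walking (J/kg/m) used by the generator.

    Linear in grade with a mild slow-speed penalty; level walking near
    3.2 J/kg/m, about 2 J/kg/m at -8% and 5.2-5.9 J/kg/m at +8%.
    """
    return 3.2 + 24.0 * incline + 0.5 * (1.3 - speed)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    n_subjects: int = 12
    speeds: Sequence[float] = SPEEDS
    inclines: Sequence[float] = INCLINES
    models: Sequence[str] = ALL_MODELS
    negative_work: str = "subtract"            # or "clamp_zero"
    fmax_scaling: str = "nominal"
    calorimetry_equation: str = "weir"
    objective: str = "activation_squared"
    updated_lengthening: bool = True
    seed: int = 1
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    solver_tol: float = 0.3
    out_dir: str | Path | None = None
    cost_model: Callable[[float, float], float] | None = None
    missing_trial: tuple | None = None          # (subject_id, speed, incline)

    def __post_init__(self):
        if not self.models:
            raise ValueError("at least one model is required")
        if any(s <= 0 for s in self.speeds):
            raise ValueError("speeds must be positive")
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown models {unknown}")
        if self.fmax_scaling not in FMAX_MODES:
            raise ValueError(f"unknown fmax scaling {self.fmax_scaling!r}")

    def config_hash(self) -> str:
        payload = {k: repr(v) for k, v in dataclasses.asdict(self).items()
                   if k not in ("out_dir", "cost_model")}
        return hashlib.sha256(json.dumps(payload, sort_keys=True)
                              .encode()).hexdigest()[:12]


def scaled_muscles(config: RunConfig, subject: SubjectMeta,
                   cohort_mean_mass: float) -> tuple[list[MuscleParams], float]:
    """Apply the configured maximum-isometric-force scaling mode.

    Returns the muscle set and the specific tension to use for muscle
    mass (doubling the muscle stress halves the mass).
    """
    muscles = default_muscles()
    sigma = SPECIFIC_TENSION
    mode = config.fmax_scaling
    if mode == "nominal":
        factor = 1.0
    elif mode == "plus10":
        factor = 1.1
    elif mode == "minus10":
        factor = 0.9
    elif mode == "mass_personalized":
        factor = subject.mass / cohort_mean_mass
    else:  # double_stress
        factor = 1.0
        sigma = 2.0 * SPECIFIC_TENSION
    if factor != 1.0:
        muscles = [replace(m, F_max=m.F_max * factor,
                           k_SEE=m.k_SEE * factor, k_PEE=m.k_PEE * factor)
                   for m in muscles]
    return muscles, sigma


def calculated_cost(trial, muscles, sigma, config: RunConfig):
    """Inverse dynamics + state estimation + all models for one trial.

    Returns (dict model -> EnergyResult, solver diagnostics).  Rates are
    doubled to account for both legs of the symmetric gait.
    """
    cycle = process_trial(trial)
    problem = build_problem(cycle, muscles, objective=config.objective)
    traj = solve(problem, tol=config.solver_tol, max_sweeps=3,
                 tc_maxiter=640, polish_nfev=80)
    m = trial.subject.mass
    v = trial.speed
    results = {}
    for model in config.models:
        rates = 2.0 * energy.trajectory_rates(
            model, traj, cycle=cycle, specific_tension=sigma,
            updated_lengthening=config.updated_lengthening)
        c_calc = energy.metabolic_cost(rates, cycle.duration, m, v,
                                       config.negative_work)
        if model == "KIMR15":
            from gaitmet.inverse_dynamics import JOINTS

            per_joint = {j: energy.metabolic_cost(
                rates[:, [k]], cycle.duration, m, v, config.negative_work)
                for k, j in enumerate(JOINTS)}
        else:
            per_joint = energy.joint_breakdown(rates, muscles, cycle.duration,
                                               m, v, config.negative_work)
        results[model] = energy.EnergyResult(
            model=model, C_calc=c_calc, per_joint=per_joint,
            options={"negative_work": config.negative_work,
                     "fmax_scaling": config.fmax_scaling})
    return results, {"max_violation": traj.max_violation,
                     "objective_value": traj.objective_value}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full study emulation; returns the result bundle.

    The bundle holds per-trial calculated costs for every model, the
    measured costs, Table-style RMS-error and correlation frames, and a
    manifest with the config hash, seeds and solver diagnostics.  When
    ``config.out_dir`` is set everything is also written to CSV/JSON.
    """
    t_start = time.time()
    rng_base = int(config.seed)
    cohort = generate_cohort(config.n_subjects, rng_base)
    mean_mass = float(np.mean([s.mass for s in cohort])) if cohort else 70.0
    cost_model = config.cost_model or reference_cost

    rows = []
    diagnostics = []
    for si, subject in enumerate(cohort):
        muscles, sigma = scaled_muscles(config, subject, mean_mass)
        resting = generate_pulmonary(
            subject, "resting", 0.0, 0.0, None,
            seed=rng_base + 7919 * (si + 1), noise=config.noise)
        for ci, (speed, incline) in enumerate(
                (s, i) for s in config.speeds for i in config.inclines):
            trial_seed = rng_base + 104729 * (si + 1) + 1299709 * (ci + 1)
            trial_seed %= 2**31
            t0 = time.time()
            trial = generate_gait_trial(subject, speed, incline,
                                        seed=trial_seed, noise=config.noise)
            try:
                per_model, diag = calculated_cost(trial, muscles, sigma, config)
            except SolverFailure as exc:
                log.error("solver failure for %s at (%s, %s): %s",
                          subject.id, speed, incline, exc)
                raise
            walking = generate_pulmonary(
                subject, "walking", speed, incline, cost_model,
                seed=(trial_seed + 15485863) % 2**31, noise=config.noise)
            if config.missing_trial == (subject.id, speed, incline):
                walking.missing = True
            meas = calorimetry.measured_cost(
                walking, resting, speed, config.calorimetry_equation)
            for model, result in per_model.items():
                rows.append({
                    "subject": subject.id, "speed": speed, "incline": incline,
                    "model": model, "C_calc": result.C_calc,
                    "C_meas": np.nan if meas is None else meas.C_meas,
                    **{f"C_{j}": cj for j, cj in result.per_joint.items()},
                })
            diagnostics.append({"subject": subject.id, "speed": speed,
                                "incline": incline,
                                "seconds": round(time.time() - t0, 2), **diag})
            log.info("trial %s (%.1f m/s, %+.0f%%) done in %.1fs",
                     subject.id, speed, 100 * incline, time.time() - t0)

    trial_table = pd.DataFrame(rows)
    rms_tables = {}
    rmcorr_table = []
    for model in config.models:
        sub = trial_table[trial_table["model"] == model]
        rms_tables[model] = stats.rms_error(
            sub["C_calc"], sub["C_meas"],
            list(zip(sub["speed"], sub["incline"])))
        ok = sub.dropna(subset=["C_meas"])
        try:
            res = stats.rmcorr(ok["C_meas"], ok["C_calc"], ok["subject"])
            row = {"model": model, "r_rm": res.r_rm, "ci_low": res.ci95[0],
                   "ci_high": res.ci95[1], "slope": res.slope, "df": res.df}
        except ValueError:   # too few subjects/points for the ANCOVA
            row = {"model": model, "r_rm": np.nan, "ci_low": np.nan,
                   "ci_high": np.nan, "slope": np.nan, "df": 0}
        rmcorr_table.append(row)
    rmcorr_table = pd.DataFrame(rmcorr_table)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "models": list(config.models),
        "negative_work": config.negative_work,
        "fmax_scaling": config.fmax_scaling,
        "calorimetry_equation": config.calorimetry_equation,
        "solver": diagnostics,
        "elapsed_s": round(time.time() - t_start, 1),
    }
    bundle = {"trials": trial_table, "rms": rms_tables,
              "rmcorr": rmcorr_table, "manifest": manifest}
    if config.out_dir is not None:
        _write_bundle(bundle, Path(config.out_dir), config)
    return bundle


def _write_bundle(bundle: dict, out: Path, config: RunConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    bundle["trials"].to_csv(out / "trial_costs.csv", index=False)
    for model, tab in bundle["rms"].items():
        tab.to_csv(out / f"rms_{model}.csv", index=False)
    bundle["rmcorr"].to_csv(out / "rmcorr.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=1))


# ----------------------------------------------------------------------
# report figures
# ----------------------------------------------------------------------


def plot_verification_grid(out_path, models=None):
    """Bar chart of the soleus verification grid for the muscle models."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from gaitmet.energy import GRID_CONDITIONS, MUSCLE_MODELS, verification_grid
    from gaitmet.muscle import default_muscles

    models = models or MUSCLE_MODELS
    soleus = next(m for m in default_muscles() if m.name == "soleus")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    tables = {m: verification_grid(m, soleus) for m in models}
    for ax, cond in zip(axes, GRID_CONDITIONS):
        for m in models:
            t = tables[m]
            sel = t[t.condition == cond]
            ax.plot(sel.activation, sel.E, marker="o", label=m)
        ax.set_title(cond)
        ax.set_xlabel("activation")
    axes[0].set_ylabel("metabolic rate (W)")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return tables


def plot_cost_breakdown(trials: pd.DataFrame, out_path):
    """Stacked per-joint cost bars per model and condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    models = sorted(trials["model"].unique())
    fig, axes = plt.subplots(1, len(models), figsize=(2.4 * len(models), 3.2),
                             sharey=True)
    if len(models) == 1:
        axes = [axes]
    for ax, model in zip(axes, models):
        sub = trials[trials["model"] == model]
        agg = sub.groupby(["incline", "speed"])[
            ["C_hip", "C_knee", "C_ankle"]].mean()
        bottoms = np.zeros(len(agg))
        xs = np.arange(len(agg))
        for joint in ("C_hip", "C_knee", "C_ankle"):
            ax.bar(xs, agg[joint], bottom=bottoms, label=joint[2:])
            bottoms += agg[joint].to_numpy()
        ax.set_xticks(xs)
        ax.set_xticklabels([f"{i:+.0%}\n{s}" for i, s in agg.index],
                           fontsize=6)
        ax.set_title(model, fontsize=9)
    axes[0].set_ylabel("cost (J/kg/m)")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_correlations(trials: pd.DataFrame, rmcorr_table: pd.DataFrame, out_path):
    """Measured-vs-calculated scatter with per-subject fitted lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from gaitmet.stats import rmcorr

    models = sorted(trials["model"].unique())
    ncol = min(4, len(models))
    nrow = int(np.ceil(len(models) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow),
                             squeeze=False)
    for ax, model in zip(axes.ravel(), models):
        sub = trials[trials["model"] == model].dropna(subset=["C_meas"])
        try:
            res = rmcorr(sub["C_meas"], sub["C_calc"], sub["subject"])
        except ValueError:
            res = None
        for sid, grp in sub.groupby("subject"):
            ax.scatter(grp["C_meas"], grp["C_calc"], s=8)
            if res is not None:
                xs = np.linspace(grp["C_meas"].min(), grp["C_meas"].max(), 2)
                ax.plot(xs, res.intercepts[sid] + res.slope * xs, lw=0.7)
        title = model if res is None else f"{model}  r_rm={res.r_rm:.2f}"
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("measured (J/kg/m)")
        ax.set_ylabel("calculated (J/kg/m)")
    for ax in axes.ravel()[len(models):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
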