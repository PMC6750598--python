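"""Synthetic cohorts, gait trials and pulmonary records.

The generator emulates the statistical structure of a treadmill walking
study: a cohort of subjects (mass 70 +/- 12 kg, height 1.73 +/- 0.08 m),
each walking at two speeds (0.8 and 1.3 m/s) and three inclines (-8%,
level, +8%), with periodic marker and ground-reaction-force waveforms
built from smooth Fourier templates, and breath-by-breath pulmonary
gas-exchange records whose implied measured cost equals a configurable
cost model plus a latent per-subject intercept.

All generators are deterministic given their seed.  Noise magnitudes are
held in :class:`NoiseConfig`; a zero-noise configuration makes the
pulmonary round trip through the calorimetry module exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

G = 9.80665

SPEEDS = (0.8, 1.3)
INCLINES = (-0.08, 0.0, 0.08)

MARKER_ROLES = ("shoulder", "hip", "knee", "ankle", "toe")
SIDES = ("right", "left")


def _load_templates() -> dict:
    ref = resources.files("gaitmet.data").joinpath("gait_templates.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)


_TEMPLATES = None


def templates() -> dict:
    global _TEMPLATES
    if _TEMPLATES is None:
        _TEMPLATES = _load_templates()
    return _TEMPLATES


@dataclass(frozen=True)
class NoiseConfig:
    """Magnitudes of the generator's stochastic components."""

    marker_sd: float = 0.002        # m, additive Gaussian on marker positions
    grf_sd: float = 5.0             # N, additive Gaussian on forces
    cycle_jitter: float = 0.02      # relative cycle-to-cycle amplitude jitter
    vo2_sigma: float = 0.04         # lognormal sigma on breath-wise V̇O2
    rq_sd: float = 0.01             # additive Gaussian on breath-wise R

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(marker_sd=0.0, grf_sd=0.0, cycle_jitter=0.0,
                   vo2_sigma=0.0, rq_sd=0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Population parameters of the simulated cohort."""

    mass_mean: float = 70.0         # kg
    mass_sd: float = 12.0
    height_mean: float = 1.73       # m
    height_sd: float = 0.08
    resting_rate_mean: float = 1.4  # W/kg standing rest
    resting_rate_sd: float = 0.15
    intercept_sd: float = 0.15      # J/kg/m, latent per-subject cost offset


@dataclass(frozen=True)
class SubjectMeta:
    id: str
    mass: float                     # kg
    height: float                   # m
    sex: str
    resting_rate_true: float        # W/kg, latent ground truth
    cost_intercept: float           # J/kg/m, latent per-subject offset

    def __post_init__(self):
        if self.mass <= 0 or self.height <= 0 or self.resting_rate_true <= 0:
            raise ValueError("mass, height and resting rate must be positive")

    @property
    def leg_segments(self) -> dict[str, float]:
        """Winter segment lengths (m) scaled from stature."""
        h = self.height
        return {"thigh": 0.245 * h, "shank": 0.246 * h, "foot": 0.152 * h,
                "trunk": 0.288 * h, "hip_height": 0.53 * h}


@dataclass
class GaitTrial:
    subject: SubjectMeta
    speed: float                    # m/s
    incline: float                  # signed grade, e.g. -0.08
    time: np.ndarray                # s, (n,)
    markers: dict                   # (side, role) -> (n, 2) positions, m
    grf: dict                       # side -> {"fy": (n,), "fx": (n,), "cop": (n,)}
    sample_rate: float
    duration: float
    cycle_period: float             # ground-truth cycle duration, s


@dataclass
class PulmonaryRecord:
    breath_times: np.ndarray        # s
    vo2: np.ndarray                 # mL/min/kg per breath
    rq: np.ndarray                  # respiratory quotient per breath
    trial_kind: str                 # "resting" | "walking"
    subject_id: str = ""
    speed: float = 0.0
    incline: float = 0.0
    missing: bool = False           # flagged-missing measurement

    def __post_init__(self):
        if self.trial_kind not in ("resting", "walking"):
            raise ValueError(f"unknown trial_kind {self.trial_kind!r}")


# ----------------------------------------------------------------------
# cohort
# ----------------------------------------------------------------------


def generate_cohort(n_subjects: int, seed: int,
                    config: CohortConfig = CohortConfig()) -> list[SubjectMeta]:
    """Draw a cohort of subjects from the configured population laws."""
    if n_subjects < 0:
        raise ValueError("n_subjects must be nonnegative")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        mass = 0.0
        while mass <= 40.0:  # truncate implausibly light draws
            mass = rng.normal(config.mass_mean, config.mass_sd)
        height = max(rng.normal(config.height_mean, config.height_sd), 1.4)
        rest = max(rng.normal(config.resting_rate_mean, config.resting_rate_sd), 0.5)
        cohort.append(SubjectMeta(
            id=f"S{i + 1:02d}",
            mass=float(mass),
            height=float(height),
            sex="F" if i % 2 == 0 else "M",
            resting_rate_true=float(rest),
            cost_intercept=float(rng.normal(0.0, config.intercept_sd)),
        ))
    return cohort


# ----------------------------------------------------------------------
# gait trials
# ----------------------------------------------------------------------


def _fourier(coeffs: Sequence[float], phi: np.ndarray) -> np.ndarray:
    out = np.full_like(phi, coeffs[0], dtype=float)
    nh = (len(coeffs) - 1) // 2
    for k in range(1, nh + 1):
        out += coeffs[2 * k - 1] * np.cos(2 * np.pi * k * phi)
        out += coeffs[2 * k] * np.sin(2 * np.pi * k * phi)
    return out


def joint_angle_templates(phi: np.ndarray, speed: float, incline: float) -> dict:
    """Winter-convention joint angles (rad) at cycle phases ``phi``."""
    tpl = templates()
    shift = tpl["incline_shift_deg"]
    amp = 0.85 + 0.15 * speed / 1.3
    out = {}
    for joint, coeffs in tpl["joint_angles_deg"].items():
        base = _fourier(coeffs, phi)
        mean = np.mean(_fourier(coeffs, np.linspace(0, 1, 200, endpoint=False)))
        theta = mean + amp * (base - mean) + shift[joint] * incline
        out[joint] = np.deg2rad(theta)
    return out


def _grf_templates(phi: np.ndarray, speed: float, incline: float,
                   weight: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-leg vertical force, fore-aft force and CoP progression (0..1)."""
    g = templates()["grf"]
    duty = g["duty_factor"]
    s = np.where(phi < duty, phi / duty, np.nan)
    stance = phi < duty
    valley = g["valley_base"] + g["valley_speed_gain"] * max(speed - 0.8, 0.0)
    sc = np.where(stance, s, 0.0)
    shape = np.where(stance, np.sin(np.pi * sc)
                     * (1.0 + valley * np.cos(2 * np.pi * sc)), 0.0)
    # descending: the push-off hump fades (the leg absorbs, not propels)
    late = np.clip(2.0 * sc - 1.0, 0.0, 1.0)
    shape = shape * (1.0 + 3.0 * min(incline, 0.0) * late)
    fy = weight * shape
    fx_wave = -np.sin(2 * np.pi * np.where(stance, s, 0.0))
    fx = np.where(stance, g["fore_aft_amp"] * (speed / 1.3) * weight * fx_wave,
                  0.0)
    # incline component carried in proportion to the vertical force
    fx = fx + fy * np.tan(np.arctan(incline))
    # the CoP stops short of the toes when descending
    travel = g["cop_travel"] * (1.0 + 1.5 * min(incline, 0.0))
    cop_s = travel * np.where(stance, s, 0.0) ** 1.3
    return fy, fx, cop_s


def cycle_duration(speed: float, incline: float = 0.0) -> float:
    """Nominal gait-cycle duration (s): stride length 0.8 + 0.5 v over v.

    """
    stride = (0.8 + 0.5 * speed)
    return stride / speed


def generate_gait_trial(subject: SubjectMeta, speed: float, incline: float,
                        seed: int, n_cycles: int = 12, sample_rate: float = 100.0,
                        noise: NoiseConfig = NoiseConfig()) -> GaitTrial:
    """One treadmill recording: periodic markers + GRFs for >= 10 cycles.

    Marker kinematics are built by forward kinematics from the joint-angle
    templates; ground reaction forces from double-hump vertical and
    braking/propulsion fore-aft templates, phase-shifted half a cycle
    between the legs.  The vertical force is rescaled so its cycle mean
    equals the belt-normal component of body weight exactly (before
    additive noise); the fore-aft force carries the along-belt gravity
    component, so the propulsive impulse grows uphill.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    if abs(incline) >= 0.2:
        raise ValueError("incline magnitude must be below 0.2")
    rng = np.random.default_rng(seed)
    tpl = templates()
    T = cycle_duration(speed, incline)
    duration = n_cycles * T
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    segs = subject.leg_segments
    alpha = np.arctan(incline)
    weight_normal = subject.mass * G * np.cos(alpha)

    lean = np.deg2rad(tpl["trunk_lean_deg"]
                      + tpl["trunk_lean_incline_deg"] * incline)

    markers: dict = {}
    grf: dict = {}
    for side, phase0 in (("right", 0.0), ("left", 0.5)):
        phi = (t / T + phase0) % 1.0
        ang = joint_angle_templates(phi, speed, incline)
        # small smooth cycle-to-cycle amplitude jitter
        if noise.cycle_jitter > 0:
            jit = 1.0 + noise.cycle_jitter * rng.standard_normal()
            wobble = 1.0 + noise.cycle_jitter * 0.5 * np.sin(
                2 * np.pi * t / (n_cycles * T) * rng.integers(1, 4))
            for j in ang:
                ang[j] = ang[j] * jit * wobble

        sigma_trunk = lean + 0.02 * np.sin(4 * np.pi * phi)
        sigma_thigh = ang["hip"] - sigma_trunk
        sigma_shank = sigma_thigh - ang["knee"]
        foot_pitch = sigma_shank + ang["ankle"]

        hip_x = 0.02 * np.sin(2 * np.pi * phi)
        hip_y = segs["hip_height"] + 0.015 * np.cos(4 * np.pi * phi)
        hip = np.stack([hip_x, hip_y], axis=1)
        knee = hip + segs["thigh"] * np.stack(
            [np.sin(sigma_thigh), -np.cos(sigma_thigh)], axis=1)
        ankle = knee + segs["shank"] * np.stack(
            [np.sin(sigma_shank), -np.cos(sigma_shank)], axis=1)
        # the ankle projects onto the foot line ~25% from the heel
        toe = ankle + (segs["foot"] - 0.05) * np.stack(
            [np.cos(foot_pitch), np.sin(foot_pitch)], axis=1)
        shoulder = hip + segs["trunk"] * np.stack(
            [np.sin(sigma_trunk), np.cos(sigma_trunk)], axis=1)
        for role, pos in (("shoulder", shoulder), ("hip", hip), ("knee", knee),
                          ("ankle", ankle), ("toe", toe)):
            if noise.marker_sd > 0:
                pos = pos + rng.normal(0.0, noise.marker_sd, pos.shape)
            markers[(side, role)] = pos

        fy, fx, cop_s = _grf_templates(phi, speed, incline, weight_normal)
        stance = fy > 0
        # anchor the CoP to the foot: heel 5 cm behind the ankle marker,
        # progressing to the toe marker during stance
        heel_x = ankle[:, 0] - 0.05
        cop = np.where(stance, heel_x + cop_s * (toe[:, 0] - heel_x), 0.0)
        grf[side] = {"fy": fy, "fx": fx, "cop": cop}

    # rescale so the mean total vertical force equals the normal weight
    total_fy = grf["right"]["fy"] + grf["left"]["fy"]
    scale = weight_normal / total_fy.mean()
    for side in SIDES:
        grf[side]["fy"] = grf[side]["fy"] * scale
        grf[side]["fx"] = grf[side]["fx"] * scale
        if noise.grf_sd > 0:
            stance = grf[side]["fy"] > 0
            grf[side]["fy"] = np.maximum(
                grf[side]["fy"] + stance * rng.normal(0, noise.grf_sd, n), 0.0)
            grf[side]["fx"] = grf[side]["fx"] + stance * rng.normal(
                0, noise.grf_sd, n)

    return GaitTrial(subject=subject, speed=speed, incline=incline, time=t,
                     markers=markers, grf=grf, sample_rate=sample_rate,
                     duration=duration, cycle_period=T)


# ----------------------------------------------------------------------
# pulmonary records
# ----------------------------------------------------------------------


def _vo2_from_rate(w: float, rq: float) -> float:
    """Invert the Weir equation: V̇O2 (mL/min/kg) giving rate w (W/kg)."""
    return w * 60.0 / (4.184 * (3.972 + 1.078 * rq))


def generate_pulmonary(subject: SubjectMeta, trial_kind: str, speed: float,
                       incline: float, cost_model: Callable[[float, float], float] | None,
                       seed: int, noise: NoiseConfig = NoiseConfig(),
                       duration: float | None = None,
                       breath_interval: float = 2.5) -> PulmonaryRecord:
    """Breath-by-breath V̇O2 and R for a resting or walking trial.

    For a walking trial the steady-state rate is constructed so that the
    calorimetry pipeline (trim, Weir, resting subtraction, divide by
    speed) returns ``cost_model(speed, incline) + subject.cost_intercept``
    plus measurement noise.  A startup transient occupies exactly the trim
    window (30 s resting, 3 min walking), so trimming rules matter but a
    noise-free record inverts exactly.
    """
    if trial_kind not in ("resting", "walking"):
        raise ValueError(f"unknown trial_kind {trial_kind!r}")
    if trial_kind == "walking" and speed <= 0:
        raise ValueError("walking requires positive speed")
    rng = np.random.default_rng(seed)
    from gaitmet.calorimetry import REST_TRIM, WALK_TRIM

    if trial_kind == "resting":
        duration = 240.0 if duration is None else duration
        trim = REST_TRIM
        w_ss = subject.resting_rate_true
        rq_ss = 0.82
        w_start = 1.3 * w_ss
    else:
        duration = 420.0 if duration is None else duration
        trim = WALK_TRIM
        cost = cost_model(speed, incline) if cost_model is not None else 0.0
        w_ss = subject.resting_rate_true + (cost + subject.cost_intercept) * speed
        rq_ss = float(np.clip(0.80 + 0.03 * w_ss, 0.75, 1.05))
        w_start = subject.resting_rate_true

    n_breaths = int(duration / breath_interval)
    times = np.arange(1, n_breaths + 1) * breath_interval
    ramp = np.maximum(1.0 - times / trim, 0.0) ** 2   # exactly 0 after trim
    w = w_ss + (w_start - w_ss) * ramp
    rq = np.full_like(w, rq_ss)
    vo2 = np.array([_vo2_from_rate(wi, ri) for wi, ri in zip(w, rq)])
    if noise.vo2_sigma > 0:
        vo2 = vo2 * rng.lognormal(0.0, noise.vo2_sigma, vo2.shape)
    if noise.rq_sd > 0:
        rq = np.clip(rq + rng.normal(0.0, noise.rq_sd, rq.shape), 0.7, 1.3)
    return PulmonaryRecord(breath_times=times, vo2=vo2, rq=rq,
                           trial_kind=trial_kind, subject_id=subject.id,
                           speed=speed, incline=incline)


# ----------------------------------------------------------------------
# external interfaces (CSV + JSON sidecar)
# ----------------------------------------------------------------------


def write_gait_trial(trial: GaitTrial, path: str | Path) -> None:
    """Write a trial as CSV (one row per frame) + JSON sidecar metadata."""
    path = Path(path)
    cols = {"time": trial.time}
    for (side, role), pos in trial.markers.items():
        cols[f"{side}_{role}_x"] = pos[:, 0]
        cols[f"{side}_{role}_y"] = pos[:, 1]
    for side in SIDES:
        for ch in ("fy", "fx", "cop"):
            cols[f"{side}_grf_{ch}"] = trial.grf[side][ch]
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {
        "subject": trial.subject.id, "mass": trial.subject.mass,
        "height": trial.subject.height, "speed": trial.speed,
        "incline": trial.incline, "sample_rate": trial.sample_rate,
        "duration": trial.duration, "cycle_period": trial.cycle_period,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_gait_trial(path: str | Path, subject: SubjectMeta | None = None) -> GaitTrial:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if subject is None:
        subject = SubjectMeta(id=meta["subject"], mass=meta["mass"],
                              height=meta["height"], sex="",
                              resting_rate_true=1.0, cost_intercept=0.0)
    markers = {}
    for side in SIDES:
        for role in MARKER_ROLES:
            markers[(side, role)] = df[[f"{side}_{role}_x", f"{side}_{role}_y"]].to_numpy()
    grf = {side: {ch: df[f"{side}_grf_{ch}"].to_numpy() for ch in ("fy", "fx", "cop")}
           for side in SIDES}
    return GaitTrial(subject=subject, speed=meta["speed"], incline=meta["incline"],
                     time=df["time"].to_numpy(), markers=markers, grf=grf,
                     sample_rate=meta["sample_rate"], duration=meta["duration"],
                     cycle_period=meta["cycle_period"])


def write_pulmonary(record: PulmonaryRecord, path: str | Path) -> None:
    pd.DataFrame({"breath_time": record.breath_times, "vo2": record.vo2,
                  "rq": record.rq}).to_csv(path, index=False)


def read_pulmonary(path: str | Path, trial_kind: str, **meta) -> PulmonaryRecord:
    df = pd.read_csv(path)
    return PulmonaryRecord(breath_times=df["breath_time"].to_numpy(),
                           vo2=df["vo2"].to_numpy(), rq=df["rq"].to_numpy(),
                           trial_kind=trial_kind, **meta)
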