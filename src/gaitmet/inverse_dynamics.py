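"""Sagittal-plane inverse dynamics: filtering, segmentation, angles, moments.

The processing chain follows the classic link-segment approach: marker and
force signals are low-pass filtered with a zero-phase second-order
Butterworth filter (6 Hz cut-off), joint angles come from the orientations
of proximal-to-distal marker vectors, joint moments from bottom-up
Newton-Euler recursion over foot, shank and thigh with Winter's
anthropometric segment parameters, and everything is segmented into gait
cycles (heel strike to ipsilateral heel strike from a vertical-GRF
threshold), resampled to 100 nodes per cycle and averaged over all left
and right cycles.

Sign conventions (Winter): hip and knee flexion angles positive, ankle
dorsiflexion angle positive; hip and knee extension moments positive,
ankle plantarflexion moment positive.  Coordinates are expressed in the
treadmill-belt frame (x along the belt, y normal to it); on an incline the
gravity vector is rotated by atan(grade).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from gaitmet.synthetic import G, GaitTrial, SIDES

JOINTS = ("hip", "knee", "ankle")

#: Winter anthropometric segment parameters: mass fraction of body mass,
#: CoM location as a fraction of segment length from the proximal end, and
#: radius of gyration about the CoM as a fraction of segment length.
WINTER_SEGMENTS = {
    "foot": {"mass_frac": 0.0145, "com_frac": 0.50, "rog_frac": 0.475},
    "shank": {"mass_frac": 0.0465, "com_frac": 0.433, "rog_frac": 0.302},
    "thigh": {"mass_frac": 0.100, "com_frac": 0.433, "rog_frac": 0.323},
}

N_NODES = 100


@dataclass
class CycleTrajectory:
    """One averaged gait cycle resampled to 100 nodes.

    ``joint_angles`` and ``joint_moments`` have shape (100, 3), columns
    ordered hip, knee, ankle in the Winter sign convention.  ``grf`` has
    shape (100, 2): vertical and fore-aft force of the ipsilateral foot.
    ``sd`` maps channel name -> (100,) standard-deviation band.
    """

    joint_angles: np.ndarray
    joint_moments: np.ndarray
    grf: np.ndarray
    duration: float
    sd: dict = field(default_factory=dict)
    n_cycles: int = 0

    def __post_init__(self):
        for arr in (self.joint_angles, self.joint_moments):
            if arr.shape[0] != N_NODES:
                raise ValueError(f"cycle must have exactly {N_NODES} nodes")
        if self.duration <= 0:
            raise ValueError("cycle duration must be positive")

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, N_NODES, endpoint=False)

    def to_frame(self) -> pd.DataFrame:
        cols = {"phase": self.nodes}
        for i, j in enumerate(JOINTS):
            cols[f"angle_{j}"] = self.joint_angles[:, i]
            cols[f"moment_{j}"] = self.joint_moments[:, i]
        cols["grf_fy"] = self.grf[:, 0]
        cols["grf_fx"] = self.grf[:, 1]
        return pd.DataFrame(cols)


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------


def filter_zero_phase(signal, fs: float, fc: float = 6.0):
    """Zero-phase second-order Butterworth low-pass (applied fore and aft).

    One second of reflective padding suppresses the forward-backward edge
    transients.  Output has the same length as the input.
    """
    if fc >= fs / 2.0:
        raise ValueError("cut-off must be below the Nyquist frequency")
    signal = np.asarray(signal, float)
    b, a = butter(2, fc / (fs / 2.0))
    padlen = min(int(fs), signal.shape[0] - 1)
    return filtfilt(b, a, signal, axis=0, padlen=padlen)


# ----------------------------------------------------------------------
# gait events
# ----------------------------------------------------------------------


def segment_cycles(grf_vertical, threshold: float, hysteresis: float = 0.5):
    """Heel-strike to ipsilateral heel-strike index pairs.

    A heel strike is a rising crossing of ``threshold``; the force must
    first fall below ``hysteresis * threshold`` before the next strike can
    be detected.  Partial first/last cycles are dropped.
    """
    f = np.asarray(grf_vertical, float)
    if np.any(f < -1e-9):
        raise ValueError("vertical GRF must be nonnegative")
    lo = hysteresis * threshold
    strikes = []
    armed = f[0] < lo
    for i in range(1, f.size):
        if armed and f[i] >= threshold:
            strikes.append(i)
            armed = False
        elif not armed and f[i] < lo:
            armed = True
    if len(strikes) < 2:
        warnings.warn("no complete gait cycles found")
        return []
    return [(strikes[i], strikes[i + 1]) for i in range(len(strikes) - 1)]


# ----------------------------------------------------------------------
# joint angles
# ----------------------------------------------------------------------


def _segment_angle_down(prox, dist, name):
    """Orientation of a downward segment: 0 when vertical, + distal forward."""
    d = dist - prox
    if np.any(np.hypot(d[:, 0], d[:, 1]) < 1e-9):
        frame = int(np.argmax(np.hypot(d[:, 0], d[:, 1]) < 1e-9))
        raise ValueError(f"coincident markers for {name} at frame {frame}")
    return np.arctan2(d[:, 0], -d[:, 1])


def joint_angles_from_markers(markers: dict, side: str = "right",
                              ankle_neutral: float = 0.0) -> dict[str, np.ndarray]:
    """Winter-convention joint angles (rad) from one side's marker set.

    Segment orientations come from the proximal-to-distal marker vector;
    joint angles are differences of adjacent segment orientations.  The
    trunk runs hip->shoulder, the foot ankle->toe; ``ankle_neutral`` is
    the dorsiflexion angle assigned to a flat foot under a vertical shank.
    """
    get = lambda role: np.asarray(markers[(side, role)], float)
    shoulder, hip, knee, ankle, toe = map(get, ("shoulder", "hip", "knee",
                                                "ankle", "toe"))
    d_tr = shoulder - hip
    if np.any(np.hypot(d_tr[:, 0], d_tr[:, 1]) < 1e-9):
        frame = int(np.argmax(np.hypot(d_tr[:, 0], d_tr[:, 1]) < 1e-9))
        raise ValueError(f"coincident markers for trunk at frame {frame}")
    sigma_trunk = np.arctan2(d_tr[:, 0], d_tr[:, 1])
    sigma_thigh = _segment_angle_down(hip, knee, "thigh")
    sigma_shank = _segment_angle_down(knee, ankle, "shank")
    d_ft = toe - ankle
    if np.any(np.hypot(d_ft[:, 0], d_ft[:, 1]) < 1e-9):
        frame = int(np.argmax(np.hypot(d_ft[:, 0], d_ft[:, 1]) < 1e-9))
        raise ValueError(f"coincident markers for foot at frame {frame}")
    sigma_foot = np.arctan2(d_ft[:, 1], d_ft[:, 0])
    return {
        "hip": sigma_thigh + sigma_trunk,
        "knee": sigma_thigh - sigma_shank,
        "ankle": sigma_foot - sigma_shank + ankle_neutral,
    }


# ----------------------------------------------------------------------
# Winter joint moments
# ----------------------------------------------------------------------


def _derivatives(x, fs):
    """Central differences with one-sided endpoint stencils."""
    x = np.asarray(x, float)
    v = np.gradient(x, 1.0 / fs, axis=0)
    a = np.gradient(v, 1.0 / fs, axis=0)
    return v, a


def _cross2(r, f):
    return r[..., 0] * f[..., 1] - r[..., 1] * f[..., 0]


def joint_moments_winter(markers: dict, grf: dict, mass: float, height: float,
                         fs: float, side: str = "right",
                         incline: float = 0.0) -> dict[str, np.ndarray]:
    """Bottom-up Newton-Euler joint moments (N·m, Winter convention).

    ``markers`` holds (side, role) -> (n, 2) positions in the belt frame;
    ``grf`` the side's vertical force, fore-aft force and CoP.  Segment
    masses, CoM locations and radii of gyration use Winter's fractions of
    body mass and stature.  Gravity is rotated by atan(incline) into the
    belt frame.
    """
    for key in ("hip", "knee", "ankle", "toe"):
        if (side, key) not in markers:
            raise ValueError(f"missing marker {key!r} for side {side!r}")
    if mass <= 0 or height <= 0:
        raise ValueError("anthropometry (mass, height) required")
    hip = np.asarray(markers[(side, "hip")], float)
    knee = np.asarray(markers[(side, "knee")], float)
    ankle = np.asarray(markers[(side, "ankle")], float)
    toe = np.asarray(markers[(side, "toe")], float)
    n = hip.shape[0]
    alpha = np.arctan(incline)
    g_vec = G * np.array([-np.sin(alpha), -np.cos(alpha)])

    fy = np.asarray(grf["fy"], float)
    fx = np.asarray(grf["fx"], float)
    cop = np.asarray(grf["cop"], float)
    f_ground = np.stack([fx, fy], axis=1)
    # CoP is only meaningful during contact; zero force elsewhere
    r_cop = np.stack([cop, np.zeros(n)], axis=1)

    segments = {
        "foot": (ankle, toe),
        "shank": (knee, ankle),
        "thigh": (hip, knee),
    }
    seg_lengths = {"foot": 0.152 * height, "shank": 0.246 * height,
                   "thigh": 0.245 * height}

    moments_z = {}
    f_distal = f_ground
    r_distal = r_cop
    m_distal = np.zeros(n)
    for seg in ("foot", "shank", "thigh"):
        prox, dist = segments[seg]
        pars = WINTER_SEGMENTS[seg]
        m_seg = pars["mass_frac"] * mass
        L = seg_lengths[seg]
        inertia = m_seg * (pars["rog_frac"] * L) ** 2
        com = prox + pars["com_frac"] * (dist - prox)
        _, a_com = _derivatives(com, fs)
        d = dist - prox
        theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
        _, ang_acc = _derivatives(theta, fs)

        f_prox = m_seg * a_com - m_seg * g_vec[None, :] - f_distal
        m_prox = (inertia * ang_acc - m_distal
                  - _cross2(r_distal - com, f_distal)
                  - _cross2(prox - com, f_prox))
        joint = {"foot": "ankle", "shank": "knee", "thigh": "hip"}[seg]
        moments_z[joint] = m_prox
        f_distal = -f_prox
        r_distal = prox
        m_distal = -m_prox

    # map CCW-positive z moments onto the Winter convention
    return {
        "ankle": -moments_z["ankle"],   # plantarflexion positive
        "knee": moments_z["knee"],      # extension positive
        "hip": -moments_z["hip"],       # extension positive
    }


# ----------------------------------------------------------------------
# cycle averaging
# ----------------------------------------------------------------------


def resample_cycle(signal, start: int, end: int, n_nodes: int = N_NODES):
    """Resample one cycle's samples [start, end) to ``n_nodes`` phases."""
    x = np.asarray(signal, float)[start:end]
    phase_in = np.linspace(0.0, 1.0, x.shape[0])
    phase_out = np.linspace(0.0, 1.0, n_nodes, endpoint=False)
    return np.interp(phase_out, phase_in, x)


def average_cycles(channels: dict, cycles_by_side: dict, fs: float) -> CycleTrajectory:
    """Average per-cycle resampled channels over all left and right cycles.

    ``channels`` maps side -> channel name -> full time series; channel
    names must include ``angle_{hip,knee,ankle}``, ``moment_{...}``,
    ``grf_fy`` and ``grf_fx``.  ``cycles_by_side`` maps side -> list of
    (start, end) index pairs.  In the sagittal plane both sides share the
    same sign conventions, so left cycles are pooled directly after
    phase-normalizing each cycle to its own heel strike.
    """
    n_total = sum(len(v) for v in cycles_by_side.values())
    if n_total == 0:
        raise ValueError("no gait cycles to average")
    names = [f"angle_{j}" for j in JOINTS] + [f"moment_{j}" for j in JOINTS] \
        + ["grf_fy", "grf_fx"]
    stacks = {name: [] for name in names}
    durations = []
    for side, cycles in cycles_by_side.items():
        for start, end in cycles:
            durations.append((end - start) / fs)
            for name in names:
                stacks[name].append(resample_cycle(channels[side][name], start, end))
    mean = {name: np.mean(stacks[name], axis=0) for name in names}
    sd = {name: (np.std(stacks[name], axis=0, ddof=1) if n_total > 1
                 else np.zeros(N_NODES)) for name in names}
    angles = np.stack([mean[f"angle_{j}"] for j in JOINTS], axis=1)
    moments = np.stack([mean[f"moment_{j}"] for j in JOINTS], axis=1)
    grf = np.stack([mean["grf_fy"], mean["grf_fx"]], axis=1)
    return CycleTrajectory(joint_angles=angles, joint_moments=moments, grf=grf,
                           duration=float(np.mean(durations)), sd=sd,
                           n_cycles=n_total)


# ----------------------------------------------------------------------
# end-to-end trial processing
# ----------------------------------------------------------------------


def process_trial(trial: GaitTrial, fc: float = 6.0,
                  event_threshold_frac: float = 0.05) -> CycleTrajectory:
    """Markers + GRFs -> averaged 100-node cycle.

    Order of operations: filter, differentiate (inside the moment
    computation), segment, resample, average.  Gait events use a
    vertical-GRF threshold at 5% body weight with hysteresis.
    """
    fs = trial.sample_rate
    filt_markers = {k: filter_zero_phase(v, fs, fc) for k, v in trial.markers.items()}
    channels = {}
    cycles_by_side = {}
    threshold = event_threshold_frac * trial.subject.mass * G
    for side in SIDES:
        grf_f = {ch: filter_zero_phase(trial.grf[side][ch], fs, fc)
                 for ch in ("fy", "fx")}
        grf_f["fy"] = np.maximum(grf_f["fy"], 0.0)
        grf_f["cop"] = trial.grf[side]["cop"]
        angles = joint_angles_from_markers(filt_markers, side=side)
        moments = joint_moments_winter(filt_markers, grf_f, trial.subject.mass,
                                       trial.subject.height, fs, side=side,
                                       incline=trial.incline)
        side_channels = {}
        for j in JOINTS:
            side_channels[f"angle_{j}"] = angles[j]
            side_channels[f"moment_{j}"] = moments[j]
        side_channels["grf_fy"] = grf_f["fy"]
        side_channels["grf_fx"] = grf_f["fx"]
        channels[side] = side_channels
        cycles = segment_cycles(grf_f["fy"], threshold)
        # drop the outermost cycles where filter/differentiation edge
        # effects could linger
        cycles_by_side[side] = cycles[1:-1] if len(cycles) > 2 else cycles
    return average_cycles(channels, cycles_by_side, fs)
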