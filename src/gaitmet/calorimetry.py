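"""Indirect calorimetry: pulmonary gas exchange to metabolic rate and cost.

The measured metabolic rate comes from the rate of oxygen consumption
(V̇O2, mL/min/kg) and the respiratory quotient R.  The Weir equation gives
the energetic equivalent per litre of O2 as 4.184*(3.972 + 1.078 R) kJ; the
Peronnet & Massicotte nonprotein table is its common alternative.  The net
walking rate (resting rate subtracted) divided by speed is the measured
cost of transport C_meas in J/kg/m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Trim windows (s) before averaging: startup transients are discarded.
REST_TRIM = 30.0
WALK_TRIM = 180.0


@dataclass
class MeasuredCost:
    subject: str
    condition: tuple[float, float]  # (speed m/s, incline grade)
    W_gross: float                  # W/kg
    W_net: float                    # W/kg
    C_meas: float                   # J/kg/m
    equation: str


def trim_and_average(record) -> tuple[float, float]:
    """Time-weighted mean V̇O2 and R of the retained part of a record.

    The first 30 s of a resting trial and the first 3 min of a walking
    trial are disregarded.  Breaths are weighted by the inter-breath
    interval (the last breath gets the mean interval).
    """
    t = np.asarray(record.breath_times, float)
    trim = REST_TRIM if record.trial_kind == "resting" else WALK_TRIM
    if t.size == 0 or t[-1] <= trim:
        raise ValueError(
            f"record of duration {0 if t.size == 0 else t[-1]:.0f} s is "
            f"shorter than its {trim:.0f} s trim window"
        )
    keep = t >= trim
    tk = t[keep]
    dt = np.diff(tk, append=tk[-1] + (np.diff(tk).mean() if tk.size > 1 else 1.0))
    w = dt / dt.sum()
    vo2 = float(np.asarray(record.vo2, float)[keep] @ w)
    rq = float(np.asarray(record.rq, float)[keep] @ w)
    return vo2, rq


def weir_rate(vo2, R):
    """Weir metabolic rate in W/kg from V̇O2 (mL/min/kg) and R."""
    return 4.184 / 60.0 * (3.972 + 1.078 * np.asarray(R, float)) * np.asarray(vo2, float)


def peronnet_rate(vo2, R):
    """Peronnet & Massicotte energetic equivalent, same interface as Weir.

    Linear interpolation of the nonprotein table between pure fat
    oxidation (R=0.707, 19.61 kJ/L O2) and pure carbohydrate oxidation
    (R=1.0, 21.12 kJ/L O2).
    """
    e_fat, e_cho = 19.61, 21.12  # kJ per litre O2
    slope = (e_cho - e_fat) / (1.0 - 0.707)
    e = e_fat + slope * (np.asarray(R, float) - 0.707)  # kJ/L
    return e * np.asarray(vo2, float) / 60.0  # -> W/kg


_EQUATIONS = {"weir": weir_rate, "peronnet": peronnet_rate}


def metabolic_rate(record, equation: str = "weir") -> float:
    """Trimmed, averaged metabolic rate of one record in W/kg."""
    vo2, rq = trim_and_average(record)
    return float(_EQUATIONS[equation](vo2, rq))


def measured_cost(walking, resting, v: float, equation: str = "weir") -> MeasuredCost | None:
    """Measured cost of transport: C_meas = (W_walk - W_rest) / v.

    Returns ``None`` for a flagged-missing walking record (propagating the
    absent data point).  A negative net rate passes through with a warning.
    """
    if v <= 0:
        raise ValueError("speed must be positive")
    if resting is None:
        raise ValueError("resting record is required")
    if walking is None or getattr(walking, "missing", False):
        return None
    w_walk = metabolic_rate(walking, equation)
    w_rest = metabolic_rate(resting, equation)
    w_net = w_walk - w_rest
    if w_net < 0:
        warnings.warn("net metabolic rate is negative (walking below resting)")
    return MeasuredCost(
        subject=getattr(walking, "subject_id", ""),
        condition=(v, getattr(walking, "incline", 0.0)),
        W_gross=w_walk,
        W_net=w_net,
        C_meas=w_net / v,
        equation=equation,
    )
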