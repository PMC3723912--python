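"""Dose–response and phase–response curve assembly from rhythm fits.

Dose–response: free-running period as a function of inhibitor dose, each
dose compared against vehicle-treated wells in the identical well position
on a different plate.

Phase–response: phase change Delta-phi (minutes) of rhythms resuming after
a timed inhibitor pulse, versus the pulse start time.  Delays are negative
by consensus.  Because phases are circular, per-pair differences are
wrapped to (-T/2, T/2] and averaged circularly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ArrhythmicError, PairingError, ParameterError
from .rhythm import RhythmFit

__all__ = [
    "DoseResponsePoint",
    "PhaseResponsePoint",
    "dose_response",
    "phase_change",
    "build_prc",
    "fit_hill",
]

logger = logging.getLogger(__name__)


@dataclass
class DoseResponsePoint:
    """Period summary at one inhibitor dose."""

    dose: float  # uM
    mean_period: float  # hours
    sd_period: float
    n: int
    period_difference: float  # hours, vs paired vehicle mean
    compound: str = ""
    line: str = ""


@dataclass
class PhaseResponsePoint:
    """Phase change at one pulse start time; delays negative (minutes)."""

    pulse_start: float  # hours after transfer to constant light
    delta_phi: float  # minutes, wrapped to (-T*30, T*30]
    sd: float  # minutes, circular
    n: int
    p_value: float  # one-sample t-test of per-pair deltas vs 0
    compound: str = ""
    pulse_duration: float = 4.0
    error: str | None = None


def _pair_key(fit: RhythmFit):
    return fit.metadata.get("well")


def _pair(treated: Sequence[RhythmFit], controls: Sequence[RhythmFit]):
    """Match treated to control fits by well position; fall back to order
    when wells are not annotated."""
    t_keys = [_pair_key(f) for f in treated]
    c_keys = [_pair_key(f) for f in controls]
    if None in t_keys or None in c_keys:
        if len(treated) != len(controls):
            raise PairingError(
                "no well annotations and group sizes differ; cannot pair"
            )
        return list(zip(treated, controls))
    c_by_well = {k: f for k, f in zip(c_keys, controls)}
    pairs, unmatched = [], []
    for k, f in zip(t_keys, treated):
        if k in c_by_well:
            pairs.append((f, c_by_well[k]))
        else:
            unmatched.append(k)
    if unmatched:
        logger.warning("dropping unpaired treated wells: %s", unmatched)
    if not pairs:
        raise PairingError(f"no treated well matched a control well: {unmatched}")
    return pairs


def dose_response(
    treated: Sequence[RhythmFit], controls: Sequence[RhythmFit]
) -> list[DoseResponsePoint]:
    """Per-dose mean/SD of period and the difference from paired vehicle.

    ``treated`` fits are grouped by their ``dose_uM`` metadata; every dose
    group is paired with ``controls`` by well position.
    """
    by_dose: dict[float, list[RhythmFit]] = {}
    for f in treated:
        if not f.rhythmic_flag:
            continue
        by_dose.setdefault(float(f.metadata.get("dose_uM", 0.0)), []).append(f)
    ctrl_rhythmic = [f for f in controls if f.rhythmic_flag]
    if len(ctrl_rhythmic) < 2:
        raise PairingError("need >= 2 rhythmic control fits")
    points = []
    for dose in sorted(by_dose):
        fits = by_dose[dose]
        if len(fits) < 2:
            raise PairingError(f"dose {dose} uM has < 2 rhythmic fits")
        pairs = _pair(fits, ctrl_rhythmic)
        periods = np.array([t.period for t, _ in pairs])
        ctrl_mean = float(np.mean([c.period for _, c in pairs]))
        points.append(
            DoseResponsePoint(
                dose=dose,
                mean_period=float(periods.mean()),
                sd_period=float(periods.std(ddof=1)),
                n=len(pairs),
                period_difference=float(periods.mean() - ctrl_mean),
                compound=str(fits[0].metadata.get("treatment", "")),
                line=str(fits[0].metadata.get("line", "")),
            )
        )
    return points


def _wrap_minutes(delta_min: float, period_h: float) -> float:
    """Wrap a phase change in minutes into (-T*30, T*30]."""
    cycle = period_h * 60.0
    wrapped = delta_min % cycle  # in [0, cycle)
    if wrapped > cycle / 2.0 or math.isclose(wrapped, cycle / 2.0):
        # exactly half a cycle reports as an advance (+T/2)
        return wrapped if math.isclose(wrapped, cycle / 2.0) else wrapped - cycle
    return wrapped


def phase_change(
    treated: Sequence[RhythmFit],
    vehicle: Sequence[RhythmFit],
    period_ref: float,
) -> tuple[float, float]:
    """Circular-mean phase change Delta-phi in minutes, delays negative.

    Per replicate pair, ``-(phi_treated - phi_vehicle)`` converted to
    minutes and wrapped to (-T/2, T/2]; a treated peak occurring later than
    the vehicle peak therefore reports as a negative (delay) value.
    Returns ``(delta_phi, circular_sd)`` in minutes.
    """
    if period_ref <= 0:
        raise ParameterError("period_ref must be > 0")
    for grp, name in ((treated, "treated"), (vehicle, "vehicle")):
        if not any(f.rhythmic_flag for f in grp):
            raise ArrhythmicError(f"{name} group has no rhythmic fits")
    pairs = _pair(
        [f for f in treated if f.rhythmic_flag],
        [f for f in vehicle if f.rhythmic_flag],
    )
    deltas = np.array(
        [
            _wrap_minutes(-(t.phase - v.phase) * 60.0, period_ref)
            for t, v in pairs
        ]
    )
    cycle = period_ref * 60.0
    angles = 2.0 * np.pi * deltas / cycle
    mean_angle = math.atan2(np.sin(angles).mean(), np.cos(angles).mean())
    R = float(np.hypot(np.sin(angles).mean(), np.cos(angles).mean()))
    delta_phi = _wrap_minutes(mean_angle * cycle / (2.0 * np.pi), period_ref)
    circ_sd = math.sqrt(max(-2.0 * math.log(max(R, 1e-300)), 0.0)) * cycle / (
        2.0 * np.pi
    )
    return float(delta_phi), float(circ_sd)


def _per_pair_deltas(treated, vehicle, period_ref):
    pairs = _pair(
        [f for f in treated if f.rhythmic_flag],
        [f for f in vehicle if f.rhythmic_flag],
    )
    return np.array(
        [_wrap_minutes(-(t.phase - v.phase) * 60.0, period_ref) for t, v in pairs]
    )


def build_prc(
    experiments: Sequence[tuple],
    period_ref: float = 24.0,
) -> list[PhaseResponsePoint]:
    """Assemble a phase–response curve from pulse experiments.

    ``experiments`` is a sequence of ``(pulse_start, treated_fits,
    vehicle_fits)``.  Failing points (e.g. arrhythmic post-washout groups)
    are flagged in ``error`` rather than aborting the curve.  Each point
    carries a one-sample t-test p-value of the per-pair phase changes
    against zero.
    """
    if len(experiments) == 0:
        raise ParameterError("need at least one experiment")
    points = []
    for pulse_start, treated, vehicle in experiments:
        try:
            dphi, sd = phase_change(treated, vehicle, period_ref)
            deltas = _per_pair_deltas(treated, vehicle, period_ref)
            if deltas.size >= 2 and deltas.std(ddof=1) > 0:
                _, p = stats.ttest_1samp(deltas, 0.0)
                p = float(p)
            else:
                p = 1.0 if np.allclose(deltas, 0.0) else float("nan")
            md = treated[0].metadata if treated else {}
            points.append(
                PhaseResponsePoint(
                    pulse_start=float(pulse_start),
                    delta_phi=dphi,
                    sd=sd,
                    n=int(deltas.size),
                    p_value=p,
                    compound=str(md.get("treatment", "")),
                    pulse_duration=float(md.get("pulse_duration_h", 4.0)),
                )
            )
        except (ArrhythmicError, PairingError) as exc:
            points.append(
                PhaseResponsePoint(
                    pulse_start=float(pulse_start),
                    delta_phi=float("nan"),
                    sd=float("nan"),
                    n=0,
                    p_value=float("nan"),
                    error=str(exc),
                )
            )
    return sorted(points, key=lambda p: p.pulse_start)


def fit_hill(points: Sequence[DoseResponsePoint]) -> dict:
    """Optional 4-parameter logistic summary of a dose–response curve.

    Returns dict with bottom, top, ec50, hill.  Provided as a convenience
    summary only; raw per-dose means are the primary output.
    """
    doses = np.array([p.dose for p in points])
    resp = np.array([p.mean_period for p in points])
    if doses.size < 4:
        raise ParameterError("need >= 4 dose points for a Hill fit")

    def model(d, bottom, top, ec50, hill):
        with np.errstate(invalid="ignore", over="ignore"):
            return bottom + (top - bottom) / (
                1.0 + (np.abs(ec50) / np.maximum(d, 1e-12)) ** hill
            )

    p0 = [resp.min(), resp.max(), np.median(doses[doses > 0]), 1.0]
    popt, _ = optimize.curve_fit(model, doses, resp, p0=p0, maxfev=20000)
    return {
        "bottom": float(popt[0]),
        "top": float(popt[1]),
        "ec50": float(popt[2]),
        "hill": float(popt[3]),
    }
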