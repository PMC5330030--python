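"""Clinical AVPD measures derived from the 8 tracked landmark curves.

The left-ventricular AVPD curve is the frame-wise mean of the six left-
sided landmark curves (both 2-chamber points, LV lateral + septum in the
3- and 4-chamber views).  The right-ventricular curve combines the two
right-sided points with the septal mean:

    RVAVPD = (rv_lateral + rv_outflow + mean(septum_3ch, septum_4ch)) / 3

End systole is the frame where the curve is at its minimum (the plane
farthest from its end-diastolic position).  Velocities are chord slopes
around the extrema of the forward-difference derivative of the 3-sample
moving-averaged curve: the emptying chord spans [t*-2, t*+2] around the
most negative derivative (apex-ward motion, so emptying velocity is
negative), the filling chord spans the asymmetric window [t*-1, t*+2]
around the most positive derivative.  Atrial contraction is the late-
diastolic AVPD step from the diastasis plateau back to baseline,
expressed as a percentage of the end-systolic AVPD; the plateau frame is
where |second derivative| of the averaged curve is smallest after peak
filling.  All curve indexing is cyclic — retrospective gating covers the
whole cardiac cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np

from avpdtrack.geometry import LV_LANDMARKS, landmark_key
from avpdtrack.prior import DisplacementCurve

_LV_KEYS = frozenset(landmark_key(v, l) for v, l in LV_LANDMARKS)


def _values(curve) -> np.ndarray:
    if isinstance(curve, DisplacementCurve):
        return curve.values
    return np.asarray(curve, dtype=float)


def lv_avpd(curves: Mapping[str, "np.ndarray | DisplacementCurve"]) -> np.ndarray:
    """Mean displacement curve of the 6 left-sided landmarks."""
    if set(curves) != _LV_KEYS:
        raise ValueError(f"expected exactly the LV landmark set {sorted(_LV_KEYS)}, "
                         f"got {sorted(curves)}")
    stack = np.vstack([_values(curves[k]) for k in sorted(curves)])
    return stack.mean(axis=0)


def rv_avpd(rv_lateral, rv_outflow, septum_3ch, septum_4ch) -> np.ndarray:
    """Right-ventricular AVPD: two RV points plus the septal mean, over 3."""
    arrs = [_values(a) for a in (rv_lateral, rv_outflow, septum_3ch, septum_4ch)]
    if len({a.size for a in arrs}) != 1:
        raise ValueError("curve frame counts differ")
    return (arrs[0] + arrs[1] + 0.5 * (arrs[2] + arrs[3])) / 3.0


def end_systole(values: Sequence[float]) -> int:
    """Frame of the curve minimum (maximal apex-ward excursion); earliest on ties."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty curve")
    return int(np.argmin(values))


def moving_average(values: Sequence[float], window: int = 3) -> np.ndarray:
    """Centered moving average with cyclic wrap (the cycle is periodic)."""
    values = np.asarray(values, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    half = window // 2
    out = np.zeros_like(values)
    for k in range(-half, half + 1):
        out += np.roll(values, -k)
    return out / window


def derivative(values: Sequence[float], cycle_duration: float) -> np.ndarray:
    """First-order forward-difference velocity in cm/s, wrapping the last frame.

    ``values`` are mm per frame; the frame spacing is
    ``cycle_duration / n_frames`` ms, and 1 mm/ms = 100 cm/s.
    """
    values = np.asarray(values, dtype=float)
    dt_ms = cycle_duration / values.size
    return (np.roll(values, -1) - values) / dt_ms * 100.0


def _chord_slope(curve: np.ndarray, t0: int, t1: int, dt_ms: float) -> float:
    n = curve.size
    return float(curve[t1 % n] - curve[t0 % n]) / ((t1 - t0) * dt_ms) * 100.0


def peak_emptying_velocity(values: Sequence[float], cycle_duration: float) -> float:
    """Peak systolic (emptying) AV-plane velocity in cm/s, negative by convention.

    The emptying extremum is the most negative forward-difference
    derivative of the moving-averaged curve (apex-ward motion); the
    velocity is the chord slope of the averaged curve between two frames
    before and two after that extremum.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 frames for the velocity chord")
    m = moving_average(values)
    d = derivative(m, cycle_duration)
    t_star = int(np.argmin(d))
    return _chord_slope(m, t_star - 2, t_star + 2, cycle_duration / values.size)


def peak_filling_velocity(values: Sequence[float], cycle_duration: float) -> float:
    """Peak early-diastolic (filling) velocity in cm/s, positive by convention.

    Analogous to the emptying velocity but at the most positive
    derivative, with the asymmetric chord window [t*-1, t*+2].
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 frames for the velocity chord")
    m = moving_average(values)
    d = derivative(m, cycle_duration)
    t_star = int(np.argmax(d))
    return _chord_slope(m, t_star - 1, t_star + 2, cycle_duration / values.size)


def _peak_filling_frame(values: np.ndarray, cycle_duration: float) -> int:
    return int(np.argmax(derivative(moving_average(values), cycle_duration)))


def atrial_contraction(
    values: Sequence[float], cycle_duration: float
) -> tuple[float, bool]:
    """Atrial-contraction AVPD step as % of the end-systolic AVPD.

    Locates the diastasis plateau as the frame after peak filling where
    the |second forward difference| of the moving-averaged curve is
    smallest, and reports 100 * |AVPD(ED) - AVPD(plateau)| / |AVPD(ES)|.

    Returns ``(percent, flagged)``.  When peak filling falls on the last
    frame there is no post-filling window (no diastasis — typical of
    high heart rates); the value is then computed over the full diastole
    and flagged.
    """
    values = np.asarray(values, dtype=float)
    es = end_systole(values)
    if values[es] == 0.0:
        # flat curve: no excursion to express the step against
        return 0.0, True
    m = moving_average(values)
    d1 = (np.roll(m, -1) - m)
    d2 = np.abs(np.roll(d1, -1) - d1)  # second forward difference, cyclic
    n = values.size
    t_fill = _peak_filling_frame(values, cycle_duration)
    flagged = t_fill >= n - 1
    lo = es if flagged else t_fill
    window = np.arange(lo + 1, n)
    if window.size == 0:
        raise ValueError("no diastolic frames after end systole")
    t_ac = int(window[np.argmin(d2[window])])
    percent = 100.0 * abs(values[0] - values[t_ac]) / abs(values[es])
    return percent, flagged


def curve_2norm(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean norm of the frame-wise difference of two curves."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves differ in length")
    return float(np.linalg.norm(a - b))


@dataclass
class AVPDResult:
    """All derived AVPD measures of one study (units in field names)."""

    lv_curve_mm: np.ndarray
    rv_curve_mm: np.ndarray
    lv_es_frame: int
    rv_es_frame: int
    lv_avpd_es_mm: float
    rv_avpd_es_mm: float
    lv_peak_emptying_velocity_cm_s: float
    rv_peak_emptying_velocity_cm_s: float
    lv_peak_filling_velocity_cm_s: float
    rv_peak_filling_velocity_cm_s: float
    lv_atrial_contraction_pct: float
    rv_atrial_contraction_pct: float
    lv_atrial_contraction_flagged: bool
    rv_atrial_contraction_flagged: bool
    cycle_duration_ms: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lv_curve_mm"] = self.lv_curve_mm.tolist()
        d["rv_curve_mm"] = self.rv_curve_mm.tolist()
        return d


def assemble_result(
    curves: Mapping[str, "np.ndarray | DisplacementCurve"], cycle_duration: float
) -> AVPDResult:
    """Combine the 8 landmark curves into the full measure set."""
    lv = lv_avpd({k: curves[k] for k in _LV_KEYS})
    rv = rv_avpd(curves[landmark_key("4ch", "rv_lateral")],
                 curves[landmark_key("3ch", "rv_outflow")],
                 curves[landmark_key("3ch", "septum")],
                 curves[landmark_key("4ch", "septum")])
    lv_es, rv_es = end_systole(lv), end_systole(rv)
    lv_ac, lv_flag = atrial_contraction(lv, cycle_duration)
    rv_ac, rv_flag = atrial_contraction(rv, cycle_duration)
    return AVPDResult(
        lv_curve_mm=lv,
        rv_curve_mm=rv,
        lv_es_frame=lv_es,
        rv_es_frame=rv_es,
        lv_avpd_es_mm=float(lv[lv_es]),
        rv_avpd_es_mm=float(rv[rv_es]),
        lv_peak_emptying_velocity_cm_s=peak_emptying_velocity(lv, cycle_duration),
        rv_peak_emptying_velocity_cm_s=peak_emptying_velocity(rv, cycle_duration),
        lv_peak_filling_velocity_cm_s=peak_filling_velocity(lv, cycle_duration),
        rv_peak_filling_velocity_cm_s=peak_filling_velocity(rv, cycle_duration),
        lv_atrial_contraction_pct=lv_ac,
        rv_atrial_contraction_pct=rv_ac,
        lv_atrial_contraction_flagged=lv_flag,
        rv_atrial_contraction_flagged=rv_flag,
        cycle_duration_ms=cycle_duration,
    )
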