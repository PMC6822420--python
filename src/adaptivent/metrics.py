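"""Endpoint metrics computed from ventilator waveforms and blood gases.

Implements the measured quantities of the study protocol: static driving
pressure from an end-inspiratory occlusion, static compliance, total
mechanical power by pressure-volume integration, mean airway pressure,
the expiratory time constant from the flow-volume relation of passive
expiration, Bohr dead space from the arterial/end-tidal CO2 pair, and
alveolar minute ventilation.  A window-averaging helper reproduces the
"last 5 minutes of each phase" endpoint convention.

All integration is trapezoidal on the native 100-Hz grid; nothing is
resampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .exceptions import (
    InsufficientDataError,
    InvalidArgumentError,
    MissingManeuverError,
)
from .mechanics import J_PER_CMH2O_ML
from .simulator import DT, BreathWaveform

#: Minimum occlusion length accepted as a plateau maneuver, s.
MIN_HOLD_S = 2.0
#: Portion of the hold averaged to read the plateau, s.
PLATEAU_READ_S = 0.5
#: |flow| below this is treated as zero (ml/s).
ZERO_FLOW_ML_S = 0.5


@dataclass(frozen=True)
class BreathMetrics:
    """Per-breath (or window-averaged) endpoint values.

    Fields that require an occlusion maneuver (``delta_p_stat``,
    ``plateau``, ``crs``) are NaN on ordinary breaths.
    """

    vt_insp: float
    vt_exp: float
    delta_p_stat: float
    plateau: float
    crs: float
    mp_total: float
    paw_mean: float
    rce_est: float
    rr_measured: float
    t_start: float = 0.0
    t_end: float = 0.0


def _hold_segment(wave: BreathWaveform, sl: slice) -> slice | None:
    """Locate a >= MIN_HOLD_S zero-flow inspiratory occlusion in a breath."""
    flow = wave.flow[sl]
    vol = wave.volume[sl]
    near_peak = vol > 0.9 * vol.max() if vol.max() > 0 else np.zeros_like(vol, bool)
    is_zero = (np.abs(flow) <= ZERO_FLOW_ML_S) & near_peak
    if not is_zero.any():
        return None
    # longest run of zero-flow samples at high volume
    idx = np.flatnonzero(is_zero)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    best = max(runs, key=len)
    if len(best) * DT < MIN_HOLD_S:
        return None
    start = sl.start + int(best[0])
    return slice(start, start + len(best))


def driving_pressure_static(wave: BreathWaveform, peep: float) -> float:
    """Static driving pressure: occlusion plateau minus set PEEP, cmH2O.

    The plateau is the mean airway pressure over the final 0.5 s of a
    zero-flow end-inspiratory hold of at least 2 s.  Referencing to set
    PEEP (not total PEEP) follows the bedside convention; auto-PEEP, if
    present, is contained in the returned value.
    """
    for sl in wave.breath_slices():
        hold = _hold_segment(wave, sl)
        if hold is not None:
            n_read = int(round(PLATEAU_READ_S / DT))
            plateau = float(np.mean(wave.paw[hold][-n_read:]))
            return plateau - peep
    raise MissingManeuverError("no >= 2 s zero-flow inspiratory hold found")


def static_compliance(vt_exp: float, delta_p_stat: float) -> float:
    """Static compliance, ml/cmH2O: expired tidal volume over delta P."""
    if delta_p_stat <= 0:
        raise InvalidArgumentError("delta_p_stat must be positive")
    if vt_exp < 0:
        raise InvalidArgumentError("vt_exp must be >= 0")
    return vt_exp / delta_p_stat


def _insp_end(wave: BreathWaveform, sl: slice) -> int:
    """Index (relative to slice) of end-inspiration = volume maximum."""
    return int(np.argmax(wave.volume[sl]))


def mechanical_power(wave: BreathWaveform) -> float:
    """Total mechanical power, J/min.

    Per breath, the trapezoidal integral of absolute airway pressure
    over inspired volume (the inspiratory limb of the PV loop, PEEP
    included); breath-averaged work times the measured rate gives J/min.
    """
    slices = wave.breath_slices()
    if not slices:
        raise InvalidArgumentError("waveform contains no complete breath")
    works = []
    for sl in slices:
        peak = _insp_end(wave, sl)
        if peak < 1:
            continue
        seg = slice(sl.start, sl.start + peak + 1)
        works.append(np.trapezoid(wave.paw[seg], wave.volume[seg]) * J_PER_CMH2O_ML)
    if not works:
        raise InvalidArgumentError("no inspiratory limb found")
    rr = measured_rate(wave)
    return float(np.mean(works) * rr)


def mean_airway_pressure(wave: BreathWaveform) -> float:
    """Time-averaged airway pressure over complete breath cycles, cmH2O."""
    if len(wave.paw) == 0 or wave.n_breaths == 0:
        raise InvalidArgumentError("empty waveform")
    return float(np.mean(wave.paw[wave.breath_starts[0] :]))


def measured_rate(wave: BreathWaveform) -> float:
    """Respiratory rate from breath boundaries, breaths/min."""
    duration = len(wave.time[wave.breath_starts[0] :]) * DT
    return wave.n_breaths / duration * 60.0


def expiratory_time_constant(wave: BreathWaveform) -> float:
    """Expiratory time constant, s, from the passive flow-volume relation.

    Over the 75% -> 25% expired-volume interval of each breath, expired
    volume remaining is regressed on flow (with intercept, so trapped
    volume below the end-expiratory level does not bias the slope); for
    a single-compartment exponential the slope is exactly -tau_e.
    Breaths are averaged.
    """
    taus = []
    for sl in wave.breath_slices():
        peak = _insp_end(wave, sl)
        flow = wave.flow[sl][peak:]
        vol = wave.volume[sl][peak:]
        exp_mask = flow < -ZERO_FLOW_ML_S
        if exp_mask.sum() < 4:
            continue
        flow = flow[exp_mask]
        vol = vol[exp_mask]
        expired_total = vol[0] - vol[-1]
        if expired_total <= 0:
            continue
        frac_remaining = (vol - vol[-1]) / expired_total
        win = (frac_remaining <= 0.75) & (frac_remaining >= 0.25)
        if win.sum() < 4:
            # short/truncated expiration: widen to everything available
            win = np.ones_like(frac_remaining, bool)
        if win.sum() < 4:
            continue
        slope = np.polyfit(flow[win], vol[win], 1)[0]
        if slope < 0:
            taus.append(-slope)
    if not taus:
        raise InsufficientDataError("no usable passive expiration found")
    return float(np.mean(taus))


def bohr_dead_space(paco2: float, etco2: float, vt: float) -> float:
    """Physiological dead space, ml, by the modified Bohr equation.

    ``VD = VT * (PaCO2 - expired CO2)/PaCO2``.  The second argument is
    the expired-gas CO2 tension: the mixed-expired value where
    volumetric capnography (or, in the simulator, CO2 mass balance)
    provides it, or the end-tidal value as a bedside surrogate.
    """
    if paco2 <= 0:
        raise InvalidArgumentError("paco2 must be positive")
    if etco2 < 0 or etco2 > paco2:
        raise InvalidArgumentError("require 0 <= etco2 <= paco2")
    if vt < 0:
        raise InvalidArgumentError("vt must be >= 0")
    return vt * (paco2 - etco2) / paco2


def alveolar_minute_ventilation(vt: float, vd: float, rr: float) -> float:
    """Alveolar minute ventilation, ml/min: ``(VT - VD) * RR``."""
    if not 0 <= vd <= vt:
        raise InvalidArgumentError("require 0 <= vd <= vt")
    if rr < 0:
        raise InvalidArgumentError("rr must be >= 0")
    return (vt - vd) * rr


def breath_metrics(wave: BreathWaveform, peep: float) -> list[BreathMetrics]:
    """Per-breath metrics for every complete breath in the waveform."""
    out = []
    rr = measured_rate(wave)
    for sl in wave.breath_slices():
        vol = wave.volume[sl]
        paw = wave.paw[sl]
        peak = _insp_end(wave, sl)
        vt_insp = float(vol[peak] - vol[0])
        vt_exp = float(vol[peak] - vol[-1])
        hold = _hold_segment(wave, sl)
        if hold is not None:
            n_read = int(round(PLATEAU_READ_S / DT))
            plateau = float(np.mean(wave.paw[hold][-n_read:]))
            dp_stat = plateau - peep
            crs = static_compliance(vt_exp, dp_stat)
        else:
            plateau = dp_stat = crs = math.nan
        work = np.trapezoid(paw[: peak + 1], vol[: peak + 1]) * J_PER_CMH2O_ML
        try:
            single = BreathWaveform(
                time=wave.time[sl],
                paw=paw,
                flow=wave.flow[sl],
                volume=vol,
                breath_starts=np.array([0]),
            )
            rce = expiratory_time_constant(single)
        except InsufficientDataError:
            rce = math.nan
        out.append(
            BreathMetrics(
                vt_insp=vt_insp,
                vt_exp=vt_exp,
                delta_p_stat=dp_stat,
                plateau=plateau,
                crs=crs,
                mp_total=float(work * rr),
                paw_mean=float(np.mean(paw)),
                rce_est=rce,
                rr_measured=rr,
                t_start=float(wave.time[sl][0]),
                t_end=float(wave.time[sl][-1]) + DT,
            )
        )
    return out


def window_average(metrics: list[BreathMetrics], window: float = 300.0) -> BreathMetrics:
    """Field-wise mean over complete breaths inside the final window (s).

    Occlusion-only fields are averaged over the breaths where they are
    defined (NaNs ignored); the result's ``rr_measured`` is recomputed
    from the breath count in the window.
    """
    if not metrics:
        raise InsufficientDataError("no breaths to average")
    t_end = metrics[-1].t_end
    duration = t_end - metrics[0].t_start
    if duration < window:
        raise InsufficientDataError(
            f"stream duration {duration:.1f} s shorter than window {window} s"
        )
    inside = [m for m in metrics if m.t_start >= t_end - window]
    if not inside:
        raise InsufficientDataError("no complete breath inside the window")
    values = {}
    for f in fields(BreathMetrics):
        col = np.array([getattr(m, f.name) for m in inside], dtype=float)
        with np.errstate(invalid="ignore"):
            values[f.name] = float(np.nanmean(col)) if not np.all(np.isnan(col)) else math.nan
    values["t_start"] = inside[0].t_start
    values["t_end"] = inside[-1].t_end
    values["rr_measured"] = len(inside) / (values["t_end"] - values["t_start"]) * 60.0
    return BreathMetrics(**values)


def metrics_to_frame(metrics: list[BreathMetrics]) -> pd.DataFrame:
    """Per-breath metrics as a DataFrame (one row per breath)."""
    return pd.DataFrame([m.__dict__ for m in metrics])
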