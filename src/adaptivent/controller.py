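"""Closed-loop settings selection for the two adaptive modes.

Given a target minute ventilation, the measured compliance and
expiratory time constant, and the mode (AVM: Otis rule; AVM2: minimum
inspiratory power), :func:`controller_step` emits the next set of
pressure-controlled ventilator settings.  :func:`minvol_adjustment`
implements the protocol rule that trims the minute-ventilation target
(%MinVol) whenever end-tidal CO2 drifts more than 2 mmHg from its
baseline value.

The inspiratory-time rules reproduce the characteristic timing of the
two modes: AVM2 splits the cycle 1:1 (the square-wave power objective
is derived with Ti = half cycle); AVM targets an I:E of 1:2, shortening
inspiration further if that is needed to leave at least three
expiratory time constants for exhalation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import math

from .exceptions import InvalidArgumentError
from .mechanics import RRSelectionInput, RRSolution, select_rr_minpower, select_rr_otis
from .simulator import VentilatorSettings

#: Protocol band around baseline end-tidal CO2, mmHg.
ETCO2_BAND_MMHG = 2.0


@dataclass(frozen=True)
class IERuleParams:
    """Tunables of the inspiratory-time rules (fractions of the cycle)."""

    avm2_duty: float = 0.5
    avm_duty: float = 1.0 / 3.0
    avm_te_rce_factor: float = 3.0
    avm_min_duty: float = 0.2


@dataclass(frozen=True)
class ModeConfig:
    """Configuration of one adaptive-mode phase."""

    mode: str  # "AVM" | "AVM2"
    nominal_ve: float  # ml/min at %MinVol = 100
    vda: float  # ml
    pct_minvol: float = 100.0
    rr_bounds: tuple[float, float] = (4.0, 60.0)
    delta_p_max: float = 40.0
    ie_params: IERuleParams = field(default_factory=IERuleParams)

    def __post_init__(self) -> None:
        if self.mode not in ("AVM", "AVM2"):
            raise InvalidArgumentError("mode must be 'AVM' or 'AVM2'")
        if self.pct_minvol <= 0:
            raise InvalidArgumentError("pct_minvol must be positive")
        if self.nominal_ve <= 0:
            raise InvalidArgumentError("nominal_ve must be positive")
        if self.delta_p_max <= 0:
            raise InvalidArgumentError("delta_p_max must be positive")
        lo, hi = self.rr_bounds
        if not 4.0 <= lo < hi <= 60.0:
            raise InvalidArgumentError("rr_bounds must lie within [4, 60]")

    @property
    def target_ve(self) -> float:
        """Current minute-ventilation target, ml/min."""
        return self.pct_minvol / 100.0 * self.nominal_ve


@dataclass
class ControllerState:
    """Mutable closed-loop state carried between control steps."""

    settings: VentilatorSettings
    rce_measured: float
    crs_measured: float
    tau_insp_measured: float | None = None
    etco2_last: float = math.nan
    flags: list[str] = field(default_factory=list)


def ie_rule(mode: str, rr: float, rce: float, params: IERuleParams | None = None) -> float:
    """Inspiratory time, s, for the given mode, rate, and time constant.

    AVM2 uses half the cycle.  AVM defaults to one third of the cycle
    (I:E = 1:2) but shortens inspiration when three expiratory time
    constants would not fit into the expiratory window; a floor of
    ``avm_min_duty`` of the cycle keeps the breath physiological.
    """
    p = params or IERuleParams()
    if rr <= 0:
        raise InvalidArgumentError("rr must be positive")
    cycle = 60.0 / rr
    if mode == "AVM2":
        return p.avm2_duty * cycle
    if mode == "AVM":
        ti = min(p.avm_duty * cycle, cycle - p.avm_te_rce_factor * rce)
        return min(max(ti, p.avm_min_duty * cycle), p.avm2_duty * cycle)
    raise InvalidArgumentError("mode must be 'AVM' or 'AVM2'")


def minvol_adjustment(
    etco2: float,
    baseline_etco2: float,
    pct_minvol: float,
    band: float = ETCO2_BAND_MMHG,
    step: float = 0.10,
    bounds: tuple[float, float] = (25.0, 350.0),
) -> float:
    """Protocol %MinVol adjustment keeping etCO2 at baseline +/- band.

    Inside the band the target is unchanged; above it the target is
    raised by ``step`` (more ventilation washes out CO2), below it
    lowered by ``step``; the result is bounded to the device range.
    """
    if etco2 <= 0 or baseline_etco2 <= 0 or pct_minvol <= 0:
        raise InvalidArgumentError("inputs must be positive")
    if abs(etco2 - baseline_etco2) <= band:
        return pct_minvol
    factor = 1.0 + step if etco2 > baseline_etco2 else 1.0 - step
    return min(max(pct_minvol * factor, bounds[0]), bounds[1])


def controller_step(
    state: ControllerState, cfg: ModeConfig
) -> tuple[VentilatorSettings, RRSolution]:
    """One control step: select RR, tidal volume, Ti, and delta-P.

    The rate comes from the mode's fixed-point equation; the target
    tidal volume is ``VE/RR``; the inspiratory pressure is the value
    that delivers it within Ti on a single-compartment system with the
    *measured* compliance and time constants, clamped at the mode's
    pressure limit.  Deterministic: identical inputs give identical
    settings.
    """
    inp = RRSelectionInput(
        ve=cfg.target_ve,
        vda=cfg.vda,
        rce=state.rce_measured,
        rr_min=cfg.rr_bounds[0],
        rr_max=cfg.rr_bounds[1],
    )
    selector = select_rr_otis if cfg.mode == "AVM" else select_rr_minpower
    sol = selector(inp)
    if sol.clamped:
        state.flags.append(f"rr_clamped:{sol.rr_unclamped:.2f}->{sol.rr:.2f}")
    rr = sol.rr
    vt_target = cfg.target_ve / rr
    ti = ie_rule(cfg.mode, rr, state.rce_measured, cfg.ie_params)
    tau_i = (
        state.tau_insp_measured
        if state.tau_insp_measured is not None
        else state.rce_measured
    )
    inflation = -math.expm1(-ti / tau_i) if tau_i > 0 else 1.0
    delta_p = vt_target / (state.crs_measured * inflation)
    if delta_p > cfg.delta_p_max:
        state.flags.append(f"delta_p_clamped:{delta_p:.1f}->{cfg.delta_p_max:.1f}")
        delta_p = cfg.delta_p_max
    settings = replace(
        state.settings, delta_p=delta_p, rr=rr, ti=ti, hold_duration=0.0
    )
    state.settings = settings
    return settings, sol
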