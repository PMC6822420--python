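"""Single-compartment breath simulator for pressure-controlled ventilation.

The respiratory system is a linear one-compartment model with separate
inspiratory and expiratory resistances.  During inspiration the airway
pressure is an ideal square wave (optionally with a linear rise), during
expiration it falls back to PEEP and the lung empties passively with
time constant ``rce``.  An optional end-inspiratory occlusion (hold)
freezes flow so the plateau pressure can be read.

Volumes are tracked above the relaxation volume at set PEEP; each
emitted :class:`BreathWaveform` stores volume above the breath's own
end-expiratory level (so it starts at zero even when gas is trapped).
Breaths are generated directly at the cyclic steady state, which is the
closed-form fixed point of the affine per-breath volume map; auto-PEEP
from incomplete exhalation is therefore captured exactly.

All waveforms are sampled at 100 Hz (0.01 s grid) to mirror ventilator
recordings, and the whole module is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .mechanics import PatientMechanics

#: Sampling interval, s (100 Hz ventilator recording).
DT = 0.01


@dataclass(frozen=True)
class VentilatorSettings:
    """One set of pressure-controlled ventilation parameters.

    ``delta_p`` is the inspiratory pressure above PEEP; the set
    inspiratory pressure is ``peep + delta_p``.  ``hold_duration`` of 0
    means no occlusion; when requested it must lie in the 2-3 s range
    used for plateau measurements.
    """

    peep: float
    delta_p: float
    rr: float
    ti: float
    hold_duration: float = 0.0
    rise_time: float = 0.0

    def __post_init__(self) -> None:
        if self.peep < 0:
            raise InvalidArgumentError("peep must be >= 0")
        if self.delta_p <= 0:
            raise InvalidArgumentError("delta_p must be positive")
        if self.rr <= 0:
            raise InvalidArgumentError("rr must be positive")
        if self.ti <= 0:
            raise InvalidArgumentError("ti must be positive")
        if self.hold_duration != 0.0 and not 2.0 <= self.hold_duration <= 3.0:
            raise InvalidArgumentError("hold_duration must be 0 or within [2, 3] s")
        if self.rise_time < 0 or self.rise_time > self.ti:
            raise InvalidArgumentError("rise_time must be in [0, ti]")
        if self.ti + self.hold_duration >= self.cycle:
            raise InvalidArgumentError(
                "ti + hold_duration must leave a positive expiratory time"
            )

    @property
    def cycle(self) -> float:
        """Breath cycle duration 60/rr, s."""
        return 60.0 / self.rr

    @property
    def te(self) -> float:
        """Expiratory time, s."""
        return self.cycle - self.ti - self.hold_duration

    @property
    def p_insp(self) -> float:
        """Absolute inspiratory pressure, cmH2O."""
        return self.peep + self.delta_p


@dataclass(frozen=True)
class BreathWaveform:
    """100-Hz airway pressure / flow / volume record.

    ``volume`` is in ml above the end-expiratory lung volume of each
    breath; ``flow`` is in ml/s with inspiration positive.
    ``breath_starts`` holds the sample index of each breath onset, and
    ``v_trapped`` the trapped volume above the relaxation volume at set
    PEEP at the start of each breath (auto-PEEP diagnostic, ml).
    """

    time: np.ndarray
    paw: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    breath_starts: np.ndarray
    v_trapped: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_breaths(self) -> int:
        return len(self.breath_starts)

    def breath_slices(self) -> list[slice]:
        """Slices delimiting each complete breath."""
        bounds = list(self.breath_starts) + [len(self.time)]
        return [slice(bounds[i], bounds[i + 1]) for i in range(self.n_breaths)]

    def to_csv(self, path: str | Path, boundaries_path: str | Path | None = None) -> None:
        """Write the waveform (and optionally breath boundaries) as CSV."""
        df = pd.DataFrame(
            {
                "time_s": self.time,
                "paw_cmh2o": self.paw,
                "flow_ml_s": self.flow,
                "volume_ml": self.volume,
            }
        )
        df.to_csv(path, index=False)
        if boundaries_path is not None:
            bounds = list(self.breath_starts) + [len(self.time)]
            pd.DataFrame(
                {
                    "breath_index": np.arange(self.n_breaths),
                    "start_sample": bounds[:-1],
                    "end_sample": [b - 1 for b in bounds[1:]],
                }
            ).to_csv(boundaries_path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, boundaries_path: str | Path | None = None
    ) -> "BreathWaveform":
        """Read a waveform written by :meth:`to_csv`.

        Without a boundaries file, breath onsets are detected as
        transitions from non-positive to positive flow.
        """
        df = pd.read_csv(path)
        flow = df["flow_ml_s"].to_numpy()
        if boundaries_path is not None:
            starts = pd.read_csv(boundaries_path)["start_sample"].to_numpy()
        else:
            pos = flow > 0
            onset = pos & ~np.roll(pos, 1)
            onset[0] = pos[0]
            starts = np.flatnonzero(onset)
        return cls(
            time=df["time_s"].to_numpy(),
            paw=df["paw_cmh2o"].to_numpy(),
            flow=flow,
            volume=df["volume_ml"].to_numpy(),
            breath_starts=np.asarray(starts, dtype=int),
        )


@dataclass(frozen=True)
class GasState:
    """Steady-state CO2 gas exchange for one ventilation condition."""

    paco2: float
    etco2: float
    va: float

    def __post_init__(self) -> None:
        if not self.paco2 >= self.etco2 >= 0:
            raise InvalidArgumentError("require paco2 >= etco2 >= 0")
        if self.va <= 0:
            raise InvalidArgumentError("va must be positive")


def _n_samples(duration: float) -> int:
    return int(round(duration / DT))


def _inspiration_volume(
    mech: PatientMechanics, set_: VentilatorSettings, v0: float, t: np.ndarray
) -> np.ndarray:
    """Volume above relaxation at set PEEP during inspiration, analytic.

    With a linear pressure rise over ``rise_time`` the driving pressure is
    ``delta_p*t/tr``; afterwards it is constant ``delta_p``.  Both pieces
    of the linear ODE ``R*dV/dt = p(t) - V/C`` have closed forms.
    """
    tau = mech.tau_insp
    c = mech.crs
    dp = set_.delta_p
    tr = set_.rise_time
    v = np.empty_like(t)
    if tr > 0:
        ramp = t <= tr
        tt = t[ramp]
        v[ramp] = dp * c * (tt / tr - tau / tr * (1.0 - np.exp(-tt / tau))) + v0 * np.exp(
            -tt / tau
        )
        v_tr = dp * c * (1.0 - tau / tr * (1.0 - math.exp(-tr / tau))) + v0 * math.exp(
            -tr / tau
        )
        tt = t[~ramp] - tr
        v[~ramp] = dp * c + (v_tr - dp * c) * np.exp(-tt / tau)
    else:
        v[:] = dp * c + (v0 - dp * c) * np.exp(-t / tau)
    return v


def _end_inspiratory_volume(
    mech: PatientMechanics, set_: VentilatorSettings, v0: float
) -> float:
    return float(
        _inspiration_volume(mech, set_, v0, np.array([set_.ti]))[0]
    )


def steady_state_volumes(
    mech: PatientMechanics, set_: VentilatorSettings
) -> tuple[float, float]:
    """Closed-form cyclic steady state ``(v_ei, v_ee)``.

    The per-breath map ``v_ee -> v_ei -> v_ee'`` is affine
    (``v_ei = A + B*v_ee`` with ``B = exp(-ti/tau_i)``, then
    ``v_ee' = v_ei*exp(-te/tau_e)``); its fixed point is the geometric-
    series limit and equals the volumes of every breath at steady state.
    """
    b_insp = math.exp(-set_.ti / mech.tau_insp)
    a_insp = _end_inspiratory_volume(mech, set_, 0.0)
    b_exp = math.exp(-set_.te / mech.rce)
    v_ee = a_insp * b_exp / (1.0 - b_insp * b_exp)
    v_ei = a_insp + b_insp * v_ee
    return v_ei, v_ee


def delivered_tidal_volume(mech: PatientMechanics, set_: VentilatorSettings) -> float:
    """Steady-state delivered tidal volume, ml."""
    v_ei, v_ee = steady_state_volumes(mech, set_)
    return v_ei - v_ee


def _synthesize_breath(
    mech: PatientMechanics,
    set_: VentilatorSettings,
    v_start: float,
    t0: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """One breath starting from absolute volume ``v_start``.

    Returns (time, paw, flow, volume_above_relaxation, v_end).
    """
    n_ti = _n_samples(set_.ti)
    n_hold = _n_samples(set_.hold_duration)
    n_cycle = _n_samples(set_.cycle)
    n_te = n_cycle - n_ti - n_hold
    if n_te <= 0:
        raise InvalidArgumentError("expiratory time shorter than one sample")

    t_insp = np.arange(n_ti) * DT
    v_insp = _inspiration_volume(mech, set_, v_start, t_insp)
    if set_.rise_time > 0:
        p_drive = np.minimum(t_insp / set_.rise_time, 1.0) * set_.delta_p
    else:
        p_drive = np.full(n_ti, set_.delta_p)
    paw_insp = set_.peep + p_drive
    flow_insp = (p_drive - v_insp / mech.crs) / mech.r_insp * 1000.0

    v_ei = _end_inspiratory_volume(mech, set_, v_start)
    paw_hold = np.full(n_hold, set_.peep + v_ei / mech.crs)
    flow_hold = np.zeros(n_hold)
    v_hold = np.full(n_hold, v_ei)

    t_exp = np.arange(n_te) * DT
    v_exp = v_ei * np.exp(-t_exp / mech.rce)
    flow_exp = -v_exp / mech.rce
    paw_exp = np.full(n_te, set_.peep)

    paw = np.concatenate([paw_insp, paw_hold, paw_exp])
    flow = np.concatenate([flow_insp, flow_hold, flow_exp])
    volume = np.concatenate([v_insp, v_hold, v_exp])
    time = t0 + np.arange(n_cycle) * DT
    v_end = float(v_ei * math.exp(-(n_te * DT) / mech.rce))
    return time, paw, flow, volume, v_end


def simulate_breath(
    mech: PatientMechanics, settings: VentilatorSettings
) -> BreathWaveform:
    """One breath at cyclic steady state (hold included in every cycle)."""
    _, v_ee = steady_state_volumes(mech, settings)
    time, paw, flow, vol, _ = _synthesize_breath(mech, settings, v_ee, 0.0)
    return BreathWaveform(
        time=time,
        paw=paw,
        flow=flow,
        volume=vol - v_ee,
        breath_starts=np.array([0]),
        v_trapped=np.array([v_ee]),
    )


def with_hold(settings: VentilatorSettings, hold: float = 2.5) -> VentilatorSettings:
    """Derive the occlusion-maneuver breath for a set of regular settings.

    The hold prolongs the breath cycle so that the full expiratory time
    of the regular breath is preserved (as on a ventilator that stretches
    the maneuver breath rather than truncating exhalation).
    """
    cycle_m = settings.ti + hold + settings.te
    return VentilatorSettings(
        peep=settings.peep,
        delta_p=settings.delta_p,
        rr=60.0 / cycle_m,
        ti=settings.ti,
        hold_duration=hold,
        rise_time=settings.rise_time,
    )


def simulate_phase(
    mech: PatientMechanics,
    settings: VentilatorSettings,
    n_breaths: int,
    maneuver: VentilatorSettings | None = None,
) -> BreathWaveform:
    """Concatenated steady-state breaths standing in for a ventilation phase.

    Regular breaths carry no occlusion; when ``settings.hold_duration``
    is positive (or an explicit ``maneuver`` breath is given), the final
    breath performs the plateau maneuver, starting from the regular
    steady state.
    """
    if n_breaths < 1:
        raise InvalidArgumentError("n_breaths must be >= 1")
    regular = settings
    if settings.hold_duration > 0:
        regular = VentilatorSettings(
            peep=settings.peep,
            delta_p=settings.delta_p,
            rr=settings.rr,
            ti=settings.ti,
            hold_duration=0.0,
            rise_time=settings.rise_time,
        )
        if maneuver is None:
            maneuver = settings
    _, v_ee = steady_state_volumes(mech, regular)

    parts: list[tuple[np.ndarray, ...]] = []
    starts = []
    trapped = []
    t0 = 0.0
    idx = 0
    v = v_ee
    for i in range(n_breaths):
        use = maneuver if (maneuver is not None and i == n_breaths - 1) else regular
        time, paw, flow, vol, v_end = _synthesize_breath(mech, use, v, t0)
        starts.append(idx)
        trapped.append(v)
        parts.append((time, paw, flow, vol - v))
        idx += len(time)
        t0 = t0 + len(time) * DT
        v = v_end
    return BreathWaveform(
        time=np.concatenate([p[0] for p in parts]),
        paw=np.concatenate([p[1] for p in parts]),
        flow=np.concatenate([p[2] for p in parts]),
        volume=np.concatenate([p[3] for p in parts]),
        breath_starts=np.asarray(starts, dtype=int),
        v_trapped=np.asarray(trapped),
    )


def gas_exchange_steady_state(mech: PatientMechanics, va: float) -> GasState:
    """Steady-state CO2 state at alveolar minute ventilation ``va`` (ml/min).

    Uses the alveolar ventilation equation
    ``PaCO2 = 0.863 * VCO2 / VA`` (VA in l/min, VCO2 in ml/min STPD);
    end-tidal CO2 is PaCO2 minus the patient's fixed gradient, floored
    at zero.
    """
    if va <= 0:
        raise InvalidArgumentError("va must be positive")
    paco2 = 0.863 * mech.vco2 / (va / 1000.0)
    etco2 = max(paco2 - mech.etco2_gradient, 0.0)
    return GasState(paco2=paco2, etco2=etco2, va=va)
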