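"""Respiratory-mechanics types and automated rate selection.

Two closed-loop ventilation strategies select the respiratory rate (RR)
that delivers a target expiratory minute ventilation ``VE`` given the
patient's anatomical dead space ``VDA`` and expiratory time constant
``RCe``:

* **AVM** — Otis' least-work-of-breathing rule, whose fixed point is::

      RR = (sqrt(1 + 4*pi**2*RCe*(VE - VDA*RR)/VDA) - 1) / (2*pi**2*RCe)

* **AVM2** — minimisation of inspiratory power for a square-wave
  pressure-controlled breath (inspiratory time = half the cycle)::

      RR = VE/(2*VDA) * (1 - x/expm1(x)),   x = 1/(2*RR*RCe)

Both maps are evaluated in coherent units (RR in breaths/s, VE in ml/s,
VDA in ml, RCe in s) and solved by damped fixed-point iteration with a
bracketed root-finding fallback.  Results are reported in breaths/min.

The brute-force :func:`oracle_power_curve` evaluates the inspiratory-power
objective on a dense RR grid and serves as an independent check that the
AVM2 fixed point really is the power minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .exceptions import ConvergenceError, InvalidArgumentError, NoSolutionError

#: Joules per (cmH2O * ml); exact by definition of the cmH2O.
J_PER_CMH2O_ML = 9.80665e-5

#: Anatomical dead space per kg predicted body weight (ml/kg).
VDA_PER_KG = 2.2

#: Eligibility bound on the expiratory time constant (s).
RCE_ELIGIBILITY_LIMIT = 1.5


@dataclass(frozen=True)
class PatientMechanics:
    """Linear single-compartment respiratory system.

    Parameters
    ----------
    crs : float
        Respiratory-system compliance, ml/cmH2O.
    r_insp, r_exp : float
        Inspiratory / expiratory resistance, cmH2O*s/l.
    rce : float
        Expiratory time constant, s.  Must equal ``r_exp*crs/1000``.
    pbw : float
        Predicted body weight, kg.
    vda : float
        Anatomical (series) dead space, ml.
    vco2 : float
        CO2 production, ml/min.
    etco2_gradient : float
        Arterial minus end-tidal CO2 partial-pressure difference, mmHg.
    """

    crs: float
    r_insp: float
    r_exp: float
    rce: float
    pbw: float
    vda: float
    vco2: float
    etco2_gradient: float

    def __post_init__(self) -> None:
        for name in ("crs", "r_insp", "r_exp", "pbw", "vda", "vco2"):
            if not getattr(self, name) > 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.etco2_gradient < 0:
            raise InvalidArgumentError("etco2_gradient must be >= 0")
        if abs(self.rce - self.r_exp * self.crs / 1000.0) > 1e-9:
            raise InvalidArgumentError(
                "rce inconsistent with r_exp*crs/1000 "
                f"({self.rce} vs {self.r_exp * self.crs / 1000.0})"
            )

    @classmethod
    def create(
        cls,
        crs: float,
        r_insp: float,
        rce: float,
        pbw: float,
        vco2: float = 200.0,
        etco2_gradient: float = 0.0,
        vda: float | None = None,
    ) -> "PatientMechanics":
        """Build mechanics from the measurable triplet (crs, r_insp, rce).

        ``r_exp`` is derived as ``rce*1000/crs`` and the anatomical dead
        space defaults to 2.2 ml/kg predicted body weight.
        """
        if crs <= 0:
            raise InvalidArgumentError("crs must be positive")
        return cls(
            crs=crs,
            r_insp=r_insp,
            r_exp=rce * 1000.0 / crs,
            rce=rce,
            pbw=pbw,
            vda=anatomical_dead_space(pbw) if vda is None else vda,
            vco2=vco2,
            etco2_gradient=etco2_gradient,
        )

    @property
    def tau_insp(self) -> float:
        """Inspiratory time constant r_insp*crs/1000, s."""
        return self.r_insp * self.crs / 1000.0

    @property
    def eligible(self) -> bool:
        """Study eligibility: no severe expiratory flow limitation."""
        return self.rce <= RCE_ELIGIBILITY_LIMIT


@dataclass(frozen=True)
class RRSelectionInput:
    """Inputs to the rate selectors.

    ``ve`` is the target expiratory minute ventilation in ml/min; ``vda``
    the anatomical dead space in ml; ``rce`` the expiratory time constant
    in s; ``rr_min``/``rr_max`` the admissible rate band in breaths/min.
    """

    ve: float
    vda: float
    rce: float
    rr_min: float = 4.0
    rr_max: float = 60.0

    def __post_init__(self) -> None:
        if self.ve <= 0:
            raise InvalidArgumentError("ve must be positive")
        if self.vda <= 0:
            raise InvalidArgumentError("vda must be positive")
        if self.rce < 0:
            raise InvalidArgumentError("rce must be >= 0")
        if not 0 < self.rr_min < self.rr_max:
            raise InvalidArgumentError("require 0 < rr_min < rr_max")


@dataclass(frozen=True)
class RRSolution:
    """A solved respiratory rate, breaths/min, with solver diagnostics."""

    rr: float
    clamped: bool
    residual: float
    iterations: int
    rr_unclamped: float

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.rr


@dataclass(frozen=True)
class PowerCurve:
    """Inspiratory power evaluated on a dense RR grid."""

    rr_grid: np.ndarray
    power: np.ndarray
    argmin_rr: float
    boundary: bool = field(default=False)


def anatomical_dead_space(pbw: float) -> float:
    """Anatomical dead space, ml, assumed 2.2 ml/kg predicted body weight."""
    if pbw <= 0:
        raise InvalidArgumentError("pbw must be positive")
    return VDA_PER_KG * pbw


def predicted_body_weight(height_cm: float, sex: str) -> float:
    """Predicted body weight (kg) from height and sex (ARDSNet formula)."""
    if not 120.0 <= height_cm <= 220.0:
        raise InvalidArgumentError("height must be in [120, 220] cm")
    sex = sex.lower()
    if sex == "male":
        return 50.0 + 0.905 * (height_cm - 152.4)
    if sex == "female":
        return 45.5 + 0.905 * (height_cm - 152.4)
    raise InvalidArgumentError("sex must be 'male' or 'female'")


def _otis_map(rr_s: float, ve_s: float, vda: float, rce: float) -> float:
    """Right-hand side of Otis' equation, breaths/s."""
    va = ve_s - vda * rr_s
    radicand = 1.0 + 4.0 * math.pi**2 * rce * va / vda
    if radicand < 0.0:
        raise NoSolutionError("alveolar ventilation not positive at iterate")
    if rce <= 0.0:
        # RCe -> 0 limit of the map (sqrt(1+z) ~ 1 + z/2): f -> VA/VDA,
        # whose fixed point is VE/(2*VDA).
        return va / vda
    return (math.sqrt(radicand) - 1.0) / (2.0 * math.pi**2 * rce)


def _minpower_map(rr_s: float, ve_s: float, vda: float, rce: float) -> float:
    """Right-hand side of the minimum-inspiratory-power equation, breaths/s.

    The correction factor ``1 - x/expm1(x)`` with ``x = 1/(2*RR*RCe)``
    lies strictly in (0, 1), so the fixed point is always below the
    shared small-RCe limit VE/(2*VDA).
    """
    k = ve_s / (2.0 * vda)
    if rce <= 0.0 or rr_s <= 0.0:
        return k
    x = 1.0 / (2.0 * rr_s * rce)
    if x > 700.0:  # expm1 overflow; x/expm1(x) -> 0
        return k
    return k * (1.0 - x / math.expm1(x))


def _solve_fixed_point(
    f,
    ve_s: float,
    vda: float,
    rce: float,
    rr_min_s: float,
    rr_max_s: float,
    damping: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> tuple[float, float, int]:
    """Damped fixed-point iteration with a bracketed fallback.

    Returns ``(rr_s, residual, iterations)`` in breaths/s.
    """
    rr = 15.0 / 60.0
    for it in range(1, max_iter + 1):
        try:
            fx = f(rr, ve_s, vda, rce)
        except NoSolutionError:
            break
        new = (1.0 - damping) * rr + damping * fx
        if new <= 0.0:
            break
        if abs(new - rr) < tol * damping:
            rr = new
            return rr, abs(rr - f(rr, ve_s, vda, rce)), it
        rr = new
    # Fallback: bracketed root of g(rr) = rr - f(rr) over a wide interval.
    lo = min(rr_min_s, 1e-6)
    hi = max(rr_max_s, ve_s / vda - 1e-12)

    def g(r: float) -> float:
        return r - f(r, ve_s, vda, rce)

    try:
        root = brentq(g, lo, hi, xtol=tol)
    except ValueError as exc:
        raise NoSolutionError(
            "no admissible fixed point with positive alveolar ventilation"
        ) from exc
    residual = abs(g(root))
    if residual > 1e-6:
        raise ConvergenceError(f"fixed point residual {residual:.3e} too large")
    return root, residual, max_iter


def _select_rr(f, inp: RRSelectionInput) -> RRSolution:
    ve_s = inp.ve / 60.0
    rr_s, residual, iterations = _solve_fixed_point(
        f, ve_s, inp.vda, inp.rce, inp.rr_min / 60.0, inp.rr_max / 60.0
    )
    rr_min_ = inp.rr_min
    rr_max_ = inp.rr_max
    rr = rr_s * 60.0
    if ve_s - inp.vda * rr_s <= 0.0:
        raise NoSolutionError("alveolar ventilation not positive at solution")
    clamped = not (rr_min_ <= rr <= rr_max_)
    return RRSolution(
        rr=min(max(rr, rr_min_), rr_max_),
        clamped=clamped,
        residual=residual * 60.0,
        iterations=iterations,
        rr_unclamped=rr,
    )


def select_rr_otis(inp: RRSelectionInput) -> RRSolution:
    """Rate selected by Otis' least-work-of-breathing rule (AVM)."""
    return _select_rr(_otis_map, inp)


def select_rr_minpower(inp: RRSelectionInput) -> RRSolution:
    """Rate minimising inspiratory power of a square-wave breath (AVM2)."""
    return _select_rr(_minpower_map, inp)


def inspiratory_power_square_wave(rr: float, delta_p: float, vt: float) -> float:
    """Inspiratory power, J/min, of an ideal square-wave breath.

    The pressure above PEEP times tidal volume is the area of the
    pressure-volume loop (work per breath); multiplying by the rate
    yields power: ``rr * delta_p * vt * 9.80665e-5``.
    """
    if rr < 0 or delta_p < 0 or vt < 0:
        raise InvalidArgumentError("arguments must be non-negative")
    return rr * delta_p * vt * J_PER_CMH2O_ML


def oracle_power_curve(
    inp: RRSelectionInput,
    crs: float,
    ie_inspiratory_fraction: float = 0.5,
    grid_step: float = 0.01,
) -> PowerCurve:
    """Brute-force inspiratory-power curve over the RR grid.

    Holds alveolar ventilation fixed at the value implied by the AVM2
    fixed point, then for each grid rate computes the tidal volume, the
    inspiratory pressure needed to deliver it within the finite
    inspiratory time (single-compartment inflation with time constant
    ``rce``), and the resulting power.  The argmin is the independent
    check on :func:`select_rr_minpower`.
    """
    if crs <= 0:
        raise InvalidArgumentError("crs must be positive")
    if not 0.0 < ie_inspiratory_fraction < 1.0:
        raise InvalidArgumentError("ie_inspiratory_fraction must be in (0, 1)")
    sol = select_rr_minpower(inp)
    rr_star_s = sol.rr_unclamped / 60.0
    ve_s = inp.ve / 60.0
    va_star = ve_s - inp.vda * rr_star_s  # ml/s, held fixed along the curve

    rr_grid = np.arange(inp.rr_min, inp.rr_max + grid_step / 2.0, grid_step)
    rr_s = rr_grid / 60.0
    vt = va_star / rr_s + inp.vda
    ti = ie_inspiratory_fraction / rr_s
    if inp.rce > 0:
        inflation = -np.expm1(-ti / inp.rce)
    else:
        inflation = np.ones_like(ti)
    delta_p = vt / (crs * inflation)
    power = rr_s * delta_p * vt * J_PER_CMH2O_ML * 60.0  # J/min
    i = int(np.argmin(power))
    boundary = i in (0, len(rr_grid) - 1)
    return PowerCurve(
        rr_grid=rr_grid, power=power, argmin_rr=float(rr_grid[i]), boundary=boundary
    )
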