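"""Synthetic patients emulating the study population.

Each virtual patient is a linear single-compartment respiratory system
plus a steady-state CO2 production, drawn from truncated-normal
marginals calibrated to the published cohort: compliance 55 +/- 13
ml/cmH2O (ARDS subgroup 47.3 +/- 9.1), expiratory time constant
0.82 +/- 0.22 s truncated at the 1.5-s eligibility bound (ARDS
0.73 +/- 0.18), predicted body weight 74 +/- 10 kg, baseline tidal
volume 7.5 +/- 0.8 ml/kg at rate 15.3 +/- 1.8 /min, PaCO2 43 +/- 6
mmHg, and PEEP drawn from a discrete distribution with median 8 and
IQR 8-10 cmH2O.

Compliance and the expiratory time constant are coupled through a
Gaussian copula (latent correlation 0.4) so that the implied expiratory
resistance stays physiological.  CO2 production is derived so that the
baseline ventilation reproduces the sampled PaCO2 under the steady-state
gas model, making every patient self-consistent.  Draws violating any
invariant are rejected and resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import InfeasibleParametersError, InvalidArgumentError
from .mechanics import PatientMechanics, anatomical_dead_space
from .simulator import GasState, VentilatorSettings, gas_exchange_steady_state

#: (mean, sd, lower bound, upper bound)
Marginal = tuple[float, float, float, float]


@dataclass(frozen=True)
class CohortParams:
    """Distributional parameters of the virtual cohort."""

    pbw: Marginal = (74.0, 10.0, 45.0, 110.0)
    crs: Marginal = (55.0, 13.0, 20.0, 100.0)
    crs_ards: Marginal = (47.3, 9.1, 20.0, 100.0)
    r_insp: Marginal = (11.1, 2.3, 4.0, 20.0)
    rce: Marginal = (0.82, 0.22, 0.3, 1.5)
    rce_ards: Marginal = (0.73, 0.18, 0.3, 1.5)
    vt_per_kg: Marginal = (7.5, 0.8, 5.0, 10.0)
    rr_baseline: Marginal = (15.3, 1.8, 10.0, 25.0)
    paco2: Marginal = (43.0, 6.0, 30.0, 70.0)
    etco2_gradient: Marginal = (5.0, 3.0, 0.0, 15.0)
    crs_rce_corr: float = 0.4
    r_exp_bounds: tuple[float, float] = (3.0, 45.0)
    vco2_bounds: tuple[float, float] = (80.0, 500.0)
    peep_values: tuple[int, ...] = (5, 6, 7, 8, 9, 10, 11, 12, 13, 14)
    peep_weights: tuple[float, ...] = (
        0.05, 0.05, 0.10, 0.35, 0.15, 0.20, 0.04, 0.03, 0.02, 0.01,
    )

    def __post_init__(self) -> None:
        for name in (
            "pbw", "crs", "crs_ards", "r_insp", "rce", "rce_ards",
            "vt_per_kg", "rr_baseline", "paco2", "etco2_gradient",
        ):
            mean, sd, lo, hi = getattr(self, name)
            if sd < 0 or not lo < hi:
                raise InvalidArgumentError(f"invalid marginal for {name}")
        if not -1.0 < self.crs_rce_corr < 1.0:
            raise InvalidArgumentError("crs_rce_corr must be in (-1, 1)")
        if abs(sum(self.peep_weights) - 1.0) > 1e-9:
            raise InvalidArgumentError("peep_weights must sum to 1")


@dataclass(frozen=True)
class SyntheticPatient:
    """One virtual trial participant."""

    id: str
    mech: PatientMechanics
    baseline_settings: VentilatorSettings
    baseline_gas: GasState
    baseline_vt_per_kg: float
    ards: bool

    @property
    def baseline_ve(self) -> float:
        """Baseline minute ventilation, ml/min."""
        return self.baseline_vt_per_kg * self.mech.pbw * self.baseline_settings.rr


def _trunc_norm_ppf(u: float, marg: Marginal) -> float:
    mean, sd, lo, hi = marg
    if sd == 0:
        return mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd))


def _draw_trunc(rng: np.random.Generator, marg: Marginal) -> float:
    return _trunc_norm_ppf(float(rng.uniform()), marg)


def sample_patient(
    rng_seed: int,
    params: CohortParams | None = None,
    ards: bool = False,
    patient_id: str = "P00",
    max_attempts: int = 1000,
) -> SyntheticPatient:
    """Draw one eligible, self-consistent synthetic patient.

    Rejection-samples until every mechanics invariant, the eligibility
    rule (rce <= 1.5 s), and the physiological bounds on derived
    quantities hold; raises :class:`InfeasibleParametersError` when the
    attempt budget is exhausted.
    """
    p = params or CohortParams()
    rng = np.random.default_rng(rng_seed)
    crs_marg = p.crs_ards if ards else p.crs
    rce_marg = p.rce_ards if ards else p.rce
    rho = p.crs_rce_corr
    chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))

    for _ in range(max_attempts):
        z = chol @ rng.standard_normal(2)
        u = stats.norm.cdf(z)
        crs = _trunc_norm_ppf(float(u[0]), crs_marg)
        rce = _trunc_norm_ppf(float(u[1]), rce_marg)
        r_exp = rce * 1000.0 / crs
        if not p.r_exp_bounds[0] <= r_exp <= p.r_exp_bounds[1]:
            continue
        pbw = _draw_trunc(rng, p.pbw)
        r_insp = _draw_trunc(rng, p.r_insp)
        vt_kg = _draw_trunc(rng, p.vt_per_kg)
        rr_base = _draw_trunc(rng, p.rr_baseline)
        paco2 = _draw_trunc(rng, p.paco2)
        gradient = _draw_trunc(rng, p.etco2_gradient)
        peep = float(rng.choice(p.peep_values, p=p.peep_weights))

        vda = anatomical_dead_space(pbw)
        vt = vt_kg * pbw
        va_baseline = (vt - vda) * rr_base  # ml/min
        if va_baseline <= 0:
            continue
        vco2 = paco2 * (va_baseline / 1000.0) / 0.863
        if not p.vco2_bounds[0] <= vco2 <= p.vco2_bounds[1]:
            continue
        mech = PatientMechanics.create(
            crs=crs,
            r_insp=r_insp,
            rce=rce,
            pbw=pbw,
            vco2=vco2,
            etco2_gradient=gradient,
            vda=vda,
        )
        if not mech.eligible:
            continue
        # baseline conventional pressure-controlled settings (I:E 1:2)
        cycle = 60.0 / rr_base
        ti = cycle / 3.0
        inflation = -np.expm1(-ti / mech.tau_insp)
        delta_p = vt / (crs * inflation)
        try:
            settings = VentilatorSettings(
                peep=peep, delta_p=float(delta_p), rr=rr_base, ti=ti
            )
        except InvalidArgumentError:
            continue
        gas = gas_exchange_steady_state(mech, va_baseline)
        return SyntheticPatient(
            id=patient_id,
            mech=mech,
            baseline_settings=settings,
            baseline_gas=gas,
            baseline_vt_per_kg=vt_kg,
            ards=ards,
        )
    raise InfeasibleParametersError(
        f"could not draw an eligible patient in {max_attempts} attempts"
    )


def generate_cohort(
    n: int,
    ards_n: int,
    seed: int,
    params: CohortParams | None = None,
) -> list[SyntheticPatient]:
    """Deterministic cohort of ``n`` patients, ``ards_n`` of them ARDS.

    Per-patient seeds are spawned from the master seed, so any cohort is
    a pure function of ``(n, ards_n, seed, params)``.
    """
    if n <= 0:
        raise InvalidArgumentError("n must be positive")
    if not 0 <= ards_n <= n:
        raise InvalidArgumentError("require 0 <= ards_n <= n")
    seeds = np.random.SeedSequence(seed).generate_state(n)
    return [
        sample_patient(
            int(seeds[i]) % (2**31 - 1),
            params=params,
            ards=i < ards_n,
            patient_id=f"P{i + 1:02d}",
        )
        for i in range(n)
    ]


def cohort_to_frame(cohort: list[SyntheticPatient]):
    """Cohort as a tidy DataFrame, one row per patient."""
    import pandas as pd

    rows = []
    for pt in cohort:
        rows.append(
            {
                "id": pt.id,
                "ards": pt.ards,
                "pbw_kg": pt.mech.pbw,
                "crs_ml_cmh2o": pt.mech.crs,
                "r_insp_cmh2o_s_l": pt.mech.r_insp,
                "r_exp_cmh2o_s_l": pt.mech.r_exp,
                "rce_s": pt.mech.rce,
                "vda_ml": pt.mech.vda,
                "vco2_ml_min": pt.mech.vco2,
                "etco2_gradient_mmhg": pt.mech.etco2_gradient,
                "peep_cmh2o": pt.baseline_settings.peep,
                "baseline_vt_ml_kg": pt.baseline_vt_per_kg,
                "baseline_rr_min": pt.baseline_settings.rr,
                "baseline_ve_ml_min": pt.baseline_ve,
                "baseline_paco2_mmhg": pt.baseline_gas.paco2,
                "baseline_etco2_mmhg": pt.baseline_gas.etco2,
            }
        )
    return pd.DataFrame(rows)
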