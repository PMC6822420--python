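"""Randomized cross-over trial on a synthetic cohort, with statistics.

Each virtual patient is ventilated for one phase per adaptive mode (AVM:
Otis rule, AVM2: minimum inspiratory power) in a randomized sequence.
The phase protocol mirrors the clinical study: the last clinically
selected minute ventilation becomes the mode's target, the %MinVol loop
trims the target until end-tidal CO2 returns to its baseline band, and
the endpoints are averaged over the final five minutes of the phase,
with one end-inspiratory occlusion for the static measurements.

The statistical layer reproduces the published analysis plan: the
D'Agostino-Pearson K2 omnibus test decides normality of the paired
differences per endpoint, a paired two-sided t test handles parametric
endpoints and the Wilcoxon matched-pairs test the rest, Pearson's r
quantifies the tidal-volume/compliance relation per mode, and the
sample-size routine inverts the noncentral-t power function of the
paired t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics as wm
from .cohort import SyntheticPatient
from .controller import ControllerState, ModeConfig, controller_step, minvol_adjustment
from .exceptions import (
    InsufficientDataError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)
from .simulator import (
    VentilatorSettings,
    delivered_tidal_volume,
    gas_exchange_steady_state,
    simulate_phase,
    with_hold,
)

MODES = ("AVM", "AVM2")
#: Endpoints compared between modes, in reporting order.
ENDPOINTS = (
    "vt_per_kg", "delta_p_stat", "p_insp", "rr", "mp",
    "va", "paw_mean", "crs", "rce", "paco2",
)


@dataclass(frozen=True)
class PhaseSummary:
    """Last-5-min averaged endpoints of one 1-h mode phase."""

    patient_id: str
    mode: str
    vt_per_kg: float
    vt_ml: float
    delta_p_stat: float
    p_insp: float
    rr: float
    mp: float
    va: float  # l/min
    paw_mean: float
    crs: float
    rce: float
    paco2: float
    etco2: float
    pct_minvol: float
    loop_steps: int
    converged: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class PairedTestResult:
    """Result of one within-patient mode comparison."""

    endpoint: str
    test: str  # "paired_t" | "wilcoxon" | "degenerate"
    statistic: float
    p_value: float
    diff_mean: float
    diff_sd: float
    normality_p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidArgumentError("p_value must be in [0, 1]")


@dataclass
class TrialResult:
    """Paired per-patient summaries plus the test battery."""

    summaries: dict[str, dict[str, PhaseSummary]]
    sequences: list[str]
    tests: dict[str, PairedTestResult] = field(default_factory=dict)
    #: r(VT, measured static compliance of the phase), per mode
    correlations: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: r(VT, generator compliance), per mode -- free of the intrinsic-PEEP
    #: contamination that the occlusion measurement carries at short
    #: expiratory times
    correlations_true_crs: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )
    failures: list[str] = field(default_factory=list)
    seed: int = 0

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            s.__dict__ | {"flags": ";".join(s.flags)}
            for by_mode in self.summaries.values()
            for s in by_mode.values()
        ]
        return pd.DataFrame(rows)

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.tests.values()])

    def endpoint_pairs(self, endpoint: str) -> tuple[np.ndarray, np.ndarray]:
        """(AVM values, AVM2 values) paired by patient."""
        avm = [m["AVM"] for m in self.summaries.values() if "AVM" in m and "AVM2" in m]
        avm2 = [m["AVM2"] for m in self.summaries.values() if "AVM" in m and "AVM2" in m]
        return (
            np.array([getattr(s, endpoint) for s in avm]),
            np.array([getattr(s, endpoint) for s in avm2]),
        )


def randomize_sequence(rng_seed: int, n: int) -> list[str]:
    """Sealed-envelope 1:1 randomization of phase order.

    Exactly ``n/2`` patients start with each mode; the assignment order
    is a seeded shuffle of the fixed envelope pool.
    """
    if n % 2 != 0 or n <= 0:
        raise InvalidArgumentError("n must be positive and even")
    pool = ["AVM_first"] * (n // 2) + ["AVM2_first"] * (n // 2)
    rng = np.random.default_rng(rng_seed)
    rng.shuffle(pool)
    return pool


def dagostino_pearson(x: np.ndarray) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus K2 normality test (requires n >= 8)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        raise InsufficientDataError("K2 test requires at least 8 values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        k2, p = stats.normaltest(x)
    return float(k2), float(p)


def _wilcoxon(d: np.ndarray) -> tuple[float, float]:
    """Wilcoxon matched-pairs test on differences, zeros dropped.

    Exact null distribution for n <= 25; normal approximation with
    continuity correction above.
    """
    d = d[d != 0]
    if len(d) == 0:
        return float("nan"), 1.0
    method = "exact" if len(d) <= 25 else "approx"
    try:
        res = stats.wilcoxon(d, method=method, correction=(method == "approx"))
    except ValueError:
        res = stats.wilcoxon(d, method="approx", correction=True)
    return float(res.statistic), float(res.pvalue)


def paired_compare(
    x: np.ndarray,
    y: np.ndarray,
    endpoint: str = "",
    normality_alpha: float = 0.05,
) -> PairedTestResult:
    """Paired two-sided comparison with the published test-selection rule.

    Differences are tested for normality with the K2 omnibus test (only
    possible for n >= 8; smaller samples default to Wilcoxon); normal
    differences get the paired t test, the rest the Wilcoxon
    matched-pairs test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidArgumentError("need equal-length paired samples, n >= 3")
    d = x - y
    if np.allclose(d, 0.0, atol=1e-12):
        return PairedTestResult(
            endpoint=endpoint, test="degenerate", statistic=float("nan"),
            p_value=1.0, diff_mean=0.0, diff_sd=0.0, normality_p=float("nan"),
        )
    normality_p = float("nan")
    use_t = False
    if len(d) >= 8:
        try:
            _, normality_p = dagostino_pearson(d)
            use_t = normality_p > normality_alpha
        except InsufficientDataError:  # pragma: no cover - guarded by len
            use_t = False
    if use_t:
        res = stats.ttest_rel(x, y)
        test, statistic, p = "paired_t", float(res.statistic), float(res.pvalue)
    else:
        statistic, p = _wilcoxon(d)
        test = "wilcoxon"
    return PairedTestResult(
        endpoint=endpoint, test=test, statistic=statistic, p_value=p,
        diff_mean=float(np.mean(d)), diff_sd=float(np.std(d, ddof=1)),
        normality_p=normality_p,
    )


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with two-sided t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidArgumentError("need equal-length samples, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidArgumentError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in an input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _paired_t_power(n: int, effect: float, alpha: float) -> float:
    nc = np.sqrt(n) * effect
    tc = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    p = float(1.0 - stats.nct.cdf(tc, n - 1, nc) + stats.nct.cdf(-tc, n - 1, nc))
    if not np.isfinite(p):  # nct loses precision at extreme noncentrality
        p = float(stats.norm.cdf(nc - tc) + stats.norm.cdf(-nc - tc))
    return p


def sample_size_paired(
    delta: float, sd_change: float, power: float = 0.80, alpha: float = 0.05
) -> int:
    """Smallest n giving the paired two-sided t test the requested power.

    Uses the noncentral-t power function (noncentrality sqrt(n)*d/sd),
    not the normal approximation.
    """
    if delta <= 0 or sd_change <= 0:
        raise InvalidArgumentError("delta and sd_change must be positive")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise InvalidArgumentError("power and alpha must be in (0, 1)")
    effect = delta / sd_change
    for n in range(2, 100001):
        if _paired_t_power(n, effect, alpha) >= power:
            return n
    raise InvalidArgumentError("requested power unattainable for n <= 100000")


# ---------------------------------------------------------------------------
# protocol execution


def _measure_mechanics(
    patient: SyntheticPatient, hold: float = 2.5, n_breaths: int = 6
) -> tuple[float, float]:
    """Estimate (crs, rce) from a short recording with one occlusion."""
    base = patient.baseline_settings
    wave = simulate_phase(
        patient.mech, base, n_breaths, maneuver=with_hold(base, hold)
    )
    peep = base.peep
    per_breath = wm.breath_metrics(wave, peep)
    dp = wm.driving_pressure_static(wave, peep)
    vt_exp = float(np.nanmean([m.vt_exp for m in per_breath[:-1]]))
    crs = wm.static_compliance(vt_exp, dp)
    rce = float(np.nanmean([m.rce_est for m in per_breath[:-1]]))
    return crs, rce


def _adapt_pressure(
    patient: SyntheticPatient,
    settings: VentilatorSettings,
    vt_target: float,
    delta_p_max: float,
    n_iter: int = 2,
) -> tuple[VentilatorSettings, float, bool]:
    """Fine-tune delta-P breath-by-breath until the target VT is delivered.

    The compartment is linear, so one multiplicative correction is exact;
    a second pass guards the pressure clamp.  Returns the adapted
    settings, the delivered VT, and whether the clamp engaged.
    """
    clamped = False
    vt = delivered_tidal_volume(patient.mech, settings)
    for _ in range(n_iter):
        dp = settings.delta_p * vt_target / vt
        if dp > delta_p_max:
            dp, clamped = delta_p_max, True
        settings = replace(settings, delta_p=dp)
        vt = delivered_tidal_volume(patient.mech, settings)
    return settings, vt, clamped


def run_phase(
    patient: SyntheticPatient,
    mode: str,
    crs_measured: float,
    rce_measured: float,
    window: float = 300.0,
    etco2_tol: float = 0.5,
    max_steps: int = 20,
    hold: float = 2.5,
    delta_p_max: float = 40.0,
    perfect_measurement: bool = False,
) -> PhaseSummary:
    """One adaptive-mode phase: %MinVol loop, steady phase, endpoints.

    ``etco2_tol`` is the loop's convergence target (a quarter of the
    protocol band by default, so the closed loop settles well inside
    the baseline +/- 2 mmHg corridor and the alveolar-ventilation match
    between a patient's two phases is tight).
    """
    mech = patient.mech
    cfg = ModeConfig(
        mode=mode,
        nominal_ve=patient.baseline_ve,
        vda=mech.vda,
        delta_p_max=delta_p_max,
    )
    state = ControllerState(
        settings=patient.baseline_settings,
        rce_measured=mech.rce if perfect_measurement else rce_measured,
        crs_measured=mech.crs if perfect_measurement else crs_measured,
        tau_insp_measured=mech.tau_insp if perfect_measurement else None,
    )
    target_etco2 = patient.baseline_gas.etco2
    pct = cfg.pct_minvol
    converged = False
    steps = 0
    settings = state.settings
    gas = patient.baseline_gas
    vt = float("nan")
    # %MinVol search: protocol steps of 10%, halved whenever the etCO2
    # error changes sign (overshoot), so the loop settles inside the
    # tolerance even when the etCO2 response gain is high.
    step_size = 0.10
    prev_sign = 0
    for steps in range(1, max_steps + 1):
        step_cfg = replace(cfg, pct_minvol=pct)
        settings, _ = controller_step(state, step_cfg)
        vt_target = step_cfg.target_ve / settings.rr
        settings, vt, clamped = _adapt_pressure(
            patient, settings, vt_target, delta_p_max
        )
        if clamped:
            state.flags.append("delta_p_clamped_adaptation")
        va_model = (vt - mech.vda) * settings.rr
        gas = gas_exchange_steady_state(mech, va_model)
        state.etco2_last = gas.etco2
        err = gas.etco2 - target_etco2
        if abs(err) <= etco2_tol:
            converged = True
            break
        sign = 1 if err > 0 else -1
        if prev_sign and sign != prev_sign:
            step_size = max(step_size / 2.0, 0.005)
        prev_sign = sign
        pct = minvol_adjustment(
            gas.etco2, target_etco2, pct, band=etco2_tol, step=step_size
        )

    n_breaths = int(np.ceil(window / settings.cycle)) + 2
    wave = simulate_phase(mech, settings, n_breaths, maneuver=with_hold(settings, hold))
    per_breath = wm.breath_metrics(wave, settings.peep)
    avg = wm.window_average(per_breath, window=window)

    # Modified Bohr dead space with the mixed-expired CO2 tension (known
    # exactly from CO2 mass balance: all produced CO2 leaves in the
    # expired minute volume), then alveolar VT * RR.
    ve_delivered = avg.vt_exp * avg.rr_measured  # ml/min
    peco2 = 0.863 * mech.vco2 / (ve_delivered / 1000.0)
    vd = wm.bohr_dead_space(gas.paco2, peco2, avg.vt_exp)
    va = wm.alveolar_minute_ventilation(avg.vt_exp, vd, avg.rr_measured) / 1000.0
    return PhaseSummary(
        patient_id=patient.id,
        mode=mode,
        vt_per_kg=avg.vt_exp / mech.pbw,
        vt_ml=avg.vt_exp,
        delta_p_stat=avg.delta_p_stat,
        p_insp=settings.p_insp,
        rr=avg.rr_measured,
        mp=avg.mp_total,
        va=va,
        paw_mean=avg.paw_mean,
        crs=avg.crs,
        rce=avg.rce_est,
        paco2=gas.paco2,
        etco2=gas.etco2,
        pct_minvol=pct,
        loop_steps=steps,
        converged=converged,
        flags=tuple(state.flags),
    )


def run_crossover_trial(
    cohort: list[SyntheticPatient],
    seed: int,
    window: float = 300.0,
    etco2_tol: float = 0.5,
    max_steps: int = 20,
    perfect_measurement: bool = False,
) -> TrialResult:
    """Execute the full randomized cross-over protocol on a cohort."""
    n = len(cohort)
    sequences = randomize_sequence(seed, n)
    result = TrialResult(summaries={}, sequences=sequences, seed=seed)
    for patient, seq in zip(cohort, sequences):
        order = ("AVM", "AVM2") if seq == "AVM_first" else ("AVM2", "AVM")
        try:
            crs_m, rce_m = _measure_mechanics(patient)
            by_mode = {}
            for mode in order:
                by_mode[mode] = run_phase(
                    patient,
                    mode,
                    crs_m,
                    rce_m,
                    window=window,
                    etco2_tol=etco2_tol,
                    max_steps=max_steps,
                    perfect_measurement=perfect_measurement,
                )
            result.summaries[patient.id] = by_mode
        except Exception as exc:  # controller failure: record, continue
            result.failures.append(f"{patient.id}: {exc}")
    for endpoint in ENDPOINTS:
        avm, avm2 = result.endpoint_pairs(endpoint)
        if len(avm) >= 3:
            result.tests[endpoint] = paired_compare(avm, avm2, endpoint=endpoint)
    true_crs = {p.id: p.mech.crs for p in cohort}
    for mode in MODES:
        done = [pid for pid, m in result.summaries.items() if mode in m]
        vt = np.array([result.summaries[pid][mode].vt_ml for pid in done])
        crs_meas = np.array([result.summaries[pid][mode].crs for pid in done])
        crs_gen = np.array([true_crs[pid] for pid in done])
        if len(done) >= 3:
            for target, values in (
                (result.correlations, crs_meas),
                (result.correlations_true_crs, crs_gen),
            ):
                try:
                    target[mode] = pearson_correlation(vt, values)
                except UndefinedCorrelationError:
                    target[mode] = (float("nan"), float("nan"))
    return result
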