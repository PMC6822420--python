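"""Waveform-derived endpoint metrics: recovery, arithmetic, windows."""

import math

import numpy as np
import pytest
from dataclasses import replace

from adaptivent import (
    BreathMetrics,
    BreathWaveform,
    PatientMechanics,
    VentilatorSettings,
    alveolar_minute_ventilation,
    bohr_dead_space,
    breath_metrics,
    driving_pressure_static,
    expiratory_time_constant,
    mean_airway_pressure,
    mechanical_power,
    simulate_breath,
    simulate_phase,
    static_compliance,
    window_average,
    with_hold,
)
from adaptivent.exceptions import (
    InsufficientDataError,
    InvalidArgumentError,
    MissingManeuverError,
)
from adaptivent.mechanics import J_PER_CMH2O_ML


def recording(crs=50.0, rce=0.8, peep=8.0, delta_p=10.0, rr=6.0, ti=2.0, n=6):
    """Slow-rate recording with a terminal occlusion and full exhalation."""
    mech = PatientMechanics.create(crs=crs, r_insp=11.0, rce=rce, pbw=74.0)
    settings = VentilatorSettings(peep=peep, delta_p=delta_p, rr=rr, ti=ti)
    return mech, settings, simulate_phase(
        mech, settings, n, maneuver=with_hold(settings, 2.5)
    )


def square_wave(peep, delta_p, ti_frac, cycle=4.0, n=3, vt=500.0):
    """Hand-built ideal square waveform, independent of the simulator."""
    n_c = int(round(cycle / 0.01))
    n_ti = int(round(cycle * ti_frac / 0.01))
    paw1 = np.where(np.arange(n_c) < n_ti, peep + delta_p, peep)
    t_in = np.linspace(0.0, vt, n_ti)
    t_ex = vt * np.exp(-np.arange(n_c - n_ti) * 0.01 / 0.5)
    vol1 = np.concatenate([t_in, t_ex])
    flow1 = np.gradient(vol1, 0.01)
    return BreathWaveform(
        time=np.arange(n * n_c) * 0.01,
        paw=np.tile(paw1, n),
        flow=np.tile(flow1, n),
        volume=np.tile(vol1, n),
        breath_starts=np.arange(n) * n_c,
    )


class TestParameterRecovery:
    def test_static_compliance_recovered_within_one_percent(self):
        mech, settings, wave = recording()
        dp = driving_pressure_static(wave, settings.peep)
        m = breath_metrics(wave, settings.peep)
        vt_exp = np.nanmean([b.vt_exp for b in m[:-1]])
        assert static_compliance(vt_exp, dp) == pytest.approx(mech.crs, rel=0.01)

    def test_expiratory_time_constant_exact_on_noiseless_model(self):
        _, settings, wave = recording(rce=0.8)
        assert expiratory_time_constant(wave) == pytest.approx(0.8, rel=1e-3)

    def test_time_constant_recovered_under_flow_noise(self, rng):
        _, settings, wave = recording(rce=1.2)
        for _ in range(10):
            noisy = replace(wave, flow=wave.flow + rng.normal(0.0, 5.0, len(wave.flow)))
            assert expiratory_time_constant(noisy) == pytest.approx(1.2, rel=0.05)

    def test_truncated_expiration_still_within_ten_percent(self):
        # te = 1 tau_e only
        mech = PatientMechanics.create(crs=50.0, r_insp=11.0, rce=1.0, pbw=74.0)
        settings = VentilatorSettings(peep=8.0, delta_p=10.0, rr=15.0, ti=3.0)
        wave = simulate_breath(mech, settings)
        assert expiratory_time_constant(wave) == pytest.approx(1.0, rel=0.10)


class TestDrivingPressure:
    def test_plateau_minus_peep_on_fully_exhaled_breath(self):
        mech, settings, wave = recording()
        m = breath_metrics(wave, settings.peep)
        vt_exp = np.nanmean([b.vt_exp for b in m[:-1]])
        dp = driving_pressure_static(wave, settings.peep)
        assert dp == pytest.approx(vt_exp / mech.crs, rel=0.01)

    def test_auto_peep_contaminates_set_peep_referenced_value(self):
        """With trapped gas, the plateau referenced to set PEEP exceeds
        the elastic VT/C by exactly the intrinsic PEEP."""
        mech = PatientMechanics.create(crs=50.0, r_insp=11.0, rce=1.0, pbw=74.0)
        settings = VentilatorSettings(peep=8.0, delta_p=10.0, rr=18.0, ti=1.6)
        wave = simulate_phase(mech, settings, 6, maneuver=with_hold(settings, 2.5))
        dp = driving_pressure_static(wave, settings.peep)
        sl = wave.breath_slices()[-1]
        vol = wave.volume[sl]
        vt = vol.max() - vol[0]
        auto_peep = wave.v_trapped[-1] / mech.crs
        assert auto_peep > 0.5
        assert dp == pytest.approx(vt / mech.crs + auto_peep, abs=0.05)

    def test_missing_maneuver_raises(self):
        mech = PatientMechanics.create(crs=50.0, r_insp=11.0, rce=0.8, pbw=74.0)
        wave = simulate_breath(mech, VentilatorSettings(8.0, 10.0, 10.0, 1.5))
        with pytest.raises(MissingManeuverError):
            driving_pressure_static(wave, 8.0)


class TestStaticCompliance:
    @pytest.mark.parametrize(
        "vt,dp,expected", [(500.0, 10.0, 50.0), (606.8, 12.6, 48.159), (0.0, 10.0, 0.0)]
    )
    def test_ratio(self, vt, dp, expected):
        assert static_compliance(vt, dp) == pytest.approx(expected, abs=1e-3)

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(InvalidArgumentError):
            static_compliance(500.0, 0.0)


class TestMechanicalPower:
    def test_ideal_square_wave_closed_form(self):
        """MP of an ideal square wave is RR*(PEEP+dP)*VT*9.80665e-5."""
        mech, settings, wave = recording(peep=5.0, delta_p=10.0, rr=6.0)
        m = breath_metrics(wave, settings.peep)
        vt = np.nanmean([b.vt_insp for b in m])
        rr = m[0].rr_measured
        expected = rr * (5.0 + 10.0) * vt * J_PER_CMH2O_ML
        assert mechanical_power(wave) == pytest.approx(expected, rel=0.02)

    def test_pressure_ramp_lowers_power(self):
        mech = PatientMechanics.create(crs=50.0, r_insp=11.0, rce=0.8, pbw=74.0)
        sq = VentilatorSettings(peep=5.0, delta_p=10.0, rr=10.0, ti=3.0)
        ramped = replace(sq, rise_time=0.3)
        assert mechanical_power(simulate_breath(mech, ramped)) < mechanical_power(
            simulate_breath(mech, sq)
        )

    def test_table_style_arithmetic(self):
        # constant paw 23.9 over 606.8 ml at 12.9 breaths/min
        wave = square_wave(peep=23.9, delta_p=1e-9, ti_frac=0.4, vt=606.8,
                           cycle=60.0 / 12.9)
        assert mechanical_power(wave) == pytest.approx(18.35, rel=0.02)

    def test_empty_waveform_rejected(self):
        with pytest.raises((InvalidArgumentError, IndexError)):
            mechanical_power(
                BreathWaveform(
                    time=np.array([]), paw=np.array([]), flow=np.array([]),
                    volume=np.array([]), breath_starts=np.array([], dtype=int),
                )
            )


class TestMeanAirwayPressure:
    @pytest.mark.parametrize("ti_frac,expected", [(0.5, 14.0), (1.0 / 3.0, 12.0)])
    def test_duty_cycle_weighted_mean(self, ti_frac, expected):
        wave = square_wave(peep=8.0, delta_p=12.0, ti_frac=ti_frac)
        assert mean_airway_pressure(wave) == pytest.approx(expected, abs=0.05)

    def test_longer_duty_raises_mean_pressure_despite_lower_dp(self):
        half = square_wave(peep=8.0, delta_p=10.0, ti_frac=0.5)
        third = square_wave(peep=8.0, delta_p=12.0, ti_frac=1.0 / 3.0)
        assert mean_airway_pressure(half) > mean_airway_pressure(third)


class TestDeadSpaceAndVa:
    @pytest.mark.parametrize(
        "paco2,etco2,vt,expected",
        [(40.0, 40.0, 500.0, 0.0), (40.0, 30.0, 500.0, 125.0), (40.0, 0.0, 500.0, 500.0)],
    )
    def test_bohr_fraction(self, paco2, etco2, vt, expected):
        assert bohr_dead_space(paco2, etco2, vt) == pytest.approx(expected)

    def test_negative_dead_space_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bohr_dead_space(40.0, 45.0, 500.0)

    @pytest.mark.parametrize(
        "vt,vd,rr,expected",
        [(500.0, 125.0, 15.0, 5625.0), (500.0, 500.0, 15.0, 0.0),
         (532.8, 150.0, 15.8, 6048.24)],
    )
    def test_alveolar_minute_ventilation(self, vt, vd, rr, expected):
        assert alveolar_minute_ventilation(vt, vd, rr) == pytest.approx(expected)

    def test_dead_space_exceeding_tidal_volume_rejected(self):
        with pytest.raises(InvalidArgumentError):
            alveolar_minute_ventilation(500.0, 600.0, 15.0)

    @pytest.mark.parametrize("paco2,etco2,vt,rr", [(42.0, 35.0, 480.0, 16.0),
                                                   (55.0, 40.0, 620.0, 11.0)])
    def test_bohr_va_identity(self, paco2, etco2, vt, rr):
        """(VT - VD_Bohr)*RR == VE * etCO2/PaCO2, the closed-form identity
        of the end-tidal Bohr form."""
        vd = bohr_dead_space(paco2, etco2, vt)
        va = alveolar_minute_ventilation(vt, vd, rr)
        assert va == pytest.approx(vt * rr * etco2 / paco2, rel=1e-12)


def _metric(t0, t1, value):
    return BreathMetrics(
        vt_insp=value, vt_exp=value, delta_p_stat=math.nan, plateau=math.nan,
        crs=math.nan, mp_total=value / 100.0, paw_mean=10.0, rce_est=0.8,
        rr_measured=15.0, t_start=t0, t_end=t1,
    )


class TestWindowAverage:
    def test_steady_stream_mean_equals_any_breath(self):
        stream = [_metric(i * 4.0, (i + 1) * 4.0, 500.0) for i in range(100)]
        avg = window_average(stream, window=300.0)
        assert avg.vt_exp == pytest.approx(500.0)

    def test_window_excludes_pre_step_breaths(self):
        # step change 400 s before the end of a 800 s stream
        stream = [
            _metric(i * 4.0, (i + 1) * 4.0, 400.0 if i * 4.0 < 400.0 else 600.0)
            for i in range(200)
        ]
        avg = window_average(stream, window=300.0)
        assert avg.vt_exp == pytest.approx(600.0)

    def test_alternating_breaths_average(self):
        stream = [
            _metric(i * 4.0, (i + 1) * 4.0, 400.0 if i % 2 else 600.0)
            for i in range(100)
        ]
        # 304 s window -> 76 breaths, an even split of the two values
        assert window_average(stream, window=304.0).vt_exp == pytest.approx(500.0)

    def test_short_stream_rejected(self):
        stream = [_metric(i * 4.0, (i + 1) * 4.0, 500.0) for i in range(10)]
        with pytest.raises(InsufficientDataError):
            window_average(stream, window=300.0)
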