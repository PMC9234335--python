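"""Thermogram integration and the single-site (Wiseman) isotherm fit."""

import dataclasses

import numpy as np
import pytest

from specbind import (
    ITCGroundTruth,
    fit_one_site,
    gen_itc_experiment,
    integrate_injections,
    one_site_heats,
    subtract_control,
)
from specbind.itc import ITCThermogram

PAPER_GEOMETRY = dict(cell_volume=300e-6, cell_conc=30e-6, syringe_conc=600e-6)
VOLS20 = np.full(20, 2e-6)


class TestForwardModel:
    def test_zero_enthalpy_gives_zero_heats(self):
        heats = one_site_heats(1.0, 1e5, 0.0, injection_volumes=VOLS20, **PAPER_GEOMETRY)
        assert np.allclose(heats, 0.0)

    def test_stoichiometric_limit_first_injection(self):
        # binding so tight every injected mole binds: heat = dH x injected moles
        heats = one_site_heats(1.0, 1e12, -20.0, injection_volumes=VOLS20,
                               **PAPER_GEOMETRY)
        assert heats[0] == pytest.approx(-24.0, rel=1e-3)

    def test_cumulative_conservation(self):
        # sum of per-injection heats telescopes back to the cumulative heat
        # plus the displaced-volume half-sum terms
        n, ka, dh = 1.2, 5e4, -15.0
        heats = one_site_heats(n, ka, dh, injection_volumes=VOLS20, **PAPER_GEOMETRY)
        v0 = PAPER_GEOMETRY["cell_volume"]
        dv = np.cumsum(VOLS20)
        m = PAPER_GEOMETRY["cell_conc"] * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0))
        x = PAPER_GEOMETRY["syringe_conc"] * (dv / v0) / (1 + dv / (2 * v0))
        b = 1 + x / (n * m) + 1 / (ka * n * m)
        theta = (b - np.sqrt(b * b - 4 * x / (n * m))) / 2
        q = n * theta * m * v0 * dh * 1000.0
        q_prev = np.concatenate([[0.0], q[:-1]])
        displaced = np.sum((VOLS20 / v0) * (q + q_prev) / 2)
        assert np.sum(heats) * 1e-6 == pytest.approx(q[-1] + displaced, rel=1e-12)


class TestIntegration:
    def test_pulse_areas_recovered_from_thermogram(self):
        truth = ITCGroundTruth()
        tg = gen_itc_experiment(truth, seed=0)
        heats = integrate_injections(tg)
        expected = one_site_heats(truth.n_sites, truth.ka, truth.dh,
                                  truth.cell_volume, truth.cell_conc,
                                  truth.syringe_conc, VOLS20)
        assert np.allclose(heats.heats_uJ, expected, rtol=1e-3)

    def test_flat_trace_integrates_to_zero(self):
        t = np.arange(0.0, 2000.0, 1.0)
        tg = ITCThermogram(time=t, power=np.zeros_like(t),
                           injections=tuple((100.0 + 200.0 * i, 2e-6) for i in range(8)),
                           **PAPER_GEOMETRY)
        assert np.allclose(integrate_injections(tg).heats_uJ, 0.0)

    def test_final_molar_ratio_matches_protocol_stoichiometry(self):
        # 20 x 2 µL of 600 µM into 300 µL of 30 µM -> 24 nmol / 9 nmol
        tg = gen_itc_experiment(ITCGroundTruth(), seed=0)
        heats = integrate_injections(tg)
        assert heats.molar_ratio[-1] == pytest.approx(2.67, abs=0.005)

    def test_overlapping_baseline_window_refused(self):
        tg = gen_itc_experiment(ITCGroundTruth(), seed=0)
        with pytest.raises(ValueError):
            integrate_injections(tg, baseline_window=500.0)


class TestControlSubtraction:
    def _heats(self, **kw):
        truth = ITCGroundTruth(**kw)
        return integrate_injections(gen_itc_experiment(truth, seed=3))

    def test_identical_control_zeroes_heats(self):
        heats = self._heats()
        out = subtract_control(heats, heats)
        assert np.allclose(out.heats_uJ, 0.0)

    def test_zero_control_is_identity(self):
        heats = self._heats()
        zero = dataclasses.replace(heats, heats_uJ=np.zeros_like(heats.heats_uJ))
        out = subtract_control(heats, zero)
        assert np.allclose(out.heats_uJ, heats.heats_uJ)

    def test_constant_dilution_control_restores_binding_model(self):
        sample = self._heats(dilution_heat=-2.0)
        control = self._heats(dh=0.0, dilution_heat=-2.0)
        corrected = subtract_control(sample, control)
        pure = one_site_heats(1.0, 1e5, -20.0, injection_volumes=VOLS20,
                              **PAPER_GEOMETRY)
        assert np.allclose(corrected.heats_uJ, pure, atol=0.02)

    def test_count_mismatch_refused(self):
        a = self._heats()
        b = integrate_injections(gen_itc_experiment(ITCGroundTruth(n_injections=10),
                                                    seed=0))
        with pytest.raises(ValueError):
            subtract_control(a, b)


class TestOneSiteFit:
    def test_noiseless_round_trip(self):
        truth = ITCGroundTruth()
        heats = integrate_injections(gen_itc_experiment(truth, seed=0))
        fit = fit_one_site(heats, **PAPER_GEOMETRY)
        assert fit.n_sites == pytest.approx(1.0, rel=5e-3)
        assert fit.ka == pytest.approx(1e5, rel=5e-3)
        assert fit.dh == pytest.approx(-20.0, rel=5e-3)

    def test_dilution_offset_recovered(self):
        truth = ITCGroundTruth(dilution_heat=-1.5)
        heats = integrate_injections(gen_itc_experiment(truth, seed=0))
        fit = fit_one_site(heats, **PAPER_GEOMETRY)
        assert fit.dilution_heat == pytest.approx(-1.5, abs=0.05)
        assert fit.ka == pytest.approx(1e5, rel=1e-2)

    def test_derived_dg_ds_invariants(self):
        heats = integrate_injections(gen_itc_experiment(ITCGroundTruth(), seed=0))
        fit = fit_one_site(heats, temperature=298.0, **PAPER_GEOMETRY)
        assert fit.dg == pytest.approx(-8.314 * 298.0 * np.log(fit.ka) / 1000.0)
        assert fit.ds == pytest.approx((fit.dh - fit.dg) * 1000.0 / 298.0)

    def test_null_signal_flagged(self):
        truth = ITCGroundTruth(dh=0.0)
        heats = integrate_injections(gen_itc_experiment(truth, seed=0))
        with pytest.warns(UserWarning, match="null signal or saturated"):
            fit = fit_one_site(heats, **PAPER_GEOMETRY)
        assert abs(fit.dh) < 0.5
        assert fit.warnings

    def test_time_shift_invariance(self):
        truth = ITCGroundTruth()
        tg = gen_itc_experiment(truth, seed=0)
        shifted = ITCThermogram(
            time=tg.time + 5000.0, power=tg.power,
            injections=tuple((t + 5000.0, v) for t, v in tg.injections),
            cell_volume=tg.cell_volume, cell_conc=tg.cell_conc,
            syringe_conc=tg.syringe_conc, temperature=tg.temperature,
        )
        f1 = fit_one_site(integrate_injections(tg), **PAPER_GEOMETRY)
        f2 = fit_one_site(integrate_injections(shifted), **PAPER_GEOMETRY)
        assert f1.ka == pytest.approx(f2.ka, rel=1e-9)
        assert f1.dh == pytest.approx(f2.dh, rel=1e-9)

    def test_grid_search_oracle_agreement(self):
        # coarse 3-D grid over (n, log Ka, dH): the least-squares optimum
        # must beat or match every grid node on the same residuals
        truth = ITCGroundTruth()
        heats = integrate_injections(gen_itc_experiment(truth, seed=0))
        fit = fit_one_site(heats, **PAPER_GEOMETRY)

        def sse(n, ka, dh):
            model = one_site_heats(n, ka, dh, injection_volumes=VOLS20,
                                   **PAPER_GEOMETRY)
            return float(np.sum((model - heats.heats_uJ) ** 2))

        ns = np.linspace(0.5, 2.0, 7)
        log_kas = np.linspace(4.0, 6.0, 9)
        dhs = np.linspace(-30.0, -10.0, 9)
        grid_best = min(
            ((n, lk, dh) for n in ns for lk in log_kas for dh in dhs),
            key=lambda p: sse(p[0], 10 ** p[1], p[2]),
        )
        # best grid node lies within one grid cell of the fit optimum
        assert abs(grid_best[0] - fit.n_sites) <= np.diff(ns)[0]
        assert abs(grid_best[1] - np.log10(fit.ka)) <= np.diff(log_kas)[0]
        assert abs(grid_best[2] - fit.dh) <= np.diff(dhs)[0]
        assert sse(fit.n_sites, fit.ka, fit.dh) <= sse(
            grid_best[0], 10 ** grid_best[1], grid_best[2]
        ) + 1e-9
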