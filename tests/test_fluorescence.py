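"""Stern-Volmer and double-logarithm fits, mechanism calls, EEM peaks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from specbind import (
    EEMPeak,
    QuenchModel,
    TitrationSeries,
    classify_mechanism,
    double_log_fit,
    eem_peak_extract,
    gen_eem_surface,
    gen_quench_titration,
    stern_volmer_fit,
)
from specbind.fluorescence import QuenchingResult


def make_result(ksv, temperature, tau0=1e-8):
    return QuenchingResult(ksv=ksv, kq=ksv / tau0, intercept=1.0, r_squared=1.0,
                           temperature=temperature, tau0=tau0)


class TestSternVolmer:
    def test_exact_recovery_on_noiseless_static_data(self, quench_concentrations):
        model = QuenchModel(f0=1000.0, mode="static", ksv=1.0e4)
        series = gen_quench_titration(model, quench_concentrations)
        res = stern_volmer_fit(series)
        assert res.ksv == pytest.approx(1.0e4, rel=1e-9)
        assert res.kq == pytest.approx(1.0e12, rel=1e-9)
        assert res.intercept == pytest.approx(1.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_intensity_gives_zero_ksv(self, quench_concentrations):
        series = TitrationSeries(quench_concentrations,
                                 np.full(quench_concentrations.size, 800.0), 298.0)
        res = stern_volmer_fit(series)
        assert res.ksv == pytest.approx(0.0, abs=1e-9)
        assert res.kq == pytest.approx(0.0, abs=1e-3)

    def test_sensitization_yields_negative_slope(self, quench_concentrations):
        model = QuenchModel(mode="sensitization", ksv=-5e3)
        series = gen_quench_titration(model, quench_concentrations)
        res = stern_volmer_fit(series)
        assert res.ksv < 0

    def test_kq_equals_ksv_over_tau0_exactly(self, quench_concentrations):
        series = gen_quench_titration(QuenchModel(ksv=3.1e4), quench_concentrations)
        res = stern_volmer_fit(series, tau0=2e-8)
        assert res.kq == res.ksv / 2e-8

    def test_refuses_too_few_points(self):
        with pytest.raises(ValueError):
            TitrationSeries(np.array([0.0, 1e-6]), np.array([1000.0, 900.0]), 298.0)

    def test_refuses_nonpositive_intensity(self, quench_concentrations):
        bad = np.linspace(1000.0, -10.0, quench_concentrations.size)
        with pytest.raises(ValueError):
            TitrationSeries(quench_concentrations, bad, 298.0)


class TestDoubleLog:
    def test_exact_log_linear_recovery(self, quench_concentrations):
        series = gen_quench_titration(
            QuenchModel(mode="binding", ka=2e4, n_sites=1.0), quench_concentrations
        )
        res = double_log_fit(series)
        assert res.n_sites == pytest.approx(1.0, abs=1e-9)
        assert res.log10_ka == pytest.approx(np.log10(2e4), abs=1e-9)

    @pytest.mark.parametrize("ka,n", [(5e4, 1.2), (1e3, 0.8), (1e5, 1.0)])
    def test_round_trip_vs_generator(self, quench_concentrations, ka, n):
        series = gen_quench_titration(
            QuenchModel(mode="binding", ka=ka, n_sites=n), quench_concentrations
        )
        res = double_log_fit(series)
        assert res.ka == pytest.approx(ka, rel=1e-6)
        assert res.n_sites == pytest.approx(n, rel=1e-6)

    def test_agrees_with_stern_volmer_at_single_site(self, quench_concentrations):
        # the two forward models coincide at n=1, so K_a must equal K_SV
        series = gen_quench_titration(QuenchModel(mode="static", ksv=1e4),
                                      quench_concentrations)
        assert double_log_fit(series).ka == pytest.approx(
            stern_volmer_fit(series).ksv, rel=1e-6
        )

    def test_refuses_sensitization_series(self, quench_concentrations):
        series = gen_quench_titration(QuenchModel(mode="sensitization", ksv=-5e3),
                                      quench_concentrations)
        with pytest.raises(ValueError, match="quenching only"):
            double_log_fit(series)


class TestMechanism:
    @staticmethod
    def oracle(ksvs, kqs, threshold):
        """Independent re-statement of the rule ladder."""
        if all(k < 0 for k in ksvs):
            return "sensitization"
        above = all(abs(q) > threshold for q in kqs)
        if len(ksvs) == 1:
            return "static" if above else "dynamic"
        diffs = np.diff(ksvs)
        trend = ("increasing" if np.all(diffs > 0)
                 else "decreasing" if np.all(diffs < 0) else "none")
        if above:
            return "ambiguous" if trend == "increasing" else "static"
        if trend == "increasing":
            return "dynamic"
        if trend == "decreasing":
            return "static"
        return "ambiguous"

    @pytest.mark.parametrize("ksvs", [
        (3.1e4, 2.8e4, 2.5e4),   # static: huge kq, falling with T
        (-5e3, -4e3, -3e3),      # sensitization: enhancement at all T
        (1e1, 2e1, 3e1),         # dynamic: small kq, rising with T
        (3e1, 2e1, 1e1),         # static by trend despite small kq
        (2.5e4, 2.8e4, 3.1e4),   # conflict: kq says static, trend says dynamic
        (2e4, 3e4, 2.5e4),       # non-monotone
        (1e4,),                  # single temperature
        (5e0,),                  # single temperature, below threshold
    ])
    def test_matches_independent_rule_oracle(self, ksvs):
        temps = [288.0, 298.0, 308.0][: len(ksvs)]
        results = [make_result(k, t) for k, t in zip(ksvs, temps)]
        call = classify_mechanism(results)
        kqs = [k / 1e-8 for k in ksvs]
        assert call.label == self.oracle(list(ksvs), kqs, 2.0e10)
        assert len(call.evidence) >= 1

    def test_exhaustive_sign_threshold_trend_table(self):
        # every slope magnitude x ordering combination against the oracle
        magnitudes = [5e0, 5e4]  # kq below / above the diffusion ceiling
        for mag in magnitudes:
            for signs in [(1, 1, 1), (-1, -1, -1), (1, -1, 1)]:
                for order in [(1.0, 2.0, 3.0), (3.0, 2.0, 1.0), (1.0, 3.0, 2.0)]:
                    ksvs = [s * mag * o for s, o in zip(signs, order)]
                    if len(set(ksvs)) < 3:
                        continue
                    results = [make_result(k, t) for k, t in
                               zip(ksvs, (288.0, 298.0, 308.0))]
                    call = classify_mechanism(results)
                    assert call.label == self.oracle(ksvs, [k / 1e-8 for k in ksvs], 2e10)


class TestEEM:
    def test_single_peak_located_exactly(self):
        surface = gen_eem_surface([EEMPeak(280.0, 334.0, 500.0)])
        out = eem_peak_extract(surface, {"a": (260.0, 300.0, 310.0, 360.0)})
        assert out["a"]["excitation_nm"] == 280.0
        assert out["a"]["emission_nm"] == 334.0
        assert out["a"]["intensity"] == pytest.approx(500.0)

    def test_intensity_ratio_against_reference(self):
        strong = gen_eem_surface([EEMPeak(280.0, 334.0, 500.0)])
        weak = gen_eem_surface([EEMPeak(280.0, 334.0, 400.0)])
        out = eem_peak_extract(weak, {"a": (260.0, 300.0, 310.0, 360.0)},
                               reference=strong)
        assert out["a"]["intensity_ratio_vs_reference"] == pytest.approx(0.8)

    def test_empty_window_refused(self):
        surface = gen_eem_surface([EEMPeak(280.0, 334.0, 500.0)])
        with pytest.raises(ValueError):
            eem_peak_extract(surface, {"bad": (401.0, 402.0, 300.0, 310.0)})

    def test_noisy_peak_located_within_one_grid_step(self):
        hits = 0
        for seed in range(60):
            surface = gen_eem_surface([EEMPeak(280.0, 334.0, 500.0)],
                                      noise_sd=5.0, seed=seed)
            out = eem_peak_extract(surface, {"a": (260.0, 300.0, 310.0, 360.0)})
            if (abs(out["a"]["excitation_nm"] - 280.0) <= 5.0
                    and abs(out["a"]["emission_nm"] - 334.0) <= 2.0):
                hits += 1
        assert hits >= 57  # >= 95% of runs


@given(ksv=st.floats(min_value=-1e5, max_value=1e5, allow_nan=False),
       tau0=st.sampled_from([1e-8, 2e-8, 5e-9]))
def test_quenching_result_kq_invariant(ksv, tau0):
    res = make_result(ksv, 298.0, tau0)
    assert res.kq * tau0 == pytest.approx(res.ksv, rel=1e-12, abs=1e-12)
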