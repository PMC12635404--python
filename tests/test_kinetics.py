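"""Forward-model and T1-conversion behaviour of the two-pool system."""

import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hypermet as hm
from conftest import normalized_pair


class TestClosedForm:
    def test_no_conversion_gives_zero_product(self):
        params = hm.KineticParams(0.0, 30.0, 16.0, "apparent", S0=1.0, P0=0.0)
        out = hm.evolve_closed_form(params, None, np.arange(0.0, 100.0, 2.0))
        assert np.all(out.product_signal == 0.0)

    def test_degenerate_equal_rates_limit(self):
        # choose T1_p so that b = k + 1/T1_s exactly: L'Hopital branch
        k, t1s = 1e-4, 20.0
        t1p = 1.0 / (k + 1.0 / t1s)
        params = hm.KineticParams(k, t1s, t1p, "apparent", S0=2.0)
        t = np.arange(0.0, 200.0, 2.0)
        out = hm.evolve_closed_form(params, None, t)
        a = k + 1.0 / t1s
        expected = k * 2.0 * t * np.exp(-a * t)
        np.testing.assert_allclose(out.product_signal, expected, rtol=1e-12)
        # and the degenerate branch is continuous with the general form
        params_eps = hm.KineticParams(k, t1s, t1p * (1 + 1e-7), "apparent", S0=2.0)
        near = hm.evolve_closed_form(params_eps, None, t)
        np.testing.assert_allclose(near.product_signal, expected, rtol=1e-5)

    def test_matches_numerical_ode(self):
        params = hm.KineticParams(10.7e-5, 30.0, 16.0, "apparent", S0=1.0)
        t = np.arange(0.0, 241.0, 2.0)
        cf = hm.evolve_closed_form(params, None, t)
        ode = hm.evolve_ode(params, None, t, rel_tol=1e-12)
        for trace_cf, trace_ode in (
            (cf.substrate_signal, ode.substrate_signal),
            (cf.product_signal, ode.product_signal),
        ):
            scale = np.max(np.abs(trace_cf))
            assert np.max(np.abs(trace_cf - trace_ode)) / scale <= 1e-8

    def test_non_increasing_times_rejected(self):
        params = hm.KineticParams(1e-4, 30.0, 16.0, "apparent")
        with pytest.raises(ValueError, match="strictly increasing"):
            hm.evolve_closed_form(params, None, np.array([0.0, 2.0, 2.0]))

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            hm.KineticParams(-1e-4, 30.0, 16.0)
        with pytest.raises(ValueError):
            hm.KineticParams(1e-4, -30.0, 16.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        k=st.floats(0.0, 1e-3),
        t1s=st.floats(5.0, 60.0),
        t1p=st.floats(5.0, 60.0),
    )
    def test_closed_form_vs_ode_randomized(self, k, t1s, t1p):
        """Analytic and numerical solutions agree to 1e-8 over the parameter grid."""
        params = hm.KineticParams(k, t1s, t1p, "apparent", S0=1.0)
        t = np.linspace(0.0, 180.0, 91)
        cf = hm.evolve_closed_form(params, None, t)
        ode = hm.evolve_ode(params, None, t, rel_tol=1e-12)
        assert np.max(np.abs(cf.substrate_signal - ode.substrate_signal)) <= 1e-8
        scale = max(np.max(np.abs(cf.product_signal)), 1e-30)
        assert np.max(np.abs(cf.product_signal - ode.product_signal)) / scale <= 1e-8


class TestEvolveODE:
    def test_single_time_returns_initial_state(self):
        params = hm.KineticParams(1e-4, 30.0, 16.0, "apparent", S0=3.0, P0=0.5)
        out = hm.evolve_ode(params, None, np.array([0.0]))
        assert out.substrate_signal[0] == 3.0 and out.product_signal[0] == 0.5

    def test_equal_t1_no_conversion_symmetry(self):
        params = hm.KineticParams(0.0, 25.0, 25.0, "apparent", S0=2.0, P0=0.7)
        out = hm.evolve_ode(params, None, np.arange(0.0, 120.0, 2.0))
        np.testing.assert_allclose(
            out.substrate_signal / 2.0, out.product_signal / 0.7, rtol=1e-9
        )


class TestDiscretePulses:
    def test_zero_flip_records_nothing_and_preserves_evolution(self):
        true = hm.KineticParams(1e-4, 38.0, 17.0, "true", S0=1.0)
        acq = hm.AcquisitionParams(0.0, 1.0, 60)
        out = hm.simulate_discrete_pulses(true, acq)
        assert np.all(out.substrate_signal == 0.0) and np.all(out.product_signal == 0.0)
        # longitudinal state after the run equals undisturbed evolution
        free = dataclasses.replace(true, T1_mode="apparent")
        t_end = acq.scan_times()[-1] + acq.repetition_time_s
        ref = hm.evolve_closed_form(free, None, np.array([0.0, t_end]))
        S_end, P_end = out.meta["longitudinal_final"]
        np.testing.assert_allclose([S_end, P_end], [ref.substrate_signal[-1], ref.product_signal[-1]], rtol=1e-12)

    def test_pure_rf_depletion_is_geometric(self):
        # no relaxation, no conversion: signal drops by cos(pw) per scan
        true = hm.KineticParams(0.0, np.inf, np.inf, "true", S0=1.0)
        acq = hm.AcquisitionParams(12.0, 1.0, 50)
        out = hm.simulate_discrete_pulses(true, acq)
        ratio = out.substrate_signal[1:] / out.substrate_signal[:-1]
        np.testing.assert_allclose(ratio, np.cos(np.radians(12.0)), rtol=1e-12)

    def test_conservation_without_losses(self):
        true = hm.KineticParams(5e-3, np.inf, np.inf, "true", S0=1.0, P0=0.1)
        acq = hm.AcquisitionParams(0.0, 1.0, 100)
        out = hm.simulate_discrete_pulses(true, acq)
        S_end, P_end = out.meta["longitudinal_final"]
        np.testing.assert_allclose(S_end + P_end, 1.1, rtol=1e-12)

    def test_apparent_t1_approximation_example(self, acq_8deg_1s):
        """38 s true T1 sampled at 8 deg / TR 1 s decays with ~28 s apparent T1."""
        true = hm.KineticParams(0.0, 38.0, 17.0, "true", S0=1.0)
        out = hm.simulate_discrete_pulses(true, acq_8deg_1s)
        t1_app = hm.apparent_from_true_t1(38.0, acq_8deg_1s)
        assert t1_app == pytest.approx(28.0, abs=0.5)
        rec = out.substrate_signal / out.substrate_signal[0]
        mono = np.exp(-acq_8deg_1s.scan_times() / t1_app)
        assert np.max(np.abs(rec - mono)) <= 0.01

    @pytest.mark.parametrize(
        "pw,tr", [(5.0, 1.0), (10.0, 2.0), (20.0, 1.0), (20.0, 2.0)]
    )
    def test_discrete_vs_apparent_model_within_1pct(self, pw, tr):
        """The continuous apparent-T1 model tracks the pulse-by-pulse physics."""
        for t1s, t1p, k in itertools.product([9.0, 30.0], [9.0, 17.0], [0.0, 1e-4]):
            acq = hm.AcquisitionParams(pw, tr, 120)
            true = hm.KineticParams(k, t1s, t1p, "true", S0=1.0)
            disc = hm.simulate_discrete_pulses(true, acq)
            app = hm.KineticParams(
                k,
                hm.apparent_from_true_t1(t1s, acq),
                hm.apparent_from_true_t1(t1p, acq),
                "apparent",
                S0=1.0,
            )
            cont = hm.evolve_closed_form(app, None, acq.scan_times())
            ds, dp = normalized_pair(disc)
            cs, cp = normalized_pair(cont)
            # recorded signals carry a sin(pw) factor; pair normalization removes it
            assert np.max(np.abs(ds - cs)) <= 0.01
            assert np.max(np.abs(dp - cp)) <= 0.01

    def test_flip_angle_90_rejected(self):
        with pytest.raises(ValueError):
            hm.AcquisitionParams(90.0, 1.0, 10)

    def test_product_peak_monotone_in_k(self):
        acq = hm.AcquisitionParams(8.0, 1.0, 120)
        peaks = []
        for k in np.linspace(0.0, 5e-4, 8):
            params = hm.KineticParams(k, 30.0, 16.0, "apparent", S0=1.0)
            out = hm.evolve_closed_form(params, None, acq.scan_times())
            peaks.append(np.max(out.product_signal))
        assert np.all(np.diff(peaks) >= 0)


class TestT1Conversions:
    def test_paper_corrections(self, acq_8deg_1s, acq_15deg_1s):
        """Apparent 28 s at 8 deg -> ~38 s; apparent 17 s at 15 deg -> ~41 s."""
        t1_pyr = hm.correct_t1_apparent(28.0, acq_8deg_1s)
        assert t1_pyr == pytest.approx(38.5, abs=0.05)
        t1_lac = hm.correct_t1_apparent(17.0, acq_15deg_1s)
        assert t1_lac == pytest.approx(40.4, abs=0.05)

    def test_zero_flip_is_identity(self):
        acq = hm.AcquisitionParams(0.0, 1.0, 10)
        assert hm.correct_t1_apparent(23.0, acq) == pytest.approx(23.0, rel=1e-15)
        assert hm.apparent_from_true_t1(23.0, acq) == pytest.approx(23.0, rel=1e-15)

    def test_infeasible_apparent_t1_rejected(self):
        # pulsing losses alone imply a faster decay than the given apparent T1
        acq = hm.AcquisitionParams(30.0, 1.0, 10)  # p ~ 0.134 /s
        with pytest.raises(ValueError, match="pulsing rate"):
            hm.correct_t1_apparent(20.0, acq)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        t1=st.floats(1.0, 200.0),
        pw=st.floats(0.0, 60.0),
        tr=st.floats(0.5, 5.0),
    )
    def test_round_trip_identity(self, t1, pw, tr):
        acq = hm.AcquisitionParams(pw, tr, 10)
        t1_app = hm.apparent_from_true_t1(t1, acq)
        assert hm.correct_t1_apparent(t1_app, acq) == pytest.approx(t1, rel=1e-12)


class TestDynamicSeriesCSV:
    def test_round_trip(self, tmp_path, day7_series):
        path = tmp_path / "series.csv"
        day7_series.to_csv(path)
        back = hm.DynamicSeries.from_csv(path)
        np.testing.assert_array_equal(back.times_s, day7_series.times_s)
        np.testing.assert_array_equal(back.substrate_signal, day7_series.substrate_signal)
        np.testing.assert_array_equal(back.product_signal, day7_series.product_signal)

    def test_shuffled_columns_parse_by_header(self, tmp_path):
        path = tmp_path / "shuffled.csv"
        path.write_text("product,time_s,substrate\n0.1,0,1\n0.2,1,0.9\n")
        s = hm.DynamicSeries.from_csv(path)
        np.testing.assert_array_equal(s.substrate_signal, [1.0, 0.9])
        np.testing.assert_array_equal(s.product_signal, [0.1, 0.2])

    def test_bad_header_and_truncation_diagnosed(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(ValueError, match="header"):
            hm.DynamicSeries.from_csv(bad)
        trunc = tmp_path / "trunc.csv"
        trunc.write_text("time_s,substrate,product\n0,1\n")
        with pytest.raises(ValueError, match="line 2"):
            hm.DynamicSeries.from_csv(trunc)
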