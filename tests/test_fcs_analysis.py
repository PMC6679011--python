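import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleophys import (
    D_RH6G,
    D_to_tau,
    DetectionVolume,
    FAFCurve,
    IntensityTrace,
    SimSpec,
    autocorrelate,
    average_fafs,
    calibrate_D,
    characteristic_D,
    faf_model,
    fit_faf,
    model_gtau,
    select_model,
    simulate_trace,
    tau_to_D,
)
from nucleophys.fcs_analysis import FitResult, multi_tau_lag_set

from conftest import direct_g


def make_fit(n_components, tau_d, fractions=None, D=None, N=2.0):
    return FitResult(
        n_components=n_components,
        N=N,
        fractions=tuple(fractions or ([1.0] if n_components == 1 else [0.5, 0.5])),
        tau_d=tuple(tau_d),
        s=5.0,
        triplet=None,
        D=tuple(D) if D else None,
        rss=0.0,
        red_chi2=0.0,
        n_points=50,
    )


class TestAutocorrelate:
    def test_constant_trace_gives_flat_one(self):
        tr = IntensityTrace(counts=np.full(200, 7.0), dt=1e-5)
        c = autocorrelate(tr, scheme="direct", lags=[1, 2, 5])
        assert np.allclose(c.g, 1.0)

    def test_zero_trace_rejected(self):
        tr = IntensityTrace(counts=np.zeros(200), dt=1e-5)
        with pytest.raises(ValueError, match="zero mean"):
            autocorrelate(tr, scheme="direct", lags=[1])

    def test_alternating_trace_oracle_values(self):
        """2,0,2,0,... has G(dt) = 0 and G(2 dt) = 2 by direct summation."""
        tr = IntensityTrace(counts=np.tile([2.0, 0.0], 100), dt=1e-5)
        c = autocorrelate(tr, scheme="direct", lags=[1, 2])
        assert c.g[0] == pytest.approx(0.0, abs=1e-12)
        assert c.g[1] == pytest.approx(2.0, rel=1e-12)

    def test_level0_multitau_identical_to_direct(self, short_trace):
        """Unbinned multi-tau lags coincide exactly with direct sums."""
        mt = autocorrelate(short_trace, scheme="multi_tau", m=16)
        dc = autocorrelate(short_trace, scheme="direct", lags=list(range(1, 17)))
        sel = np.isin(mt.lags, dc.lags)
        assert np.allclose(mt.g[sel], dc.g, rtol=1e-12, atol=0)

    def test_multitau_equals_triangular_average_of_direct(self, volume):
        """At binned levels the multi-tau estimate equals the triangularly
        weighted average of direct autocorrelations over the bin window
        (up to end-of-trace truncation terms)."""
        tr = simulate_trace(SimSpec(duration=0.004, seed=5), volume)  # 2000 samples
        mt = autocorrelate(tr, scheme="multi_tau", m=16)
        for lag, g in zip(mt.lags, mt.g):
            k = int(round(lag / tr.dt))
            b = 1
            while (k // b) > 16:
                b *= 2
            if b == 1:
                ref = direct_g(tr.counts, k)
            else:
                js = np.arange(-(b - 1), b)
                wts = (b - np.abs(js)) / b**2
                ref = sum(w * direct_g(tr.counts, k + j) for j, w in zip(js, wts))
            assert g == pytest.approx(ref, abs=5e-3)

    def test_lag_set_quasi_logarithmic(self):
        lags = multi_tau_lag_set(10_000, m=16)
        assert lags[0] == 1
        assert np.all(np.diff(lags) > 0)
        # past the unbinned level the relative spacing stays in (1/16, 1/8]
        coarse = lags[lags > 16].astype(float)
        rel = np.diff(coarse) / coarse[:-1]
        assert np.all(rel <= 1 / 8 + 1e-9)
        assert np.all(rel > 1 / 17)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            autocorrelate(IntensityTrace(counts=np.arange(10.0) + 1, dt=1e-5))


class TestAverageFafs:
    def test_identical_curves_average_to_themselves_sd_zero(self):
        c = model_gtau(np.geomspace(1e-6, 1e-2, 40), N=2.0)
        avg = average_fafs([c] * 5)
        assert np.allclose(avg.g, c.g)
        assert np.allclose(avg.sd, 0.0)

    def test_mirror_curves_average_to_flat_one(self):
        lags = np.geomspace(1e-6, 1e-2, 40)
        c = model_gtau(lags, N=2.0)
        mirror = FAFCurve(lags=lags, g=2.0 - c.g)
        avg = average_fafs([c, mirror])
        assert np.allclose(avg.g, 1.0)

    def test_mismatched_grids_rejected(self):
        a = model_gtau(np.geomspace(1e-6, 1e-2, 40), N=2.0)
        b = model_gtau(np.geomspace(1e-6, 1e-2, 41), N=2.0)
        with pytest.raises(ValueError, match="lag grid"):
            average_fafs([a, b])

    def test_averaging_replicates_reduces_fit_scatter(self, volume):
        """Fits of 5-replicate averaged curves scatter less across seeds
        than single-replicate fits."""
        from nucleophys import replicate_traces

        single, averaged = [], []
        for seed in range(4):
            spec = SimSpec(duration=0.5, seed=300 + seed)
            reps = replicate_traces(spec, volume, n_reps=5, rep_duration=0.1)
            curves = [autocorrelate(t) for t in reps]
            single.append(fit_faf(curves[0]).tau_d[0])
            averaged.append(fit_faf(average_fafs(curves)).tau_d[0])
        assert np.std(averaged) < np.std(single)


class TestModel:
    def test_amplitude_limit_one_component(self):
        g = faf_model(np.array([1e-19]), N=2.0, fractions=[1.0], tau_d=[1e-4])
        assert g[0] == pytest.approx(1.0 + 0.5, rel=1e-14)

    def test_closed_form_at_tau_equals_taud_large_s(self):
        g = faf_model(np.array([1e-4]), N=1.0, fractions=[1.0], tau_d=[1e-4], s=1e9)
        assert g[0] == pytest.approx(1.5, rel=1e-9)

    def test_two_component_linearity(self):
        lags = np.geomspace(1e-6, 1e-1, 50)
        mix = faf_model(lags, N=2.0, fractions=[0.5, 0.5], tau_d=[1e-4, 1e-2])
        a = faf_model(lags, N=2.0, fractions=[1.0], tau_d=[1e-4])
        b = faf_model(lags, N=2.0, fractions=[1.0], tau_d=[1e-2])
        # the mixture equals the pointwise mean of the two pure curves at the same N
        assert np.allclose(mix, 0.5 * a + 0.5 * b)

    def test_triplet_raises_short_lag_amplitude(self):
        g = faf_model(np.array([1e-19]), N=1.0, fractions=[1.0], tau_d=[1e-4],
                      triplet=(0.2, 1e-6))
        assert g[0] == pytest.approx(1.0 + 1.0 / 0.8, rel=1e-12)

    def test_model_monotone_nonincreasing_without_triplet(self):
        lags = np.geomspace(1e-7, 1.0, 200)
        g = faf_model(lags, N=1.5, fractions=[0.3, 0.7], tau_d=[1e-4, 1e-2])
        assert np.all(np.diff(g) <= 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            faf_model(np.array([1e-4]), N=1.0, fractions=[1.0], tau_d=[-1e-4])
        with pytest.raises(ValueError):
            faf_model(np.array([1e-4]), N=1.0, fractions=[1.0], tau_d=[1e-4], s=0.0)


class TestFit:
    def test_noise_free_one_component_recovered_exactly(self):
        lags = np.geomspace(2e-6, 5e-2, 80)
        curve = model_gtau(lags, N=2.0, tau_d=[1e-4], s=5.0)
        fit = fit_faf(curve, n_components=1, s_policy=("fixed", 5.0))
        assert fit.N == pytest.approx(2.0, rel=1e-6)
        assert fit.tau_d[0] == pytest.approx(1e-4, rel=1e-6)

    def test_noise_free_two_component_recovered(self):
        lags = np.geomspace(2e-6, 5e-1, 120)
        curve = model_gtau(lags, N=2.0, fractions=[0.5, 0.5], tau_d=[1e-4, 5e-3], s=5.0)
        fit = fit_faf(curve, n_components=2, s_policy=("fixed", 5.0))
        assert fit.tau_d[0] == pytest.approx(1e-4, rel=0.01)
        assert fit.tau_d[1] == pytest.approx(5e-3, rel=0.01)

    def test_simulated_trace_amplitude_recovers_n(self, short_trace, volume):
        curve = autocorrelate(short_trace)
        fit = fit_faf(curve, w=volume.w)
        assert 1.0 / fit.N == pytest.approx(0.5, rel=0.15)
        assert fit.D is not None and fit.D[0] > 0

    def test_needs_ten_lag_points(self):
        curve = model_gtau(np.geomspace(1e-6, 1e-3, 5), N=1.0)
        with pytest.raises(ValueError, match="10 lag"):
            fit_faf(curve)

    def test_weighted_fit_uses_replicate_sd(self):
        lags = np.geomspace(2e-6, 5e-2, 60)
        g = faf_model(lags, N=2.0, fractions=[1.0], tau_d=[1e-4])
        curve = FAFCurve(lags=lags, g=g, sd=np.full_like(lags, 0.01))
        fit = fit_faf(curve)
        assert fit.tau_d[0] == pytest.approx(1e-4, rel=1e-4)


class TestSelectModel:
    def test_pure_one_component_curve_selects_one(self):
        lags = np.geomspace(2e-6, 5e-2, 80)
        curve = model_gtau(lags, N=2.0, tau_d=[1e-4])
        fit = select_model(curve)
        assert fit.n_components == 1

    def test_single_candidate_returned_unconditionally(self):
        lags = np.geomspace(2e-6, 5e-2, 80)
        curve = model_gtau(lags, N=2.0, fractions=[0.5, 0.5], tau_d=[1e-4, 5e-3])
        assert select_model(curve, candidates={1}).n_components == 1
        assert select_model(curve, candidates={2}).n_components == 2

    def test_clear_mixture_selects_two_components(self, volume):
        spec = SimSpec(components=((30.0, 0.5), (1.0, 0.5)), duration=1.0, seed=77)
        curve = autocorrelate(simulate_trace(spec, volume))
        fit = select_model(curve, w=volume.w)
        assert fit.n_components == 2


class TestConversionsAndCalibration:
    def test_tau_to_d_worked_example(self):
        assert tau_to_D(2e-4, w=0.2) == pytest.approx(50.0)

    @given(d=st.sampled_from([0.1, 1.0, 280.0]), w=st.floats(0.05, 1.0))
    @settings(derandomize=True, max_examples=30)
    def test_roundtrip_identity(self, d, w):
        assert tau_to_D(D_to_tau(d, w), w) == pytest.approx(d, rel=1e-12)

    def test_doubling_w_quadruples_d(self):
        assert tau_to_D(1e-4, 0.4) == pytest.approx(4 * tau_to_D(1e-4, 0.2))

    def test_reference_dye_constant_returned_at_equal_taus(self):
        assert calibrate_D(3e-5, 3e-5) == 280.0
        assert D_RH6G == 280.0

    def test_calibration_proportionality(self):
        assert calibrate_D(6e-5, 3e-5) == pytest.approx(140.0)

    def test_calibration_consistent_with_waist_conversion(self):
        """calibrate_D equals tau_to_D when w is set from the reference:
        w = sqrt(4 D_ref tau_ref)."""
        tau_ref, tau_probe = 3e-5, 2e-4
        w = np.sqrt(4 * D_RH6G * tau_ref)
        assert calibrate_D(tau_probe, tau_ref) == pytest.approx(
            tau_to_D(tau_probe, w), rel=1e-12
        )

    def test_nonpositive_inputs_rejected(self):
        for fn, args in [
            (tau_to_D, (0.0, 0.2)),
            (tau_to_D, (1e-4, -1.0)),
            (calibrate_D, (0.0, 1e-5)),
        ]:
            with pytest.raises(ValueError):
                fn(*args)


class TestCharacteristicD:
    def test_one_component_returns_its_d(self):
        fit = make_fit(1, tau_d=[1e-4], fractions=[1.0], D=[12.0])
        assert characteristic_D(fit, "nucleolus") == 12.0

    def test_nucleolus_reports_slow_component(self):
        fit = make_fit(2, tau_d=[3e-4, 3e-3], D=[30.0, 3.0])
        assert characteristic_D(fit, "nucleolus") == 3.0

    def test_tied_components_unambiguous(self):
        fit = make_fit(2, tau_d=[2e-3, 2e-3], D=[5.0, 5.0])
        assert characteristic_D(fit, "nucleolus") == 5.0

    def test_other_compartments_fraction_weighted(self):
        fit = make_fit(2, tau_d=[3e-4, 3e-3], fractions=[0.25, 0.75], D=[30.0, 3.0])
        assert characteristic_D(fit, "nucleoplasm") == pytest.approx(0.25 * 30 + 0.75 * 3)

    def test_requires_d_values(self):
        fit = make_fit(1, tau_d=[1e-4], fractions=[1.0])
        with pytest.raises(ValueError):
            characteristic_D(fit)
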