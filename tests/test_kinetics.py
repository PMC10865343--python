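import numpy as np
import pytest

from nullelab.kinetics import (
    CensoredHalfTimeError,
    DoseResponse,
    HillFit,
    KineticTrace,
    NoTransitionError,
    dose_response,
    extract_half_time,
    half_time,
    hill_fit,
    kic50,
    normalize_trace,
    normalized_half_time,
    read_traces_csv,
    write_traces_csv,
)
from nullelab.synthetic import TraceSpec, gen_dose_series, gen_kinetic_trace


def logistic_trace(t_half=20.0, k=1.5, scale=1.0, offset=0.0, t_max=60.0, n=121, conc=0.0):
    t = np.linspace(0, t_max, n)
    y = offset + scale / (1.0 + np.exp(-k * (t - t_half)))
    return KineticTrace(times=t, signal=y, concentration_um=conc)


class TestTraceValidation:
    def test_too_few_points(self):
        with pytest.raises(ValueError):
            KineticTrace(times=[0, 1, 2, 3], signal=[0, 0, 1, 1])

    def test_non_increasing_times(self):
        with pytest.raises(ValueError):
            KineticTrace(times=[0, 1, 1, 2, 3], signal=np.zeros(5))


class TestNormalizeTrace:
    def test_idempotent_on_unit_sigmoid(self):
        tr = logistic_trace()
        norm = normalize_trace(tr)
        assert np.allclose(norm.signal, tr.signal, atol=1e-9)

    def test_affine_invariance(self):
        a = normalize_trace(logistic_trace())
        b = normalize_trace(logistic_trace(scale=5000.0, offset=300.0))
        assert np.allclose(a.signal, b.signal, atol=1e-9)

    def test_flat_trace_flagged(self):
        tr = KineticTrace(times=np.arange(10.0), signal=np.full(10, 3.0))
        with pytest.raises(NoTransitionError):
            normalize_trace(tr)


class TestHalfTime:
    @pytest.mark.parametrize("planted", [5.0, 12.5, 20.0, 35.0, 50.0])
    def test_recovers_planted_crossing(self, planted):
        tr = logistic_trace(t_half=planted, t_max=60.0, n=241)
        res = extract_half_time(tr)
        assert res.defined and res.t_half == pytest.approx(planted, abs=0.1)

    def test_already_above_half_censored_at_start(self):
        tr = KineticTrace(times=np.arange(5.0), signal=np.array([0.8, 0.9, 0.95, 1.0, 1.0]))
        assert half_time(tr).censored == "start"

    def test_never_crossing_censored_at_end(self):
        tr = KineticTrace(times=np.arange(5.0), signal=np.array([0.0, 0.1, 0.2, 0.3, 0.4]))
        res = half_time(tr)
        assert res.censored == "end" and res.t_half == 4.0

    def test_time_shift_equivariance(self):
        base = logistic_trace(t_half=20.0, t_max=80.0, n=321)
        shifted = KineticTrace(times=base.times + 5.0, signal=base.signal)
        assert extract_half_time(shifted).t_half == pytest.approx(
            extract_half_time(base).t_half + 5.0, abs=1e-6
        )


class TestNormalizedHalfTime:
    def test_control_vs_itself(self):
        r = extract_half_time(logistic_trace())
        assert normalized_half_time(r, r) == 1.0

    def test_direct_ratio_and_sign_convention(self):
        sample = extract_half_time(logistic_trace(t_half=30.0, t_max=90.0, n=361))
        control = extract_half_time(logistic_trace(t_half=20.0, t_max=90.0, n=361))
        ratio = normalized_half_time(sample, control)
        assert ratio == pytest.approx(1.5, rel=1e-3)
        assert ratio > 1  # inhibitor slows aggregation

    def test_censored_propagates(self):
        censored = half_time(
            KineticTrace(times=np.arange(5.0), signal=np.array([0.8, 0.9, 1.0, 1.0, 1.0]))
        )
        ok = extract_half_time(logistic_trace())
        with pytest.raises(CensoredHalfTimeError):
            normalized_half_time(censored, ok)


class TestDoseResponse:
    def test_control_anchored_at_100(self):
        traces = gen_dose_series(25.0)
        dr = dose_response(traces)
        assert dr.rates[dr.concentrations == 0][0] == pytest.approx(100.0)

    def test_reciprocal_ratios(self):
        control = logistic_trace(t_half=20.0, t_max=160.0, n=641)
        doubled = logistic_trace(t_half=40.0, t_max=160.0, n=641, conc=10.0)
        one_and_half = logistic_trace(t_half=30.0, t_max=160.0, n=641, conc=5.0)
        dr = dose_response([doubled, one_and_half], control)
        by_conc = dict(zip(dr.concentrations, dr.rates))
        assert by_conc[10.0] == pytest.approx(50.0, rel=1e-3)
        assert by_conc[5.0] == pytest.approx(66.67, rel=1e-3)

    def test_fully_inhibited_concentration_excluded(self):
        control = logistic_trace(t_half=20.0, t_max=60.0, n=241)
        # full inhibition: no transition within the observed window
        flat = KineticTrace(times=control.times, signal=np.full(241, 0.01),
                            concentration_um=50.0)
        dr = dose_response([flat], control)
        assert 50.0 in dr.excluded and 50.0 not in dr.concentrations


class TestHillFit:
    def test_recovers_planted_parameters(self):
        c = np.array([0.0, 3.0, 10.0, 30.0, 100.0, 300.0])
        rates = 0.0 + (100.0 - 0.0) / (1.0 + (c / 30.0) ** 1.0)
        dr = DoseResponse(concentrations=c, rates=rates, control_t_half=20.0)
        fit = hill_fit(dr)
        assert fit.converged
        assert fit.midpoint == pytest.approx(30.0, rel=0.01)
        assert fit.slope == pytest.approx(1.0, rel=0.01)

    def test_no_effect_is_degenerate(self):
        dr = DoseResponse(concentrations=np.array([0.0, 1.0, 10.0, 100.0, 1000.0]),
                          rates=np.full(5, 100.0), control_t_half=20.0)
        assert not hill_fit(dr).converged

    def test_point_order_invariance(self):
        c = np.array([0.0, 3.0, 10.0, 30.0, 100.0])
        rates = 100.0 / (1.0 + (c / 20.0) ** 1.5)
        perm = np.array([3, 1, 4, 0, 2])
        f1 = hill_fit(DoseResponse(c, rates, 20.0))
        f2 = hill_fit(DoseResponse(c[perm], rates[perm], 20.0))
        assert f1.midpoint == pytest.approx(f2.midpoint, rel=1e-6)

    def test_too_few_concentrations_rejected(self):
        dr = DoseResponse(np.array([0.0, 1.0, 10.0]), np.array([100.0, 80.0, 40.0]), 20.0)
        with pytest.raises(ValueError, match="4 distinct"):
            hill_fit(dr)


class TestKic50:
    DR = DoseResponse(np.array([0.0, 5.0, 15.0, 45.0, 135.0]),
                      np.array([100.0, 90.0, 70.0, 40.0, 15.0]), 20.0)

    def test_closed_form_h1(self):
        fit = HillFit(midpoint=30.0, slope=1.0, top=100.0, bottom=0.0, rss=0.0, converged=True)
        res = kic50(fit, self.DR)
        assert res.kic50 == pytest.approx(15.0, rel=1e-6)

    def test_closed_form_h2(self):
        fit = HillFit(midpoint=30.0, slope=2.0, top=100.0, bottom=0.0, rss=0.0, converged=True)
        res = kic50(fit, self.DR)
        assert res.kic50 == pytest.approx(30.0 * 2 ** -0.5, rel=1e-6)

    def test_flat_response_undefined(self):
        fit = HillFit(midpoint=30.0, slope=1.0, top=100.0, bottom=80.0, rss=0.0, converged=True)
        res = kic50(fit, self.DR)
        assert not res.defined and "no inhibition" in res.reason

    def test_extrapolation_flagged(self):
        fit = HillFit(midpoint=600.0, slope=1.0, top=100.0, bottom=0.0, rss=0.0, converged=True)
        res = kic50(fit, self.DR)  # solution at 300 uM, beyond the tested 135
        assert res.defined and res.extrapolated

    def test_concentration_scale_equivariance(self):
        for s in (0.1, 10.0):
            fit = HillFit(midpoint=30.0 * s, slope=1.3, top=100.0, bottom=0.0,
                          rss=0.0, converged=True)
            base = HillFit(midpoint=30.0, slope=1.3, top=100.0, bottom=0.0,
                           rss=0.0, converged=True)
            assert kic50(fit, self.DR).kic50 == pytest.approx(
                s * kic50(base, self.DR).kic50, rel=1e-9
            )


def test_trace_csv_round_trip(tmp_path):
    traces = gen_dose_series(25.0, noise_sd=0.02, seed=3)
    path = tmp_path / "traces.csv"
    write_traces_csv(path, traces)
    back = read_traces_csv(path)
    assert len(back) == len(traces)
    total_in = sum(tr.times.size for tr in traces)
    total_out = sum(tr.times.size for tr in back)
    assert total_in == total_out
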