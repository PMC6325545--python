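"""Forward/inverse alignment maps and the rate change of variables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sniffalign as sa
from conftest import make_trial


def spec_with_ref(model, mean_dur=250.0, mean_inh=100.0, lam=None,
                  mean_tau_f=0.0, qnorm=None):
    ref = sa.AlignmentReference(mean_dur=mean_dur, mean_inh=mean_inh,
                                mean_exh=mean_dur - mean_inh,
                                mean_tau_f=mean_tau_f, qnorm=qnorm)
    return sa.AlignmentSpec(model, lam=lam, reference=ref)


def linear_flux(t_inh=100.0, slope=1.0):
    tau = np.linspace(0.0, t_inh, 101)
    return sa.InhalationFlux(tau=tau, cum=slope * tau)


class TestFdDelay:
    def test_constant_pressure_midpoint(self):
        d = sa.fd_delay(linear_flux(100.0), lam=0.5, qnorm=100.0)
        assert d.tau_f == pytest.approx(50.0) and not d.capped

    def test_steeper_trial_reaches_target_sooner(self):
        # P = -2 over 50 ms: total 100, target 0.4*100 reached at 20 ms
        d = sa.fd_delay(linear_flux(50.0, slope=2.0), lam=0.4, qnorm=100.0)
        assert d.tau_f == pytest.approx(20.0)

    def test_lambda_zero_gives_zero_delay(self):
        for f in (linear_flux(100.0), linear_flux(50.0, 2.0)):
            assert sa.fd_delay(f, 0.0, 100.0).tau_f == 0.0

    def test_capped_when_target_exceeds_total(self):
        d = sa.fd_delay(linear_flux(100.0), lam=0.9, qnorm=200.0)
        assert d.capped and d.tau_f == pytest.approx(100.0)


class TestTransformSpikeTrain:
    def test_phase_scaling(self):
        trial = make_trial([100.0], duration=200.0)
        out = sa.transform_spike_train(trial, spec_with_ref("phase"))
        assert out[0] == pytest.approx(125.0)

    def test_two_interval_phase_piecewise(self):
        trial = make_trial([40.0, 140.0], duration=200.0, t_inh=80.0)
        out = sa.transform_spike_train(trial, spec_with_ref("two_interval_phase"))
        assert out[0] == pytest.approx(50.0)
        assert out[1] == pytest.approx(100.0 + 60.0 * 150.0 / 120.0)  # 175

    def test_fd_common_front_alignment(self):
        # two trials whose spikes trail the odor front by the same 30 ms
        spec_a = spec_with_ref("fd", lam=0.4, mean_tau_f=30.0, qnorm=100.0)
        fa = linear_flux(100.0)  # tau_f = 40
        fb = linear_flux(50.0, slope=2.0)  # tau_f = 20
        ta = make_trial([70.0], duration=200.0, flux=fa)
        tb = make_trial([50.0], duration=200.0, flux=fb)
        assert sa.transform_spike_train(ta, spec_a)[0] == pytest.approx(60.0)
        assert sa.transform_spike_train(tb, spec_a)[0] == pytest.approx(60.0)

    def test_fd_lambda_zero_is_identity(self, fd_session):
        trials, _ = fd_session
        spec = sa.compute_reference(trials, "fd", lam=0.0)
        for t in trials[:10]:
            out = sa.transform_spike_train(t, spec)
            assert np.allclose(out, t.spike_times, atol=1e-12)

    def test_time_model_identity(self):
        trial = make_trial([10.0, 90.0], duration=200.0)
        out = sa.transform_spike_train(trial, spec_with_ref("time"))
        assert np.array_equal(out, trial.spike_times)


class TestMapProperties:
    @settings(derandomize=True, max_examples=50)
    @given(
        dur=st.floats(80.0, 500.0),
        inh_frac=st.floats(0.2, 0.7),
        model=st.sampled_from([m for m in sa.MODELS if m != "fd"]),
    )
    def test_cycle_end_maps_to_reference_end(self, dur, inh_frac, model):
        trial = make_trial([], duration=dur, t_inh=inh_frac * dur)
        spec = spec_with_ref(model)
        x, y = sa.map_knots(trial, spec)
        expected = {
            "time": dur,
            "phase": spec.reference.mean_dur,
            "two_interval_phase": spec.reference.mean_inh + spec.reference.mean_exh,
            "inhalation_proportional": dur * spec.reference.mean_inh / (inh_frac * dur),
        }[model]
        assert y[-1] == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        dur=st.floats(80.0, 500.0),
        inh_frac=st.floats(0.2, 0.7),
        model=st.sampled_from(list(sa.MODELS)),
        pts=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8),
    )
    def test_forward_map_increasing_and_invertible(self, dur, inh_frac, model, pts):
        flux = linear_flux(inh_frac * dur)
        spec = spec_with_ref(model, lam=0.3 if model == "fd" else None,
                             mean_tau_f=20.0, qnorm=flux.total)
        trial = make_trial([], duration=dur, t_inh=inh_frac * dur, flux=flux)
        x, y = sa.map_knots(trial, spec)
        assert np.all(np.diff(y) > 0)
        t = np.sort(np.asarray(pts)) * dur
        fwd = np.interp(t, x, y)
        back = np.interp(fwd, y, x)
        assert np.allclose(back, t, atol=1e-9)

    def test_zero_duration_interval_rejected(self):
        trial = make_trial([], duration=100.0, t_inh=100.0 - 1e-12)
        trial.cycle.inhalation_offset = 100.0  # force degenerate remainder
        with pytest.raises(ValueError):
            sa.map_knots(trial, spec_with_ref("two_interval_phase"))


class TestInverseTransformRate:
    @staticmethod
    def _flat_psth(rate_hz, lo, hi, bin_ms=10.0):
        edges = np.arange(lo, hi + bin_ms / 2, bin_ms)
        return sa.RatePSTH(bin_edges=edges,
                           rates=np.full(edges.size - 1, rate_hz),
                           n_trials=1, support=(lo, hi))

    def test_time_model_is_identity_on_psth(self):
        psth = self._flat_psth(10.0, 0.0, 200.0)
        trial = make_trial([], duration=200.0)
        rate = sa.inverse_transform_rate(psth, trial, spec_with_ref("time"))
        assert np.allclose(rate(np.array([5.0, 100.0, 195.0])), 10.0)

    def test_phase_jacobian_halves_rate_on_doubled_cycle(self):
        # flat 10 Hz PSTH over the reference cycle; a cycle twice as long
        # maps to a 5 Hz rate so the expected count is conserved
        psth = self._flat_psth(10.0, 0.0, 250.0)
        trial = make_trial([], duration=500.0, t_inh=200.0)
        spec = spec_with_ref("phase", mean_dur=250.0)
        rate = sa.inverse_transform_rate(psth, trial, spec)
        assert np.allclose(rate(np.array([10.0, 250.0, 490.0])), 5.0)
        assert rate.expected_count(0.0, 500.0) == pytest.approx(10.0 * 0.25)

    @pytest.mark.parametrize("model", sa.MODELS)
    def test_round_trip_conserves_expected_count(self, model, fd_session):
        """Transform spikes, histogram, inverse-transform: the pulled-back
        rate integrates to the same expected count as the PSTH does over the
        trial's image interval (change of variables, checked numerically on
        the union grid of knots)."""
        trials, _ = fd_session
        lam = 0.4 if model == "fd" else None
        spec = sa.compute_reference(trials, model, lam=lam)
        transformed = [sa.transform_spike_train(t, spec) for t in trials]
        los = [sa.map_knots(t, spec)[1][0] for t in trials]
        his = [sa.map_knots(t, spec)[1][-1] for t in trials]
        psth = sa.estimate_psth(transformed, 10.0, (min(los + [0.0]), max(his)))
        for trial in trials[:8]:
            rate = sa.inverse_transform_rate(psth, trial, spec, floor=0.0)
            count = rate.expected_count(0.0, trial.cycle.duration)
            # independent integral of f~ between the image endpoints
            x, y = sa.map_knots(trial, spec)
            centers = psth.bin_centers
            xs = np.concatenate(([psth.bin_edges[0]], centers,
                                 [psth.bin_edges[-1]]))
            ys = np.concatenate(([psth.rates[0]], psth.rates,
                                 [psth.rates[-1]]))
            grid = np.unique(np.concatenate([xs, y, np.linspace(y[0], y[-1], 5000)]))
            grid = grid[(grid >= y[0]) & (grid <= y[-1])]
            direct = np.trapezoid(np.interp(grid, xs, ys), grid) / 1000.0
            assert count == pytest.approx(direct, rel=1e-9, abs=1e-12)

    def test_extrapolation_flagged_and_edge_extended(self):
        psth = self._flat_psth(10.0, 0.0, 100.0)
        trial = make_trial([], duration=300.0)
        rate = sa.inverse_transform_rate(psth, trial, spec_with_ref("time"))
        assert rate.extrapolated
        assert rate(np.array([250.0]))[0] == pytest.approx(10.0)

    def test_jacobian_switch_off_plain_interpolation(self):
        psth = self._flat_psth(10.0, 0.0, 250.0)
        trial = make_trial([], duration=500.0, t_inh=200.0)
        ref = sa.AlignmentReference(mean_dur=250.0, mean_inh=100.0, mean_exh=150.0)
        spec = sa.AlignmentSpec("phase", reference=ref, jacobian=False)
        rate = sa.inverse_transform_rate(psth, trial, spec)
        assert np.allclose(rate(np.array([100.0])), 10.0)  # no 1/2 factor
        # without the Jacobian the count over the long cycle is inflated
        assert rate.expected_count(0.0, 500.0) == pytest.approx(10.0 * 0.5)
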