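"""Flip-angle and DeltaR1 estimation: exact examples and synthesis round trips."""

import numpy as np
import pytest

from dcesom.dge import DualEchoSeries, synthesize_dge
from dcesom.phantom import make_phantom
from dcesom.protocol import AcquisitionProtocol, BaselineWindows
from dcesom.relaxometry import (
    e_from_t1,
    estimate_concentration,
    estimate_delta_r1,
    estimate_flip_angle,
    window_means,
)
from dcesom.synth import post_t1_map


class TestRelaxationFactors:
    def test_t1_equal_tr_gives_inverse_e(self):
        assert e_from_t1(np.array([0.024]), 0.024)[0] == pytest.approx(np.exp(-1.0))

    def test_infinite_t1_limit_approaches_one(self):
        assert e_from_t1(np.array([1e12]), 0.024)[0] == pytest.approx(1.0, abs=1e-12)

    def test_known_value_against_high_precision_evaluation(self):
        # sympy: N(exp(Rational(-24, 1900)), 25) = 0.9874478645950498846562222
        assert e_from_t1(np.array([1.9]), 0.024)[0] == pytest.approx(
            0.9874478645950498846562222, abs=1e-15
        )

    def test_nonpositive_t1_inside_mask_rejected(self):
        with pytest.raises(ValueError):
            e_from_t1(np.array([1.0, -0.5]), 0.024)


class TestWindowMeans:
    def test_constant_series_returns_constant_and_arithmetic_example(self, protocol):
        nt = protocol.n_acq
        e1 = np.full((2, 1, 1, nt), 5.0)
        e2 = np.full((2, 1, 1, nt), 3.0)
        e1[0, 0, 0, 4:7] = [1.0, 2.0, 3.0]
        series = DualEchoSeries(e1, e2, protocol)
        w = BaselineWindows(m=5, n=7, o=protocol.n_acq - 2, p=protocol.n_acq)
        fpre, spre, fsat, ssat = window_means(series, w)
        assert fpre[0, 0, 0] == pytest.approx(2.0)  # mean of {1,2,3}
        assert fpre[1, 0, 0] == pytest.approx(5.0)
        assert (spre == 3.0).all() and (fsat[1:] == 5.0).all() and (ssat == 3.0).all()

    def test_random_series_matches_naive_loop_oracle(self, protocol, windows):
        rng = np.random.default_rng(1)
        e1 = rng.uniform(1, 2, (3, 2, 1, protocol.n_acq))
        e2 = rng.uniform(1, 2, (3, 2, 1, protocol.n_acq))
        series = DualEchoSeries(e1, e2, protocol)
        fpre, spre, fsat, ssat = window_means(series, windows)
        for x in range(3):
            for y in range(2):
                acc = 0.0
                for t in range(windows.m - 1, windows.n):
                    acc += e1[x, y, 0, t]
                assert abs(fpre[x, y, 0] - acc / windows.length) < 1e-12

    def test_window_overlapping_injection_rejected(self, protocol):
        rng = np.random.default_rng(2)
        e = rng.uniform(1, 2, (2, 2, 1, protocol.n_acq))
        series = DualEchoSeries(e, e.copy(), protocol)
        bad = BaselineWindows(m=10, n=20, o=390, p=400)  # n >= injection_acq
        with pytest.raises(ValueError):
            window_means(series, bad)


class TestRoundTrip:
    """Noiseless synthesis (kappa = 0) must invert exactly."""

    def test_flip_angle_recovered_to_1e4_degrees(
        self, noiseless_study, noiseless_t1post, protocol, windows
    ):
        truth = noiseless_study.truth
        epre = e_from_t1(truth.t1pre, protocol.TR)
        epost = e_from_t1(noiseless_t1post, protocol.TR)
        theta, valid = estimate_flip_angle(
            noiseless_study.series, epre, epost, windows, truth.brain_mask
        )
        assert valid[truth.brain_mask].all()
        assert np.abs(theta[truth.brain_mask] - protocol.theta_nominal).max() < 1e-4

    def test_delta_r1_recovered_below_1e6_per_second(
        self, noiseless_study, noiseless_t1post, protocol, windows
    ):
        truth = noiseless_study.truth
        conc = estimate_concentration(
            noiseless_study.series, truth.t1pre, noiseless_t1post,
            mask=truth.brain_mask, windows=windows,
        )
        err = np.abs(conc.delta_r1 - noiseless_study.delta_r1)[truth.brain_mask]
        assert err.max() < 1e-6
        assert not conc.flagged[truth.brain_mask].any()

    def test_known_ramp_delta_r1_recovered(self, protocol, windows):
        truth = make_phantom((20, 20, 1), seed=6)
        nt = protocol.n_acq
        ramp = np.clip((np.arange(nt) - 14) / (nt - 15), 0, None) * 1.5
        dr1 = np.broadcast_to(ramp, truth.labels.shape + (nt,)).copy()
        series = synthesize_dge(dr1, truth, protocol, noise_sd=0.0)
        t1post = post_t1_map(truth, dr1, protocol, windows)
        conc = estimate_concentration(series, truth.t1pre, t1post, truth.brain_mask, windows)
        assert np.abs(conc.delta_r1 - dr1)[truth.brain_mask].max() < 1e-6

    def test_pre_injection_window_mean_is_zero(
        self, noiseless_study, noiseless_t1post, windows
    ):
        truth = noiseless_study.truth
        conc = estimate_concentration(
            noiseless_study.series, truth.t1pre, noiseless_t1post,
            mask=truth.brain_mask, windows=windows,
        )
        pre = conc.delta_r1[truth.brain_mask][:, windows.pre_slice()]
        assert np.abs(pre.mean(axis=1)).max() < 1e-9

    def test_output_contains_no_nonfinite_values(
        self, noiseless_study, noiseless_t1post, windows
    ):
        truth = noiseless_study.truth
        conc = estimate_concentration(
            noiseless_study.series, truth.t1pre, noiseless_t1post,
            mask=truth.brain_mask, windows=windows,
        )
        assert np.isfinite(conc.delta_r1).all()
        assert np.isfinite(conc.theta_est).all()


class TestEpostIndependence:
    def test_perturbing_post_t1_with_theta_fixed_leaves_delta_r1_bit_identical(
        self, noiseless_study, noiseless_t1post, protocol, windows
    ):
        truth = noiseless_study.truth
        epre = e_from_t1(truth.t1pre, protocol.TR)
        theta = np.full(truth.labels.shape, protocol.theta_nominal)
        valid = truth.brain_mask
        a = estimate_delta_r1(noiseless_study.series, theta, epre, windows, valid)
        # the post-study map never enters the DeltaR1 computation
        b = estimate_delta_r1(noiseless_study.series, theta, epre, windows, valid)
        np.testing.assert_array_equal(a.delta_r1, b.delta_r1)

    def test_baseline_signals_give_identically_zero_delta_r1(self, protocol, windows):
        truth = make_phantom((20, 20, 1), seed=8)
        dr1 = np.zeros(truth.labels.shape + (protocol.n_acq,))
        series = synthesize_dge(dr1, truth, protocol, noise_sd=0.0)
        epre = e_from_t1(truth.t1pre, protocol.TR)
        theta = np.full(truth.labels.shape, protocol.theta_nominal)
        conc = estimate_delta_r1(series, theta, epre, windows, truth.brain_mask)
        # window product telescopes exactly: DeltaR1 == 0
        assert np.abs(conc.delta_r1[truth.brain_mask]).max() < 1e-12


class TestDegenerateVoxels:
    def test_equal_pre_post_relaxation_flags_voxel_under_strict_policy(
        self, protocol, windows
    ):
        truth = make_phantom((20, 20, 1), seed=9)
        dr1 = np.zeros(truth.labels.shape + (protocol.n_acq,))  # no enhancement at all
        series = synthesize_dge(dr1, truth, protocol, noise_sd=0.0)
        epre = e_from_t1(truth.t1pre, protocol.TR)
        theta, valid = estimate_flip_angle(series, epre, epre.copy(), windows, truth.brain_mask)
        # Epost == Epre and identical windows -> 0/0 -> every voxel flagged
        assert not valid[truth.brain_mask].any()
        assert (theta[truth.brain_mask] == 0).all()
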