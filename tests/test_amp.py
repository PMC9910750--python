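"""Message-passing reconstruction: iteration, metrics, alignment, estimator."""

import itertools

import numpy as np
import pytest
from sklearn.base import clone

from memrec import (
    AMPOptions,
    AMPReconstructor,
    PriorSpec,
    align_patterns,
    fisher_score,
    generate_instance,
    iterate_se,
    reconstruction_error,
    run_amp,
    sample_patterns,
)

from conftest import channel_for_delta


def _instance(prior, delta, N, P, seed, tau=0.0):
    ch = channel_for_delta(delta, tau)
    inst = generate_instance(prior, ch, N, P, seed)
    return inst, fisher_score(inst.connectivity, ch)


class TestReconstructionError:
    def test_perfect_estimate_scores_zero(self, prior):
        X = sample_patterns(prior, 2, 100, seed=0)
        assert reconstruction_error(X.T, X, prior=prior) == 0.0

    def test_zero_estimate_scores_trivial_error(self, prior):
        X = sample_patterns(prior, 2, 4000, seed=1)
        zero = np.zeros_like(X.T)
        raw = reconstruction_error(zero, X, normalized=False, prior=prior)
        m2 = prior.second_moment
        assert raw == pytest.approx(2 * m2, rel=0.05)
        assert reconstruction_error(zero, X, prior=prior) == pytest.approx(
            raw / (2 * m2)
        )

    def test_sign_flip_is_free_for_symmetric_prior(self):
        prior = PriorSpec("binary")
        X = sample_patterns(prior, 1, 200, seed=2)
        assert reconstruction_error(-X.T, X, prior=prior) == pytest.approx(0.0)

    def test_sign_flip_costs_for_skewed_prior(self):
        prior = PriorSpec("low_coding", 0.3)
        X = sample_patterns(prior, 1, 500, seed=3)
        assert reconstruction_error(-X.T, X, prior=prior) > 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_error(np.zeros((10, 2)), np.zeros((3, 10)))


class TestAlignPatterns:
    def test_anticorrelated_single_pattern_gets_negative_sign(self):
        prior = PriorSpec("binary")
        X = sample_patterns(prior, 1, 100, seed=0)
        perm, signs = align_patterns(-X.T, X, prior=prior)
        assert perm.tolist() == [0]
        assert signs.tolist() == [-1.0]

    def test_recovers_permutation_and_signs(self):
        prior = PriorSpec("binary")
        X = sample_patterns(prior, 4, 300, seed=1)
        order = [2, 0, 3, 1]
        flips = np.array([1.0, -1.0, 1.0, -1.0])
        est = (X[order].T) * flips  # columns are permuted, flipped patterns
        perm, signs = align_patterns(est, X, prior=prior)
        aligned = est[:, perm] * signs
        np.testing.assert_allclose(aligned, X.T)

    def test_greedy_matches_exhaustive_on_correlated_estimates(self):
        # oracle: best signed permutation by total |overlap|, P <= 3
        prior = PriorSpec("binary")
        rng = np.random.default_rng(7)
        for P in (2, 3):
            X = sample_patterns(prior, P, 400, seed=rng.integers(2**31))
            est = X.T + rng.normal(scale=0.8, size=(400, P))
            est = est[:, rng.permutation(P)] * rng.choice([-1, 1], size=P)
            perm, signs = align_patterns(est, X, prior=prior)
            best, best_val = None, -np.inf
            M = est.T @ X.T / 400
            for order in itertools.permutations(range(P)):
                val = sum(abs(M[order[mu], mu]) for mu in range(P))
                if val > best_val:
                    best, best_val = order, val
            assert perm.tolist() == list(best)

    def test_skewed_prior_keeps_identity_signs(self):
        prior = PriorSpec("low_coding", 0.3)
        X = sample_patterns(prior, 2, 300, seed=2)
        perm, signs = align_patterns(-X.T, X, prior=prior)
        assert signs.tolist() == [1.0, 1.0]

    def test_random_estimate_matching_is_deterministic(self):
        prior = PriorSpec("binary")
        X = sample_patterns(prior, 2, 1000, seed=3)
        est = np.random.default_rng(9).normal(size=(1000, 2))
        out1 = align_patterns(est, X, prior=prior)
        out2 = align_patterns(est, X, prior=prior)
        np.testing.assert_array_equal(out1[0], out2[0])
        np.testing.assert_array_equal(out1[1], out2[1])


class TestRunAmp:
    def test_exact_and_meanfield_agree_for_single_pattern(self):
        prior = PriorSpec("binary")
        inst, S = _instance(prior, 0.5, 1000, 1, seed=0)
        r_ex = run_amp(S, prior, AMPOptions(mode="exact", seed=1), inst.patterns)
        r_mf = run_amp(S, prior, AMPOptions(mode="meanfield", seed=1), inst.patterns)
        assert np.max(np.abs(r_ex.estimate - r_mf.estimate)) < 1e-6

    def test_informed_init_stays_at_informative_fixed_point(self, prior):
        from memrec import critical_delta

        delta = 0.5 * critical_delta(prior)
        inst, S = _instance(prior, delta, 1500, 1, seed=1)
        res = run_amp(
            S, prior, AMPOptions(init="informed", seed=2), inst.patterns
        )
        mse = reconstruction_error(res.estimate, inst.patterns, prior=prior)
        se = iterate_se(delta, prior, init="informed")
        assert mse < se.mse_predicted + 0.08

    def test_estimate_collapses_above_critical_noise(self):
        prior = PriorSpec("binary")
        inst, S = _instance(prior, 1.5, 1500, 1, seed=3)
        res = run_amp(S, prior, AMPOptions(seed=4), inst.patterns)
        mse = reconstruction_error(res.estimate, inst.patterns, prior=prior)
        assert mse == pytest.approx(1.0, abs=0.08)
        assert np.max(np.abs(res.estimate)) < 0.5  # collapsed toward zero

    def test_onsager_correction_is_necessary(self):
        # removing the memory term must break the state-evolution match
        prior = PriorSpec("binary")
        delta = 0.6
        inst, S = _instance(prior, delta, 1500, 1, seed=5)
        se = iterate_se(delta, prior).mse_predicted
        with_t = run_amp(S, prior, AMPOptions(seed=6), inst.patterns)
        without = run_amp(
            S, prior, AMPOptions(seed=6), inst.patterns, _onsager=False
        )
        err_with = abs(
            reconstruction_error(with_t.estimate, inst.patterns, prior=prior) - se
        )
        err_without = abs(
            reconstruction_error(without.estimate, inst.patterns, prior=prior) - se
        )
        assert err_with < 0.05
        assert err_without > err_with

    def test_estimates_respect_prior_support_bounds(self, prior):
        inst, S = _instance(prior, 0.4, 800, 2, seed=7)
        res = run_amp(S, prior, AMPOptions(seed=8), inst.patterns)
        lo, hi = prior.support.min(), prior.support.max()
        assert res.estimate.min() >= lo - 1e-10
        assert res.estimate.max() <= hi + 1e-10

    def test_overlap_definition(self):
        prior = PriorSpec("binary")
        inst, S = _instance(prior, 0.5, 500, 1, seed=9)
        res = run_amp(S, prior, AMPOptions(seed=10), inst.patterns)
        expect = res.estimate.T @ inst.patterns.T / 500
        np.testing.assert_allclose(res.overlap, expect)

    def test_shape_and_validation_errors(self):
        prior = PriorSpec("binary")
        with pytest.raises(ValueError):
            run_amp(np.zeros((4, 5)), prior, n_patterns=1)
        S = np.zeros((4, 4))
        with pytest.raises(ValueError):
            run_amp(S, prior)  # no P and no truth
        with pytest.raises(ValueError):
            run_amp(S, prior, AMPOptions(init="informed"), n_patterns=1)
        with pytest.raises(ValueError):
            run_amp(S, prior, ground_truth=np.zeros((1, 3)))

    def test_invalid_options_rejected(self):
        with pytest.raises(ValueError):
            AMPOptions(damping=1.0)
        with pytest.raises(ValueError):
            AMPOptions(mode="laplace")
        with pytest.raises(ValueError):
            AMPOptions(tol=0.0)


class TestChannelUniversality:
    def test_equal_delta_channels_perform_alike(self):
        # tau=0 and tau=0.5 realisations of the same effective noise
        prior = PriorSpec("binary")
        delta = 0.5
        mses = {}
        for tau in (0.0, 0.5):
            vals = []
            for seed in range(3):
                inst, S = _instance(prior, delta, 2000, 1, seed=20 + seed, tau=tau)
                res = run_amp(
                    S, prior, AMPOptions(mode="meanfield", seed=seed), inst.patterns
                )
                vals.append(
                    reconstruction_error(res.estimate, inst.patterns, prior=prior)
                )
            mses[tau] = np.median(vals)
        assert abs(mses[0.0] - mses[0.5]) < 0.05


class TestAMPReconstructor:
    def test_sklearn_interface(self):
        est = AMPReconstructor(prior_family="sparse", rho=0.3, n_patterns=2)
        params = est.get_params()
        assert params["rho"] == 0.3
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_fit_reconstructs_patterns(self):
        prior = PriorSpec("binary")
        ch = channel_for_delta(0.4)
        inst = generate_instance(prior, ch, 1200, 1, seed=0)
        est = AMPReconstructor(
            prior_family="binary",
            tau=ch.tau,
            nu=ch.nu,
            n_patterns=1,
            mode="meanfield",
            random_state=1,
        ).fit(inst.connectivity, patterns=inst.patterns)
        assert est.components_.shape == (1, 1200)
        assert est.converged_
        assert est.reconstruction_error(inst.patterns) < 0.35
        assert est.delta_ == pytest.approx(0.4, abs=1e-9)
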