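"""Parameter space, priors, likelihood, sampler and diagnostics."""
import math

import numpy as np
import pytest

from tibd import (
    build_parameter_space,
    burn_in_and_filter,
    default_priors,
    gelman_rubin,
    log_likelihood,
    log_prior,
)
from tibd.calibration import (
    MCMCResult,
    dream_sample,
    gaussian_loglik,
    retained_after_burn_in,
    sample_prior,
)
from tibd.params import TUMOR_PARAMS


class TestParameterSpace:
    def test_two_tumor_types_give_35_dimensions(self, params):
        space = build_parameter_space(params, ("bone_adapted", "parental"))
        assert space.ndim == 35
        names = space.names
        assert sum("[" not in n for n in names) == 25
        for tt in ("bone_adapted", "parental"):
            per_type = {n.split("[")[0] for n in names if n.endswith(f"[{tt}]")}
            assert per_type == set(TUMOR_PARAMS)

    def test_single_type_matches_full_adjustable_count(self, params):
        assert build_parameter_space(params, ("bone_adapted",)).ndim == 30

    def test_no_tumor_types_rejected(self, params):
        with pytest.raises(ValueError):
            build_parameter_space(params, ())

    def test_fixed_parameters_never_sampled(self, params):
        space = build_parameter_space(params, ("bone_adapted",))
        sampled = {n.split("[")[0] for n in space.names}
        assert sampled.isdisjoint({"fO", "IL", "IO", "IP", "nB", "nC"})

    def test_round_trip_theta_to_params(self, params):
        space = build_parameter_space(params, ("bone_adapted", "parental"))
        theta = space.center()
        by_type = space.params_for(theta)
        for name, v in params.as_dict().items():
            assert getattr(by_type["bone_adapted"], name) == pytest.approx(v, rel=1e-12)
        theta2 = theta.copy()
        theta2[space.index("kTdiv", "parental")] += 1.0
        assert by_type["bone_adapted"].kTdiv * 10 == pytest.approx(
            space.params_for(theta2)["parental"].kTdiv
        )


class TestPriors:
    def test_default_prior_structure(self, params):
        space = build_parameter_space(params, ("bone_adapted", "parental"))
        priors = default_priors(space)
        assert len(priors) == 35
        kinds = {p.name: p.kind for p in priors}
        assert kinds["M"] == "log-uniform"
        assert kinds["kZC"] == "log-normal"

    def test_mode_at_centers(self, params):
        space = build_parameter_space(params, ("bone_adapted",))
        priors = default_priors(space)
        center = np.array([p.center for p in priors])
        lp0 = log_prior(center, priors)
        shifted = center.copy()
        shifted[0] += 0.5
        assert log_prior(shifted, priors) < lp0

    def test_gaussian_kernel_scaling(self, params):
        space = build_parameter_space(params, ("bone_adapted",))
        priors = default_priors(space, sigma=2.0)
        center = np.array([p.center for p in priors])
        i = space.index("kTdiv", "bone_adapted")
        shifted = center.copy()
        shifted[i] += 2.0  # one scale unit
        assert log_prior(center, priors) - log_prior(shifted, priors) == pytest.approx(0.5)

    def test_carrying_capacity_support(self, params):
        space = build_parameter_space(params, ("bone_adapted",))
        priors = default_priors(space, m_width=0.3)
        center = np.array([p.center for p in priors])
        i = space.index("M")
        out = center.copy()
        out[i] = math.log10(0.9) + 0.16  # just outside the 0.3-wide interval
        assert log_prior(out, priors) == -math.inf
        inside = center.copy()
        inside[i] = math.log10(0.9) + 0.14
        assert math.isfinite(log_prior(inside, priors))

    def test_dimension_mismatch_rejected(self, params):
        space = build_parameter_space(params, ("bone_adapted",))
        priors = default_priors(space)
        with pytest.raises(ValueError):
            log_prior(np.zeros(3), priors)

    def test_prior_sampling_within_support(self, params, rng):
        space = build_parameter_space(params, ("bone_adapted",))
        priors = default_priors(space)
        draws = sample_prior(priors, rng, 200)
        i = space.index("M")
        assert np.all(np.abs(draws[:, i] - math.log10(0.9)) <= 0.15)


class TestGaussianLoglik:
    def test_zero_residuals(self):
        sigma = np.array([1.0, 2.0, 5.0])
        expected = float(np.sum(-0.5 * np.log(2 * np.pi * sigma**2)))
        assert gaussian_loglik(np.zeros(3), np.zeros(3), sigma) == pytest.approx(expected)

    def test_one_sigma_residual_costs_half(self):
        base = gaussian_loglik([0.0], [0.0], [2.0])
        assert gaussian_loglik([2.0], [0.0], [2.0]) == pytest.approx(base - 0.5)

    def test_two_point_worked_example(self):
        # residuals {1, 2} with sigma {1, 2}
        val = gaussian_loglik([1.0, 2.0], [0.0, 0.0], [1.0, 2.0])
        assert val == pytest.approx(-3.531, abs=5e-4)


class TestLogLikelihood:
    def test_ordering_invariance(self, benchmark):
        datasets = list(benchmark.datasets)
        a = log_likelihood(benchmark.theta_true, datasets, benchmark.space)
        b = log_likelihood(benchmark.theta_true, datasets[::-1], benchmark.space)
        assert a == pytest.approx(b, rel=1e-12)

    def test_split_invariance(self, benchmark):
        from dataclasses import replace

        datasets = list(benchmark.datasets)
        ds = datasets[0]
        first = replace(ds, days=ds.days[:1], means=ds.means[:1], ses=ds.ses[:1])
        rest = replace(ds, days=ds.days[1:], means=ds.means[1:], ses=ds.ses[1:])
        a = log_likelihood(benchmark.theta_true, datasets, benchmark.space)
        b = log_likelihood(
            benchmark.theta_true, [first, rest] + datasets[1:], benchmark.space
        )
        assert a == pytest.approx(b, rel=1e-9)

    def test_pathological_sample_rejected_with_neg_inf(self, benchmark):
        theta = benchmark.theta_true.copy()
        theta[:] = 15.0  # absurd rates: solver cannot integrate this
        assert log_likelihood(theta, benchmark.datasets, benchmark.space) == -math.inf

    def test_truth_scores_finite_and_plausible(self, benchmark):
        ll = log_likelihood(benchmark.theta_true, benchmark.datasets, benchmark.space)
        n_points = sum(ds.days.size for ds in benchmark.datasets)
        assert math.isfinite(ll)
        # residuals at truth should be of order the claimed errors
        assert ll > -10 * n_points


class TestGelmanRubin:
    def test_identically_distributed_chains(self, rng):
        chains = rng.normal(size=(5, 2000, 3))
        gr = gelman_rubin(chains)
        assert np.all((gr > 0.99) & (gr < 1.05))

    def test_disjoint_chains_flagged(self, rng):
        chains = rng.normal(size=(2, 500, 1))
        chains[1] += 10.0
        assert gelman_rubin(chains)[0] > 1.2

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.normal(size=(1, 100, 2)))

    def test_zero_variance_reported_infinite(self, rng):
        chains = np.zeros((3, 100, 1))
        chains[2] += 1.0
        with pytest.warns(RuntimeWarning):
            gr = gelman_rubin(chains)
        assert np.isinf(gr[0])

    def test_agrees_with_arviz_on_behaved_chains(self, rng):
        arviz = pytest.importorskip("arviz")
        chains = rng.normal(size=(4, 4000, 2))
        ours = gelman_rubin(chains)
        theirs = arviz.rhat(
            arviz.convert_to_dataset(chains[:, 2000:, :])
        ).x.values
        np.testing.assert_allclose(ours, theirs, atol=0.02)


class TestDreamSampler:
    @staticmethod
    def _gaussian_target(mean, cov):
        inv = np.linalg.inv(cov)

        def fn(theta):
            d = theta - mean
            lp = -0.5 * float(d @ inv @ d)
            return lp, lp

        return fn

    def test_conjugate_gaussian_moments(self):
        mean = np.array([1.0, -2.0])
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        fn = self._gaussian_target(mean, cov)
        rng = np.random.default_rng(42)
        draw = lambda r, n: r.normal(0.0, 3.0, size=(n, 2))
        samples, _, _, _ = dream_sample(fn, 2, draw, n_chains=5, n_iters=4000, rng=rng)
        kept = samples[:, 2000:, :].reshape(-1, 2)
        np.testing.assert_allclose(kept.mean(axis=0), mean, atol=0.15)
        np.testing.assert_allclose(np.cov(kept.T), cov, atol=0.35)

    def test_posterior_tightens_with_more_data(self):
        # conjugate normal-mean model: doubling the data halves the
        # posterior variance; the sampler must track that
        rng0 = np.random.default_rng(0)
        widths = []
        for n_obs in (10, 40):
            post_var = 1.0 / n_obs
            fn = self._gaussian_target(np.array([0.5]), np.array([[post_var]]))
            rng = np.random.default_rng(7)
            draw = lambda r, n: r.normal(0.0, 1.0, size=(n, 1))
            samples, _, _, _ = dream_sample(fn, 1, draw, 5, 3000, rng)
            widths.append(samples[:, 1500:, 0].std())
        assert widths[1] < widths[0]
        assert widths[1] == pytest.approx(math.sqrt(1.0 / 40), rel=0.3)

    def test_bit_identical_given_seed(self):
        fn = self._gaussian_target(np.zeros(2), np.eye(2))
        draw = lambda r, n: r.normal(0.0, 2.0, size=(n, 2))
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            samples, lps, lls, _ = dream_sample(fn, 2, draw, 4, 300, rng)
            runs.append((samples, lps))
        np.testing.assert_array_equal(runs[0][0], runs[1][0])
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_state_continuation_matches_single_run(self):
        fn = self._gaussian_target(np.zeros(1), np.eye(1))
        draw = lambda r, n: r.normal(0.0, 2.0, size=(n, 1))
        rng = np.random.default_rng(5)
        s1, _, _, state = dream_sample(fn, 1, draw, 3, 200, rng)
        s2, _, _, _ = dream_sample(fn, 1, draw, 3, 200, rng, state=state)
        rng2 = np.random.default_rng(5)
        full, _, _, _ = dream_sample(fn, 1, draw, 3, 400, rng2)
        np.testing.assert_allclose(np.concatenate([s1, s2], axis=1), full)


class TestBurnInAndFilter:
    @staticmethod
    def _result(chains, lls):
        chains = np.asarray(chains, dtype=float)
        lls = np.asarray(lls, dtype=float)
        return MCMCResult(
            chains=chains,
            logpost=lls.copy(),
            loglik=lls,
            gr=np.ones(chains.shape[2]),
            names=tuple(f"p{i}" for i in range(chains.shape[2])),
        )

    def test_full_scale_sample_arithmetic(self):
        assert retained_after_burn_in(5, 500_000) == (2_500_000, 1_250_000)

    def test_reduced_scale_counts(self, rng):
        chains = rng.normal(size=(5, 1000, 2))
        lls = rng.normal(size=(5, 1000))
        ens = burn_in_and_filter(self._result(chains, lls))
        assert ens.samples.shape[0] == 2500  # half of 5 x 1000

    def test_two_sd_filter_worked_example(self):
        # retained log-likelihoods {0,0,0,0,-10}: mean -2, sd 4 -> keep all
        chains = np.zeros((5, 2, 1))
        lls = np.zeros((5, 2))
        lls[4, 1] = -10.0
        ens = burn_in_and_filter(self._result(chains, lls))
        assert ens.mask.all()

    def test_outlier_below_threshold_dropped(self):
        # 10 retained values, one far outlier: mean - 2 sd sits above it
        chains = np.zeros((5, 4, 1))
        lls = np.zeros((5, 4))
        lls[4, 3] = -1e6
        ens = burn_in_and_filter(self._result(chains, lls))
        assert ens.n_filtered == 9

    def test_identical_loglikelihoods_all_retained(self):
        chains = np.zeros((3, 10, 1))
        lls = np.full((3, 10), -5.0)
        ens = burn_in_and_filter(self._result(chains, lls))
        assert ens.mask.all()

    def test_marginal_lookup(self, rng):
        chains = rng.normal(size=(2, 100, 2))
        lls = np.zeros((2, 100))
        ens = burn_in_and_filter(self._result(chains, lls))
        assert ens.marginal("p0").size == ens.n_filtered
        with pytest.raises(KeyError):
            ens.marginal("nope")
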