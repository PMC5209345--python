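"""EM/Newton fitting: correctness, monotonicity, recovery, uncertainty."""

import numpy as np
import pytest

from mixirt.model import (
    ModelSpec,
    ParameterSet,
    QuadratureGrid,
    ResponseMatrix,
    log_likelihood,
)
from mixirt.estimation import (
    FitOptions,
    assign_modal_classes,
    e_step,
    fit,
    m_step,
    posterior_class_probabilities,
    standard_errors,
)
from mixirt.simulate import generate_responses

FAST = FitOptions(n_starts=4, seed=0, burn_in_iterations=20)


class TestEStep:
    def test_single_class_marginal_is_one(self, small_mixture_data, grid21):
        data, _ = small_mixture_data
        params = ParameterSet(
            np.array([[[-1.0, 0.5], [0.0, 1.0]]]),
            np.ones((1, 2)),
            np.ones(1),
            np.ones(1),
            [3, 3],
        )
        resp, r, totals, ll = e_step(data, params, grid21)
        assert np.allclose(resp.sum(axis=(1, 2)), 1.0, atol=1e-10)
        assert totals == pytest.approx(data.n_persons)

    def test_identical_classes_give_prior_marginals(self, grid21):
        tau = np.array([[-0.5, 0.5]])
        params = ParameterSet(
            np.repeat(tau[None, None, :], 2, axis=0).reshape(2, 1, 2),
            np.ones((2, 1)),
            np.array([0.7, 0.3]),
            np.ones(2),
            [3],
        )
        data = ResponseMatrix(np.array([[0], [1], [2]]), ["a"], [3])
        resp, _, _, _ = e_step(data, params, grid21)
        class_marg = resp.sum(axis=2)
        assert np.allclose(class_marg, [0.7, 0.3], atol=1e-12)

    def test_hand_computed_bayes_case(self):
        """1 dichotomous item, 2 nodes: responsibilities by direct Bayes rule."""
        grid = QuadratureGrid(nodes=np.array([-1.0, 1.0]), weights=np.array([0.5, 0.5]))
        params = ParameterSet(
            np.array([[[0.0]]]), np.ones((1, 1)), np.ones(1), np.ones(1), [2]
        )
        data = ResponseMatrix(np.array([[1]]), ["a"], [2])
        resp, _, _, ll = e_step(data, params, grid)
        p_neg = np.exp(-1) / (1 + np.exp(-1))
        p_pos = np.exp(1) / (1 + np.exp(1))
        marg = 0.5 * p_neg + 0.5 * p_pos
        assert resp[0, 0, 0] == pytest.approx(0.5 * p_neg / marg, abs=1e-12)
        assert resp[0, 0, 1] == pytest.approx(0.5 * p_pos / marg, abs=1e-12)
        assert ll == pytest.approx(np.log(marg), abs=1e-12)


class TestMStep:
    def test_mixing_update_is_responsibility_mean(self, small_mixture, small_mixture_data, grid21):
        data, _ = small_mixture_data
        spec = ModelSpec("mpcm", 2, [3, 3])
        resp, r, totals, _ = e_step(data, small_mixture, grid21)
        updated = m_step(r, totals, small_mixture, spec, grid21, maxiter=1)
        assert np.allclose(updated.mixing, totals / totals.sum(), atol=1e-12)

    def test_mpcm_never_alters_discriminations(self, small_mixture, small_mixture_data, grid21):
        data, _ = small_mixture_data
        spec = ModelSpec("mpcm", 2, [3, 3])
        resp, r, totals, _ = e_step(data, small_mixture, grid21)
        updated = m_step(r, totals, small_mixture, spec, grid21, maxiter=15)
        assert np.all(updated.discriminations == 1.0)

    def test_converged_fit_is_em_fixed_point(self, small_mixture_data, grid21):
        """One extra E/M cycle at the optimum must not move parameters."""
        data, _ = small_mixture_data
        spec = ModelSpec("mpcm", 2, [3, 3])
        fitted = fit(data, spec, FAST)
        resp, r, totals, _ = e_step(data, fitted.params, fitted.grid)
        updated = m_step(r, totals, fitted.params, spec, fitted.grid, maxiter=50)
        assert np.allclose(updated.mixing, fitted.params.mixing, atol=1e-3)
        assert np.allclose(
            updated.thresholds, fitted.params.thresholds, atol=1e-3, equal_nan=True
        )


class TestFit:
    def test_single_class_pcm_matches_grid_search_oracle(self):
        """Fitted LL vs an exhaustive coordinate grid search (step 0.01)."""
        gen = ParameterSet(
            np.array([[[-0.8, 0.3], [0.2, 1.1]]]),
            np.ones((1, 2)),
            np.ones(1),
            np.array([0.8]),
            [3, 3],
        )
        data, _ = generate_responses(gen, 200, seed=3)
        spec = ModelSpec("pcm", 1, [3, 3])
        fitted = fit(data, spec, FitOptions(n_starts=3, seed=0))
        grid = fitted.grid

        # oracle: cyclic 1-D grid sweeps over each threshold and log-sigma
        tau = np.zeros(4)
        log_sd = 0.0
        tau_axis = np.arange(-2.0, 2.0001, 0.01)
        sd_axis = np.arange(np.log(0.2), np.log(3.0), 0.01)

        def oracle_ll(tau_vec, ls):
            p = ParameterSet(
                tau_vec.reshape(1, 2, 2),
                np.ones((1, 2)),
                np.ones(1),
                np.array([np.exp(2 * ls)]),
                [3, 3],
            )
            return log_likelihood(data, p, grid)

        best = oracle_ll(tau, log_sd)
        for _ in range(8):
            improved = False
            for j in range(4):
                cand = np.tile(tau, (tau_axis.size, 1))
                cand[:, j] = tau_axis
                lls = [oracle_ll(c, log_sd) for c in cand]
                k = int(np.argmax(lls))
                if lls[k] > best + 1e-12:
                    best, tau = lls[k], cand[k]
                    improved = True
            lls = [oracle_ll(tau, s) for s in sd_axis]
            k = int(np.argmax(lls))
            if lls[k] > best + 1e-12:
                best, log_sd = lls[k], sd_axis[k]
                improved = True
            if not improved:
                break
        assert fitted.log_likelihood >= best - 1e-3

    def test_same_seed_is_bit_identical(self, small_mixture_data):
        data, _ = small_mixture_data
        spec = ModelSpec("mpcm", 2, [3, 3])
        f1 = fit(data, spec, FAST)
        f2 = fit(data, spec, FAST)
        assert f1.log_likelihood == f2.log_likelihood
        assert np.array_equal(
            np.nan_to_num(f1.params.thresholds), np.nan_to_num(f2.params.thresholds)
        )

    def test_em_trace_monotone_every_run(self, small_mixture_data):
        data, _ = small_mixture_data
        for variant, G in [("mpcm", 2), ("rmgpcm", 2), ("pcm", 1)]:
            spec = ModelSpec(variant, G, [3, 3])
            fitted = fit(data, spec, FitOptions(n_starts=2, seed=1))
            tr = np.asarray(fitted.trace["em_log_likelihood"])
            slack = 1e-10 * (1.0 + np.abs(tr[:-1]))
            assert np.all(np.diff(tr) >= -slack)

    def test_classes_ordered_by_descending_mixing(self, small_mixture_data):
        data, _ = small_mixture_data
        fitted = fit(data, ModelSpec("mpcm", 2, [3, 3]), FAST)
        assert fitted.params.mixing[0] >= fitted.params.mixing[1]

    def test_variant_nesting_of_likelihoods(self, small_mixture_data):
        """mGPCM >= rmGPCM >= mPCM when each is seeded from the nested fit."""
        data, _ = small_mixture_data
        opts = FitOptions(n_starts=3, seed=2)
        f_mpcm = fit(data, ModelSpec("mpcm", 2, [3, 3]), opts)
        f_rm = fit(
            data, ModelSpec("rmgpcm", 2, [3, 3]), opts, extra_starts=[f_mpcm.params]
        )
        f_mg = fit(
            data, ModelSpec("mgpcm", 2, [3, 3]), opts, extra_starts=[f_rm.params]
        )
        assert f_rm.log_likelihood >= f_mpcm.log_likelihood - 1e-6
        assert f_mg.log_likelihood >= f_rm.log_likelihood - 1e-6

    def test_threshold_rmse_decreases_with_sample_size(self, hilda_stable_params):
        """Median aligned threshold RMSE must shrink from n=800 to n=3200."""
        from scipy.optimize import linear_sum_assignment

        truth = hilda_stable_params
        spec = ModelSpec("rmgpcm", 3, np.full(5, 11))
        med = {}
        for n in (800, 3200):
            rmses = []
            for seed in range(3):
                data, _ = generate_responses(truth, n, seed=100 + seed)
                f = fit(data, spec, FitOptions(n_starts=6, seed=seed, burn_in_iterations=15))
                cost = np.zeros((3, 3))
                for a in range(3):
                    for b in range(3):
                        cost[a, b] = np.nanmean(
                            (f.params.thresholds[a] - truth.thresholds[b]) ** 2
                        )
                r, c = linear_sum_assignment(cost)
                order = np.empty(3, dtype=int)
                order[c] = r
                rmses.append(
                    np.sqrt(
                        np.nanmean(
                            (f.params.thresholds[order] - truth.thresholds) ** 2
                        )
                    )
                )
            med[n] = np.median(rmses)
        assert med[3200] < med[800]


class TestPosteriorAndAssignment:
    def test_single_class_posterior_is_one(self, small_mixture_data, grid21):
        data, _ = small_mixture_data
        fitted = fit(data, ModelSpec("pcm", 1, [3, 3]), FAST)
        post = posterior_class_probabilities(fitted, data)
        assert np.allclose(post, 1.0)

    def test_separated_classes_give_confident_posteriors(self, grid21):
        # classes prefer opposite categories on alternating items — a
        # pattern difference no single-trait class can mimic
        lo, hi = [1.5, 2.5], [-2.5, -1.5]
        tau = np.array([[lo, hi, lo, hi], [hi, lo, hi, lo]], dtype=float)
        params = ParameterSet(
            tau, np.ones((2, 4)), np.array([0.5, 0.5]),
            np.full(2, 0.09), [3] * 4,
        )
        data, truth = generate_responses(params, 300, seed=9)
        fitted = fit(data, ModelSpec("mpcm", 2, [3] * 4), FAST)
        post = posterior_class_probabilities(fitted, data)
        assert np.mean(post.max(axis=1) > 0.99) > 0.95

    def test_relabeling_permutes_posterior_columns(self, small_mixture, small_mixture_data, grid21):
        data, _ = small_mixture_data
        from mixirt.estimation import FittedModel

        def make(params):
            fm = FittedModel(
                spec=ModelSpec("mpcm", 2, [3, 3]),
                params=params,
                log_likelihood=0.0,
                n_free_parameters=0,
                posterior=np.zeros((1, 2)),
                trace={},
                grid=grid21,
                start_index=0,
                converged=True,
            )
            return posterior_class_probabilities(fm, data)

        p_ab = make(small_mixture)
        p_ba = make(small_mixture.reorder_classes([1, 0]))
        assert np.allclose(p_ab, p_ba[:, ::-1], atol=1e-12)

    def test_modal_assignment_hand_case(self):
        post = np.array([[0.9, 0.1], [0.6, 0.4]])
        labels, means = assign_modal_classes(post)
        assert labels.tolist() == [0, 0]
        assert means[0] == pytest.approx(0.75)
        assert np.isnan(means[1])

    def test_tie_goes_to_lowest_class(self):
        with pytest.warns(UserWarning):
            labels, _ = assign_modal_classes(np.array([[0.5, 0.5], [0.2, 0.8]]))
        assert labels[0] == 0

    def test_identity_posterior_means_are_one(self):
        labels, means = assign_modal_classes(np.eye(3))
        assert np.allclose(means, 1.0)


@pytest.fixture(scope="module")
def binary_mixture():
    """Well-separated symmetric 2-class mixture (anti-correlated styles)."""
    lo, hi = [1.5, 2.5], [-2.5, -1.5]
    tau = np.array([[lo, hi, lo, hi], [hi, lo, hi, lo]], dtype=float)
    return ParameterSet(
        tau, np.ones((2, 4)), np.array([0.5, 0.5]), np.full(2, 0.09), [3] * 4
    )


class TestStandardErrors:
    def test_mixing_se_shrinks_like_root_n(self, binary_mixture):
        spec = ModelSpec("mpcm", 2, [3] * 4)
        ns = [500, 2000, 8000]
        ses = []
        for n in ns:
            vals = []
            for seed in range(3):
                data, _ = generate_responses(binary_mixture, n, seed=seed)
                f = fit(data, spec, FitOptions(n_starts=3, seed=seed))
                se = standard_errors(f, data)
                vals.append(se["mixing"][0])
            ses.append(np.median(vals))
        slope = np.polyfit(np.log(ns), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_fixed_reference_slope_has_no_se(self, small_mixture_data):
        data, _ = small_mixture_data
        f = fit(data, ModelSpec("rmgpcm", 2, [3, 3]), FAST)
        se = standard_errors(f, data)
        assert np.all(np.isnan(se["discriminations"][:, 0]))
        assert np.all(np.isfinite(se["discriminations"][:, 1]))

    def test_se_matches_parametric_bootstrap_sd(self):
        """Information-based SE of a threshold vs bootstrap spread."""
        gen = ParameterSet(
            np.array([[[-0.4], [0.6]]]), np.ones((1, 2)), np.ones(1),
            np.ones(1), [2, 2],
        )
        spec = ModelSpec("pcm", 1, [2, 2])
        data, _ = generate_responses(gen, 1000, seed=0)
        opts = FitOptions(n_starts=2, seed=0)
        f = fit(data, spec, opts)
        se = standard_errors(f, data)["thresholds"][0, 0, 0]
        boots = []
        for b in range(200):
            sim, _ = generate_responses(f.params, 1000, seed=10_000 + b)
            fb = fit(sim, spec, FitOptions(n_starts=1, seed=b), extra_starts=[f.params])
            boots.append(fb.params.thresholds[0, 0, 0])
        sd = np.std(boots, ddof=1)
        assert se == pytest.approx(sd, rel=0.15)
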