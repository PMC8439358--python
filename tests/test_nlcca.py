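import numpy as np
import pytest

from ssvepkit import (
    ValidationError,
    bicor,
    bicor_gradient,
    forward_map,
    lp_norm,
    nlcca_classify,
    train_nlcca,
)
from ssvepkit.detectors import cca_fit
from ssvepkit.nlcca import (
    DegenerateScaleError,
    ForwardNet,
    NLCCAHyper,
    NLCCAModel,
    cost_c1,
    cost_reconstruction,
    inverse_map,
)


def bicor_frozen_scale(x, y, med_x, mad_x, med_y, mad_y):
    """Independent re-derivation of the biweight midcorrelation with the
    location/scale estimates held fixed — the differentiation convention."""
    u = (x - med_x) / (9 * mad_x)
    v = (y - med_y) / (9 * mad_y)
    w_x = (1 - u**2) ** 2 * (np.abs(u) < 1)
    w_y = (1 - v**2) ** 2 * (np.abs(v) < 1)
    a_x = (x - med_x) * w_x
    a_y = (y - med_y) * w_y
    return (a_x / np.sqrt(a_x @ a_x)) @ (a_y / np.sqrt(a_y @ a_y))


class TestLpNorm:
    def test_pythagorean(self):
        assert lp_norm([3.0, 4.0], 2) == pytest.approx(5.0)

    def test_absolute_sum(self):
        assert lp_norm([1.0, -1.0, 1.0], 1) == pytest.approx(3.0)

    def test_l1_dominates_l2(self, rng):
        for _ in range(20):
            e = rng.standard_normal(10)
            assert lp_norm(e, 1) >= lp_norm(e, 2)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValidationError):
            lp_norm([], 2)


class TestBicor:
    def test_perfect_self_agreement(self, rng):
        x = rng.standard_normal(50)
        assert bicor(x, x) == pytest.approx(1.0)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_close_to_pearson_on_clean_gaussian(self):
        rng = np.random.default_rng(1)
        cov = [[1.0, 0.8], [0.8, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=10_000)
        pearson = np.corrcoef(xy.T)[0, 1]
        assert abs(bicor(xy[:, 0], xy[:, 1]) - pearson) < 0.03

    def test_bounded_and_near_pearson_property(self):
        rng = np.random.default_rng(2)
        for rho in (-0.5, 0.0, 0.9):
            cov = [[1.0, rho], [rho, 1.0]]
            xy = rng.multivariate_normal([0, 0], cov, size=5000)
            delta = bicor(xy[:, 0], xy[:, 1])
            assert -1.0 <= delta <= 1.0
            assert abs(delta - np.corrcoef(xy.T)[0, 1]) < 0.02

    def test_resists_single_gross_outlier(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        y = x.copy()
        y[13] = 100.0 * y.std()
        assert abs(bicor(x, y)) > 0.95
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.5

    def test_affine_invariance_and_symmetry(self, rng):
        x, y = rng.standard_normal(60), rng.standard_normal(60)
        assert bicor(3.0 * x + 7.0, y) == pytest.approx(bicor(x, y))
        assert bicor(x, y) == pytest.approx(bicor(y, x))

    def test_intermediate_invariants(self, rng):
        x, y = rng.standard_normal(80), rng.standard_normal(80)
        _, parts = bicor(x, y, return_intermediate=True)
        assert np.all((parts.w_x >= 0) & (parts.w_x <= 1))
        assert np.all(parts.w_x[np.abs(parts.u) >= 1] == 0)
        assert parts.x_tilde @ parts.x_tilde == pytest.approx(1.0)
        assert parts.y_tilde @ parts.y_tilde == pytest.approx(1.0)

    def test_zero_mad_is_degenerate(self):
        with pytest.raises(DegenerateScaleError):
            bicor(np.ones(10), np.arange(10.0))

    def test_strict_indicator_differs_below_minus_one(self):
        x = np.array([0.0, 0.1, -0.1, 0.2, -0.2, 50.0, -50.0])
        y = np.array([0.0, 0.2, -0.1, 0.1, -0.3, 0.4, -0.4])
        default = bicor(x, y)
        strict = bicor(x, y, strict_paper_indicator=True)
        assert default != pytest.approx(strict)


class TestBicorGradient:
    def test_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        h = 1e-6
        worst = 0.0
        for _ in range(100):
            x = rng.standard_normal(50)
            y = 0.5 * x + rng.standard_normal(50)
            _, parts = bicor(x, y, return_intermediate=True)
            analytic = bicor_gradient(x, y)
            for i in rng.choice(50, size=5, replace=False):
                xp, xm = x.copy(), x.copy()
                xp[i] += h
                xm[i] -= h
                fd = (
                    bicor_frozen_scale(xp, y, parts.med_x, parts.mad_x,
                                       parts.med_y, parts.mad_y)
                    - bicor_frozen_scale(xm, y, parts.med_x, parts.mad_x,
                                         parts.med_y, parts.mad_y)
                ) / (2 * h)
                worst = max(worst, abs(analytic[i] - fd))
        assert worst < 1e-5

    def test_zero_weight_samples_have_zero_gradient(self):
        x = np.array([0.0, 0.1, -0.1, 0.2, -0.2, 50.0])
        y = np.array([0.0, 0.2, -0.1, 0.1, -0.3, 0.4])
        _, parts = bicor(x, y, return_intermediate=True)
        grad = bicor_gradient(x, y)
        assert np.all(np.abs(parts.u[5]) >= 1)  # the outlier is clipped
        assert grad[5] == 0.0

    def test_stationary_at_self_correlation_maximum(self, rng):
        x = rng.standard_normal(40)
        np.testing.assert_allclose(bicor_gradient(x, x), 0.0, atol=1e-12)


class TestForwardMap:
    def test_zero_parameters_give_zero_output(self, rng):
        net = ForwardNet(np.zeros((3, 4)), np.zeros(4), np.zeros(4), 0.0)
        x = rng.standard_normal((20, 3))
        np.testing.assert_array_equal(forward_map(net, x), 0.0)

    def test_tiny_weights_are_linear(self, rng):
        w = 1e-4 * rng.standard_normal((3, 4))
        w_out = 1e-4 * rng.standard_normal(4)
        net = ForwardNet(w, np.zeros(4), w_out, 0.0)
        x = rng.standard_normal((50, 3))
        u = forward_map(net, x)
        linear = x @ (w @ w_out)
        np.testing.assert_allclose(u, linear, rtol=1e-6, atol=1e-14)

    def test_dimension_mismatch(self, rng):
        net = ForwardNet(np.zeros((3, 4)), np.zeros(4), np.zeros(4), 0.0)
        with pytest.raises(ValidationError):
            forward_map(net, rng.standard_normal((10, 5)))


class TestCosts:
    def test_identical_standardized_variates_cost_minus_one(self):
        u = np.tile([-1.0, 1.0], 30)  # exact zero mean, unit mean square
        assert cost_c1(u, u.copy(), [], 0.1) == pytest.approx(-1.0)

    def test_independent_variates_cost_near_zero(self):
        rng = np.random.default_rng(8)
        u = rng.standard_normal(20_000)
        v = rng.standard_normal(20_000)
        u = (u - u.mean()) / np.sqrt(np.mean((u - u.mean()) ** 2))
        v = (v - v.mean()) / np.sqrt(np.mean((v - v.mean()) ** 2))
        assert abs(cost_c1(u, v, [], 0.0)) < 0.05

    def test_penalty_linear_in_p1(self, rng):
        u = np.tile([-1.0, 1.0], 30)
        w = [rng.standard_normal((3, 4)), rng.standard_normal((2, 4))]
        base = cost_c1(u, u.copy(), [], 0.0)
        c_single = cost_c1(u, u.copy(), w, 0.5) - base
        c_double = cost_c1(u, u.copy(), w, 1.0) - base
        assert c_double == pytest.approx(2 * c_single)

    def test_reconstruction_cost_examples(self):
        x = np.arange(12.0).reshape(4, 3)
        assert cost_reconstruction(x, x, 0.0, np.zeros(2)) == 0.0
        assert cost_reconstruction(x + 1, x, 0.0, np.zeros(2), "mae") == pytest.approx(1.0)
        assert cost_reconstruction(x + 1, x, 0.0, np.zeros(2), "mse") == pytest.approx(1.0)
        assert cost_reconstruction(x + 2, x, 0.0, np.zeros(2), "mae") == pytest.approx(2.0)
        assert cost_reconstruction(x + 2, x, 0.0, np.zeros(2), "mse") == pytest.approx(4.0)

    def test_reconstruction_shape_mismatch(self):
        with pytest.raises(ValidationError):
            cost_reconstruction(np.zeros((3, 2)), np.zeros((2, 3)), 0.0, np.zeros(1))


def linear_views(n=600, seed=0, noise=0.1):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    a = rng.standard_normal((3, 2))
    return x, x @ a + noise * rng.standard_normal((n, 2))


class TestTraining:
    def test_deterministic_given_seed(self):
        x, y = linear_views(n=200)
        hyper = NLCCAHyper(restarts=2, max_iter=100, seed=5)
        m1 = train_nlcca(x, y, hyper)
        m2 = train_nlcca(x, y, hyper)
        np.testing.assert_array_equal(m1.x_net.weights, m2.x_net.weights)
        np.testing.assert_array_equal(m1.template_v, m2.template_v)

    def test_every_restart_descends_and_best_is_reported(self):
        x, y = linear_views(n=200, seed=3)
        model = train_nlcca(x, y, NLCCAHyper(restarts=4, max_iter=150, seed=1))
        log = model.diagnostics["restarts"]
        for entry in log:
            assert entry["final_c1"] <= entry["initial_c1"]
        assert model.diagnostics["final_c1"] == pytest.approx(
            min(e["final_c1"] for e in log)
        )

    def test_linear_limit_matches_linear_cca(self):
        x, y = linear_views(n=1000, seed=0)
        rho1 = cca_fit(x.T, y.T).rho[0]
        model = train_nlcca(x, y, NLCCAHyper(p1=10.0, restarts=3, max_iter=300,
                                             seed=1))
        delta = bicor(model.map_x(x), model.map_y(y))
        assert abs(abs(delta) - rho1) < 0.05

    def test_quadratic_relation_beats_linear_cca(self):
        rng = np.random.default_rng(0)
        n = 2000
        z = rng.uniform(-1, 1, n)
        x = np.column_stack([z, 0.5 * z]) + 0.02 * rng.standard_normal((n, 2))
        y = np.column_stack([z**2, 0.3 * z**2]) + 0.02 * rng.standard_normal((n, 2))
        rho1 = cca_fit(x.T, y.T).rho[0]
        model = train_nlcca(x, y, NLCCAHyper(p1=0.01, restarts=3, max_iter=300,
                                             seed=1))
        delta = abs(bicor(model.map_x(x), model.map_y(y)))
        assert delta >= rho1 + 0.1

    def test_larger_p1_gives_more_linear_map(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((150, 3))
        a = rng.standard_normal((3, 2))
        y = x @ a + 0.5 * rng.standard_normal((150, 2))
        deviations = []
        for p1 in (0.01, 0.1, 1.0, 10.0):
            model = train_nlcca(
                x, y, NLCCAHyper(p1=p1, restarts=4, max_iter=400, seed=3)
            )
            u = model.map_x(x)
            xs = model.standardize_x(x)
            design = np.column_stack([xs, np.ones(len(xs))])
            fit = design @ np.linalg.lstsq(design, u, rcond=None)[0]
            deviations.append(
                np.linalg.norm(u - fit) / np.linalg.norm(u - u.mean())
            )
        # optimizer noise keeps the ladder from being strictly monotone,
        # but heavier penalties must land in the more linear regime
        assert deviations[-1] < deviations[0]
        assert int(np.argmin(deviations)) >= 2

    def test_inverse_maps_reconstruct(self):
        x, y = linear_views(n=400, seed=2)
        model = train_nlcca(x, y, NLCCAHyper(restarts=2, max_iter=300, seed=0))
        xs = model.standardize_x(x)
        recon = inverse_map(model.inv_u, model.map_x(x))
        # a scalar variate cannot reconstruct all of x, but it must beat
        # the constant (per-variable mean) predictor
        null = np.mean(np.abs(xs - xs.mean(axis=0)))
        assert np.mean(np.abs(recon - xs)) < 0.9 * null
        assert model.diagnostics["final_c2"] < 0.9 * null

    def test_too_few_samples_rejected(self):
        x, y = linear_views(n=10)
        with pytest.raises(ValidationError):
            train_nlcca(x, y)


class TestClassification:
    def test_end_to_end_round_trip(self, high_snr_split, nlcca_models):
        _, test = high_snr_split
        window = test.data[3][:, :256]
        result = nlcca_classify(window, nlcca_models)
        assert result.decided == test.labels[3]
        assert not result.low_confidence

    def test_pure_noise_scores_low_confidence(self, nlcca_models):
        rng = np.random.default_rng(6)
        deltas = []
        for _ in range(5):
            window = rng.standard_normal((8, 256))
            result = nlcca_classify(window, nlcca_models)
            deltas.append(result.scores.max())
            assert result.low_confidence
        assert np.median(np.abs(deltas)) < 0.3

    def test_inference_is_deterministic(self, nlcca_models, rng):
        window = rng.standard_normal((8, 256))
        a = nlcca_classify(window, nlcca_models)
        b = nlcca_classify(window, nlcca_models)
        np.testing.assert_array_equal(a.scores, b.scores)
        assert a.decided == b.decided

    def test_exact_tie_breaks_to_lowest_index(self, nlcca_models, rng):
        window = rng.standard_normal((8, 256))
        twin = [nlcca_models[4], nlcca_models[4]]
        result = nlcca_classify(window, twin)
        assert result.scores[0] == result.scores[1]
        assert result.decided == 1

    def test_template_length_mismatch(self, nlcca_models, rng):
        with pytest.raises(ValidationError):
            nlcca_classify(rng.standard_normal((8, 128)), nlcca_models)

    def test_json_round_trip_preserves_decisions(self, nlcca_models, rng):
        window = rng.standard_normal((8, 256))
        import json

        revived = [
            NLCCAModel.from_json(json.loads(json.dumps(m.to_json())))
            for m in nlcca_models[:3]
        ]
        original = nlcca_classify(window, nlcca_models[:3])
        restored = nlcca_classify(window, revived)
        np.testing.assert_array_equal(original.scores, restored.scores)


class TestLowSnrComparison:
    def test_nlcca_at_least_as_accurate_as_cca_at_minus_five_db(self):
        """Sign test over seeds of per-seed accuracy on 1 s windows."""
        from ssvepkit import (
            CCADetector,
            GeneratorConfig,
            NLCCADetector,
            bandpass_zero_phase,
            generate_dataset,
            train_stimulus_models,
        )

        wins, losses = 0, 0
        for seed in range(10):
            cfg = GeneratorConfig(snr_db=-5.0, phase_mode="fixed", n_blocks=3,
                                  seed=seed)
            epochs = bandpass_zero_phase(generate_dataset(cfg))
            epochs = epochs.with_data(epochs.data[:, :, 50:], onset_offset=50)
            train, test = epochs.split_blocks([2])
            models = train_stimulus_models(
                train, 256, hyper=NLCCAHyper(restarts=2, max_iter=200, seed=seed)
            )
            nlcca = NLCCADetector(models)
            cca = CCADetector(epochs.grid, epochs.sample_rate)
            n_correct = c_correct = 0
            for i in range(test.n_trials):
                window = test.data[i][:, :256]
                n_correct += nlcca.classify(window).decided == test.labels[i]
                c_correct += cca.classify(window).decided == test.labels[i]
            wins += n_correct > c_correct
            losses += n_correct < c_correct
        # one-sided sign test at 5%: losses must not dominate wins
        from scipy.stats import binomtest

        if wins + losses:
            p = binomtest(losses, wins + losses, 0.5, alternative="greater").pvalue
            assert p > 0.05
        else:
            assert losses == 0  # all ties: the >= relation holds everywhere
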