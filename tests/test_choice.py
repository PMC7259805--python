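import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentcp import (
    GeneratorConfig,
    SessionData,
    choice_probability,
    cp_time_course,
    estimate_pta,
    fit_choice_decoder,
    generate_session,
    mapping_frame,
    nested_lr_tests,
    regress_out_pulses,
    rotate_to_stimulus_axis,
    run_choice_pipeline,
    select_weak_trials,
)
from latentcp.choice import ResidualActivity


def _session_with_levels(level_counts, level_rates, seed=0):
    """Session whose |pulse sum| levels have exact correct-rate fractions."""
    rng = np.random.default_rng(seed)
    pulses, correct = [], []
    for lv, (n, rate) in enumerate(zip(level_counts, level_rates)):
        p = np.zeros((n, 7), dtype=np.int16)
        p[:, 0] = lv
        pulses.append(p)
        n_correct = int(round(n * rate))
        c = np.zeros(n, dtype=np.uint8)
        c[:n_correct] = 1
        correct.append(c)
    pulses = np.concatenate(pulses)
    correct = np.concatenate(correct)
    n = len(pulses)
    return SessionData(
        session_id="levels",
        spikes=np.zeros((n, 1500, 1), dtype=np.uint8),
        pulses=pulses,
        choice=rng.integers(0, 2, n),
        correct=correct,
        frozen=np.zeros(n, dtype=np.uint8),
    )


class TestWeakTrials:
    def test_worked_inclusion_table(self):
        # pooled rates after each level: .52, .55, .5867, .64 -- all below .65
        sess = _session_with_levels([100] * 4, [0.52, 0.58, 0.66, 0.80])
        weak = select_weak_trials(sess)
        assert weak.coherence_levels_included == [0, 1, 2, 3]
        assert weak.n_trials == 400
        assert weak.achieved_correct_rate == pytest.approx(0.64)
        assert not weak.excluded

    def test_only_zero_level_included_when_rest_perfect(self):
        sess = _session_with_levels([120, 120, 120], [0.50, 1.0, 1.0])
        weak = select_weak_trials(sess)
        assert weak.coherence_levels_included == [0]
        assert weak.n_trials == 120

    def test_small_set_flagged_excluded(self):
        sess = _session_with_levels([80, 100], [0.50, 1.0])
        weak = select_weak_trials(sess)
        assert weak.n_trials == 80
        assert weak.excluded

    def test_level_zero_always_included_even_above_threshold(self):
        sess = _session_with_levels([50, 50], [0.9, 0.9])
        weak = select_weak_trials(sess)
        assert weak.coherence_levels_included == [0]


class TestResidualization:
    def test_linear_activity_fully_removed(self, rng):
        pulses = rng.integers(-3, 4, size=(60, 7)).astype(float)
        W = rng.standard_normal((7, 3))
        activity = np.repeat((pulses @ W)[:, None, :], 15, axis=1)
        res = regress_out_pulses(activity, pulses,
                                 gamma_grid=np.logspace(-12, -8, 3))
        assert np.abs(res.residual_bins).max() < 1e-6

    def test_zero_pulses_leave_activity_untouched(self, rng):
        activity = rng.standard_normal((20, 15, 2))
        res = regress_out_pulses(activity, np.zeros((20, 7)))
        np.testing.assert_array_equal(res.residual_bins, activity)
        assert not res.weights.any()

    def test_stimulus_correlation_reduced(self):
        cfg = GeneratorConfig(n_neurons=4, n_trials=250, seed=13)
        sess, truth = generate_session(cfg)
        lat100 = truth.latents.reshape(250, 15, 100, 4).sum(axis=2)
        res = regress_out_pulses(lat100, sess.pulses.astype(float))
        s = sess.pulses.sum(axis=1)
        before = abs(np.corrcoef(lat100.sum(axis=1)[:, 0], s)[0, 1])
        after = abs(np.corrcoef(res.residual_sum[:, 0], s)[0, 1])
        assert after < before

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            regress_out_pulses(rng.standard_normal((5, 15, 2)),
                               rng.integers(-2, 3, (5, 7)))


class TestDecoder:
    def test_separable_residuals_give_perfect_heldout_cp(self):
        x = np.concatenate([np.full(30, -2.0), np.full(30, 2.0)])
        x += np.linspace(0, 0.1, 60)  # break ties, keep separation
        y = (x > 0).astype(int)
        _, mapping = fit_choice_decoder(x[:, None], y, seed=0)
        assert choice_probability(mapping, y).cp == 1.0

    def test_shuffled_choices_give_chance_cp(self, rng):
        x = rng.standard_normal((400, 3))
        y = rng.integers(0, 2, 400)
        _, mapping = fit_choice_decoder(x, y, seed=1)
        assert 0.45 < choice_probability(mapping, y).cp < 0.55

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_choice_decoder(np.zeros((10, 1)), np.ones(10), seed=0)

    def test_folds_are_stratified(self, rng):
        x = rng.standard_normal((90, 2))
        y = np.repeat([0, 1], [30, 60])
        dec, _ = fit_choice_decoder(x, y, seed=3)
        for f in range(3):
            fold_y = y[dec.fold_assignment == f]
            assert abs(fold_y.mean() - 2 / 3) < 0.05

    def test_decoder_map_is_sigmoid_of_linear_score(self, rng):
        x = rng.standard_normal((40, 2))
        y = (x[:, 0] + 0.3 * rng.standard_normal(40) > 0).astype(int)
        dec, _ = fit_choice_decoder(x, y, seed=0)
        c = dec.map(x)
        manual = 1 / (1 + np.exp(-(x @ dec.weights + dec.bias)))
        np.testing.assert_allclose(c, manual, atol=1e-12)


def _brute_force_cp(c1, c0):
    wins = sum((a > b) + 0.5 * (a == b) for a in c1 for b in c0)
    return wins / (len(c1) * len(c0))


class TestChoiceProbability:
    def test_fully_separated_values(self):
        c = np.array([0.9, 0.8, 0.1, 0.2])
        y = np.array([1, 1, 0, 0])
        assert choice_probability(c, y).cp == 1.0

    def test_all_ties_give_half(self):
        c = np.full(10, 0.5)
        y = np.array([0, 1] * 5)
        assert choice_probability(c, y).cp == 0.5

    def test_hand_counted_pairs(self):
        c = np.array([0.6, 0.4, 0.7, 0.5, 0.3])
        y = np.array([1, 1, 1, 0, 0])
        assert choice_probability(c, y).cp == pytest.approx(5 / 6)

    def test_one_empty_class_rejected(self):
        with pytest.raises(ValueError):
            choice_probability(np.array([0.5, 0.6]), np.array([1, 1]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        y = np.zeros(n, dtype=int)
        y[: int(rng.integers(1, n - 1))] = 1
        rng.shuffle(y)
        c = np.round(rng.random(n), 2)  # coarse values force ties
        cp = choice_probability(c, y).cp
        assert cp == pytest.approx(_brute_force_cp(c[y == 1], c[y == 0]),
                                   abs=1e-12)

    def test_matches_trapezoidal_roc_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        c = np.round(rng.random(80), 2)
        y = rng.integers(0, 2, 80)
        assert choice_probability(c, y).cp == pytest.approx(
            roc_auc_score(y, c), abs=1e-10)

    def test_bootstrap_se_is_reported(self, rng):
        c = rng.random(60)
        y = rng.integers(0, 2, 60)
        res = choice_probability(c, y, n_boot=50, seed=0)
        assert res.se is not None and 0 < res.se < 0.2


class TestNestedLR:
    def test_lr_never_exceeds_one(self, rng):
        for _ in range(5):
            n = 120
            cs, cn, cp_ = rng.random((3, n))
            y = (cs + 0.3 * rng.standard_normal(n) > 0.5).astype(int)
            res = nested_lr_tests(cs, cn, cp_, y)
            assert res.lr1 <= 1.0 and res.lr2 <= 1.0
            assert res.loglik_stim <= res.loglik_stim_nonstim <= res.loglik_full

    def test_null_p_values_are_calibrated(self):
        rng = np.random.default_rng(99)
        n_reject = 0
        for _ in range(100):
            n = 150
            cs = rng.random(n)
            y = (cs + 0.5 * rng.standard_normal(n) > 0.5).astype(int)
            cn = rng.random(n)       # independent of choice given cs
            cp_ = rng.random(n)
            res = nested_lr_tests(cs, cn, cp_, y)
            n_reject += res.p1 < 0.05
        assert n_reject <= 10

    def test_informative_added_regressor_detected(self, rng):
        n = 400
        z = rng.standard_normal(n)
        y = (z > 0).astype(int)
        cs = rng.random(n)
        cn = 1 / (1 + np.exp(-2 * z + rng.standard_normal(n)))
        res = nested_lr_tests(cs, cn, rng.random(n), y)
        assert res.p1 < 1e-6

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError):
            nested_lr_tests(np.zeros(5), np.zeros(4), np.zeros(5),
                            np.zeros(5, dtype=int))


class TestTimeCourse:
    def test_null_curves_stay_near_chance(self):
        cfg = GeneratorConfig(n_neurons=10, n_trials=600, seed=1)
        sess, truth = generate_session(cfg)
        pta = estimate_pta(truth.latents, sess.pulses)
        _, rotated = rotate_to_stimulus_axis(pta, truth.latents)
        res = run_choice_pipeline(sess, rotated, seed=1)
        nonstim = res.residual_latent.subset([1, 2, 3])
        tc = cp_time_course(nonstim, res.choices, seed=1)
        for curve in tc.cp.values():
            assert 0.45 < curve.mean() < 0.55
            assert np.all((curve > 0.40) & (curve < 0.60))

    def test_own_epoch_cp_beats_null_epoch(self, rng):
        # decoder trained on signal-bearing epoch scores >= chance in-sample
        n = 300
        r = rng.standard_normal((n, 15, 2))
        y = rng.integers(0, 2, n)
        r[:, 3:6, 0] += 0.8 * (2 * y - 1)[:, None]
        res = ResidualActivity(residual_bins=r, weights=np.zeros((15, 7, 2)))
        tc = cp_time_course(res, y, epochs={"early": (200, 500)}, seed=0)
        curve = tc.cp["early"]
        assert curve[3:6].mean() > 0.6
        assert curve[3:6].mean() > curve[10:13].mean()

    def test_bad_epoch_rejected(self, rng):
        res = ResidualActivity(residual_bins=rng.standard_normal((30, 15, 1)),
                               weights=np.zeros((15, 7, 1)))
        with pytest.raises(ValueError):
            cp_time_course(res, rng.integers(0, 2, 30),
                           epochs={"late": (1300, 1600)})


class TestPipeline:
    def test_pooled_cp_lies_within_per_session_hull(self):
        rng = np.random.default_rng(5)
        cps, cs, ys = [], [], []
        for s in range(2):
            n = 150
            y = rng.integers(0, 2, n)
            c = 0.5 + 0.2 * (2 * y - 1) * rng.random(n) \
                + 0.1 * rng.standard_normal(n)
            cps.append(choice_probability(c, y).cp)
            cs.append(c)
            ys.append(y)
        pooled = choice_probability(np.concatenate(cs), np.concatenate(ys)).cp
        assert min(cps) - 1e-9 <= pooled <= max(cps) + 1e-9

    def test_summary_and_mapping_export(self):
        cfg = GeneratorConfig(n_neurons=8, n_trials=300, seed=17)
        sess, truth = generate_session(cfg)
        pta = estimate_pta(truth.latents, sess.pulses)
        _, rotated = rotate_to_stimulus_axis(pta, truth.latents)
        res = run_choice_pipeline(sess, rotated, seed=0)
        text = res.summary()
        assert "stimulus" in text and "LR1" in text
        frame = mapping_frame(list(res.mappings.values()), res.choices)
        assert set(frame.columns) == {"session_id", "trial", "axis_set",
                                      "c_value", "choice"}
        assert len(frame) == 4 * res.weak.n_trials
        assert frame["c_value"].between(0, 1).all()


class TestSessionPooling:
    def test_pooling_similar_sessions_keeps_choice_information(self):
        from latentcp import session_pooled_likelihood_ratio

        rng = np.random.default_rng(8)
        cs, ys = [], []
        for _ in range(3):
            n = 200
            z = rng.standard_normal(n)
            y = (z + 0.5 * rng.standard_normal(n) > 0).astype(int)
            c = 1 / (1 + np.exp(-np.column_stack(
                [z + rng.standard_normal(n),
                 0.5 * z + rng.standard_normal(n),
                 rng.standard_normal(n)])))
            cs.append(c)
            ys.append(y)
        ratios = session_pooled_likelihood_ratio(cs, ys)
        assert len(ratios) == 3
        assert np.all((ratios > 0) & (ratios <= 1))
        # statistically identical sessions: the pooled fit loses at most the
        # per-session overfitting advantage (~df/2 nats), never collapses
        assert ratios.min() > np.exp(-4)
        assert ratios.mean() > 0.5
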