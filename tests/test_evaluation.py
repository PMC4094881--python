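"""Label decision strategies and the five multilabel metrics."""

import numpy as np
import pytest

from ihcloc.evaluation import compute_metrics, decide, tune_threshold

from _oracles import metrics_oracle


def sets_to_pm1(sets, L=6):
    out = -np.ones((len(sets), L))
    for i, s in enumerate(sets):
        for l in s:
            out[i, l - 1] = 1
    return out


def pm1_to_sets(M):
    return [set((np.flatnonzero(row > 0) + 1).tolist()) for row in M]


def random_label_sets(rng, n, allow_empty=False):
    sets = []
    for _ in range(n):
        k = rng.integers(0 if allow_empty else 1, 4)
        sets.append(set(rng.choice(6, size=k, replace=False) + 1))
    return sets


# ---------------------------------------------------------------------------
# decide / tune_threshold
# ---------------------------------------------------------------------------

def test_decide_threshold_strategy():
    y = decide(np.array([0.5, -1, -1, -1, -1, -1]), T=0.0, guarantee=False)
    np.testing.assert_array_equal(y, [1, -1, -1, -1, -1, -1])


def test_decide_guarantee_assigns_argmax_when_all_below():
    y = decide(np.array([-0.5, -0.2, -0.9, -1, -1, -1]), T=0.0,
               guarantee=True)
    np.testing.assert_array_equal(y, [-1, 1, -1, -1, -1, -1])


def test_decide_guarantee_tie_breaks_to_lowest_index():
    y = decide(np.array([-0.3, -0.3, -0.3, -0.3, -0.3, -0.3]), T=0.0)
    np.testing.assert_array_equal(y, [1, -1, -1, -1, -1, -1])


def test_decide_without_guarantee_can_be_empty():
    y = decide(np.full(6, -1.0), T=0.0, guarantee=False)
    assert np.all(y == -1)


def test_decide_threshold_is_inclusive():
    y = decide(np.array([0.3, 0.0, -0.1, -1, -1, -1]), T=0.0,
               guarantee=False)
    np.testing.assert_array_equal(y, [1, 1, -1, -1, -1, -1])


def test_decide_rejects_nonfinite():
    with pytest.raises(ValueError):
        decide(np.array([np.nan, 0, 0, 0, 0, 0]), 0.0)


def test_tune_threshold_separated_scores_smallest_optimum():
    """With +1/-1 separated scores, every grid point in (-1, 1] is optimal;
    the smallest (-0.9) is returned."""
    truth_sets = [{1}, {2, 3}, {4}]
    truth = sets_to_pm1(truth_sets)
    scores = np.where(truth > 0, 1.0, -1.0)
    T = tune_threshold(scores, truth)
    assert T == pytest.approx(-0.9)


def test_tune_threshold_matches_bruteforce_grid():
    rng = np.random.default_rng(3)
    scores = rng.normal(0, 1, size=(30, 6))
    truth = sets_to_pm1(random_label_sets(rng, 30))
    T = tune_threshold(scores, truth)
    grid = -2.0 + 0.1 * np.arange(41)
    accs = [compute_metrics(decide(scores, t), truth).subset_accuracy
            for t in grid]
    best = grid[int(np.argmax(accs))]
    assert T == pytest.approx(best)


def test_tune_threshold_single_sample_binary_outcome():
    truth = sets_to_pm1([{2}])
    scores = np.array([[-1.0, 2.0, -1, -1, -1, -1]])
    T = tune_threshold(scores, truth)
    acc = compute_metrics(decide(scores, T), truth).subset_accuracy
    assert acc in (0.0, 1.0)


def test_tune_threshold_validates_input():
    with pytest.raises(ValueError):
        tune_threshold(np.empty((0, 6)), np.empty((0, 6)))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_perfect_prediction_gives_all_ones():
    truth = sets_to_pm1([{1}, {2, 3}, {4, 5, 6}])
    rep = compute_metrics(truth, truth)
    assert rep.subset_accuracy == 1.0
    assert rep.accuracy == 1.0
    assert rep.recall == 1.0
    assert rep.precision == 1.0
    assert rep.average_label_accuracy == 1.0


def test_partial_credit_point_score():
    """truth {1,3}, pred {1}: one correct label over a union of two."""
    truth = sets_to_pm1([{1, 3}])
    pred = sets_to_pm1([{1}])
    rep = compute_metrics(pred, truth)
    assert rep.subset_accuracy == 0.0
    assert rep.accuracy == pytest.approx(0.5)


def test_metrics_match_set_arithmetic_oracle():
    """200 random prediction/truth pairs agree with the independent
    set-arithmetic implementation to 1e-12."""
    rng = np.random.default_rng(42)
    for trial in range(10):
        n = 20
        truth_sets = random_label_sets(rng, n)
        pred_sets = random_label_sets(rng, n, allow_empty=True)
        rep = compute_metrics(sets_to_pm1(pred_sets), sets_to_pm1(truth_sets))
        sub, acc, rec, prec, avg = metrics_oracle(truth_sets, pred_sets)
        assert rep.subset_accuracy == pytest.approx(sub, abs=1e-12)
        assert rep.accuracy == pytest.approx(acc, abs=1e-12)
        assert rep.recall == pytest.approx(rec, abs=1e-12)
        assert rep.precision == pytest.approx(prec, abs=1e-12)
        assert rep.average_label_accuracy == pytest.approx(avg, abs=1e-12)


def test_subset_accuracy_never_exceeds_accuracy():
    rng = np.random.default_rng(7)
    for trial in range(20):
        truth = sets_to_pm1(random_label_sets(rng, 15))
        pred = sets_to_pm1(random_label_sets(rng, 15, allow_empty=True))
        rep = compute_metrics(pred, truth)
        assert rep.subset_accuracy <= rep.accuracy + 1e-12


def test_guarantee_never_leaves_empty_prediction():
    rng = np.random.default_rng(9)
    scores = rng.normal(-3, 1, size=(50, 6))  # mostly below any T in grid
    pred = decide(scores, T=0.0, guarantee=True)
    assert np.all((pred > 0).sum(axis=1) >= 1)


def test_metrics_permutation_invariant():
    rng = np.random.default_rng(11)
    truth = sets_to_pm1(random_label_sets(rng, 25))
    pred = sets_to_pm1(random_label_sets(rng, 25))
    rep1 = compute_metrics(pred, truth)
    perm = rng.permutation(25)
    rep2 = compute_metrics(pred[perm], truth[perm])
    d1, d2 = rep1.as_dict(), rep2.as_dict()
    assert d1.keys() == d2.keys()
    for k in d1:
        np.testing.assert_allclose(np.asarray(d1[k], float),
                                   np.asarray(d2[k], float), equal_nan=True)


def test_average_label_accuracy_is_mean_of_per_label():
    rng = np.random.default_rng(13)
    truth = sets_to_pm1(random_label_sets(rng, 12))
    pred = sets_to_pm1(random_label_sets(rng, 12))
    rep = compute_metrics(pred, truth)
    assert rep.average_label_accuracy == pytest.approx(
        rep.per_label_accuracy.mean())
    assert np.all((0 <= rep.per_label_accuracy)
                  & (rep.per_label_accuracy <= 1))


def test_metrics_validate_shapes():
    with pytest.raises(ValueError):
        compute_metrics(np.ones((3, 6)), np.ones((4, 6)))
    with pytest.raises(ValueError):
        compute_metrics(np.ones((3, 5)), np.ones((3, 5)))
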