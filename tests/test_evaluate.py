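import numpy as np
import pandas as pd
import pytest

from conftest import naive_auroc
from sitefold.evaluate import (
    BaselineScorer,
    EvaluationReport,
    PredictionSet,
    bootstrap_auroc,
    compare_auroc,
    crossval_evaluate,
    ovr_auroc,
    tile_fp_chi2,
)


def binary_preds(scores, labels, folds=None, slides=None):
    n = len(scores)
    frame = pd.DataFrame(
        {
            "slide_id": slides or [f"s{i}" for i in range(n)],
            "patient_id": [f"p{(slides or [f's{i}' for i in range(n)])[i]}" for i in range(n)],
            "fold": folds or [0] * n,
            "label": labels,
            "score_pos": scores,
            "score_neg": [1 - s for s in scores],
        }
    )
    return PredictionSet(frame=frame, class_labels=["neg", "pos"])


def report_of(fold_aurocs):
    return EvaluationReport(
        per_fold=pd.DataFrame(),
        fold_auroc=np.asarray(fold_aurocs, dtype=float),
        mean_auroc=float(np.mean(fold_aurocs)),
        aggregate="slide",
    )


# ---------------------------------------------------------------------------
# AUROC


def test_ovr_auroc_hand_example():
    preds = binary_preds([0.1, 0.4, 0.35, 0.8], ["neg", "neg", "pos", "pos"])
    out = ovr_auroc(preds)
    assert out["pos"] == pytest.approx(0.75)


def test_perfect_and_tied_scores():
    assert ovr_auroc(binary_preds([0.1, 0.2, 0.8, 0.9], ["neg", "neg", "pos", "pos"]))[
        "pos"
    ] == pytest.approx(1.0)
    assert ovr_auroc(binary_preds([0.5] * 6, ["neg", "pos"] * 3))["pos"] == pytest.approx(0.5)


def test_auroc_matches_pair_count_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(5, 50))
        labels = rng.integers(0, 2, size=n).astype(bool)
        if labels.all() or not labels.any():
            continue
        scores = np.round(rng.uniform(0, 1, size=n), 2)  # rounded so ties occur
        preds = binary_preds(scores.tolist(), ["pos" if y else "neg" for y in labels])
        assert ovr_auroc(preds)["pos"] == pytest.approx(
            naive_auroc(labels.tolist(), scores.tolist()), abs=1e-12
        )


def test_binary_class_symmetry(rng):
    labels = ["pos" if v else "neg" for v in rng.integers(0, 2, size=20)]
    scores = rng.uniform(0, 1, size=20).tolist()
    out = ovr_auroc(binary_preds(scores, labels))
    # with complementary scores, the neg-vs-rest ranking mirrors the pos one
    assert out["neg"] == pytest.approx(out["pos"], abs=1e-12)
    # swapping the target while keeping the pos score gives the complement
    flipped = naive_auroc([y == "neg" for y in labels], scores)
    assert flipped == pytest.approx(1.0 - out["pos"], abs=1e-12)


def test_degenerate_class_skipped_with_warning():
    preds = binary_preds([0.2, 0.8, 0.5], ["pos", "pos", "pos"])
    with pytest.warns(UserWarning, match="degenerate"):
        with pytest.raises(ValueError):
            ovr_auroc(preds)


# ---------------------------------------------------------------------------
# Cross-validated evaluation


def test_slide_aggregation_means_tile_scores():
    frame = pd.DataFrame(
        {
            "slide_id": ["s1", "s1", "s2", "s2"],
            "patient_id": ["p1", "p1", "p2", "p2"],
            "fold": [0, 0, 0, 0],
            "label": ["pos", "pos", "neg", "neg"],
            "score_pos": [0.2, 0.8, 0.3, 0.5],
            "score_neg": [0.8, 0.2, 0.7, 0.5],
        }
    )
    preds = PredictionSet(frame=frame, class_labels=["neg", "pos"])
    agg = preds.aggregated("slide").set_index("slide_id")
    assert agg.loc["s1", "score_pos"] == pytest.approx(0.5)
    assert agg.loc["s2", "score_pos"] == pytest.approx(0.4)


def test_mean_auroc_over_folds():
    scores, labels, folds, slides = [], [], [], []
    per_fold = {0: 1.0, 1: 1.0, 2: 0.0}
    for fold, auc in per_fold.items():
        pos, neg = (0.9, 0.1) if auc == 1.0 else (0.1, 0.9)
        scores += [pos, neg]
        labels += ["pos", "neg"]
        folds += [fold, fold]
        slides += [f"f{fold}a", f"f{fold}b"]
    rep = crossval_evaluate(binary_preds(scores, labels, folds, slides))
    assert rep.fold_auroc.tolist() == [1.0, 1.0, 0.0]
    assert rep.mean_auroc == pytest.approx(2 / 3)


def test_crossval_needs_two_folds():
    with pytest.raises(ValueError, match="folds"):
        crossval_evaluate(binary_preds([0.2, 0.8], ["neg", "pos"]))


# ---------------------------------------------------------------------------
# Bootstrap


def test_bootstrap_constant_scores_all_half():
    preds = binary_preds(
        [0.5] * 8, ["pos", "neg"] * 4, folds=[0, 0, 0, 0, 1, 1, 1, 1]
    )
    reps = bootstrap_auroc(preds, reps=10, seed=0)
    assert reps.shape == (2, 10)
    assert np.allclose(reps, 0.5)


def test_bootstrap_spread_shrinks_with_more_slides(rng):
    def preds_of(n):
        labels = ["pos", "neg"] * n
        scores = np.clip(
            [0.7 + rng.normal(0, 0.15) if y == "pos" else 0.3 + rng.normal(0, 0.15) for y in labels],
            0.0,
            1.0,
        )
        return binary_preds(list(scores), labels)

    small = bootstrap_auroc(preds_of(10), reps=10, seed=1)
    large = bootstrap_auroc(preds_of(100), reps=10, seed=1)
    assert large.var() < small.var()


# ---------------------------------------------------------------------------
# t-tests


def test_paired_identical_reports_tie():
    res = compare_auroc(report_of([0.7, 0.8, 0.9]), report_of([0.7, 0.8, 0.9]),
                        "paired_two_sided_df2")
    assert res.tie and res.p == 1.0 and res.df == 2


def test_constant_aurocs_above_chance_infinite_t():
    res = compare_auroc(report_of([0.9, 0.9, 0.9]), None, "vs_chance_one_sided_df2")
    assert np.isinf(res.t) and res.t > 0
    assert res.p == 0.0 and res.df == 2


def test_two_sample_mode_degrees_of_freedom_and_direction():
    res = compare_auroc(
        report_of([0.9, 0.85, 0.95]), report_of([0.5, 0.55, 0.45]),
        "two_sample_one_sided_df4",
    )
    assert res.df == 4
    assert res.t > 0 and res.p < 0.01
    rev = compare_auroc(
        report_of([0.5, 0.55, 0.45]), report_of([0.9, 0.85, 0.95]),
        "two_sample_one_sided_df4",
    )
    assert rev.p > 0.95


def test_unknown_mode_rejected():
    with pytest.raises(ValueError, match="mode"):
        compare_auroc(report_of([0.5]), None, "anova")


# ---------------------------------------------------------------------------
# Tile-level false positives


def fp_preds(fp, tp, other=50):
    """PredictionSet with fp false and tp true tiles predicted 'target'."""
    n = fp + tp + other
    labels = ["other"] * fp + ["target"] * tp + ["other"] * other
    score_t = [0.9] * (fp + tp) + [0.1] * other
    frame = pd.DataFrame(
        {
            "slide_id": [f"s{i}" for i in range(n)],
            "patient_id": [f"p{i}" for i in range(n)],
            "fold": [0] * n,
            "label": labels,
            "score_target": score_t,
            "score_other": [1 - s for s in score_t],
        }
    )
    return PredictionSet(frame=frame, class_labels=["other", "target"])


def test_identical_sets_zero_chi2():
    a, b = fp_preds(10, 40), fp_preds(10, 40)
    out = tile_fp_chi2(a, b, "target")
    assert out["chi2"] == pytest.approx(0.0)
    assert out["df"] == 1


def test_fp_chi2_pearson_value_and_proportions():
    out = tile_fp_chi2(fp_preds(30, 70), fp_preds(10, 90), "target")
    # Pearson without correction on [[30,70],[10,90]]
    assert out["chi2"] == pytest.approx(12.5)
    assert out["proportions"]["standard"]["fp_proportion"] == pytest.approx(0.3)
    assert out["proportions"]["preserved"]["fp_proportion"] == pytest.approx(0.1)
    sd = out["proportions"]["standard"]["sd"]
    assert sd == pytest.approx(np.sqrt(0.3 * 0.7 / 100))


def test_empty_predicted_class_is_an_error():
    with pytest.raises(ValueError, match="predicted"):
        tile_fp_chi2(fp_preds(0, 0, other=10), fp_preds(5, 5), "target")


# ---------------------------------------------------------------------------
# Baseline scorer


def test_scorer_learns_separable_classes(rng):
    X = np.vstack([rng.normal(0, 1, (60, 5)), rng.normal(4, 1, (60, 5))])
    y = np.array(["a"] * 60 + ["b"] * 60)
    test_X = np.vstack([rng.normal(0, 1, (20, 5)), rng.normal(4, 1, (20, 5))])
    test_y = [True] * 20 + [False] * 20
    scorer = BaselineScorer(seed=0).fit(X, y)
    proba = scorer.predict_proba(test_X)[:, scorer.classes_.index("a")]
    assert naive_auroc(test_y, proba.tolist()) >= 0.95


def test_scorer_shuffled_labels_near_chance(rng):
    X = rng.normal(0, 1, (200, 5))
    y = np.array(["a", "b"] * 100)
    scorer = BaselineScorer(seed=1).fit(X[:150], y[:150])
    proba = scorer.predict_proba(X[150:])[:, scorer.classes_.index("a")]
    auc = naive_auroc([v == "a" for v in y[150:]], proba.tolist())
    assert 0.3 <= auc <= 0.7


def test_scorer_deterministic_and_single_class_error(rng):
    X = rng.normal(0, 1, (40, 4))
    y = np.array(["a", "b"] * 20)
    p1 = BaselineScorer(seed=3).fit(X, y).predict_proba(X)
    p2 = BaselineScorer(seed=3).fit(X, y).predict_proba(X)
    assert np.array_equal(p1, p2)
    with pytest.raises(ValueError, match="single class"):
        BaselineScorer(seed=0).fit(X, np.array(["a"] * 40))


# ---------------------------------------------------------------------------
# PredictionSet invariants


def test_prediction_set_invariants():
    frame = pd.DataFrame(
        {
            "slide_id": ["s1", "s2"],
            "patient_id": ["p1", "p1"],
            "fold": [0, 1],
            "label": ["pos", "neg"],
            "score_pos": [0.6, 0.4],
            "score_neg": [0.4, 0.6],
        }
    )
    with pytest.raises(ValueError, match="fold"):
        PredictionSet(frame=frame, class_labels=["neg", "pos"])
    bad = frame.assign(patient_id=["p1", "p2"], score_neg=[0.3, 0.3])
    with pytest.raises(ValueError, match="sum"):
        PredictionSet(frame=bad, class_labels=["neg", "pos"])
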