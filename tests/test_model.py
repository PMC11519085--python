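"""Pair classifier, vote aggregation, pipeline, CV and grid search."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairlr import (
    CohortSpec,
    PairlrError,
    PairSet,
    PipelineConfig,
    aggregate_votes,
    crossvalidate,
    fit_pair_classifier,
    fit_pipeline,
    fit_plain_classifier,
    generate_cohort,
    grid_optimize,
    predict,
    roc_auc,
    split_cohort,
)


def _pairset(vectors, labels):
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim == 1:
        vectors = vectors[:, None]
    n = len(vectors)
    return PairSet(
        vectors=vectors,
        pair_labels=np.asarray(labels, dtype=int),
        template_ids=[f"t{i}" for i in range(n)],
        sample_ids=[f"s{i}" for i in range(n)],
    )


# --- pair classifier -------------------------------------------------------

def test_gaussian_nb_hand_posterior():
    # positives at {-0.1, 0, 0.1}, negatives at {1.9, 2, 2.1}
    pairs = _pairset([-0.1, 0.0, 0.1, 1.9, 2.0, 2.1], [1, 1, 1, 0, 0, 0])
    clf = fit_pair_classifier(pairs, "gaussian_nb")
    # hand Gaussian NB: equal priors, both classes var 1/150 (+ smoothing)
    eps = 1e-9 * np.var(pairs.vectors[:, 0])
    var = 0.02 / 3 + eps

    def posterior(x):
        lp = np.exp(-((x - 0.0) ** 2) / (2 * var))
        ln = np.exp(-((x - 2.0) ** 2) / (2 * var))
        return lp / (lp + ln)

    assert clf.predict_ppp([[-0.05]])[0] == pytest.approx(posterior(-0.05), abs=1e-9)
    assert clf.predict_ppp([[-0.05]])[0] > 0.5
    assert clf.predict_ppp([[1.5]])[0] < 0.5          # nearer the negatives
    assert clf.predict_ppp([[1.0]])[0] == pytest.approx(0.5, abs=1e-9)  # midpoint
    assert clf.estimator.predict([[1.0]])[0] == 0      # midpoint tie -> negative


def test_duplicate_feature_pairs_train_with_variance_floor():
    # a zero-variance pair dimension must not crash the Gaussian fit
    vecs = np.column_stack([[0.0, 0.1, 2.0, 2.1], [1.0, 1.0, 1.0, 1.0]])
    clf = fit_pair_classifier(_pairset(vecs, [1, 1, 0, 0]), "gaussian_nb")
    assert np.isfinite(clf.predict_ppp([[1.0, 1.0]])).all()


def test_fit_deterministic_under_seed():
    rng = np.random.default_rng(0)
    vecs = rng.standard_normal((40, 3))
    labels = (vecs[:, 0] > 0).astype(int)
    c1 = fit_pair_classifier(_pairset(vecs, labels), "random_forest", seed=4)
    c2 = fit_pair_classifier(_pairset(vecs, labels), "random_forest", seed=4)
    np.testing.assert_array_equal(
        c1.predict_ppp(vecs), c2.predict_ppp(vecs)
    )


def test_single_pair_class_rejected():
    with pytest.raises(PairlrError, match="positive and negative"):
        fit_pair_classifier(_pairset([0.0, 1.0], [1, 1]))


# --- vote aggregation ------------------------------------------------------

def test_vote_hand_example():
    # labels [1,1,0], P_PP [0.8,0.6,0.3] -> s [0.8,0.6,0.7], P 0.7, class 1
    p, cls, s = aggregate_votes([0.8, 0.6, 0.3], [1, 1, 0])
    np.testing.assert_allclose(s, [0.8, 0.6, 0.7])
    assert p == pytest.approx(0.7)
    assert cls == 1


def test_vote_unanimous_positive():
    p, cls, _ = aggregate_votes([1.0, 1.0], [1, 1])
    assert p == 1.0 and cls == 1


def test_vote_tie_goes_to_event_class():
    p, cls, _ = aggregate_votes([0.5, 0.5], [1, 0])
    assert p == 0.5 and cls == 1


def test_vote_input_validation():
    with pytest.raises(PairlrError, match="empty"):
        aggregate_votes([], [])
    with pytest.raises(PairlrError, match="\\[0, 1\\]"):
        aggregate_votes([1.2], [1])


def _brute_force_vote(probs, labels, threshold=0.5):
    """Independent loop implementation of the template-voting rule."""
    total = 0.0
    for p_pp, m in zip(probs, labels):
        total += p_pp if m == 1 else 1.0 - p_pp
    p_i = total / len(probs)
    if p_i >= threshold:
        return p_i, 1
    return p_i, 0


def test_vote_matches_exhaustive_brute_force():
    grid = [0.0, 0.25, 0.5, 0.75, 1.0]
    for n_templates in range(1, 5):
        for labels in product([0, 1], repeat=n_templates):
            for probs in product(grid, repeat=n_templates):
                p_ref, c_ref = _brute_force_vote(probs, labels)
                p, c, _ = aggregate_votes(probs, labels)
                assert abs(p - p_ref) <= 1e-12
                assert c == c_ref


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(st.floats(0, 1), min_size=1, max_size=8),
    st.data(),
)
def test_vote_label_symmetry_and_range(probs, data):
    labels = data.draw(
        st.lists(st.integers(0, 1), min_size=len(probs), max_size=len(probs))
    )
    p, cls, _ = aggregate_votes(probs, labels)
    assert 0.0 <= p <= 1.0
    p_flip, cls_flip, _ = aggregate_votes(probs, [1 - m for m in labels])
    assert p_flip == pytest.approx(1.0 - p, abs=1e-12)
    if abs(p - 0.5) > 1e-9:
        assert cls_flip == 1 - cls


def test_duplicate_template_shifts_vote_by_at_most_one_slot():
    probs, labels = [0.9, 0.2, 0.6], [1, 0, 1]
    p, _, _ = aggregate_votes(probs, labels)
    p_dup, _, _ = aggregate_votes(probs + [probs[0]], labels + [labels[0]])
    assert abs(p_dup - p) <= 1.0 / 4 + 1e-12


# --- cohort splitting ------------------------------------------------------

def test_split_reproduces_cohort_sizes(cohort):
    train, test = split_cohort(cohort, cohort.labels, 0.7, seed=0)
    assert (train.n_samples, test.n_samples) == (91, 39)
    assert (int(train.labels.sum()), int(test.labels.sum())) == (45, 19)


def test_split_partition_properties(cohort):
    train, test = split_cohort(cohort, cohort.labels, 0.7, seed=1)
    assert set(train.sample_ids) | set(test.sample_ids) == set(cohort.sample_ids)
    assert set(train.sample_ids) & set(test.sample_ids) == set()
    t2, _ = split_cohort(cohort, cohort.labels, 0.7, seed=2)
    assert t2.n_samples == train.n_samples
    assert set(t2.sample_ids) != set(train.sample_ids)


# --- pipeline --------------------------------------------------------------

def test_pipeline_smoke_self_auc_above_chance(cohort):
    model = fit_pipeline(cohort, cohort.labels, PipelineConfig(seed=42))
    res = predict(model, cohort)
    assert roc_auc(res.probabilities, cohort.labels) > 0.5


def test_pipeline_stores_requested_feature_count(cohort):
    model = fit_pipeline(cohort, cohort.labels,
                         PipelineConfig(n_features=12, seed=0))
    assert len(model.selected_features) == 12


def test_pipeline_rejects_oversized_feature_request(small_table):
    cfg = PipelineConfig(n_features=50, n_templates=2, seed=0)
    with pytest.raises(PairlrError, match="n_features"):
        fit_pipeline(small_table, small_table.labels, cfg)


def test_predict_row_order_invariant(cohort):
    model = fit_pipeline(cohort, cohort.labels, PipelineConfig(seed=3))
    res = predict(model, cohort)
    perm = np.random.default_rng(0).permutation(cohort.n_samples)
    shuffled = cohort.select_samples(perm)
    res_perm = predict(model, shuffled)
    lookup = dict(zip(res.sample_ids, res.probabilities))
    for sid, p in zip(res_perm.sample_ids, res_perm.probabilities):
        assert p == lookup[sid]


def test_predict_single_sample(cohort):
    model = fit_pipeline(cohort, cohort.labels, PipelineConfig(seed=3))
    res = predict(model, cohort.select_samples([0]))
    assert len(res.sample_ids) == 1
    assert res.contributions.shape == (1, 7)


def test_predict_missing_feature_column_named(cohort):
    model = fit_pipeline(cohort, cohort.labels, PipelineConfig(seed=3))
    crippled = cohort.select_features(cohort.feature_names[1:])
    with pytest.raises(PairlrError, match=cohort.feature_names[0]):
        predict(model, crippled)


def test_stored_template_scores_above_threshold(cohort):
    model = fit_pipeline(cohort, cohort.labels, PipelineConfig(seed=5))
    tpl_ids = model.templates.sample_ids
    idx = [cohort.sample_ids.index(s) for s in tpl_ids]
    res = predict(model, cohort.select_samples(idx))
    # class-1 templates should score as events against their own model
    for p, lab in zip(res.probabilities, model.templates.labels):
        if lab == 1:
            assert p > 0.5


def test_pca_reduction_path_runs(cohort):
    cfg = PipelineConfig(reduction="pca", n_features=5, seed=1)
    model = fit_pipeline(cohort, cohort.labels, cfg)
    res = predict(model, cohort)
    assert roc_auc(res.probabilities, cohort.labels) > 0.5


# --- cross-validation ------------------------------------------------------

def test_cv_fold_sizes_and_mean(cohort):
    train, _ = split_cohort(cohort, cohort.labels, 0.7, seed=0)
    cv = crossvalidate(train, train.labels, PipelineConfig(seed=0))
    sizes = sorted(f["n_val"] for f in cv["folds"])
    assert sizes == [18, 18, 18, 18, 19]
    assert cv["mean_auc_val"] == pytest.approx(
        np.mean([f["auc_val"] for f in cv["folds"]])
    )


def test_cv_no_validation_sample_in_fitted_statistics(cohort):
    train, _ = split_cohort(cohort, cohort.labels, 0.7, seed=0)
    cv = crossvalidate(train, train.labels, PipelineConfig(seed=0))
    for fold in cv["folds"]:
        assert set(fold["fitted_on"]) & set(fold["val_sample_ids"]) == set()
        assert set(fold["fitted_on"]) == set(fold["train_sample_ids"])


def test_cv_rejects_too_many_folds(small_table):
    cfg = PipelineConfig(cv_folds=6, n_templates=2, n_features=2, seed=0)
    with pytest.raises(PairlrError, match="folds"):
        crossvalidate(small_table, small_table.labels, cfg)


# --- grid search -----------------------------------------------------------

def test_grid_single_cell_returns_that_config(cohort):
    train, _ = split_cohort(cohort, cohort.labels, 0.7, seed=0)
    grid = {"n_features": [3], "classifier": ["gaussian_nb"]}
    ranked, best = grid_optimize(train, train.labels, grid,
                                 PipelineConfig(seed=0))
    assert len(ranked) == 1
    assert best.config.n_features == 3
    assert best.config.classifier == "gaussian_nb"


def test_grid_ranking_reproducible(cohort):
    train, _ = split_cohort(cohort, cohort.labels, 0.7, seed=0)
    grid = {"n_features": [2, 4], "classifier": ["gaussian_nb", "lda"]}
    r1, _ = grid_optimize(train, train.labels, grid, PipelineConfig(seed=1))
    r2, _ = grid_optimize(train, train.labels, grid, PipelineConfig(seed=1))
    assert r1.to_csv() == r2.to_csv()
    assert (r1["cv_auc_val"].values[:-1] >= r1["cv_auc_val"].values[1:]).all()


def test_grid_records_failed_cells(cohort):
    train, _ = split_cohort(cohort, cohort.labels, 0.7, seed=0)
    grid = {"n_features": [3, 500], "classifier": ["gaussian_nb"]}
    ranked, _ = grid_optimize(train, train.labels, grid, PipelineConfig(seed=0))
    assert (ranked["status"] == "failed").sum() == 1
    assert (ranked["status"] == "ok").sum() == 1


# --- plain (non-pairwise) baseline ----------------------------------------

def test_plain_classifier_separable_training_auc_one():
    rng = np.random.default_rng(0)
    from pairlr import FeatureTable
    labels = np.array([0] * 20 + [1] * 20)
    x = rng.standard_normal((40, 3))
    x[:, 0] += labels * 10.0
    t = FeatureTable([f"s{i}" for i in range(40)], ["a", "b", "c"], x,
                     labels=labels)
    cfg = PipelineConfig(n_features=3, n_templates=2, seed=0)
    model = fit_plain_classifier(t, labels, "gaussian_nb", cfg)
    res = predict(model, t)
    assert roc_auc(res.probabilities, labels) == 1.0


def test_plain_and_pairwise_share_predict_api(cohort):
    cfg = PipelineConfig(n_features=5, seed=0)
    pair = fit_pipeline(cohort, cohort.labels, cfg)
    plain = fit_plain_classifier(cohort, cohort.labels, "gaussian_nb", cfg)
    rp, rq = predict(pair, cohort), predict(plain, cohort)
    assert rp.sample_ids == rq.sample_ids
    for r in (rp, rq):
        assert ((r.probabilities >= 0) & (r.probabilities <= 1)).all()
        assert set(np.unique(r.predicted)) <= {0, 1}
    assert rq.contributions is None and rp.contributions is not None
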