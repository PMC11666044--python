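"""Nested-CV plan integrity, metrics, grid selection, robustness harness,
and the PCA report."""

import numpy as np
import pandas as pd
import pytest

from popgcn.benchmark import (
    compute_metrics,
    make_splits,
    pca_report,
    robustness_test,
    run_nested_cv,
    subset_task,
    sweep_beta,
    default_grids,
)
from popgcn.synthetic_cohort import Cohort


# ---------------------------------------------------------------------------
# split plan
# ---------------------------------------------------------------------------

def test_plan_has_twenty_models_and_partition_structure(small_cohort, small_plan):
    plan = small_plan
    assert plan.n_models == 20
    n = small_cohort.n
    # the 5 outer test folds partition the cohort
    outer_tests = {}
    for rec in plan.records:
        outer_tests.setdefault(rec.outer_fold, rec.test_idx)
    all_test = np.concatenate(list(outer_tests.values()))
    assert sorted(all_test) == list(range(n))
    # per record: disjoint test/train/val covering everything
    for rec in plan.records:
        combined = np.concatenate([rec.test_idx, rec.train_idx, rec.val_idx])
        assert sorted(combined) == list(range(n))
    # each subject is a test case exactly inner_k=4 times
    counts = np.zeros(n, int)
    for rec in plan.records:
        counts[rec.test_idx] += 1
    assert np.all(counts == 4)


def test_plan_stratification_within_one_subject(small_cohort, small_plan):
    labels = small_cohort.labels
    for rec in small_plan.records:
        fold_labels = labels[rec.test_idx]
        for cls in np.unique(labels):
            expect = (labels == cls).sum() / 5
            got = (fold_labels == cls).sum()
            assert abs(got - expect) <= 1


def test_plan_deterministic_and_guards(small_cohort):
    p1 = make_splits(small_cohort.labels, seed=3)
    p2 = make_splits(small_cohort.labels, seed=3)
    for a, b in zip(p1.records, p2.records):
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.val_idx, b.val_idx)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)
    with pytest.raises(ValueError):
        make_splits(np.array([0, 0, 0, 1, 1, 1, 2, 2, 2]), outer_k=5)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_metrics_perfect_prediction():
    y = np.array([0, 0, 2, 2])
    scores = np.array([0.1, 0.2, 0.9, 0.8])
    m = compute_metrics(y, y, scores)
    assert m["accuracy"] == m["precision"] == m["recall"] == m["f1"] == 1.0
    assert m["auc"] == 1.0


def test_metrics_f1_harmonic_mean_and_confusion_identity():
    # precision 0.5, recall 1.0 -> F1 = 2/3
    y_true = np.array([2, 2, 0, 0])
    y_pred = np.array([2, 2, 2, 2])
    m = compute_metrics(y_true, y_pred)
    assert m["precision"] == pytest.approx(0.5)
    assert m["recall"] == pytest.approx(1.0)
    assert m["f1"] == pytest.approx(2 / 3)
    assert m["accuracy"] == pytest.approx(np.trace(m["confusion"]) / m["confusion"].sum())


def test_metrics_positive_class_is_advanced_stage_and_zero_division_flag():
    # all predictions negative: recall for the advanced class is 0, flagged
    y_true = np.array([0, 0, 2, 2])
    y_pred = np.array([0, 0, 0, 0])
    m = compute_metrics(y_true, y_pred)
    assert m["recall"] == 0.0 and m["precision"] == 0.0 and m["f1"] == 0.0
    assert m["zero_division_flag"]
    with pytest.raises(ValueError):
        compute_metrics(np.array([]), np.array([]))


# ---------------------------------------------------------------------------
# nested CV
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def ed_report(small_cohort, small_plan):
    return run_nested_cv(
        small_cohort, "gcn-ed", small_plan,
        {"beta": [0.3], "alpha": [31.0], "hidden_units": [16]},
        seed=0, keep_artifacts=True,
    )


def test_nested_cv_report_counts_and_ranges(ed_report, small_cohort, small_plan):
    assert len(ed_report.per_model) == 20
    mean, sd = ed_report.summary["accuracy"]
    assert 0.0 <= mean <= 1.0 and sd >= 0.0
    # pooled multiclass confusion total = sum of test-fold sizes x inner_k
    assert ed_report.pooled_confusion.sum() == small_cohort.n * small_plan.inner_k


def test_nested_cv_single_candidate_selection_is_noop(ed_report):
    assert ed_report.best_params == {"alpha": 31.0, "beta": 0.3, "hidden_units": 16}
    assert len(ed_report.grid_results) == 1


def test_grid_selection_by_mean_validation_loss(small_cohort, small_plan):
    report = run_nested_cv(
        small_cohort, "gcn-ed", small_plan,
        {"beta": [0.2, 0.8], "alpha": [31.0], "hidden_units": [16]},
        seed=0,
    )
    gr = report.grid_results
    best_row = gr.loc[gr["mean_val_loss"].idxmin()]
    assert report.best_params["beta"] == best_row["beta"]


def test_selection_leakage_audit_test_labels_do_not_steer_selection(small_cohort, small_plan):
    """With the plan restricted to one outer loop (where the perturbed
    subjects are test-only), flipping their labels changes neither the
    candidate validation losses nor the selected hyperparameters — only the
    reported test metrics."""
    from popgcn.benchmark import SplitPlan

    sub_plan = SplitPlan(outer_k=5, inner_k=4, seed=0, records=small_plan.records[:4])
    grid = {"beta": [0.2, 0.8], "alpha": [31.0], "hidden_units": [8]}
    base = run_nested_cv(small_cohort, "gcn-ed", sub_plan, grid, seed=0)
    fold0 = sub_plan.records[0].test_idx
    labels2 = small_cohort.labels.copy()
    labels2[fold0] = (labels2[fold0] + 1) % 3
    cohort2 = Cohort(
        subject_ids=small_cohort.subject_ids,
        labels=labels2,
        clinical=small_cohort.clinical,
        latent_features=small_cohort.latent_features,
    )
    perturbed = run_nested_cv(cohort2, "gcn-ed", sub_plan, grid, seed=0)
    pd.testing.assert_frame_equal(base.grid_results, perturbed.grid_results)
    assert base.best_params == perturbed.best_params
    # but the perturbation is visible where it should be: in test metrics
    assert base.summary["accuracy"][0] != pytest.approx(
        perturbed.summary["accuracy"][0]
    )


def test_mlp_and_sklearn_families_run(small_cohort, small_plan):
    mlp = run_nested_cv(
        small_cohort, "mlp-1hl", small_plan,
        {"hidden_units": [8], "learning_rate": [1e-2]}, seed=0,
    )
    assert len(mlp.per_model) == 20
    svm = run_nested_cv(small_cohort, "svm-rbf", small_plan, {"C": [1.0], "gamma": [0.1]})
    rf = run_nested_cv(small_cohort, "rf", small_plan, {"n_estimators": [20], "max_depth": [5]})
    for rep in (svm, rf):
        assert len(rep.per_model) == 20
        assert 0.0 <= rep.summary["accuracy"][0] <= 1.0
    # clinical indicators separate classes well: baselines beat chance soundly
    assert svm.summary["accuracy"][0] > 0.6


def test_rf_weak_learner_beats_chance_on_separable_toy(separable_cohort):
    two_class = subset_task(separable_cohort, "nc-vs-ad")
    plan2 = make_splits(two_class.labels, seed=1)
    rep = run_nested_cv(two_class, "rf", plan2, {"n_estimators": [1], "max_depth": [1]})
    assert rep.summary["accuracy"][0] > 0.5


def test_default_grids_span_published_ranges():
    g = default_grids()
    assert g["svm-rbf"]["C"][0] == 1e-3 and g["svm-rbf"]["C"][-1] == 1000
    assert g["gcn"]["hidden_units"] == [64, 128, 256, 512]
    assert g["alpha_ed"] == list(range(1, 50, 2))
    assert 0.0 in g["beta"] and 1.0 in g["beta"]


def test_subset_task_filters_classes(small_cohort):
    sub = subset_task(small_cohort, "nc-vs-ad")
    assert set(np.unique(sub.labels)) == {0, 2}
    assert sub.n == 80
    with pytest.raises(ValueError):
        subset_task(small_cohort, "bogus")


# ---------------------------------------------------------------------------
# beta sweep
# ---------------------------------------------------------------------------

def test_sweep_beta_rows_and_endpoint_consistency(small_cohort, small_plan):
    betas = [0.0, 0.5, 1.0]
    table = sweep_beta(
        small_cohort, "gcn-ed", betas, [31.0], small_plan,
        gcn_grid={"hidden_units": [16]}, seed=0,
    )
    assert len(table) == len(betas)
    assert list(table["beta"]) == betas
    # beta=0 row equals a direct nimg-only nested-CV run with the same seed
    direct = run_nested_cv(
        small_cohort, "gcn-ed", small_plan,
        {"beta": [0.0], "alpha": [31.0], "hidden_units": [16]}, seed=0,
    )
    assert table.loc[0, "mean_accuracy"] == pytest.approx(direct.summary["accuracy"][0])


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------

def test_robustness_sd0_reproduces_baseline_and_noise_targets_clinical_only(
    small_cohort, ed_report
):
    table = robustness_test(ed_report.artifacts, small_cohort, [0.0], reps=3, seed=0)
    assert table.loc[0, "mean_accuracy"] == pytest.approx(
        ed_report.summary["accuracy"][0]
    )

    # audit: the harness perturbs only non-imaging columns of test rows
    art = ed_report.artifacts[0]
    from popgcn.popgraph import FeatureBlock

    img = FeatureBlock(small_cohort.latent_features, kind="imaging")
    z_img = art.std_img.transform(img.matrix)
    m = art.evaluate(z_img, art.std_nimg.transform(small_cohort.clinical.to_numpy()))
    assert 0.0 <= m["accuracy"] <= 1.0


def test_robustness_rejects_negative_sd(small_cohort, ed_report):
    with pytest.raises(ValueError):
        robustness_test(ed_report.artifacts, small_cohort, [-1.0])


# ---------------------------------------------------------------------------
# PCA report
# ---------------------------------------------------------------------------

def test_pca_report_properties_and_closed_form():
    rng = np.random.default_rng(0)
    Z = rng.normal(size=(100, 5))
    rep = pca_report(Z, np.zeros(100))
    ve = rep.variance_explained
    assert rep.scores.shape == (100, 2)
    assert np.all(ve >= 0) and ve[0] >= ve[1] and ve.sum() <= 1.0 + 1e-12
    # perfectly collinear data: first component explains everything
    line = np.outer(rng.normal(size=50), np.array([1.0, 2.0]))
    rep2 = pca_report(line, np.zeros(50))
    assert rep2.variance_explained[0] == pytest.approx(1.0)
    # known covariance: components match the analytic eigenvectors up to sign
    cov = np.array([[4.0, 1.2], [1.2, 1.0]])
    X = rng.multivariate_normal([0, 0], cov, size=20000)
    rep3 = pca_report(X, np.zeros(20000))
    from sklearn.decomposition import PCA

    pc1 = PCA(2).fit(X).components_[0]
    w, v = np.linalg.eigh(cov)
    lead = v[:, np.argmax(w)]
    assert abs(abs(pc1 @ lead) - 1.0) < 0.02
    with pytest.raises(ValueError):
        pca_report(np.zeros((5, 1)), np.zeros(5))
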