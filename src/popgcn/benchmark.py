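"""Evaluation engine: stratified nested 5x4-fold CV, grid search, metrics,
usage-ratio sweeps, robustness tests, and PCA reports.

The nested-CV protocol: the cohort is split into ``outer_k`` stratified
folds; with each outer fold held out as the test set, the remaining subjects
are split into ``inner_k`` stratified folds, each serving once as the
validation set (the rest training).  Every hyperparameter candidate is
trained on all ``outer_k * inner_k`` (train, val) pairs; the candidate with
the lowest mean validation loss wins, and the report averages the test
metrics of those already-trained winner models — each outer fold is thus
tested ``inner_k`` times, by models that never saw it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .baselines import MLPConfig, predict_mlp, train_mlp
from .densenet3d import (
    DenseNetConfig,
    build_extractor,
    predict_extractor,
    train_extractor,
)
from .gcn import GCNConfig, predict, train_gcn
from .popgraph import (
    FeatureBlock,
    GraphConfig,
    PopulationGraph,
    Standardizer,
    build_population_graph,
    concat_features,
    fit_standardizer,
)
from .synthetic_cohort import Cohort

__all__ = [
    "SplitRecord",
    "SplitPlan",
    "MetricsReport",
    "make_splits",
    "compute_metrics",
    "run_nested_cv",
    "sweep_beta",
    "robustness_test",
    "pca_report",
    "default_grids",
    "subset_task",
    "TASKS",
]

TASKS = {
    "nc-vs-ad": (0, 2),
    "nc-vs-mci": (0, 1),
    "mci-vs-ad": (1, 2),
    "3class": (0, 1, 2),
}

GCN_FAMILIES = ("gcn-cs", "gcn-ed")
MLP_FAMILIES = ("mlp-1hl", "mlp-2hl", "mlp-3hl")
ALL_FAMILIES = GCN_FAMILIES + MLP_FAMILIES + ("svm-rbf", "rf", "densenet")


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitRecord:
    outer_fold: int
    inner_fold: int
    test_idx: np.ndarray
    train_idx: np.ndarray
    val_idx: np.ndarray


@dataclass
class SplitPlan:
    outer_k: int
    inner_k: int
    seed: int
    records: list[SplitRecord]

    @property
    def n_models(self) -> int:
        return len(self.records)


def make_splits(labels: np.ndarray, outer_k: int = 5, inner_k: int = 4,
                seed: int = 0) -> SplitPlan:
    """Stratified nested outer_k x inner_k split plan (deterministic per seed)."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < outer_k:
        raise ValueError(
            f"every class needs >= outer_k={outer_k} members, smallest has {counts.min()}"
        )
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    records: list[SplitRecord] = []
    idx_all = np.arange(len(labels))
    for o, (rest_idx, test_idx) in enumerate(outer.split(idx_all, labels)):
        inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed + o + 1)
        for i, (tr, va) in enumerate(inner.split(rest_idx, labels[rest_idx])):
            records.append(
                SplitRecord(
                    outer_fold=o,
                    inner_fold=i,
                    test_idx=test_idx.copy(),
                    train_idx=rest_idx[tr],
                    val_idx=rest_idx[va],
                )
            )
    return SplitPlan(outer_k=outer_k, inner_k=inner_k, seed=seed, records=records)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
    positive_label=None,
) -> dict:
    """Accuracy / precision / recall / F1 / AUC and the confusion matrix.

    For binary tasks the positive class is the more advanced disease stage
    (the larger label value) unless overridden.  Zero-denominator precision
    or recall is reported as 0 with ``zero_division_flag`` set.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    out: dict = {"accuracy": accuracy_score(y_true, y_pred)}
    out["confusion"] = confusion_matrix(y_true, y_pred, labels=classes)
    out["classes"] = classes
    out["zero_division_flag"] = False
    if len(classes) == 2:
        pos = positive_label if positive_label is not None else classes.max()
        kw = dict(pos_label=pos, zero_division=np.nan)
        prec = precision_score(y_true, y_pred, **kw)
        rec = recall_score(y_true, y_pred, **kw)
        if np.isnan(prec) or np.isnan(rec):
            out["zero_division_flag"] = True
        prec = 0.0 if np.isnan(prec) else prec
        rec = 0.0 if np.isnan(rec) else rec
        out["precision"] = prec
        out["recall"] = rec
        out["f1"] = (
            0.0 if prec + rec == 0 else 2.0 * prec * rec / (prec + rec)
        )
        if scores is not None:
            s = np.asarray(scores)
            if s.ndim == 2:
                s = s[:, -1] if s.shape[1] > 1 else s[:, 0]
            if len(np.unique(y_true)) == 2:
                out["auc"] = roc_auc_score((y_true == pos).astype(int), s)
            else:
                out["auc"] = np.nan
    return out


# ---------------------------------------------------------------------------
# per-fold artifacts (frozen models reusable for robustness tests)
# ---------------------------------------------------------------------------

@dataclass
class FoldArtifact:
    """A trained fold model plus everything needed to re-evaluate it on
    perturbed standardized features."""

    record: SplitRecord
    std_img: Standardizer | None
    std_nimg: Standardizer | None
    labels: np.ndarray
    kind: str
    payload: dict = field(default_factory=dict)

    def evaluate(self, z_img: np.ndarray, z_nimg: np.ndarray) -> dict:
        """Recompute test metrics from (possibly perturbed) standardized blocks."""
        test = self.record.test_idx
        if self.kind == "gcn":
            cfg: GraphConfig = self.payload["graph_config"]
            from . import popgraph as pg

            X = concat_features(z_img, z_nimg)
            if cfg.measure == "cosine":
                M = pg.blend_affinity(
                    pg.cosine_affinity(z_img), pg.cosine_affinity(z_nimg), cfg.beta
                )
                A = pg.threshold_cosine(M, cfg.alpha_cs)
            else:
                M = pg.blend_affinity(
                    pg.euclidean_affinity(z_img),
                    pg.euclidean_affinity(z_nimg),
                    cfg.beta,
                )
                A = (M <= self.payload["q_ed"]).astype(float)
                np.fill_diagonal(A, 0.0)
            A_hat = pg.normalize_adjacency(A)
            graph = PopulationGraph(
                X=X, A=A, A_hat=A_hat, labels=self.labels,
                train_mask=_mask(len(self.labels), self.record.train_idx),
                val_mask=_mask(len(self.labels), self.record.val_idx),
                test_mask=_mask(len(self.labels), test),
            )
            y_pred, scores = predict(graph, self.payload["params"], graph.test_mask)
        elif self.kind == "mlp":
            X = concat_features(z_img, z_nimg)
            y_pred, scores = predict_mlp(
                self.payload["model"], X, self.labels, _mask(len(self.labels), test)
            )
        elif self.kind == "sklearn":
            X = concat_features(z_img, z_nimg)[test]
            est = self.payload["estimator"]
            y_pred = est.predict(X)
            scores = _sklearn_scores(est, X)
        else:
            raise ValueError(f"robustness evaluation unsupported for {self.kind!r}")
        return compute_metrics(self.labels[test], y_pred, scores)


def _mask(n: int, idx: np.ndarray) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    m[np.asarray(idx)] = True
    return m


def _sklearn_scores(est, X) -> np.ndarray | None:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)
    if hasattr(est, "decision_function"):
        return est.decision_function(X)
    return None


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

def default_grids() -> dict:
    """Full production search ranges (SVM / RF / MLP / GCN) plus the
    graph-level usage-ratio and threshold candidates."""
    return {
        "svm-rbf": {
            "C": [10.0 ** e for e in range(-3, 4)],
            "gamma": [1e-3, 1e-2, 1e-1, 1.0, 2.0, 3.0, 4.0],
        },
        "rf": {
            "n_estimators": list(range(100, 1001, 100)),
            "max_depth": list(range(10, 51, 10)),
            "min_samples_split": [2, 5],
            "min_samples_leaf": [1, 2],
            "max_features": ["sqrt", "log2"],
        },
        "mlp": {
            "learning_rate": [1e-5, 1e-4, 1e-3, 1e-2],
            "dropout": [0.1, 0.2, 0.3, 0.4, 0.5],
            "hidden_units": [64, 128, 256, 512],
        },
        "gcn": {
            "learning_rate": [1e-5, 1e-4, 1e-3, 1e-2],
            "dropout": [0.1, 0.2, 0.3, 0.4, 0.5],
            "hidden_units": [64, 128, 256, 512],
        },
        "beta": [0.0] + [round(0.05 + 0.05 * i, 2) for i in range(19)] + [1.0],
        "alpha_cs": [round(0.1 * i, 1) for i in range(11)],
        "alpha_ed": list(range(1, 50, 2)),
    }


def _candidates(grid: dict) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]


# ---------------------------------------------------------------------------
# nested CV
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    family: str
    best_params: dict
    per_model: pd.DataFrame  # one row per inner-loop model
    summary: dict  # metric -> (mean, sd)
    grid_results: pd.DataFrame  # candidate -> mean val loss
    pooled_confusion: np.ndarray | None = None
    artifacts: list[FoldArtifact] | None = None


def subset_task(cohort: Cohort, task: str) -> Cohort:
    """Restrict a cohort to the classes of one classification task."""
    if task not in TASKS:
        raise ValueError(f"task must be one of {sorted(TASKS)}, got {task!r}")
    keep = np.isin(cohort.labels, TASKS[task])
    return cohort.subset(np.flatnonzero(keep))


def _blocks(cohort: Cohort) -> tuple[FeatureBlock, FeatureBlock]:
    if cohort.latent_features is None:
        raise ValueError("cohort has no latent imaging features")
    img = FeatureBlock(cohort.latent_features, kind="imaging")
    nimg = FeatureBlock(cohort.clinical.to_numpy(), kind="non-imaging")
    return img, nimg


def _eval_record(
    family: str,
    cand: dict,
    cohort: Cohort,
    record: SplitRecord,
    rec_index: int,
    n_classes: int,
    seed: int,
    extractor_config: DenseNetConfig | None,
) -> tuple[float, dict, FoldArtifact]:
    """Train one candidate on one (train, val) pair; return
    (validation loss, test metrics, frozen artifact)."""
    labels = cohort.labels
    tr, va, te = record.train_idx, record.val_idx, record.test_idx
    rec_seed = seed + rec_index

    if family == "densenet":
        cfg = extractor_config or DenseNetConfig()
        cfg = DenseNetConfig(
            **{
                **vars(cfg),
                "learning_rate": cand.get("learning_rate", cfg.learning_rate),
                "dropout": cand.get("dropout", cfg.dropout),
                "seed": rec_seed,
            }
        )
        vols = cohort.get_volumes()
        ext = build_extractor(cfg, n_classes, input_shape=vols.shape[1:])
        ext = train_extractor(ext, vols, labels, tr, va)
        y_pred, scores = predict_extractor(ext, vols[te], labels)
        metrics = compute_metrics(labels[te], y_pred, scores)
        art = FoldArtifact(record, None, None, labels, "densenet", {"extractor": ext})
        return ext.training_history.best_val_loss, metrics, art

    img, nimg = _blocks(cohort)
    std_img = fit_standardizer(img, tr)
    std_nimg = fit_standardizer(nimg, tr)
    z_img = std_img.transform(img.matrix)
    z_nimg = std_nimg.transform(nimg.matrix)

    if family in GCN_FAMILIES:
        measure = "cosine" if family == "gcn-cs" else "euclidean"
        gcfg = GraphConfig(
            measure=measure,
            beta=cand["beta"],
            alpha_cs=cand["alpha"] if measure == "cosine" else None,
            alpha_ed=cand["alpha"] if measure == "euclidean" else None,
        )
        graph = build_population_graph(img, nimg, labels, gcfg, tr, va, te)
        ncfg = GCNConfig(
            hidden_units=cand.get("hidden_units", 64),
            learning_rate=cand.get("learning_rate", 1e-3),
            dropout=cand.get("dropout", 0.2),
            n_classes=n_classes,
            seed=rec_seed,
        )
        params, state = train_gcn(graph, ncfg)
        y_pred, scores = predict(graph, params, graph.test_mask)
        metrics = compute_metrics(labels[te], y_pred, scores)
        art = FoldArtifact(
            record, std_img, std_nimg, labels, "gcn",
            {"params": params, "graph_config": gcfg, "q_ed": gcfg.q_ed},
        )
        return state.best_val_loss, metrics, art

    X = concat_features(z_img, z_nimg)

    if family in MLP_FAMILIES:
        mcfg = MLPConfig(
            hidden_units=cand.get("hidden_units", 64),
            n_hidden_layers=int(family[4]),
            learning_rate=cand.get("learning_rate", 1e-3),
            dropout=cand.get("dropout", 0.2),
            n_classes=n_classes,
            seed=rec_seed,
        )
        model, state = train_mlp(X, labels, _mask(len(labels), tr), _mask(len(labels), va), mcfg)
        y_pred, scores = predict_mlp(model, X, labels, _mask(len(labels), te))
        metrics = compute_metrics(labels[te], y_pred, scores)
        art = FoldArtifact(record, std_img, std_nimg, labels, "mlp", {"model": model})
        return state.best_val_loss, metrics, art

    if family == "svm-rbf":
        est = SVC(C=cand.get("C", 1.0), gamma=cand.get("gamma", "scale"), kernel="rbf")
    elif family == "rf":
        est = RandomForestClassifier(
            n_estimators=cand.get("n_estimators", 100),
            max_depth=cand.get("max_depth", None),
            min_samples_split=cand.get("min_samples_split", 2),
            min_samples_leaf=cand.get("min_samples_leaf", 1),
            max_features=cand.get("max_features", "sqrt"),
            random_state=rec_seed,
        )
    else:
        raise ValueError(f"unknown model family {family!r}")
    est.fit(X[tr], labels[tr])
    # no epoch-wise loss for margin/ensemble models: validation error rate
    val_loss = 1.0 - accuracy_score(labels[va], est.predict(X[va]))
    y_pred = est.predict(X[te])
    metrics = compute_metrics(labels[te], y_pred, _sklearn_scores(est, X[te]))
    art = FoldArtifact(record, std_img, std_nimg, labels, "sklearn", {"estimator": est})
    return val_loss, metrics, art


_SCALAR_METRICS = ("accuracy", "precision", "recall", "f1", "auc")


def run_nested_cv(
    cohort: Cohort,
    family: str,
    plan: SplitPlan,
    grid: dict | None = None,
    seed: int = 0,
    extractor_config: DenseNetConfig | None = None,
    keep_artifacts: bool = False,
) -> MetricsReport:
    """Grid search + evaluation over a nested-CV plan.

    Every candidate is trained on all inner-loop (train, val) pairs; the
    candidate with the lowest mean validation loss is selected, and the
    report averages the test metrics of its (already trained) models.
    Candidates that fail on any fold are excluded with a warning.
    """
    import warnings

    if family not in ALL_FAMILIES:
        raise ValueError(f"family must be one of {ALL_FAMILIES}, got {family!r}")
    n_classes = len(np.unique(cohort.labels))
    cands = _candidates(grid) if grid else [{}]
    results = []
    for ci, cand in enumerate(cands):
        val_losses, metrics_list, artifacts = [], [], []
        try:
            for ri, record in enumerate(plan.records):
                vl, metrics, art = _eval_record(
                    family, cand, cohort, record, ri, n_classes, seed, extractor_config
                )
                val_losses.append(vl)
                metrics_list.append(metrics)
                artifacts.append(art)
        except Exception as exc:  # noqa: BLE001 - candidate-level quarantine
            warnings.warn(f"candidate {cand} failed and was excluded: {exc}")
            continue
        results.append(
            {
                "candidate": cand,
                "mean_val_loss": float(np.mean(val_losses)),
                "metrics": metrics_list,
                "artifacts": artifacts,
            }
        )
    if not results:
        raise RuntimeError("every grid candidate failed")
    best = min(results, key=lambda r: r["mean_val_loss"])
    per_model = pd.DataFrame(
        [
            {m: r.get(m, np.nan) for m in _SCALAR_METRICS}
            | {"outer_fold": rec.outer_fold, "inner_fold": rec.inner_fold}
            for r, rec in zip(best["metrics"], plan.records)
        ]
    )
    summary = {
        m: (float(per_model[m].mean()), float(per_model[m].std(ddof=0)))
        for m in _SCALAR_METRICS
        if per_model[m].notna().any()
    }
    pooled = None
    if n_classes > 2:
        pooled = np.sum([r["confusion"] for r in best["metrics"]], axis=0)
    grid_df = pd.DataFrame(
        [{**r["candidate"], "mean_val_loss": r["mean_val_loss"]} for r in results]
    )
    return MetricsReport(
        family=family,
        best_params=best["candidate"],
        per_model=per_model,
        summary=summary,
        grid_results=grid_df,
        pooled_confusion=pooled,
        artifacts=best["artifacts"] if keep_artifacts else None,
    )


# ---------------------------------------------------------------------------
# usage-ratio sweep
# ---------------------------------------------------------------------------

def sweep_beta(
    cohort: Cohort,
    family: str,
    beta_grid: list[float],
    alpha_grid: list[float],
    plan: SplitPlan,
    gcn_grid: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean test accuracy versus the imaging/non-imaging usage ratio beta.

    At each beta the threshold alpha (and any GCN hyperparameters in
    ``gcn_grid``) are tuned by mean inner-loop validation loss; the reported
    accuracy is the 20-model mean at the per-beta best alpha.  beta=0 and
    beta=1 rows are by definition the non-imaging-only and imaging-only
    variants.
    """
    if family not in GCN_FAMILIES:
        raise ValueError(f"sweep_beta applies to {GCN_FAMILIES}, got {family!r}")
    if any(not 0.0 <= b <= 1.0 for b in beta_grid):
        raise ValueError("beta grid must lie in [0, 1]")
    rows = []
    for beta in beta_grid:
        grid = {"beta": [beta], "alpha": list(alpha_grid), **(gcn_grid or {})}
        report = run_nested_cv(cohort, family, plan, grid, seed=seed)
        mean, sd = report.summary["accuracy"]
        rows.append(
            {
                "beta": beta,
                "best_alpha": report.best_params["alpha"],
                "mean_accuracy": mean,
                "sd_accuracy": sd,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------

def robustness_test(
    artifacts: list[FoldArtifact],
    cohort: Cohort,
    noise_sds: list[float],
    reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy under Gaussian noise on standardized test-row clinical features.

    For each noise SD and repetition, noise is added only to the non-imaging
    columns of test-mask rows (after standardization with training
    statistics); imaging columns and train/val rows are untouched.  Edges are
    rebuilt from the perturbed features before re-prediction.  SD 0 is the
    noise-free baseline.
    """
    if any(sd < 0 for sd in noise_sds):
        raise ValueError("noise SDs must be non-negative")
    img, nimg = _blocks(cohort)
    rows = []
    for sd in noise_sds:
        rep_count = 1 if sd == 0 else reps
        rep_accs = []
        for rep in range(rep_count):
            rng = np.random.default_rng([seed, int(round(sd * 1000)), rep])
            accs = []
            for art in artifacts:
                z_img = art.std_img.transform(img.matrix)
                z_nimg = art.std_nimg.transform(nimg.matrix)
                if sd > 0:
                    te = art.record.test_idx
                    z_nimg[te] += rng.normal(0.0, sd, size=z_nimg[te].shape)
                accs.append(art.evaluate(z_img, z_nimg)["accuracy"])
            rep_accs.append(float(np.mean(accs)))
        rows.append(
            {
                "noise_sd": sd,
                "mean_accuracy": float(np.mean(rep_accs)),
                "sd_accuracy": float(np.std(rep_accs)),
                "reps": rep_count,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA report
# ---------------------------------------------------------------------------

@dataclass
class PCAReport:
    scores: np.ndarray  # N x 2
    variance_explained: np.ndarray  # length 2
    labels: np.ndarray


def pca_report(Z: np.ndarray, labels: np.ndarray) -> PCAReport:
    """First two principal-component scores of a standardized feature block."""
    Z = np.asarray(Z, float)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValueError("need an N x p matrix with p >= 2")
    pca = PCA(n_components=2)
    scores = pca.fit_transform(Z)
    return PCAReport(
        scores=scores,
        variance_explained=pca.explained_variance_ratio_,
        labels=np.asarray(labels),
    )
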