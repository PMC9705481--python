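"""Organ classification experiments and histogram-distance analysis.

Two experiments quantify whether harmonized radiomic features transfer
across sites and time:

* **leave-one-site-out (LOSO)**: a random forest (1000 trees, max depth
  10) is trained on all sites but one and predicts the held-out site's
  organ labels; repeated over 10 seeded runs, accuracies are reported
  per site as mean ± SD over runs.
* **test-retest**: the forest is trained on all first-timepoint rows
  and predicts the retest rows; 5 seeded runs.

ROC curves are macro-averaged one-vs-rest over runs × organs × sites on
a fixed 101-point false-positive grid. The first Wasserstein distance
between ROI intensity distributions provides a classifier-free view of
the same structure; a tSNE embedding of the selected features serves as
qualitative visualization only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.metrics import roc_curve

from dwiharm.errors import FoldError, PairingError
from dwiharm.radiomics import feature_columns

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationReport",
    "DistanceMatrix",
    "loso_cv",
    "test_retest_cv",
    "roc_auc",
    "tsne_embed",
    "wasserstein_matrix",
    "collect_roi_samples",
]

RF_TREES = 1000
RF_MAX_DEPTH = 10


@dataclass
class PredictionRecord:
    """Raw predictions of one (run, fold), kept for ROC aggregation."""

    run: int
    site: str
    y_true: np.ndarray
    proba: np.ndarray
    classes: np.ndarray


@dataclass
class ClassificationReport:
    """Accuracy summary of a repeated classification experiment.

    ``per_site`` has one row per held-out site (or the single pooled
    fold for test-retest) with the mean and SD of accuracy across the
    repeated runs; ``overall_accuracy`` is the grand mean over sites and
    runs.
    """

    mode: str
    per_site: pd.DataFrame
    overall_accuracy: float
    config: dict
    predictions: list[PredictionRecord] = field(default_factory=list, repr=False)

    @property
    def accuracy_sd(self) -> float:
        run_means = self.run_accuracies.mean(axis=1)
        return float(run_means.std(ddof=1)) if len(run_means) > 1 else 0.0

    @property
    def run_accuracies(self) -> np.ndarray:
        """(n_runs, n_folds) accuracy array."""
        return self._run_acc

    def __post_init__(self) -> None:
        self._run_acc = self.per_site.attrs.get("run_accuracies")


def _forest(seed: int, n_estimators: int, max_depth: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=n_estimators, max_depth=max_depth,
                                  random_state=seed)


def _sub_seed(seed: int, run: int) -> int:
    ss = np.random.SeedSequence([seed, run])
    return int(ss.generate_state(1)[0] % (2**31))


def loso_cv(
    features: pd.DataFrame,
    feature_names: list[str] | None = None,
    n_runs: int = 10,
    seed: int = 0,
    n_estimators: int = RF_TREES,
    max_depth: int = RF_MAX_DEPTH,
    shared_seed: bool = False,
) -> ClassificationReport:
    """Leave-one-site-out organ prediction, repeated over seeded runs.

    Each run re-seeds the forest (unless ``shared_seed`` is set, in
    which case all runs use one seed and the SD over runs is exactly
    zero). Every training fold must contain every organ class.
    """
    feats = feature_names or feature_columns(features)
    sites = sorted(features["site"].unique())
    if len(sites) < 3:
        raise ValueError("LOSO cross-validation needs at least 3 sites")
    all_classes = set(features["organ_class"].unique())
    for held in sites:
        train_classes = set(features.loc[features["site"] != held, "organ_class"])
        missing = all_classes - train_classes
        if missing:
            raise FoldError(
                f"training fold without site {held} is missing classes {sorted(missing)}"
            )
    acc = np.zeros((n_runs, len(sites)))
    predictions: list[PredictionRecord] = []
    for run in range(n_runs):
        rf_seed = _sub_seed(seed, 0 if shared_seed else run)
        for j, held in enumerate(sites):
            train = features[features["site"] != held]
            test = features[features["site"] == held]
            clf = _forest(rf_seed, n_estimators, max_depth)
            clf.fit(train[feats].to_numpy(), train["organ_class"].to_numpy())
            y_true = test["organ_class"].to_numpy()
            proba = clf.predict_proba(test[feats].to_numpy())
            y_pred = clf.classes_[np.argmax(proba, axis=1)]
            acc[run, j] = float(np.mean(y_pred == y_true))
            predictions.append(PredictionRecord(run, held, y_true, proba,
                                                clf.classes_))
    per_site = pd.DataFrame({
        "site": sites,
        "accuracy_mean": acc.mean(axis=0),
        "accuracy_sd": acc.std(axis=0, ddof=1) if n_runs > 1 else np.zeros(len(sites)),
    })
    per_site.attrs["run_accuracies"] = acc
    return ClassificationReport(
        mode="loso",
        per_site=per_site,
        overall_accuracy=float(acc.mean()),
        config={"trees": n_estimators, "max_depth": max_depth, "n_runs": n_runs,
                "seed": seed, "shared_seed": shared_seed},
        predictions=predictions,
    )


def test_retest_cv(
    features_t1: pd.DataFrame,
    features_t2: pd.DataFrame,
    feature_names: list[str] | None = None,
    n_runs: int = 5,
    seed: int = 0,
    n_estimators: int = RF_TREES,
    max_depth: int = RF_MAX_DEPTH,
) -> ClassificationReport:
    """Train on timepoint 1, predict organ classes of timepoint 2."""
    feats = feature_names or feature_columns(features_t1)
    k1 = set(map(tuple, features_t1[["site", "roi_label"]].to_numpy()))
    k2 = set(map(tuple, features_t2[["site", "roi_label"]].to_numpy()))
    if k1 != k2:
        raise PairingError(
            f"unmatched (site, roi_label) keys: {sorted(k1 ^ k2)}"
        )
    acc = np.zeros((n_runs, 1))
    predictions: list[PredictionRecord] = []
    y_true = features_t2["organ_class"].to_numpy()
    for run in range(n_runs):
        clf = _forest(_sub_seed(seed, run), n_estimators, max_depth)
        clf.fit(features_t1[feats].to_numpy(), features_t1["organ_class"].to_numpy())
        proba = clf.predict_proba(features_t2[feats].to_numpy())
        y_pred = clf.classes_[np.argmax(proba, axis=1)]
        acc[run, 0] = float(np.mean(y_pred == y_true))
        predictions.append(PredictionRecord(run, "all", y_true, proba, clf.classes_))
    per_site = pd.DataFrame({
        "site": ["all"],
        "accuracy_mean": [acc.mean()],
        "accuracy_sd": [acc[:, 0].std(ddof=1) if n_runs > 1 else 0.0],
    })
    per_site.attrs["run_accuracies"] = acc
    return ClassificationReport(
        mode="test_retest",
        per_site=per_site,
        overall_accuracy=float(acc.mean()),
        config={"trees": n_estimators, "max_depth": max_depth, "n_runs": n_runs,
                "seed": seed},
        predictions=predictions,
    )


def roc_auc(
    probabilities,
    labels,
    grouping=None,
    classes=None,
    n_grid: int = 101,
) -> dict:
    """Macro-averaged one-vs-rest ROC over groups (runs × sites) and classes.

    ``probabilities`` is (n, k) class-probability scores (or a 1-D score
    array for a binary problem, scoring the positive class). Curves are
    interpolated onto a fixed ``n_grid``-point false-positive grid
    before averaging; groups containing a single class are skipped with
    a log entry.

    Returns a dict with ``fpr_grid``, ``mean_tpr``, ``sd_tpr``,
    ``aucs``, ``mean_auc``, ``sd_auc`` and ``n_curves``.
    """
    proba = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    if proba.ndim == 1:
        proba = np.column_stack([1.0 - proba, proba])
        if classes is None:
            classes = np.array([0, 1]) if labels.dtype.kind in "biuf" else np.unique(labels)
    if classes is None:
        classes = np.unique(labels)
    classes = np.asarray(classes)
    groups = (np.zeros(len(labels), dtype=int) if grouping is None
              else np.asarray(grouping))
    fpr_grid = np.linspace(0.0, 1.0, n_grid)
    tprs, aucs = [], []
    for g in np.unique(groups):
        sel = groups == g
        y_g = labels[sel]
        if np.unique(y_g).size < 2:
            logger.warning("group %r has a single class; skipped", g)
            continue
        for ci, cls in enumerate(classes):
            y_bin = (y_g == cls).astype(int)
            if y_bin.min() == y_bin.max():
                continue
            fpr, tpr, _ = roc_curve(y_bin, proba[sel, ci])
            tpr_i = np.interp(fpr_grid, fpr, tpr)
            tpr_i[0] = 0.0
            tprs.append(tpr_i)
            aucs.append(float(np.trapezoid(tpr, fpr)))  # AUC from the raw curve
    if not tprs:
        raise ValueError("no group contained both classes for any label")
    tprs = np.asarray(tprs)
    aucs = np.asarray(aucs)
    return {
        "fpr_grid": fpr_grid,
        "mean_tpr": tprs.mean(axis=0),
        "sd_tpr": tprs.std(axis=0, ddof=1) if len(tprs) > 1 else np.zeros(n_grid),
        "aucs": aucs,
        "mean_auc": float(aucs.mean()),
        "sd_auc": float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        "n_curves": int(len(aucs)),
    }


def roc_from_report(report: ClassificationReport, n_grid: int = 101) -> dict:
    """ROC macro-average across a report's stored (run, site) predictions."""
    proba = np.concatenate([p.proba for p in report.predictions], axis=0)
    labels = np.concatenate([p.y_true for p in report.predictions])
    grouping = np.concatenate([
        np.full(len(p.y_true), i) for i, p in enumerate(report.predictions)
    ])
    classes = report.predictions[0].classes
    return roc_auc(proba, labels, grouping=grouping, classes=classes, n_grid=n_grid)


def tsne_embed(
    features,
    seed: int = 0,
    perplexity: float = 30.0,
) -> np.ndarray:
    """Seeded 2D tSNE embedding of the selected features (plotting only)."""
    if isinstance(features, pd.DataFrame):
        X = features[feature_columns(features)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("tSNE embedding needs at least 5 rows")
    max_perp = max(1.0, (n - 1) / 3.0)
    if perplexity > max_perp:
        warnings.warn(
            f"perplexity {perplexity} too large for {n} rows; shrunk to {max_perp:.1f}",
            stacklevel=2,
        )
        perplexity = max_perp
    emb = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
               init="pca").fit_transform(X)
    return np.asarray(emb, dtype=float)


@dataclass
class DistanceMatrix:
    """Pairwise first-Wasserstein distances between ROI distributions."""

    labels: list
    raw: np.ndarray
    normalized: np.ndarray


def wasserstein_matrix(roi_voxel_samples: dict) -> DistanceMatrix:
    """First Wasserstein distance between all pairs of ROI samples.

    Inputs are raw intensity samples per ROI identity (a 1-D array
    each), or ``(values, weights)`` tuples for pre-binned histograms.
    The raw matrix is min-max normalized over its off-diagonal entries
    to [0, 1] with the diagonal forced to 0.
    """
    labels = list(roi_voxel_samples)
    samples = []
    for key in labels:
        s = roi_voxel_samples[key]
        if isinstance(s, tuple):
            vals, w = np.asarray(s[0], float), np.asarray(s[1], float)
        else:
            vals, w = np.asarray(s, float), None
        if vals.size == 0:
            raise ValueError(f"empty sample for ROI {key!r}")
        samples.append((vals, w))
    n = len(labels)
    raw = np.zeros((n, n))
    for i in range(n):
        vi, wi = samples[i]
        for j in range(i + 1, n):
            vj, wj = samples[j]
            d = wasserstein_distance(vi, vj, u_weights=wi, v_weights=wj)
            raw[i, j] = raw[j, i] = d
    off = ~np.eye(n, dtype=bool)
    if n > 1 and raw[off].max() > raw[off].min():
        lo, hi = raw[off].min(), raw[off].max()
        normalized = (raw - lo) / (hi - lo)
    else:
        normalized = np.zeros_like(raw)
    np.fill_diagonal(normalized, 0.0)
    normalized = np.clip(normalized, 0.0, 1.0)
    return DistanceMatrix(labels=labels, raw=raw, normalized=normalized)


def collect_roi_samples(
    volume: np.ndarray,
    rois,
    valid_mask: np.ndarray | None = None,
    site: str | None = None,
    timepoint: str | None = None,
) -> dict:
    """ROI intensity samples keyed (organ_class, site, timepoint, roi_name).

    The key order (organ class first) gives Wasserstein heatmaps the
    organ-block structure when keys are sorted.
    """
    out = {}
    for label in rois.labels:
        sel = rois.mask_for(label)
        if valid_mask is not None:
            sel = sel & valid_mask
        vals = np.asarray(volume)[sel]
        if vals.size:
            key = (rois.organ_of_label[label], site, timepoint,
                   rois.label_names[label])
            out[key] = vals
    return out
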