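"""Harmonization preprocessing, feature extraction and feature selection.

The chain mirrors a cross-site radiomics harmonization workflow:

1. resample images and masks to 1 × 1 × 1 mm³ (trilinear / nearest
   neighbor) so voxel counts are comparable across protocols;
2. histogram-match arbitrary-unit intensities (single-shot T2w) to a
   reference site using quantile landmarks (10 match points over a
   128-level histogram, foreground thresholded at the volume mean) —
   the ITK filter behind 3D Slicer's implementation;
3. extract a defined set of 26 features per ROI: 18 first-order
   statistics plus 8 gray-level co-occurrence (GLCM) features on a
   fixed-bin-count discretization, distance-1 offsets averaged over the
   13 unique 3D directions;
4. select features in two stages: a cross-site *stability* filter
   (mean absolute Pearson correlation of per-site feature vectors
   indexed by anatomical position, over all site pairs; survivors need
   score ≥ 0.75) followed by ANOVA F ranking against the organ classes
   (top N = 15).

External extractors (e.g. a full radiomics toolkit) can substitute any
feature table with the same key columns; the selection stages are
extractor-agnostic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import SimpleITK as sitk
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import f_classif

from dwiharm.core import ROISet, check_same_grid, require_spacing
from dwiharm.errors import DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "META_COLUMNS",
    "SelectionResult",
    "StabilityFilter",
    "AnovaFSelector",
    "resample_isotropic",
    "histogram_match",
    "extract_features",
    "feature_columns",
    "stability_filter",
    "anova_select",
]

#: non-feature key columns of a feature table
META_COLUMNS = ("site", "timepoint", "roi_label", "roi_name", "organ_class")

#: the 13 unique 3D direction offsets at distance 1
_GLCM_OFFSETS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature (non-key) columns of a feature table, in table order."""
    return [c for c in table.columns if c not in META_COLUMNS]


# ---------------------------------------------------------------------------
# geometry / intensity preprocessing (SimpleITK-backed)


def _to_sitk(volume: np.ndarray, spacing) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.T))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).T


def resample_isotropic(
    volume: np.ndarray,
    spacing,
    target_spacing=(1.0, 1.0, 1.0),
    is_mask: bool = False,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Resample a volume to the target (default 1 mm isotropic) grid.

    Trilinear interpolation for images, nearest neighbor for masks
    (label images stay label images). Output size is chosen to preserve
    the physical extent to within one voxel.
    """
    spacing = require_spacing(spacing)
    target = require_spacing(target_spacing)
    arr = np.asarray(volume)
    if is_mask:
        img = _to_sitk(arr.astype(np.float64), spacing)
    else:
        img = _to_sitk(arr.astype(np.float64), spacing)
    new_size = [max(1, int(round(n * s / t)))
                for n, s, t in zip(arr.shape, spacing, target)]
    rf = sitk.ResampleImageFilter()
    rf.SetSize(new_size)
    rf.SetInterpolator(sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear)
    rf.SetOutputOrigin(img.GetOrigin())
    rf.SetOutputSpacing(tuple(target))
    rf.SetOutputDirection(img.GetDirection())
    rf.SetUseNearestNeighborExtrapolator(True)  # edge voxels, not zeros
    out = rf.Execute(img)
    res = _from_sitk(out)
    if is_mask:
        res = res.astype(np.asarray(volume).dtype)
    return res, tuple(target)


def histogram_match(
    source: np.ndarray,
    reference: np.ndarray,
    match_points: int = 10,
    levels: int = 128,
) -> np.ndarray:
    """Quantile-landmark histogram matching of source onto reference.

    Foreground is selected by thresholding at the volume mean; the
    landmark quantiles of the source foreground are mapped onto the
    reference's via a monotone piecewise-linear transfer function over a
    ``levels``-bin histogram and the transform is applied to every
    voxel. Removes global gain/offset differences between sites while
    preserving intensity ordering.
    """
    src = np.asarray(source, dtype=float)
    ref = np.asarray(reference, dtype=float)
    for name, arr in (("source", src), ("reference", ref)):
        if float(arr.max()) == float(arr.min()):
            raise DegenerateInputError(f"{name} volume has zero intensity range")
    matched = sitk.HistogramMatching(
        _to_sitk(src, (1, 1, 1)),
        _to_sitk(ref, (1, 1, 1)),
        numberOfHistogramLevels=int(levels),
        numberOfMatchPoints=int(match_points),
        thresholdAtMeanIntensity=True,
    )
    return _from_sitk(matched)


# ---------------------------------------------------------------------------
# feature extraction


def _first_order(vals: np.ndarray, bins: int) -> dict[str, float]:
    n = vals.size
    mean = float(vals.mean())
    var = float(vals.var())  # population convention
    sd = float(np.sqrt(var))
    centered = vals - mean
    if var > 0:
        skew = float(np.mean(centered**3) / var**1.5)
        kurt = float(np.mean(centered**4) / var**2)  # normal → 3
    else:
        skew, kurt = 0.0, 0.0
    p10, p25, p75, p90 = np.percentile(vals, [10, 25, 75, 90])
    core = vals[(vals >= p10) & (vals <= p90)]
    rmad = float(np.abs(core - core.mean()).mean()) if core.size else 0.0
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax > vmin:
        hist, _ = np.histogram(vals, bins=bins, range=(vmin, vmax))
        p = hist / n
    else:
        p = np.array([1.0])
    p_nz = p[p > 0]
    return {
        "fo_mean": mean,
        "fo_median": float(np.median(vals)),
        "fo_sd": sd,
        "fo_variance": var,
        "fo_skewness": skew,
        "fo_kurtosis": kurt,
        "fo_min": vmin,
        "fo_max": vmax,
        "fo_range": vmax - vmin,
        "fo_p10": float(p10),
        "fo_p90": float(p90),
        "fo_iqr": float(p75 - p25),
        "fo_energy": float(np.sum(vals**2)),
        "fo_rms": float(np.sqrt(np.mean(vals**2))),
        "fo_mad": float(np.abs(centered).mean()),
        "fo_rmad": rmad,
        "fo_entropy": float(-np.sum(p_nz * np.log2(p_nz))),
        "fo_uniformity": float(np.sum(p**2)),
    }


def _discretize(vals: np.ndarray, bins: int) -> np.ndarray:
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        return np.zeros(vals.shape, dtype=np.int32)
    lev = np.floor((vals - vmin) / (vmax - vmin) * bins).astype(np.int32)
    return np.clip(lev, 0, bins - 1)


def _glcm_features(mask: np.ndarray, levels: np.ndarray, bins: int) -> dict[str, float]:
    """GLCM features averaged over the 13 distance-1 directions.

    Each direction's co-occurrence matrix counts within-ROI voxel pairs
    symmetrically; directions yielding no pairs are skipped.
    """
    per_dir: list[dict[str, float]] = []
    idx = np.arange(bins, dtype=float)
    for off in _GLCM_OFFSETS:
        src_sl, dst_sl = [], []
        ok = True
        for o, n in zip(off, mask.shape):
            if abs(o) >= n:
                ok = False
                break
            if o >= 0:
                src_sl.append(slice(0, n - o))
                dst_sl.append(slice(o, n))
            else:
                src_sl.append(slice(-o, n))
                dst_sl.append(slice(0, n + o))
        if not ok:
            continue
        src_sl, dst_sl = tuple(src_sl), tuple(dst_sl)
        both = mask[src_sl] & mask[dst_sl]
        if not both.any():
            continue
        li = levels[src_sl][both]
        lj = levels[dst_sl][both]
        pmat = np.zeros((bins, bins))
        np.add.at(pmat, (li, lj), 1.0)
        pmat = pmat + pmat.T  # symmetric co-occurrence
        pmat /= pmat.sum()
        pi = pmat.sum(axis=1)
        mu_i = float(np.dot(idx, pi))
        sig_i = float(np.sqrt(np.dot((idx - mu_i) ** 2, pi)))
        ii, jj = np.meshgrid(idx, idx, indexing="ij")
        diff = ii - jj
        if sig_i > 0:
            corr = float((np.sum(pmat * ii * jj) - mu_i * mu_i) / (sig_i * sig_i))
        else:
            corr = 0.0
        spread = ii + jj - 2.0 * mu_i
        p_nz = pmat[pmat > 0]
        per_dir.append({
            "glcm_contrast": float(np.sum(pmat * diff**2)),
            "glcm_dissimilarity": float(np.sum(pmat * np.abs(diff))),
            "glcm_homogeneity": float(np.sum(pmat / (1.0 + diff**2))),
            "glcm_asm": float(np.sum(pmat**2)),
            "glcm_joint_entropy": float(-np.sum(p_nz * np.log2(p_nz))),
            "glcm_correlation": corr,
            "glcm_cluster_shade": float(np.sum(pmat * spread**3)),
            "glcm_cluster_prominence": float(np.sum(pmat * spread**4)),
        })
    if not per_dir:
        return {k: 0.0 for k in (
            "glcm_contrast", "glcm_dissimilarity", "glcm_homogeneity",
            "glcm_asm", "glcm_joint_entropy", "glcm_correlation",
            "glcm_cluster_shade", "glcm_cluster_prominence")}
    keys = per_dir[0].keys()
    return {k: float(np.mean([d[k] for d in per_dir])) for k in keys}


def extract_features(
    volume: np.ndarray,
    rois: ROISet,
    bins: int = 32,
    min_voxels: int = 10,
    valid_mask: np.ndarray | None = None,
    site: str | None = None,
    timepoint: str | None = None,
) -> pd.DataFrame:
    """Per-ROI feature table: 18 first-order + 8 GLCM features.

    ROIs with fewer than ``min_voxels`` usable voxels are skipped with a
    log entry. Texture discretization uses a fixed bin count per ROI so
    that bins stay aligned across sites after histogram matching.
    """
    check_same_grid(volume.shape, rois.masks.shape)
    vol = np.asarray(volume, dtype=float)
    rows = []
    for label in rois.labels:
        sel = rois.mask_for(label)
        if valid_mask is not None:
            sel = sel & valid_mask
        vals = vol[sel]
        if vals.size < min_voxels:
            logger.warning("ROI %s (%d voxels) below minimum %d; skipped",
                           rois.label_names[label], vals.size, min_voxels)
            continue
        # crop to the ROI bounding box (+1 voxel) before texture analysis
        nz = np.nonzero(sel)
        bbox = tuple(slice(max(int(a.min()) - 1, 0), int(a.max()) + 2) for a in nz)
        sel_c = sel[bbox]
        levels = np.zeros(sel_c.shape, dtype=np.int32)
        levels[sel_c] = _discretize(vol[bbox][sel_c], bins)
        row = {
            "site": site,
            "timepoint": timepoint,
            "roi_label": label,
            "roi_name": rois.label_names[label],
            "organ_class": rois.organ_of_label[label],
        }
        row.update(_first_order(vals, bins))
        row.update(_glcm_features(sel_c, levels, bins))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-stage feature selection


def stability_filter(
    tables: dict[str, pd.DataFrame] | pd.DataFrame,
    threshold: float = 0.75,
) -> tuple[pd.Series, list[str]]:
    """Cross-site stability scores and surviving features.

    For every feature, each site contributes the vector of its values
    over the (shared) anatomical ROI positions; the score is the mean
    absolute Pearson correlation over all unordered site pairs. Pairs
    where either vector has zero variance contribute r = 0 (logged).
    Survivors satisfy score ≥ threshold. Being correlation-based, the
    score is invariant to per-site affine rescaling of a feature — the
    designed tolerance to vendor gain differences.
    """
    if isinstance(tables, pd.DataFrame):
        tables = {s: g for s, g in tables.groupby("site")}
    if len(tables) < 2:
        raise ValueError("stability filtering needs at least 2 sites")
    site_ids = sorted(tables)
    ref_labels = None
    feats = None
    vectors: dict[str, pd.DataFrame] = {}
    for s in site_ids:
        df = tables[s].sort_values("roi_label")
        labels = tuple(df["roi_label"])
        if ref_labels is None:
            ref_labels = labels
            feats = feature_columns(df)
        elif labels != ref_labels:
            raise ValueError(f"site {s} covers different roi_labels")
        vectors[s] = df[feats].reset_index(drop=True)
    scores = {}
    for feat in feats:
        rs = []
        for a, b in itertools.combinations(site_ids, 2):
            va = vectors[a][feat].to_numpy(dtype=float)
            vb = vectors[b][feat].to_numpy(dtype=float)
            if va.std() == 0 or vb.std() == 0:
                logger.warning("zero-variance %s at site pair (%s, %s); r := 0",
                               feat, a, b)
                rs.append(0.0)
            else:
                rs.append(abs(float(np.corrcoef(va, vb)[0, 1])))
        scores[feat] = float(np.mean(rs))
    score_series = pd.Series(scores, name="stability_score")
    survivors = [f for f in feats if scores[f] >= threshold]
    return score_series, survivors


@dataclass
class SelectionResult:
    """Outcome of the two-stage (stability → ANOVA-F) selection."""

    stability_score: dict[str, float]
    f_score: dict[str, float]
    selected: list[str]


def anova_select(
    table: pd.DataFrame,
    survivors: list[str],
    n_select: int = 15,
    class_col: str = "organ_class",
) -> SelectionResult:
    """Rank surviving features by one-way ANOVA F against organ classes.

    The top ``n_select`` features by F are selected, ties broken
    lexicographically by feature name. With fewer survivors than
    ``n_select`` all survivors are selected (with a warning).
    """
    classes = table[class_col]
    counts = classes.value_counts()
    if len(counts) < 2:
        raise ValueError("ANOVA selection needs at least 2 organ classes")
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"classes with < 2 samples: {list(small.index)}")
    if not survivors:
        return SelectionResult({}, {}, [])
    X = table[survivors].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_vals, _ = f_classif(X, classes.to_numpy())
    f_vals = np.nan_to_num(f_vals, nan=0.0, posinf=np.inf)
    f_score = {feat: float(f) for feat, f in zip(survivors, f_vals)}
    ranked = sorted(survivors, key=lambda ft: (-f_score[ft], ft))
    if len(ranked) < n_select:
        logger.warning("only %d survivors for n_select=%d; selecting all",
                       len(ranked), n_select)
    selected = ranked[: min(n_select, len(ranked))]
    return SelectionResult({}, f_score, selected)


# ---------------------------------------------------------------------------
# sklearn-style transformer facades


class StabilityFilter(BaseEstimator, TransformerMixin):
    """Transformer facade over :func:`stability_filter`.

    Operates on long-format feature tables (key columns + feature
    columns). ``transform`` keeps the key columns and the surviving
    feature columns only.

    Attributes
    ----------
    stability_scores_ : pandas.Series
    survivors_ : list of str
    """

    def __init__(self, threshold: float = 0.75):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        scores, survivors = stability_filter(X, threshold=self.threshold)
        self.stability_scores_ = scores
        self.survivors_ = survivors
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        keys = [c for c in META_COLUMNS if c in X.columns]
        return X[keys + self.survivors_]


class AnovaFSelector(BaseEstimator, TransformerMixin):
    """Transformer facade over :func:`anova_select` (top-N by ANOVA F)."""

    def __init__(self, n_select: int = 15, class_col: str = "organ_class"):
        self.n_select = n_select
        self.class_col = class_col

    def fit(self, X: pd.DataFrame, y=None):
        feats = feature_columns(X)
        res = anova_select(X, feats, n_select=self.n_select,
                           class_col=self.class_col)
        self.f_scores_ = res.f_score
        self.selected_ = res.selected
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        keys = [c for c in META_COLUMNS if c in X.columns]
        return X[keys + self.selected_]
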