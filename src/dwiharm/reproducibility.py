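"""ROI-level test-retest and cross-site reproducibility statistics.

Agreement between two measurements of the same quantity is assessed in
the Bland-Altman fashion: per-pair relative differences
(m2 − m1) / ((m1 + m2) / 2) · 100, summarized by their mean, SD and
limits of agreement (mean ± 1.96 SD). Traveling-volunteer comparisons
are expressed relative to a designated reference site (deviation of the
reference from itself is identically zero). Paired distributional shifts
are tested with the Wilcoxon signed-rank test at a Bonferroni-adjusted
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from dwiharm.core import ROISet, check_same_grid
from dwiharm.errors import PairingError

__all__ = [
    "BlandAltmanResult",
    "roi_stats",
    "bland_altman",
    "traveling_comparison",
    "paired_wilcoxon",
]


def roi_stats(
    volume: np.ndarray,
    rois: ROISet,
    valid_mask: np.ndarray | None = None,
    site: str | None = None,
    timepoint: str | None = None,
) -> pd.DataFrame:
    """Mean / SD / voxel count per ROI label over valid voxels.

    ROIs left empty after masking are flagged (``flagged=True``, NaN
    statistics) rather than dropped, so downstream pairing can report
    them explicitly.
    """
    check_same_grid(volume.shape, rois.masks.shape)
    if valid_mask is not None:
        check_same_grid(volume.shape, valid_mask.shape)
    rows = []
    for label in rois.labels:
        sel = rois.mask_for(label)
        if valid_mask is not None:
            sel = sel & valid_mask
        vals = volume[sel]
        n = int(vals.size)
        rows.append({
            "site": site,
            "timepoint": timepoint,
            "roi_label": label,
            "roi_name": rois.label_names[label],
            "organ_class": rois.organ_of_label[label],
            "mean": float(vals.mean()) if n else np.nan,
            "sd": float(vals.std(ddof=1)) if n > 1 else (0.0 if n else np.nan),
            "n_voxels": n,
            "flagged": n == 0,
        })
    return pd.DataFrame(rows)


@dataclass
class BlandAltmanResult:
    """Bland-Altman summary of paired ROI means, on the percent scale."""

    pairs: pd.DataFrame
    mean_diff_pct: float
    sd_diff_pct: float
    loa: tuple[float, float]

    @property
    def per_pair_rel_diff_pct(self) -> np.ndarray:
        return self.pairs["rel_diff_pct"].to_numpy()


_PAIR_KEYS = ["site", "roi_label"]


def bland_altman(test: pd.DataFrame, retest: pd.DataFrame) -> BlandAltmanResult:
    """Bland-Altman analysis of matched (site, roi_label) ROI means.

    The primary relative difference uses the pair mean as denominator;
    ``rel_diff_first_pct`` (first measurement as denominator) is carried
    along for comparison since published percent deviations do not
    always state their convention.
    """
    t = test.set_index(_PAIR_KEYS)
    r = retest.set_index(_PAIR_KEYS)
    unmatched = sorted(set(t.index).symmetric_difference(r.index))
    if unmatched:
        raise PairingError(f"unmatched (site, roi_label) keys: {unmatched}")
    merged = t[["roi_name", "organ_class", "mean"]].join(
        r[["mean"]], lsuffix="_1", rsuffix="_2"
    ).reset_index()
    m1 = merged["mean_1"].to_numpy(dtype=float)
    m2 = merged["mean_2"].to_numpy(dtype=float)
    pair_mean = (m1 + m2) / 2.0
    merged["pair_mean"] = pair_mean
    merged["rel_diff_pct"] = 100.0 * (m2 - m1) / pair_mean
    merged["rel_diff_first_pct"] = 100.0 * (m2 - m1) / m1
    mean_diff = float(merged["rel_diff_pct"].mean())
    sd_diff = float(merged["rel_diff_pct"].std(ddof=1)) if len(merged) > 1 else 0.0
    return BlandAltmanResult(
        pairs=merged,
        mean_diff_pct=mean_diff,
        sd_diff_pct=sd_diff,
        loa=(mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff),
    )


def traveling_comparison(
    stats_by_site: dict[str, pd.DataFrame],
    reference_site: str,
) -> pd.DataFrame:
    """Per (site, ROI) percent deviation from the reference site's mean.

    deviation = (m_site − m_ref) / m_ref · 100; the reference site's own
    rows are exactly zero by construction.
    """
    if reference_site not in stats_by_site:
        raise ValueError(f"reference site {reference_site!r} not present")
    ref = stats_by_site[reference_site].set_index("roi_label")["mean"]
    frames = []
    for site, df in stats_by_site.items():
        out = df[["roi_label", "roi_name", "organ_class", "mean"]].copy()
        out["site"] = site
        ref_means = ref.reindex(out["roi_label"]).to_numpy(dtype=float)
        out["ref_mean"] = ref_means
        out["deviation_pct"] = 100.0 * (out["mean"].to_numpy() - ref_means) / ref_means
        if site == reference_site:
            out["deviation_pct"] = 0.0
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def paired_wilcoxon(
    x,
    y,
    alpha_adjusted: float = 0.007,
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test for paired measurements.

    Zero differences are dropped (Wilcoxon's original rule). The exact
    null distribution is used for n ≤ 25 retained pairs (falling back
    to the normal approximation when ties make the exact distribution
    unavailable), the normal approximation above. The significance flag
    applies the Bonferroni-adjusted threshold, 0.007 by default.

    Returns ``(statistic, p_two_sided, significant)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = y - x
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0, False
    if n < 5:
        raise ValueError(f"need ≥ 5 non-zero differences, got {n}")
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                       method=method)
    p = float(res.pvalue)
    return float(res.statistic), p, bool(p < alpha_adjusted)
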