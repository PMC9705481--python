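"""Central, vendor-independent ADC map computation.

The apparent diffusion coefficient is estimated per voxel from the
monoexponential decay model S(b) = S0 exp(-b * ADC) by ordinary least
squares of ln S(b) on b; the negated slope, converted from mm²/s to
μm²/s, is the ADC. By default b = 0 is omitted from the fit so that
perfusion (IVIM) effects at low b do not inflate the estimate — the same
choice a central post-processing pipeline imposes on all sites
regardless of which b-values the scanner-side fit used.

The fit is deliberately unweighted: no per-b signal-average weighting is
applied, and negative fitted slopes (negative ADC) are retained so the
raw estimator remains auditable in QA statistics. Voxels with any
non-positive signal among the used b-values are excluded from
``valid_mask`` instead of being clamped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dwiharm.core import ADCMap, DWISeries, ROISet, check_same_grid

__all__ = ["compute_adc_map", "compare_inline_vs_central"]


def compute_adc_map(series: DWISeries, omit_b0: bool = True) -> ADCMap:
    """Per-voxel log-linear OLS fit of the monoexponential decay.

    Parameters
    ----------
    series : DWISeries
        Aligned per-b-value magnitude volumes.
    omit_b0 : bool
        Drop the b = 0 volume (if present) before fitting; the central
        processing default.

    Returns
    -------
    ADCMap
        Values in μm²/s; ``valid_mask`` is False wherever any used
        signal is non-positive.
    """
    b = np.asarray(series.b_values, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative b-values are invalid")
    keep = b > 0 if omit_b0 else np.ones_like(b, dtype=bool)
    b_used = b[keep]
    if b_used.size < 2:
        raise ValueError(f"need at least 2 b-values to fit, got {b_used.size}")
    stack = np.stack([series.volumes[i] for i in np.flatnonzero(keep)], axis=0)

    valid = np.all(stack > 0, axis=0)
    logs = np.full_like(stack, np.nan)
    np.log(stack, out=logs, where=stack > 0)

    # closed-form OLS slope of ln S on b, vectorized over voxels
    b_cent = b_used - b_used.mean()
    denom = float(np.sum(b_cent**2))
    with np.errstate(invalid="ignore"):
        slope = np.tensordot(b_cent, logs, axes=(0, 0)) / denom
    values = np.where(valid, -slope * 1e6, np.nan)  # mm²/s → μm²/s
    return ADCMap(values=values, valid_mask=valid,
                  b_used=tuple(float(x) for x in b_used),
                  spacing=series.spacing, affine=series.affine)


def compare_inline_vs_central(
    inline_adc: ADCMap,
    central_adc: ADCMap,
    rois: ROISet,
) -> pd.DataFrame:
    """Paired per-ROI means of a scanner-style and a central ADC map.

    Returns one row per ROI label with both means, their difference and
    relative difference (percent of the central mean). ROIs empty on
    either map's valid mask are flagged rather than silently dropped.
    """
    check_same_grid(inline_adc.values.shape, central_adc.values.shape)
    check_same_grid(inline_adc.values.shape, rois.masks.shape)
    rows = []
    for label in rois.labels:
        sel = rois.mask_for(label)
        m_in = sel & inline_adc.valid_mask
        m_ct = sel & central_adc.valid_mask
        flagged = (m_in.sum() == 0) or (m_ct.sum() == 0)
        mean_in = float(inline_adc.values[m_in].mean()) if m_in.any() else np.nan
        mean_ct = float(central_adc.values[m_ct].mean()) if m_ct.any() else np.nan
        diff = mean_in - mean_ct
        rows.append({
            "roi_label": label,
            "roi_name": rois.label_names[label],
            "organ_class": rois.organ_of_label[label],
            "inline_mean": mean_in,
            "central_mean": mean_ct,
            "diff": diff,
            "rel_diff_pct": 100.0 * diff / mean_ct if mean_ct else np.nan,
            "flagged": flagged,
        })
    return pd.DataFrame(rows)
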