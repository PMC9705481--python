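"""High-level orchestration over simulated or loaded studies.

These helpers wire the per-module operations into the study-level
workflows the command-line interface and the acceptance analyses run:
per-site ADC maps and ROI statistics, harmonized feature tables
(resampling, reference-site histogram matching for T2w), and the
two-stage feature selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dwiharm.adcfit import compute_adc_map
from dwiharm.core import ROISet
from dwiharm.radiomics import (
    SelectionResult,
    anova_select,
    extract_features,
    histogram_match,
    resample_isotropic,
    stability_filter,
)
from dwiharm.reproducibility import roi_stats
from dwiharm.synthdata import Study, reference_site

__all__ = [
    "study_roi_stats",
    "study_feature_table",
    "select_features",
]


def _modality_volume(rec, modality: str, timepoint: str):
    """(volume, valid_mask) for one site record and timepoint."""
    if modality == "adc":
        series = rec.dwi if timepoint == "t1" else rec.dwi_retest
        if series is None:
            return None, None
        adc = compute_adc_map(series, omit_b0=True)
        return adc.values, adc.valid_mask
    if modality == "t2w":
        vol = rec.t2w if timepoint == "t1" else rec.t2w_retest
        return vol, None
    raise ValueError(f"unknown modality {modality!r}")


def _rois_for(rec, timepoint: str) -> ROISet | None:
    return rec.rois if timepoint == "t1" else (rec.rois_retest or rec.rois)


def study_roi_stats(
    study: Study,
    modality: str = "adc",
    timepoint: str = "t1",
) -> dict[str, pd.DataFrame]:
    """Per-site ROI mean/SD tables for one modality and timepoint."""
    out = {}
    for site_id, rec in study.sites.items():
        vol, valid = _modality_volume(rec, modality, timepoint)
        rois = _rois_for(rec, timepoint)
        if vol is None or rois is None:
            continue
        out[site_id] = roi_stats(vol, rois, valid_mask=valid,
                                 site=site_id, timepoint=timepoint)
    return out


def study_feature_table(
    study: Study,
    modality: str = "adc",
    timepoint: str = "t1",
    resample: bool = True,
    match_histograms: bool | None = None,
    bins: int = 32,
    min_voxels: int = 10,
) -> pd.DataFrame:
    """Harmonized per-ROI feature table across all sites of a study.

    Volumes (and masks) are resampled to 1 mm isotropic. For T2w the
    arbitrary-unit intensities are histogram-matched to the reference
    site by default; the ADC stream skips matching (ADC is already
    quantitative — matching it would erase the very scale the pipeline
    harmonizes), overridable via ``match_histograms``.
    """
    if match_histograms is None:
        match_histograms = modality == "t2w"
    ref_id = reference_site(study.manifest).site_id

    ref_vol = None
    if match_histograms:
        ref_vol, _ = _modality_volume(study.sites[ref_id], modality, timepoint)
        if resample:
            ref_vol, _ = resample_isotropic(ref_vol, study.spacing)

    frames = []
    for site_id, rec in study.sites.items():
        vol, valid = _modality_volume(rec, modality, timepoint)
        rois = _rois_for(rec, timepoint)
        if vol is None or rois is None:
            continue
        spacing = study.spacing
        if modality == "adc":
            # fit failures are rare interior voxels; fill with 0 before
            # resampling, the valid mask travels alongside
            vol = np.where(valid, vol, 0.0)
        masks = rois.masks
        if resample:
            vol, new_spacing = resample_isotropic(vol, spacing)
            masks, _ = resample_isotropic(masks, spacing, is_mask=True)
            if valid is not None:
                v, _ = resample_isotropic(valid.astype(np.uint8), spacing,
                                          is_mask=True)
                valid = v.astype(bool)
            spacing = new_spacing
        if match_histograms and site_id != ref_id:
            vol = histogram_match(vol, ref_vol)
        rois_rs = ROISet(masks=masks, label_names=rois.label_names,
                         organ_of_label=rois.organ_of_label, spacing=spacing,
                         nominal_area_mm2=rois.nominal_area_mm2)
        frames.append(extract_features(vol, rois_rs, bins=bins,
                                       min_voxels=min_voxels, valid_mask=valid,
                                       site=site_id, timepoint=timepoint))
    return pd.concat(frames, ignore_index=True)


def select_features(
    table: pd.DataFrame,
    threshold: float = 0.75,
    n_select: int = 15,
) -> SelectionResult:
    """Two-stage selection: stability filter then ANOVA-F top-N."""
    scores, survivors = stability_filter(table, threshold=threshold)
    res = anova_select(table, survivors, n_select=n_select)
    return SelectionResult(stability_score=scores.to_dict(),
                           f_score=res.f_score, selected=res.selected)
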