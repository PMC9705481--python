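"""Seeded multi-site synthetic phantom and volunteer datasets.

The generator emulates the statistical structure of a seven-site
traveling-phantom / traveling-volunteer study: per-site receiver gain,
Rician noise, smooth multiplicative bias shading, one site whose scanner
requires a b = 0 volume (perfusion-inflated inline ADC), a spherical
diffusion phantom with a temperature-dependent ADC, and a volunteer
abdomen abstracted to ellipsoidal organs around the 11 standard ROI
positions. Anatomy realism is explicitly out of scope: only ROI-level
statistics need to be faithful.

Signal model (DWI, per voxel)::

    S(b) = gain * bias(x) * S0 * [(1 - f) exp(-b D) + f exp(-b D*)]

with D the true ADC, f an IVIM-like perfusion fraction and D* its
pseudo-diffusion coefficient; Rician noise of scale
``noise_sigma / sqrt(averages_b)`` is added per b-value volume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from dwiharm.core import (
    DEFAULT_DWI_ACQ,
    DWI_ACQ_WITH_B0,
    AcquisitionSpec,
    DWISeries,
    ROISet,
    SiteProfile,
    TissueMap,
    TissueSpec,
    require_spacing,
    spacing_affine,
)
from dwiharm.errors import LayoutError, ShapeError

logger = logging.getLogger(__name__)

#: default voxel spacing of the standardized DWI protocol (mm)
DEFAULT_SPACING = (2.6, 2.6, 5.0)

#: phantom ground truth: PVP sphere, 200 mm diameter, 1600 μm²/s at 20 °C
PHANTOM_ADC_20C = 1600.0
PHANTOM_DIAMETER_MM = 200.0
#: physical temperature sensitivity of the phantom ADC (fraction per °C)
PHANTOM_ALPHA_PER_C = 0.024

#: default organ ground truth. Liver ADC/T2w anchored at the printed
#: in-vivo means (965 μm²/s, gray value 480, with ~23%/26% in-ROI spread);
#: the remaining organs are stipulated at literature-plausible values.
DEFAULT_TISSUES: dict[str, TissueSpec] = {
    "kidney": TissueSpec("kidney", adc_true=1800.0, s0=1100.0, t2w_mean=700.0,
                         heterogeneity_sigma=0.10),
    "liver": TissueSpec("liver", adc_true=965.0, s0=1000.0, t2w_mean=480.0,
                        heterogeneity_sigma=0.22),
    "spleen": TissueSpec("spleen", adc_true=850.0, s0=1200.0, t2w_mean=750.0,
                         heterogeneity_sigma=0.06),
    "muscle": TissueSpec("muscle", adc_true=1350.0, s0=800.0, t2w_mean=300.0,
                         heterogeneity_sigma=0.08),
    "vertebra": TissueSpec("vertebra", adc_true=500.0, s0=700.0, t2w_mean=600.0,
                           heterogeneity_sigma=0.12),
}

#: unspecific soft tissue filling the volunteer volume around the organ
#: blobs, so intensity histograms are body-dominated rather than
#: air-dominated (as in abdominal imaging)
BODY_TISSUE = TissueSpec("body", adc_true=1200.0, s0=900.0, t2w_mean=200.0,
                         heterogeneity_sigma=0.15)
BODY_LABEL = 99

#: the 11 standard ROI positions: (label, name, organ class, center in mm)
DEFAULT_ROI_GEOMETRY: tuple[tuple[int, str, str, tuple[float, float, float]], ...] = (
    (1, "kidney_left", "kidney", (50.0, 50.0, 22.5)),
    (2, "kidney_right", "kidney", (190.0, 50.0, 22.5)),
    (3, "liver_segment_4", "liver", (50.0, 120.0, 22.5)),
    (4, "liver_segment_7", "liver", (120.0, 120.0, 22.5)),
    (5, "liver_segment_8", "liver", (190.0, 120.0, 22.5)),
    (6, "spleen_1", "spleen", (50.0, 190.0, 22.5)),
    (7, "spleen_2", "spleen", (50.0, 50.0, 47.5)),
    (8, "quadratus_lumborum_left", "muscle", (120.0, 50.0, 47.5)),
    (9, "quadratus_lumborum_right", "muscle", (190.0, 50.0, 47.5)),
    (10, "vertebra_L1", "vertebra", (120.0, 190.0, 47.5)),
    (11, "vertebra_L2", "vertebra", (190.0, 190.0, 47.5)),
)

DEFAULT_VOLUNTEER_SHAPE = (96, 96, 14)
#: ellipsoid semi-axes of each synthetic organ blob (mm)
ORGAN_SEMIAXES_MM = (16.0, 16.0, 11.0)

_SITE_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


# ---------------------------------------------------------------------------
# site manifests


def generate_site_manifest(n_sites: int, seed: int) -> list[SiteProfile]:
    """Draw a seeded manifest of heterogeneous site profiles.

    Exactly one site is the harmonization reference (site "F" when at
    least six sites exist, mirroring a DKFZ-style reference center) and,
    for manifests of ≥ 7 sites, exactly one non-reference site requires
    b = 0 in its scanner-side fit (site "B").
    """
    if n_sites < 2:
        raise ValueError("a multicenter manifest needs at least 2 sites")
    rng = np.random.default_rng(seed)
    reference_idx = 5 if n_sites >= 6 else 0
    b0_idx = 1 if n_sites >= 7 else None
    profiles = []
    for i in range(n_sites):
        site_id = (_SITE_LETTERS[i] if i < len(_SITE_LETTERS)
                   else f"S{i + 1}")
        profiles.append(
            SiteProfile(
                site_id=site_id,
                vendor_tag=("A-style", "B-style", "C-style")[i % 3],
                gain=float(rng.uniform(0.8, 1.25)),
                noise_sigma=float(rng.uniform(10.0, 30.0)),
                bias_amplitude=float(rng.uniform(0.02, 0.08)),
                includes_b0=(i == b0_idx),
                is_reference=(i == reference_idx),
            )
        )
    return profiles


def reference_site(manifest: Sequence[SiteProfile]) -> SiteProfile:
    refs = [p for p in manifest if p.is_reference]
    if len(refs) != 1:
        raise ValueError(f"manifest must contain exactly one reference, got {len(refs)}")
    return refs[0]


# ---------------------------------------------------------------------------
# signal simulation


def bias_field(shape: tuple[int, int, int], amplitude: float) -> np.ndarray:
    """Smooth multiplicative shading: 1 + a * Π_i cos(π u_i), u centered.

    A minimal separable model of coil-sensitivity shading (center-bright,
    edge-neutral) that histogram matching is expected to remove.
    """
    if amplitude == 0:
        return np.ones(shape)
    axes = [np.cos(np.pi * (np.arange(n) / max(n - 1, 1) - 0.5)) for n in shape]
    prod = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return 1.0 + amplitude * prod


def _rician(noise_free: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return noise_free.copy()
    re = noise_free + rng.normal(0.0, sigma, noise_free.shape)
    im = rng.normal(0.0, sigma, noise_free.shape)
    return np.hypot(re, im)


def simulate_dwi(
    tissue_map: TissueMap,
    site: SiteProfile,
    acq: AcquisitionSpec = DEFAULT_DWI_ACQ,
    seed: int | None = None,
) -> DWISeries:
    """Simulate one multi-b DWI acquisition of ``tissue_map`` at ``site``."""
    if acq.modality != "dwi":
        raise ValueError("simulate_dwi needs a dwi acquisition spec")
    require_spacing(tissue_map.spacing)
    rng = np.random.default_rng(seed)
    bias = bias_field(tissue_map.shape, site.bias_amplitude)
    # μm²/s → mm²/s so that b*D is dimensionless
    d = tissue_map.adc * 1e-6
    d_star = tissue_map.d_star * 1e-6
    f = tissue_map.f
    base = site.gain * bias * tissue_map.s0
    volumes = []
    for b, averages in zip(acq.b_values, acq.averages):
        signal = base * ((1.0 - f) * np.exp(-b * d) + f * np.exp(-b * d_star))
        sigma = site.noise_sigma / np.sqrt(averages)
        volumes.append(_rician(signal, sigma, rng))
    return DWISeries(volumes=volumes, spacing=tissue_map.spacing, acquisition=acq)


def simulate_t2w(
    tissue_map: TissueMap,
    site: SiteProfile,
    seed: int | None = None,
) -> np.ndarray:
    """Gray-value surrogate of a single-shot T2w volume (arbitrary units)."""
    rng = np.random.default_rng(seed)
    bias = bias_field(tissue_map.shape, site.bias_amplitude)
    vol = site.gain * bias * tissue_map.t2w
    if site.noise_sigma > 0:
        vol = vol + rng.normal(0.0, site.noise_sigma, vol.shape)
    return vol


# ---------------------------------------------------------------------------
# ROI geometry


def rasterize_circle(
    shape2d: tuple[int, int],
    center_mm: tuple[float, float],
    spacing2d: tuple[float, float],
    area_mm2: float,
) -> np.ndarray:
    """2D disc of (approximately) the requested physical area.

    Pixels are ranked by distance of their center from the circle center
    and the closest ``round(area / pixel_area)`` pixels are taken, with
    deterministic index tie-breaks — a disc whose rasterized area is
    always within half a pixel of the target.
    """
    px_area = spacing2d[0] * spacing2d[1]
    radius = float(np.sqrt(area_mm2 / np.pi))
    if min(spacing2d) > radius:
        raise LayoutError(
            f"in-plane spacing {spacing2d} exceeds circle radius {radius:.2f} mm"
        )
    n_target = int(round(area_mm2 / px_area))
    xs = (np.arange(shape2d[0]) + 0.5) * spacing2d[0]
    ys = (np.arange(shape2d[1]) + 0.5) * spacing2d[1]
    dist2 = (xs[:, None] - center_mm[0]) ** 2 + (ys[None, :] - center_mm[1]) ** 2
    flat = dist2.ravel()
    order = np.lexsort((np.arange(flat.size), flat))
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:n_target]] = True
    return mask.reshape(shape2d)


def make_roi_masks(
    geometry: Sequence[tuple[int, str, str, tuple[float, float, float]]] = DEFAULT_ROI_GEOMETRY,
    spacing: Sequence[float] = DEFAULT_SPACING,
    shape: tuple[int, int, int] = DEFAULT_VOLUNTEER_SHAPE,
    area_mm2: float = 250.0,
    jitter_mm: Sequence[tuple[float, float]] | None = None,
) -> ROISet:
    """Rasterize the 11 circular 2D ROI masks onto a voxel grid.

    ``jitter_mm`` optionally shifts each circle center in-plane (one
    (dx, dy) per ROI), emulating re-drawn ROIs after repositioning.
    """
    spacing = require_spacing(spacing)
    masks = np.zeros(shape, dtype=np.int16)
    label_names: dict[int, str] = {}
    organ_of_label: dict[int, str] = {}
    for idx, (label, name, organ, center) in enumerate(geometry):
        cx, cy, cz = center
        if jitter_mm is not None:
            cx, cy = cx + jitter_mm[idx][0], cy + jitter_mm[idx][1]
        z_idx = int(round(cz / spacing[2] - 0.5))
        if not 0 <= z_idx < shape[2]:
            raise LayoutError(f"ROI {name} slice {z_idx} outside volume")
        disc = rasterize_circle(shape[:2], (cx, cy), spacing[:2], area_mm2)
        if np.any(masks[:, :, z_idx][disc] != 0):
            raise LayoutError(f"ROI {name} overlaps a previously placed ROI")
        plane = masks[:, :, z_idx]
        plane[disc] = label
        label_names[label] = name
        organ_of_label[label] = organ
    return ROISet(masks=masks, label_names=label_names,
                  organ_of_label=organ_of_label, spacing=spacing,
                  nominal_area_mm2=area_mm2)


# ---------------------------------------------------------------------------
# tissue maps


def make_phantom_map(
    temperature_c: float = 20.0,
    spacing: Sequence[float] = (4.0, 4.0, 4.0),
    shape: tuple[int, int, int] = (64, 64, 56),
    adc_20c: float = PHANTOM_ADC_20C,
    alpha_per_c: float = PHANTOM_ALPHA_PER_C,
) -> TissueMap:
    """Homogeneous 200 mm PVP sphere at the given bath temperature."""
    spacing = require_spacing(spacing)
    adc_t = adc_20c * (1.0 + alpha_per_c * (temperature_c - 20.0))
    center = [(n * s) / 2.0 for n, s in zip(shape, spacing)]
    grids = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    labels = (r2 <= (PHANTOM_DIAMETER_MM / 2.0) ** 2).astype(np.int16)
    spec = TissueSpec("phantom", adc_true=adc_t, s0=1500.0, t2w_mean=900.0)
    # organ_class "phantom" is not one of the 5 in-vivo classes; allowed here
    return TissueMap.from_labels(labels, {1: spec}, spacing, seed=0)


def make_volunteer_map(
    seed: int,
    tissues: dict[str, TissueSpec] | None = None,
    geometry: Sequence[tuple[int, str, str, tuple[float, float, float]]] = DEFAULT_ROI_GEOMETRY,
    spacing: Sequence[float] = DEFAULT_SPACING,
    shape: tuple[int, int, int] = DEFAULT_VOLUNTEER_SHAPE,
) -> TissueMap:
    """Volunteer abdomen abstracted to ellipsoidal organ blobs.

    One ellipsoid per ROI position, large enough that the 250 mm² circle
    plus ≤ 3 mm repositioning jitter stays inside homogeneous(ly
    heterogeneous) tissue. The space between organ blobs is filled with
    unspecific body tissue so global intensity histograms behave like
    abdominal images rather than air.
    """
    spacing = require_spacing(spacing)
    tissues = dict(DEFAULT_TISSUES if tissues is None else tissues)
    labels = np.full(shape, BODY_LABEL, dtype=np.int16)
    grids = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    label_specs: dict[int, TissueSpec] = {}
    for label, name, organ, center in geometry:
        d2 = sum(((g - c) / a) ** 2
                 for g, c, a in zip(grids, center, ORGAN_SEMIAXES_MM))
        inside = d2 <= 1.0
        if np.any(labels[inside] != BODY_LABEL):
            raise LayoutError(f"organ blob for {name} overlaps another blob")
        labels[inside] = label
        label_specs[label] = tissues[organ]
    label_specs[BODY_LABEL] = BODY_TISSUE
    return TissueMap.from_labels(labels, label_specs, spacing, seed=seed)


# ---------------------------------------------------------------------------
# study generation


@dataclass
class SiteRecord:
    """One site's simulated data within a study (in-memory form)."""

    profile: SiteProfile
    dwi: DWISeries | None = None
    dwi_retest: DWISeries | None = None
    t2w: np.ndarray | None = None
    t2w_retest: np.ndarray | None = None
    rois: ROISet | None = None
    rois_retest: ROISet | None = None
    temperature_c: float | None = None
    tissue_hash: str | None = None


@dataclass
class Study:
    """A full simulated scenario across all sites."""

    scenario: str
    manifest: list[SiteProfile]
    sites: dict[str, SiteRecord]
    seed: int
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    roi_geometry: tuple = DEFAULT_ROI_GEOMETRY


def _site_acq(site: SiteProfile) -> AcquisitionSpec:
    return DWI_ACQ_WITH_B0 if site.includes_b0 else DEFAULT_DWI_ACQ


def _sub_seed(seed: int, *parts: int) -> int:
    """Derive a stream seed below 2**31 from a base seed and indices."""
    ss = np.random.SeedSequence([seed, *parts])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_study(
    manifest: Sequence[SiteProfile],
    scenario: str,
    seed: int,
    spacing: Sequence[float] = DEFAULT_SPACING,
    phantom_spacing: Sequence[float] = (4.0, 4.0, 4.0),
) -> Study:
    """Simulate one scenario (in memory) for every site in the manifest.

    Scenarios
    ---------
    ``phantom``
        One homogeneous-sphere DWI per site at a site-specific bath
        temperature drawn uniformly from 18–24 °C.
    ``test_retest``
        A distinct volunteer per site, imaged twice with re-seeded noise
        and a ≤ 3 mm in-plane ROI re-placement jitter for the retest.
    ``traveling_volunteer``
        One fixed volunteer tissue map imaged under every site profile.
    """
    scenario = scenario.replace("-", "_")
    if scenario not in ("phantom", "test_retest", "traveling_volunteer"):
        raise ValueError(f"unknown scenario {scenario!r}")
    reference_site(manifest)  # validates the manifest
    rng = np.random.default_rng(_sub_seed(seed, 0))
    sites: dict[str, SiteRecord] = {}

    traveling_map = None
    if scenario == "traveling_volunteer":
        traveling_map = make_volunteer_map(_sub_seed(seed, 1), spacing=spacing)

    for i, profile in enumerate(manifest):
        rec = SiteRecord(profile=profile)
        acq = _site_acq(profile)
        if scenario == "phantom":
            rec.temperature_c = float(rng.uniform(18.0, 24.0))
            tmap = make_phantom_map(rec.temperature_c, spacing=phantom_spacing)
            rec.dwi = simulate_dwi(tmap, profile, acq, seed=_sub_seed(seed, 2, i))
            rec.tissue_hash = tmap.content_hash()
        elif scenario == "test_retest":
            tmap = make_volunteer_map(_sub_seed(seed, 3, i), spacing=spacing)
            rec.tissue_hash = tmap.content_hash()
            rec.dwi = simulate_dwi(tmap, profile, acq, seed=_sub_seed(seed, 4, i))
            rec.dwi_retest = simulate_dwi(tmap, profile, acq, seed=_sub_seed(seed, 5, i))
            rec.t2w = simulate_t2w(tmap, profile, seed=_sub_seed(seed, 6, i))
            rec.t2w_retest = simulate_t2w(tmap, profile, seed=_sub_seed(seed, 7, i))
            rec.rois = make_roi_masks(spacing=spacing, shape=tmap.shape)
            jit_rng = np.random.default_rng(_sub_seed(seed, 8, i))
            jitter = [tuple(jit_rng.uniform(-3.0, 3.0, 2)) for _ in DEFAULT_ROI_GEOMETRY]
            rec.rois_retest = make_roi_masks(spacing=spacing, shape=tmap.shape,
                                             jitter_mm=jitter)
        else:  # traveling_volunteer
            rec.tissue_hash = traveling_map.content_hash()
            rec.dwi = simulate_dwi(traveling_map, profile, acq,
                                   seed=_sub_seed(seed, 9, i))
            rec.t2w = simulate_t2w(traveling_map, profile, seed=_sub_seed(seed, 10, i))
            rec.rois = make_roi_masks(spacing=spacing, shape=traveling_map.shape)
        sites[profile.site_id] = rec
    return Study(scenario=scenario, manifest=list(manifest), sites=sites,
                 seed=seed, spacing=require_spacing(spacing))


# ---------------------------------------------------------------------------
# on-disk layout: one NIfTI per b-value plus a JSON index


def _save_nifti(path: Path, data: np.ndarray, spacing: Sequence[float]) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          spacing_affine(spacing))
    nib.save(img, str(path))


def _save_mask(path: Path, data: np.ndarray, spacing: Sequence[float]) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data, dtype=np.int16),
                          spacing_affine(spacing))
    nib.save(img, str(path))


def write_study(study: Study, out_dir: str | Path) -> Path:
    """Write a study as NIfTI volumes plus an ``index.json`` sidecar."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    index: dict = {
        "scenario": study.scenario,
        "seed": study.seed,
        "spacing": list(study.spacing),
        "sites": {},
    }
    for site_id, rec in study.sites.items():
        sdir = out / site_id
        sdir.mkdir(exist_ok=True)
        entry: dict = {
            "profile": asdict(rec.profile),
            "tissue_hash": rec.tissue_hash,
        }
        if rec.temperature_c is not None:
            entry["temperature_c"] = rec.temperature_c

        def _write_dwi(series: DWISeries, tag: str) -> dict:
            files = {}
            for b, vol in zip(series.b_values, series.volumes):
                name = f"{tag}_dwi_b{int(b)}.nii.gz"
                _save_nifti(sdir / name, vol, series.spacing)
                files[str(int(b))] = f"{site_id}/{name}"
            return {"b_values": list(series.b_values),
                    "averages": list(series.acquisition.averages),
                    "files": files}

        if rec.dwi is not None:
            entry["dwi_t1"] = _write_dwi(rec.dwi, "t1")
        if rec.dwi_retest is not None:
            entry["dwi_t2"] = _write_dwi(rec.dwi_retest, "t2")
        if rec.t2w is not None:
            _save_nifti(sdir / "t1_t2w.nii.gz", rec.t2w, study.spacing)
            entry["t2w_t1"] = f"{site_id}/t1_t2w.nii.gz"
        if rec.t2w_retest is not None:
            _save_nifti(sdir / "t2_t2w.nii.gz", rec.t2w_retest, study.spacing)
            entry["t2w_t2"] = f"{site_id}/t2_t2w.nii.gz"
        for rois, tag in ((rec.rois, "t1"), (rec.rois_retest, "t2")):
            if rois is not None:
                name = f"rois_{tag}.nii.gz"
                _save_mask(sdir / name, rois.masks, rois.spacing)
                entry[f"rois_{tag}"] = {
                    "file": f"{site_id}/{name}",
                    "label_names": {str(k): v for k, v in rois.label_names.items()},
                    "organ_of_label": {str(k): v for k, v in rois.organ_of_label.items()},
                }
        index["sites"][site_id] = entry
    (out / "index.json").write_text(json.dumps(index, indent=2))
    return out / "index.json"


def load_study(dataset_dir: str | Path) -> Study:
    """Load a study previously written by :func:`write_study`."""
    import nibabel as nib

    root = Path(dataset_dir)
    index = json.loads((root / "index.json").read_text())
    spacing = tuple(index["spacing"])
    manifest = []
    sites: dict[str, SiteRecord] = {}

    def _load(rel: str) -> np.ndarray:
        return np.asarray(nib.load(str(root / rel)).dataobj, dtype=np.float64)

    for site_id, entry in index["sites"].items():
        profile = SiteProfile(**entry["profile"])
        manifest.append(profile)
        rec = SiteRecord(profile=profile,
                         temperature_c=entry.get("temperature_c"),
                         tissue_hash=entry.get("tissue_hash"))

        for key, attr in (("dwi_t1", "dwi"), ("dwi_t2", "dwi_retest")):
            if key in entry:
                meta = entry[key]
                acq = AcquisitionSpec(tuple(float(b) for b in meta["b_values"]),
                                      tuple(int(a) for a in meta["averages"]))
                vols = [_load(meta["files"][str(int(b))]) for b in acq.b_values]
                setattr(rec, attr, DWISeries(vols, spacing, acq))
        if "t2w_t1" in entry:
            rec.t2w = _load(entry["t2w_t1"])
        if "t2w_t2" in entry:
            rec.t2w_retest = _load(entry["t2w_t2"])
        for key, attr in (("rois_t1", "rois"), ("rois_t2", "rois_retest")):
            if key in entry:
                meta = entry[key]
                masks = np.asarray(nib.load(str(root / meta["file"])).dataobj,
                                   dtype=np.int16)
                setattr(rec, attr, ROISet(
                    masks=masks,
                    label_names={int(k): v for k, v in meta["label_names"].items()},
                    organ_of_label={int(k): v for k, v in meta["organ_of_label"].items()},
                    spacing=spacing,
                ))
        sites[site_id] = rec
    return Study(scenario=index["scenario"], manifest=manifest, sites=sites,
                 seed=index["seed"], spacing=spacing)
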