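"""Domain containers shared across the pipeline.

Conventions
-----------
* Volumes are numpy arrays with axes ordered (x, y, z), matching the
  column order of the accompanying RAS affine.
* ADC values are expressed in μm²/s (1 μm²/s = 1e-6 mm²/s) throughout;
  b-values in s/mm².
* Spacing is millimetres per voxel along each array axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from dwiharm.errors import MetadataError, ShapeError, TemperatureRangeError

ORGAN_CLASSES = ("kidney", "liver", "spleen", "muscle", "vertebra")
VENDOR_TAGS = ("A-style", "B-style", "C-style")

#: nominal in-plane ROI area, mm²
ROI_AREA_MM2 = 250.0


def spacing_affine(spacing: Sequence[float]) -> np.ndarray:
    """RAS affine with the given voxel spacing and origin at zero."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass(frozen=True)
class SiteProfile:
    """Per-site acquisition heterogeneity used for simulation and QA.

    ``gain`` multiplies all intensities (receiver chain), ``noise_sigma``
    is the Rician noise scale before signal averaging, ``bias_amplitude``
    the fractional amplitude of a smooth multiplicative shading field.
    ``includes_b0`` marks a site whose scanner-side fit must include
    b = 0 s/mm² (inflating ADC through perfusion); ``is_reference``
    marks the harmonization reference site.
    """

    site_id: str
    vendor_tag: str = "A-style"
    gain: float = 1.0
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    includes_b0: bool = False
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.vendor_tag not in VENDOR_TAGS:
            raise ValueError(f"unknown vendor_tag {self.vendor_tag!r}")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0 <= self.bias_amplitude < 1:
            raise ValueError("bias_amplitude must lie in [0, 1)")


@dataclass(frozen=True)
class AcquisitionSpec:
    """b-values (s/mm²) with per-b signal averages, or a T2w acquisition."""

    b_values: tuple[float, ...]
    averages: tuple[int, ...]
    modality: str = "dwi"

    def __post_init__(self) -> None:
        if self.modality not in ("dwi", "t2w"):
            raise ValueError("modality must be 'dwi' or 't2w'")
        if any(b < 0 for b in self.b_values):
            raise ValueError("b-values must be non-negative")
        if list(self.b_values) != sorted(set(self.b_values)):
            raise ValueError("b-values must be strictly increasing")
        if len(self.b_values) != len(self.averages):
            raise ValueError("b_values and averages must have equal length")
        if any(a < 1 for a in self.averages):
            raise ValueError("averages must be positive integers")


#: the standardized protocol: b = 100/500/900 s/mm² with 1/6/23 averages
DEFAULT_DWI_ACQ = AcquisitionSpec((100.0, 500.0, 900.0), (1, 6, 23))
#: the same protocol with a mandatory b = 0 volume prepended
DWI_ACQ_WITH_B0 = AcquisitionSpec((0.0, 100.0, 500.0, 900.0), (1, 1, 6, 23))


@dataclass(frozen=True)
class TissueSpec:
    """Ground-truth tissue parameters for one organ class.

    ``adc_true`` (μm²/s) and ``s0`` parameterize monoexponential decay;
    ``perfusion_fraction``/``pseudo_diffusion`` add an IVIM-like fast
    compartment that only matters near b = 0; ``heterogeneity_sigma`` is
    the fractional voxel-to-voxel spread of the true ADC (and T2w value)
    within the organ.
    """

    organ_class: str
    adc_true: float
    s0: float = 1000.0
    t2w_mean: float = 500.0
    perfusion_fraction: float = 0.0
    pseudo_diffusion: float = 0.0
    heterogeneity_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.adc_true <= 0:
            raise ValueError("adc_true must be positive")
        if not 0 <= self.perfusion_fraction < 1:
            raise ValueError("perfusion_fraction must lie in [0, 1)")
        if self.perfusion_fraction > 0 and self.pseudo_diffusion <= self.adc_true:
            raise ValueError("pseudo_diffusion must exceed adc_true when f > 0")
        if self.heterogeneity_sigma < 0:
            raise ValueError("heterogeneity_sigma must be non-negative")


@dataclass
class TissueMap:
    """Voxelized ground truth: an organ label volume plus per-voxel fields.

    ``labels`` uses 0 for signal-free background. The per-voxel ``adc``,
    ``s0``, ``f``, ``d_star`` and ``t2w`` arrays are materialized from the
    per-label :class:`TissueSpec` (with seeded heterogeneity) so that
    test/retest acquisitions of the same subject share identical tissue.
    """

    labels: np.ndarray
    tissues: Mapping[int, TissueSpec]
    spacing: tuple[float, float, float]
    adc: np.ndarray = field(repr=False, default=None)
    s0: np.ndarray = field(repr=False, default=None)
    f: np.ndarray = field(repr=False, default=None)
    d_star: np.ndarray = field(repr=False, default=None)
    t2w: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_labels(
        cls,
        labels: np.ndarray,
        tissues: Mapping[int, TissueSpec],
        spacing: Sequence[float],
        seed: int | None = None,
    ) -> "TissueMap":
        rng = np.random.default_rng(seed)
        shape = labels.shape
        adc = np.zeros(shape)
        s0 = np.zeros(shape)
        f = np.zeros(shape)
        d_star = np.zeros(shape)
        t2w = np.zeros(shape)
        for lab in sorted(int(v) for v in np.unique(labels) if v != 0):
            spec = tissues[lab]
            sel = labels == lab
            n = int(sel.sum())
            h = spec.heterogeneity_sigma
            adc_mult = 1.0 + h * rng.standard_normal(n) if h > 0 else np.ones(n)
            t2w_mult = 1.0 + h * rng.standard_normal(n) if h > 0 else np.ones(n)
            adc[sel] = spec.adc_true * np.clip(adc_mult, 0.05, None)
            t2w[sel] = spec.t2w_mean * np.clip(t2w_mult, 0.0, None)
            s0[sel] = spec.s0
            f[sel] = spec.perfusion_fraction
            d_star[sel] = spec.pseudo_diffusion
        return cls(labels=labels, tissues=dict(tissues), spacing=tuple(spacing),
                   adc=adc, s0=s0, f=f, d_star=d_star, t2w=t2w)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def affine(self) -> np.ndarray:
        return spacing_affine(self.spacing)

    def content_hash(self) -> str:
        """Hash of the voxelized ground truth (site-independent)."""
        import hashlib

        h = hashlib.sha256()
        for arr in (self.labels, self.adc, self.s0, self.f, self.d_star, self.t2w):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


@dataclass
class DWISeries:
    """One 3D magnitude volume per b-value, on a common grid."""

    volumes: list[np.ndarray]
    spacing: tuple[float, float, float]
    acquisition: AcquisitionSpec
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.acquisition.b_values):
            raise ShapeError("one volume per b-value required")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) != 1:
            raise ShapeError("all volumes must share one shape")
        if any(float(np.min(v)) < 0 for v in self.volumes):
            raise ValueError("magnitude intensities must be non-negative")
        if self.affine is None:
            self.affine = spacing_affine(self.spacing)

    @property
    def b_values(self) -> tuple[float, ...]:
        return self.acquisition.b_values

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes[0].shape

    def volume_for(self, b: float) -> np.ndarray:
        try:
            return self.volumes[self.b_values.index(b)]
        except ValueError:
            raise KeyError(f"no volume for b={b}") from None


@dataclass
class ROISet:
    """Integer label volume for the 11 anatomical ROI positions.

    Labels 1..11 map via ``organ_of_label`` onto the 5 organ classes.
    Each ROI is a 2D circle of nominally 250 mm² rasterized in one slice.
    """

    masks: np.ndarray
    label_names: dict[int, str]
    organ_of_label: dict[int, str]
    spacing: tuple[float, float, float]
    nominal_area_mm2: float = ROI_AREA_MM2

    def __post_init__(self) -> None:
        present = {int(v) for v in np.unique(self.masks) if v != 0}
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        for lab in self.label_names:
            if lab not in self.organ_of_label:
                raise ValueError(f"label {lab} has no organ class")

    @property
    def labels(self) -> list[int]:
        return sorted(self.label_names)

    def mask_for(self, label: int) -> np.ndarray:
        return self.masks == label

    def area_mm2(self, label: int) -> float:
        return float(self.mask_for(label).sum()) * self.spacing[0] * self.spacing[1]


@dataclass
class ADCMap:
    """Fitted apparent-diffusion-coefficient map in μm²/s."""

    values: np.ndarray
    valid_mask: np.ndarray
    b_used: tuple[float, ...]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.valid_mask.shape:
            raise ShapeError("values and valid_mask must share shape")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("ADC values must be finite on valid_mask")
        if self.affine is None:
            self.affine = spacing_affine(self.spacing)


@dataclass(frozen=True)
class CalibrationCurve:
    """Temperature dependence of phantom ADC, linear in T around 20 °C.

    ratio(T) = 1 + alpha * (T - reference_temp); dividing a measured ADC
    by ratio(T) maps it to the reference temperature. The default alpha
    of 0.024/°C is water-like; actual coefficients are phantom-specific
    configuration, not a constant of nature.
    """

    model: str = "linear_ratio"
    alpha: float = 0.024
    reference_temp: float = 20.0
    valid_range: tuple[float, float] = (15.0, 30.0)

    def __post_init__(self) -> None:
        if self.model != "linear_ratio":
            raise ValueError("only the linear_ratio model is implemented")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive (curve strictly increasing)")
        lo, hi = self.valid_range
        if 1 + self.alpha * (lo - self.reference_temp) <= 0:
            raise ValueError("ratio must stay positive over the validity range")

    def ratio(self, temp_c: float) -> float:
        lo, hi = self.valid_range
        if not lo <= temp_c <= hi:
            raise TemperatureRangeError(
                f"temperature {temp_c} °C outside validity range [{lo}, {hi}]"
            )
        return 1.0 + self.alpha * (temp_c - self.reference_temp)


def check_same_grid(a_shape: tuple[int, ...], b_shape: tuple[int, ...]) -> None:
    if a_shape != b_shape:
        raise ShapeError(f"grids differ: {a_shape} vs {b_shape}")


def require_spacing(spacing: Sequence[float] | None) -> tuple[float, float, float]:
    if spacing is None:
        raise MetadataError("voxel spacing metadata is required")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise MetadataError(f"invalid spacing {spacing}")
    return spacing
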