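"""Voxelwise shifted-ADC and virtual-stiffness map computation.

The shifted apparent diffusion coefficient (sADC) is the log-ratio
diffusivity between two non-zero b-values (defaults 200 and 1500 s/mm^2),
chosen so that perfusion effects are suppressed::

    sADC = ln(S_low / S_high) / (b_high - b_low)

Virtual MR elastography (VMRE) converts sADC into a surrogate stiffness via
a linear calibration against conventional MR elastography::

    VMRE [kPa] = alpha * sADC + beta

with sADC expressed in 1e-3 mm^2/s (the scale on which the published
calibration constants alpha = -12.740 and beta = 14.0 apply).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib

from .errors import CalibrationError, InputError, UnitError, ValidationError

#: unit tag for sADC maps, stored in 1e-3 mm^2/s
UNIT_SADC = "sadc_e3_mm2_per_s"
#: unit tag for virtual-stiffness maps
UNIT_KPA = "kPa"

DEFAULT_ALPHA = -12.740
DEFAULT_BETA = 14.0


@dataclass(frozen=True)
class CalibrationParams:
    """Linear sADC -> stiffness calibration. ``alpha`` is kPa per 1e-3 mm^2/s."""

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or not np.isfinite(self.beta):
            raise CalibrationError("calibration parameters must be finite")
        if self.alpha >= 0:
            raise CalibrationError(
                "alpha must be negative: stiffness decreases with diffusivity"
            )


@dataclass
class DWISeries:
    """Paired b-value magnitude volumes with shared geometry."""

    signal_low_b: np.ndarray
    signal_high_b: np.ndarray
    b_low: float = 200.0
    b_high: float = 1500.0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.signal_low_b = np.asarray(self.signal_low_b, dtype=float)
        self.signal_high_b = np.asarray(self.signal_high_b, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal_low_b.shape != self.signal_high_b.shape:
            raise InputError("b-value volumes must share one shape")
        if self.signal_low_b.ndim != 3:
            raise InputError("volumes must be 3-D")
        if self.affine.shape != (4, 4):
            raise InputError("affine must be 4x4")
        if not (self.b_high > self.b_low > 0):
            raise InputError("require b_high > b_low > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal_low_b.shape

    @classmethod
    def from_nifti(
        cls, path_low: str | Path, path_high: str | Path,
        b_low: float = 200.0, b_high: float = 1500.0,
    ) -> "DWISeries":
        img_lo = nib.load(str(path_low))
        img_hi = nib.load(str(path_high))
        if not np.allclose(img_lo.affine, img_hi.affine):
            raise InputError("b-value volumes have different affines")
        zooms = tuple(float(z) for z in img_lo.header.get_zooms()[:3])
        return cls(
            signal_low_b=np.asarray(img_lo.get_fdata()),
            signal_high_b=np.asarray(img_hi.get_fdata()),
            b_low=b_low, b_high=b_high,
            affine=img_lo.affine, voxel_size_mm=zooms,
        )

    def to_nifti(self, path_low: str | Path, path_high: str | Path) -> None:
        for vol, path in ((self.signal_low_b, path_low), (self.signal_high_b, path_high)):
            nib.save(nib.Nifti1Image(vol.astype(np.float64), self.affine), str(path))


@dataclass
class ParametricMap:
    """A voxelwise sADC or stiffness field with a validity mask.

    ``valid_mask`` marks voxels where the value is defined (positive input
    signals).  For sADC maps a secondary ``physical_mask`` additionally
    excludes noise-inverted (non-positive) diffusivities; those voxels keep
    their values so noisy-ROI statistics are not silently biased.
    """

    values: np.ndarray
    unit: str
    valid_mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    physical_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise InputError("values and valid_mask must share one shape")
        if self.unit not in (UNIT_SADC, UNIT_KPA):
            raise UnitError(f"unknown unit tag {self.unit!r}")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise InputError("values must be finite wherever valid_mask is true")

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.float64), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, unit: str) -> "ParametricMap":
        img = nib.load(str(path))
        values = np.asarray(img.get_fdata())
        return cls(values=values, unit=unit, valid_mask=np.isfinite(values),
                   affine=img.affine)


def compute_sadc_map(dwi: DWISeries) -> ParametricMap:
    """Shifted-ADC map in 1e-3 mm^2/s from a paired b-value series.

    Voxels with a non-positive signal in either channel are masked invalid
    (masking rather than clamping avoids fabricating extreme diffusivities).
    Negative sADC values produced by noise-inverted decay are retained but
    excluded from the ``physical_mask``.
    """
    s_lo, s_hi = dwi.signal_low_b, dwi.signal_high_b
    valid = (s_lo > 0) & (s_hi > 0)
    values = np.full(dwi.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[valid] = (
            np.log(s_lo[valid] / s_hi[valid]) / (dwi.b_high - dwi.b_low) * 1e3
        )
    physical = valid & (values > 0)
    return ParametricMap(values=values, unit=UNIT_SADC, valid_mask=valid,
                         affine=dwi.affine, physical_mask=physical)


def sadc_to_vmre(
    pmap: ParametricMap, calib: CalibrationParams = CalibrationParams()
) -> ParametricMap:
    """Virtual stiffness map: VMRE = alpha * sADC + beta (kPa)."""
    if pmap.unit != UNIT_SADC:
        raise UnitError(f"expected unit {UNIT_SADC!r}, got {pmap.unit!r}")
    values = calib.alpha * pmap.values + calib.beta
    return ParametricMap(values=values, unit=UNIT_KPA,
                         valid_mask=pmap.valid_mask.copy(), affine=pmap.affine,
                         physical_mask=None if pmap.physical_mask is None
                         else pmap.physical_mask.copy())


def vmre_to_sadc(
    pmap: ParametricMap, calib: CalibrationParams = CalibrationParams()
) -> ParametricMap:
    """Exact inverse of :func:`sadc_to_vmre`: sADC = (VMRE - beta) / alpha."""
    if pmap.unit != UNIT_KPA:
        raise UnitError(f"expected unit {UNIT_KPA!r}, got {pmap.unit!r}")
    if calib.alpha == 0:
        raise CalibrationError("alpha must be non-zero")
    values = (pmap.values - calib.beta) / calib.alpha
    return ParametricMap(values=values, unit=UNIT_SADC,
                         valid_mask=pmap.valid_mask.copy(), affine=pmap.affine)


def export_color_map(
    pmap: ParametricMap,
    range_kpa: tuple[float, float],
    palette: str = "turbo",
    out: str | Path = "vmre_map.png",
    slice_index: int | None = None,
    background: tuple[int, int, int] = (0, 0, 0),
) -> list[Path]:
    """Render map slices as raster images with a fixed color window.

    Values are clamped to ``range_kpa``; invalid voxels take the background
    color.  With ``slice_index=None`` every axial slice is written as
    ``<out stem>_z###.png``; otherwise a single file at ``out``.
    """
    import matplotlib

    lo, hi = range_kpa
    if not lo < hi:
        raise ValidationError("color range must satisfy lo < hi")
    if not pmap.valid_mask.any():
        warnings.warn("empty valid mask: exporting background-only image",
                      stacklevel=2)
    cmap = matplotlib.colormaps[palette]
    out = Path(out)
    if slice_index is None:
        indices = range(pmap.values.shape[2])
        paths = [out.with_name(f"{out.stem}_z{k:03d}.png") for k in indices]
    else:
        indices, paths = [slice_index], [out]

    from PIL import Image

    written: list[Path] = []
    for k, path in zip(indices, paths):
        sl = pmap.values[:, :, k]
        msk = pmap.valid_mask[:, :, k]
        frac = np.zeros_like(sl)
        frac[msk] = np.clip((sl[msk] - lo) / (hi - lo), 0.0, 1.0)
        rgb = (cmap(frac)[:, :, :3] * 255).astype(np.uint8)
        rgb[~msk] = background
        Image.fromarray(rgb).save(path)
        written.append(path)
    return written
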