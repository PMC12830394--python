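"""ROI construction, per-patient aggregation and measurement QC.

Virtual-elastography ROIs must span at least three consecutive axial slices
of the organ; ultrasound ROIs are 10 mm circles, two per acquisition, with
the elastography quality rule IQR/median <= 30% applied to repeated values.
"""
from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import MeasurementError, QCError, ValidationError
from .maps import ParametricMap

USE_DEFAULT_DIAMETER_MM = 10.0


@dataclass(frozen=True)
class CircleROI:
    """In-plane circular ROI: center in world mm, diameter mm, axial slice."""

    slice_index: int
    cx_mm: float
    cy_mm: float
    diameter_mm: float = USE_DEFAULT_DIAMETER_MM


@dataclass
class ROISet:
    """A collection of mask or circle ROIs for one modality.

    ``rois`` entries are either ``(slice_index, 2-D boolean mask)`` pairs or
    :class:`CircleROI` specs.  Virtual-elastography sets must cover at least
    three consecutive slices.
    """

    rois: list
    modality: str = "VMRE"

    def __post_init__(self) -> None:
        if self.modality not in ("VMRE", "USE"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        if not self.rois:
            raise ValidationError("ROI set is empty")
        for roi in self.rois:
            if isinstance(roi, CircleROI):
                if roi.diameter_mm <= 0:
                    raise ValidationError("circle diameter must be positive")
            else:
                k, mask = roi
                if not np.asarray(mask).any():
                    raise ValidationError("mask ROIs must be non-empty")
        if self.modality == "VMRE":
            self._check_consecutive_slices()

    def slice_indices(self) -> list[int]:
        out = []
        for roi in self.rois:
            out.append(roi.slice_index if isinstance(roi, CircleROI)
                       else int(roi[0]))
        return out

    def _check_consecutive_slices(self) -> None:
        slices = sorted(set(self.slice_indices()))
        run = best = 1
        for a, b in zip(slices, slices[1:]):
            run = run + 1 if b == a + 1 else 1
            best = max(best, run)
        if best < 3:
            raise ValidationError(
                "VMRE ROI sets must span >= 3 consecutive slices")

    @classmethod
    def from_label_volume(cls, labels: np.ndarray, modality: str = "VMRE",
                          label: int = 1) -> "ROISet":
        """One mask ROI per axial slice where ``labels == label``."""
        labels = np.asarray(labels)
        rois = []
        for k in range(labels.shape[2]):
            mask = labels[:, :, k] == label
            if mask.any():
                rois.append((k, mask))
        return cls(rois=rois, modality=modality)

    @classmethod
    def from_circle_csv(cls, path: str | Path, modality: str = "USE") -> "ROISet":
        rois = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                rois.append(CircleROI(
                    slice_index=int(row["slice"]),
                    cx_mm=float(row["cx_mm"]), cy_mm=float(row["cy_mm"]),
                    diameter_mm=float(row["diameter_mm"])))
        return cls(rois=rois, modality=modality)


def _rasterize_circle(circle: CircleROI, pmap: ParametricMap) -> np.ndarray:
    """Voxel membership: voxel center inside the circle, boundary included."""
    nx, ny = pmap.values.shape[:2]
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    k = circle.slice_index
    coords = pmap.affine @ np.stack(
        [ii.ravel(), jj.ravel(), np.full(ii.size, k), np.ones(ii.size)])
    x, y = coords[0].reshape(nx, ny), coords[1].reshape(nx, ny)
    r = circle.diameter_mm / 2.0
    return (x - circle.cx_mm) ** 2 + (y - circle.cy_mm) ** 2 <= r ** 2


@dataclass
class MeasurementSet:
    """Per-patient summary of map values over an ROI set."""

    patient_id: str
    modality: str
    per_roi_values: list[float]
    summary: float
    qc_pass: bool | None = None
    qc_ratio: float | None = None


def summarize_map_over_rois(
    pmap: ParametricMap, rois: ROISet, stat: str = "mean",
    patient_id: str = "", use_physical_mask: bool = False,
) -> MeasurementSet:
    """Per-ROI statistic over valid voxels, then the same statistic across ROIs.

    ROIs containing no valid voxel are dropped with a warning; an all-empty
    set raises.  The default per-patient summary is the mean of per-ROI
    means; ``stat="median"`` switches both levels to medians.
    """
    if stat not in ("mean", "median"):
        raise ValidationError(f"unknown statistic {stat!r}")
    reducer = np.mean if stat == "mean" else np.median
    mask_total = pmap.valid_mask
    if use_physical_mask and pmap.physical_mask is not None:
        mask_total = mask_total & pmap.physical_mask

    per_roi: list[float] = []
    for roi in rois.rois:
        if isinstance(roi, CircleROI):
            k = roi.slice_index
            if not 0 <= k < pmap.values.shape[2]:
                raise ValidationError(f"slice {k} outside volume")
            sel = _rasterize_circle(roi, pmap) & mask_total[:, :, k]
            vals = pmap.values[:, :, k][sel]
        else:
            k, mask2d = roi
            if not 0 <= int(k) < pmap.values.shape[2]:
                raise ValidationError(f"slice {k} outside volume")
            mask2d = np.asarray(mask2d, dtype=bool)
            if mask2d.shape != pmap.values.shape[:2]:
                raise ValidationError("mask ROI shape does not match volume")
            sel = mask2d & mask_total[:, :, int(k)]
            vals = pmap.values[:, :, int(k)][sel]
        if vals.size == 0:
            warnings.warn(f"ROI on slice {k} has no valid voxels; dropped",
                          stacklevel=2)
            continue
        per_roi.append(float(reducer(vals)))

    if not per_roi:
        raise MeasurementError("no ROI contained valid voxels")
    summary = float(reducer(per_roi))
    qc_pass = qc_ratio = None
    if rois.modality == "USE" and len(per_roi) >= 2:
        qc_ratio, qc_pass = qc_iqr_median(per_roi)
    return MeasurementSet(patient_id=patient_id, modality=rois.modality,
                          per_roi_values=per_roi, summary=summary,
                          qc_pass=qc_pass, qc_ratio=qc_ratio)


def combine_readers(r1_kpa: float, r2_kpa: float) -> float:
    """Per-patient virtual stiffness: arithmetic mean of the two readers."""
    if not (r1_kpa > 0 and r2_kpa > 0):
        raise ValidationError("reader values must be positive")
    return (r1_kpa + r2_kpa) / 2.0


def combine_use_acquisitions(
    acq1: tuple[float, float], acq2: tuple[float, float]
) -> float:
    """Ultrasound protocol: mean of the two ROIs per acquisition, then the
    mean of the two acquisition means."""
    for acq in (acq1, acq2):
        if acq is None or len(acq) != 2:
            raise ValidationError("each acquisition needs two ROI values")
        if not all(v > 0 for v in acq):
            raise ValidationError("stiffness values must be positive")
    return (float(np.mean(acq1)) + float(np.mean(acq2))) / 2.0


def qc_iqr_median(values: Sequence[float]) -> tuple[float, bool]:
    """Elastography quality rule: IQR/median ratio, pass iff <= 0.30.

    Quartiles use linear interpolation (numpy default, type 7); the boundary
    ratio 0.30 passes (rule is inclusive).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise QCError("QC needs at least two values")
    med = float(np.median(values))
    if med <= 0:
        raise QCError("QC undefined for non-positive median")
    q1, q3 = np.percentile(values, [25, 75])
    ratio = float((q3 - q1) / med)
    return ratio, ratio <= 0.30
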