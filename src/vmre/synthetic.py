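"""Synthetic DWI phantoms and patient cohorts.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage of the pipeline is testable without clinical data:

* stage-labeled stiffness fields drawn from published per-stage MR
  elastography means/SDs, converted to shifted-ADC through the inverse of
  the VMRE calibration line and to DWI magnitude signals through the
  mono-exponential decay between the two b-values;
* Rician magnitude noise parameterized by SNR at the low b-value (the
  standard MR magnitude noise model);
* a 49-patient cohort with the study's METAVIR stage mix (8/16/6/12/7),
  ~67% HBV etiology, two virtual-elastography readers with small
  independent Gaussian reading noise, and two shear-wave ultrasound
  acquisitions per patient drawn from per-stage normal distributions.

A single global seed fans out to keyed substreams (one per component and
stage) so adding a stage or component does not shift the other streams.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .maps import (CalibrationParams, DWISeries, ParametricMap, UNIT_KPA)
from .staging import DEFAULT_STAGE_STIFFNESS, Stage

#: per-stage 2D shear-wave ultrasound stiffness (mean kPa, SD kPa),
#: all-etiology defaults
DEFAULT_USE_PARAMS: dict[Stage, tuple[float, float]] = {
    Stage.F0: (6.00, 4.11),
    Stage.F1: (8.74, 4.18),
    Stage.F2: (10.74, 3.57),
    Stage.F3: (13.68, 4.18),
    Stage.F4: (18.05, 4.84),
}

#: METAVIR stage histogram of the emulated 49-patient cohort
DEFAULT_STAGE_COUNTS: dict[Stage, int] = {
    Stage.F0: 8, Stage.F1: 16, Stage.F2: 6, Stage.F3: 12, Stage.F4: 7,
}

STIFFNESS_FLOOR_KPA = 0.1

ETIOLOGIES = ("HBV", "MASLD", "other")


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Independent, stable random stream keyed by component/stage."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    ``snr`` is the ratio of the baseline b=200 signal to the Rician sigma;
    ``numpy.inf`` disables noise.  ``reader_sd_kpa`` is the SD of each
    reader's independent measurement noise (default 0.21 kPa, the value a
    variance-components calibration places in the ICC ~0.97 regime and the
    per-reader sigma implied by an inter-reader difference SD of ~0.3 kPa).
    """

    seed: int = 0
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 6.0)
    s0: float = 1000.0
    snr: float = 30.0
    stage_counts: dict[Stage, int] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_COUNTS))
    hbv_fraction: float = 0.67
    reader_sd_kpa: float = 0.21
    use_params: dict[Stage, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_USE_PARAMS))
    stage_stiffness: dict[Stage, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_STIFFNESS))

    def __post_init__(self) -> None:
        self.stage_counts = {Stage.parse(k): int(v)
                             for k, v in self.stage_counts.items()}
        self.use_params = {Stage.parse(k): (float(m), float(s))
                           for k, (m, s) in self.use_params.items()}
        self.stage_stiffness = {Stage.parse(k): (float(m), float(s))
                                for k, (m, s) in self.stage_stiffness.items()}
        if not self.s0 > 0:
            raise ConfigurationError("s0 must be positive")
        if not self.snr > 0:
            raise ConfigurationError("snr must be positive")
        if self.reader_sd_kpa < 0:
            raise ConfigurationError("reader_sd_kpa must be >= 0")
        if not 0.0 <= self.hbv_fraction <= 1.0:
            raise ConfigurationError("hbv_fraction must be in [0, 1]")
        if any(n < 0 for n in self.stage_counts.values()):
            raise ConfigurationError("stage counts must be non-negative")
        if sum(self.stage_counts.values()) == 0:
            raise ConfigurationError("stage counts sum to zero")
        for table in (self.use_params, self.stage_stiffness):
            if any(sd < 0 for _, sd in table.values()):
                raise ConfigurationError("SDs must be non-negative")
        if any(len(x) != 3 for x in (self.grid_shape, self.voxel_size_mm)):
            raise ConfigurationError("grid_shape and voxel_size_mm are 3-vectors")

    @property
    def n_patients(self) -> int:
        return sum(self.stage_counts.values())

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([*self.voxel_size_mm, 1.0])
        return aff

    # -- config file round-trip ------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("grid_shape", "voxel_size_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "snr" in raw and raw["snr"] in ("inf", ".inf", None):
            raw["snr"] = np.inf
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["grid_shape"] = list(self.grid_shape)
        raw["voxel_size_mm"] = list(self.voxel_size_mm)
        raw["snr"] = "inf" if np.isinf(self.snr) else float(self.snr)
        for key in ("stage_counts", "use_params", "stage_stiffness"):
            raw[key] = {Stage.parse(k).name: (list(v) if isinstance(v, tuple)
                                              else v)
                        for k, v in raw[key].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class PatientRecord:
    """One simulated (or imported) patient."""

    id: str
    metavir_stage: Stage
    etiology: str
    vmre_reader1_kpa: float
    vmre_reader2_kpa: float
    use_acq1_kpa: float
    use_acq2_kpa: float
    true_stiffness_kpa: float | None = None

    def __post_init__(self) -> None:
        self.metavir_stage = Stage.parse(self.metavir_stage)
        if self.etiology not in ETIOLOGIES:
            raise ConfigurationError(f"unknown etiology {self.etiology!r}")
        for v in (self.vmre_reader1_kpa, self.vmre_reader2_kpa,
                  self.use_acq1_kpa, self.use_acq2_kpa):
            if not v > 0:
                raise ConfigurationError("stiffness values must be positive")


@dataclass
class Cohort:
    """Ordered patient collection with provenance tag."""

    records: list[PatientRecord]
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        if not self.records:
            raise ConfigurationError("cohort must be non-empty")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("patient ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": [r.id for r in self.records],
            "stage": [r.metavir_stage.name for r in self.records],
            "etiology": [r.etiology for r in self.records],
            "vmre_r1": [r.vmre_reader1_kpa for r in self.records],
            "vmre_r2": [r.vmre_reader2_kpa for r in self.records],
            "use_a1": [r.use_acq1_kpa for r in self.records],
            "use_a2": [r.use_acq2_kpa for r in self.records],
            "truth": [r.true_stiffness_kpa for r in self.records],
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.8g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "imported") -> "Cohort":
        records = [
            PatientRecord(
                id=str(row.id), metavir_stage=Stage.parse(row.stage),
                etiology=str(row.etiology),
                vmre_reader1_kpa=float(row.vmre_r1),
                vmre_reader2_kpa=float(row.vmre_r2),
                use_acq1_kpa=float(row.use_a1), use_acq2_kpa=float(row.use_a2),
                true_stiffness_kpa=(None if pd.isna(row.truth)
                                    else float(row.truth)),
            )
            for row in df.itertuples()
        ]
        return cls(records=records, provenance=provenance)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "imported") -> "Cohort":
        return cls.from_frame(pd.read_csv(path), provenance=provenance)

    def stage_histogram(self) -> dict[Stage, int]:
        hist = {s: 0 for s in Stage}
        for r in self.records:
            hist[r.metavir_stage] += 1
        return hist


def _rician(noiseless: np.ndarray, sigma: float,
            rng: np.random.Generator) -> np.ndarray:
    """Magnitude of a complex signal with i.i.d. Gaussian channel noise."""
    if sigma == 0:
        return noiseless.copy()
    n1 = rng.normal(0.0, sigma, noiseless.shape)
    n2 = rng.normal(0.0, sigma, noiseless.shape)
    return np.sqrt((noiseless + n1) ** 2 + n2 ** 2)


def generate_phantom(
    config: SimulationConfig, stage: Stage | int | str,
    calib: CalibrationParams = CalibrationParams(),
) -> tuple[DWISeries, np.ndarray, np.ndarray]:
    """Single-organ block phantom for one fibrosis stage.

    Returns the paired-b-value series, a label volume (1 = organ voxel with
    a physically representable stiffness, 0 = excluded) and the generating
    stiffness field.  Stiffness is drawn from the stage's (mean, SD),
    floored at 0.1 kPa; voxels whose stiffness would map to a non-positive
    sADC (possible at the high end of the calibration line) are excluded
    from the label volume.
    """
    stage = Stage.parse(stage)
    rng = _substream(config.seed, 0, int(stage))
    mean, sd = config.stage_stiffness[stage]
    shape = tuple(config.grid_shape)

    stiffness = np.maximum(rng.normal(mean, sd, shape), STIFFNESS_FLOOR_KPA)
    sadc = (calib.beta - stiffness) / (-calib.alpha)  # 1e-3 mm^2/s
    labels = (sadc > 0).astype(np.int16)

    s200 = np.full(shape, config.s0)
    decay = np.exp(-(1500.0 - 200.0) * np.where(labels > 0, sadc, 0.0) * 1e-3)
    s1500 = config.s0 * decay

    sigma = 0.0 if np.isinf(config.snr) else config.s0 / config.snr
    dwi = DWISeries(
        signal_low_b=_rician(s200, sigma, rng),
        signal_high_b=_rician(s1500, sigma, rng),
        b_low=200.0, b_high=1500.0,
        affine=config.affine, voxel_size_mm=tuple(config.voxel_size_mm),
    )
    return dwi, labels, stiffness


def write_phantom(dwi: DWISeries, labels: np.ndarray, stiffness: np.ndarray,
                  outdir: str | Path, prefix: str) -> dict[str, Path]:
    """Write a phantom as NIfTI volumes sharing one affine."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "b200": outdir / f"{prefix}_b200.nii",
        "b1500": outdir / f"{prefix}_b1500.nii",
        "labels": outdir / f"{prefix}_labels.nii",
        "stiffness": outdir / f"{prefix}_stiffness.nii",
    }
    dwi.to_nifti(paths["b200"], paths["b1500"])
    nib.save(nib.Nifti1Image(labels.astype(np.int16), dwi.affine),
             str(paths["labels"]))
    nib.save(nib.Nifti1Image(stiffness.astype(np.float64), dwi.affine),
             str(paths["stiffness"]))
    return paths


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, floor: float = STIFFNESS_FLOOR_KPA) -> np.ndarray:
    return np.maximum(rng.normal(mean, sd, size), floor)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate the patient cohort.

    Per stage: true virtual stiffness from the stage's reference (mean, SD);
    two reader values = truth + independent N(0, reader_sd^2), floored
    positive; two ultrasound acquisition means drawn from the stage's
    ultrasound (mean, SD), truncated positive.  Etiology is HBV for a fixed
    round(hbv_fraction * n) patients chosen by a seeded permutation, the
    remainder alternating MASLD/other.
    """
    records: list[PatientRecord] = []
    pid = 0
    for stage in Stage:
        n_s = config.stage_counts.get(stage, 0)
        if n_s == 0:
            continue
        rng_truth = _substream(config.seed, 1, int(stage))
        rng_read = _substream(config.seed, 2, int(stage))
        rng_use = _substream(config.seed, 3, int(stage))
        mean, sd = config.stage_stiffness[stage]
        truth = _truncated_normal(rng_truth, mean, sd, n_s)
        r1 = np.maximum(truth + rng_read.normal(0, config.reader_sd_kpa, n_s),
                        STIFFNESS_FLOOR_KPA)
        r2 = np.maximum(truth + rng_read.normal(0, config.reader_sd_kpa, n_s),
                        STIFFNESS_FLOOR_KPA)
        um, us = config.use_params[stage]
        a1 = _truncated_normal(rng_use, um, us, n_s)
        a2 = _truncated_normal(rng_use, um, us, n_s)
        for i in range(n_s):
            pid += 1
            records.append(PatientRecord(
                id=f"P{pid:03d}", metavir_stage=stage, etiology="HBV",
                vmre_reader1_kpa=float(r1[i]), vmre_reader2_kpa=float(r2[i]),
                use_acq1_kpa=float(a1[i]), use_acq2_kpa=float(a2[i]),
                true_stiffness_kpa=float(truth[i]),
            ))

    n = len(records)
    n_hbv = int(np.floor(config.hbv_fraction * n + 0.5))
    rng_etio = _substream(config.seed, 4)
    order = rng_etio.permutation(n)
    non_hbv = order[n_hbv:]
    for j, idx in enumerate(sorted(non_hbv)):
        records[idx].etiology = "MASLD" if j % 2 == 0 else "other"
    return Cohort(records=records, provenance="simulated")
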