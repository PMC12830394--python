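"""METAVIR staging of stiffness values against fixed MR-elastography thresholds.

A continuous stiffness (kPa) is assigned to one of the five METAVIR fibrosis
stages (F0 none ... F4 cirrhosis) using per-stage reference stiffness means.
The default boundary rule places cut points at the midpoints of consecutive
stage means, which partitions the real line completely and preserves order;
a nearest-mean rule is kept for sensitivity analysis.  Boundary ties go to
the lower (less severe) stage.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError, ValidationError


class Stage(IntEnum):
    """METAVIR fibrosis stage: F0 no fibrosis ... F4 cirrhosis."""

    F0 = 0
    F1 = 1
    F2 = 2
    F3 = 3
    F4 = 4

    @classmethod
    def parse(cls, value: "Stage | int | str") -> "Stage":
        if isinstance(value, Stage):
            return value
        if isinstance(value, str):
            return cls[value.upper()]
        return cls(int(value))


# Published per-stage liver-stiffness reference values (kPa) from conventional
# MR elastography, used to categorize virtual-stiffness measurements.
DEFAULT_STAGE_STIFFNESS: dict[Stage, tuple[float, float]] = {
    Stage.F0: (2.13, 0.27),
    Stage.F1: (2.49, 0.28),
    Stage.F2: (2.83, 0.32),
    Stage.F3: (3.60, 0.81),
    Stage.F4: (5.20, 1.02),
}

BINARY_SCHEMES = ("F01_vs_F24", "F02_vs_F34")


@dataclass(frozen=True)
class StageThresholdTable:
    """Per-stage (mean, SD) stiffness references and a boundary rule."""

    stage_params: dict[Stage, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_STIFFNESS))
    boundary_rule: str = "midpoint"

    def __post_init__(self) -> None:
        if set(self.stage_params) != set(Stage):
            raise InputError("table must cover stages F0..F4")
        means = self.means
        if not np.all(np.diff(means) > 0):
            raise InputError("stage means must be strictly increasing F0->F4")
        if any(sd < 0 for _, sd in self.stage_params.values()):
            raise InputError("SDs must be non-negative")
        if self.boundary_rule not in ("midpoint", "nearest_mean"):
            raise InputError(f"unknown boundary rule {self.boundary_rule!r}")

    @property
    def means(self) -> np.ndarray:
        return np.array([self.stage_params[s][0] for s in Stage])

    @property
    def midpoint_boundaries(self) -> np.ndarray:
        """Cut points between consecutive stage means (4 values for 5 stages)."""
        m = self.means
        return (m[:-1] + m[1:]) / 2.0

    @classmethod
    def from_csv(cls, path: str | Path, boundary_rule: str = "midpoint"
                 ) -> "StageThresholdTable":
        params: dict[Stage, tuple[float, float]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                params[Stage.parse(row["stage"])] = (
                    float(row["mean_kpa"]), float(row["sd_kpa"]))
        return cls(stage_params=params, boundary_rule=boundary_rule)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["stage", "mean_kpa", "sd_kpa"])
            for s in Stage:
                mean, sd = self.stage_params[s]
                w.writerow([s.name, f"{mean:.6g}", f"{sd:.6g}"])


def classify_stage(value_kpa: float,
                   table: StageThresholdTable = StageThresholdTable()) -> Stage:
    """Assign a stiffness value to a METAVIR stage.

    Midpoint rule: stage boundaries halfway between consecutive stage means;
    a value exactly on a boundary takes the lower stage.  Nearest-mean rule:
    closest stage mean, ties to the lower stage.
    """
    if not value_kpa > 0:
        raise ValidationError("stiffness must be positive")
    if table.boundary_rule == "midpoint":
        return Stage(int(np.sum(value_kpa > table.midpoint_boundaries)))
    dist = np.abs(table.means - value_kpa)
    return Stage(int(np.argmin(dist)))  # argmin takes the first (lower) tie


def binarize_stage(stage: Stage | int | str, scheme: str) -> bool:
    """Binary fibrosis grouping; True marks the positive (more fibrotic) class.

    ``F01_vs_F24``: significant fibrosis (>= F2 positive).
    ``F02_vs_F34``: advanced fibrosis (>= F3 positive).
    """
    stage = Stage.parse(stage)
    if scheme == "F01_vs_F24":
        return stage >= Stage.F2
    if scheme == "F02_vs_F34":
        return stage >= Stage.F3
    raise InputError(f"unknown binarization scheme {scheme!r}")


def _pct(count: int, n: int) -> int:
    """Integer percentage, half away from zero (report convention)."""
    return int(np.floor(100.0 * count / n + 0.5))


@dataclass
class StagingResult:
    """Concordance of predicted vs reference stages."""

    n: int
    predicted: list[Stage]
    reference: list[Stage]
    exact_count: int
    within_one_count: int
    binary_concordance: dict[str, int]

    @property
    def exact_pct(self) -> int:
        return _pct(self.exact_count, self.n)

    @property
    def within_one_pct(self) -> int:
        return _pct(self.within_one_count, self.n)

    def binary_pct(self, scheme: str) -> int:
        return _pct(self.binary_concordance[scheme], self.n)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "exact": {"count": self.exact_count, "pct": self.exact_pct},
            "within_one": {"count": self.within_one_count,
                           "pct": self.within_one_pct},
            "binary": {
                scheme: {"count": cnt, "pct": self.binary_pct(scheme)}
                for scheme, cnt in self.binary_concordance.items()
            },
        }


def concordance_summary(predicted: Sequence[Stage | int | str],
                        reference: Sequence[Stage | int | str]) -> StagingResult:
    """Exact, within-one-stage and binary concordance counts."""
    if len(predicted) != len(reference):
        raise InputError("predicted and reference must have equal length")
    if len(predicted) == 0:
        raise InputError("empty staging comparison")
    pred = [Stage.parse(s) for s in predicted]
    ref = [Stage.parse(s) for s in reference]
    exact = sum(p == r for p, r in zip(pred, ref))
    within = sum(abs(int(p) - int(r)) <= 1 for p, r in zip(pred, ref))
    binary = {
        scheme: sum(binarize_stage(p, scheme) == binarize_stage(r, scheme)
                    for p, r in zip(pred, ref))
        for scheme in BINARY_SCHEMES
    }
    return StagingResult(n=len(pred), predicted=pred, reference=ref,
                         exact_count=exact, within_one_count=within,
                         binary_concordance=binary)
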