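"""End-to-end orchestration: simulate -> map -> ROI -> stage -> statistics.

Two data paths feed the statistics: the cohort generator draws per-patient
reader/acquisition values directly (fast, used for the full cohort), and
the imaging path exercises phantom -> NIfTI -> sADC/VMRE maps -> ROI
aggregation on one phantom per stage to validate the voxel pipeline.
All randomness derives from one seed; rerunning with the same config and
seed reproduces byte-identical CSV/JSON payloads.
"""
from __future__ import annotations

import json
import logging
import sys
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .diagnostics import (AgreementResult, bland_altman, descriptive_by_stage,
                          dunn_posthoc, icc, kruskal_wallis, ks_normality,
                          one_way_anova, roc_analysis)
from .errors import AnalysisError, VMREError
from .maps import compute_sadc_map, sadc_to_vmre
from .roi import ROISet, combine_readers, summarize_map_over_rois
from .staging import (Stage, StageThresholdTable, binarize_stage,
                      classify_stage, concordance_summary, BINARY_SCHEMES)
from .synthetic import (Cohort, SimulationConfig, generate_cohort,
                        generate_phantom, write_phantom)

REPORT_SCHEMA_VERSION = 1

log = logging.getLogger("vmre.pipeline")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[vmre:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _stagelog(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config: dict
    seed: int
    version: str
    files: dict[str, str] = field(default_factory=dict)
    wall_clock_s: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def subset_by_etiology(cohort: Cohort, etiology: str) -> Cohort | None:
    """Order-preserving etiology filter; empty result warns and returns None."""
    records = [r for r in cohort.records if r.etiology == etiology]
    if not records:
        warnings.warn(f"no patients with etiology {etiology!r}; subset skipped",
                      stacklevel=2)
        return None
    return Cohort(records=records, provenance=cohort.provenance)


def _roc_block(values: np.ndarray, stages: list[Stage], scheme: str,
               seed: int) -> dict:
    labels = np.array([int(binarize_stage(s, scheme)) for s in stages])
    try:
        res = roc_analysis(values, labels, seed=seed)
        return res.to_dict()
    except AnalysisError as exc:
        return {"error": f"roc_analysis: {exc}"}


def _cohort_stats(cohort: Cohort, seed: int) -> dict:
    """Descriptives, group comparisons, agreement and ROC for one cohort."""
    df = cohort.to_frame()
    stages = [r.metavir_stage for r in cohort.records]
    vmre = np.array([combine_readers(r.vmre_reader1_kpa, r.vmre_reader2_kpa)
                     for r in cohort.records])
    use = np.array([(r.use_acq1_kpa + r.use_acq2_kpa) / 2.0
                    for r in cohort.records])
    df["vmre"] = vmre
    df["use"] = use

    out: dict = {"n": len(cohort)}

    out["descriptives"] = {
        "vmre_kpa": descriptive_by_stage(df, "vmre").round(6).to_dict("index"),
        "use_kpa": descriptive_by_stage(df, "use").round(6).to_dict("index"),
    }

    present = [s for s in Stage if any(st == s for st in stages)]
    groups_v = [vmre[[st == s for st in stages]] for s in present]
    groups_u = [use[[st == s for st in stages]] for s in present]

    try:
        kw = kruskal_wallis(groups_v)
        out["kruskal_wallis_vmre"] = kw.to_dict()
        if kw.p_value < 0.05:
            pairwise = dunn_posthoc(groups_v)
            out["kruskal_wallis_vmre"]["pairwise"] = {
                f"{present[i].name}-{present[j].name}": round(p, 4)
                for (i, j), p in pairwise.items()}
    except AnalysisError as exc:
        out["kruskal_wallis_vmre"] = {"error": f"kruskal_wallis: {exc}"}
    try:
        out["anova_use"] = one_way_anova(groups_u).to_dict()
    except AnalysisError as exc:
        out["anova_use"] = {"error": f"one_way_anova: {exc}"}

    for name, vals in (("vmre", vmre), ("use", use)):
        try:
            out[f"ks_normality_{name}_p"] = round(
                ks_normality(vals, seed=seed + 17), 4)
        except AnalysisError as exc:
            out[f"ks_normality_{name}_p"] = f"error: {exc}"

    reader_mat = df[["vmre_r1", "vmre_r2"]].to_numpy()
    use_mat = df[["use_a1", "use_a2"]].to_numpy()
    agreement: dict = {}
    try:
        res = icc(reader_mat)
        ba = bland_altman(reader_mat)
        agreement["vmre_readers"] = {**res.to_dict(), **ba.to_dict()}
        res = icc(use_mat)
        ba = bland_altman(use_mat)
        agreement["use_acquisitions"] = {**res.to_dict(), **ba.to_dict()}
    except AnalysisError as exc:
        agreement["error"] = f"agreement: {exc}"
    out["agreement"] = agreement

    out["roc"] = {}
    for scheme in BINARY_SCHEMES:
        out["roc"][scheme] = {
            "vmre": _roc_block(vmre, stages, scheme, seed + 101),
            "use": _roc_block(use, stages, scheme, seed + 103),
        }

    table = StageThresholdTable()
    predicted = [classify_stage(v, table) for v in vmre]
    out["staging_vs_reference"] = concordance_summary(predicted, stages).to_dict()
    return out


def run_all(config: SimulationConfig, outdir: str | Path,
            seed: int | None = None, phantom_stages: int = 2) -> RunManifest:
    """Execute the full pipeline and write cohort CSV, report and manifest.

    ``phantom_stages`` caps how many per-stage phantoms run through the
    imaging path (NIfTI round-trip, map computation, ROI aggregation); the
    cohort statistics use the directly generated per-patient values.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})
    manifest = RunManifest(config=json.loads(json.dumps(
        config.__dict__, default=str)), seed=config.seed, version=__version__)

    t0 = time.perf_counter()
    _stagelog("simulate", f"generating cohort of {config.n_patients} patients")
    cohort = generate_cohort(config)
    cohort_csv = outdir / "cohort.csv"
    cohort.to_csv(cohort_csv)
    manifest.files["cohort_csv"] = str(cohort_csv)
    manifest.wall_clock_s["simulate"] = round(time.perf_counter() - t0, 3)

    # imaging path on a small number of per-stage phantoms
    t0 = time.perf_counter()
    imaging: dict = {}
    present = [s for s in Stage if config.stage_counts.get(s, 0) > 0]
    for stage in present[:phantom_stages]:
        _stagelog("map", f"phantom imaging path for stage {stage.name}")
        dwi, labels, stiffness = generate_phantom(config, stage)
        paths = write_phantom(dwi, labels, stiffness, outdir / "phantoms",
                              f"{stage.name}")
        sadc = compute_sadc_map(dwi)
        vmre_map = sadc_to_vmre(sadc)
        vmre_map.to_nifti(outdir / "phantoms" / f"{stage.name}_vmre.nii")
        rois = ROISet.from_label_volume(labels, modality="VMRE")
        meas = summarize_map_over_rois(vmre_map, rois, stat="median",
                                       patient_id=stage.name)
        imaging[stage.name] = {
            "true_mean_kpa": round(float(stiffness[labels > 0].mean()), 4),
            "measured_median_kpa": round(meas.summary, 4),
            "n_roi_slices": len(meas.per_roi_values),
        }
        manifest.files[f"phantom_{stage.name}_b200"] = str(paths["b200"])
        manifest.files[f"phantom_{stage.name}_b1500"] = str(paths["b1500"])
    manifest.wall_clock_s["map_roi"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    _stagelog("stats", "cohort statistics: all patients")
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "imaging_path": imaging,
        "all_patients": _cohort_stats(cohort, seed=config.seed),
    }
    hbv = subset_by_etiology(cohort, "HBV")
    if hbv is not None and len(hbv) >= 5:
        _stagelog("stats", f"cohort statistics: HBV subset (n={len(hbv)})")
        report["hbv_patients"] = _cohort_stats(hbv, seed=config.seed + 1)
    else:
        report["hbv_patients"] = {"skipped": "HBV subset absent or too small"}
    manifest.wall_clock_s["stats"] = round(time.perf_counter() - t0, 3)

    report_json = outdir / "report.json"
    with open(report_json, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    manifest.files["report_json"] = str(report_json)
    manifest_json = outdir / "manifest.json"
    manifest.to_json(manifest_json)
    for key, path in manifest.files.items():
        if not Path(path).exists():  # pragma: no cover - consistency guard
            raise VMREError(f"manifest lists missing output {key}: {path}")
    _stagelog("done", f"report at {report_json}")
    return manifest
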