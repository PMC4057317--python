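"""End-to-end study driver: simulate -> fit -> cluster -> classify -> evaluate.

`run_study` composes the whole analysis in memory and is what the tests and
the acceptance script call; the ``stage_*`` functions are the disk-backed
equivalents used by the CLI, reading and writing NIfTI volumes and CSV
tables under an output directory so each stage can be re-run independently.
Every stage logs its parameters, seeds and wall time; re-running with the
same configuration reproduces all outputs (bit-identically for integer
artifacts).
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as hio
from .evaluation import (EvaluationReport, FractionPair, evaluate_feature_vectors,
                         histology_volume_fraction, rim_misassignment_fraction)
from .isodata import (ISODATAParams, ClusterModel, assemble_feature_matrix,
                      isodata_cluster, labels_by_scan, labels_to_volume,
                      normalize_features, spec_key)
from .mapping import ParameterMapSet, fit_parameter_maps
from .synthetic import (AcquisitionProtocol, AnimalPlan, Cohort, CohortDesign,
                        LesionSettings, RawSeriesSet, TIMEPOINTS,
                        generate_cohort, simulate_cohort_histology,
                        LABEL_BACKGROUND)
from .viability import (ClusterClassMap, classify_clusters,
                        cluster_fraction_table, make_viability_map,
                        summarize_parameters)

__all__ = ["RunConfig", "SpecResult", "StudyResult", "run_study", "run_pipeline",
           "stage_simulate", "stage_fit", "stage_cluster", "stage_classify",
           "stage_evaluate"]

log = logging.getLogger("hifuseg")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _build(cls, data: dict | None, what: str):
    data = dict(data or {})
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {what} option(s): {sorted(unknown)}")
    for key, val in data.items():
        if isinstance(val, list):
            data[key] = tuple(tuple(v) if isinstance(v, list) else v for v in val)
    return cls(**data)


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``analysis/config_demo.yaml``)."""

    seed: int
    design: CohortDesign = field(default_factory=CohortDesign)
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    lesions: LesionSettings = field(default_factory=LesionSettings)
    isodata: ISODATAParams = field(default_factory=ISODATAParams)
    feature_vectors: tuple[tuple[str, ...], ...] = (("T1", "T2", "ADC"),)
    alpha: float = 0.05
    r2_threshold: float = 0.7
    rim_thickness: int = 3
    exclusion_k: float = 3.0
    histology_spacing_mm: float = 0.3
    histology_noise_cv: float = 0.05
    tissue_table: str = "default"    # "default" | "weak_mtr"

    def tissues(self):
        from .synthetic import default_tissue_params, weak_mtr_tissue_params
        if self.tissue_table == "default":
            return default_tissue_params()
        if self.tissue_table == "weak_mtr":
            return weak_mtr_tissue_params()
        raise ValueError(f"unknown tissue table {self.tissue_table!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if "seed" not in data or data["seed"] is None:
            raise ValueError("config must state an explicit seed")
        fv = data.get("feature_vectors") or [["T1", "T2", "ADC"]]
        return cls(
            seed=int(data["seed"]),
            design=_build(CohortDesign, data.get("design"), "design"),
            protocol=_build(AcquisitionProtocol, data.get("protocol"), "protocol"),
            lesions=_build(LesionSettings, data.get("lesions"), "lesions"),
            isodata=_build(ISODATAParams, data.get("isodata"), "isodata"),
            feature_vectors=tuple(tuple(v) for v in fv),
            alpha=float(data.get("alpha", 0.05)),
            r2_threshold=float(data.get("r2_threshold", 0.7)),
            rim_thickness=int(data.get("rim_thickness", 3)),
            exclusion_k=float(data.get("exclusion_k", 3.0)),
            histology_spacing_mm=float(data.get("histology_spacing_mm", 0.3)),
            histology_noise_cv=float(data.get("histology_noise_cv", 0.05)),
            tissue_table=str(data.get("tissue_table", "default")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(hio.load_yaml(path))

    def as_dict(self) -> dict:
        def plain(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {f.name: plain(getattr(obj, f.name))
                        for f in fields(obj)}
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj
        return {
            "seed": self.seed, "design": plain(self.design),
            "protocol": plain(self.protocol), "lesions": plain(self.lesions),
            "isodata": plain(self.isodata),
            "feature_vectors": [list(v) for v in self.feature_vectors],
            "alpha": self.alpha, "r2_threshold": self.r2_threshold,
            "rim_thickness": self.rim_thickness, "exclusion_k": self.exclusion_k,
            "histology_spacing_mm": self.histology_spacing_mm,
            "histology_noise_cv": self.histology_noise_cv,
            "tissue_table": self.tissue_table,
        }

    def hash(self) -> str:
        return hio.config_hash(self.as_dict())


# ---------------------------------------------------------------------------
# in-memory study
# ---------------------------------------------------------------------------

@dataclass
class SpecResult:
    """Everything derived from clustering with one feature vector."""

    spec: tuple[str, ...]
    model: ClusterModel
    fraction_table: pd.DataFrame
    class_map: ClusterClassMap
    viability_by_scan: dict[tuple[str, str], np.ndarray]
    nonviable_fractions: dict[tuple[str, str], float]
    pairs: list[FractionPair]
    rim_misassignment: float


@dataclass
class StudyResult:
    cohort: Cohort
    maps_by_scan: dict[tuple[str, str], ParameterMapSet]
    histology_fractions: dict[str, float]
    per_spec: dict[str, SpecResult]
    report: EvaluationReport
    parameter_summary: pd.DataFrame | None = None
    parameter_tests: pd.DataFrame | None = None


def _sacrifice_group(plan: AnimalPlan) -> str:
    if plan.group == "control":
        return "control"
    return "1h" if plan.sacrifice_timepoint == "post1h" else "72h"


def fit_cohort_maps(cohort: Cohort,
                    exclusion_k: float = 3.0) -> dict[tuple[str, str], ParameterMapSet]:
    """Fit parameter maps for every scan from its noisy raw series."""
    maps = {}
    for key in cohort.scan_keys():
        scan = cohort.scans[key]
        if scan.raw is None:
            raise ValueError(f"scan {key} has no raw series; generate with include_raw")
        background = scan.truth.labels == LABEL_BACKGROUND
        maps[key] = fit_parameter_maps(scan.raw, scan.truth.tumor_mask,
                                       background, k=exclusion_k)
    return maps


def analyze_feature_vector(cohort: Cohort,
                           maps_by_scan: Mapping[tuple[str, str], ParameterMapSet],
                           spec: Sequence[str],
                           isodata_params: ISODATAParams,
                           alpha: float = 0.05,
                           rim_thickness: int = 3,
                           histology_fractions: Mapping[str, float] | None = None,
                           ) -> SpecResult:
    """Cluster, classify and score one feature vector."""
    spec = tuple(spec)
    matrix = assemble_feature_matrix(maps_by_scan, spec)
    normalized, stats = normalize_features(matrix)
    model = isodata_cluster(normalized, isodata_params, stats=stats)
    assignments = labels_by_scan(matrix, model.labels)
    table = cluster_fraction_table(assignments, model.n_clusters)
    class_map = classify_clusters(table, cohort.design, alpha=alpha)

    viability, fractions = {}, {}
    for key, labels in assignments.items():
        vol = labels_to_volume(maps_by_scan[key], labels)
        vmap, frac = make_viability_map(vol, class_map)
        viability[key] = vmap
        fractions[key] = frac

    pairs = []
    if histology_fractions is not None:
        for plan in cohort.design.animals():
            key = (plan.animal_id, plan.sacrifice_timepoint)
            pairs.append(FractionPair(
                tumor_id=plan.animal_id, group=_sacrifice_group(plan),
                histology=float(histology_fractions[plan.animal_id]),
                isodata=float(np.clip(fractions[key], 0.0, 1.0))))

    rims = []
    for plan in cohort.design.animals():
        if plan.group != "treated":
            continue
        key = (plan.animal_id, "pre")
        rims.append(rim_misassignment_fraction(
            viability[key], maps_by_scan[key].tumor_mask, rim_thickness))
    rim = float(np.mean(rims)) if rims else 0.0

    return SpecResult(spec=spec, model=model, fraction_table=table,
                      class_map=class_map, viability_by_scan=viability,
                      nonviable_fractions=fractions, pairs=pairs,
                      rim_misassignment=rim)


def run_study(config: RunConfig, cohort: Cohort | None = None,
              fit_maps: bool = True,
              summarize: bool = True) -> StudyResult:
    """Run the full analysis for every configured feature vector.

    With ``fit_maps`` the parameter maps are fitted from the noisy raw
    series; otherwise the generator's ground-truth maps are used directly
    (useful for isolating the clustering stages).
    """
    t0 = time.perf_counter()
    if cohort is None:
        cohort = generate_cohort(design=config.design, protocol=config.protocol,
                                 tissues=config.tissues(),
                                 lesions=config.lesions, seed=config.seed,
                                 include_raw=fit_maps)
    log.info("cohort: %d scans, seed=%d", len(cohort.scans), config.seed)

    if fit_maps:
        maps_by_scan = fit_cohort_maps(cohort, exclusion_k=config.exclusion_k)
    else:
        maps_by_scan = cohort.truth_maps()
    log.info("maps ready (%.1f s)", time.perf_counter() - t0)

    sections = simulate_cohort_histology(cohort, config.histology_spacing_mm,
                                         config.histology_noise_cv,
                                         seed=config.seed + 1)
    histology = {aid: histology_volume_fraction(s) for aid, s in sections.items()}

    per_spec: dict[str, SpecResult] = {}
    for i, spec in enumerate(config.feature_vectors):
        params = replace(config.isodata, seed=(config.isodata.seed + 7919 * i) % 2 ** 31)
        res = analyze_feature_vector(cohort, maps_by_scan, spec, params,
                                     alpha=config.alpha,
                                     rim_thickness=config.rim_thickness,
                                     histology_fractions=histology)
        per_spec[spec_key(spec)] = res
        log.info("feature vector %s: %d clusters, %d non-viable, rim=%.3f",
                 spec_key(spec), res.model.n_clusters,
                 len(res.class_map.nonviable_clusters), res.rim_misassignment)

    report = evaluate_feature_vectors(
        {k: r.pairs for k, r in per_spec.items()},
        {k: r.rim_misassignment for k, r in per_spec.items()},
        r2_threshold=config.r2_threshold)

    summary = tests = None
    if summarize:
        pick = report.selected or next(iter(per_spec))
        res = per_spec[pick]
        summary, tests = summarize_parameters(cohort, maps_by_scan,
                                              res.viability_by_scan,
                                              alpha=config.alpha)
    log.info("study complete (%.1f s); selected=%s",
             time.perf_counter() - t0, report.selected)
    return StudyResult(cohort=cohort, maps_by_scan=maps_by_scan,
                       histology_fractions=histology, per_spec=per_spec,
                       report=report, parameter_summary=summary,
                       parameter_tests=tests)


# ---------------------------------------------------------------------------
# disk-backed stages (CLI)
# ---------------------------------------------------------------------------

def _scan_stem(animal_id: str, timepoint: str) -> str:
    return f"{animal_id}_{timepoint}"


def stage_simulate(config: RunConfig, outdir: str | Path) -> Cohort:
    """Generate the cohort and write raw series, truth labels, manifest,
    histology sections and the echoed config."""
    t0 = time.perf_counter()
    outdir = Path(outdir)
    cohort = generate_cohort(design=config.design, protocol=config.protocol,
                             tissues=config.tissues(),
                             lesions=config.lesions, seed=config.seed)
    vx = config.protocol.voxel_size_mm
    h = config.hash()
    rows = []
    plans = {p.animal_id: p for p in config.design.animals()}
    for key in cohort.scan_keys():
        scan = cohort.scans[key]
        stem = _scan_stem(*key)
        raw = scan.raw
        p = config.protocol
        dwi_flat = raw.dwi.reshape(-1, *p.shape)
        paths = {
            "raw_ir": hio.write_volume(outdir / "raw" / f"{stem}_ir.nii.gz",
                                       np.moveaxis(raw.ir, 0, -1), vx),
            "raw_t2series": hio.write_volume(outdir / "raw" / f"{stem}_t2series.nii.gz",
                                             np.moveaxis(raw.t2_series, 0, -1), vx),
            "raw_dwi": hio.write_volume(outdir / "raw" / f"{stem}_dwi.nii.gz",
                                        np.moveaxis(dwi_flat, 0, -1), vx),
            "raw_mt": hio.write_volume(outdir / "raw" / f"{stem}_mt.nii.gz",
                                       np.stack([raw.mt_unsat, raw.mt_sat], axis=-1), vx),
            "raw_t2w": hio.write_volume(outdir / "raw" / f"{stem}_t2w.nii.gz",
                                        raw.t2w, vx),
            "truth_labels": hio.write_volume(outdir / "truth" / f"{stem}_labels.nii.gz",
                                             scan.truth.labels, vx),
            "tumor_mask": hio.write_volume(outdir / "truth" / f"{stem}_tumor.nii.gz",
                                           scan.truth.tumor_mask, vx),
        }
        plan = plans[scan.animal_id]
        rows.append({"animal_id": scan.animal_id, "group": scan.group,
                     "timepoint": scan.timepoint,
                     "sacrifice": scan.timepoint == plan.sacrifice_timepoint,
                     "true_nonviable_fraction": scan.truth.true_nonviable_fraction,
                     **{k: str(v) for k, v in paths.items()}})
    hio.write_table(pd.DataFrame(rows), outdir / "manifest.csv", h)

    sections = simulate_cohort_histology(cohort, config.histology_spacing_mm,
                                         config.histology_noise_cv,
                                         seed=config.seed + 1)
    hrows = []
    for aid in sorted(sections):
        for i, (nv, tot) in enumerate(sections[aid]):
            hrows.append({"animal_id": aid, "section": i,
                          "nonviable_area_mm2": nv, "total_area_mm2": tot})
    hio.write_table(pd.DataFrame(hrows), outdir / "histology.csv", h)
    hio.dump_yaml(config.as_dict(), outdir / "config.yaml")
    log.info("stage simulate: %d scans in %.1f s",
             len(cohort.scans), time.perf_counter() - t0)
    return cohort


def _load_manifest(outdir: Path) -> pd.DataFrame:
    path = outdir / "manifest.csv"
    if not path.exists():
        raise FileNotFoundError(f"no manifest at {path}; run the simulate stage first")
    return hio.read_table(path)


def _plans_from_manifest(df: pd.DataFrame) -> list[AnimalPlan]:
    order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    plans = []
    for aid, sub in df.groupby("animal_id"):
        tps = tuple(sorted(sub["timepoint"].unique(), key=order.get))
        sac = sub.loc[sub["sacrifice"], "timepoint"]
        plans.append(AnimalPlan(aid, sub["group"].iloc[0], tps,
                                sac.iloc[0] if len(sac) else tps[-1]))
    return plans


class _ManifestDesign:
    """Minimal design view reconstructed from a manifest."""

    def __init__(self, plans: list[AnimalPlan]):
        self._plans = plans

    def animals(self) -> list[AnimalPlan]:
        return self._plans


def stage_fit(config: RunConfig, outdir: str | Path) -> None:
    """Fit parameter maps for every scan listed in the manifest."""
    t0 = time.perf_counter()
    outdir = Path(outdir)
    df = _load_manifest(outdir)
    h = config.hash()
    p = config.protocol
    excl_rows = []
    for _, row in df.iterrows():
        stem = _scan_stem(row["animal_id"], row["timepoint"])
        ir, vx = hio.read_volume(row["raw_ir"])
        t2s, _ = hio.read_volume(row["raw_t2series"])
        dwi, _ = hio.read_volume(row["raw_dwi"])
        mt, _ = hio.read_volume(row["raw_mt"])
        t2w, _ = hio.read_volume(row["raw_t2w"])
        labels, _ = hio.read_volume(row["truth_labels"])
        tumor, _ = hio.read_volume(row["tumor_mask"])
        if ir.shape[:3] != p.shape:
            raise ValueError(f"{stem}: raw grid {ir.shape[:3]} does not match "
                             f"protocol {p.shape}")
        raw = RawSeriesSet(
            protocol=p,
            ir=np.moveaxis(ir, -1, 0).astype(float),
            t2_series=np.moveaxis(t2s, -1, 0).astype(float),
            dwi=np.moveaxis(dwi, -1, 0).reshape(
                p.n_diffusion_directions, len(p.b_values), *p.shape).astype(float),
            mt_unsat=mt[..., 0].astype(float), mt_sat=mt[..., 1].astype(float),
            t2w=t2w.astype(float))
        maps = fit_parameter_maps(raw, tumor.astype(bool),
                                  labels == LABEL_BACKGROUND, k=config.exclusion_k)
        for name, vol in (("t1", maps.t1_ms), ("t2", maps.t2_ms),
                          ("adc", maps.adc), ("mtr", maps.mtr)):
            hio.write_volume(outdir / "maps" / f"{stem}_{name}.nii.gz", vol, vx)
        hio.write_volume(outdir / "maps" / f"{stem}_exclusion.nii.gz",
                         maps.exclusion_mask, vx)
        excl_rows.append({"animal_id": row["animal_id"],
                          "timepoint": row["timepoint"],
                          "excluded_fraction": maps.excluded_fraction()})
    hio.write_table(pd.DataFrame(excl_rows), outdir / "exclusion_report.csv", h)
    log.info("stage fit: %d scans in %.1f s", len(df), time.perf_counter() - t0)


def _load_maps(outdir: Path, df: pd.DataFrame,
               voxel_size) -> dict[tuple[str, str], ParameterMapSet]:
    maps = {}
    for _, row in df.iterrows():
        stem = _scan_stem(row["animal_id"], row["timepoint"])
        vols = {}
        for name in ("t1", "t2", "adc", "mtr", "exclusion"):
            path = outdir / "maps" / f"{stem}_{name}.nii.gz"
            if not path.exists():
                raise FileNotFoundError(f"missing fitted map {path}; "
                                        f"run the fit stage first")
            vols[name], _ = hio.read_volume(path)
        tumor, _ = hio.read_volume(row["tumor_mask"])
        maps[(row["animal_id"], row["timepoint"])] = ParameterMapSet(
            t1_ms=vols["t1"].astype(float), t2_ms=vols["t2"].astype(float),
            adc=vols["adc"].astype(float), mtr=vols["mtr"].astype(float),
            tumor_mask=tumor.astype(bool),
            exclusion_mask=vols["exclusion"].astype(bool),
            voxel_size_mm=voxel_size)
    return maps


def stage_cluster(config: RunConfig, outdir: str | Path,
                  spec: Sequence[str], spec_index: int = 0) -> ClusterModel:
    """Pool, normalize and cluster one feature vector; write label volumes
    and the centroid table."""
    t0 = time.perf_counter()
    outdir = Path(outdir)
    df = _load_manifest(outdir)
    h = config.hash()
    key = spec_key(spec)
    maps = _load_maps(outdir, df, config.protocol.voxel_size_mm)
    matrix = assemble_feature_matrix(maps, spec)
    normalized, stats = normalize_features(matrix)
    params = replace(config.isodata,
                     seed=(config.isodata.seed + 7919 * spec_index) % 2 ** 31)
    model = isodata_cluster(normalized, params, stats=stats)
    assignments = labels_by_scan(matrix, model.labels)
    subdir = outdir / f"cluster_{key}"
    for scan_key, labels in assignments.items():
        vol = labels_to_volume(maps[scan_key], labels)
        hio.write_volume(subdir / f"{_scan_stem(*scan_key)}_labels.nii.gz",
                         vol, config.protocol.voxel_size_mm)
    cent = pd.DataFrame(model.stats.inverse(model.centroids),
                        columns=list(model.feature_names))
    cent.insert(0, "cluster", np.arange(model.n_clusters))
    cent["size"] = model.sizes
    hio.write_table(cent, subdir / "centroids.csv", h)
    hio.write_table(pd.DataFrame({"feature": list(model.feature_names),
                                  "mean": model.stats.mean, "sd": model.stats.sd}),
                    subdir / "normalization.csv", h)
    log.info("stage cluster %s: %d clusters over %d voxels in %.1f s",
             key, model.n_clusters, matrix.n_rows, time.perf_counter() - t0)
    return model


def stage_classify(config: RunConfig, outdir: str | Path,
                   spec: Sequence[str]) -> pd.DataFrame:
    """Classify clusters into viable/non-viable and write viability maps,
    per-tumor fractions and the cluster-class table."""
    t0 = time.perf_counter()
    outdir = Path(outdir)
    df = _load_manifest(outdir)
    h = config.hash()
    key = spec_key(spec)
    subdir = outdir / f"cluster_{key}"
    if not (subdir / "centroids.csv").exists():
        raise FileNotFoundError(f"no clustering artifacts for {key}; "
                                f"run the cluster stage first")
    n_clusters = len(hio.read_table(subdir / "centroids.csv"))

    assignments, volumes = {}, {}
    for _, row in df.iterrows():
        scan_key = (row["animal_id"], row["timepoint"])
        vol, _ = hio.read_volume(subdir / f"{_scan_stem(*scan_key)}_labels.nii.gz")
        volumes[scan_key] = vol
        assignments[scan_key] = vol[vol >= 0]
    table = cluster_fraction_table(assignments, n_clusters)
    plans = _plans_from_manifest(df)
    class_map = classify_clusters(table, _ManifestDesign(plans), alpha=config.alpha)

    outsub = outdir / f"classify_{key}"
    frac_rows = []
    rim_vals = []
    tumors = {}
    for _, row in df.iterrows():
        tumors[(row["animal_id"], row["timepoint"])], _ = \
            hio.read_volume(row["tumor_mask"])
    for scan_key, vol in volumes.items():
        vmap, frac = make_viability_map(vol, class_map)
        hio.write_volume(outsub / f"{_scan_stem(*scan_key)}_viability.nii.gz",
                         vmap, config.protocol.voxel_size_mm)
        frac_rows.append({"animal_id": scan_key[0], "timepoint": scan_key[1],
                          "nonviable_fraction": frac})
        plan = next(p for p in plans if p.animal_id == scan_key[0])
        if plan.group == "treated" and scan_key[1] == "pre":
            rim_vals.append(rim_misassignment_fraction(
                vmap, tumors[scan_key].astype(bool), config.rim_thickness))
    fractions = pd.DataFrame(frac_rows)
    hio.write_table(fractions, outsub / "fractions.csv", h)
    hio.write_table(class_map.tests.assign(
        cls=class_map.tests["cluster"].map(class_map.classes)),
        outsub / "clusters.csv", h)
    hio.write_table(pd.DataFrame([{
        "feature_vector": key,
        "rim_misassignment": float(np.mean(rim_vals)) if rim_vals else 0.0,
        "n_nonviable_clusters": len(class_map.nonviable_clusters),
        "n_clusters": n_clusters}]), outsub / "stats.csv", h)
    log.info("stage classify %s: done in %.1f s", key, time.perf_counter() - t0)
    return fractions


def stage_evaluate(config: RunConfig, outdir: str | Path) -> EvaluationReport:
    """Score all configured feature vectors against histology and write the
    evaluation report."""
    t0 = time.perf_counter()
    outdir = Path(outdir)
    df = _load_manifest(outdir)
    h = config.hash()
    hist = hio.read_table(outdir / "histology.csv")
    histology = {aid: histology_volume_fraction(
        list(zip(sub["nonviable_area_mm2"], sub["total_area_mm2"])))
        for aid, sub in hist.groupby("animal_id")}

    plans = _plans_from_manifest(df)
    pairs_by_spec, rims = {}, {}
    scatter_rows = []
    for spec in config.feature_vectors:
        key = spec_key(spec)
        outsub = outdir / f"classify_{key}"
        fractions = hio.read_table(outsub / "fractions.csv")
        stats = hio.read_table(outsub / "stats.csv")
        rims[key] = float(stats["rim_misassignment"].iloc[0])
        pairs = []
        for plan in plans:
            sub = fractions[(fractions["animal_id"] == plan.animal_id)
                            & (fractions["timepoint"] == plan.sacrifice_timepoint)]
            iso = float(np.clip(sub["nonviable_fraction"].iloc[0], 0, 1))
            pair = FractionPair(plan.animal_id, _sacrifice_group(plan),
                                float(histology[plan.animal_id]), iso)
            pairs.append(pair)
            scatter_rows.append({"feature_vector": key, "tumor_id": pair.tumor_id,
                                 "group": pair.group, "histology": pair.histology,
                                 "isodata": pair.isodata})
        pairs_by_spec[key] = pairs
    report = evaluate_feature_vectors(pairs_by_spec, rims,
                                      r2_threshold=config.r2_threshold)
    hio.write_table(report.table, outdir / "evaluation.csv", h)
    hio.write_table(report.wolfe, outdir / "wolfe_tests.csv", h)
    hio.write_table(pd.DataFrame(scatter_rows), outdir / "fraction_scatter.csv", h)
    hio.write_table(pd.DataFrame([{"selected": report.selected or "",
                                   "r2_threshold": config.r2_threshold}]),
                    outdir / "selection.csv", h)
    log.info("stage evaluate: selected=%s in %.1f s",
             report.selected, time.perf_counter() - t0)
    return report


def run_pipeline(config: RunConfig, outdir: str | Path) -> EvaluationReport:
    """Run every stage in order on disk; artifacts of completed stages are
    preserved if a later stage fails."""
    stages = [("simulate", lambda: stage_simulate(config, outdir)),
              ("fit", lambda: stage_fit(config, outdir))]
    for i, spec in enumerate(config.feature_vectors):
        stages.append((f"cluster[{spec_key(spec)}]",
                       lambda s=spec, j=i: stage_cluster(config, outdir, s, j)))
        stages.append((f"classify[{spec_key(spec)}]",
                       lambda s=spec: stage_classify(config, outdir, s)))
    stages.append(("evaluate", lambda: stage_evaluate(config, outdir)))
    result = None
    for name, fn in stages:
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return result
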