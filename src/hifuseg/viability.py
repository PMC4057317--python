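"""Temporal viability classification of ISODATA clusters.

Clusters are divided into a non-viable and a viable class from the fraction
of each tumor's included voxels they hold at the different time points: a
cluster is non-viable when its per-animal fraction in the treated group
increased significantly after ablation (pre vs 1 h over all treated animals,
or pre vs 72 h over the treated animals with a 72 h scan; paired Student's
t-test, p < alpha, with a positive mean paired difference enforcing the
stated direction). All remaining clusters are viable; control animals never
enter the tests. The classification depends only on the partition, so it is
invariant to cluster relabeling.

From the per-voxel class lookup each tumor's non-viable volume fraction is
computed over included voxels only (excluded, noise-level voxels sit in
neither numerator nor denominator), and Table-2-style per-class parameter
summaries (R1, R2 as voxelwise reciprocals of the fitted times, ADC, MTR)
are derived.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .mapping import ParameterMapSet
from .synthetic import Cohort, CohortDesign

__all__ = [
    "VIABILITY_EXCLUDED", "VIABILITY_VIABLE", "VIABILITY_NONVIABLE",
    "VIABILITY_OUTSIDE", "PairedTResult", "ClusterClassMap",
    "cluster_fraction_table", "paired_t_test", "classify_clusters",
    "make_viability_map", "nonviable_fraction", "summarize_parameters",
]

VIABILITY_OUTSIDE = -1
VIABILITY_EXCLUDED = 0
VIABILITY_VIABLE = 1
VIABILITY_NONVIABLE = 2


def cluster_fraction_table(assignments: Mapping[tuple[str, str], np.ndarray],
                           n_clusters: int) -> pd.DataFrame:
    """Fraction of each tumor's included voxels per cluster and time point.

    ``assignments`` maps (animal, time point) to the cluster labels of that
    scan's included voxels. Clusters absent from a tumor get fraction 0; per
    scan the fractions sum to 1.
    """
    records = []
    for (animal_id, timepoint), labels in assignments.items():
        labels = np.asarray(labels)
        if labels.size == 0:
            raise ValueError(f"scan ({animal_id}, {timepoint}) has no included voxels")
        if labels.min() < 0 or labels.max() >= n_clusters:
            raise ValueError(f"labels of ({animal_id}, {timepoint}) outside "
                             f"[0, {n_clusters})")
        counts = np.bincount(labels, minlength=n_clusters)
        fracs = counts / labels.size
        for c in range(n_clusters):
            records.append({"animal_id": animal_id, "timepoint": timepoint,
                            "cluster": c, "fraction": fracs[c],
                            "n_voxels": int(counts[c])})
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    mean_diff: float
    n: int


def paired_t_test(before: np.ndarray, after: np.ndarray) -> PairedTResult:
    """Two-sided paired Student's t-test on per-animal values.

    ``t = dbar / (s_d / sqrt(n))`` with ``df = n - 1``. Zero-variance
    differences use the convention p = 0 for a nonzero mean difference and
    p = 1 when all differences vanish.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before/after must be 1-D arrays of equal length")
    n = before.size
    if n < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = after - before
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(t=0.0, p=1.0, mean_diff=0.0, n=n)
        return PairedTResult(t=float(np.sign(mean)) * np.inf, p=0.0,
                             mean_diff=mean, n=n)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(sstats.t.sf(abs(t), df=n - 1))
    return PairedTResult(t=float(t), p=p, mean_diff=mean, n=n)


@dataclass
class ClusterClassMap:
    """Cluster id -> class, with the supporting paired-test statistics."""

    classes: dict[int, str]            # cluster -> "viable" | "nonviable"
    tests: pd.DataFrame                # cluster, comparison, n, t, p, mean_diff

    def is_nonviable(self, cluster: int) -> bool:
        return self.classes[cluster] == "nonviable"

    @property
    def nonviable_clusters(self) -> list[int]:
        return sorted(c for c, cls in self.classes.items() if cls == "nonviable")


def classify_clusters(table: pd.DataFrame, design: CohortDesign,
                      alpha: float = 0.05) -> ClusterClassMap:
    """Apply the temporal increase rule to a cluster fraction table.

    A cluster is non-viable iff, among treated animals only, the paired test
    pre vs 1 h (all treated) or pre vs 72 h (the treated subset with a 72 h
    scan) is significant at ``alpha`` with a positive mean difference.
    """
    treated = [p for p in design.animals() if p.group == "treated"]
    if not treated:
        raise ValueError("no treated animals in the design")

    pivot = table.pivot_table(index=["animal_id", "timepoint"], columns="cluster",
                              values="fraction", fill_value=0.0)
    clusters = sorted(table["cluster"].unique())

    def fractions(ids, timepoint, cluster):
        vals = []
        for aid in ids:
            try:
                vals.append(float(pivot.loc[(aid, timepoint), cluster]))
            except KeyError:
                raise ValueError(f"missing cluster fractions for ({aid}, {timepoint})")
        return np.asarray(vals)

    ids_1h = [p.animal_id for p in treated if "post1h" in p.timepoints]
    ids_72h = [p.animal_id for p in treated if "post72h" in p.timepoints]

    classes: dict[int, str] = {}
    rows = []
    for c in clusters:
        nonviable = False
        for comp, ids, tp in (("pre_vs_1h", ids_1h, "post1h"),
                              ("pre_vs_72h", ids_72h, "post72h")):
            if len(ids) < 2:
                continue
            res = paired_t_test(fractions(ids, "pre", c), fractions(ids, tp, c))
            rows.append({"cluster": c, "comparison": comp, "n": res.n,
                         "t": res.t, "p": res.p, "mean_diff": res.mean_diff})
            if res.p < alpha and res.mean_diff > 0:
                nonviable = True
        classes[c] = "nonviable" if nonviable else "viable"
    return ClusterClassMap(classes=classes, tests=pd.DataFrame.from_records(rows))


def make_viability_map(cluster_volume: np.ndarray,
                       class_map: ClusterClassMap) -> tuple[np.ndarray, float]:
    """Per-voxel viable/non-viable/excluded map and the non-viable fraction.

    ``cluster_volume`` uses the label-volume convention: cluster id on
    included voxels, -1 excluded tumor voxels, -2 outside the tumor. The
    fraction is non-viable voxels over included voxels.
    """
    cluster_volume = np.asarray(cluster_volume)
    out = np.full(cluster_volume.shape, VIABILITY_OUTSIDE, dtype=np.int8)
    out[cluster_volume == -1] = VIABILITY_EXCLUDED
    included = cluster_volume >= 0
    present = np.unique(cluster_volume[included])
    for c in present:
        if int(c) not in class_map.classes:
            raise KeyError(f"cluster {int(c)} has no class assignment")
        code = VIABILITY_NONVIABLE if class_map.is_nonviable(int(c)) else VIABILITY_VIABLE
        out[cluster_volume == c] = code
    n_inc = int(included.sum())
    frac = float((out == VIABILITY_NONVIABLE).sum()) / n_inc if n_inc else 0.0
    return out, frac


def nonviable_fraction(viability_volume: np.ndarray) -> float:
    """Non-viable fraction of a viability map (included voxels only)."""
    n_nv = int((viability_volume == VIABILITY_NONVIABLE).sum())
    n_v = int((viability_volume == VIABILITY_VIABLE).sum())
    total = n_nv + n_v
    return n_nv / total if total else 0.0


def summarize_parameters(cohort: Cohort,
                         maps_by_scan: Mapping[tuple[str, str], ParameterMapSet],
                         viability_by_scan: Mapping[tuple[str, str], np.ndarray],
                         alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class mean +/- SD of R1, R2, ADC and MTR across treated animals.

    Per animal, parameters are averaged over voxels classified viable (pooled
    over all of that animal's time points) and over voxels classified
    non-viable at 1 h and at 72 h; R1 and R2 are computed voxelwise as
    reciprocals of the fitted T1/T2 before averaging. Returns the summary
    table (parameter, tissue class, mean, sd, n) and the paired
    viable-vs-non-viable tests; animals without non-viable voxels at a
    compared time point are dropped from that pairing with a warning.
    """
    params = {"R1": lambda m: m.r1_per_s, "R2": lambda m: m.r2_per_s,
              "ADC": lambda m: m.adc, "MTR": lambda m: m.mtr}
    treated = [p for p in cohort.design.animals() if p.group == "treated"]

    per_animal: dict[str, dict[str, float]] = {name: {} for name in (
        "viable", "nonviable_1h", "nonviable_72h")}
    values: dict[tuple[str, str], dict[str, float]] = {}
    for plan in treated:
        pooled: dict[str, list[np.ndarray]] = {p: [] for p in params}
        for tp in plan.timepoints:
            key = (plan.animal_id, tp)
            vol = viability_by_scan[key]
            maps = maps_by_scan[key]
            viable = vol == VIABILITY_VIABLE
            nonviable = vol == VIABILITY_NONVIABLE
            for pname, getter in params.items():
                vals = getter(maps)
                pooled[pname].append(vals[viable])
                if tp in ("post1h", "post72h") and nonviable.any():
                    cls = "nonviable_1h" if tp == "post1h" else "nonviable_72h"
                    values.setdefault((plan.animal_id, cls), {})[pname] = float(
                        np.nanmean(vals[nonviable]))
        for pname in params:
            allv = np.concatenate(pooled[pname]) if pooled[pname] else np.array([])
            if allv.size:
                values.setdefault((plan.animal_id, "viable"), {})[pname] = float(
                    np.nanmean(allv))

    summary_rows, test_rows = [], []
    for cls in ("viable", "nonviable_1h", "nonviable_72h"):
        for pname in params:
            vals = [values[(p.animal_id, cls)][pname] for p in treated
                    if (p.animal_id, cls) in values
                    and pname in values[(p.animal_id, cls)]]
            arr = np.asarray(vals)
            summary_rows.append({
                "parameter": pname, "tissue_class": cls, "n": arr.size,
                "mean": float(arr.mean()) if arr.size else np.nan,
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else np.nan,
            })
    for cls in ("nonviable_1h", "nonviable_72h"):
        ids = [p.animal_id for p in treated
               if (p.animal_id, cls) in values and (p.animal_id, "viable") in values]
        dropped = [p.animal_id for p in treated
                   if (p.animal_id, "viable") in values and (p.animal_id, cls) not in values
                   and (cls != "nonviable_72h" or "post72h" in p.timepoints)]
        if dropped:
            warnings.warn(f"animals without non-viable voxels dropped from "
                          f"{cls} comparison: {dropped}", stacklevel=2)
        if len(ids) < 2:
            continue
        for pname in params:
            viable_vals = np.array([values[(a, "viable")][pname] for a in ids])
            nv_vals = np.array([values[(a, cls)][pname] for a in ids])
            res = paired_t_test(viable_vals, nv_vals)
            test_rows.append({"parameter": pname, "comparison": f"viable_vs_{cls}",
                              "n": res.n, "t": res.t, "p": res.p,
                              "mean_diff": res.mean_diff,
                              "significant": res.p < alpha})
    return pd.DataFrame(summary_rows), pd.DataFrame(test_rows)
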