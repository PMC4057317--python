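"""Agreement scoring between clustering-derived and histology-derived
non-viable tumor fractions, and feature-vector selection.

The unit of comparison is one tumor's pair of non-viable volume fractions:
the area-weighted histology fraction (sum of non-viable section areas over
sum of total section areas) versus the fraction of included voxels the
classified segmentation calls non-viable at the animal's sacrifice-time
scan. Feature vectors are ranked by three criteria applied in order:

1. one-to-one correspondence — the coefficient of determination of the
   fraction pairs to the line of identity y = x (may be negative for
   systematic over/under-estimation);
2. strength of the linear relationship — Pearson correlations within the
   '1 h + control' and '72 h + control' sacrifice groups, with differences
   between dependent correlations tested by Wolfe's test;
3. pre-treatment specificity — the mean fraction of tumor-rim pixels (rim
   thickness 3) incorrectly labeled non-viable before treatment, a
   peritumoral-edema artifact.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sstats

from .viability import VIABILITY_NONVIABLE

__all__ = [
    "FractionPair", "EvaluationReport", "histology_volume_fraction",
    "r2_to_identity", "pearson_r", "wolfe_dependent_correlation_test",
    "rim_misassignment_fraction", "evaluate_feature_vectors",
]

GROUPS = ("1h", "72h", "control")


@dataclass(frozen=True)
class FractionPair:
    """One tumor's histology vs clustering-derived non-viable fraction."""

    tumor_id: str
    group: str                    # "1h" | "72h" | "control" (sacrifice group)
    histology: float
    isodata: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        for name in ("histology", "isodata"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} fraction {v} outside [0, 1]")


def histology_volume_fraction(sections: Sequence[tuple[float, float]]) -> float:
    """Area-weighted non-viable volume fraction over all tumor sections.

    ``sum(non-viable areas) / sum(total areas)`` — not the mean of per-section
    ratios, so large sections weigh more.
    """
    if not sections:
        raise ValueError("no histology sections")
    nonviable = np.asarray([s[0] for s in sections], dtype=float)
    total = np.asarray([s[1] for s in sections], dtype=float)
    if np.any(total <= 0):
        raise ValueError("total section areas must be positive")
    if np.any(nonviable > total + 1e-12):
        raise ValueError("non-viable area exceeds total area in a section")
    if np.any(nonviable < 0):
        raise ValueError("negative non-viable area")
    return float(nonviable.sum() / total.sum())


def r2_to_identity(x: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination of (x, y) points to the line y = x.

    ``R^2 = 1 - sum((y - x)^2) / sum((y - ybar)^2)``; values may be negative
    when the identity line fits worse than the mean of y (systematic over- or
    under-estimation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two 1-D arrays of equal length >= 2")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("zero variance in y; R^2 to identity is undefined")
    ss_res = float(((y - x) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two 1-D arrays of equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(sstats.pearsonr(x, y).statistic)


def wolfe_dependent_correlation_test(x: np.ndarray, y1: np.ndarray,
                                     y2: np.ndarray) -> tuple[float, float]:
    """Test H0: corr(x, y1) = corr(x, y2) for correlations sharing x.

    Realized as the significance of ``corr(x, y1* - y2*)`` where y1*, y2* are
    standardized to unit variance: since ``cov(x, y1* - y2*)`` is proportional
    to ``rho(x, y1) - rho(x, y2)``, a nonzero correlation of x with the
    standardized difference indicates unequal dependent correlations. Returns
    the t statistic and the two-sided p-value; identical inputs give (0, 1),
    and swapping y1 and y2 flips the statistic's sign.
    """
    x = np.asarray(x, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if not (x.shape == y1.shape == y2.shape) or x.ndim != 1:
        raise ValueError("need three aligned 1-D samples")
    n = x.size
    if n < 4:
        raise ValueError("Wolfe's test needs n >= 4")
    if x.std(ddof=1) == 0 or y1.std(ddof=1) == 0 or y2.std(ddof=1) == 0:
        raise ValueError("degenerate variance in an input sample")
    d = y1 / y1.std(ddof=1) - y2 / y2.std(ddof=1)
    if d.std(ddof=1) == 0:
        return 0.0, 1.0
    r = float(np.corrcoef(x, d)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return float(np.sign(r)) * np.inf, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sstats.t.sf(abs(t), df=n - 2))
    return float(t), p


def rim_misassignment_fraction(viability_volume: np.ndarray,
                               tumor_mask: np.ndarray,
                               rim_thickness: int = 3) -> float:
    """Fraction of tumor-rim voxels labeled non-viable in one tumor.

    The rim is the tumor mask minus its 2-D per-slice erosion (4-connected,
    ``rim_thickness`` iterations); slices where erosion empties the mask
    degenerate to the whole in-slice tumor. The fraction counts non-viable
    rim voxels over all rim voxels.
    """
    if rim_thickness < 1:
        raise ValueError("rim thickness must be >= 1")
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    viability_volume = np.asarray(viability_volume)
    if viability_volume.shape != tumor_mask.shape:
        raise ValueError("viability map and tumor mask shapes differ")
    if not tumor_mask.any():
        raise ValueError("empty tumor mask")
    cross = ndimage.generate_binary_structure(2, 1)
    rim = np.zeros_like(tumor_mask)
    for z in range(tumor_mask.shape[2]):
        sl = tumor_mask[:, :, z]
        if not sl.any():
            continue
        eroded = ndimage.binary_erosion(sl, structure=cross, iterations=rim_thickness)
        rim[:, :, z] = sl & ~eroded
    n_rim = int(rim.sum())
    if n_rim == 0:  # tumor thinner than the rim everywhere
        rim = tumor_mask
        n_rim = int(rim.sum())
    n_bad = int((viability_volume[rim] == VIABILITY_NONVIABLE).sum())
    return n_bad / n_rim


@dataclass
class EvaluationReport:
    """Per-feature-vector agreement statistics and the selected vector."""

    table: pd.DataFrame                 # one row per feature vector
    wolfe: pd.DataFrame                 # pairwise tests among retained vectors
    retained: list[str]
    selected: str | None
    r2_threshold: float


def _group_values(pairs: Sequence[FractionPair],
                  groups: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    sel = [p for p in pairs if p.group in groups]
    x = np.asarray([p.histology for p in sel])
    y = np.asarray([p.isodata for p in sel])
    return x, y


def evaluate_feature_vectors(fraction_pairs: Mapping[str, Sequence[FractionPair]],
                             rim_fractions: Mapping[str, float],
                             r2_threshold: float = 0.7) -> EvaluationReport:
    """Score every feature vector and apply the three selection criteria.

    ``fraction_pairs`` maps a feature-vector key to its per-tumor fraction
    pairs; ``rim_fractions`` maps the same keys to the mean pre-treatment rim
    misassignment fraction. Vectors with identity-line R^2 above the
    threshold are retained (criterion 1); group-wise Pearson correlations
    with pairwise Wolfe tests are reported among them (criterion 2); the
    retained vector with the lowest rim fraction is selected (criterion 3).
    An empty retained set yields ``selected=None`` with all statistics still
    reported.
    """
    keys = list(fraction_pairs)
    rows = []
    for key in keys:
        pairs = list(fraction_pairs[key])
        x_all = np.asarray([p.histology for p in pairs])
        y_all = np.asarray([p.isodata for p in pairs])
        try:
            r2 = r2_to_identity(x_all, y_all)
        except ValueError:
            # constant derived fractions: no one-to-one correspondence at all
            r2 = -np.inf
        stats_row = {"feature_vector": key, "n_tumors": len(pairs),
                     "r2_identity": r2,
                     "rim_misassignment": float(rim_fractions[key])}
        for gname, groups in (("r_1h_control", ("1h", "control")),
                              ("r_72h_control", ("72h", "control"))):
            x, y = _group_values(pairs, groups)
            try:
                stats_row[gname] = pearson_r(x, y)
            except ValueError:
                stats_row[gname] = np.nan
        rows.append(stats_row)
    table = pd.DataFrame.from_records(rows)
    table["retained"] = table["r2_identity"] > r2_threshold
    retained = table.loc[table["retained"], "feature_vector"].tolist()

    wolfe_rows = []
    for gname, groups in (("1h_control", ("1h", "control")),
                          ("72h_control", ("72h", "control"))):
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                ki, kj = retained[i], retained[j]
                x, y1 = _group_values(fraction_pairs[ki], groups)
                _, y2 = _group_values(fraction_pairs[kj], groups)
                try:
                    stat, p = wolfe_dependent_correlation_test(x, y1, y2)
                except ValueError:
                    stat, p = np.nan, np.nan
                wolfe_rows.append({"group": gname, "vector_a": ki, "vector_b": kj,
                                   "statistic": stat, "p": p})
    wolfe = pd.DataFrame.from_records(
        wolfe_rows, columns=["group", "vector_a", "vector_b", "statistic", "p"])

    selected: str | None = None
    if retained:
        sub = table[table["retained"]]
        selected = str(sub.loc[sub["rim_misassignment"].idxmin(), "feature_vector"])
    return EvaluationReport(table=table, wolfe=wolfe, retained=retained,
                            selected=selected, r2_threshold=r2_threshold)
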