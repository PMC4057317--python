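"""Synthetic longitudinal multiparametric tumor-MRI cohorts.

Emulates a partial thermal-ablation (HIFU) study in a subcutaneous mouse tumor
model so that every downstream stage — parameter-map fitting, pooled ISODATA
clustering, temporal viability classification and histology agreement — can be
exercised with known ground truth and no external data:

* a longitudinal cohort design (treated animals scanned before and 1 h after
  ablation, a subset also at 72 h; non-treated controls at matching days, with
  each animal's last scan paired with histology at sacrifice);
* ellipsoidal tumors on a 128x128 multi-slice grid (~0.31 mm in-plane, 1 mm
  slices by default) containing a growing non-viable lesion core after
  treatment, an optional peritumoral-edema rim, and hemorrhage signal voids;
* per-tissue parameter values drawn from truncated Gaussians (R1, R2, ADC,
  MTR) with class means and SDs describing viable tumor, freshly ablated and
  late-stage non-viable tissue, edematous rim and surrounding muscle;
* forward-simulated raw signal series (inversion-recovery Look-Locker,
  multi-echo T2, multi-b diffusion per direction, MT on/off pair, T2-weighted
  anatomical reference) with Rician magnitude noise and per-series signal
  averaging;
* sparse-section synthetic histology: non-viable/total area pairs sampled
  along the slice axis with multiplicative area noise.

Within-tissue voxel values are drawn independently per time point: the
analysis clusters time points as independent pooled samples and makes no
claim of voxelwise registration across days. Within-tumor spatial texture
beyond the tissue-class partition is deliberately not modeled.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats

from .mapping import ParameterMapSet

__all__ = [
    "TIMEPOINTS", "LABEL_BACKGROUND", "LABEL_MUSCLE", "LABEL_VIABLE",
    "LABEL_NONVIABLE", "LABEL_EDEMA",
    "TissueClassParams", "default_tissue_params", "weak_mtr_tissue_params",
    "AcquisitionProtocol",
    "RawSeriesSet", "GroundTruthLabels", "CohortDesign", "AnimalPlan",
    "LesionSettings", "Scan", "Cohort",
    "generate_cohort", "simulate_signal_series", "add_rician_noise",
    "rician_sample", "simulate_histology", "simulate_cohort_histology",
]

#: Ordered scan time points. For treated animals these are pre-treatment,
#: 1 h post and 72 h post; for controls the matching days 0, 1 and 4.
TIMEPOINTS = ("pre", "post1h", "post72h")

LABEL_BACKGROUND = 0
LABEL_MUSCLE = 1
LABEL_VIABLE = 2
LABEL_NONVIABLE = 3
LABEL_EDEMA = 4

_TUMOR_LABELS = (LABEL_VIABLE, LABEL_NONVIABLE, LABEL_EDEMA)


@dataclass(frozen=True)
class TissueClassParams:
    """Gaussian voxel-value distribution of one tissue class.

    Rates are in s^-1, ADC in mm^2/s, MTR in percent. Draws are truncated at
    physical bounds (small positive floor for rates and ADC, [0, 100] for
    MTR).
    """

    name: str
    r1_mean: float
    r1_sd: float
    r2_mean: float
    r2_sd: float
    adc_mean: float
    adc_sd: float
    mtr_mean: float
    mtr_sd: float

    def __post_init__(self) -> None:
        for attr in ("r1_mean", "r2_mean", "adc_mean"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}: {attr} must be positive")
        for attr in ("r1_sd", "r2_sd", "adc_sd", "mtr_sd"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be non-negative")
        if not 0.0 <= self.mtr_mean <= 100.0:
            raise ValueError(f"{self.name}: mtr_mean must be within [0, 100]")


def default_tissue_params() -> dict[str, TissueClassParams]:
    """Default tissue-class distributions.

    Viable tumor and the two non-viable states carry the mean +/- SD values
    measured for those tissue states in the ablation study this generator
    emulates; the edematous rim (elevated T2 and ADC at viable-like R1/MTR)
    and surrounding muscle are generator choices documented in the methods
    note.
    """
    return {
        "viable": TissueClassParams("viable", 0.45, 0.01, 21.7, 1.4,
                                    0.84e-3, 0.12e-3, 23.3, 1.2),
        "nonviable_1h": TissueClassParams("nonviable_1h", 0.61, 0.13, 35.8, 19.5,
                                          1.09e-3, 0.20e-3, 26.4, 2.7),
        "nonviable_72h": TissueClassParams("nonviable_72h", 0.60, 0.06, 34.0, 21.0,
                                           1.25e-3, 0.16e-3, 26.4, 3.5),
        "edema": TissueClassParams("edema", 0.45, 0.01, 12.0, 2.0,
                                   1.40e-3, 0.15e-3, 23.3, 1.2),
        "muscle": TissueClassParams("muscle", 0.70, 0.05, 35.0, 3.0,
                                    1.40e-3, 0.10e-3, 35.0, 3.0),
    }


def weak_mtr_tissue_params(mtr_sd: float = 6.0) -> dict[str, TissueClassParams]:
    """Tissue table with the magnetization-transfer contrast made unreliable.

    Class means are unchanged, but the within-tumor voxelwise MTR SD is
    raised to ``mtr_sd`` percentage points for every tumor tissue class, so
    the subtle between-class MTR shift (~3 points) is buried in voxel-level
    variability. This emulates tumors in which MT changes after ablation are
    real but too weak and heterogeneous to support segmentation, and lets the
    clustering stage demonstrate the cost of including such a feature.
    """
    out = {}
    for name, p in default_tissue_params().items():
        if name == "muscle":
            out[name] = p
        else:
            out[name] = replace(p, mtr_sd=mtr_sd)
    return out


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Acquisition geometry, series timing and noise level.

    Defaults follow the emulated protocol: 15-point inversion-recovery
    Look-Locker series starting at 30 ms with 400 ms pulse separation and a
    20 degree flip angle (2 averages); 7 echo times from 1 to 82 ms
    (2 averages); b-values {0, 100, 200, 400} s/mm^2 in 3 orthogonal
    directions (4 averages); an MT on/off pair (2 averages); 128x128 matrix,
    4x4 cm^2 field of view, 1 mm slices. ``noise_sigma`` is the per-
    acquisition Rician noise SD in signal units (default S0/40).
    """

    shape: tuple[int, int, int] = (128, 128, 14)
    fov_mm: float = 40.0
    slice_thickness_mm: float = 1.0
    ir_first_time_ms: float = 30.0
    ir_spacing_ms: float = 400.0
    ir_n_points: int = 15
    ir_flip_deg: float = 20.0
    ir_n_averages: int = 2
    echo_times_ms: tuple[float, ...] = (1.0, 14.5, 28.0, 41.5, 55.0, 68.5, 82.0)
    t2_n_averages: int = 2
    b_values: tuple[float, ...] = (0.0, 100.0, 200.0, 400.0)
    n_diffusion_directions: int = 3
    dwi_n_averages: int = 4
    mt_n_averages: int = 2
    t2w_echo_time_ms: float = 30.0
    s0: float = 1000.0
    noise_sigma: float = 25.0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be three positive dimensions")
        b = np.asarray(self.b_values)
        if b.size < 2 or np.any(b < 0) or np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be non-negative and strictly increasing")
        te = np.asarray(self.echo_times_ms)
        if te.size < 2 or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing with >= 2 samples")
        if self.ir_n_points < 3:
            raise ValueError("inversion-recovery series needs >= 3 points")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")

    @property
    def ir_times_ms(self) -> np.ndarray:
        return self.ir_first_time_ms + self.ir_spacing_ms * np.arange(self.ir_n_points)

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return (self.fov_mm / self.shape[0], self.fov_mm / self.shape[1],
                self.slice_thickness_mm)


@dataclass
class RawSeriesSet:
    """Per-voxel raw signal arrays for one scan, shaped ``(n_samples, *grid)``.

    ``dwi`` is ``(n_directions, n_b, *grid)``; ``mt_unsat``/``mt_sat`` and the
    anatomical ``t2w`` reference are single volumes.
    """

    protocol: AcquisitionProtocol
    ir: np.ndarray
    t2_series: np.ndarray
    dwi: np.ndarray
    mt_unsat: np.ndarray
    mt_sat: np.ndarray
    t2w: np.ndarray

    def __post_init__(self) -> None:
        p = self.protocol
        expect = {
            "ir": (p.ir_n_points,) + p.shape,
            "t2_series": (len(p.echo_times_ms),) + p.shape,
            "dwi": (p.n_diffusion_directions, len(p.b_values)) + p.shape,
            "mt_unsat": p.shape,
            "mt_sat": p.shape,
            "t2w": p.shape,
        }
        for name, shape in expect.items():
            if np.shape(getattr(self, name)) != shape:
                raise ValueError(f"{name} has shape {np.shape(getattr(self, name))}, "
                                 f"expected {shape}")


@dataclass
class GroundTruthLabels:
    """Voxelwise tissue labels plus derived ground-truth quantities."""

    labels: np.ndarray            # int8 tissue codes (LABEL_* constants)
    void: np.ndarray              # hemorrhage-induced signal voids (subset of tumor)
    true_nonviable_fraction: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.void = np.asarray(self.void, dtype=bool)
        if self.void.shape != self.labels.shape:
            raise ValueError("void mask must share the label grid")
        if np.any(self.void & ~self.tumor_mask):
            raise ValueError("void voxels must lie inside the tumor")
        n_tumor = int(self.tumor_mask.sum())
        n_nv = int((self.labels == LABEL_NONVIABLE).sum())
        expect = n_nv / n_tumor if n_tumor else 0.0
        if abs(self.true_nonviable_fraction - expect) > 1e-12:
            raise ValueError("true non-viable fraction must equal the voxel-count ratio")

    @property
    def tumor_mask(self) -> np.ndarray:
        return np.isin(self.labels, _TUMOR_LABELS)

    @property
    def nonviable_mask(self) -> np.ndarray:
        return self.labels == LABEL_NONVIABLE

    @property
    def edema_mask(self) -> np.ndarray:
        return self.labels == LABEL_EDEMA


@dataclass(frozen=True)
class AnimalPlan:
    animal_id: str
    group: str                      # "treated" | "control"
    timepoints: tuple[str, ...]
    sacrifice_timepoint: str

    def __post_init__(self) -> None:
        if self.timepoints[0] != TIMEPOINTS[0]:
            raise ValueError(f"{self.animal_id}: every animal needs a pre/Day-0 scan")
        if self.sacrifice_timepoint not in self.timepoints:
            raise ValueError(f"{self.animal_id}: sacrifice time point "
                             f"{self.sacrifice_timepoint!r} is not scanned")


@dataclass(frozen=True)
class CohortDesign:
    """Longitudinal study structure.

    Default: 14 treated animals scanned pre and 1 h post-ablation, 7 of which
    are also scanned at 72 h (and sacrificed then; the other 7 are sacrificed
    after the 1 h scan), plus 7 non-treated controls scanned at the matching
    days and sacrificed after the last scan.
    """

    n_treated: int = 14
    n_treated_72h: int = 7
    n_control: int = 7

    def __post_init__(self) -> None:
        if self.n_treated < 1:
            raise ValueError("need at least one treated animal")
        if not 0 <= self.n_treated_72h <= self.n_treated:
            raise ValueError("n_treated_72h must be between 0 and n_treated")
        if self.n_control < 0:
            raise ValueError("n_control must be non-negative")

    def animals(self) -> list[AnimalPlan]:
        plans = []
        n_1h_only = self.n_treated - self.n_treated_72h
        for i in range(self.n_treated):
            aid = f"T{i + 1:02d}"
            if i < n_1h_only:
                plans.append(AnimalPlan(aid, "treated", TIMEPOINTS[:2], "post1h"))
            else:
                plans.append(AnimalPlan(aid, "treated", TIMEPOINTS, "post72h"))
        for i in range(self.n_control):
            plans.append(AnimalPlan(f"C{i + 1:02d}", "control", TIMEPOINTS, "post72h"))
        return plans

    @property
    def treated_ids(self) -> tuple[str, ...]:
        return tuple(p.animal_id for p in self.animals() if p.group == "treated")

    @property
    def control_ids(self) -> tuple[str, ...]:
        return tuple(p.animal_id for p in self.animals() if p.group == "control")


@dataclass(frozen=True)
class LesionSettings:
    """Lesion geometry, edema and hemorrhage settings.

    The non-viable core is an ellipsoid (same axis ratios as the tumor)
    centred at ``center_offset`` (in units of the tumor semi-axes) and grown
    between 1 h and 72 h; per-animal 1 h voxel fractions are taken from
    ``fractions_1h`` (cycled over treated animals), the 72 h fraction is
    ``growth_factor`` times the 1 h value unless ``fractions_72h`` is given.
    The edema rim is the outer in-plane shell of the tumor mask
    (``edema_thickness`` voxels); it is present at every time point, in
    controls too, since peritumoral edema is a property of the tumor rather
    than of the treatment. ``void_fraction`` of lesion voxels lose their
    signal (hemorrhage) at post-treatment time points.
    """

    fractions_1h: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)
    fractions_72h: tuple[float, ...] | None = None
    growth_factor: float = 1.5
    max_fraction: float = 0.9
    center_offset: tuple[float, float, float] = (0.35, 0.0, 0.0)
    edema: bool = True
    edema_thickness: int = 3
    edema_in_controls: bool = True
    void_fraction: float = 0.02
    tumor_rel_semiaxes: tuple[float, float, float] = (0.30, 0.30, 0.40)
    size_jitter: float = 0.06

    def __post_init__(self) -> None:
        fracs = list(self.fractions_1h) + list(self.fractions_72h or ())
        if any(not 0.0 <= f <= 0.9 for f in fracs):
            raise ValueError("requested lesion fractions must lie in [0, 0.9]")
        if self.growth_factor < 1.0:
            raise ValueError("lesion must not shrink between 1 h and 72 h")
        if not 0.0 <= self.void_fraction <= 1.0:
            raise ValueError("void fraction must lie in [0, 1]")

    def fraction_1h(self, i: int) -> float:
        return self.fractions_1h[i % len(self.fractions_1h)]

    def fraction_72h(self, i: int) -> float:
        if self.fractions_72h is not None:
            f = self.fractions_72h[i % len(self.fractions_72h)]
        else:
            f = min(self.growth_factor * self.fraction_1h(i), self.max_fraction)
        if f < self.fraction_1h(i) - 1e-12:
            raise ValueError("72 h lesion fraction must be >= the 1 h fraction")
        return f


@dataclass
class Scan:
    """One animal at one time point: ground truth, maps and raw series."""

    animal_id: str
    group: str
    timepoint: str
    truth: GroundTruthLabels
    maps: ParameterMapSet          # ground-truth maps (empty exclusion mask)
    s0: np.ndarray                 # equilibrium signal volume
    raw: RawSeriesSet | None = None


@dataclass
class Cohort:
    """A realized synthetic cohort."""

    design: CohortDesign
    protocol: AcquisitionProtocol
    tissues: dict[str, TissueClassParams]
    lesions: LesionSettings
    seed: int
    scans: dict[tuple[str, str], Scan] = field(default_factory=dict)

    def scan_keys(self) -> list[tuple[str, str]]:
        """Deterministic (animal, time point) order: animal id, then time."""
        order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
        return sorted(self.scans, key=lambda k: (k[0], order[k[1]]))

    def truth_maps(self) -> dict[tuple[str, str], ParameterMapSet]:
        return {k: self.scans[k].maps for k in self.scan_keys()}

    def sacrifice_scans(self) -> dict[str, Scan]:
        """Each animal's scan at its sacrifice time point (pairs with histology)."""
        out = {}
        for plan in self.design.animals():
            out[plan.animal_id] = self.scans[(plan.animal_id, plan.sacrifice_timepoint)]
        return out


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _ellipsoid_radius(shape: tuple[int, int, int],
                      center: np.ndarray,
                      semiaxes: np.ndarray) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return np.sqrt(r2)


def _rim_shell(tumor: np.ndarray, thickness: int) -> np.ndarray:
    """Outer in-plane shell of ``thickness`` voxels (2-D 4-connected erosion)."""
    cross = ndimage.generate_binary_structure(2, 1)
    eroded = np.zeros_like(tumor)
    for z in range(tumor.shape[2]):
        sl = tumor[:, :, z]
        if sl.any():
            eroded[:, :, z] = ndimage.binary_erosion(sl, structure=cross,
                                                     iterations=thickness)
    return tumor & ~eroded


# ---------------------------------------------------------------------------
# value draws and map synthesis
# ---------------------------------------------------------------------------

_R_FLOOR = 0.05      # s^-1; avoids infinite relaxation times
_ADC_FLOOR = 1.0e-5  # mm^2/s


def _draw_truncated(mean: float, sd: float, low: float, high: float,
                    size: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(np.clip(mean, low, high)))
    a = (low - mean) / sd
    b = (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _tissue_for_label(label: int, timepoint: str) -> str:
    if label == LABEL_VIABLE:
        return "viable"
    if label == LABEL_EDEMA:
        return "edema"
    if label == LABEL_MUSCLE:
        return "muscle"
    if label == LABEL_NONVIABLE:
        return "nonviable_72h" if timepoint == "post72h" else "nonviable_1h"
    raise ValueError(f"no tissue distribution for label {label}")


def _synthesize_maps(truth: GroundTruthLabels, timepoint: str,
                     tissues: Mapping[str, TissueClassParams],
                     protocol: AcquisitionProtocol,
                     rng: np.random.Generator) -> tuple[ParameterMapSet, np.ndarray]:
    shape = truth.labels.shape
    t1 = np.full(shape, np.nan)
    t2 = np.full(shape, np.nan)
    adc = np.full(shape, np.nan)
    mtr = np.full(shape, np.nan)
    for label in (LABEL_MUSCLE, LABEL_VIABLE, LABEL_NONVIABLE, LABEL_EDEMA):
        idx = truth.labels == label
        n = int(idx.sum())
        if n == 0:
            continue
        p = tissues[_tissue_for_label(label, timepoint)]
        r1 = _draw_truncated(p.r1_mean, p.r1_sd, _R_FLOOR, np.inf, n, rng)
        r2 = _draw_truncated(p.r2_mean, p.r2_sd, _R_FLOOR, np.inf, n, rng)
        t1[idx] = 1000.0 / r1
        t2[idx] = 1000.0 / r2
        adc[idx] = _draw_truncated(p.adc_mean, p.adc_sd, _ADC_FLOOR, np.inf, n, rng)
        mtr[idx] = _draw_truncated(p.mtr_mean, p.mtr_sd, 0.0, 100.0, n, rng)
    s0 = np.where((truth.labels != LABEL_BACKGROUND) & ~truth.void, protocol.s0, 0.0)
    maps = ParameterMapSet(t1_ms=t1, t2_ms=t2, adc=adc, mtr=mtr,
                           tumor_mask=truth.tumor_mask,
                           exclusion_mask=np.zeros(shape, dtype=bool),
                           voxel_size_mm=protocol.voxel_size_mm)
    return maps, s0


# ---------------------------------------------------------------------------
# forward signal model and noise
# ---------------------------------------------------------------------------

def simulate_signal_series(maps: ParameterMapSet, s0: np.ndarray,
                           protocol: AcquisitionProtocol) -> RawSeriesSet:
    """Forward-simulate noiseless raw series from ground-truth maps.

    Signal models: ``S(TE) = S0 exp(-TE/T2)``; ``S(b) = S0 exp(-b ADC)`` per
    direction (isotropic truth); a magnitude three-parameter Look-Locker
    inversion recovery with the apparent time constant implied by the flip
    angle and pulse separation; and an MT pair ``S_sat = S0 (1 - MTR/100)``.
    Voxels with ``s0 == 0`` (background, hemorrhage voids) produce zero
    signal.
    """
    s0 = np.asarray(s0, dtype=float)
    if s0.shape != protocol.shape:
        raise ValueError("s0 volume does not match the acquisition grid")
    live = s0 > 0
    inside = live & maps.tumor_mask
    for name in ("t1_ms", "t2_ms", "adc"):
        vals = getattr(maps, name)[inside]
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError(f"non-positive {name} inside the tumor mask")

    t1 = np.where(live, maps.t1_ms, np.nan)
    t2 = np.where(live, maps.t2_ms, np.nan)
    adc = np.where(live, maps.adc, np.nan)
    mtr = np.where(live, maps.mtr, np.nan)

    te = np.asarray(protocol.echo_times_ms)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        t2_series = s0[None] * np.exp(-te.reshape(-1, 1, 1, 1) / t2[None])
        b = np.asarray(protocol.b_values).reshape(1, -1, 1, 1, 1)
        decay = s0[None, None] * np.exp(-b * adc[None, None])
        dwi = np.broadcast_to(decay, (protocol.n_diffusion_directions,) + decay.shape[1:]).copy()

        # Look-Locker: apparent recovery shortened by the readout pulses
        cos_a = np.cos(np.deg2rad(protocol.ir_flip_deg))
        inv_t1_star = 1.0 / t1 - np.log(cos_a) / protocol.ir_spacing_ms
        t1_star = 1.0 / inv_t1_star
        a_amp = s0 * t1_star / t1
        b_amp = a_amp * (1.0 + t1 / t1_star)
        t_ir = protocol.ir_times_ms.reshape(-1, 1, 1, 1)
        ir = np.abs(a_amp[None] - b_amp[None] * np.exp(-t_ir / t1_star[None]))

        mt_unsat = s0.copy()
        mt_sat = s0 * (1.0 - mtr / 100.0)
        t2w = s0 * np.exp(-protocol.t2w_echo_time_ms / t2)

    def clean(arr):
        return np.nan_to_num(arr, nan=0.0, posinf=0.0, neginf=0.0)

    return RawSeriesSet(protocol=protocol, ir=clean(ir), t2_series=clean(t2_series),
                        dwi=clean(dwi), mt_unsat=clean(mt_unsat),
                        mt_sat=clean(mt_sat), t2w=clean(t2w))


def rician_sample(signal: np.ndarray, sigma: float,
                  rng: np.random.Generator, n_averages: int = 1) -> np.ndarray:
    """Rician magnitude sample(s) of a noiseless signal.

    Each draw is ``sqrt((s + g1)^2 + g2^2)`` with independent zero-mean
    Gaussians of SD ``sigma``; ``n_averages > 1`` returns the mean of that
    many independent draws (signal averaging reduces the noise SD but keeps
    the magnitude bias). ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    acc = np.zeros_like(signal)
    for _ in range(n_averages):
        g1 = rng.normal(0.0, sigma, size=signal.shape)
        g2 = rng.normal(0.0, sigma, size=signal.shape)
        acc += np.sqrt((signal + g1) ** 2 + g2 ** 2)
    return acc / n_averages


def add_rician_noise(series: RawSeriesSet, sigma: float, seed: int) -> RawSeriesSet:
    """Apply Rician noise to every series, honoring per-series averaging.

    Each acquisition in the protocol carries its own number of signal
    averages (the anatomical reference uses a single acquisition); noise is
    applied per average and the averages are then combined. ``sigma = 0``
    returns the input unchanged. Fully seeded.
    """
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    p = series.protocol
    rng = np.random.default_rng(seed)
    return RawSeriesSet(
        protocol=p,
        ir=rician_sample(series.ir, sigma, rng, p.ir_n_averages),
        t2_series=rician_sample(series.t2_series, sigma, rng, p.t2_n_averages),
        dwi=rician_sample(series.dwi, sigma, rng, p.dwi_n_averages),
        mt_unsat=rician_sample(series.mt_unsat, sigma, rng, p.mt_n_averages),
        mt_sat=rician_sample(series.mt_sat, sigma, rng, p.mt_n_averages),
        t2w=rician_sample(series.t2w, sigma, rng, 1),
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _animal_geometry(protocol: AcquisitionProtocol, lesions: LesionSettings,
                     rng: np.random.Generator):
    """Tumor mask and lesion-orderable radii for one animal."""
    shape = protocol.shape
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    jitter = 1.0 + lesions.size_jitter * (2.0 * rng.random() - 1.0)
    semi = np.asarray(lesions.tumor_rel_semiaxes) * np.asarray(shape) * jitter
    tumor = _ellipsoid_radius(shape, center, semi) <= 1.0

    lesion_center = center + np.asarray(lesions.center_offset) * semi
    radius = _ellipsoid_radius(shape, lesion_center, semi)
    # rank tumor voxels by distance from the lesion centre: the k nearest
    # voxels form the lesion, so the 72 h region is a superset of 1 h exactly
    flat_idx = np.flatnonzero(tumor)
    order = flat_idx[np.argsort(radius.ravel()[flat_idx], kind="stable")]
    return tumor, order


def _lesion_mask(shape, order: np.ndarray, k: int) -> np.ndarray:
    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(shape)


def _build_truth(tumor: np.ndarray, lesion: np.ndarray, muscle: np.ndarray,
                 edema_rim: np.ndarray | None, void_fraction: float,
                 rng: np.random.Generator) -> GroundTruthLabels:
    labels = np.full(tumor.shape, LABEL_BACKGROUND, dtype=np.int8)
    labels[muscle] = LABEL_MUSCLE
    labels[tumor] = LABEL_VIABLE
    if edema_rim is not None:
        labels[edema_rim & tumor & ~lesion] = LABEL_EDEMA
    labels[lesion] = LABEL_NONVIABLE

    void = np.zeros(tumor.shape, dtype=bool)
    n_lesion = int(lesion.sum())
    if void_fraction > 0 and n_lesion > 0:
        n_void = int(round(void_fraction * n_lesion))
        if n_void > 0:
            flat = np.flatnonzero(lesion)
            chosen = rng.choice(flat, size=n_void, replace=False)
            void.ravel()[chosen] = True

    n_tumor = int(tumor.sum())
    frac = int(lesion.sum()) / n_tumor if n_tumor else 0.0
    return GroundTruthLabels(labels=labels, void=void, true_nonviable_fraction=frac)


def generate_cohort(design: CohortDesign | None = None,
                    protocol: AcquisitionProtocol | None = None,
                    tissues: Mapping[str, TissueClassParams] | None = None,
                    lesions: LesionSettings | None = None,
                    seed: int = 0,
                    include_raw: bool = True,
                    noise_sigma: float | None = None) -> Cohort:
    """Generate a full longitudinal cohort with ground truth.

    Treated animals have no lesion at the pre scan, a non-viable core at 1 h
    and an enlarged (superset) core at 72 h; controls have zero non-viable
    voxels at every time point. Parameter values are drawn per tissue class
    from truncated Gaussians, independently per time point. With
    ``include_raw`` the raw series are forward-simulated and Rician noise of
    SD ``noise_sigma`` (default: the protocol's) is added. Bit-reproducible
    for a fixed ``seed``.
    """
    design = design or CohortDesign()
    protocol = protocol or AcquisitionProtocol()
    tissues = dict(tissues or default_tissue_params())
    lesions = lesions or LesionSettings()
    sigma = protocol.noise_sigma if noise_sigma is None else noise_sigma

    cohort = Cohort(design=design, protocol=protocol, tissues=tissues,
                    lesions=lesions, seed=seed)
    root = np.random.SeedSequence(seed)
    plans = design.animals()
    animal_seqs = root.spawn(len(plans))

    treated_index = 0
    for plan, seq in zip(plans, animal_seqs):
        geom_rng = np.random.default_rng(seq.spawn(1)[0])
        tumor, order = _animal_geometry(protocol, lesions, geom_rng)
        n_tumor = int(tumor.sum())
        muscle = (_ellipsoid_radius(
            tumor.shape, (np.asarray(tumor.shape) - 1.0) / 2.0,
            np.asarray(lesions.tumor_rel_semiaxes) * np.asarray(tumor.shape) * 1.4,
        ) <= 1.0) & ~tumor

        if plan.group == "treated":
            f1h = lesions.fraction_1h(treated_index)
            f72h = lesions.fraction_72h(treated_index)
            treated_index += 1
        else:
            f1h = f72h = 0.0
        k_by_tp = {"pre": 0,
                   "post1h": int(round(f1h * n_tumor)),
                   "post72h": int(round(f72h * n_tumor))}
        if k_by_tp["post72h"] < k_by_tp["post1h"]:
            k_by_tp["post72h"] = k_by_tp["post1h"]

        edema_rim = None
        if lesions.edema and (plan.group == "treated" or lesions.edema_in_controls):
            edema_rim = _rim_shell(tumor, lesions.edema_thickness)

        scan_seqs = seq.spawn(len(plan.timepoints))
        for tp, scan_seq in zip(plan.timepoints, scan_seqs):
            rng = np.random.default_rng(scan_seq)
            lesion = _lesion_mask(tumor.shape, order, k_by_tp[tp])
            void_frac = lesions.void_fraction if tp != "pre" else 0.0
            truth = _build_truth(tumor, lesion, muscle, edema_rim, void_frac, rng)
            maps, s0 = _synthesize_maps(truth, tp, tissues, protocol, rng)
            raw = None
            if include_raw:
                raw = simulate_signal_series(maps, s0, protocol)
                noise_seed = int(scan_seq.generate_state(1, np.uint32)[0]) % (2 ** 31)
                raw = add_rician_noise(raw, sigma, noise_seed)
            cohort.scans[(plan.animal_id, tp)] = Scan(
                animal_id=plan.animal_id, group=plan.group, timepoint=tp,
                truth=truth, maps=maps, s0=s0, raw=raw)
    return cohort


# ---------------------------------------------------------------------------
# synthetic histology
# ---------------------------------------------------------------------------

def simulate_histology(truth: GroundTruthLabels,
                       voxel_size_mm: tuple[float, float, float],
                       section_spacing_mm: float = 0.3,
                       area_noise_cv: float = 0.05,
                       seed: int = 0) -> list[tuple[float, float]]:
    """Sparse-section histology: (non-viable area, total area) per section.

    Sections are sampled along the slice axis at ``section_spacing_mm``
    across the tumor extent; each section reports the non-viable and total
    tumor areas of the MRI slice it falls in (mm^2), independently perturbed
    by multiplicative noise of coefficient of variation ``area_noise_cv``.
    With zero noise and one section per slice the aggregated area ratio
    equals the true volume fraction exactly.
    """
    if section_spacing_mm <= 0:
        raise ValueError("section spacing must be positive")
    if area_noise_cv < 0:
        raise ValueError("area noise CV must be non-negative")
    rng = np.random.default_rng(seed)
    tumor = truth.tumor_mask
    lesion = truth.nonviable_mask
    pixel_area = voxel_size_mm[0] * voxel_size_mm[1]
    thickness = voxel_size_mm[2]

    slices = np.flatnonzero(tumor.any(axis=(0, 1)))
    if slices.size == 0:
        raise ValueError("empty tumor mask")
    z0, z1 = slices[0], slices[-1]
    extent = (z1 - z0 + 1) * thickness
    positions = np.arange(section_spacing_mm / 2.0, extent, section_spacing_mm)
    if positions.size < 2:
        warnings.warn("fewer than two histology sections span the tumor",
                      stacklevel=2)
    sections = []
    for pos in positions:
        z = z0 + min(int(pos // thickness), z1 - z0)
        total = float(tumor[:, :, z].sum()) * pixel_area
        nonviable = float(lesion[:, :, z].sum()) * pixel_area
        if area_noise_cv > 0:
            nonviable *= max(0.0, 1.0 + area_noise_cv * rng.standard_normal())
            total *= max(0.0, 1.0 + area_noise_cv * rng.standard_normal())
            nonviable = min(nonviable, total)
        sections.append((nonviable, total))
    return sections


def simulate_cohort_histology(cohort: Cohort,
                              section_spacing_mm: float = 0.3,
                              area_noise_cv: float = 0.05,
                              seed: int = 0) -> dict[str, list[tuple[float, float]]]:
    """Histology sections for every animal's sacrifice-time tumor."""
    root = np.random.SeedSequence(seed)
    sacrifice = cohort.sacrifice_scans()
    out: dict[str, list[tuple[float, float]]] = {}
    for aid, seq in zip(sorted(sacrifice), root.spawn(len(sacrifice))):
        scan = sacrifice[aid]
        child_seed = int(seq.generate_state(1, np.uint32)[0]) % (2 ** 31)
        out[aid] = simulate_histology(scan.truth, cohort.protocol.voxel_size_mm,
                                      section_spacing_mm, area_noise_cv,
                                      seed=child_seed)
    return out
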