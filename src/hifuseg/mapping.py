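"""Voxelwise quantitative MRI parameter mapping.

Fits the four quantitative maps used throughout the package from raw signal
series:

* T2 — mono-exponential fit of a multi-echo series, ``S(TE) = S0 exp(-TE/T2)``;
* ADC — mono-exponential fit of the diffusion decay ``S(b) = S0 exp(-b ADC)``
  per encoding direction, averaged over the three orthogonal directions to an
  orientation-invariant value;
* T1 — three-parameter Look-Locker model ``S(t) = A - B exp(-t/T1*)`` fitted to
  inversion-recovery magnitude data with polarity restoration, corrected to the
  true longitudinal time via ``T1 = T1* (B/A - 1)``;
* MTR — two-point magnetization-transfer ratio ``(1 - S/S0) * 100`` in percent.

All fitters are vectorized over voxels: mono-exponential fits use a weighted
log-linear initialization refined by damped Gauss-Newton steps, and the
Look-Locker fit uses variable projection (the amplitudes A, B are solved in
closed form for each candidate apparent time constant) with a coarse
logarithmic grid followed by a golden-section refinement.

Voxels whose series cannot be fitted (non-finite samples, zero decay where a
decay is required, non-physical Look-Locker amplitudes) are flagged rather than
imputed; the map-fitting driver folds them into the exclusion mask together
with voxels whose anatomical-reference signal is at noise level.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import RawSeriesSet

__all__ = [
    "FEATURE_NAMES",
    "ParameterMapSet",
    "fit_monoexponential",
    "fit_t2_monoexp",
    "fit_adc",
    "fit_t1_look_locker",
    "compute_mtr",
    "build_exclusion_mask",
    "fit_parameter_maps",
]

#: Canonical order of the quantitative features used for clustering.
FEATURE_NAMES = ("T1", "T2", "ADC", "MTR")


@dataclass
class ParameterMapSet:
    """Co-registered quantitative maps for one animal at one time point.

    T1 and T2 are stored in milliseconds, ADC in mm^2/s and MTR in percent.
    ``exclusion_mask`` marks tumor voxels dropped from analysis (noise-level
    reference signal or unfittable series) and is always a subset of
    ``tumor_mask``. Voxels outside the tumor may hold NaN.
    """

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    adc: np.ndarray
    mtr: np.ndarray
    tumor_mask: np.ndarray
    exclusion_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (0.3125, 0.3125, 1.0)

    def __post_init__(self) -> None:
        shape = np.shape(self.t1_ms)
        for name in ("t2_ms", "adc", "mtr", "tumor_mask", "exclusion_mask"):
            if np.shape(getattr(self, name)) != shape:
                raise ValueError(f"{name} shape {np.shape(getattr(self, name))} "
                                 f"does not match map grid {shape}")
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
        if np.any(self.exclusion_mask & ~self.tumor_mask):
            raise ValueError("exclusion mask must be a subset of the tumor mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t1_ms.shape

    @property
    def included_mask(self) -> np.ndarray:
        """Tumor voxels that enter clustering (tumor minus exclusions)."""
        return self.tumor_mask & ~self.exclusion_mask

    @property
    def r1_per_s(self) -> np.ndarray:
        """Longitudinal relaxation rate R1 = 1/T1 in s^-1, voxelwise."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return 1000.0 / self.t1_ms

    @property
    def r2_per_s(self) -> np.ndarray:
        """Transverse relaxation rate R2 = 1/T2 in s^-1, voxelwise."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return 1000.0 / self.t2_ms

    def feature_volume(self, name: str) -> np.ndarray:
        """Return the volume for feature ``name`` in {T1, T2, ADC, MTR}."""
        try:
            return {"T1": self.t1_ms, "T2": self.t2_ms,
                    "ADC": self.adc, "MTR": self.mtr}[name]
        except KeyError:
            raise KeyError(f"unknown feature {name!r}; expected one of {FEATURE_NAMES}")

    def excluded_fraction(self) -> float:
        """Fraction of tumor voxels carrying the exclusion flag."""
        n_tumor = int(self.tumor_mask.sum())
        if n_tumor == 0:
            return 0.0
        return float(self.exclusion_mask.sum()) / n_tumor


# ---------------------------------------------------------------------------
# mono-exponential fitting (shared by T2 and ADC)
# ---------------------------------------------------------------------------

def _as_2d(signals: np.ndarray, n_samples: int) -> tuple[np.ndarray, tuple[int, ...]]:
    y = np.asarray(signals, dtype=float)
    if y.shape[-1] != n_samples:
        raise ValueError(f"series length {y.shape[-1]} does not match "
                         f"{n_samples} sample points")
    lead = y.shape[:-1]
    return y.reshape(-1, n_samples), lead


def _monoexp_gauss_newton(y: np.ndarray, x: np.ndarray, a: np.ndarray,
                          r: np.ndarray, n_iter: int = 30,
                          tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Refine ``y ~ exp(a - r x)`` by damped Gauss-Newton, vectorized over rows."""

    def sse(a_, r_):
        f = np.exp(a_[:, None] - r_[:, None] * x[None, :])
        return ((y - f) ** 2).sum(axis=1)

    cur = sse(a, r)
    for _ in range(n_iter):
        f = np.exp(a[:, None] - r[:, None] * x[None, :])
        res = y - f
        f2 = f * f
        g_aa = f2.sum(axis=1)
        g_ar = -(x[None, :] * f2).sum(axis=1)
        g_rr = (x[None, :] ** 2 * f2).sum(axis=1)
        b_a = (f * res).sum(axis=1)
        b_r = -(x[None, :] * f * res).sum(axis=1)
        det = g_aa * g_rr - g_ar * g_ar
        safe = np.abs(det) > 1e-300
        da = np.where(safe, (b_a * g_rr - g_ar * b_r) / np.where(safe, det, 1.0), 0.0)
        dr = np.where(safe, (g_aa * b_r - g_ar * b_a) / np.where(safe, det, 1.0), 0.0)
        # step halving where the full step overshoots
        step = np.ones_like(da)
        for _ in range(12):
            new = sse(a + step * da, r + step * dr)
            worse = new > cur + 1e-30
            if not np.any(worse):
                break
            step[worse] *= 0.5
        a = a + step * da
        r = r + step * dr
        cur = sse(a, r)
        if np.max(np.abs(step * da)) < tol and np.max(np.abs(step * dr)) < tol:
            break
    return a, r


def fit_monoexponential(signals: np.ndarray, x: np.ndarray,
                        refine: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares fit of ``S = S0 exp(-rate * x)`` per row.

    Parameters
    ----------
    signals
        Array of shape ``(..., len(x))``.
    x
        Sample abscissa (echo times in ms, or b-values in s/mm^2).
    refine
        Apply Gauss-Newton refinement after the weighted log-linear
        initialization (recommended for noisy data; exact data are already
        recovered by the initialization).

    Returns
    -------
    rate, s0, ok
        Decay rate (1/units of ``x``), amplitude, and a finite/fittable flag
        per row. Rows with non-finite or entirely non-positive samples are
        flagged unfittable and carry NaN.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two sample points")
    y, lead = _as_2d(signals, x.size)

    finite = np.isfinite(y).all(axis=1)
    has_signal = finite & (np.nanmax(np.where(np.isfinite(y), y, -np.inf), axis=1) > 0)

    yc = np.where(y > 0, y, np.nan)
    # weighted log-linear fit: weights y^2 make it the small-noise ML estimate
    with np.errstate(invalid="ignore", divide="ignore"):
        ln = np.log(yc)
    w = np.where(np.isfinite(ln), y * y, 0.0)
    ln = np.where(np.isfinite(ln), ln, 0.0)
    sw = w.sum(axis=1)
    ok = has_signal & (sw > 0) & ((w > 0).sum(axis=1) >= 2)
    sw = np.where(sw > 0, sw, 1.0)
    xw = (w * x[None, :]).sum(axis=1) / sw
    lw = (w * ln).sum(axis=1) / sw
    sxx = (w * (x[None, :] - xw[:, None]) ** 2).sum(axis=1)
    sxl = (w * (x[None, :] - xw[:, None]) * (ln - lw[:, None])).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0, sxl / np.where(sxx > 0, sxx, 1.0), 0.0)
    rate = -slope
    a = lw + rate * xw  # ln S0

    if refine and np.any(ok):
        idx = np.nonzero(ok)[0]
        a_r, rate_r = _monoexp_gauss_newton(y[idx], x, a[idx], rate[idx])
        a[idx] = a_r
        rate[idx] = rate_r

    rate = np.where(ok, rate, np.nan)
    s0 = np.where(ok, np.exp(a), np.nan)
    return rate.reshape(lead), s0.reshape(lead), ok.reshape(lead)


def fit_t2_monoexp(signals: np.ndarray,
                   echo_times_ms: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``S(TE) = S0 exp(-TE/T2)`` per voxel.

    Returns ``(t2_ms, s0, ok)``. Voxels with zero or negative decay (constant
    or growing series) get ``t2 = inf`` and are flagged unfittable, mirroring
    the exclusion of non-decaying pixels rather than crashing.
    """
    rate, s0, ok = fit_monoexponential(signals, np.asarray(echo_times_ms, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = 1.0 / rate
    decaying = ok & np.isfinite(rate) & (rate > 0)
    t2 = np.where(decaying, t2, np.inf)
    t2 = np.where(ok, t2, np.nan)
    return t2, s0, decaying


def fit_adc(signals: np.ndarray,
            b_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Direction-averaged apparent diffusion coefficient.

    Parameters
    ----------
    signals
        Array of shape ``(..., n_directions, len(b_values))`` — one diffusion
        decay per encoding direction.
    b_values
        Diffusion weightings in s/mm^2 (non-negative, strictly increasing).

    Returns
    -------
    adc, ok
        ADC in mm^2/s (arithmetic mean of the per-direction rates, invariant
        under permutation of the direction labels) and a validity flag.
        Negative ADC (signal increase with b) is returned but flagged.
    """
    b = np.asarray(b_values, dtype=float)
    if np.any(np.diff(b) <= 0) or np.any(b < 0):
        raise ValueError("b-values must be non-negative and strictly increasing")
    y = np.asarray(signals, dtype=float)
    if y.ndim < 2:
        raise ValueError("signals must have shape (..., n_directions, n_b)")
    rate, _, okdir = fit_monoexponential(y, b)
    adc = rate.mean(axis=-1)
    adc = np.where(np.abs(adc) < 1e-16, 0.0, adc)  # exact-flat decay
    ok = okdir.all(axis=-1) & np.isfinite(adc) & (adc >= 0)
    return adc, ok


# ---------------------------------------------------------------------------
# Look-Locker T1
# ---------------------------------------------------------------------------

def _ll_solve(y: np.ndarray, t: np.ndarray,
              tau: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form (A, B) and SSE for ``y ~ A - B exp(-t/tau)`` per row."""
    e = np.exp(-t[None, :] / tau[:, None])
    m = float(t.size)
    se = e.sum(axis=1)
    see = (e * e).sum(axis=1)
    sy = y.sum(axis=1)
    sye = (y * e).sum(axis=1)
    det = m * see - se * se
    safe = np.abs(det) > 1e-12
    det_s = np.where(safe, det, 1.0)
    a = np.where(safe, (sy * see - se * sye) / det_s, sy / m)
    b = np.where(safe, (se * sy - m * sye) / det_s, 0.0)
    sse = (y * y).sum(axis=1) - a * sy + b * sye
    sse = np.where(safe, sse, np.inf)
    return a, b, np.maximum(sse, 0.0)


def fit_t1_look_locker(signals: np.ndarray, sample_times_ms: np.ndarray,
                       magnitude: bool = True,
                       t1_star_bounds: tuple[float, float] = (5.0, 2.0e4),
                       n_grid: int = 40, n_golden: int = 80,
                       full_output: bool = False):
    """Fit the three-parameter Look-Locker model and apply the flip correction.

    The apparent recovery ``S(t) = A - B exp(-t/T1*)`` is fitted by variable
    projection: for each candidate ``T1*`` the amplitudes solve a 2x2 linear
    system, so only the time constant is searched (coarse log grid plus
    golden-section refinement). For magnitude data the inversion polarity is
    restored by trying sign-flip positions around the signal minimum and
    keeping the fit with the lowest residual. The corrected longitudinal
    relaxation time is ``T1 = T1* (B/A - 1)``.

    Returns ``(t1_ms, ok)``; with ``full_output=True`` also the dict of
    ``t1_star_ms``, ``a``, ``b`` and ``sse``. Voxels with ``A <= 0`` or
    ``B/A <= 1`` (non-physical, e.g. zero effective inversion) get the
    sentinel ``t1 = 0`` and are flagged.
    """
    t = np.asarray(sample_times_ms, dtype=float)
    if t.size < 3:
        raise ValueError("Look-Locker fit needs at least three sample times")
    y, lead = _as_2d(signals, t.size)
    n = y.shape[0]

    if magnitude:
        jmin = np.argmin(np.abs(y), axis=1)
        cand = np.stack([np.zeros(n, dtype=int),
                         np.maximum(jmin - 1, 0), jmin,
                         np.minimum(jmin + 1, t.size)], axis=1)
    else:
        cand = np.zeros((n, 1), dtype=int)

    grid = np.geomspace(t1_star_bounds[0], t1_star_bounds[1], n_grid)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    idx = np.arange(t.size)

    # each polarity candidate is refined to convergence before comparison, so
    # a degenerate series cannot be claimed by a coarsely-gridded wrong flip
    best = None
    for c in range(cand.shape[1]):
        signs = np.where(idx[None, :] < cand[:, c][:, None], -1.0, 1.0)
        ys = y * signs
        grid_sse = np.empty((n_grid, n))
        for gi, tau in enumerate(grid):
            _, _, grid_sse[gi] = _ll_solve(ys, t, np.full(n, tau))
        gi_best = np.argmin(grid_sse, axis=0)
        lo = grid[np.maximum(gi_best - 1, 0)]
        hi = grid[np.minimum(gi_best + 1, n_grid - 1)]
        for _ in range(n_golden):
            x1 = hi - invphi * (hi - lo)
            x2 = lo + invphi * (hi - lo)
            _, _, f1 = _ll_solve(ys, t, x1)
            _, _, f2 = _ll_solve(ys, t, x2)
            first = f1 < f2
            hi = np.where(first, x2, hi)
            lo = np.where(first, lo, x1)
        tau_c = 0.5 * (lo + hi)
        a_c, b_c, sse_c = _ll_solve(ys, t, tau_c)
        if best is None:
            best = [tau_c, a_c, b_c, sse_c]
        else:
            win = sse_c < best[3]
            for i, arr in enumerate((tau_c, a_c, b_c, sse_c)):
                best[i] = np.where(win, arr, best[i])
    tau, a, b, sse = best

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(a != 0, b / a, np.nan)
    # strict margin so an exactly saturating recovery (B = A) flags reliably
    ok = np.isfinite(ratio) & (a > 0) & (ratio > 1.0 + 1e-9)
    t1 = np.where(ok, tau * (ratio - 1.0), 0.0)

    t1 = t1.reshape(lead)
    ok = ok.reshape(lead)
    if full_output:
        extra = {"t1_star_ms": tau.reshape(lead), "a": a.reshape(lead),
                 "b": b.reshape(lead), "sse": sse.reshape(lead)}
        return t1, ok, extra
    return t1, ok


# ---------------------------------------------------------------------------
# MTR and exclusion mask
# ---------------------------------------------------------------------------

def compute_mtr(s_sat: np.ndarray, s_unsat: np.ndarray) -> np.ndarray:
    """Magnetization transfer ratio ``(1 - S/S0) * 100`` in percent.

    ``S0`` (unsaturated) must be positive; voxels with ``S0 <= 0`` return NaN
    so the caller can fold them into the exclusion mask.
    """
    s = np.asarray(s_sat, dtype=float)
    s0 = np.asarray(s_unsat, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mtr = (1.0 - s / s0) * 100.0
    return np.where(s0 > 0, mtr, np.nan)


def build_exclusion_mask(reference: np.ndarray, tumor_mask: np.ndarray,
                         background_mask: np.ndarray,
                         k: float = 3.0) -> tuple[np.ndarray, float]:
    """Flag tumor voxels whose reference signal is at noise level.

    The noise statistics are estimated from ``background_mask`` (non-tissue
    voxels of the anatomical T2-weighted reference); tumor voxels below
    ``mean_bg + k * sd_bg`` are excluded — hemorrhage-induced signal voids in
    particular fall below this threshold.

    Returns the boolean exclusion mask and the excluded fraction of tumor
    voxels.
    """
    reference = np.asarray(reference, dtype=float)
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    bg = reference[background_mask]
    if bg.size == 0:
        raise ValueError("empty background sample; cannot estimate noise level")
    threshold = bg.mean() + k * bg.std()
    mask = tumor_mask & (reference < threshold)
    n_tumor = int(tumor_mask.sum())
    frac = float(mask.sum()) / n_tumor if n_tumor else 0.0
    return mask, frac


def fit_parameter_maps(raw: "RawSeriesSet", tumor_mask: np.ndarray,
                       background_mask: np.ndarray, k: float = 3.0,
                       fit_outside_tumor: bool = False) -> ParameterMapSet:
    """Fit all four parameter maps from a raw series set.

    Only tumor voxels are fitted (maps are NaN elsewhere) unless
    ``fit_outside_tumor`` is set. Unfittable voxels and voxels at noise level
    in the T2-weighted reference are folded into the exclusion mask.
    """
    protocol = raw.protocol
    shape = protocol.shape
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if tumor_mask.shape != shape:
        raise ValueError("tumor mask does not match the acquisition grid")
    sel = np.ones(shape, dtype=bool) if fit_outside_tumor else tumor_mask

    t1_map = np.full(shape, np.nan)
    t2_map = np.full(shape, np.nan)
    adc_map = np.full(shape, np.nan)
    mtr_map = np.full(shape, np.nan)

    # series arrays are (n_samples, *grid); voxel-major views for fitting
    ir = np.moveaxis(raw.ir, 0, -1)[sel]
    te = np.moveaxis(raw.t2_series, 0, -1)[sel]
    dwi = np.moveaxis(raw.dwi, (0, 1), (-2, -1))[sel]

    t2, _, ok_t2 = fit_t2_monoexp(te, protocol.echo_times_ms)
    adc, ok_adc = fit_adc(dwi, protocol.b_values)
    t1, ok_t1 = fit_t1_look_locker(ir, protocol.ir_times_ms)
    mtr = compute_mtr(raw.mt_sat[sel], raw.mt_unsat[sel])
    ok_mtr = np.isfinite(mtr)

    t1_map[sel] = np.where(ok_t1, t1, np.nan)
    t2_map[sel] = np.where(ok_t2, t2, np.nan)
    adc_map[sel] = np.where(ok_adc, adc, np.nan)
    mtr_map[sel] = mtr

    exclusion, _ = build_exclusion_mask(raw.t2w, tumor_mask, background_mask, k=k)
    unfittable = np.zeros(shape, dtype=bool)
    unfittable[sel] = ~(ok_t1 & ok_t2 & ok_adc & ok_mtr)
    exclusion |= unfittable & tumor_mask

    return ParameterMapSet(t1_ms=t1_map, t2_ms=t2_map, adc=adc_map, mtr=mtr_map,
                           tumor_mask=tumor_mask, exclusion_mask=exclusion,
                           voxel_size_mm=protocol.voxel_size_mm)
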