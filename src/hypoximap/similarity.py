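"""Similarity statistic and threshold calibration against pimonidazole.

The agreement between MRI-derived and pimonidazole hypoxic fractions is
scored with an adapted, slope-sensitive version of the Pearson correlation:

    Similarity(x, y) = sum_i (x_i - xbar)(y_i - ybar)
                       / [ (N - 1) * (var(x) + var(y)) / 2 ]
                     = 2 cov(x, y) / (var(x) + var(y))

It equals 1 exactly when y = x + constant (perfect correlation with slope 1)
and is below 1 for imperfect correlation or any other slope, which makes it
suitable for calibrating a threshold so that HF_MRI matches HF_PIM one-to-one
rather than merely co-varying with it.  Calibration sweeps the threshold(s)
over a grid, computes HF_MRI for every tumor at each candidate, and picks the
candidate maximizing the Similarity against HF_PIM (ties broken toward
smaller thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .classify import HypoxiaRule, classify_voxels, hf_curve, _canonical_strategy
from .cohorts import TumorObservation
from .maps import ParameterMaps

__all__ = [
    "similarity",
    "agreement_stats",
    "AgreementStats",
    "ThresholdGrid",
    "CalibrationResult",
    "calibrate_1d",
    "calibrate_2d",
    "default_preclinical_grid",
]


def similarity(x, y) -> float:
    """The adapted slope-sensitive correlation, 2 cov(x,y)/(var x + var y).

    Symmetric in its arguments and bounded by [-1, 1]; equals 1 iff
    y = x + constant.  Undefined (raises ValueError) when both inputs are
    constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    # guard against exactly-constant inputs whose variance only survives as
    # float cancellation residue
    scale = max(1.0, x.mean() ** 2 + y.mean() ** 2)
    if vx + vy <= 1e-20 * scale:
        raise ValueError("similarity undefined: zero total variance")
    cov = np.sum((x - x.mean()) * (y - y.mean())) / (n - 1)
    return float(2.0 * cov / (vx + vy))


@dataclass(frozen=True)
class AgreementStats:
    """Pearson r^2 with two-sided p-value, and the OLS line y = a + b x."""

    r2: float
    p_value: float
    slope: float
    intercept: float


def agreement_stats(x, y) -> AgreementStats:
    """Squared Pearson correlation (with p) and ordinary least-squares fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("agreement statistics undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return AgreementStats(
        r2=float(r**2), p_value=float(p), slope=float(fit.slope), intercept=float(fit.intercept)
    )


@dataclass(frozen=True)
class ThresholdGrid:
    """Ordered candidate thresholds for K0trans (min^-1) and/or ve0."""

    k0trans_values: np.ndarray | None = None
    ve0_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("k0trans_values", "ve0_values"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if v.ndim != 1 or v.size == 0:
                raise ValueError(f"{name} must be a non-empty 1-D array")
            if np.any(v <= 0) or np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} must be positive and strictly increasing")
            object.__setattr__(self, name, v)


def default_preclinical_grid(strategy: str) -> ThresholdGrid:
    """Default calibration grids bracketing plausible preclinical optima.

    K0trans: 0.001–0.100 min^-1 in steps of 0.001.  ve0: 0.01–1.0 in steps
    of 0.01 for the conjunction, and 50 log-spaced points over 0.1–16 for
    the weighted sum (whose useful ve0 range extends far above 1).
    """
    strategy = _canonical_strategy(strategy)
    k0 = np.round(np.arange(0.001, 0.1001, 0.001), 10)
    if strategy == "ktrans_only":
        return ThresholdGrid(k0trans_values=k0)
    if strategy == "ve_only":
        return ThresholdGrid(ve0_values=np.round(np.arange(0.01, 1.001, 0.01), 10))
    if strategy == "conjunction":
        return ThresholdGrid(
            k0trans_values=k0, ve0_values=np.round(np.arange(0.01, 1.001, 0.01), 10)
        )
    return ThresholdGrid(
        k0trans_values=k0, ve0_values=np.geomspace(0.1, 16.0, 50)
    )


@dataclass
class CalibrationResult:
    """Outcome of a Similarity threshold sweep.

    ``similarity_surface`` has one value per grid point (1-D for strategies
    i/ii, shape (n_k0, n_ve0) for iii/iv); NaN marks grid points where the
    Similarity is undefined.  ``optimal_rule`` is None when every grid point
    is undefined (``all_undefined``).
    """

    strategy: str
    grid: ThresholdGrid
    similarity_surface: np.ndarray
    optimal_rule: HypoxiaRule | None
    similarity_at_optimum: float
    stats_at_optimum: AgreementStats | None
    hf_mri_at_optimum: np.ndarray | None
    hf_pim: np.ndarray
    all_undefined: bool = False
    # 2-D sweeps also expose the two profile curves through the optimum.
    profile_vs_k0trans: np.ndarray | None = None
    profile_vs_ve0: np.ndarray | None = None


def _viable(maps: ParameterMaps) -> tuple[np.ndarray, np.ndarray]:
    kt, ve = maps.roi_values()
    ok = np.isfinite(kt) & np.isfinite(ve) & (ve <= 1.0)
    if not ok.any():
        raise ValueError("tumor has no classifiable voxel")
    return kt[ok], ve[ok]


def _similarity_columns(hf_matrix: np.ndarray, hf_pim: np.ndarray) -> np.ndarray:
    """Similarity of each column of ``hf_matrix`` against ``hf_pim`` (NaN
    where the total variance vanishes)."""
    y = hf_pim
    n = y.size
    vy = y.var(ddof=1)
    xc = hf_matrix - hf_matrix.mean(axis=0, keepdims=True)
    vx = np.sum(xc**2, axis=0) / (n - 1)
    cov = (xc * (y - y.mean())[:, None]).sum(axis=0) / (n - 1)
    denom = vx + vy
    scale = max(1.0, float(y.mean() ** 2)) + np.maximum(1.0, hf_matrix.mean(axis=0) ** 2)
    defined = denom > 1e-20 * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(defined, 2.0 * cov / denom, np.nan)
    return sim


def _gather(tumors: Sequence[TumorObservation], maps: Mapping[str, ParameterMaps]):
    if len(tumors) < 3:
        raise ValueError("calibration needs at least 3 tumors")
    hf_pim = np.array([t.hf_pim for t in tumors], dtype=float)
    viable = [_viable(maps[t.tumor_id]) for t in tumors]
    return hf_pim, viable


def _finalize(strategy, grid, surface, hf_matrix_at, hf_pim, k0_opt, ve0_opt,
              profile_k=None, profile_v=None) -> CalibrationResult:
    if np.all(np.isnan(surface)):
        return CalibrationResult(
            strategy=strategy, grid=grid, similarity_surface=surface,
            optimal_rule=None, similarity_at_optimum=float("nan"),
            stats_at_optimum=None, hf_mri_at_optimum=None, hf_pim=hf_pim,
            all_undefined=True,
        )
    rule = HypoxiaRule(strategy=strategy, k0trans=k0_opt, ve0=ve0_opt)
    try:
        st = agreement_stats(hf_matrix_at, hf_pim)
    except ValueError:
        st = None
    return CalibrationResult(
        strategy=strategy, grid=grid, similarity_surface=surface,
        optimal_rule=rule,
        similarity_at_optimum=float(np.nanmax(surface)),
        stats_at_optimum=st, hf_mri_at_optimum=hf_matrix_at, hf_pim=hf_pim,
        profile_vs_k0trans=profile_k, profile_vs_ve0=profile_v,
    )


def calibrate_1d(
    tumors: Sequence[TumorObservation],
    maps: Mapping[str, ParameterMaps],
    strategy: str,
    grid: ThresholdGrid | None = None,
) -> CalibrationResult:
    """Sweep a single threshold (strategy i or ii) maximizing Similarity.

    For every candidate threshold, HF_MRI is computed for each tumor over
    its viable voxels and compared with HF_PIM; the argmax of the resulting
    Similarity curve is the calibrated threshold (first, i.e. smallest, on
    ties).  Grid points with undefined Similarity are NaN and excluded.
    """
    strategy = _canonical_strategy(strategy)
    if strategy not in ("ktrans_only", "ve_only"):
        raise ValueError("calibrate_1d needs strategy i (ktrans_only) or ii (ve_only)")
    if grid is None:
        grid = default_preclinical_grid(strategy)
    thr = grid.k0trans_values if strategy == "ktrans_only" else grid.ve0_values
    if thr is None:
        raise ValueError("grid lacks the threshold axis required by the strategy")
    hf_pim, viable = _gather(tumors, maps)
    hf_matrix = np.stack([hf_curve(kt, ve, strategy, thr) for kt, ve in viable])
    sim = _similarity_columns(hf_matrix, hf_pim)
    if np.all(np.isnan(sim)):
        return _finalize(strategy, grid, sim, None, hf_pim, None, None)
    i_opt = int(np.nanargmax(sim))
    k0_opt = float(thr[i_opt]) if strategy == "ktrans_only" else None
    ve0_opt = float(thr[i_opt]) if strategy == "ve_only" else None
    return _finalize(strategy, grid, sim, hf_matrix[:, i_opt], hf_pim, k0_opt, ve0_opt)


def calibrate_2d(
    tumors: Sequence[TumorObservation],
    maps: Mapping[str, ParameterMaps],
    strategy: str,
    grid: ThresholdGrid | None = None,
) -> CalibrationResult:
    """Sweep (K0trans, ve0) jointly (strategy iii or iv) maximizing Similarity.

    The surface has shape (n_k0trans, n_ve0).  Ties in the maximum are
    broken toward the smallest K0trans, then the smallest ve0.  The result
    also carries the two profile curves through the optimum.
    """
    strategy = _canonical_strategy(strategy)
    if strategy not in ("conjunction", "weighted_sum"):
        raise ValueError("calibrate_2d needs strategy iii or iv")
    if grid is None:
        grid = default_preclinical_grid(strategy)
    if grid.k0trans_values is None or grid.ve0_values is None:
        raise ValueError("2-D calibration needs both threshold axes")
    k0s, ve0s = grid.k0trans_values, grid.ve0_values
    hf_pim, viable = _gather(tumors, maps)
    # hf_cube[t, i_k, i_v]
    hf_cube = np.empty((len(viable), k0s.size, ve0s.size))
    for ti, (kt, ve) in enumerate(viable):
        for vi, v0 in enumerate(ve0s):
            hf_cube[ti, :, vi] = hf_curve(kt, ve, strategy, k0s, ve0=v0)
    flat = hf_cube.reshape(len(viable), -1)
    sim = _similarity_columns(flat, hf_pim).reshape(k0s.size, ve0s.size)
    if np.all(np.isnan(sim)):
        return _finalize(strategy, grid, sim, None, hf_pim, None, None)
    # C-order flattening iterates ve0 fastest within ascending k0trans, so the
    # first occurrence of the max is the smallest (k0trans, then ve0) pair.
    i_k, i_v = np.unravel_index(int(np.nanargmax(sim)), sim.shape)
    return _finalize(
        strategy, grid, sim, hf_cube[:, i_k, i_v], hf_pim,
        float(k0s[i_k]), float(ve0s[i_v]),
        profile_k=sim[:, i_v].copy(), profile_v=sim[i_k, :].copy(),
    )
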