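"""Tofts generalized pharmacokinetic model: forward curves and voxel fitting.

The standard (non-extended) Tofts model describes the tissue contrast
concentration as the convolution of the plasma input with a mono-exponential
impulse response,

    C_t(t) = Ktrans * integral_0^t C_a(u) exp(-k_ep (t - u)) du,

where ``Ktrans`` (min^-1) is the volume transfer rate constant from plasma to
the extravascular extracellular space, ``v_e`` its fractional distribution
volume, and ``k_ep = Ktrans / v_e`` the efflux rate.  With a bi-exponential
population AIF the convolution has the closed form

    C_t(t) = Ktrans * sum_i  M_i (exp(-m_i t) - exp(-k_ep t)) / (k_ep - m_i)

over the fast and slow AIF components (amplitude M_i, rate m_i), switching to
the analytic limit ``Ktrans * M_i * t * exp(-m_i t)`` when k_ep coincides
with an AIF rate.  All rates are handled internally in min^-1 (AIF rates,
reported in s^-1, are multiplied by 60), matching the unit in which Ktrans
thresholds are conventionally quoted.

Voxel fitting is bounded trust-region least squares.  The v_e upper bound
deliberately admits unphysiological values above 1 so that necrotic voxels —
where the model assumptions fail and fitted v_e exceeds 1 — remain
representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .aif import AifParameters

__all__ = [
    "ConcentrationCurve",
    "VoxelFit",
    "tofts_forward",
    "fit_tofts_voxel",
    "fit_tofts_map",
    "KTRANS_BOUNDS",
    "VE_BOUNDS",
]

# Fit bounds (min^-1 and dimensionless).  The ve upper bound of 3 admits the
# unphysiological ve > 1 regime seen in necrotic tissue.
KTRANS_BOUNDS = (0.0, 5.0)
VE_BOUNDS = (1e-3, 3.0)
# Two starts: a typical viable-tissue point and a slow-efflux/high-ve point.
# The second rescues fits in the near-degenerate small-k_ep regime (necrosis),
# where the residual landscape has a flat ridge in ve and a single start can
# stall in a spurious low-ve minimum.
_STARTS = ((0.1, 0.3), (0.01, 1.5))
# Below this k_ep / AIF-rate separation (min^-1) the closed form is replaced
# by its analytic limit to avoid 0/0.
_DEGENERATE_RATE_GAP = 1e-8


@dataclass(frozen=True)
class ConcentrationCurve:
    """A tissue concentration-time series for one voxel.

    ``times`` are seconds since contrast arrival (first sample at t = 0,
    strictly increasing); ``concentrations`` are in mM.
    """

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise ValueError("times and concentrations must be 1-D of equal length")
        if t.size < 4:
            raise ValueError("curve needs at least 4 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] != 0:
            raise ValueError("first sample must be at contrast arrival t = 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class VoxelFit:
    """Result of fitting the Tofts model to one voxel.

    ``ktrans`` in min^-1, ``ve`` dimensionless (may exceed 1 in necrotic
    voxels), ``residual_norm`` the RMS residual in mM, ``converged`` the
    optimizer status (False also marks non-informative inputs).
    """

    ktrans: float
    ve: float
    residual_norm: float
    converged: bool


def _tofts_curve(ktrans: float, ve: float, params: AifParameters, times_s: np.ndarray):
    """Closed-form Tofts curve at times in seconds; internal minutes-based."""
    if ktrans < 0:
        raise ValueError("ktrans must be non-negative")
    if ktrans == 0:
        return np.zeros_like(times_s, dtype=float)
    if ve <= 0:
        raise ValueError("ve must be positive when ktrans > 0 (k_ep undefined)")
    t = np.asarray(times_s, dtype=float) / 60.0  # minutes
    kep = ktrans / ve
    out = np.zeros_like(t)
    for amp, rate_s in (
        (params.amp_fast, params.rate_fast),
        (params.amp_slow, params.rate_slow),
    ):
        m = rate_s * 60.0  # min^-1
        if abs(kep - m) < _DEGENERATE_RATE_GAP:
            out += ktrans * amp * t * np.exp(-m * t)
        else:
            out += ktrans * amp * (np.exp(-m * t) - np.exp(-kep * t)) / (kep - m)
    return out


def tofts_forward(
    ktrans: float, ve: float, params: AifParameters, times
) -> ConcentrationCurve:
    """Simulate a noise-free tissue curve from (Ktrans, v_e) and an AIF.

    Parameters
    ----------
    ktrans:
        Volume transfer rate constant (min^-1), >= 0.
    ve:
        Fractional distribution volume (dimensionless), > 0 unless ktrans = 0.
    params:
        Population AIF.
    times:
        Sample times in seconds, sorted, starting at 0.
    """
    times = np.asarray(times, dtype=float)
    return ConcentrationCurve(times, _tofts_curve(ktrans, ve, params, times))


def fit_tofts_voxel(curve: ConcentrationCurve, params: AifParameters) -> VoxelFit:
    """Fit (Ktrans, v_e) to a single concentration curve.

    Bounded trust-region least squares from two starts (a viable-tissue
    point and a high-ve point covering the slow-efflux regime of necrosis);
    the lower-residual solution wins.  All-zero or non-finite curves are not
    fitted: they return a Ktrans = 0 placeholder with ``converged=False``.
    """
    c = curve.concentrations
    if not np.all(np.isfinite(c)) or not np.any(c):
        return VoxelFit(ktrans=0.0, ve=VE_BOUNDS[0], residual_norm=0.0, converged=False)

    t = curve.times

    def residuals(x):
        return _tofts_curve(x[0], x[1], params, t) - c

    res = None
    for x0 in _STARTS:
        cand = least_squares(
            residuals,
            x0=x0,
            bounds=([KTRANS_BOUNDS[0], VE_BOUNDS[0]], [KTRANS_BOUNDS[1], VE_BOUNDS[1]]),
            method="trf",
            ftol=1e-10,
            xtol=1e-12,
            gtol=1e-10,
        )
        if res is None or cand.cost < res.cost:
            res = cand
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return VoxelFit(
        ktrans=float(res.x[0]),
        ve=float(res.x[1]),
        residual_norm=rms,
        converged=bool(res.success),
    )


def fit_tofts_map(times, concentrations, roi, params: AifParameters):
    """Fit the Tofts model voxel-by-voxel over an ROI.

    Parameters
    ----------
    times:
        Shared time axis in seconds (length nt).
    concentrations:
        Array with time on the first axis, shape ``(nt, *grid)``.
    roi:
        Boolean mask of shape ``grid``; only masked voxels are fitted.
    params:
        Population AIF.

    Returns
    -------
    ParameterMaps
        Ktrans and v_e maps (NaN outside the ROI), with per-voxel
        convergence and residual maps attached.
    """
    from .maps import ParameterMaps

    times = np.asarray(times, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if conc.shape[0] != times.size:
        raise ValueError("time axis length does not match concentration array")
    if conc.shape[1:] != roi.shape:
        raise ValueError("ROI shape does not match concentration grid")

    ktrans = np.full(roi.shape, np.nan)
    ve = np.full(roi.shape, np.nan)
    resid = np.full(roi.shape, np.nan)
    conv = np.zeros(roi.shape, dtype=bool)
    for idx in zip(*np.nonzero(roi)):
        fit = fit_tofts_voxel(
            ConcentrationCurve(times, conc[(slice(None), *idx)]), params
        )
        ktrans[idx] = fit.ktrans
        ve[idx] = fit.ve
        resid[idx] = fit.residual_norm
        conv[idx] = fit.converged
    return ParameterMaps(
        ktrans=ktrans, ve=ve, roi=roi, residual_norm=resid, converged=conv
    )
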