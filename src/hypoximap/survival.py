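"""Survival stratification by MRI hypoxic fraction and threshold sweeps.

A cohort is split into the one-third of patients with the highest HF_MRI and
the remaining two-thirds (high-risk fraction chosen because first-line
treatment fails in roughly one-third of locally-advanced cervical cancer
patients; floor(N/3) reproduces the 26/54 split of an 80-patient cohort).
The two groups are compared per endpoint (DFS, OS) with Kaplan–Meier curves
and the log-rank test.  Sweeping the classification threshold(s) over a grid
and recording the log-rank p-value at each candidate yields p-value curves
(1-D) or images (2-D) from which threshold ranges associated with outcome
(p < 0.05) can be read off.  No multiplicity correction is applied across
the sweep; the number of thresholds tested is recorded instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .classify import hf_curve, _canonical_strategy
from .cohorts import PatientObservation
from .maps import ParameterMaps
from .similarity import ThresholdGrid

__all__ = [
    "SurvivalCurve",
    "LogrankResult",
    "StratificationResult",
    "SweepResult",
    "split_cohort",
    "km_estimator",
    "logrank_test",
    "stratify_cohort",
    "survival_sweep_1d",
    "survival_sweep_2d",
    "hf_matrix_from_maps",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan–Meier product-limit estimate as a right-continuous step
    function, with the number at risk just before each observed time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t) -> np.ndarray | float:
        """S(t) evaluated at arbitrary time(s)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        s = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return s if s.ndim else float(s)


@dataclass(frozen=True)
class LogrankResult:
    """Two-group log-rank chi-square (1 df) and two-sided p-value.

    ``degenerate`` marks comparisons with zero events, for which the
    statistic is 0 and p = 1 by convention.
    """

    chi_square: float
    p_value: float
    degenerate: bool = False


def km_estimator(times, events) -> SurvivalCurve:
    """Kaplan–Meier estimate for one group.

    ``times`` in months (>= 0), ``events`` True where the event was
    observed (False = right-censored).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    grid = np.asarray(kmf.survival_function_.index, dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    # number at risk just before each tabulated time
    order = np.sort(times)
    at_risk = times.size - np.searchsorted(order, grid, side="left")
    return SurvivalCurve(times=grid, survival=surv, at_risk=at_risk)


def logrank_test(group1, group2) -> LogrankResult:
    """Standard two-group log-rank test.

    Each group is a (times, events) pair.  Uses the hypergeometric-variance
    form with simultaneous risk-set accounting for ties.
    """
    t1, e1 = (np.asarray(a) for a in group1)
    t2, e2 = (np.asarray(a) for a in group2)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.any(e1) or np.any(e2)):
        return LogrankResult(chi_square=0.0, p_value=1.0, degenerate=True)
    res = _ll_logrank(t1, t2, event_observed_A=e1.astype(bool), event_observed_B=e2.astype(bool))
    chi = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi):
        return LogrankResult(chi_square=0.0, p_value=1.0, degenerate=True)
    return LogrankResult(chi_square=chi, p_value=p)


def split_cohort(
    patients: Sequence[PatientObservation], rule_key: str | None = None,
    hf_values=None,
) -> tuple[list[PatientObservation], list[PatientObservation]]:
    """Split into the floor(N/3) highest-HF patients and the rest.

    HF comes from ``patients[i].hf_mri[rule_key]`` or, alternatively, from
    an explicit ``hf_values`` vector aligned with ``patients``.  Patients
    missing the HF value are excluded with a warning.  Ties at the boundary
    are broken deterministically by patient_id order (and flagged with a
    warning when they straddle the boundary).
    """
    if hf_values is None:
        if rule_key is None:
            raise ValueError("provide rule_key or hf_values")
        kept, hfs = [], []
        for p in patients:
            if rule_key in p.hf_mri:
                kept.append(p)
                hfs.append(p.hf_mri[rule_key])
            else:
                warnings.warn(
                    f"patient {p.patient_id} lacks hf_mri[{rule_key!r}]; excluded"
                )
        patients = kept
        hf = np.asarray(hfs, dtype=float)
    else:
        patients = list(patients)
        hf = np.asarray(hf_values, dtype=float)
        if hf.size != len(patients):
            raise ValueError("hf_values length must match patients")
    n = len(patients)
    if n < 3:
        raise ValueError("cohort split needs at least 3 patients with HF")
    order = sorted(range(n), key=lambda i: (-hf[i], patients[i].patient_id))
    n_high = n // 3
    if n_high >= 1 and n_high < n and hf[order[n_high - 1]] == hf[order[n_high]]:
        warnings.warn("HF ties straddle the one-third split boundary; "
                      "resolved by patient_id order")
    high = [patients[i] for i in order[:n_high]]
    low = [patients[i] for i in order[n_high:]]
    return high, low


@dataclass
class StratificationResult:
    """High/low-HF group comparison at one fixed rule."""

    rule_key: str
    high_ids: list[str]
    low_ids: list[str]
    logrank: dict[str, LogrankResult]
    km_high: dict[str, SurvivalCurve]
    km_low: dict[str, SurvivalCurve]


def stratify_cohort(
    patients: Sequence[PatientObservation], rule_key: str,
    endpoints: Sequence[str] = ("dfs", "os"),
) -> StratificationResult:
    """Split by HF and compare the groups per endpoint (KM + log-rank)."""
    high, low = split_cohort(patients, rule_key)
    logrank, km_h, km_l = {}, {}, {}
    for ep in endpoints:
        th, eh = zip(*(p.endpoint(ep) for p in high))
        tl, el = zip(*(p.endpoint(ep) for p in low))
        logrank[ep] = logrank_test((th, eh), (tl, el))
        km_h[ep] = km_estimator(th, eh)
        km_l[ep] = km_estimator(tl, el)
    return StratificationResult(
        rule_key=rule_key,
        high_ids=[p.patient_id for p in high],
        low_ids=[p.patient_id for p in low],
        logrank=logrank, km_high=km_h, km_low=km_l,
    )


@dataclass
class SweepResult:
    """Log-rank p-values over a threshold grid for one endpoint.

    1-D sweeps: ``p_values`` aligned with the threshold axis.  2-D sweeps:
    shape (n_k0trans, n_ve0).  NaN marks degenerate grid points (all HF
    equal).  ``optimal_*`` give the argmin-p candidate, ties broken toward
    smaller thresholds; ``n_tested`` counts non-degenerate grid points
    (no multiplicity correction is applied).
    """

    endpoint: str
    strategy: str
    grid: ThresholdGrid
    p_values: np.ndarray
    chi_squares: np.ndarray
    optimal_k0trans: float | None
    optimal_ve0: float | None
    optimal_p: float
    n_tested: int

    @property
    def significant_mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.p_values < SIGNIFICANCE_LEVEL


def hf_matrix_from_maps(
    patients: Sequence[PatientObservation],
    maps: Mapping[str, ParameterMaps],
    strategy: str,
    k0_grid,
    ve0: float | None = None,
) -> np.ndarray:
    """Per-patient HF over a threshold axis, shape (n_patients, n_thresholds).

    For strategy ii pass the ve0 candidates as ``k0_grid``.
    """
    rows = []
    for p in patients:
        m = maps[p.patient_id]
        kt, ve = m.roi_values()
        ok = np.isfinite(kt) & np.isfinite(ve) & (ve <= 1.0)
        rows.append(hf_curve(kt[ok], ve[ok], strategy, k0_grid, ve0=ve0))
    return np.stack(rows)


def _sweep_columns(patients, hf_matrix, endpoint):
    times = np.array([p.endpoint(endpoint)[0] for p in patients])
    events = np.array([p.endpoint(endpoint)[1] for p in patients], dtype=bool)
    n = len(patients)
    n_high = n // 3
    ids = [p.patient_id for p in patients]
    p_out = np.full(hf_matrix.shape[1], np.nan)
    chi_out = np.full(hf_matrix.shape[1], np.nan)
    for j in range(hf_matrix.shape[1]):
        hf = hf_matrix[:, j]
        if np.all(hf == hf[0]):
            continue  # degenerate split
        order = sorted(range(n), key=lambda i: (-hf[i], ids[i]))
        hi = order[:n_high]
        lo = order[n_high:]
        res = logrank_test((times[hi], events[hi]), (times[lo], events[lo]))
        p_out[j] = res.p_value
        chi_out[j] = res.chi_square
    return p_out, chi_out


def survival_sweep_1d(
    patients: Sequence[PatientObservation],
    strategy: str,
    grid: ThresholdGrid,
    endpoint: str,
    *,
    maps: Mapping[str, ParameterMaps] | None = None,
    hf_matrix: np.ndarray | None = None,
) -> SweepResult:
    """One-threshold sweep (strategy i or ii): log-rank p per candidate.

    HF per patient per threshold is recomputed from ``maps`` or taken from a
    precomputed ``hf_matrix`` (n_patients, n_thresholds).  Degenerate grid
    points (all patients share one HF) are recorded as NaN.
    """
    strategy = _canonical_strategy(strategy)
    if strategy not in ("ktrans_only", "ve_only"):
        raise ValueError("1-D sweep needs strategy i or ii")
    thr = grid.k0trans_values if strategy == "ktrans_only" else grid.ve0_values
    if thr is None:
        raise ValueError("grid lacks the threshold axis required by the strategy")
    if hf_matrix is None:
        if maps is None:
            raise ValueError("provide maps or hf_matrix")
        hf_matrix = hf_matrix_from_maps(patients, maps, strategy, thr)
    if hf_matrix.shape != (len(patients), thr.size):
        raise ValueError("hf_matrix shape must be (n_patients, n_thresholds)")
    p, chi = _sweep_columns(patients, hf_matrix, endpoint)
    if np.all(np.isnan(p)):
        k_opt = v_opt = None
        p_opt = float("nan")
    else:
        j = int(np.nanargmin(p))
        p_opt = float(p[j])
        k_opt = float(thr[j]) if strategy == "ktrans_only" else None
        v_opt = float(thr[j]) if strategy == "ve_only" else None
    return SweepResult(
        endpoint=endpoint, strategy=strategy, grid=grid,
        p_values=p, chi_squares=chi,
        optimal_k0trans=k_opt, optimal_ve0=v_opt, optimal_p=p_opt,
        n_tested=int(np.sum(~np.isnan(p))),
    )


def survival_sweep_2d(
    patients: Sequence[PatientObservation],
    strategy: str,
    grid: ThresholdGrid,
    endpoint: str,
    *,
    maps: Mapping[str, ParameterMaps] | None = None,
    hf_cube: np.ndarray | None = None,
) -> SweepResult:
    """Joint (K0trans, ve0) sweep (strategy iii or iv): a p-value image.

    ``hf_cube``, if given, has shape (n_patients, n_k0trans, n_ve0).
    The optimum is the argmin p, ties broken toward the smallest K0trans,
    then the smallest ve0.
    """
    strategy = _canonical_strategy(strategy)
    if strategy not in ("conjunction", "weighted_sum"):
        raise ValueError("2-D sweep needs strategy iii or iv")
    if grid.k0trans_values is None or grid.ve0_values is None:
        raise ValueError("2-D sweep needs both threshold axes")
    k0s, ve0s = grid.k0trans_values, grid.ve0_values
    if hf_cube is None:
        if maps is None:
            raise ValueError("provide maps or hf_cube")
        hf_cube = np.stack(
            [hf_matrix_from_maps(patients, maps, strategy, k0s, ve0=v0)
             for v0 in ve0s], axis=2,
        )
    if hf_cube.shape != (len(patients), k0s.size, ve0s.size):
        raise ValueError("hf_cube shape must be (n_patients, n_k0, n_ve0)")
    flat = hf_cube.reshape(len(patients), -1)
    p, chi = _sweep_columns(patients, flat, endpoint)
    p = p.reshape(k0s.size, ve0s.size)
    chi = chi.reshape(k0s.size, ve0s.size)
    if np.all(np.isnan(p)):
        k_opt = v_opt = None
        p_opt = float("nan")
    else:
        i_k, i_v = np.unravel_index(int(np.nanargmin(p)), p.shape)
        k_opt, v_opt, p_opt = float(k0s[i_k]), float(ve0s[i_v]), float(p[i_k, i_v])
    return SweepResult(
        endpoint=endpoint, strategy=strategy, grid=grid,
        p_values=p, chi_squares=chi,
        optimal_k0trans=k_opt, optimal_ve0=v_opt, optimal_p=p_opt,
        n_tested=int(np.sum(~np.isnan(p))),
    )
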