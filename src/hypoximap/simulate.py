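"""Synthetic tumors, cohorts and DCE acquisitions for pipeline validation.

The generators emulate the statistical structure the analysis assumes rather
than anatomical realism:

* a tumor *phantom* is a disc with a necrotic core (low Ktrans, v_e well
  above 1 so the Tofts assumptions fail there), a peri-necrotic hypoxic
  annulus with Ktrans below a known ground-truth threshold, and a
  well-perfused periphery — the concentric arrangement in which hypoxia
  surrounds necrosis;
* a *preclinical cohort* is a set of phantoms with varied geometry whose
  pimonidazole hypoxic fraction is the phantom's true HF plus truncated
  Gaussian noise;
* a *clinical cohort* draws per-patient hypoxic fractions and generates
  exponential proportional-hazards event times (hazard h0 * exp(beta * HF))
  with independent uniform censoring, for DFS and OS with a shared HF
  effect (OS event times never precede DFS event times);
* a *DCE acquisition* samples the closed-form Tofts curve of every ROI voxel
  at a fixed temporal resolution and adds Gaussian concentration noise.
  Necrotic voxels are simulated at their stored (low Ktrans, v_e > 1)
  parameters, which produces the characteristic low, slowly and steadily
  rising uptake of necrosis and makes the fit return unphysiological v_e.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .aif import AifParameters
from .classify import HypoxiaRule, classify_voxels, HYPOXIC, NORMOXIC
from .cohorts import PatientObservation, TumorObservation
from .maps import ParameterMaps
from .tofts import _tofts_curve

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "Phantom",
    "simulate_phantom",
    "simulate_preclinical_cohort",
    "simulate_clinical_cohort",
    "simulate_dce_acquisition",
    "preclinical_spec",
    "clinical_spec",
]

#: Xenograft model labels cycled over a preclinical cohort.
PRECLINICAL_MODELS = ("BK-12", "ED-15", "HL-16", "LA-19")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue parameters of one synthetic tumor.

    The disc of radius ``tumor_radius`` (voxels) holds a necrotic core of
    radius ``core_fraction * tumor_radius``; of the remaining viable area a
    fraction ``hypoxic_fraction`` (the peri-necrotic annulus) receives the
    low Ktrans mean.  Ktrans values get multiplicative lognormal noise of
    log-scale sigma ``ktrans_sigma``; v_e is Gaussian around ``ve_mean``
    (clipped to stay in (0, 1] for viable tissue).  Necrotic voxels get
    ``ktrans_necrotic`` and v_e = 1 + ``necrotic_ve_offset``.
    """

    shape: tuple[int, int] = (64, 64)
    tumor_radius: float = 24.0
    core_fraction: float = 0.3
    hypoxic_fraction: float = 0.3
    rule: HypoxiaRule = field(
        default_factory=lambda: HypoxiaRule("ktrans_only", k0trans=0.015)
    )
    ktrans_periphery: float = 0.05
    ktrans_hypoxic: float = 0.007
    ktrans_sigma: float = 0.5
    ve_mean: float = 0.25
    ve_sigma: float = 0.05
    ktrans_necrotic: float = 0.03
    ktrans_core_sigma: float = 0.2
    necrotic_ve_offset: float = 1.5
    voxel_size: tuple[float, float, float] = (0.23, 0.23, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_radius <= 0:
            raise ValueError("tumor radius must be positive")
        if not 0.0 <= self.core_fraction < 1.0:
            raise ValueError("necrotic core must be smaller than the tumor")
        if not 0.0 <= self.hypoxic_fraction <= 1.0:
            raise ValueError("hypoxic_fraction must lie in [0, 1]")
        if min(self.ktrans_sigma, self.ve_sigma) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.necrotic_ve_offset <= 0:
            raise ValueError("necrotic ve offset must be positive (ve > 1)")


@dataclass(frozen=True)
class Phantom:
    """A generated tumor: maps, ground-truth labels and the true HF."""

    maps: ParameterMaps
    true_labels: np.ndarray
    true_hf: float
    spec: PhantomSpec


def simulate_phantom(spec: PhantomSpec, rng: np.random.Generator | None = None) -> Phantom:
    """Generate one concentric tumor phantom.

    Ground-truth labels are obtained by applying the phantom's true rule to
    the generated parameter fields (necrotic voxels are unphysiological and
    excluded); the true HF is the hypoxic fraction over viable voxels.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ny, nx = spec.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - cy, xx - cx)

    R = spec.tumor_radius
    r_core = spec.core_fraction * R
    # annulus radius putting hypoxic_fraction of the viable area next to core
    r_hyp = np.sqrt(r_core**2 + spec.hypoxic_fraction * (R**2 - r_core**2))

    roi = r <= R
    core = roi & (r <= r_core)
    hyp_zone = roi & (r > r_core) & (r <= r_hyp)
    periphery = roi & (r > r_hyp)

    ktrans = np.full(spec.shape, np.nan)
    ve = np.full(spec.shape, np.nan)

    def lognoise(n, sigma):
        if sigma == 0:
            return np.ones(n)
        return np.exp(rng.normal(0.0, sigma, n))

    ktrans[hyp_zone] = spec.ktrans_hypoxic * lognoise(int(hyp_zone.sum()), spec.ktrans_sigma)
    ktrans[periphery] = spec.ktrans_periphery * lognoise(int(periphery.sum()), spec.ktrans_sigma)
    # necrosis: passive-diffusion uptake, much less heterogeneous than the
    # vascular-driven viable tissue
    ktrans[core] = spec.ktrans_necrotic * lognoise(int(core.sum()), spec.ktrans_core_sigma)

    n_viable = int((hyp_zone | periphery).sum())
    ve_viable = rng.normal(spec.ve_mean, spec.ve_sigma, n_viable)
    ve_viable = np.clip(ve_viable, 0.01, 1.0)
    ve[hyp_zone | periphery] = ve_viable
    ve[core] = 1.0 + spec.necrotic_ve_offset * (
        1.0 + 0.1 * rng.standard_normal(int(core.sum()))
    )
    ve[core] = np.maximum(ve[core], 1.0 + 1e-6)

    maps = ParameterMaps(ktrans=ktrans, ve=ve, roi=roi, voxel_size=spec.voxel_size)
    img = classify_voxels(maps, spec.rule)
    n_h = img.n_hypoxic
    n_v = img.n_hypoxic + img.n_normoxic
    true_hf = n_h / n_v if n_v else float("nan")
    return Phantom(maps=maps, true_labels=img.labels, true_hf=true_hf, spec=spec)


@dataclass(frozen=True)
class CohortSpec:
    """Size, noise and acquisition settings shared by cohort generators.

    ``hazard_baseline`` (events per month at HF = 0) and ``hazard_beta``
    (log-hazard per unit HF) drive the clinical survival generator;
    ``censoring_horizon`` is the uniform administrative-censoring window in
    months.  ``temporal_resolution`` / ``duration`` (seconds) and
    ``concentration_sigma`` (mM) describe the DCE acquisition.
    """

    n: int = 80
    hf_pim_sigma: float = 0.05
    hazard_baseline: float = 0.01
    hazard_beta: float = 3.0
    censoring_horizon: float = 60.0
    temporal_resolution: float = 29.0
    duration: float = 900.0
    concentration_sigma: float = 0.02
    tumor_perfusion_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        if min(self.hf_pim_sigma, self.concentration_sigma) < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.censoring_horizon <= 0:
            raise ValueError("censoring horizon must be positive")
        if self.temporal_resolution <= 0:
            raise ValueError("temporal resolution must be positive")

    def times(self) -> np.ndarray:
        """Acquisition time axis in seconds (first frame at arrival)."""
        return np.arange(0.0, self.duration + 1e-9, self.temporal_resolution)


def preclinical_spec(**overrides) -> CohortSpec:
    """Preclinical defaults: 98 tumors, 14.8 s temporal resolution."""
    base = dict(n=98, temporal_resolution=14.8)
    base.update(overrides)
    return CohortSpec(**base)


def clinical_spec(**overrides) -> CohortSpec:
    """Clinical defaults: 80 patients, 29 s temporal resolution."""
    base = dict(n=80, temporal_resolution=29.0)
    base.update(overrides)
    return CohortSpec(**base)


def _varied_phantom_spec(
    template: PhantomSpec, rng: np.random.Generator, seed: int,
    perfusion_sigma: float = 0.6,
) -> PhantomSpec:
    """Draw per-tumor geometry and perfusion level around a template.

    Besides geometry, each tumor's Ktrans means are rescaled by a lognormal
    factor (log-scale sigma ``perfusion_sigma``) emulating the strong
    between-tumor perfusion differences of xenograft lines; this inter-tumor
    heterogeneity is what makes a classification threshold identifiable from
    cohort-level hypoxic fractions.
    """
    scale = float(np.exp(rng.normal(0.0, perfusion_sigma)))
    return replace(
        template,
        tumor_radius=float(template.tumor_radius * rng.uniform(0.6, 1.0)),
        core_fraction=float(rng.uniform(0.05, 0.4)),
        hypoxic_fraction=float(rng.uniform(0.05, 0.6)),
        ktrans_hypoxic=template.ktrans_hypoxic * scale,
        ktrans_periphery=template.ktrans_periphery * scale,
        seed=seed,
    )


def simulate_preclinical_cohort(
    spec: CohortSpec, template: PhantomSpec | None = None
) -> tuple[list[TumorObservation], dict[str, ParameterMaps], dict[str, Phantom]]:
    """Generate a preclinical cohort of phantoms with HF_PIM observations.

    Each tumor is a phantom with geometry drawn around ``template``;
    hf_pim = true HF plus truncated Gaussian noise (sigma ``hf_pim_sigma``),
    clipped to [0, 1].  Model labels cycle over the four xenograft lines and
    every fourth tumor is labelled bevacizumab-treated (labels only — the
    generator gives treatment no effect).
    """
    if template is None:
        template = PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    tumors: list[TumorObservation] = []
    maps: dict[str, ParameterMaps] = {}
    phantoms: dict[str, Phantom] = {}
    for i in range(spec.n):
        pspec = _varied_phantom_spec(
            template, rng, seed=int(rng.integers(2**31)),
            perfusion_sigma=spec.tumor_perfusion_sigma,
        )
        ph = simulate_phantom(pspec)
        tid = f"T{i:03d}"
        hf_pim = float(np.clip(ph.true_hf + rng.normal(0.0, spec.hf_pim_sigma), 0.0, 1.0))
        tumors.append(
            TumorObservation(
                tumor_id=tid,
                model=PRECLINICAL_MODELS[i % len(PRECLINICAL_MODELS)],
                treatment="bevacizumab" if i % 4 == 3 else "untreated",
                hf_pim=hf_pim,
            )
        )
        maps[tid] = ph.maps
        phantoms[tid] = ph
    return tumors, maps, phantoms


def simulate_clinical_cohort(
    spec: CohortSpec,
    include_maps: bool = False,
    template: PhantomSpec | None = None,
) -> tuple[list[PatientObservation], dict[str, ParameterMaps]]:
    """Generate a clinical cohort with HF-dependent survival.

    Per patient, a hypoxic fraction is drawn (Beta(2, 4) marginal, or the
    true HF of a per-patient phantom when ``include_maps``).  DFS event
    times are exponential with hazard h0 * exp(beta * HF); the OS event time
    adds an independent exponential with the same hazard, so OS >= DFS.
    A shared uniform censoring time on [0, horizon] right-censors both.
    The drawn HF is stored under the key ``"true"``.
    """
    rng = np.random.default_rng(spec.seed)
    if template is None:
        template = PhantomSpec(shape=(32, 32), tumor_radius=12.0,
                               voxel_size=(0.78, 0.78, 5.0))
    patients: list[PatientObservation] = []
    maps: dict[str, ParameterMaps] = {}
    for i in range(spec.n):
        pid = f"P{i:03d}"
        if include_maps:
            pspec = _varied_phantom_spec(
                template, rng, seed=int(rng.integers(2**31)),
                perfusion_sigma=spec.tumor_perfusion_sigma,
            )
            ph = simulate_phantom(pspec)
            hf = ph.true_hf
            maps[pid] = ph.maps
        else:
            hf = float(rng.beta(2.0, 4.0))
        hazard = spec.hazard_baseline * np.exp(spec.hazard_beta * hf)
        t_dfs = float(rng.exponential(1.0 / hazard))
        t_os = t_dfs + float(rng.exponential(1.0 / hazard))
        c = float(rng.uniform(0.0, spec.censoring_horizon))
        patients.append(
            PatientObservation(
                patient_id=pid,
                hf_mri={"true": float(hf)},
                dfs_time=min(t_dfs, c), dfs_event=t_dfs <= c,
                os_time=min(t_os, c), os_event=t_os <= c,
            )
        )
    return patients, maps


def simulate_dce_acquisition(
    maps: ParameterMaps, aif: AifParameters, spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate concentration-time curves for every ROI voxel.

    Returns ``(times_s, concentrations)`` with time on the first axis of the
    concentration array (shape ``(nt, *grid)``); voxels outside the ROI are
    zero.  Each ROI voxel follows the closed-form Tofts curve at its stored
    (Ktrans, v_e) — necrotic voxels therefore show the low, slowly rising
    uptake typical of necrosis — plus i.i.d. Gaussian noise of sigma
    ``concentration_sigma`` (mM).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    times = spec.times()
    conc = np.zeros((times.size, *maps.shape))
    for idx in zip(*np.nonzero(maps.roi)):
        kt = maps.ktrans[idx]
        ve = maps.ve[idx]
        curve = _tofts_curve(float(kt), float(ve), aif, times)
        if spec.concentration_sigma > 0:
            curve = curve + rng.normal(0.0, spec.concentration_sigma, times.size)
        conc[(slice(None), *idx)] = curve
    return times, conc
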