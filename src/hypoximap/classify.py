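"""Threshold-based voxel hypoxia classification and hypoxic fractions.

Four strategies turn a (Ktrans, v_e) pair into a hypoxia call, using
thresholds K0trans (min^-1) and ve0 (dimensionless):

  i.   ktrans_only:   hypoxic iff  Ktrans < K0trans
  ii.  ve_only:       hypoxic iff  v_e < ve0
  iii. conjunction:   hypoxic iff  Ktrans < K0trans  and  v_e < ve0
  iv.  weighted_sum:  hypoxic iff  Ktrans/K0trans + v_e/ve0 < 1

All inequalities are strict: a voxel exactly at a threshold is normoxic.
Voxels with v_e > 1 violate the Tofts model assumptions (necrosis) and are
labelled unphysiological; they are never hypoxic and, by default, are
excluded from the hypoxic-fraction denominator — mirroring the definition of
the pimonidazole hypoxic fraction over viable tissue only.  The DCE-MRI
hypoxic fraction is

    HF_MRI = (# hypoxic) / (# hypoxic + # normoxic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import ParameterMaps

__all__ = [
    "Strategy",
    "HypoxiaRule",
    "HypoxiaImage",
    "classify_voxels",
    "hypoxic_fraction",
    "hf_curve",
    "OUTSIDE_ROI",
    "NORMOXIC",
    "HYPOXIC",
    "UNPHYSIOLOGICAL",
]

# Integer label codes (also the on-disk NIfTI coding).
OUTSIDE_ROI, NORMOXIC, HYPOXIC, UNPHYSIOLOGICAL = 0, 1, 2, 3

#: Canonical strategy names and their roman-numeral aliases.
_STRATEGY_ALIASES = {
    "i": "ktrans_only",
    "ii": "ve_only",
    "iii": "conjunction",
    "iv": "weighted_sum",
}
STRATEGIES = ("ktrans_only", "ve_only", "conjunction", "weighted_sum")


def _canonical_strategy(strategy: str) -> str:
    s = _STRATEGY_ALIASES.get(strategy, strategy)
    if s not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; use one of {STRATEGIES}")
    return s


class Strategy:
    """Namespace of the four strategy names."""

    KTRANS_ONLY = "ktrans_only"
    VE_ONLY = "ve_only"
    CONJUNCTION = "conjunction"
    WEIGHTED_SUM = "weighted_sum"


@dataclass(frozen=True)
class HypoxiaRule:
    """A hypoxic-voxel predicate: a strategy plus its threshold(s).

    ``k0trans`` (min^-1) is required by strategies i, iii and iv; ``ve0``
    (dimensionless, may exceed 1 for the weighted sum) by ii, iii and iv.
    """

    strategy: str
    k0trans: float | None = None
    ve0: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategy", _canonical_strategy(self.strategy))
        needs_k = self.strategy in ("ktrans_only", "conjunction", "weighted_sum")
        needs_v = self.strategy in ("ve_only", "conjunction", "weighted_sum")
        if needs_k and (self.k0trans is None or self.k0trans <= 0):
            raise ValueError(f"strategy {self.strategy} requires a positive k0trans")
        if needs_v and (self.ve0 is None or self.ve0 <= 0):
            raise ValueError(f"strategy {self.strategy} requires a positive ve0")

    def is_hypoxic(self, ktrans, ve) -> np.ndarray:
        """Elementwise predicate on viable voxels (no ve > 1 handling here)."""
        ktrans = np.asarray(ktrans, dtype=float)
        ve = np.asarray(ve, dtype=float)
        if self.strategy == "ktrans_only":
            return ktrans < self.k0trans
        if self.strategy == "ve_only":
            return ve < self.ve0
        if self.strategy == "conjunction":
            return (ktrans < self.k0trans) & (ve < self.ve0)
        return ktrans / self.k0trans + ve / self.ve0 < 1.0


@dataclass(frozen=True)
class HypoxiaImage:
    """Per-voxel hypoxia labels and the resulting hypoxic fraction.

    ``labels`` uses the integer codes 0 = outside ROI, 1 = normoxic,
    2 = hypoxic, 3 = unphysiological (v_e > 1 or non-finite parameters).
    ``hf_mri`` is NaN when no voxel is classifiable.
    """

    labels: np.ndarray
    hf_mri: float
    rule: HypoxiaRule

    @property
    def n_hypoxic(self) -> int:
        return int(np.sum(self.labels == HYPOXIC))

    @property
    def n_normoxic(self) -> int:
        return int(np.sum(self.labels == NORMOXIC))

    @property
    def n_unphysiological(self) -> int:
        return int(np.sum(self.labels == UNPHYSIOLOGICAL))


def classify_voxels(
    maps: ParameterMaps, rule: HypoxiaRule, *, include_unphysiological: bool = False
) -> HypoxiaImage:
    """Apply a hypoxia rule to parameter maps.

    Voxels with v_e > 1 or non-finite parameters are labelled
    unphysiological and never hypoxic.  ``include_unphysiological`` keeps
    them in the hypoxic-fraction denominator (as normoxic-like viable
    voxels) instead of excluding them; the default excludes them, matching
    a viable-tissue denominator.
    """
    labels = np.full(maps.shape, OUTSIDE_ROI, dtype=np.int8)
    roi = maps.roi
    kt, ve = maps.ktrans, maps.ve
    finite = np.isfinite(kt) & np.isfinite(ve)
    unphys = roi & (~finite | (ve > 1.0))
    viable = roi & ~unphys
    hyp = np.zeros(maps.shape, dtype=bool)
    if viable.any():
        hyp[viable] = rule.is_hypoxic(kt[viable], ve[viable])
    labels[viable] = np.where(hyp[viable], HYPOXIC, NORMOXIC)
    labels[unphys] = UNPHYSIOLOGICAL

    n_h = int(np.sum(labels == HYPOXIC))
    n_n = int(np.sum(labels == NORMOXIC))
    denom = n_h + n_n + (int(unphys.sum()) if include_unphysiological else 0)
    hf = n_h / denom if denom > 0 else float("nan")
    return HypoxiaImage(labels=labels, hf_mri=hf, rule=rule)


def hypoxic_fraction(
    maps: ParameterMaps, rule: HypoxiaRule, *, include_unphysiological: bool = False
) -> float:
    """Hypoxic fraction of the classifiable (viable) ROI under ``rule``.

    Raises
    ------
    ValueError
        If the ROI contains no classifiable voxel (HF undefined).
    """
    img = classify_voxels(maps, rule, include_unphysiological=include_unphysiological)
    if np.isnan(img.hf_mri):
        raise ValueError("hypoxic fraction undefined: no classifiable voxel in ROI")
    return img.hf_mri


def hf_curve(ktrans, ve, strategy: str, k0_grid, ve0: float | None = None):
    """Hypoxic fraction versus K0trans for one tumor, vectorized over a grid.

    ``ktrans``/``ve`` are the viable-voxel values (ve <= 1 assumed already
    enforced by the caller).  For each strategy the per-voxel condition is
    rewritten as a scalar score compared against K0trans, so the whole
    threshold grid costs one sort plus one ``searchsorted``:

      i.   score = ktrans
      iii. score = ktrans where ve < ve0, else +inf
      iv.  ktrans/K0 + ve/ve0 < 1  <=>  ktrans / (1 - ve/ve0) < K0
           (voxels with ve >= ve0 can never be hypoxic)

    For strategy ii pass the candidate ve0 values as ``k0_grid`` (the score
    is then v_e itself).
    """
    strategy = _canonical_strategy(strategy)
    ktrans = np.asarray(ktrans, dtype=float)
    ve = np.asarray(ve, dtype=float)
    k0_grid = np.asarray(k0_grid, dtype=float)
    n = ktrans.size
    if n == 0:
        raise ValueError("no viable voxels")
    if strategy == "ktrans_only":
        score = ktrans
    elif strategy == "ve_only":
        score = ve
    elif strategy == "conjunction":
        if ve0 is None:
            raise ValueError("conjunction needs ve0")
        score = np.where(ve < ve0, ktrans, np.inf)
    else:  # weighted_sum
        if ve0 is None:
            raise ValueError("weighted_sum needs ve0")
        margin = 1.0 - ve / ve0
        score = np.where(margin > 0, ktrans / np.maximum(margin, 1e-300), np.inf)
    counts = np.searchsorted(np.sort(score), k0_grid, side="left")
    return counts / n
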