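"""Population arterial input functions (AIFs) for DCE-MRI.

The plasma contrast concentration after a bolus is modelled as a
bi-exponential decay

    C_a(t) = A exp(-B t) + C exp(-D t)

with a fast component (amplitude ``A``, rate ``B``) describing the initial
distribution phase and a slow component (``C``, ``D``) describing renal
clearance.  Two population presets are provided: a murine AIF measured in
BALB/c nu/nu mice with Gd-DOTA, and a human AIF measured in cervical-cancer
patients with Gd-DTPA.  Rates are stored in s^-1 as conventionally reported;
the pharmacokinetic model converts them to min^-1 where needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AifParameters", "MURINE_AIF", "HUMAN_AIF", "evaluate_aif", "get_aif"]


@dataclass(frozen=True)
class AifParameters:
    """Bi-exponential population AIF constants.

    Parameters
    ----------
    amp_fast, amp_slow:
        Amplitudes of the fast and slow exponential components (mM).
    rate_fast, rate_slow:
        Decay rates of the two components (s^-1).  ``rate_fast`` must exceed
        ``rate_slow`` so that the first term is the fast one.
    label:
        Free-text name of the preset ("murine", "human", or custom).
    """

    amp_fast: float
    rate_fast: float
    amp_slow: float
    rate_slow: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.amp_fast < 0 or self.amp_slow < 0:
            raise ValueError("AIF amplitudes must be non-negative")
        if not self.rate_fast > self.rate_slow:
            raise ValueError("rate_fast must exceed rate_slow")
        if self.rate_slow < 0:
            raise ValueError("rate_slow must be non-negative")

    @property
    def peak(self) -> float:
        """Plasma concentration at contrast arrival, C_a(0) = A + C (mM)."""
        return self.amp_fast + self.amp_slow


#: Murine population AIF (BALB/c nu/nu, Gd-DOTA).
MURINE_AIF = AifParameters(
    amp_fast=2.55, rate_fast=0.080, amp_slow=1.20, rate_slow=0.0010, label="murine"
)

#: Human population AIF (cervical carcinoma patients, Gd-DTPA).
HUMAN_AIF = AifParameters(
    amp_fast=5.10, rate_fast=14.2, amp_slow=0.99, rate_slow=0.159, label="human"
)

_PRESETS = {"murine": MURINE_AIF, "human": HUMAN_AIF}


def get_aif(name: str) -> AifParameters:
    """Return a named AIF preset ("murine" or "human")."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown AIF preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def evaluate_aif(params: AifParameters, t):
    """Evaluate the plasma concentration C_a(t) in mM.

    Parameters
    ----------
    params:
        AIF constants.
    t:
        Time(s) since contrast arrival in seconds; scalar or array, all >= 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = params.amp_fast * np.exp(-params.rate_fast * t) + params.amp_slow * np.exp(
        -params.rate_slow * t
    )
    return out if out.ndim else float(out)
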