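"""Tabular cohort records: preclinical tumors and clinical patients.

Tumor tables carry the pimonidazole hypoxic fraction (HF_PIM, the area
fraction of viable tissue staining positive); patient tables carry
disease-free survival (DFS: time to relapse or death) and overall survival
(OS: time to death) in months with event indicators.  Computed MRI hypoxic
fractions are attached under string keys naming the rule that produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "TumorObservation",
    "PatientObservation",
    "tumors_to_csv",
    "tumors_from_csv",
    "patients_to_csv",
    "patients_from_csv",
]


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class TumorObservation:
    """One preclinical tumor: labels, HF_PIM and computed HF_MRI values."""

    tumor_id: str
    model: str = "unknown"
    treatment: str = "untreated"
    hf_pim: float = 0.0
    hf_mri: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_fraction("hf_pim", self.hf_pim)
        for k, v in self.hf_mri.items():
            _check_fraction(f"hf_mri[{k}]", v)


@dataclass
class PatientObservation:
    """One clinical record: HF_MRI plus DFS/OS times (months) and events."""

    patient_id: str
    hf_mri: dict[str, float] = field(default_factory=dict)
    dfs_time: float = 0.0
    dfs_event: bool = False
    os_time: float = 0.0
    os_event: bool = False

    def __post_init__(self) -> None:
        if self.dfs_time < 0 or self.os_time < 0:
            raise ValueError("survival times must be non-negative")
        for k, v in self.hf_mri.items():
            _check_fraction(f"hf_mri[{k}]", v)

    def endpoint(self, which: str) -> tuple[float, bool]:
        """(time, event) for endpoint 'dfs' or 'os'."""
        which = which.lower()
        if which == "dfs":
            return self.dfs_time, self.dfs_event
        if which == "os":
            return self.os_time, self.os_event
        raise ValueError("endpoint must be 'dfs' or 'os'")


def tumors_to_csv(tumors: Sequence[TumorObservation], path) -> Path:
    rows = []
    for t in tumors:
        row = {"tumor_id": t.tumor_id, "model": t.model, "treatment": t.treatment,
               "hf_pim": t.hf_pim}
        for k, v in t.hf_mri.items():
            row[f"hf_mri_{k}"] = v
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def tumors_from_csv(path) -> list[TumorObservation]:
    df = pd.read_csv(path)
    required = {"tumor_id", "model", "treatment", "hf_pim"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tumor table missing column(s): {sorted(missing)}")
    hf_cols = [c for c in df.columns if c.startswith("hf_mri_")]
    return [
        TumorObservation(
            tumor_id=str(r.tumor_id), model=str(r.model), treatment=str(r.treatment),
            hf_pim=float(r.hf_pim),
            hf_mri={c[len("hf_mri_"):]: float(getattr(r, c)) for c in hf_cols
                    if pd.notna(getattr(r, c))},
        )
        for r in df.itertuples(index=False)
    ]


def patients_to_csv(patients: Sequence[PatientObservation], path) -> Path:
    rows = []
    for p in patients:
        row = {"patient_id": p.patient_id, "dfs_time": p.dfs_time,
               "dfs_event": int(p.dfs_event), "os_time": p.os_time,
               "os_event": int(p.os_event)}
        for k, v in p.hf_mri.items():
            row[f"hf_mri_{k}"] = v
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def patients_from_csv(path) -> list[PatientObservation]:
    df = pd.read_csv(path)
    required = {"patient_id", "dfs_time", "dfs_event", "os_time", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"patient table missing column(s): {sorted(missing)}")
    hf_cols = [c for c in df.columns if c.startswith("hf_mri_")]
    return [
        PatientObservation(
            patient_id=str(r.patient_id),
            dfs_time=float(r.dfs_time), dfs_event=bool(r.dfs_event),
            os_time=float(r.os_time), os_event=bool(r.os_event),
            hf_mri={c[len("hf_mri_"):]: float(getattr(r, c)) for c in hf_cols
                    if pd.notna(getattr(r, c))},
        )
        for r in df.itertuples(index=False)
    ]
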