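"""Co-registered voxel-wise parameter maps for one tumor.

A :class:`ParameterMaps` bundles the Ktrans map (min^-1), the v_e map
(dimensionless) and the tumor ROI mask on a shared grid, with voxel size
metadata.  Maps are stored as NIfTI-1 volumes (one file per parameter, 0/1
volume for the ROI) or, for toy cases, as delimited text with one voxel per
row (x, y, z, ktrans, ve).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ParameterMaps"]


@dataclass
class ParameterMaps:
    """Ktrans / v_e / ROI grids for one tumor.

    ``ktrans`` and ``ve`` are float arrays (NaN outside the ROI is
    permitted); ``roi`` is boolean; all share one shape.  ``voxel_size`` is
    (dx, dy, dz) in mm.  ``residual_norm`` and ``converged`` are optional
    per-voxel fit diagnostics.
    """

    ktrans: np.ndarray
    ve: np.ndarray
    roi: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    residual_norm: np.ndarray | None = None
    converged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ktrans = np.asarray(self.ktrans, dtype=float)
        self.ve = np.asarray(self.ve, dtype=float)
        self.roi = np.asarray(self.roi, dtype=bool)
        if not (self.ktrans.shape == self.ve.shape == self.roi.shape):
            raise ValueError("ktrans, ve and roi must share one grid shape")
        inside_kt = self.ktrans[self.roi]
        inside_ve = self.ve[self.roi]
        if np.any(inside_kt[np.isfinite(inside_kt)] < 0):
            raise ValueError("negative ktrans inside ROI")
        if np.any(inside_ve[np.isfinite(inside_ve)] < 0):
            raise ValueError("negative ve inside ROI")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.roi.shape

    @property
    def n_roi(self) -> int:
        return int(self.roi.sum())

    def roi_values(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (ktrans, ve) arrays over the ROI."""
        return self.ktrans[self.roi], self.ve[self.roi]

    # ---------------------------------------------------------------- NIfTI
    def to_nifti(self, directory, prefix: str = "tumor") -> dict[str, Path]:
        """Write ktrans/ve/roi as three NIfTI-1 volumes; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        affine = np.diag([*self.voxel_size, 1.0])
        paths = {}
        for name, data in (
            ("ktrans", self.ktrans),
            ("ve", self.ve),
            ("roi", self.roi.astype(np.uint8)),
        ):
            arr = np.atleast_3d(np.asarray(data))
            path = directory / f"{prefix}_{name}.nii"
            nib.save(nib.Nifti1Image(arr.astype(np.float64), affine), str(path))
            paths[name] = path
        return paths

    @classmethod
    def from_nifti(cls, ktrans_path, ve_path, roi_path) -> "ParameterMaps":
        imgs = [nib.load(str(p)) for p in (ktrans_path, ve_path, roi_path)]
        zooms = imgs[0].header.get_zooms()[:3]
        kt, ve, roi = (np.asanyarray(i.dataobj) for i in imgs)
        return cls(ktrans=kt, ve=ve, roi=roi > 0.5, voxel_size=tuple(float(z) for z in zooms))

    # ----------------------------------------------------------------- text
    def to_text(self, path) -> Path:
        """Write ROI voxels as 'x y z ktrans ve' rows (tab-delimited)."""
        path = Path(path)
        idx = np.argwhere(self.roi)
        coords = np.zeros((len(idx), 3), dtype=int)
        coords[:, : idx.shape[1]] = idx
        kt, ve = self.roi_values()
        with path.open("w") as fh:
            fh.write("x\ty\tz\tktrans\tve\n")
            for (x, y, z), k, v in zip(coords, kt, ve):
                fh.write(f"{x}\t{y}\t{z}\t{k:.10g}\t{v:.10g}\n")
        return path

    @classmethod
    def from_text(cls, path, shape=None) -> "ParameterMaps":
        """Read 'x y z ktrans ve' rows; grid shape inferred if not given."""
        data = np.loadtxt(str(path), skiprows=1)
        data = np.atleast_2d(data)
        coords = data[:, :3].astype(int)
        if shape is None:
            shape = tuple(coords.max(axis=0) + 1)
        kt = np.full(shape, np.nan)
        ve = np.full(shape, np.nan)
        roi = np.zeros(shape, dtype=bool)
        for (x, y, z), k, v in zip(coords, data[:, 3], data[:, 4]):
            kt[x, y, z] = k
            ve[x, y, z] = v
            roi[x, y, z] = True
        return cls(ktrans=kt, ve=ve, roi=roi)
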