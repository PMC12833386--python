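"""Volumetric containers with the spine axis convention.

All 3-D arrays in this package are indexed ``(x, y, z)`` with

* ``x`` — anterior–posterior, positive = posterior,
* ``y`` — cranial–caudal, positive = cranial,
* ``z`` — lateral, positive = right,

and isotropic voxel spacing in millimetres.  The world coordinate of voxel
``(i, j, k)`` is its centre, ``(i, j, k) * spacing``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ScalarVolume", "LabelMask"]


@dataclass
class ScalarVolume:
    """3-D scalar intensity grid with isotropic spacing (mm)."""

    data: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_centres(self) -> np.ndarray:
        """World coordinates (mm) of all voxel centres, shape ``dims + (3,)``."""
        grids = np.meshgrid(
            *(np.arange(n) * self.spacing for n in self.dims), indexing="ij"
        )
        return np.stack(grids, axis=-1)

    def save(self, path: str | Path) -> None:
        affine = np.diag([self.spacing] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ScalarVolume":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0], atol=1e-4):
            raise ValueError(f"anisotropic voxels not supported: {zooms}")
        return cls(np.asarray(img.dataobj, dtype=float), float(zooms[0]))


@dataclass
class LabelMask:
    """Integer label volume plus a name → label mapping.

    Label 0 is background.  Vertebra names are ``L1 … L5, S1``; disc names are
    ``L1-L2 … L5-S1``.
    """

    data: np.ndarray
    spacing: float
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3-D")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def region(self, name: str) -> np.ndarray:
        """Boolean array for a named region."""
        if name not in self.labels:
            raise KeyError(f"unknown region {name!r}; have {sorted(self.labels)}")
        return self.data == self.labels[name]

    @property
    def vertebra_names(self) -> list[str]:
        return [n for n in self.labels if "-" not in n]

    @property
    def disc_names(self) -> list[str]:
        return [n for n in self.labels if "-" in n]

    def save(self, path: str | Path) -> None:
        affine = np.diag([self.spacing] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), affine), str(path))
        Path(str(path) + ".labels.json").write_text(json.dumps(self.labels, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LabelMask":
        img = nib.load(str(path))
        labels = json.loads(Path(str(path) + ".labels.json").read_text())
        return cls(
            np.asarray(img.dataobj).astype(int),
            float(img.header.get_zooms()[0]),
            {str(k): int(v) for k, v in labels.items()},
        )
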