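"""Rigid-body motion estimation and removal from displacement fields.

Between two scan positions the whole anatomy undergoes a common rigid shift
and rotation that carries no deformation information.  The common motion is
estimated from the displacement field itself — translation as the mean
displacement of valid nodes, rotation as the orthogonal factor of the polar
decomposition of the best-fit linear mapping about the node centroid — and
removed by exact composition with the inverse rigid transform.  Because the
Green–Lagrange tensor is invariant under left-composed rotations, removal
changes translations and rotations but leaves strains untouched (to
numerical tolerance).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.linalg import polar

from .dvc import DisplacementField

__all__ = ["RigidTransform", "estimate_rigid", "remove_rigid"]


class RigidEstimationError(ValueError):
    """Raised when node geometry is too degenerate to fit a rigid motion."""


@dataclass(frozen=True)
class RigidTransform:
    """y = R (x − c) + c + t with orthonormal R (det +1) and centroid c."""

    translation: np.ndarray   # mm
    rotation: np.ndarray      # 3x3
    centroid: np.ndarray      # mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "translation", np.asarray(self.translation, float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))
        object.__setattr__(self, "centroid", np.asarray(self.centroid, float))
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return (pts - self.centroid) @ self.rotation.T + self.centroid + self.translation

    def invert_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return (pts - self.centroid - self.translation) @ self.rotation + self.centroid

    @property
    def angle_deg(self) -> float:
        """Rotation angle magnitude in degrees."""
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "translation_mm": self.translation.tolist(),
            "rotation": self.rotation.tolist(),
            "centroid_mm": self.centroid.tolist(),
        }, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["translation_mm"]), np.asarray(d["rotation"]),
                   np.asarray(d["centroid_mm"]))


def estimate_rigid(field: DisplacementField) -> RigidTransform:
    """Common rigid motion of a displacement field.

    Translation is the mean displacement over valid nodes.  The rotation is
    obtained by fitting, in least squares about the valid-node centroid, the
    linear mapping from reference to deformed node positions, and taking the
    orthogonal factor of its polar decomposition.
    """
    pos, disp = field.valid_nodes()
    if pos.shape[0] < 4:
        raise RigidEstimationError("need at least 4 valid nodes")
    centroid = pos.mean(axis=0)
    xc = pos - centroid
    # non-coplanarity check: positions must span 3 dimensions
    if np.linalg.matrix_rank(xc, tol=1e-8 * max(1.0, np.abs(xc).max())) < 3:
        raise RigidEstimationError("valid nodes are coplanar; rotation unidentifiable")
    translation = disp.mean(axis=0)
    yc = (pos + disp) - (pos + disp).mean(axis=0)
    # least-squares linear map F with yc ≈ xc F^T
    F, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    R, _ = polar(F.T)
    if np.linalg.det(R) < 0:
        # reflections cannot arise from physical motion; flip the smallest mode
        U, s, Vt = np.linalg.svd(R)
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return RigidTransform(translation, R, centroid)


def remove_rigid(field: DisplacementField, transform: RigidTransform) -> DisplacementField:
    """Compose the field's mapping with the inverse rigid motion.

    The residual at node x is ``T⁻¹(x + u(x)) − x``: exact for finite
    rotation angles, unlike first-order subtraction of the rigid
    displacement.  On a purely rigid field the residual vanishes.
    """
    pos = field.grid.node_positions_mm()
    mapped = pos + field.u
    residual = transform.invert_points(mapped.reshape(-1, 3)).reshape(pos.shape) - pos
    residual[~field.valid] = 0.0
    return replace(field, u=residual)
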