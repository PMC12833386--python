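"""Green–Lagrange strain mapping and per-disc strain summaries.

The displacement gradient G is computed on the node grid by central finite
differences (one-sided at grid boundaries) using the node spacing in mm; the
Green–Lagrange tensor follows as E = (G + Gᵀ + GᵀG)/2, a finite-strain
measure invariant under rigid rotation.  Principal strains ε1 ≥ ε2 ≥ ε3 are
the eigenvalues of E; maximum shear is γmax = (ε1 − ε3)/2 (tensorial
convention; the engineering convention ε1 − ε3 is available).  Per-disc
summaries report the mean over valid nodes inside the disc mask and the
signed peak (value of largest magnitude), both in percent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dvc import DisplacementField
from .volume import LabelMask

__all__ = [
    "StrainTensorField",
    "LevelStrainSummary",
    "displacement_gradient",
    "green_lagrange",
    "principal_invariants",
    "summarize_level",
    "compute_strain_field",
]


@dataclass
class StrainTensorField:
    """Per-node symmetric strain tensors with derived principal quantities."""

    grid: "object"                 # SubsetGrid of the parent field
    E: np.ndarray                  # shape + (3, 3)
    valid: np.ndarray              # shape, bool
    shear_convention: str = "tensorial"

    def __post_init__(self) -> None:
        if not np.allclose(self.E, np.swapaxes(self.E, -1, -2), atol=1e-8):
            raise ValueError("strain tensors must be symmetric")
        eig = np.linalg.eigvalsh(self.E)          # ascending
        self._principal = eig[..., ::-1]          # ε1 >= ε2 >= ε3
        spread = self._principal[..., 0] - self._principal[..., 2]
        self._gamma = spread / 2.0 if self.shear_convention == "tensorial" else spread

    @property
    def principal(self) -> np.ndarray:
        """(ε1, ε2, ε3) per node, descending, shape + (3,)."""
        return self._principal

    @property
    def max_shear(self) -> np.ndarray:
        return self._gamma

    def component(self, name: str) -> np.ndarray:
        """Named scalar per node: 'e1', 'e2', 'e3' or 'gamma_max'."""
        if name == "gamma_max":
            return self.max_shear
        idx = {"e1": 0, "e2": 1, "e3": 2}[name]
        return self._principal[..., idx]


@dataclass
class LevelStrainSummary:
    """Whole-disc strain summary, all strain values in percent."""

    level: str
    n_nodes: int
    mean: dict[str, float]                # component -> mean %
    peak: dict[str, float]                # component -> signed peak %
    peak_node: dict[str, tuple[int, int, int]]


class UnresolvableLevelError(ValueError):
    """No valid strain node falls inside the requested disc mask."""


def displacement_gradient(field: DisplacementField) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless displacement gradient G_ij = du_i/dx_j on the node grid.

    Central differences at interior nodes, one-sided at boundaries, with the
    node spacing (mm) as the step.  Returns ``(G, valid)`` where a node's
    gradient is valid only if the node and every neighbour entering its
    stencil are valid (invalid neighbours are filled by nearest-valid values
    before differencing, then masked out).
    """
    shape = field.grid.shape
    if min(shape) < 3:
        raise ValueError("gradient needs at least 3 nodes per axis")
    u = field.u
    if not field.valid.all():
        if field.valid.any():
            idx = ndimage.distance_transform_edt(
                ~field.valid, return_distances=False, return_indices=True)
            u = field.u[tuple(idx)]
        else:
            u = np.zeros_like(field.u)
    coords = [field.grid.centres_mm(a) for a in range(3)]
    G = np.empty(shape + (3, 3))
    for i in range(3):
        grads = np.gradient(u[..., i], *coords, edge_order=1)
        for j in range(3):
            G[..., i, j] = grads[j]
    # a node's stencil touches the 6-neighbourhood
    footprint = ndimage.generate_binary_structure(3, 1)
    valid = ndimage.minimum_filter(field.valid.astype(np.uint8), footprint=footprint,
                                   mode="nearest").astype(bool)
    return G, valid


def green_lagrange(gradient: np.ndarray) -> np.ndarray:
    """E = (G + Gᵀ + GᵀG) / 2, symmetric by construction."""
    G = np.asarray(gradient, float)
    if not np.all(np.isfinite(G)):
        raise ValueError("gradient must be finite")
    Gt = np.swapaxes(G, -1, -2)
    return 0.5 * (G + Gt + np.einsum("...ji,...jk->...ik", G, G))


def principal_invariants(E: np.ndarray, atol: float = 1e-6,
                         shear_convention: str = "tensorial") -> tuple[np.ndarray, ...]:
    """(ε1, ε2, ε3, γmax) per node from symmetric tensors."""
    E = np.asarray(E, float)
    if not np.allclose(E, np.swapaxes(E, -1, -2), atol=atol):
        raise ValueError("input tensors are not symmetric within tolerance")
    Es = 0.5 * (E + np.swapaxes(E, -1, -2))
    eig = np.linalg.eigvalsh(Es)[..., ::-1]
    gamma = eig[..., 0] - eig[..., 2]
    if shear_convention == "tensorial":
        gamma = gamma / 2.0
    elif shear_convention != "engineering":
        raise ValueError("shear_convention must be 'tensorial' or 'engineering'")
    return eig[..., 0], eig[..., 1], eig[..., 2], gamma


def compute_strain_field(field: DisplacementField,
                         shear_convention: str = "tensorial") -> StrainTensorField:
    """Displacement field → Green–Lagrange strain field on the same grid."""
    G, valid = displacement_gradient(field)
    return StrainTensorField(field.grid, green_lagrange(G), valid,
                             shear_convention=shear_convention)


def _nodes_in_region(grid, mask: LabelMask, region: np.ndarray) -> np.ndarray:
    """Boolean node array: subset centre voxel lies inside the region."""
    shape = grid.shape
    inside = np.zeros(shape, dtype=bool)
    cx = np.clip(np.rint(grid.centres_vox(0)).astype(int), 0, mask.dims[0] - 1)
    cy = np.clip(np.rint(grid.centres_vox(1)).astype(int), 0, mask.dims[1] - 1)
    cz = np.clip(np.rint(grid.centres_vox(2)).astype(int), 0, mask.dims[2] - 1)
    inside[:] = region[np.ix_(cx, cy, cz)]
    return inside


def summarize_level(strains: StrainTensorField, mask: LabelMask,
                    level: str) -> LevelStrainSummary:
    """Mean and signed-peak principal/shear strains over one disc, in percent.

    A node belongs to the disc if its subset centre voxel lies inside the
    disc mask.  The mean is the unweighted average over qualifying valid
    nodes; the peak is the signed value at the node of largest magnitude.
    """
    sel = _nodes_in_region(strains.grid, mask, mask.region(level)) & strains.valid
    n = int(sel.sum())
    if n == 0:
        raise UnresolvableLevelError(f"level {level!r}: no valid node inside mask")
    mean, peak, peak_node = {}, {}, {}
    flat_idx = np.argwhere(sel)
    for comp in ("e1", "e3", "gamma_max"):
        vals = strains.component(comp)[sel]
        mean[comp] = float(vals.mean() * 100.0)
        k = int(np.argmax(np.abs(vals)))
        peak[comp] = float(vals[k] * 100.0)
        peak_node[comp] = tuple(int(v) for v in flat_idx[k])
    return LevelStrainSummary(level, n, mean, peak, peak_node)
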