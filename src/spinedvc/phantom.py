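"""Synthetic phantoms with analytic ground truth.

Every downstream stage of the pipeline — volume correlation, rigid-body
removal, strain mapping, kinematics, clinical metrics and the regression
layer — is validated against phantoms generated here, because the in-vivo
MRI volumes the pipeline was designed for cannot be redistributed.

The image texture is an analytic sum of Gaussian blobs, so a deformed volume
is an *exact* resampling of the continuous texture at inverse-mapped voxel
centres: phantom pairs carry no interpolation error, and correlation error
can be attributed to the correlation engine alone.  Deformations compose a
rigid motion, a small affine gradient and an optional smooth quadratic term;
displacement ``u(x)`` and Green–Lagrange strain ``E(x)`` are both available
in closed form.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.transform import Rotation

from .landmarks import LandmarkSet
from .volume import LabelMask, ScalarVolume

__all__ = [
    "AnalyticTexture",
    "DeformationSpec",
    "PhantomTruth",
    "DiscGeometry",
    "SpineGeometry",
    "make_speckle_phantom",
    "make_spine_phantom",
    "warp_volume",
    "make_synthetic_cohort",
    "COHORT_PREDICTORS",
]


# --------------------------------------------------------------------------
# analytic texture
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyticTexture:
    """Band-limited speckle texture: background plus a sum of Gaussian blobs.

    Evaluable at any continuous coordinate (mm), which is what makes exact
    warped resamplings possible.
    """

    centres: np.ndarray          # (n, 3) mm
    widths: np.ndarray           # (n,) mm, Gaussian sigma
    amplitudes: np.ndarray       # (n,) arbitrary intensity
    background: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "centres", np.atleast_2d(np.asarray(self.centres, float)))
        object.__setattr__(self, "widths", np.atleast_1d(np.asarray(self.widths, float)))
        object.__setattr__(self, "amplitudes", np.atleast_1d(np.asarray(self.amplitudes, float)))
        if self.centres.shape[0] and np.any(self.widths <= 0):
            raise ValueError("blob widths must be positive")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Evaluate at ``points`` of shape (..., 3) mm; returns shape (...)."""
        pts = np.asarray(points, float)
        flat = pts.reshape(-1, 3)
        out = np.full(flat.shape[0], self.background, dtype=float)
        n_blob = self.centres.shape[0]
        if n_blob == 0:
            return out.reshape(pts.shape[:-1])
        cutoff = 4.0 * float(self.widths.max())
        # bin points into spatial cells and cull blobs per cell, so the cost
        # scales with local blob density rather than total blob count
        cell = 2.0 * cutoff
        keys = np.floor(flat / cell).astype(np.int64)
        order = np.lexsort(keys.T)
        sorted_keys = keys[order]
        breaks = np.nonzero(np.any(np.diff(sorted_keys, axis=0), axis=1))[0] + 1
        starts = np.concatenate([[0], breaks, [flat.shape[0]]])
        for a, b in zip(starts[:-1], starts[1:]):
            idx = order[a:b]
            sub = flat[idx]
            bb_lo = sub.min(axis=0) - cutoff
            bb_hi = sub.max(axis=0) + cutoff
            sel = np.all((self.centres >= bb_lo) & (self.centres <= bb_hi), axis=1)
            if not np.any(sel):
                continue
            d2 = ((sub[:, None, :] - self.centres[sel][None, :, :]) ** 2).sum(axis=2)
            out[idx] += (
                self.amplitudes[sel][None, :]
                * np.exp(-0.5 * d2 / self.widths[sel][None, :] ** 2)
            ).sum(axis=1)
        return out.reshape(pts.shape[:-1])


# --------------------------------------------------------------------------
# deformations
# --------------------------------------------------------------------------

class DeformationError(ValueError):
    """Raised for non-invertible deformation specifications."""


@dataclass(frozen=True)
class DeformationSpec:
    """Rigid + affine + mild quadratic deformation with analytic oracles.

    Forward mapping about the centre ``c``::

        phi(x) = c + t + M (x - c) + q(x - c),   M = R (I + A)

    where ``R`` is the rotation (axis/angle about ``c``), ``A`` a small
    displacement-gradient-like matrix, and ``q_i(xi) = xi^T Q_i xi`` a
    quadratic displacement (coefficients in 1/mm).  ``u(x) = phi(x) - x`` and
    ``F(x) = d phi / d x = M + dq`` give the exact Green–Lagrange strain
    ``E = (F^T F - I) / 2``.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))   # mm
    rotation_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    rotation_deg: float = 0.0
    centre: np.ndarray = field(default_factory=lambda: np.zeros(3))        # mm
    affine: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    quadratic: np.ndarray | None = None                                    # (3,3,3) 1/mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "translation", np.asarray(self.translation, float))
        object.__setattr__(self, "rotation_axis", np.asarray(self.rotation_axis, float))
        object.__setattr__(self, "centre", np.asarray(self.centre, float))
        object.__setattr__(self, "affine", np.asarray(self.affine, float))
        if self.quadratic is not None:
            q = np.asarray(self.quadratic, float)
            if q.shape != (3, 3, 3):
                raise ValueError("quadratic coefficients must have shape (3,3,3)")
            object.__setattr__(self, "quadratic", q)

    @property
    def rotation_matrix(self) -> np.ndarray:
        axis = self.rotation_axis
        nrm = np.linalg.norm(axis)
        if nrm == 0:
            if self.rotation_deg != 0:
                raise ValueError("zero rotation axis with non-zero angle")
            return np.eye(3)
        return Rotation.from_rotvec(np.deg2rad(self.rotation_deg) * axis / nrm).as_matrix()

    @property
    def linear(self) -> np.ndarray:
        """The homogeneous linear part M = R (I + A)."""
        return self.rotation_matrix @ (np.eye(3) + self.affine)

    def map(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        xi = pts - self.centre
        out = self.centre + self.translation + xi @ self.linear.T
        if self.quadratic is not None:
            out = out + np.einsum("ijk,...j,...k->...i", self.quadratic, xi, xi)
        return out

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Analytic u(x) (mm) at points of shape (..., 3)."""
        return self.map(points) - np.asarray(points, float)

    def gradient(self, points: np.ndarray) -> np.ndarray:
        """Analytic deformation gradient F(x), shape (..., 3, 3)."""
        pts = np.asarray(points, float)
        F = np.broadcast_to(self.linear, pts.shape[:-1] + (3, 3)).copy()
        if self.quadratic is not None:
            xi = pts - self.centre
            Q = self.quadratic
            F += np.einsum("ijk,...k->...ij", Q + np.swapaxes(Q, 1, 2), xi)
        return F

    def strain(self, points: np.ndarray) -> np.ndarray:
        """Analytic Green–Lagrange tensor E(x), shape (..., 3, 3)."""
        F = self.gradient(points)
        return 0.5 * (np.einsum("...ji,...jk->...ik", F, F)
                      - np.eye(3))

    def check_invertible(self, domain_lo: np.ndarray, domain_hi: np.ndarray) -> None:
        """Require det F > 0 at the domain corners and centre."""
        lo, hi = np.asarray(domain_lo, float), np.asarray(domain_hi, float)
        corners = np.array([[lo[i] if b & (1 << i) == 0 else hi[i] for i in range(3)]
                            for b in range(8)] + [(lo + hi) / 2])
        dets = np.linalg.det(self.gradient(corners))
        if np.any(dets <= 0):
            raise DeformationError(
                f"deformation not invertible on domain (min det F = {dets.min():.3g})")

    def inverse(self, points: np.ndarray, tol: float = 1e-10, maxiter: int = 50) -> np.ndarray:
        """Invert the mapping by Newton iteration (exact for rigid+affine)."""
        y = np.asarray(points, float)
        Minv = np.linalg.inv(self.linear)
        x = self.centre + (y - self.centre - self.translation) @ Minv.T
        if self.quadratic is None:
            return x
        for _ in range(maxiter):
            r = self.map(x) - y
            err = np.abs(r).max()
            if err < tol:
                return x
            J = self.gradient(x)
            x = x - np.linalg.solve(J, r[..., None])[..., 0]
        if np.abs(self.map(x) - y).max() > 1e-6:
            raise DeformationError("Newton inversion of the deformation did not converge")
        return x


# --------------------------------------------------------------------------
# truth container
# --------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Ground truth attached to a phantom, independent of the pipeline."""

    displacement: Callable[[np.ndarray], np.ndarray] | None = None
    strain: Callable[[np.ndarray], np.ndarray] | None = None
    metrics: dict | None = None
    betas: dict[str, float] | None = None
    noise_sd: float | None = None


# --------------------------------------------------------------------------
# speckle phantom
# --------------------------------------------------------------------------

def make_speckle_phantom(
    dims: tuple[int, int, int] | int,
    spacing: float = 0.58,
    blob_count: int = 3000,
    seed: int = 0,
    width_range_vox: tuple[float, float] = (0.8, 1.6),
    amplitude_scale: float = 1.0,
    background: float = 0.1,
) -> tuple[ScalarVolume, AnalyticTexture]:
    """Random speckle volume suitable for subset correlation.

    Blob widths are drawn in voxel units (``width_range_vox`` times the
    spacing) so the texture's spatial frequency content tracks the grid.
    ``dims`` must be at least 48 per axis so the coarsest correlation subset
    fits.
    """
    if np.isscalar(dims):
        dims = (int(dims),) * 3
    dims = tuple(int(d) for d in dims)
    if min(dims) < 48:
        raise ValueError(f"dims must be >= 48 per axis to fit the largest subset, got {dims}")
    if blob_count < 0:
        raise ValueError("blob_count must be >= 0")
    rng = np.random.default_rng(seed)
    extent = (np.asarray(dims) - 1) * spacing
    centres = rng.uniform(0.0, 1.0, size=(blob_count, 3)) * extent
    widths = rng.uniform(*width_range_vox, size=blob_count) * spacing
    amplitudes = amplitude_scale * rng.uniform(0.5, 1.0, size=blob_count)
    texture = AnalyticTexture(centres.reshape(-1, 3), widths, amplitudes, background)
    vol = sample_texture(texture, dims, spacing)
    return vol, texture


def sample_texture(texture: AnalyticTexture, dims: tuple[int, int, int],
                   spacing: float) -> ScalarVolume:
    """Sample an analytic texture at voxel centres."""
    vol = ScalarVolume(np.zeros(dims), spacing)
    vol.data = texture(vol.voxel_centres())
    return vol


def warp_volume(
    texture: AnalyticTexture,
    spec: DeformationSpec,
    dims: tuple[int, int, int],
    spacing: float,
) -> tuple[ScalarVolume, PhantomTruth]:
    """Deformed counterpart of a texture's sampling: ``g(y) = f(phi^-1(y))``.

    The deformed volume is an exact resampling of the continuous texture at
    inverse-mapped voxel centres, so a (reference, deformed) pair carries the
    prescribed displacement field with no interpolation error.
    """
    dims = tuple(int(d) for d in dims)
    hi = (np.asarray(dims) - 1) * spacing
    spec.check_invertible(np.zeros(3), hi)
    grid = ScalarVolume(np.zeros(dims), spacing).voxel_centres()
    src = spec.inverse(grid.reshape(-1, 3)).reshape(grid.shape)
    deformed = ScalarVolume(texture(src), spacing)
    truth = PhantomTruth(displacement=spec.displacement, strain=spec.strain)
    return deformed, truth


# --------------------------------------------------------------------------
# spine phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscGeometry:
    """Prescribed anterior/posterior disc heights (mm), wedge implied."""

    anterior_height: float
    posterior_height: float

    def __post_init__(self) -> None:
        if self.anterior_height <= 0 or self.posterior_height <= 0:
            raise ValueError("disc heights must be positive")

    @property
    def central_height(self) -> float:
        return 0.5 * (self.anterior_height + self.posterior_height)

    def wedge_deg(self, depth: float) -> float:
        """Wedge (segmental lordosis) angle for a vertebral depth (mm)."""
        s = (self.anterior_height - self.posterior_height) / (2.0 * depth)
        if abs(s) >= 1:
            raise ValueError("disc wedge too extreme for the vertebral depth")
        return float(np.degrees(2.0 * np.arcsin(s)))

    @classmethod
    def from_angle(cls, central_height: float, wedge_deg: float, depth: float) -> "DiscGeometry":
        """Disc with a prescribed central height and wedge angle."""
        if abs(wedge_deg) > 45:
            raise ValueError("wedge angle must be within +/-45 degrees")
        half = float(np.sin(np.radians(wedge_deg) / 2.0)) * depth
        return cls(central_height + half, central_height - half)


@dataclass(frozen=True)
class SpineGeometry:
    """Per-level geometry of the phantom lumbar spine, caudal to cranial."""

    discs: tuple[DiscGeometry, ...]
    vertebra_height: float = 25.0   # mm, parallel endplates
    depth: float = 32.0             # mm anterior-posterior
    width: float = 30.0             # mm lateral
    sacral_slope_deg: float = 40.0  # superior S1 endplate vs horizontal
    sacrum_height: float = 18.0     # mm

    def __post_init__(self) -> None:
        if abs(self.sacral_slope_deg) > 45:
            raise ValueError("sacral slope must be within +/-45 degrees")
        if self.vertebra_height <= 0 or self.depth <= 0 or self.width <= 0:
            raise ValueError("spine dimensions must be positive")

    @classmethod
    def default(cls, level_count: int = 5) -> "SpineGeometry":
        """Plausible adult lumbar geometry: slightly lordotic wedged discs."""
        if not 1 <= level_count <= 5:
            raise ValueError("level_count must be between 1 and 5")
        wedges = [2.0, 4.0, 6.0, 8.0, 10.0][-level_count:]   # caudal-most = largest
        discs = tuple(DiscGeometry.from_angle(10.0, w, 32.0) for w in reversed(wedges))
        return cls(discs=discs)


def _vertebra_names(level_count: int) -> list[str]:
    """Caudal-to-cranial vertebra names, e.g. [S1, L5, ..., L1] for 5 levels."""
    lumbar = [f"L{6 - i}" for i in range(1, level_count + 1)]   # L5 .. L(6-n)
    return ["S1"] + lumbar


def make_spine_phantom(
    level_count: int = 5,
    geometry: SpineGeometry | None = None,
    spacing: float = 1.0,
    seed: int = 0,
    margin: float = 6.0,
) -> tuple[ScalarVolume, LabelMask, LandmarkSet, PhantomTruth]:
    """Stacked rounded-box spine phantom with known heights and angles.

    Vertebral bodies are blocks with parallel endplates; discs are wedged
    slabs whose anterior/posterior heights and wedge angles are prescribed by
    ``geometry``.  Returns the intensity volume, the vertebra/disc label
    mask, the full mid-sagittal landmark set, and a :class:`PhantomTruth`
    recording every prescribed clinical metric.
    """
    if geometry is None:
        geometry = SpineGeometry.default(level_count)
    if len(geometry.discs) != level_count:
        raise ValueError("geometry must prescribe one disc per level")
    names = _vertebra_names(level_count)                      # caudal -> cranial
    disc_names = [f"{names[i + 1]}-{names[i]}" for i in range(level_count)]
    d = geometry.depth

    def direction(theta: float) -> np.ndarray:
        return np.array([np.cos(theta), np.sin(theta)])

    def normal(theta: float) -> np.ndarray:
        return np.array([-np.sin(theta), np.cos(theta)])

    # --- 2-D construction, caudal to cranial -------------------------------
    # endplates[v] = dict(sup=(mid, theta), inf=(mid, theta))
    endplates: dict[str, dict[str, tuple[np.ndarray, float]]] = {}
    # positive sacral slope: anterior S1 rim inferior, so the ant->post
    # endplate direction rises; lordotic wedges then rotate each more
    # cranial endplate clockwise (theta decreases going up)
    theta = np.radians(geometry.sacral_slope_deg)
    mid = np.zeros(2)
    endplates["S1"] = {
        "sup": (mid.copy(), theta),
        "inf": (mid - geometry.sacrum_height * normal(theta), theta),
    }
    seg_truth = []
    for disc, vert in zip(geometry.discs, names[1:]):
        phi = np.radians(disc.wedge_deg(d))
        theta_mid = theta - phi / 2.0
        mid = mid + disc.central_height * normal(theta_mid)
        theta = theta - phi
        inf_mid = mid.copy()
        sup_mid = mid + geometry.vertebra_height * normal(theta)
        endplates[vert] = {"inf": (inf_mid, theta), "sup": (sup_mid, theta)}
        mid = sup_mid
        seg_truth.append({
            "anterior_height": disc.anterior_height,
            "central_height": disc.central_height,
            "posterior_height": disc.posterior_height,
            "ap_ratio": disc.anterior_height / disc.posterior_height,
            "segmental_lordosis_deg": disc.wedge_deg(d),
        })

    # --- landmarks ----------------------------------------------------------
    points: dict[str, np.ndarray] = {}
    for vert, eps in endplates.items():
        for which, (m, th) in eps.items():
            points[f"{vert}:{which}_ant"] = m - 0.5 * d * direction(th)
            points[f"{vert}:{which}_post"] = m + 0.5 * d * direction(th)
    for dn, (sup_v, inf_v) in zip(disc_names, zip(names[1:], names[:-1])):
        for site, key in (("ant", "ant"), ("post", "post")):
            a = points[f"{sup_v}:inf_{key}"]
            b = points[f"{inf_v}:sup_{key}"]
            points[f"{dn}:{site}"] = 0.5 * (a + b)
        points[f"{dn}:cent"] = 0.25 * (
            points[f"{sup_v}:inf_ant"] + points[f"{sup_v}:inf_post"]
            + points[f"{inf_v}:sup_ant"] + points[f"{inf_v}:sup_post"])

    # shift so everything sits at positive coordinates with a margin
    all_pts = np.array(list(points.values()))
    shift = margin - all_pts.min(axis=0)
    points = {k: v + shift for k, v in points.items()}
    for vert in endplates:
        endplates[vert] = {w: (m + shift, th) for w, (m, th) in endplates[vert].items()}
    landmarks = LandmarkSet(points)

    # --- rasterise ----------------------------------------------------------
    all_pts = np.array(list(points.values()))
    extent = all_pts.max(axis=0) + margin
    nx = int(np.ceil(extent[0] / spacing)) + 1
    ny = int(np.ceil(extent[1] / spacing)) + 1
    nz = int(np.ceil((geometry.width + 2 * margin) / spacing)) + 1
    mask = np.zeros((nx, ny, nz), dtype=np.int16)
    intensity = np.zeros((nx, ny, nz), dtype=float)
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    sag = np.stack([gx, gy], axis=-1)               # (nx, ny, 2)
    z_half = geometry.width / 2.0
    zc = margin + z_half
    z_in = np.abs(np.arange(nz) * spacing - zc) <= z_half

    labels: dict[str, int] = {}

    def quad_fill(corners: np.ndarray, label: int, value: float,
                  strict: bool = True) -> None:
        """Fill voxels whose sagittal centre lies in a convex CCW quad.

        ``strict`` raises on overlap with previously filled regions; discs
        legitimately share their bounding endplate lines with the adjacent
        vertebrae, so they fill non-strictly (first label wins on the line).
        """
        inside = np.ones(sag.shape[:2], dtype=bool)
        for i in range(4):
            a, b = corners[i], corners[(i + 1) % 4]
            edge = b - a
            rel = sag - a
            inside &= (edge[0] * rel[..., 1] - edge[1] * rel[..., 0]) >= 0
        region = inside[:, :, None] & z_in[None, None, :]
        if strict:
            if np.any(region & (mask > 0)):
                raise ValueError("phantom geometry error: overlapping vertebra boxes")
        else:
            region &= mask == 0
        mask[region] = label
        intensity[region] = value

    next_label = 1
    for vert in names:
        ia = points[f"{vert}:inf_ant"]
        ip = points[f"{vert}:inf_post"]
        sa = points[f"{vert}:sup_ant"]
        sp = points[f"{vert}:sup_post"]
        quad_fill(np.array([ia, ip, sp, sa]), next_label, 1.0)
        labels[vert] = next_label
        next_label += 1
    for dn, (sup_v, inf_v) in zip(disc_names, zip(names[1:], names[:-1])):
        ia = points[f"{inf_v}:sup_ant"]
        ip = points[f"{inf_v}:sup_post"]
        sa = points[f"{sup_v}:inf_ant"]
        sp = points[f"{sup_v}:inf_post"]
        quad_fill(np.array([ia, ip, sp, sa]), next_label, 0.55, strict=False)
        labels[dn] = next_label
        next_label += 1

    for name in list(labels):
        if not np.any(mask == labels[name]):
            raise ValueError(f"phantom region {name!r} rasterised empty; "
                             "increase resolution or sizes")

    rng = np.random.default_rng(seed)
    intensity += 0.02 * rng.standard_normal(intensity.shape)  # faint texture

    metrics = {
        "levels": dict(zip(disc_names, seg_truth)),
        "lumbar_lordosis_deg": float(sum(t["segmental_lordosis_deg"] for t in seg_truth)),
        "lumbar_height_mm": float(np.linalg.norm(
            points[f"{names[-1]}:sup_ant"] - points["S1:sup_ant"])),
        "sacral_angle_deg": geometry.sacral_slope_deg,
    }
    truth = PhantomTruth(metrics=metrics)
    return (ScalarVolume(intensity, spacing),
            LabelMask(mask, spacing, labels),
            landmarks, truth)


# --------------------------------------------------------------------------
# synthetic cohort
# --------------------------------------------------------------------------

#: numeric design columns emitted by :func:`make_synthetic_cohort` (the same
#: vocabulary the clinical regression models use; degeneration enters as
#: indicator columns with the non-degenerated bin as reference).
COHORT_PREDICTORS = [
    "age", "gender_male", "bmi", "avg_disc_height", "ap_ratio",
    "degen_D", "degen_SD", "segmental_lordosis", "lumbar_height", "sacral_angle",
]


def make_synthetic_cohort(
    n: int,
    true_betas: dict[str, float],
    noise_sd: float,
    seed: int = 0,
    outcome: str = "outcome",
    predictors: list[str] | None = None,
):
    """Cohort table from a known linear model with Gaussian noise.

    Predictor marginals span plausible clinical ranges (age 20–70, BMI around
    24, anterior:posterior disc height ratio around 1–2, Pfirrmann bins as
    categories).  ``true_betas`` maps predictor names (plus optionally
    ``"intercept"``) to generating coefficients; every other predictor has a
    true coefficient of zero.
    """
    import pandas as pd

    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    predictors = list(COHORT_PREDICTORS if predictors is None else predictors)
    unknown = set(true_betas) - set(predictors) - {"intercept"}
    if unknown:
        raise ValueError(f"true_betas refer to unknown predictors: {sorted(unknown)}")
    if n < len(predictors) + 2:
        raise ValueError("n must be at least number of predictors + 2")
    rng = np.random.default_rng(seed)
    cols = {
        "age": rng.uniform(20, 70, n),
        "gender_male": rng.integers(0, 2, n).astype(float),
        "bmi": rng.normal(23.8, 2.6, n),
        "avg_disc_height": rng.normal(9.6, 1.5, n),
        "ap_ratio": rng.uniform(1.0, 2.0, n),
        "segmental_lordosis": rng.normal(8.0, 4.0, n),
        "lumbar_height": rng.normal(190.0, 12.0, n),
        "sacral_angle": rng.normal(40.0, 8.0, n),
    }
    degen = rng.choice(["ND", "D", "SD"], size=n, p=[0.6, 0.25, 0.15])
    cols["degen_D"] = (degen == "D").astype(float)
    cols["degen_SD"] = (degen == "SD").astype(float)
    table = pd.DataFrame({k: cols[k] for k in predictors if k in cols})
    for name in predictors:
        if name not in table.columns:   # caller-specified synthetic predictor
            table[name] = rng.standard_normal(n)
    lin = np.full(n, float(true_betas.get("intercept", 0.0)))
    for name, beta in true_betas.items():
        if name != "intercept":
            lin = lin + beta * table[name].to_numpy()
    table[outcome] = lin + noise_sd * rng.standard_normal(n)
    truth = PhantomTruth(betas=dict(true_betas), noise_sd=noise_sd)
    return table, truth
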