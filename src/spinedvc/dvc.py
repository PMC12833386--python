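"""Subset-based 3-D digital volume correlation (DVC).

A displacement field between a reference and a deformed volume is recovered
by matching cubic image subsets on a regular node grid.  A predictor–
corrector multipass scheme refines the field through a schedule of shrinking
subset sizes (default 48–32–24–16 voxels, passes 1-1-2-2, 50 % overlap):
coarse stages use windowed FFT cross-correlation, the final stage uses
direct zero-normalised cross-correlation (ZNCC) over a bounded search
window, both with separable three-point Gaussian sub-voxel peak fitting.

With 16-voxel subsets at 50 % overlap and 0.58 mm voxels the node spacing of
the output field is 8 voxels = 4.64 mm.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .volume import LabelMask, ScalarVolume

__all__ = [
    "SubsetSchedule",
    "SubsetGrid",
    "DisplacementField",
    "build_subset_grid",
    "correlate_pass",
    "refine_subvoxel",
    "run_multipass",
]


@dataclass(frozen=True)
class SubsetSchedule:
    """Multipass schedule: strictly decreasing subset sizes with pass counts."""

    sizes: tuple[int, ...] = (48, 32, 24, 16)
    passes: tuple[int, ...] = (1, 1, 2, 2)
    overlap: float = 0.5
    min_valid_fraction: float = 0.5

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.passes):
            raise ValueError("sizes and passes must have equal length")
        if any(b >= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("subset sizes must be strictly decreasing")
        if not 0 < self.overlap < 1:
            raise ValueError("overlap must be in (0, 1)")
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must be in (0, 1]")
        if any(p < 1 for p in self.passes):
            raise ValueError("pass counts must be >= 1")


@dataclass(frozen=True)
class SubsetGrid:
    """Regular grid of subset nodes fully contained in the volume."""

    dims: tuple[int, int, int]
    subset: int
    overlap: float
    spacing: float                       # voxel size, mm
    starts: tuple[np.ndarray, ...] = field(repr=False, default=())

    @property
    def step_vox(self) -> float:
        return self.subset * (1.0 - self.overlap)

    @property
    def node_spacing_mm(self) -> float:
        return self.step_vox * self.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(len(s) for s in self.starts)  # type: ignore[return-value]

    def centres_vox(self, axis: int) -> np.ndarray:
        """Node centre positions along one axis, voxel index units."""
        return self.starts[axis] + (self.subset - 1) / 2.0

    def centres_mm(self, axis: int) -> np.ndarray:
        return self.centres_vox(axis) * self.spacing

    def node_positions_mm(self) -> np.ndarray:
        """World coordinates of all nodes, shape ``shape + (3,)``."""
        grids = np.meshgrid(*(self.centres_mm(a) for a in range(3)), indexing="ij")
        return np.stack(grids, axis=-1)


def build_subset_grid(dims: tuple[int, int, int], subset: int, overlap: float,
                      spacing: float) -> SubsetGrid:
    """Node grid for a subset size: spacing = subset × (1 − overlap) voxels."""
    dims = tuple(int(d) for d in dims)
    if not 0 < overlap < 1:
        if overlap == 0:
            pass  # degenerate but allowed: non-overlapping tiling
        else:
            raise ValueError("overlap must be in [0, 1)")
    if subset > min(dims):
        raise ValueError(f"subset {subset} exceeds volume dims {dims}")
    step = subset * (1.0 - overlap)
    starts = []
    for d in dims:
        n = int(np.floor((d - subset) / step)) + 1
        starts.append(np.rint(np.arange(n) * step).astype(int))
    return SubsetGrid(dims, int(subset), float(overlap), float(spacing),
                      tuple(starts))


@dataclass
class DisplacementField:
    """Per-node displacements (mm) with validity and correlation quality."""

    grid: SubsetGrid
    u: np.ndarray            # shape + (3,), mm
    valid: np.ndarray        # shape, bool
    peak: np.ndarray         # shape, correlation peak value

    def __post_init__(self) -> None:
        shape = self.grid.shape
        if self.u.shape != shape + (3,):
            raise ValueError("displacement array shape mismatch")
        if np.any(~np.isfinite(self.u[self.valid])):
            raise ValueError("valid nodes must carry finite displacements")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        """(positions mm, displacements mm) of valid nodes, flattened."""
        pos = self.grid.node_positions_mm()
        m = self.valid
        return pos[m], self.u[m]

    def interpolator(self) -> RegularGridInterpolator:
        """Trilinear interpolator of the field (mm → mm); invalid nodes are
        filled with their nearest valid neighbour first."""
        u = self.u
        if not self.valid.all():
            if not self.valid.any():
                u = np.zeros_like(self.u)
            else:
                idx = ndimage.distance_transform_edt(
                    ~self.valid, return_distances=False, return_indices=True)
                u = self.u[tuple(idx)]
        axes = [self.grid.centres_mm(a) for a in range(3)]
        # degenerate single-node axes cannot be interpolated; pad by repetition
        axes_p, u_p = [], u
        for a, ax in enumerate(axes):
            if len(ax) == 1:
                axes_p.append(np.array([ax[0] - 1.0, ax[0] + 1.0]))
                u_p = np.repeat(u_p, 2, axis=a)
            else:
                axes_p.append(ax)
        return RegularGridInterpolator(axes_p, u_p, method="linear",
                                       bounds_error=False, fill_value=None)

    def sample(self, points_mm: np.ndarray) -> np.ndarray:
        """Interpolated displacement (mm) at arbitrary points, clamped to the
        grid's bounding box (no extrapolation beyond edge values)."""
        interp = self.interpolator()
        pts = np.asarray(points_mm, float).copy()
        for a in range(3):
            lo, hi = interp.grid[a][0], interp.grid[a][-1]
            pts[..., a] = np.clip(pts[..., a], lo, hi)
        return interp(pts)


# --------------------------------------------------------------------------
# correlation kernels
# --------------------------------------------------------------------------

def _gaussian_subvoxel(c_minus: float, c_0: float, c_plus: float) -> float:
    """Three-point Gaussian peak interpolation along one axis."""
    eps = 1e-12
    if c_0 <= 0 or c_minus <= 0 or c_plus <= 0:
        # fall back to parabolic fit, valid for signed correlation values
        denom = c_minus - 2.0 * c_0 + c_plus
        if abs(denom) < eps:
            return 0.0
        return float(np.clip(0.5 * (c_minus - c_plus) / denom, -0.5, 0.5))
    lm, l0, lp = np.log([c_minus, c_0, c_plus])
    denom = lm - 2.0 * l0 + lp
    if abs(denom) < eps:
        return 0.0
    return float(np.clip(0.5 * (lm - lp) / denom, -0.5, 0.5))


def _refine_peak(corr: np.ndarray, peak_idx: tuple[int, int, int]) -> np.ndarray:
    """Separable sub-voxel refinement around an interior peak."""
    sub = np.zeros(3)
    for ax in range(3):
        i = peak_idx[ax]
        if i == 0 or i == corr.shape[ax] - 1:
            continue  # peak at search border: no refinement along this axis
        sl = list(peak_idx)
        sl[ax] = slice(i - 1, i + 2)
        cm, c0, cp = corr[tuple(sl)]
        sub[ax] = _gaussian_subvoxel(cm, c0, cp)
    return sub


def _fft_correlate(ref_sub: np.ndarray, def_sub: np.ndarray,
                   window: np.ndarray, max_shift: int,
                   seed_vox: np.ndarray | None = None,
                   ) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Windowed zero-mean circular FFT cross-correlation.

    Returns (integer offset, sub-voxel offset, peak value) or None if the
    subset is textureless.
    """
    r = (ref_sub - ref_sub.mean()) * window
    d = (def_sub - def_sub.mean()) * window
    if not r.any() or not d.any():
        return None
    axes = (0, 1, 2)
    corr = np.fft.irfftn(np.conj(np.fft.rfftn(r, axes=axes))
                         * np.fft.rfftn(d, axes=axes), s=r.shape, axes=axes)
    norm = np.sqrt((r ** 2).sum() * (d ** 2).sum())
    if norm == 0:
        return None
    corr = np.fft.fftshift(corr / norm)
    centre = np.array([s // 2 for s in corr.shape])
    lo = centre - max_shift
    hi = centre + max_shift + 1
    win = corr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    flat = np.argmax(win)
    idx = np.array(np.unravel_index(flat, win.shape))
    # tie-break: among near-equal peaks prefer the lowest total displacement
    peak_val = win[tuple(idx)]
    ties = np.argwhere(win >= peak_val - 1e-12)
    if len(ties) > 1:
        base = np.zeros(3) if seed_vox is None else np.asarray(seed_vox)
        mags = np.sum((ties - max_shift + base) ** 2, axis=1)
        idx = ties[np.argmin(mags)]
    offset = idx - max_shift
    sub = _refine_peak(win, tuple(idx))
    return offset.astype(float), sub, float(peak_val)


def _zncc_correlate(ref_sub: np.ndarray, region: np.ndarray,
                    search: int, seed_vox: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Direct ZNCC of a subset against all integer offsets in ±search.

    ``region`` has shape ``subset + 2*search`` per axis.
    """
    s = ref_sub.shape[0]
    r = ref_sub - ref_sub.mean()
    r_norm = np.sqrt((r ** 2).sum())
    if r_norm == 0:
        return None
    windows = sliding_window_view(region, (s, s, s))        # (2w+1,)*3 + (s,)*3
    w_mean = windows.mean(axis=(-3, -2, -1))
    num = np.einsum("abcijk,ijk->abc", windows, r)          # means cancel: sum(r)=0
    w_sq = np.einsum("abcijk,abcijk->abc", windows, windows)
    w_var = w_sq - windows[0, 0, 0].size * w_mean ** 2
    w_var = np.maximum(w_var, 0.0)
    denom = r_norm * np.sqrt(w_var)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, -np.inf)
    flat = np.argmax(corr)
    if not np.isfinite(corr.flat[flat]):
        return None
    idx = np.array(np.unravel_index(flat, corr.shape))
    peak_val = corr[tuple(idx)]
    ties = np.argwhere(corr >= peak_val - 1e-12)
    if len(ties) > 1:
        base = np.zeros(3) if seed_vox is None else np.asarray(seed_vox)
        mags = np.sum((ties - search + base) ** 2, axis=1)
        idx = ties[np.argmin(mags)]
    offset = idx - search
    # a ZNCC of 1 is an exact integer match; sub-voxel refinement would only
    # add jitter from the asymmetry of the finite-window autocorrelation
    if peak_val >= 1.0 - 1e-9:
        sub = np.zeros(3)
    else:
        sub = _refine_peak(corr, tuple(idx))
    return offset.astype(float), sub, float(peak_val)


# --------------------------------------------------------------------------
# passes
# --------------------------------------------------------------------------

def correlate_pass(
    ref: ScalarVolume,
    deformed: ScalarVolume,
    grid: SubsetGrid,
    seed_field: DisplacementField | None = None,
    mode: str = "direct",
    mask: LabelMask | ScalarVolume | None = None,
    min_valid_fraction: float = 0.5,
    search: int = 3,
    fractional_seed: bool = False,
) -> DisplacementField:
    """One correlation pass over the node grid.

    Per node the displacement is the argmax of the correlation surface
    between the reference subset and the seed-shifted deformed region,
    refined to sub-voxel precision by three-point Gaussian peak fitting per
    axis.  Nodes whose subset holds less than ``min_valid_fraction``
    foreground (when a mask is given), is textureless, or whose shifted
    search window leaves the volume, are flagged invalid.

    With ``fractional_seed`` (direct mode only) the deformed search region is
    resampled by cubic spline at the fractional part of the seed
    displacement plus the locally interpolated displacement *gradient* of
    the seed field, so the residual correlation peak falls near zero offset
    where the three-point fit is unbiased and intra-subset rotation or
    stretch no longer distorts the peak — the corrector step of the
    predictor–corrector scheme.
    """
    if ref.dims != deformed.dims:
        raise ValueError("reference and deformed volumes must share dims")
    if abs(ref.spacing - deformed.spacing) > 1e-9:
        raise ValueError("reference and deformed volumes must share spacing")
    if mode not in ("fft", "direct"):
        raise ValueError("mode must be 'fft' or 'direct'")

    s = grid.subset
    dims = np.asarray(ref.dims)
    shape = grid.shape
    u = np.zeros(shape + (3,))
    valid = np.zeros(shape, dtype=bool)
    peak = np.zeros(shape)
    fg = None
    if mask is not None:
        fg = mask.data > 0

    if seed_field is not None:
        seed_mm = seed_field.sample(grid.node_positions_mm())
    else:
        seed_mm = np.zeros(shape + (3,))
    seed_float = seed_mm / ref.spacing
    seed_vox = np.rint(seed_float).astype(int)
    seed_frac = seed_float - seed_vox
    # local displacement gradient of the seed field (voxel/voxel), used to
    # warp the deformed window in the corrector step
    seed_grad = np.zeros(shape + (3, 3))
    if fractional_seed and all(n >= 2 for n in shape):
        node_coords = [grid.centres_vox(a) for a in range(3)]
        for i in range(3):
            for j, g in enumerate(np.gradient(seed_float[..., i], *node_coords,
                                              edge_order=1)):
                seed_grad[..., i, j] = g

    win1d = np.hanning(s) + 1e-3   # keep strictly positive so edges contribute
    window = win1d[:, None, None] * win1d[None, :, None] * win1d[None, None, :]
    max_shift = max(s // 4, 1)

    for ia, ax in enumerate(grid.starts[0]):
        for ib, ay in enumerate(grid.starts[1]):
            for ic, az in enumerate(grid.starts[2]):
                start = np.array([ax, ay, az])
                rs = ref.data[ax:ax + s, ay:ay + s, az:az + s]
                if fg is not None:
                    fg_frac = fg[ax:ax + s, ay:ay + s, az:az + s].mean()
                    if fg_frac < min_valid_fraction:
                        continue
                if rs.std() == 0:
                    continue
                d0 = seed_vox[ia, ib, ic]
                dstart = start + d0
                frac = np.zeros(3)
                if mode == "fft":
                    if np.any(dstart < 0) or np.any(dstart + s > dims):
                        continue
                    ds = deformed.data[dstart[0]:dstart[0] + s,
                                       dstart[1]:dstart[1] + s,
                                       dstart[2]:dstart[2] + s]
                    res = _fft_correlate(rs, ds, window, max_shift, seed_vox=d0)
                else:
                    lo = dstart - search
                    hi = dstart + s + search
                    if np.any(lo < 0) or np.any(hi > dims):
                        continue
                    if fractional_seed and (
                            np.abs(seed_frac[ia, ib, ic]).max() > 1e-6
                            or np.abs(seed_grad[ia, ib, ic]).max() * s > 2e-3):
                        frac = seed_frac[ia, ib, ic]
                        L = seed_grad[ia, ib, ic]
                        # warp the deformed window: fractional shift plus the
                        # seed field's local gradient about the subset centre
                        rel = [np.arange(lo[a], hi[a], dtype=float)
                               - (dstart[a] + (s - 1) / 2.0) for a in range(3)]
                        gx, gy, gz = np.meshgrid(*rel, indexing="ij")
                        relpts = np.stack([gx, gy, gz])            # (3,) + region
                        warp = np.einsum("ij,j...->i...", L, relpts)
                        base = np.stack(np.meshgrid(
                            *(np.arange(lo[a], hi[a], dtype=float) for a in range(3)),
                            indexing="ij"))
                        coords = base + frac.reshape(3, 1, 1, 1) + warp
                        if coords.min() < 0 or np.any(
                                coords.max(axis=(1, 2, 3)) > dims - 1):
                            region = deformed.data[lo[0]:hi[0], lo[1]:hi[1],
                                                   lo[2]:hi[2]]
                            frac = np.zeros(3)
                        else:
                            region = ndimage.map_coordinates(
                                deformed.data, coords, order=5, mode="nearest")
                    else:
                        region = deformed.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                    res = _zncc_correlate(rs, region, search, seed_vox=d0)
                if res is None:
                    continue
                offset, sub, pval = res
                u[ia, ib, ic] = (d0 + frac + offset + sub) * ref.spacing
                valid[ia, ib, ic] = True
                peak[ia, ib, ic] = pval
    return DisplacementField(grid, u, valid, peak)


def refine_subvoxel(
    ref: ScalarVolume,
    deformed: ScalarVolume,
    field: DisplacementField,
    max_iter: int = 3,
    tol_vox: float = 1e-3,
) -> DisplacementField:
    """Gauss–Newton sub-voxel refinement of a displacement field.

    Starting from the correlation estimate, each valid node's translation is
    refined by minimising the sum of squared intensity differences between
    the reference subset and the spline-resampled deformed subset
    (a Lucas–Kanade step, translation-only).  Because the update pools the
    intensity residual over every voxel of the subset instead of a handful
    of correlation samples, it reduces the sub-voxel error well below the
    three-point peak-fit floor.  Nodes whose resampling window would leave
    the volume keep their correlation estimate; an exact integer match
    (zero residual) is a fixed point, so exact recoveries are preserved.
    """
    grid = field.grid
    s = grid.subset
    dims = np.asarray(ref.dims)
    filtered = ndimage.spline_filter(deformed.data, order=3)
    u = field.u.copy()
    axes_rel = [np.arange(s, dtype=float) for _ in range(3)]
    for ia, ib, ic in np.argwhere(field.valid):
        start = np.array([grid.starts[0][ia], grid.starts[1][ib],
                          grid.starts[2][ic]])
        R = ref.data[start[0]:start[0] + s, start[1]:start[1] + s,
                     start[2]:start[2] + s]
        d = u[ia, ib, ic] / ref.spacing
        for _ in range(max_iter):
            base = [axes_rel[a] + start[a] + d[a] for a in range(3)]
            lo = np.array([b[0] for b in base])
            hi = np.array([b[-1] for b in base])
            if np.any(lo < 1) or np.any(hi > dims - 2):
                break
            coords = np.array(np.meshgrid(*base, indexing="ij"))
            G = ndimage.map_coordinates(filtered, coords, order=3,
                                        prefilter=False)
            J = np.stack(np.gradient(G), axis=-1).reshape(-1, 3)
            r = (R - G).reshape(-1)
            A = J.T @ J
            if np.linalg.cond(A) > 1e8:
                break
            delta = np.linalg.solve(A, J.T @ r)
            if not np.all(np.isfinite(delta)) or np.abs(delta).max() > 1.0:
                break
            d = d + delta
            u[ia, ib, ic] = d * ref.spacing
            if np.abs(delta).max() < tol_vox:
                break
    return replace(field, u=u)


def run_multipass(
    ref: ScalarVolume,
    deformed: ScalarVolume,
    schedule: SubsetSchedule = SubsetSchedule(),
    mask: LabelMask | ScalarVolume | None = None,
    search: int = 3,
    refine: bool = True,
) -> DisplacementField:
    """Predictor–corrector multipass DVC.

    Each stage seeds from the trilinearly interpolated field of the previous
    stage (or pass); repeated passes within a stage re-correct with the
    latest field.  Coarse stages correlate with windowed FFT; the final
    stage uses direct ZNCC with warped seeding, followed by a Gauss–Newton
    sub-voxel refinement (:func:`refine_subvoxel`).  The returned field
    lives on the final-stage node grid.
    """
    field_prev: DisplacementField | None = None
    n_stages = len(schedule.sizes)
    for i, (size, n_pass) in enumerate(zip(schedule.sizes, schedule.passes)):
        grid = build_subset_grid(ref.dims, size, schedule.overlap, ref.spacing)
        mode = "direct" if i == n_stages - 1 else "fft"
        for _ in range(n_pass):
            field_prev = correlate_pass(
                ref, deformed, grid, seed_field=field_prev, mode=mode,
                mask=mask, min_valid_fraction=schedule.min_valid_fraction,
                search=search,
                fractional_seed=(mode == "direct" and field_prev is not None))
    assert field_prev is not None
    if refine:
        field_prev = refine_subvoxel(ref, deformed, field_prev)
    return field_prev
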