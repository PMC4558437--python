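"""Spatial normalization, transform inversion, and VOI pull-back.

The transform model mirrors classic statistical-parametric-mapping spatial
normalization: a 12-parameter global affine composed with a nonlinear
displacement field parameterized by low-frequency 3-D cosine (DCT) basis
functions over the template grid.  A template-world point ``x`` maps to the
native-world point

    phi(x) = A (x + u(x)),        u(x) = sum_k c_k B_k(x)

where ``A`` is the affine and the ``c_k`` are mm-valued coefficients.  Both
stages minimize the sum of squared intensity differences between the
(smoothed, globally intensity-scaled) source resampled into template space
and the template; the nonlinear stage adds a bending-energy penalty on the
displacement and runs a fixed number of Gauss-Newton steps.  Everything is
deterministic: the affine starts from all-zero parameters and no stochastic
steps are taken.

Inversion of the estimated transform is what allows template-space VOIs to be
carried back onto the untouched native image: the affine factor inverts in
closed form and the displacement is inverted by fixed-point iteration, giving
a dense native-to-template coordinate map against which a template VOI is
evaluated by trilinear interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from scipy.optimize import least_squares

from .volumes import Volume, VOIMask, gaussian_smooth

logger = logging.getLogger(__name__)

__all__ = [
    "RegistrationParams",
    "Transform",
    "InverseDeformation",
    "estimate_affine",
    "estimate_nonlinear",
    "spatially_normalize",
    "invert_transform",
    "map_voi_to_native",
    "resample_to_template",
    "save_transform",
    "load_transform",
]


@dataclass
class RegistrationParams:
    """Normalization settings.

    Defaults follow the customary SPECT normalization recipe: sixteen
    nonlinear iterations, unit regularization, 8-mm FWHM smoothing of the
    source image and no smoothing of the template.
    """

    nonlinear_iterations: int = 16
    regularization_weight: float = 1.0
    source_smoothing_fwhm_mm: float = 8.0
    template_smoothing_fwhm_mm: float = 0.0
    basis_cutoff_mm: float = 25.0
    max_basis_order: int = 5        # cap on cosine frequencies per axis
    affine_dof: int = 12
    sample_stride: int = 2          # voxel stride for cost-function sampling

    def validate(self, max_voxel_mm: float) -> None:
        if self.nonlinear_iterations < 1:
            raise ValueError("nonlinear_iterations must be >= 1")
        if self.regularization_weight < 0:
            raise ValueError("regularization_weight must be >= 0")
        if self.source_smoothing_fwhm_mm < 0 or self.template_smoothing_fwhm_mm < 0:
            raise ValueError("smoothing FWHM must be >= 0")
        if self.basis_cutoff_mm <= 2 * max_voxel_mm:
            raise ValueError("basis_cutoff_mm must exceed twice the largest voxel size")


@dataclass
class Transform:
    """Affine + cosine-basis displacement mapping template world to native world."""

    affine: np.ndarray                      # 4x4, template world -> native world
    coeffs: np.ndarray                      # (3, Kx, Ky, Kz) mm displacements
    template_shape: tuple[int, int, int]
    template_affine: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        self.template_affine = np.asarray(self.template_affine, dtype=np.float64)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("transform affine is singular")
        if self.coeffs.ndim != 4 or self.coeffs.shape[0] != 3:
            raise ValueError("coeffs must have shape (3, Kx, Ky, Kz)")

    @property
    def basis_order(self) -> tuple[int, int, int]:
        return self.coeffs.shape[1:]  # type: ignore[return-value]

    def displacement_grid(self) -> np.ndarray:
        """Synthesize the displacement field (3, Nx, Ny, Nz) on the template grid."""
        return _dct_synthesize(self.coeffs, self.template_shape)


@dataclass
class InverseDeformation:
    """Dense native-voxel -> template-voxel coordinate map with residuals."""

    coords: np.ndarray           # (3, *native_shape) template voxel coordinates
    residual: np.ndarray         # per-voxel roundtrip residual, native voxel units
    native_shape: tuple[int, int, int]
    native_affine: np.ndarray
    template_affine: np.ndarray
    tolerance_voxels: float
    converged_fraction: float = 1.0


# ---------------------------------------------------------------------------
# Cosine basis helpers
# ---------------------------------------------------------------------------

def _dct_basis(n: int, k: int) -> np.ndarray:
    """DCT-II basis matrix (n x k): column j is cos(pi*j*(i+0.5)/n)."""
    i = np.arange(n)[:, None] + 0.5
    j = np.arange(k)[None, :]
    return np.cos(np.pi * j * i / n)


def _basis_order(shape, voxel, params: RegistrationParams) -> tuple[int, int, int]:
    out = []
    for n, v in zip(shape, voxel):
        fov = n * v
        k = int(2 * fov / params.basis_cutoff_mm)
        out.append(int(np.clip(k, 2, params.max_basis_order)))
    return tuple(out)  # type: ignore[return-value]


def _dct_synthesize(coeffs: np.ndarray, shape) -> np.ndarray:
    Bx = _dct_basis(shape[0], coeffs.shape[1])
    By = _dct_basis(shape[1], coeffs.shape[2])
    Bz = _dct_basis(shape[2], coeffs.shape[3])
    u = np.tensordot(coeffs, Bx, axes=([1], [1]))        # (3, Ky, Kz, Nx)
    u = np.tensordot(u, By, axes=([1], [1]))             # (3, Kz, Nx, Ny)
    u = np.tensordot(u, Bz, axes=([1], [1]))             # (3, Nx, Ny, Nz)
    return u


def _bending_diagonal(order, shape, voxel) -> np.ndarray:
    """Diagonal bending-energy penalty per coefficient, (3*K,) flattened.

    For the separable cosine basis the squared-curvature (bending) energy is
    diagonal in coefficient space, proportional to (|omega|^2)^2 with
    omega_d = pi * k_d / L_d.
    """
    L = [n * v for n, v in zip(shape, voxel)]
    kx, ky, kz = np.meshgrid(np.arange(order[0]), np.arange(order[1]),
                             np.arange(order[2]), indexing="ij")
    w2 = (np.pi * kx / L[0]) ** 2 + (np.pi * ky / L[1]) ** 2 + (np.pi * kz / L[2]) ** 2
    lam = (w2 ** 2).ravel()
    return np.concatenate([lam, lam, lam])


# ---------------------------------------------------------------------------
# Shared sampling machinery
# ---------------------------------------------------------------------------

def _sample_points(template: Volume, stride: int):
    """Strided template voxel indices with signal, plus their world coords."""
    d = template.data
    thr = 0.02 * d.max()
    sl = tuple(slice(0, n, stride) for n in d.shape)
    grid = np.stack(np.meshgrid(*[np.arange(0, n, stride) for n in d.shape],
                                indexing="ij"), axis=-1).reshape(-1, 3)
    vals = d[sl].ravel()
    keep = vals > thr
    idx = grid[keep]
    world = idx @ template.affine[:3, :3].T + template.affine[:3, 3]
    return idx.astype(float), world, vals[keep]


def _interp(vol_data: np.ndarray, vox: np.ndarray, order: int = 1) -> np.ndarray:
    return ndimage.map_coordinates(vol_data, vox.T, order=order, mode="constant", cval=0.0)


def _affine_from_params(p: np.ndarray, center: np.ndarray) -> np.ndarray:
    """12-parameter affine about ``center``: translation, rotation (rad),
    scale deviations, shears."""
    t = p[0:3]
    rx, ry, rz = p[3:6]
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Z = np.diag(1.0 + p[6:9])
    hxy, hxz, hyz = p[9:12]
    H = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]])
    M3 = Rz @ Ry @ Rx @ Z @ H
    M = np.eye(4)
    M[:3, :3] = M3
    M[:3, 3] = t + center - M3 @ center
    return M


def _check_nondegenerate(v: Volume, name: str) -> None:
    if float(v.data.std()) < 1e-12:
        raise ValueError(f"{name} image is constant; registration is undefined")


# ---------------------------------------------------------------------------
# Affine stage
# ---------------------------------------------------------------------------

def estimate_affine(source: Volume, template: Volume,
                    params: RegistrationParams | None = None) -> Transform:
    """12-parameter affine registration of ``source`` to ``template``.

    Minimizes the SSD between the globally intensity-scaled, smoothed source
    resampled into template space and the template, starting from all-zero
    parameters (identity).  The intensity scale is re-estimated in closed form
    at every cost evaluation.
    """
    params = params or RegistrationParams()
    params.validate(float(max(template.voxel_size.max(), source.voxel_size.max())))
    _check_nondegenerate(source, "source")
    _check_nondegenerate(template, "template")

    ts = gaussian_smooth(template, params.template_smoothing_fwhm_mm)
    ss = gaussian_smooth(source, params.source_smoothing_fwhm_mm)
    _, world, tvals = _sample_points(ts, params.sample_stride)
    center = np.asarray(template.shape, dtype=float) / 2.0
    center = center @ template.affine[:3, :3].T + template.affine[:3, 3]
    Sinv = np.linalg.inv(source.affine)

    def residual(p: np.ndarray) -> np.ndarray:
        M = _affine_from_params(p, center)
        pts = world @ M[:3, :3].T + M[:3, 3]
        vox = pts @ Sinv[:3, :3].T + Sinv[:3, 3]
        w = _interp(ss.data, vox)
        denom = float(w @ w)
        s = float(w @ tvals) / denom if denom > 0 else 1.0
        return s * w - tvals

    x_scale = np.array([1.0, 1.0, 1.0, 0.02, 0.02, 0.02,
                        0.01, 0.01, 0.01, 0.01, 0.01, 0.01])
    res = least_squares(residual, np.zeros(12), method="trf", x_scale=x_scale,
                        max_nfev=400)
    converged = res.status > 0
    if not converged:
        logger.warning("affine registration hit the evaluation cap; "
                       "returning best parameters so far")
    order = _basis_order(template.shape, template.voxel_size, params)
    return Transform(affine=_affine_from_params(res.x, center),
                     coeffs=np.zeros((3, *order)),
                     template_shape=template.shape,
                     template_affine=template.affine,
                     converged=converged)


# ---------------------------------------------------------------------------
# Nonlinear stage
# ---------------------------------------------------------------------------

# scales the dimensionless bending penalty so that regularization_weight = 1
# gives a mild, SPM-like constraint on a typical brain-sized FOV
_BEND_SCALE = 1.0


def estimate_nonlinear(source: Volume, template: Volume, start: Transform,
                       params: RegistrationParams | None = None) -> Transform:
    """Estimate low-frequency cosine-basis displacements on top of an affine.

    Runs exactly ``params.nonlinear_iterations`` Gauss-Newton steps on the
    penalized SSD objective; singular normal equations are ridge-stabilized.
    """
    params = params or RegistrationParams()
    params.validate(float(max(template.voxel_size.max(), source.voxel_size.max())))
    _check_nondegenerate(source, "source")

    ts = gaussian_smooth(template, params.template_smoothing_fwhm_mm)
    ss = gaussian_smooth(source, params.source_smoothing_fwhm_mm)
    grads = np.gradient(ss.data)                     # voxel-index units

    idx, world, tvals = _sample_points(ts, params.sample_stride)
    n = len(tvals)
    order = _basis_order(template.shape, template.voxel_size, params)
    K = int(np.prod(order))

    # per-sample basis values (n, K)
    Bx = _dct_basis(template.shape[0], order[0])[idx[:, 0].astype(int)]
    By = _dct_basis(template.shape[1], order[1])[idx[:, 1].astype(int)]
    Bz = _dct_basis(template.shape[2], order[2])[idx[:, 2].astype(int)]
    Bval = (Bx[:, :, None, None] * By[:, None, :, None]
            * Bz[:, None, None, :]).reshape(n, K)

    A = start.affine
    Sinv = np.linalg.inv(source.affine)
    M3 = (Sinv @ A)[:3, :3]                          # d(voxel)/d(displacement mm)
    lam_diag = _bending_diagonal(order, template.shape, template.voxel_size)
    t_ms = float(np.mean(tvals ** 2))
    penalty = params.regularization_weight * _BEND_SCALE * n * t_ms * lam_diag

    C = start.coeffs.copy()
    if C.shape[1:] != order:
        C = np.zeros((3, *order))

    def objective(cflat: np.ndarray):
        u = (Bval @ cflat.reshape(3, K).T)           # (n, 3) mm displacement
        pts = (world + u) @ A[:3, :3].T + A[:3, 3]
        vox = pts @ Sinv[:3, :3].T + Sinv[:3, 3]
        w = _interp(ss.data, vox)
        denom = float(w @ w)
        s = float(w @ tvals) / denom if denom > 0 else 1.0
        r = s * w - tvals
        ssd = float(r @ r)
        return r, vox, s, ssd + float(penalty * cflat**2 @ np.ones_like(cflat))

    cflat = C.reshape(3, K).ravel()
    for it in range(params.nonlinear_iterations):
        r, vox, s, obj0 = objective(cflat)
        g = np.stack([_interp(gr, vox) for gr in grads], axis=1)   # (n, 3)
        proj = g @ M3                                              # (n, 3)
        # Jacobian of residual wrt coefficients, blocked per component
        J = np.empty((n, 3 * K))
        for c in range(3):
            J[:, c * K:(c + 1) * K] = (s * proj[:, c])[:, None] * Bval
        H = J.T @ J
        H[np.diag_indices_from(H)] += penalty + 1e-8 * max(H.max(), 1.0)
        grad = J.T @ r + penalty * cflat
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            logger.warning("singular normal equations at iteration %d; "
                           "applying strong ridge", it)
            H[np.diag_indices_from(H)] += 1e-3 * H.max()
            step = np.linalg.solve(H, -grad)
        # backtracking keeps the fixed iteration count but guards divergence
        alpha = 1.0
        for _ in range(6):
            trial = cflat + alpha * step
            _, _, _, obj1 = objective(trial)
            if obj1 <= obj0:
                cflat = trial
                break
            alpha *= 0.5
    return Transform(affine=A.copy(), coeffs=cflat.reshape(3, *order),
                     template_shape=template.shape,
                     template_affine=template.affine,
                     converged=start.converged)


# ---------------------------------------------------------------------------
# Composition, resampling, inversion
# ---------------------------------------------------------------------------

def _forward_native_vox(t: Transform, source_affine: np.ndarray) -> np.ndarray:
    """Native voxel coordinates of every template voxel under the transform."""
    shape = t.template_shape
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"),
                   axis=-1).reshape(-1, 3).astype(float)
    world = idx @ t.template_affine[:3, :3].T + t.template_affine[:3, 3]
    u = t.displacement_grid().reshape(3, -1).T
    pts = (world + u) @ t.affine[:3, :3].T + t.affine[:3, 3]
    Sinv = np.linalg.inv(source_affine)
    return pts @ Sinv[:3, :3].T + Sinv[:3, 3]


def resample_to_template(source: Volume, t: Transform, order: int = 1) -> Volume:
    """Resample ``source`` onto the template grid through the transform."""
    vox = _forward_native_vox(t, source.affine)
    data = ndimage.map_coordinates(source.data, vox.T, order=order,
                                   mode="constant", cval=0.0)
    return Volume(data.reshape(t.template_shape), t.template_affine, space="template")


def spatially_normalize(source: Volume, template: Volume,
                        params: RegistrationParams | None = None
                        ) -> tuple[Volume, Transform]:
    """Affine followed by nonlinear normalization; returns the warped image
    (trilinear) on the template grid together with the transform."""
    params = params or RegistrationParams()
    t_aff = estimate_affine(source, template, params)
    t = estimate_nonlinear(source, template, t_aff, params)
    return resample_to_template(source, t), t


def invert_transform(t: Transform, native_grid: Volume | tuple,
                     tolerance_voxels: float = 0.1, max_iter: int = 50) -> InverseDeformation:
    """Dense inversion of the transform onto a native grid.

    The affine inverts in closed form; the displacement is inverted by
    fixed-point iteration ``y <- A^-1 x - u(y)``.  Raises on folding
    (non-positive Jacobian determinant of the forward map).
    """
    if isinstance(native_grid, Volume):
        nshape, naffine = native_grid.shape, native_grid.affine
    else:
        nshape, naffine = native_grid
        naffine = np.asarray(naffine, dtype=float)

    # folding check on the forward map over the template grid
    u_grid = t.displacement_grid()
    Tst = t.template_affine
    shape = t.template_shape
    phi = np.empty((3,) + tuple(shape))
    idx_axes = [np.arange(n, dtype=float) for n in shape]
    X = np.stack(np.meshgrid(*idx_axes, indexing="ij"), axis=0)
    world = np.einsum("ij,j...->i...", Tst[:3, :3], X) + Tst[:3, 3][:, None, None, None]
    mapped = world + u_grid
    phi = np.einsum("ij,j...->i...", t.affine[:3, :3], mapped) \
        + t.affine[:3, 3][:, None, None, None]
    vx = np.linalg.norm(Tst[:3, :3], axis=0)
    grads = [[np.gradient(phi[i], vx[d], axis=d) for d in range(3)] for i in range(3)]
    Jac = np.stack([np.stack(row, axis=-1) for row in grads], axis=-2)
    det = np.linalg.det(Jac)
    frac_fold = float(np.mean(det <= 0))
    if frac_fold > 0:
        raise ValueError(f"transform is not invertible: non-positive Jacobian on "
                         f"{100 * frac_fold:.2f}% of template voxels")

    Ainv = np.linalg.inv(t.affine)
    Tinv = np.linalg.inv(Tst)
    nidx = np.stack(np.meshgrid(*[np.arange(n) for n in nshape], indexing="ij"),
                    axis=-1).reshape(-1, 3).astype(float)
    x_world = nidx @ naffine[:3, :3].T + naffine[:3, 3]
    target = x_world @ Ainv[:3, :3].T + Ainv[:3, 3]       # A^-1 x, template world

    nat_vox_mm = np.linalg.norm(naffine[:3, :3], axis=0)

    def u_at(y_world: np.ndarray) -> np.ndarray:
        yv = y_world @ Tinv[:3, :3].T + Tinv[:3, 3]
        return np.stack([ndimage.map_coordinates(u_grid[c], yv.T, order=1,
                                                 mode="nearest") for c in range(3)],
                        axis=1)

    y = target.copy()
    for _ in range(max_iter):
        y_new = target - u_at(y)
        delta = np.abs(y_new - y).max()
        y = y_new
        if delta < 0.01 * min(vx):
            break

    # roundtrip residual in native voxel units
    phi_y = (y + u_at(y)) @ t.affine[:3, :3].T + t.affine[:3, 3]
    resid = np.linalg.norm((phi_y - x_world) / nat_vox_mm, axis=1)
    yvox = y @ Tinv[:3, :3].T + Tinv[:3, 3]
    coords = yvox.T.reshape((3,) + tuple(nshape))
    residual = resid.reshape(nshape)
    frac_ok = float(np.mean(residual <= tolerance_voxels))
    if frac_ok < 0.99:
        logger.warning("inverse deformation converged on only %.1f%% of voxels",
                       100 * frac_ok)
    return InverseDeformation(coords=coords, residual=residual,
                              native_shape=tuple(nshape), native_affine=naffine,
                              template_affine=Tst,
                              tolerance_voxels=tolerance_voxels,
                              converged_fraction=frac_ok)


def map_voi_to_native(voi: VOIMask, inv: InverseDeformation) -> VOIMask:
    """Pull a template-space VOI back onto the native grid.

    The binary mask is interpolated trilinearly at each native voxel's
    template coordinate and thresholded at 0.5, which commutes exactly with
    integer-voxel translations.
    """
    if voi.space != "template":
        raise ValueError("map_voi_to_native expects a template-space VOI")
    vals = ndimage.map_coordinates(voi.data.astype(np.float64),
                                   inv.coords.reshape(3, -1), order=1,
                                   mode="constant", cval=0.0)
    mask = (vals >= 0.5).reshape(inv.native_shape)
    if not mask.any():
        raise ValueError(f"inverse-mapped VOI (role={voi.role!r}) is empty on the native grid")
    return VOIMask(mask, inv.native_affine, space="native", role=voi.role)


# ---------------------------------------------------------------------------
# Serialization: YAML header + .npz payload
# ---------------------------------------------------------------------------

def save_transform(t: Transform, path: str | Path) -> None:
    """Write a transform as a YAML header plus an .npz binary sidecar."""
    path = Path(path)
    npz = path.with_suffix(".npz")
    np.savez(npz, affine=t.affine, coeffs=t.coeffs,
             template_affine=t.template_affine,
             template_shape=np.asarray(t.template_shape))
    meta = dict(format="srrquant-transform-1",
                affine=np.asarray(t.affine).tolist(),
                basis_order=[int(k) for k in t.basis_order],
                template_shape=[int(n) for n in t.template_shape],
                converged=bool(t.converged),
                payload=npz.name)
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_transform(path: str | Path) -> Transform:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    if meta.get("format") != "srrquant-transform-1":
        raise ValueError(f"{path}: not a srrquant transform")
    with np.load(path.with_suffix(".npz")) as z:
        return Transform(affine=z["affine"], coeffs=z["coeffs"],
                         template_shape=tuple(int(n) for n in z["template_shape"]),
                         template_affine=z["template_affine"],
                         converged=bool(meta.get("converged", True)))
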