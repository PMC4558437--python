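"""Synthetic data generation: digital DAT-SPECT brain phantoms and SRR cohorts.

Two kinds of synthetic data are produced.

*Image phantoms* (:func:`make_phantom`) are schematic brain volumes — a brain
ellipsoid with a cortical ribbon, two striatal ellipsoids at a configurable
striatal-to-cortex contrast, and a scalp shell separated from the brain by a
near-zero gap (tracer uptake in the scalp is substantial in practice, which is
why the registration target must contain one).  The anatomy is evaluated
*analytically* at each voxel after applying the pose/warp perturbation, so a
noiseless, unblurred phantom is exactly piecewise constant and its anatomical
striatum/cortex ratio equals the requested contrast exactly.  A Gaussian PSF
and intensity-proportional noise then emulate reconstructed SPECT resolution
and noise.

*Statistical cohorts* (:func:`draw_srr_cohort`) draw per-subject SRR values
from Gaussian subgroup distributions.  The default subgroup layout is a PD
cohort split by clinical duration at 2/5/10 years (n = 118/100/87/60, mean
SRR 1.55/1.48/1.43/1.35) plus healthy controls (n = 28, 2.02 ± 0.20) and
essential-tremor patients (n = 33, 1.89 ± 0.23).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .volumes import Volume, VOIMask, gaussian_smooth

__all__ = [
    "PhantomSpec",
    "PhantomResult",
    "SubgroupSpec",
    "CohortSpec",
    "make_phantom",
    "make_cohort_images",
    "draw_srr_cohort",
    "simulate_duration_cohort",
    "default_cohort_spec",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry, contrast, degradation and pose of one synthetic brain volume.

    All lengths are mm.  Intensities are relative units with the cortical
    ribbon fixed at ``ribbon_intensity``; ``contrast_left/right`` are the
    striatal-to-ribbon intensity ratios (the anatomical ground truth that the
    SRR pipeline should recover).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (2.9, 2.9, 2.9)
    brain_semiaxes: tuple[float, float, float] = (65.0, 80.0, 60.0)
    scalp_gap_mm: float = 6.0
    scalp_thickness_mm: float = 5.0
    scalp_intensity: float = 0.6
    ribbon_thickness_mm: float = 12.0
    ribbon_intensity: float = 1.0
    interior_intensity: float = 1.0
    striatum_center_left: tuple[float, float, float] = (-26.0, 10.0, 2.0)
    striatum_center_right: tuple[float, float, float] = (26.0, 10.0, 2.0)
    striatum_semiaxes: tuple[float, float, float] = (12.0, 20.0, 12.0)
    contrast_left: float = 2.0
    contrast_right: float = 2.0
    psf_fwhm_mm: float = 8.0
    noise_model: str = "none"          # none | gaussian | poisson
    noise_level: float = 0.05
    # pose: rigid (translation mm, rotation deg) + affine (scale, shear)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shear: tuple[float, float, float] = (0.0, 0.0, 0.0)
    warp_amplitude_mm: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.grid_shape) < 16:
            raise ValueError("phantom grid too small (need >= 16 per axis)")
        if self.contrast_left < 0 or self.contrast_right < 0:
            raise ValueError("striatal contrast must be >= 0")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        # striatal ellipsoids must lie inside the brain ellipsoid
        u = _unit_sphere_points(200)
        b = np.asarray(self.brain_semiaxes)
        for c, name in ((self.striatum_center_left, "left"),
                        (self.striatum_center_right, "right")):
            surf = np.asarray(c) + u * np.asarray(self.striatum_semiaxes)
            if np.any(np.sum((surf / b) ** 2, axis=1) > 1.0):
                raise ValueError(f"{name} striatal ellipsoid extends outside the brain")

    @property
    def affine(self) -> np.ndarray:
        """RAS affine with the world origin at the grid centre."""
        vs = np.asarray(self.voxel_size, dtype=float)
        n = np.asarray(self.grid_shape, dtype=float)
        A = np.diag(np.append(vs, 1.0))
        A[:3, 3] = -vs * (n - 1) / 2.0
        return A

    @property
    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.voxel_size)


def _unit_sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


@dataclass
class SubgroupSpec:
    label: str
    group: str                       # PD | HC | ET
    n: int
    mean_srr: float
    sd_srr: float
    duration_range: tuple[float, float] | None = None  # years; None for nPD

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"subgroup {self.label}: n must be >= 1")
        if self.sd_srr < 0:
            raise ValueError(f"subgroup {self.label}: sd must be >= 0")


@dataclass
class CohortSpec:
    subgroups: list[SubgroupSpec]
    seed: int = 0

    def validate(self) -> None:
        for sg in self.subgroups:
            sg.validate()


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Cohort layout of the study population this package emulates.

    PD split by clinical duration at 2/5/10 years, plus healthy controls and
    essential-tremor patients as the non-PD group.
    """
    return CohortSpec(
        subgroups=[
            SubgroupSpec("pd_le2", "PD", 118, 1.55, 0.17, (0.0, 2.0)),
            SubgroupSpec("pd_3_5", "PD", 100, 1.48, 0.19, (2.0, 5.0)),
            SubgroupSpec("pd_6_10", "PD", 87, 1.43, 0.16, (5.0, 10.0)),
            SubgroupSpec("pd_ge11", "PD", 60, 1.35, 0.17, (10.0, 33.0)),
            SubgroupSpec("hc", "HC", 28, 2.02, 0.20, None),
            SubgroupSpec("et", "ET", 33, 1.89, 0.23, None),
        ],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Analytic anatomy and pose
# ---------------------------------------------------------------------------

def _pose_matrix(spec: PhantomSpec) -> np.ndarray:
    """World-to-world pose (canonical anatomy -> native), about the origin."""
    rx, ry, rz = np.deg2rad(spec.rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Z = np.diag(spec.scale)
    hxy, hxz, hyz = spec.shear
    H = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]])
    M = np.eye(4)
    M[:3, :3] = Rz @ Ry @ Rx @ Z @ H
    M[:3, 3] = spec.translation_mm
    return M


def _warp_field(spec: PhantomSpec):
    """A smooth synthetic displacement evaluated analytically at world points.

    Low-frequency separable cosines with seeded random weights, scaled so the
    maximum displacement magnitude equals ``warp_amplitude_mm``.
    """
    if spec.warp_amplitude_mm == 0:
        return lambda pts: np.zeros_like(pts)
    rng = np.random.default_rng(spec.seed + 777)
    L = spec.fov_mm
    n_terms = 3
    freqs = rng.integers(1, 3, size=(3, n_terms, 3))       # per component, per term
    weights = rng.normal(size=(3, n_terms))
    phases = rng.uniform(0, 2 * np.pi, size=(3, n_terms))

    def raw(pts: np.ndarray) -> np.ndarray:
        # pts: (n, 3) world mm; returns (n, 3) displacements
        out = np.zeros_like(pts)
        for c in range(3):
            acc = np.zeros(pts.shape[0])
            for t in range(n_terms):
                arg = np.zeros(pts.shape[0])
                for d in range(3):
                    arg = arg + np.pi * freqs[c, t, d] * (pts[:, d] / L[d])
                acc += weights[c, t] * np.cos(arg + phases[c, t])
            out[:, c] = acc
        return out

    # normalize peak magnitude over a probe grid spanning the FOV
    probe = np.stack(np.meshgrid(*[np.linspace(-l / 2, l / 2, 9) for l in L],
                                 indexing="ij"), axis=-1).reshape(-1, 3)
    peak = np.max(np.linalg.norm(raw(probe), axis=1))
    scale = spec.warp_amplitude_mm / max(peak, 1e-12)
    return lambda pts: raw(pts) * scale


def _anatomy(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Piecewise-constant intensity of the canonical anatomy at world points."""
    b = np.asarray(self_b := spec.brain_semiaxes, dtype=float)
    r2_brain = np.sum((pts / b) ** 2, axis=1)
    inner = b - spec.ribbon_thickness_mm
    r2_inner = np.sum((pts / inner) ** 2, axis=1)
    shell_in = b + spec.scalp_gap_mm
    shell_out = shell_in + spec.scalp_thickness_mm
    r2_sin = np.sum((pts / shell_in) ** 2, axis=1)
    r2_sout = np.sum((pts / shell_out) ** 2, axis=1)

    out = np.zeros(pts.shape[0])
    out[(r2_sout <= 1.0) & (r2_sin > 1.0)] = spec.scalp_intensity
    brain = r2_brain <= 1.0
    out[brain] = spec.interior_intensity
    out[brain & (r2_inner > 1.0)] = spec.ribbon_intensity
    for c, contrast in ((spec.striatum_center_left, spec.contrast_left),
                        (spec.striatum_center_right, spec.contrast_right)):
        r2 = np.sum(((pts - np.asarray(c)) / np.asarray(spec.striatum_semiaxes)) ** 2, axis=1)
        out[r2 <= 1.0] = contrast * spec.ribbon_intensity
    return out


def _region_masks(spec: PhantomSpec, pts: np.ndarray) -> dict[str, np.ndarray]:
    b = np.asarray(spec.brain_semiaxes, dtype=float)
    inner = b - spec.ribbon_thickness_mm
    masks: dict[str, np.ndarray] = {}
    sl = np.sum(((pts - np.asarray(spec.striatum_center_left))
                 / np.asarray(spec.striatum_semiaxes)) ** 2, axis=1) <= 1.0
    sr = np.sum(((pts - np.asarray(spec.striatum_center_right))
                 / np.asarray(spec.striatum_semiaxes)) ** 2, axis=1) <= 1.0
    brain = np.sum((pts / b) ** 2, axis=1) <= 1.0
    ribbon = brain & (np.sum((pts / inner) ** 2, axis=1) > 1.0) & ~sl & ~sr
    shell_in = b + spec.scalp_gap_mm
    shell_out = shell_in + spec.scalp_thickness_mm
    scalp = (np.sum((pts / shell_out) ** 2, axis=1) <= 1.0) \
        & (np.sum((pts / shell_in) ** 2, axis=1) > 1.0)
    masks["striatum_left"] = sl
    masks["striatum_right"] = sr
    masks["reference"] = ribbon
    masks["scalp"] = scalp
    masks["brain"] = brain
    return masks


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

@dataclass
class PhantomResult:
    """A generated phantom: native image plus ground truth in both frames."""

    volume: Volume                     # degraded image in the perturbed frame
    canonical: Volume                  # noiseless, unblurred anatomy, identity pose
    masks_template: dict[str, VOIMask]  # ground truth in the unperturbed frame
    masks_native: dict[str, VOIMask]    # ground truth in the perturbed frame
    spec: PhantomSpec = field(repr=False, default=None)  # type: ignore[assignment]


def _grid_world_points(spec: PhantomSpec) -> np.ndarray:
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in spec.grid_shape],
                               indexing="ij"), axis=-1).reshape(-1, 3).astype(float)
    A = spec.affine
    return idx @ A[:3, :3].T + A[:3, 3]


def make_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build one phantom volume with ground-truth masks.

    The native image samples the analytic anatomy at the *pulled-back*
    coordinates (inverse pose followed by the synthetic warp), so the
    perturbation introduces no interpolation error.  PSF blur and noise are
    applied afterwards.
    """
    spec.validate()
    pts = _grid_world_points(spec)

    # canonical (template-frame) anatomy and ground-truth masks
    canon_data = _anatomy(spec, pts).reshape(spec.grid_shape)
    canonical = Volume(canon_data, spec.affine, space="template")
    mt = _region_masks(spec, pts)

    # native frame: canonical point corresponding to native point x is
    # warp(P^{-1} x); for identity pose/warp this is x itself.
    P = _pose_matrix(spec)
    Pinv = np.linalg.inv(P)
    back = pts @ Pinv[:3, :3].T + Pinv[:3, 3]
    warp = _warp_field(spec)
    back = back + warp(back)
    native_data = _anatomy(spec, back).reshape(spec.grid_shape)
    mn = _region_masks(spec, back)

    vol = Volume(native_data, spec.affine, space="native")
    if spec.psf_fwhm_mm > 0:
        vol = gaussian_smooth(vol, spec.psf_fwhm_mm)
    if spec.noise_model != "none" and spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "gaussian":
            # sd proportional to local intensity
            vol.data = vol.data + rng.normal(size=vol.shape) * spec.noise_level * vol.data
        else:  # poisson: scaled counts, sd = sqrt(I * level)
            counts = np.clip(vol.data, 0, None) / spec.noise_level
            vol.data = rng.poisson(counts).astype(float) * spec.noise_level

    def _masks(d: dict[str, np.ndarray], space: str) -> dict[str, VOIMask]:
        roles = {"striatum_left": "striatum_left", "striatum_right": "striatum_right",
                 "reference": "reference", "scalp": "other", "brain": "other"}
        return {k: VOIMask(v.reshape(spec.grid_shape), spec.affine, space=space,
                           role=roles[k]) for k, v in d.items()}

    return PhantomResult(volume=vol, canonical=canonical,
                         masks_template=_masks(mt, "template"),
                         masks_native=_masks(mn, "native"), spec=spec)


def random_pose(rng: np.random.Generator,
                max_translation_mm: float = 5.0,
                max_rotation_deg: float = 5.0,
                max_scale_dev: float = 0.03,
                max_shear: float = 0.02) -> dict:
    """Draw a uniform random pose perturbation within the given limits."""
    return dict(
        translation_mm=tuple(rng.uniform(-max_translation_mm, max_translation_mm, 3)),
        rotation_deg=tuple(rng.uniform(-max_rotation_deg, max_rotation_deg, 3)),
        scale=tuple(1 + rng.uniform(-max_scale_dev, max_scale_dev, 3)),
        shear=tuple(rng.uniform(-max_shear, max_shear, 3)),
    )


def make_cohort_images(cohort: CohortSpec, base: PhantomSpec,
                       records: pd.DataFrame | None = None) -> list[tuple[PhantomResult, dict]]:
    """One phantom per simulated subject.

    The subject's true anatomical striatum/cortex contrast is set to the drawn
    SRR (both sides), and each subject receives an independent random pose.
    Pass ``records`` to image an existing cohort table instead of drawing a
    fresh one.
    """
    cohort.validate()
    if records is None:
        records = draw_srr_cohort(cohort)
    rng = np.random.default_rng(cohort.seed + 10_000)
    out: list[tuple[PhantomResult, dict]] = []
    for _, row in records.iterrows():
        pose = random_pose(rng)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(base, contrast_left=float(row.srr_true),
                       contrast_right=float(row.srr_true), seed=sub_seed, **pose)
        out.append((make_phantom(spec), row.to_dict()))
    return out


# ---------------------------------------------------------------------------
# Statistical cohorts
# ---------------------------------------------------------------------------

def draw_srr_cohort(cohort: CohortSpec) -> pd.DataFrame:
    """Draw per-subject SRR values from Gaussian subgroup distributions.

    Clinical duration is drawn uniformly within each PD subgroup's duration
    range; symptomatic side is drawn at random for PD subjects and is
    ``none`` for non-PD subjects.
    """
    cohort.validate()
    rng = np.random.default_rng(cohort.seed)
    rows = []
    i = 0
    for sg in cohort.subgroups:
        srr = rng.normal(sg.mean_srr, sg.sd_srr, size=sg.n)
        if sg.duration_range is not None:
            dur = rng.uniform(sg.duration_range[0], sg.duration_range[1], size=sg.n)
        else:
            dur = np.full(sg.n, np.nan)
        if sg.group == "PD":
            sides = rng.choice(["left", "right", "bilateral"], size=sg.n,
                               p=[0.45, 0.45, 0.10])
        else:
            sides = np.full(sg.n, "none", dtype=object)
        for k in range(sg.n):
            rows.append(dict(id=f"sub-{i:04d}", group=sg.group, subgroup=sg.label,
                             side=sides[k], duration_years=float(dur[k]),
                             srr_true=float(srr[k])))
            i += 1
    return pd.DataFrame(rows)


def simulate_duration_cohort(coefficients: Sequence[float], per_year_n: Sequence[int],
                             noise_sd: float, seed: int = 0) -> pd.DataFrame:
    """Subjects on a quadratic duration curve, for parameter-recovery tests.

    For year ``x = 1..len(per_year_n)``, draws ``per_year_n[x-1]`` subjects
    with SRR ``a x^2 + b x + c + N(0, noise_sd)`` and a duration inside
    ``(x-1, x]``.
    """
    a, b, c = (float(v) for v in coefficients)
    if any(n < 0 for n in per_year_n):
        raise ValueError("per_year_n must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for year, n in enumerate(per_year_n, start=1):
        y = a * year**2 + b * year + c
        for _ in range(n):
            rows.append(dict(id=f"dur-{i:04d}", group="PD",
                             side="bilateral",
                             duration_years=float(year - rng.uniform(0, 1)),
                             srr_true=float(y + rng.normal(0, noise_sd))))
            i += 1
    return pd.DataFrame(rows)
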