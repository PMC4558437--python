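"""Striatal-to-reference ratio computation, via inverse-mapped or template VOIs.

Two per-subject pipelines are provided.  The *inverse-VOI* pipeline (the
method this package exists for) spatially normalizes the subject to the
template, inverts the transform, pulls the template VOIs back into the
subject's native space, and computes the SRR on the untouched native image.
The *conventional* pipeline applies the template-space VOIs directly to the
spatially normalized image.

The striatal mask follows the contralateral rule: symptoms on the left use
the right striatum and vice versa; bilateral or absent symptoms use both
sides.  SRR = mean(striatum) / mean(reference); the specific uptake ratio is
SRR − 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .registration import (RegistrationParams, invert_transform, map_voi_to_native,
                           save_transform, spatially_normalize)
from .voi_template import TemplateBundle
from .volumes import Volume, VOIMask, mean_in_mask, write_mask

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectRecord",
    "compute_srr",
    "sur_from_srr",
    "run_subject_pipeline",
    "run_conventional_pipeline",
]

SIDES = ("left", "right", "bilateral", "none")


@dataclass
class SubjectRecord:
    id: str
    group: str                      # PD | HC | ET
    side: str = "none"              # symptomatic side
    duration_years: float | None = None
    srr: float | None = None
    method: str | None = None       # inverse_voi | conventional

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.group == "PD" and self.duration_years is None:
            raise ValueError("PD records must carry a clinical duration")
        if self.group != "PD" and self.duration_years is not None \
                and not np.isnan(self.duration_years):
            raise ValueError("non-PD records must not carry a clinical duration")
        if self.srr is not None and self.srr <= 0:
            raise ValueError(f"srr must be positive, got {self.srr}")


def sur_from_srr(srr: float) -> float:
    """Specific uptake ratio: the specific-binding form of the SRR."""
    return srr - 1.0


def _select_striatum(striatum_left: VOIMask, striatum_right: VOIMask,
                     side: str) -> np.ndarray:
    if side == "left":          # contralateral rule
        return striatum_right.data
    if side == "right":
        return striatum_left.data
    if side in ("bilateral", "none"):
        return striatum_left.data | striatum_right.data
    raise ValueError(f"unknown symptomatic side {side!r}")


def compute_srr(native: Volume, striatum_left: VOIMask, striatum_right: VOIMask,
                reference: VOIMask, side: str = "none") -> float:
    """Mean striatal intensity over mean reference intensity.

    The striatum contralateral to the symptomatic ``side`` is used; bilateral
    or absent symptoms use the union of both sides.
    """
    for m in (striatum_left, striatum_right, reference):
        if m.space != "native":
            raise ValueError(f"mask (role={m.role!r}) must be in native space")
        if m.shape != native.shape:
            raise ValueError("mask grid does not match the native volume")
    sel = _select_striatum(striatum_left, striatum_right, side)
    if not sel.any():
        raise ValueError("selected striatal mask is empty")
    ref_mean = mean_in_mask(native, reference)
    if ref_mean <= 0:
        raise ValueError(f"reference mean must be positive, got {ref_mean}")
    return float(native.data[sel].mean() / ref_mean)


def _as_native(mask: VOIMask, affine: np.ndarray) -> VOIMask:
    return VOIMask(mask.data.copy(), affine, space="native", role=mask.role)


def run_subject_pipeline(native: Volume, bundle: TemplateBundle,
                         side: str = "none",
                         params: RegistrationParams | None = None,
                         subject_id: str = "subject", group: str = "HC",
                         duration_years: float | None = None,
                         audit_dir: str | Path | None = None) -> SubjectRecord:
    """Inverse-VOI SRR quantification of one subject.

    Normalize -> invert the transform -> pull the striatal and reference VOIs
    back to native space -> compute the SRR on the original native image.
    When ``audit_dir`` is given, the transform and native-space masks are
    written out so the VOI placement can be confirmed visually.
    """
    params = params or RegistrationParams()
    _, t = spatially_normalize(native, bundle.template, params)
    inv = invert_transform(t, native)
    sl = map_voi_to_native(bundle.striatum_left, inv)
    sr = map_voi_to_native(bundle.striatum_right, inv)
    ref = map_voi_to_native(bundle.reference, inv)
    srr = compute_srr(native, sl, sr, ref, side)
    if audit_dir is not None:
        out = Path(audit_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_transform(t, out / f"{subject_id}_transform")
        write_mask(sl, out / f"{subject_id}_striatum_left.nii.gz")
        write_mask(sr, out / f"{subject_id}_striatum_right.nii.gz")
        write_mask(ref, out / f"{subject_id}_reference.nii.gz")
    logger.info("subject %s: inverse-VOI SRR = %.4f", subject_id, srr)
    return SubjectRecord(id=subject_id, group=group, side=side,
                         duration_years=duration_years, srr=srr,
                         method="inverse_voi")


def run_conventional_pipeline(native: Volume, bundle: TemplateBundle,
                              side: str = "none",
                              params: RegistrationParams | None = None,
                              subject_id: str = "subject", group: str = "HC",
                              duration_years: float | None = None) -> SubjectRecord:
    """Conventional SRR: template-space VOIs applied to the normalized image."""
    params = params or RegistrationParams()
    normalized, _ = spatially_normalize(native, bundle.template, params)
    taff = bundle.template.affine
    srr = compute_srr(normalized.copy_with(space="native"),
                      _as_native(bundle.striatum_left, taff),
                      _as_native(bundle.striatum_right, taff),
                      _as_native(bundle.reference, taff), side)
    logger.info("subject %s: conventional SRR = %.4f", subject_id, srr)
    return SubjectRecord(id=subject_id, group=group, side=side,
                         duration_years=duration_years, srr=srr,
                         method="conventional")
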