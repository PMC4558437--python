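"""Normal-template construction and template-space VOI definition.

The normal template is the voxel-wise average of spatially normalized
healthy-control scans.  Striatal VOIs are segmented from the template itself
by thresholding at a fraction (default 60%) of the template's maximum
intensity — caudate and putamen remain merged within each side, as SPECT
resolution cannot separate them.  The cortical reference VOI is taken from a
user-supplied integer label volume (any atlas, or phantom ground truth)
restricted to a range of transverse slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .registration import RegistrationParams, spatially_normalize
from .volumes import Volume, VOIMask, read_mask, read_volume, write_mask, write_volume

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateBundle",
    "build_normal_template",
    "define_striatal_vois",
    "define_reference_voi",
]


@dataclass
class TemplateBundle:
    """The normal template together with its striatal and reference VOIs."""

    template: Volume
    striatum_left: VOIMask
    striatum_right: VOIMask
    reference: VOIMask
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in (self.striatum_left, self.striatum_right, self.reference):
            if m.shape != self.template.shape:
                raise ValueError(f"mask (role={m.role!r}) not congruent with template grid")
        if np.any(self.striatum_left.data & self.striatum_right.data):
            raise ValueError("left and right striatal masks overlap")
        ref = self.reference.data
        if np.any(ref & (self.striatum_left.data | self.striatum_right.data)):
            raise ValueError("reference mask intersects a striatal mask")

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(self.template, out / "template.nii.gz")
        write_mask(self.striatum_left, out / "striatum_left.nii.gz")
        write_mask(self.striatum_right, out / "striatum_right.nii.gz")
        write_mask(self.reference, out / "reference.nii.gz")
        (out / "provenance.yaml").write_text(yaml.safe_dump(self.provenance))

    @classmethod
    def load(cls, in_dir: str | Path) -> "TemplateBundle":
        p = Path(in_dir)
        prov_file = p / "provenance.yaml"
        prov = yaml.safe_load(prov_file.read_text()) if prov_file.exists() else {}
        return cls(
            template=read_volume(p / "template.nii.gz", space="template"),
            striatum_left=read_mask(p / "striatum_left.nii.gz", role="striatum_left"),
            striatum_right=read_mask(p / "striatum_right.nii.gz", role="striatum_right"),
            reference=read_mask(p / "reference.nii.gz", role="reference"),
            provenance=prov or {},
        )


def build_normal_template(controls: list[Volume], reference: Volume,
                          params: RegistrationParams | None = None,
                          *, register: bool = True,
                          intensity_normalize: bool = True,
                          control_ids: list[str] | None = None
                          ) -> tuple[Volume, dict]:
    """Average spatially normalized control scans into a normal template.

    Each control is normalized to ``reference`` (a scalp-bearing volume in
    template space), optionally scaled to unit mean intensity within the
    reference brain region, and the voxel-wise arithmetic mean is returned.
    Set ``register=False`` for controls already on the template grid.
    """
    if len(controls) < 2:
        raise ValueError(f"need at least 2 control volumes, got {len(controls)}")
    brain = reference.data > 0.05 * reference.data.max()
    acc = np.zeros(reference.shape)
    ids = control_ids or [f"control-{i:02d}" for i in range(len(controls))]
    failures = []
    n_ok = 0
    for cid, ctl in zip(ids, controls):
        try:
            if register:
                warped, _ = spatially_normalize(ctl, reference, params)
            else:
                if ctl.shape != reference.shape:
                    raise ValueError("unregistered control not on the template grid")
                warped = ctl
            data = warped.data
            if intensity_normalize:
                m = float(data[brain].mean())
                if m <= 0:
                    raise ValueError("non-positive mean intensity in brain region")
                data = data / m
            acc += data
            n_ok += 1
        except Exception as exc:  # noqa: BLE001 - reported per subject
            failures.append((cid, str(exc)))
            logger.error("control %s failed normalization: %s", cid, exc)
    if failures and n_ok < 2:
        raise RuntimeError(f"template construction failed: {failures}")
    template = Volume(acc / n_ok, reference.affine, space="template")
    provenance = dict(controls=ids, n_used=n_ok,
                      failures=[f"{c}: {m}" for c, m in failures],
                      intensity_normalized=bool(intensity_normalize),
                      registered=bool(register))
    return template, provenance


def define_striatal_vois(template: Volume, threshold_fraction: float = 0.6
                         ) -> tuple[VOIMask, VOIMask]:
    """Segment left/right striatal VOIs by relative thresholding.

    Voxels at or above ``threshold_fraction`` of the template maximum are
    kept; 26-connected components are extracted and the two largest are
    assigned to hemispheres by the world-space x sign of their centroids
    (RAS: +x is the subject's right).  A single component spanning the
    midline is split at the mid-sagittal plane.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    data = template.data
    cand = data >= threshold_fraction * data.max()
    if cand.mean() > 0.25:
        raise ValueError("thresholding selected most of the volume; the template "
                         "has no supra-threshold striatal structure")
    labels, n = ndimage.label(cand, structure=np.ones((3, 3, 3)))
    if n < 1:
        raise ValueError("no supra-threshold component found")

    # world x coordinate per voxel, for left/right assignment
    def centroid_x(mask: np.ndarray) -> float:
        com = ndimage.center_of_mass(mask)
        world = template.affine[:3, :3] @ np.asarray(com) + template.affine[:3, 3]
        return float(world[0])

    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    if n == 1:
        comp = labels == order[0]
        # split a midline-spanning blob at the mid-sagittal plane (world x = 0)
        i = np.arange(template.shape[0])
        wx = template.affine[0, 0] * i + template.affine[0, 3]
        right = comp & (wx[:, None, None] > 0)
        left = comp & (wx[:, None, None] <= 0)
        if not right.any() or not left.any():
            raise ValueError("single supra-threshold component cannot be split at the midline")
    else:
        a = labels == order[0]
        b = labels == order[1]
        if (centroid_x(a) > 0) == (centroid_x(b) > 0):
            raise ValueError("two largest components lie on the same side of the midline")
        right, left = (a, b) if centroid_x(a) > 0 else (b, a)
    return (VOIMask(left, template.affine, space="template", role="striatum_left"),
            VOIMask(right, template.affine, space="template", role="striatum_right"))


def define_reference_voi(labels: Volume, included_labels: set[int],
                         slice_range: tuple[int, int],
                         striatal_masks: tuple[VOIMask, ...] = ()) -> VOIMask:
    """Build the cortical reference VOI from an integer label volume.

    The mask is the union of the requested labels restricted to the inclusive
    axial (z) slice range; voxels belonging to any supplied striatal VOI are
    excluded.
    """
    lo, hi = slice_range
    nz = labels.shape[2]
    if lo > hi or lo < 0 or hi >= nz:
        raise ValueError(f"slice_range {slice_range} is empty or out of bounds [0, {nz - 1}]")
    lab = np.rint(labels.data).astype(int)
    mask = np.isin(lab, list(included_labels))
    zsel = np.zeros(nz, dtype=bool)
    zsel[lo:hi + 1] = True
    mask &= zsel[None, None, :]
    for sm in striatal_masks:
        mask &= ~sm.data
    if not mask.any():
        raise ValueError("reference VOI is empty for the given labels/slice range")
    return VOIMask(mask, labels.affine, space="template", role="reference")
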