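"""Shared fixtures: phantoms, a blur-matched template, and a truth-based bundle.

Session-scoped image fixtures are reused across registration/SRR tests to
keep the suite fast; every fixture is deterministic (fixed seeds, no ambient
randomness).
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import srrquant as sq
from srrquant.volumes import VOIMask


@pytest.fixture(scope="session")
def reg_params() -> sq.RegistrationParams:
    return sq.RegistrationParams()


@pytest.fixture(scope="session")
def canonical_phantom() -> sq.PhantomResult:
    """Identity-posed, noiseless phantom at SPECT-like resolution."""
    return sq.make_phantom(sq.PhantomSpec(psf_fwhm_mm=8.0))


@pytest.fixture(scope="session")
def blurred_template(canonical_phantom) -> sq.Volume:
    """Registration target whose smoothness matches an 8-mm-smoothed scan."""
    return sq.gaussian_smooth(canonical_phantom.volume, 8.0).copy_with(space="template")


def _erode(mask: np.ndarray) -> np.ndarray:
    return ndimage.binary_erosion(mask, np.ones((3, 3, 3)))


@pytest.fixture(scope="session")
def truth_bundle(canonical_phantom, blurred_template) -> sq.TemplateBundle:
    """Template bundle whose VOIs are eroded generator ground truth.

    Eroding by one voxel keeps the VOIs strictly inside the true anatomical
    regions, so end-to-end SRR accuracy isolates registration/inversion error
    from VOI-definition error.
    """
    aff = blurred_template.affine
    mt = canonical_phantom.masks_template
    return sq.TemplateBundle(
        template=blurred_template,
        striatum_left=VOIMask(_erode(mt["striatum_left"].data), aff,
                              space="template", role="striatum_left"),
        striatum_right=VOIMask(_erode(mt["striatum_right"].data), aff,
                               space="template", role="striatum_right"),
        reference=VOIMask(_erode(mt["reference"].data), aff,
                          space="template", role="reference"),
        provenance={"source": "synthetic phantom ground truth, eroded 1 voxel"},
    )
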