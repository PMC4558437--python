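"""Spatial normalization: affine/nonlinear estimation, inversion, VOI pull-back."""

import dataclasses

import numpy as np
import pytest

import srrquant as sq
from srrquant.registration import _bending_diagonal
from srrquant.volumes import VOIMask


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])


def _smoothed_ssd(source: sq.Volume, template: sq.Volume, t: sq.Transform,
                  fwhm: float = 8.0) -> float:
    """SSD between the warped smoothed source and the template, with the
    optimal global intensity scale (the registration's own matching domain)."""
    w = sq.resample_to_template(sq.gaussian_smooth(source, fwhm), t).data
    tm = template.data
    s = float((w * tm).sum() / (w * w).sum())
    return float(((s * w - tm) ** 2).sum())


class TestAffine:
    def test_self_registration_is_identity(self, blurred_template, reg_params):
        src = blurred_template.copy_with(space="native")
        t = sq.estimate_affine(src, blurred_template, reg_params)
        # within 0.1 voxel (0.29 mm) of identity over the brain extent
        assert np.abs(t.affine[:3, 3]).max() < 0.29
        assert np.abs(t.affine[:3, :3] - np.eye(3)).max() < 0.29 / 80.0

    def test_two_voxel_translation_recovered(self, blurred_template, reg_params):
        src = sq.make_phantom(sq.PhantomSpec(psf_fwhm_mm=8.0,
                                             translation_mm=(0.0, 5.8, 0.0))).volume
        t = sq.estimate_affine(src, blurred_template, reg_params)
        assert np.abs(t.affine[:3, 3] - (0.0, 5.8, 0.0)).max() < 0.2 * 2.9

    def test_five_degree_rotation_recovered(self, blurred_template, reg_params):
        src = sq.make_phantom(sq.PhantomSpec(psf_fwhm_mm=8.0,
                                             rotation_deg=(0.0, 0.0, 5.0))).volume
        t = sq.estimate_affine(src, blurred_template, reg_params)
        R = t.affine[:3, :3]
        angle = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
        assert angle == pytest.approx(5.0, abs=0.5)

    def test_constant_image_rejected(self, blurred_template, reg_params):
        flat = blurred_template.copy_with(data=np.ones(blurred_template.shape))
        with pytest.raises(ValueError, match="constant"):
            sq.estimate_affine(flat, blurred_template, reg_params)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="iterations"):
            sq.RegistrationParams(nonlinear_iterations=0).validate(2.9)
        with pytest.raises(ValueError, match="cutoff"):
            sq.RegistrationParams(basis_cutoff_mm=5.0).validate(2.9)


class TestNonlinear:
    def test_self_registration_warp_is_negligible(self, blurred_template, reg_params):
        src = blurred_template.copy_with(space="native")
        t0 = sq.estimate_affine(src, blurred_template, reg_params)
        t = sq.estimate_nonlinear(src, blurred_template, t0, reg_params)
        u = t.displacement_grid()
        warp_energy = float((u**2).sum())
        image_energy = float((blurred_template.data**2).sum())
        assert warp_energy <= 1e-3 * image_energy

    def test_known_warp_reduces_ssd_to_fifth(self, blurred_template, reg_params):
        src = sq.make_phantom(sq.PhantomSpec(psf_fwhm_mm=8.0, warp_amplitude_mm=4.0,
                                             seed=5)).volume
        t_aff = sq.estimate_affine(src, blurred_template, reg_params)
        t_nl = sq.estimate_nonlinear(src, blurred_template, t_aff, reg_params)
        ssd_before = _smoothed_ssd(src, blurred_template, t_aff)
        ssd_after = _smoothed_ssd(src, blurred_template, t_nl)
        assert ssd_after <= 0.2 * ssd_before

    def test_stronger_regularization_does_not_increase_bending(self, blurred_template,
                                                               reg_params):
        src = sq.make_phantom(sq.PhantomSpec(psf_fwhm_mm=8.0, warp_amplitude_mm=4.0,
                                             seed=9)).volume
        t_aff = sq.estimate_affine(src, blurred_template, reg_params)
        heavy = dataclasses.replace(reg_params, regularization_weight=2.0)
        t1 = sq.estimate_nonlinear(src, blurred_template, t_aff, reg_params)
        t2 = sq.estimate_nonlinear(src, blurred_template, t_aff, heavy)
        lam = _bending_diagonal(t1.basis_order, blurred_template.shape,
                                blurred_template.voxel_size).reshape(3, -1)
        be1 = float((lam * t1.coeffs.reshape(3, -1) ** 2).sum())
        be2 = float((lam * t2.coeffs.reshape(3, -1) ** 2).sum())
        assert be2 <= be1 + 1e-12


class TestSpatiallyNormalize:
    def test_identity_pose_high_correlation(self, canonical_phantom, blurred_template,
                                            reg_params):
        norm, _ = sq.spatially_normalize(canonical_phantom.volume, blurred_template,
                                         reg_params)
        assert _corr(norm.data, blurred_template.data) >= 0.99

    def test_registration_improves_correlation(self, blurred_template, reg_params):
        src = sq.make_phantom(sq.PhantomSpec(psf_fwhm_mm=8.0,
                                             translation_mm=(5.0, 0.0, 0.0),
                                             rotation_deg=(0.0, 0.0, 5.0),
                                             warp_amplitude_mm=3.0, seed=2)).volume
        norm, t = sq.spatially_normalize(src, blurred_template, reg_params)
        assert _corr(norm.data, blurred_template.data) > _corr(src.data,
                                                               blurred_template.data)

    def test_transform_serialization_roundtrip(self, tmp_path, blurred_template,
                                               reg_params):
        src = sq.make_phantom(sq.PhantomSpec(psf_fwhm_mm=8.0,
                                             translation_mm=(3.0, -2.0, 1.0))).volume
        norm, t = sq.spatially_normalize(src, blurred_template, reg_params)
        sq.save_transform(t, tmp_path / "t")
        t2 = sq.load_transform(tmp_path / "t")
        assert np.array_equal(t.affine, t2.affine)
        assert np.array_equal(t.coeffs, t2.coeffs)
        norm2 = sq.resample_to_template(src, t2)
        assert np.max(np.abs(norm.data - norm2.data)) < 1e-6


def _identity_transform(template: sq.Volume, order=(3, 3, 3)) -> sq.Transform:
    return sq.Transform(affine=np.eye(4), coeffs=np.zeros((3, *order)),
                        template_shape=template.shape,
                        template_affine=template.affine)


class TestInvertTransform:
    def test_identity_inverts_to_identity(self, blurred_template):
        t = _identity_transform(blurred_template)
        inv = sq.invert_transform(t, blurred_template)
        idx = np.stack(np.meshgrid(*[np.arange(n) for n in blurred_template.shape],
                                   indexing="ij"), axis=0).astype(float)
        assert np.max(np.abs(inv.coords - idx)) < 1e-10
        assert inv.residual.max() == 0.0

    def test_pure_affine_roundtrip_is_exact(self, blurred_template):
        M = np.eye(4)
        M[:3, :3] = np.array([[1.05, 0.02, 0.0], [0.0, 0.97, 0.01], [0.0, 0.0, 1.02]])
        M[:3, 3] = (4.0, -3.0, 2.0)
        t = _identity_transform(blurred_template)
        t.affine = M
        inv = sq.invert_transform(t, blurred_template)
        # composition of the affine and its closed-form inverse is identity
        assert np.max(np.abs(t.affine @ np.linalg.inv(t.affine) - np.eye(4))) < 1e-10
        assert inv.residual.max() < 1e-8

    def test_smooth_warp_roundtrip_residual(self, blurred_template):
        rng = np.random.default_rng(0)
        t = _identity_transform(blurred_template, order=(4, 4, 4))
        t.coeffs = rng.normal(scale=1.0, size=(3, 4, 4, 4))  # few-mm smooth warp
        inv = sq.invert_transform(t, blurred_template, tolerance_voxels=0.2)
        brain = blurred_template.data > 0.05 * blurred_template.data.max()
        assert np.mean(inv.residual[brain] <= 0.2) >= 0.99

    def test_folding_transform_rejected(self, blurred_template):
        t = _identity_transform(blurred_template, order=(4, 4, 4))
        t.coeffs = np.zeros((3, 4, 4, 4))
        t.coeffs[0, 3, 0, 0] = 120.0  # gradient exceeds voxel spacing: folds
        with pytest.raises(ValueError, match="not invertible"):
            sq.invert_transform(t, blurred_template)


class TestMapVoiToNative:
    def test_identity_preserves_mask(self, canonical_phantom, blurred_template):
        voi = canonical_phantom.masks_template["striatum_left"]
        inv = sq.invert_transform(_identity_transform(blurred_template),
                                  blurred_template)
        out = sq.map_voi_to_native(voi, inv)
        assert np.array_equal(out.data, voi.data)
        assert out.space == "native"
        assert out.role == "striatum_left"

    def test_integer_translation_commutes_exactly(self, canonical_phantom,
                                                  blurred_template):
        voi = canonical_phantom.masks_template["striatum_left"]
        t = _identity_transform(blurred_template)
        shift_vox = (2, -1, 3)
        t.affine = np.eye(4)
        t.affine[:3, 3] = np.asarray(shift_vox) * blurred_template.voxel_size
        inv = sq.invert_transform(t, blurred_template)
        out = sq.map_voi_to_native(voi, inv)
        expected = np.roll(voi.data, shift_vox, axis=(0, 1, 2))
        assert np.array_equal(out.data, expected)

    def test_uniform_scaling_scales_volume_cubically(self, canonical_phantom,
                                                     blurred_template):
        # large VOI so discretized-boundary effects stay well below 5%
        voi = canonical_phantom.masks_template["brain"]
        s = 0.9
        t = _identity_transform(blurred_template)
        c = (np.asarray(blurred_template.shape) - 1) / 2.0
        world_c = blurred_template.affine[:3, :3] @ c + blurred_template.affine[:3, 3]
        t.affine = np.eye(4)
        t.affine[:3, :3] *= s
        t.affine[:3, 3] = world_c - s * world_c
        inv = sq.invert_transform(t, blurred_template)
        out = sq.map_voi_to_native(voi, inv)
        assert out.n_voxels == pytest.approx(voi.n_voxels * s**3, rel=0.05)

    def test_native_space_voi_rejected(self, canonical_phantom, blurred_template):
        inv = sq.invert_transform(_identity_transform(blurred_template),
                                  blurred_template)
        native_voi = canonical_phantom.masks_native["striatum_left"]
        with pytest.raises(ValueError, match="template-space"):
            sq.map_voi_to_native(native_voi, inv)
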