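"""Normal-template construction and VOI definition."""

import numpy as np
import pytest

import srrquant as sq
from srrquant.volumes import VOIMask


def _corr(a, b):
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])


@pytest.fixture(scope="module")
def posed_controls():
    """Four noisy control phantoms with independent random poses."""
    rng = np.random.default_rng(0)
    controls = []
    for i in range(4):
        pose = sq.phantom.random_pose(rng)
        spec = sq.PhantomSpec(psf_fwhm_mm=8.0, contrast_left=2.02,
                              contrast_right=2.02, noise_model="gaussian",
                              noise_level=0.05, seed=100 + i, **pose)
        controls.append(sq.make_phantom(spec).volume)
    return controls


@pytest.fixture(scope="module")
def built_template(posed_controls, reg_params):
    ref = sq.gaussian_smooth(
        sq.make_phantom(sq.PhantomSpec(psf_fwhm_mm=8.0, contrast_left=2.02,
                                       contrast_right=2.02)).volume,
        8.0).copy_with(space="template")
    template, prov = sq.build_normal_template(posed_controls, ref, reg_params)
    return template, prov, ref


class TestBuildNormalTemplate:
    def test_average_of_identical_aligned_volumes_is_identity(self, blurred_template):
        v = blurred_template
        template, _ = sq.build_normal_template([v, v], v, register=False,
                                               intensity_normalize=False)
        assert np.max(np.abs(template.data - v.data)) < 1e-6

    def test_hand_mean_of_constant_volumes(self, blurred_template):
        aff = blurred_template.affine
        ones = sq.Volume(np.ones((16, 16, 16)), aff, space="template")
        threes = sq.Volume(3 * np.ones((16, 16, 16)), aff, space="template")
        ref = sq.Volume(np.ones((16, 16, 16)), aff, space="template")
        template, _ = sq.build_normal_template([ones, threes], ref, register=False,
                                               intensity_normalize=False)
        assert np.allclose(template.data, 2.0)

    def test_fewer_than_two_controls_rejected(self, blurred_template):
        with pytest.raises(ValueError, match="at least 2"):
            sq.build_normal_template([blurred_template], blurred_template)

    def test_template_beats_every_misaligned_input(self, built_template,
                                                   posed_controls):
        template, prov, ref = built_template
        input_corrs = [_corr(c.data, ref.data) for c in posed_controls]
        assert _corr(template.data, ref.data) >= max(input_corrs)
        assert prov["n_used"] == 4


class TestDefineStriatalVois:
    def _two_blob_template(self):
        data = np.zeros((32, 32, 32))
        data[6:10, 14:18, 14:18] = 7.0    # supra-threshold, left of midline
        data[22:26, 14:18, 14:18] = 10.0  # right of midline; max = 10
        data[14:18, 4:8, 14:18] = 3.0     # below 60% of max
        aff = np.diag([2.9, 2.9, 2.9, 1.0])
        aff[:3, 3] = -2.9 * 31 / 2
        return sq.Volume(data, aff, space="template")

    def test_two_blobs_give_one_mask_per_side(self):
        sl, sr = sq.define_striatal_vois(self._two_blob_template(), 0.6)
        assert sl.n_voxels == sr.n_voxels == 64
        assert not np.any(sl.data & sr.data)
        # left mask occupies the low-x half of the grid
        assert np.flatnonzero(sl.data.any(axis=(1, 2))).max() < 16

    def test_uniform_template_rejected(self):
        aff = np.eye(4)
        flat = sq.Volume(np.ones((16, 16, 16)), aff, space="template")
        with pytest.raises(ValueError, match="supra-threshold"):
            sq.define_striatal_vois(flat, 0.6)

    def test_phantom_template_vois_overlap_ground_truth(self, built_template,
                                                        canonical_phantom):
        template, _, _ = built_template
        sl, sr = sq.define_striatal_vois(template, 0.6)
        for mask, key in ((sl, "striatum_left"), (sr, "striatum_right")):
            truth = canonical_phantom.masks_template[key].data
            dice = 2 * np.sum(mask.data & truth) / (mask.n_voxels + truth.sum())
            assert dice >= 0.7

    def test_invariant_to_global_intensity_scaling(self, built_template):
        template, _, _ = built_template
        sl1, sr1 = sq.define_striatal_vois(template, 0.6)
        scaled = template.copy_with(data=template.data * 37.0)
        sl2, sr2 = sq.define_striatal_vois(scaled, 0.6)
        assert np.array_equal(sl1.data, sl2.data)
        assert np.array_equal(sr1.data, sr2.data)

    def test_voxel_count_nonincreasing_in_threshold(self, built_template):
        template, _, _ = built_template
        counts = []
        for frac in (0.5, 0.6, 0.7, 0.8):
            sl, sr = sq.define_striatal_vois(template, frac)
            counts.append(sl.n_voxels + sr.n_voxels)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDefineReferenceVoi:
    def test_ribbon_labels_minus_striatum(self, canonical_phantom, blurred_template):
        ribbon = canonical_phantom.masks_template["reference"]
        labels = sq.Volume(ribbon.data.astype(float), blurred_template.affine,
                           space="template")
        sl = canonical_phantom.masks_template["striatum_left"]
        nz = blurred_template.shape[2]
        voi = sq.define_reference_voi(labels, {1}, (0, nz - 1), (sl,))
        expected = ribbon.data & ~sl.data
        assert np.array_equal(voi.data, expected)
        assert voi.role == "reference"

    def test_empty_slice_range_rejected(self, canonical_phantom, blurred_template):
        ribbon = canonical_phantom.masks_template["reference"]
        labels = sq.Volume(ribbon.data.astype(float), blurred_template.affine,
                           space="template")
        with pytest.raises(ValueError, match="slice_range"):
            sq.define_reference_voi(labels, {1}, (20, 10))

    def test_restricting_slices_never_grows_mask(self, canonical_phantom,
                                                 blurred_template):
        ribbon = canonical_phantom.masks_template["reference"]
        labels = sq.Volume(ribbon.data.astype(float), blurred_template.affine,
                           space="template")
        nz = blurred_template.shape[2]
        full = sq.define_reference_voi(labels, {1}, (0, nz - 1))
        prev = full.n_voxels
        for lo, hi in ((5, nz - 6), (10, nz - 11), (20, nz - 21)):
            sub = sq.define_reference_voi(labels, {1}, (lo, hi))
            assert sub.n_voxels <= prev
            assert np.all(full.data[sub.data])  # subset property
            prev = sub.n_voxels


class TestTemplateBundle:
    def test_disjointness_enforced(self, truth_bundle):
        with pytest.raises(ValueError, match="intersects"):
            sq.TemplateBundle(template=truth_bundle.template,
                              striatum_left=truth_bundle.striatum_left,
                              striatum_right=truth_bundle.striatum_right,
                              reference=truth_bundle.striatum_left)

    def test_save_load_roundtrip(self, tmp_path, truth_bundle):
        truth_bundle.save(tmp_path / "bundle")
        back = sq.TemplateBundle.load(tmp_path / "bundle")
        assert np.allclose(back.template.data, truth_bundle.template.data)
        assert np.array_equal(back.striatum_left.data, truth_bundle.striatum_left.data)
        assert np.array_equal(back.reference.data, truth_bundle.reference.data)
        assert back.provenance == truth_bundle.provenance
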