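import numpy as np
import pytest

from anevrix.anatomy_prior import (
    LandmarkSet,
    PatchSample,
    augment_patch,
    augment_patch_param,
    map_landmarks,
    sample_negative_patches,
    sample_positive_patches,
)
from anevrix.dataio import VolumeGrid


@pytest.fixture
def landmarks():
    rng = np.random.default_rng(0)
    return LandmarkSet([f"lm{i}" for i in range(5)], rng.random((5, 3)) * 50)


class TestLandmarks:
    def test_unique_names_enforced(self):
        with pytest.raises(ValueError):
            LandmarkSet(["a", "a"], np.zeros((2, 3)))

    def test_identity_transform(self, landmarks):
        out = map_landmarks(landmarks, np.eye(4))
        assert np.allclose(out.points, landmarks.points)
        assert out.names == landmarks.names

    def test_translation(self, landmarks):
        t = np.eye(4)
        t[0, 3] = 5.0
        out = map_landmarks(landmarks, t)
        assert np.allclose(out.points[:, 0], landmarks.points[:, 0] + 5)
        assert np.allclose(out.points[:, 1:], landmarks.points[:, 1:])

    def test_scale_then_inverse(self, landmarks):
        s = np.diag([2.0, 2.0, 2.0, 1.0])
        out = map_landmarks(map_landmarks(landmarks, s), np.linalg.inv(s))
        assert np.allclose(out.points, landmarks.points, atol=1e-9)

    def test_singular_rejected(self, landmarks):
        t = np.eye(4)
        t[1, 1] = 0
        with pytest.raises(ValueError):
            map_landmarks(landmarks, t)

    def test_tsv_roundtrip(self, landmarks, tmp_path):
        landmarks.to_tsv(tmp_path / "lm.tsv")
        back = LandmarkSet.from_tsv(tmp_path / "lm.tsv")
        assert back.names == landmarks.names
        assert np.allclose(back.points, landmarks.points)


class TestPositiveSampling:
    def test_eight_per_lesion(self, phantom_case):
        patches = sample_positive_patches(phantom_case.image,
                                          phantom_case.lesion_mask, seed=0)
        assert len(patches) == 8
        for p in patches:
            assert p.provenance == "positive"
            assert p.label.any()
            assert p.side == 64

    def test_lesion_fully_contained(self, phantom_case):
        lesion_voxels = int(phantom_case.lesion_mask.data.sum())
        patches = sample_positive_patches(phantom_case.image,
                                          phantom_case.lesion_mask, seed=1)
        for p in patches:
            assert int(p.label.sum()) == lesion_voxels

    def test_corner_lesion_clamped(self):
        img = np.zeros((70, 70, 70), dtype=np.float32)
        mask = np.zeros_like(img, dtype=np.uint8)
        mask[:3, :3, :3] = 1
        g = VolumeGrid(img, np.eye(4))
        patches = sample_positive_patches(g, g.like(mask), seed=0)
        assert len(patches) == 8
        for p in patches:
            assert p.offset == (0, 0, 0)  # only valid containment offset
            assert int(p.label.sum()) == 27

    def test_two_lesions_give_16(self):
        img = np.zeros((80, 80, 80), dtype=np.float32)
        mask = np.zeros_like(img, dtype=np.uint8)
        mask[10:13, 10:13, 10:13] = 1
        mask[60:62, 60:62, 60:62] = 1
        g = VolumeGrid(img, np.eye(4))
        patches = sample_positive_patches(g, g.like(mask), seed=0)
        assert len(patches) == 16
        counts = sorted({int(p.label.sum()) for p in patches})
        assert counts == [8, 27]

    def test_oversize_lesion_errors(self):
        img = np.zeros((80, 80, 80), dtype=np.float32)
        mask = np.zeros_like(img, dtype=np.uint8)
        mask[0:70, 40, 40] = 1
        g = VolumeGrid(img, np.eye(4))
        with pytest.raises(ValueError, match="bounding box"):
            sample_positive_patches(g, g.like(mask), seed=0)

    def test_seeded_determinism(self, phantom_case):
        a = sample_positive_patches(phantom_case.image, phantom_case.lesion_mask, seed=5)
        b = sample_positive_patches(phantom_case.image, phantom_case.lesion_mask, seed=5)
        assert [p.offset for p in a] == [p.offset for p in b]


class TestNegativeSampling:
    def test_default_counts(self, phantom_case):
        neg = sample_negative_patches(phantom_case.image, phantom_case.lesion_mask,
                                      phantom_case.landmarks, seed=0)
        assert len(neg) == 50
        from collections import Counter

        c = Counter(p.provenance for p in neg)
        assert c == {"landmark_negative": 20, "vessel_negative": 20,
                     "random_negative": 10}

    def test_all_labels_empty(self, phantom_case):
        neg = sample_negative_patches(phantom_case.image, phantom_case.lesion_mask,
                                      phantom_case.landmarks, seed=0)
        assert all(not p.label.any() for p in neg)

    def test_negatives_disjoint_from_lesions(self, phantom_case):
        lesion = phantom_case.lesion_mask.data.astype(bool)
        neg = sample_negative_patches(phantom_case.image, phantom_case.lesion_mask,
                                      phantom_case.landmarks, side=32, seed=2)
        for p in neg:
            sl = tuple(slice(o, o + 32) for o in p.offset)
            assert not lesion[sl].any()

    def test_random_only_with_empty_landmarks(self, phantom_case):
        neg = sample_negative_patches(phantom_case.image, phantom_case.lesion_mask,
                                      None, counts=(0, 0, 5), seed=0)
        assert len(neg) == 5
        assert all(p.provenance == "random_negative" for p in neg)

    def test_landmark_requested_without_landmarks(self, phantom_case):
        with pytest.raises(ValueError, match="landmark"):
            sample_negative_patches(phantom_case.image, phantom_case.lesion_mask,
                                    None, counts=(5, 0, 0), seed=0)

    def test_intensity_matching_rationale(self, phantom_case):
        # anatomically-targeted negatives are brighter on average than the
        # uniform-random ones
        neg = sample_negative_patches(phantom_case.image, phantom_case.lesion_mask,
                                      phantom_case.landmarks, side=16, seed=3)
        anat = np.mean([p.intensities.mean() for p in neg
                        if p.provenance != "random_negative"])
        rand = np.mean([p.intensities.mean() for p in neg
                        if p.provenance == "random_negative"])
        assert anat > rand

    def test_seeded_determinism(self, phantom_case):
        a = sample_negative_patches(phantom_case.image, phantom_case.lesion_mask,
                                    phantom_case.landmarks, seed=9)
        b = sample_negative_patches(phantom_case.image, phantom_case.lesion_mask,
                                    phantom_case.landmarks, seed=9)
        assert [p.offset for p in a] == [p.offset for p in b]


def _toy_patch():
    rng = np.random.default_rng(0)
    img = rng.random((8, 8, 8))
    lab = np.zeros((8, 8, 8), dtype=np.uint8)
    lab[2:4, 3:5, 4:6] = 1
    return PatchSample(img, lab, "positive", (0, 0, 0))


class TestAugmentation:
    def test_rot90_four_times_identity(self):
        p = _toy_patch()
        q = p
        for _ in range(4):
            q = augment_patch(q, ["rot90"], seed=0)
        assert np.allclose(q.intensities, p.intensities)
        assert np.array_equal(q.label, p.label)

    def test_flip_twice_identity(self):
        p = _toy_patch()
        q = augment_patch(augment_patch(p, ["flip_h"], 0), ["flip_h"], 0)
        assert np.allclose(q.intensities, p.intensities)
        q = augment_patch(augment_patch(p, ["flip_v"], 0), ["flip_v"], 0)
        assert np.allclose(q.intensities, p.intensities)

    def test_identity_parameters(self):
        p = _toy_patch()
        assert np.allclose(augment_patch_param(p, "gamma", 1.0).intensities,
                           p.intensities)
        assert np.allclose(augment_patch_param(p, "contrast", 1.0).intensities,
                           p.intensities)

    def test_geometric_ops_preserve_label_count(self):
        p = _toy_patch()
        for op in ["rot90", "rot180", "rot270", "flip_h", "flip_v"]:
            q = augment_patch(p, [op], seed=1)
            assert q.label.sum() == p.label.sum()

    def test_intensity_ops_leave_label(self):
        p = _toy_patch()
        q = augment_patch(p, ["contrast", "gamma", "gauss_noise"], seed=1)
        assert np.array_equal(q.label, p.label)
        assert not np.allclose(q.intensities, p.intensities)

    def test_unknown_op(self):
        with pytest.raises(ValueError, match="unknown"):
            augment_patch(_toy_patch(), ["shear"], seed=0)


class TestPatchSampleInvariants:
    def test_positive_requires_nonempty_label(self):
        img = np.zeros((4, 4, 4))
        with pytest.raises(ValueError):
            PatchSample(img, np.zeros_like(img, dtype=np.uint8), "positive", (0, 0, 0))

    def test_cubic_required(self):
        with pytest.raises(ValueError):
            PatchSample(np.zeros((4, 4, 5)), np.zeros((4, 4, 5)), "random_negative",
                        (0, 0, 0))
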