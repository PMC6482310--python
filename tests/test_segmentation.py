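"""Reflectivity-profile tissue classification: bases, features, forest, en-face mask."""

import numpy as np
import pytest

from ocapdt.phantom import generate_attenuation_phantom
from ocapdt.segmentation import (
    ClassBases,
    ProfileFeatureSpec,
    build_class_bases,
    build_segmentation_model,
    extract_features,
    segment_volume,
    train_segmenter,
)

SPEC = ProfileFeatureSpec(profile_length=16, n_components_per_basis=2)


def decay_profiles(rate: float, n: int, length: int, rng) -> np.ndarray:
    z = np.arange(length)
    base = np.exp(-rate * z)
    return base[None, :] * (1.0 + 0.05 * rng.standard_normal((n, length)))


def sample_training_profiles(volume, mask2d, spec, n, seed):
    """Depth windows drawn from labelled en-face positions of a phantom."""
    rng = np.random.default_rng(seed)
    mag = volume.magnitude()
    nz = mag.shape[0]
    ys, xs = np.nonzero(mask2d)
    pick = rng.choice(len(ys), size=n)
    half = spec.profile_length // 2
    zs = rng.integers(half, nz - (spec.profile_length - half) + 1, size=n)
    return np.stack(
        [mag[z - half: z - half + spec.profile_length, ys[i], xs[i]]
         for z, i in zip(zs, pick)]
    )


class TestClassBases:
    def test_orthonormal(self, rng):
        normal = decay_profiles(0.05, 30, 16, rng)
        tumour = decay_profiles(0.15, 30, 16, rng)
        bases = build_class_bases(normal, tumour, SPEC)
        for b in (bases.normal_basis, bases.tumour_basis):
            np.testing.assert_allclose(b @ b.T, np.eye(2), atol=1e-10)

    def test_collinear_profiles_single_component(self, rng):
        v = rng.normal(size=16)
        profiles = np.outer(rng.uniform(0.5, 2.0, size=10), v)
        spec = ProfileFeatureSpec(profile_length=16, n_components_per_basis=1)
        bases = build_class_bases(profiles, decay_profiles(0.1, 10, 16, rng), spec)
        vhat = v - v.mean()
        vhat /= np.linalg.norm(vhat)
        assert abs(float(bases.normal_basis[0] @ vhat)) == pytest.approx(1.0, abs=1e-10)

    def test_distinct_decay_rates_give_distinct_bases(self, rng):
        normal = decay_profiles(0.05, 50, 16, rng)
        tumour = decay_profiles(0.15, 50, 16, rng)
        bases = build_class_bases(normal, tumour, SPEC)
        cos = abs(float(bases.normal_basis[0] @ bases.tumour_basis[0]))
        assert cos < 0.99

    def test_deterministic_up_to_sign(self, rng):
        normal = decay_profiles(0.05, 30, 16, rng)
        tumour = decay_profiles(0.15, 30, 16, rng)
        b1 = build_class_bases(normal, tumour, SPEC)
        b2 = build_class_bases(normal.copy(), tumour.copy(), SPEC)
        dots = np.abs(np.sum(b1.normal_basis * b2.normal_basis, axis=1))
        np.testing.assert_allclose(dots, 1.0, atol=1e-10)

    def test_rank_deficient_set_rejected_naming_class(self, rng):
        v = rng.normal(size=16)
        degenerate = np.outer(np.ones(10), v)
        with pytest.raises(ValueError, match="tumour"):
            build_class_bases(decay_profiles(0.05, 30, 16, rng), degenerate, SPEC)

    def test_too_few_profiles_rejected(self, rng):
        with pytest.raises(ValueError, match="normal"):
            build_class_bases(decay_profiles(0.05, 1, 16, rng),
                              decay_profiles(0.15, 30, 16, rng), SPEC)


class TestFeatures:
    def test_features_equal_direct_inner_products(self, rng):
        """Oracle equivalence: projection coefficients are plain dot products."""
        normal = decay_profiles(0.05, 30, 16, rng)
        tumour = decay_profiles(0.15, 30, 16, rng)
        bases = build_class_bases(normal, tumour, SPEC)
        mag = rng.uniform(0.1, 1.0, size=(16, 3, 3))
        feats = extract_features(mag, SPEC, bases)
        # centre voxel of a 16-deep volume with window 16: the full column
        col = mag[:, 1, 2].astype(float)
        w = col - col.mean()
        w /= np.linalg.norm(w)
        expected = np.array([b @ w for b in bases.stacked])
        np.testing.assert_allclose(feats[8, 1, 2], expected, rtol=1e-10)

    def test_basis_vector_profile_gives_unit_coefficient(self, rng):
        normal = decay_profiles(0.05, 30, 16, rng)
        tumour = decay_profiles(0.15, 30, 16, rng)
        bases = build_class_bases(normal, tumour, SPEC)
        b0 = bases.normal_basis[0]
        feats = extract_features(b0.reshape(16, 1, 1), SPEC, bases)
        coeffs = feats[8, 0, 0]
        assert coeffs[0] == pytest.approx(1.0, abs=1e-8) or coeffs[0] == pytest.approx(-1.0, abs=1e-8)
        assert abs(coeffs[1]) < 1e-8  # orthogonal to the second normal component

    def test_zero_profile_gives_zero_features(self, rng):
        bases = build_class_bases(
            decay_profiles(0.05, 30, 16, rng), decay_profiles(0.15, 30, 16, rng), SPEC
        )
        feats = extract_features(np.zeros((16, 2, 2)), SPEC, bases)
        assert np.all(feats == 0.0)

    def test_scale_invariance(self, rng):
        bases = build_class_bases(
            decay_profiles(0.05, 30, 16, rng), decay_profiles(0.15, 30, 16, rng), SPEC
        )
        mag = rng.uniform(0.1, 1.0, size=(20, 4, 4))
        f1 = extract_features(mag, SPEC, bases)
        f2 = extract_features(7.3 * mag, SPEC, bases)
        np.testing.assert_allclose(f1, f2, atol=1e-10)


class TestClassifier:
    def test_separable_features_high_heldout_accuracy(self, rng):
        x = np.vstack([rng.normal(-2, 0.3, (200, 4)), rng.normal(2, 0.3, (200, 4))])
        y = np.repeat([0, 1], 200)
        _, acc = train_segmenter(x, y, n_estimators=50, seed=0)
        assert acc >= 0.98

    def test_permuted_labels_chance_accuracy(self, rng):
        x = np.vstack([rng.normal(-2, 0.3, (200, 4)), rng.normal(2, 0.3, (200, 4))])
        y = rng.permutation(np.repeat([0, 1], 200))
        _, acc = train_segmenter(x, y, n_estimators=50, seed=0)
        assert abs(acc - 0.5) <= 0.1

    def test_seeded_training_is_reproducible(self, rng):
        x = np.vstack([rng.normal(-1, 1.0, (100, 4)), rng.normal(1, 1.0, (100, 4))])
        y = np.repeat([0, 1], 100)
        m1, _ = train_segmenter(x, y, seed=3)
        m2, _ = train_segmenter(x, y, seed=3)
        probe = rng.normal(size=(50, 4))
        assert np.array_equal(m1.predict(probe), m2.predict(probe))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_segmenter(np.ones((10, 4)), np.zeros(10))


@pytest.fixture(scope="module")
def trained_model():
    vol, disc = generate_attenuation_phantom(seed=100)
    normal = sample_training_profiles(vol, ~disc, SPEC, 300, seed=1)
    tumour = sample_training_profiles(vol, disc, SPEC, 300, seed=2)
    return build_segmentation_model(normal, tumour, SPEC, n_estimators=50, seed=0)


class TestSegmentVolume:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_disc_phantom_dice(self, trained_model, seed):
        """Dice overlap with the ground-truth disc is at least 0.90 across seeds."""
        vol, disc = generate_attenuation_phantom(seed=seed)
        mask = segment_volume(vol, trained_model).mask2d
        dice = 2 * (mask & disc).sum() / (mask.sum() + disc.sum())
        assert dice >= 0.90

    def test_normal_only_phantom_gives_empty_mask(self, trained_model, caplog):
        vol, _ = generate_attenuation_phantom(disc_radius_px=0.0, seed=5)
        with caplog.at_level("WARNING"):
            mask = segment_volume(vol, trained_model).mask2d
        assert not mask.any()

    def test_full_tumour_phantom_covers_field(self, trained_model):
        vol, disc = generate_attenuation_phantom(disc_radius_px=1000.0, seed=6)
        assert disc.all()
        mask = segment_volume(vol, trained_model).mask2d
        assert mask.mean() >= 0.95

    def test_global_intensity_scale_invariance(self, trained_model):
        from ocapdt.phantom import ComplexOCTVolume

        vol, _ = generate_attenuation_phantom(seed=7)
        scaled = ComplexOCTVolume(5.0 * vol.data, vol.voxel_size)
        m1 = segment_volume(vol, trained_model).mask2d
        m2 = segment_volume(scaled, trained_model).mask2d
        assert (m1 ^ m2).mean() < 0.01  # normalised profiles make features scale-free
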