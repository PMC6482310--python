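"""Tumour/normal tissue classification from depth reflectivity profiles.

Each pixel of a structural OCT image is represented by the decomposition
coefficients of its local depth reflectivity profile onto two orthonormal
bases, one learned from normal-tissue profiles and one from tumour
profiles (leading principal directions of each class).  A random-forest
classifier on the concatenated coefficients labels pixels, and the
depth-resolved labels are collapsed to a single filled en-face tumour
region.

Profiles are mean-centred and L2-normalised before projection, which makes
both training and inference invariant to a global intensity scale of the
volume.  Classification runs on log-scaled reflectivity by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import binary_fill_holes
from skimage import measure, morphology
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .phantom import ComplexOCTVolume

__all__ = [
    "ProfileFeatureSpec",
    "ClassBases",
    "SegmentationModel",
    "TumourMask",
    "build_class_bases",
    "extract_features",
    "extract_profiles",
    "train_segmenter",
    "segment_volume",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class ProfileFeatureSpec:
    profile_length: int = 32
    n_components_per_basis: int = 4

    def __post_init__(self) -> None:
        if self.profile_length < 2:
            raise ValueError("profile_length must be >= 2")
        if self.n_components_per_basis < 1:
            raise ValueError("n_components_per_basis must be >= 1")


@dataclass
class ClassBases:
    """Orthonormal profile bases for the normal and tumour classes."""

    normal_basis: np.ndarray  # (k, profile_length)
    tumour_basis: np.ndarray

    def __post_init__(self) -> None:
        for name, basis in (("normal", self.normal_basis), ("tumour", self.tumour_basis)):
            gram = basis @ basis.T
            if not np.allclose(gram, np.eye(basis.shape[0]), atol=1e-8):
                raise ValueError(f"{name} basis is not orthonormal")

    @property
    def stacked(self) -> np.ndarray:
        return np.vstack([self.normal_basis, self.tumour_basis])


@dataclass
class SegmentationModel:
    bases: ClassBases
    spec: ProfileFeatureSpec
    classifier: RandomForestClassifier
    heldout_accuracy: float
    log_scale: bool = True

    def __post_init__(self) -> None:
        expected = 2 * self.spec.n_components_per_basis
        total = self.bases.normal_basis.shape[0] + self.bases.tumour_basis.shape[0]
        if total != expected:
            raise ValueError(
                f"feature dimensionality {total} != 2 x n_components_per_basis {expected}"
            )


@dataclass
class TumourMask:
    mask2d: np.ndarray
    border: list[np.ndarray]
    pixel_size: float

    def __post_init__(self) -> None:
        self.mask2d = np.asarray(self.mask2d, dtype=bool)


def _normalize_profiles(profiles: np.ndarray) -> np.ndarray:
    """Mean-centre each profile along its last axis and scale to unit L2 norm."""
    p = np.asarray(profiles, dtype=float)
    p = p - p.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(p, axis=-1, keepdims=True)
    return np.where(norm > _EPS, p / np.where(norm > _EPS, norm, 1.0), 0.0)


def _class_basis(profiles: np.ndarray, k: int, class_name: str) -> np.ndarray:
    p = _normalize_profiles(profiles)
    if p.shape[0] < k:
        raise ValueError(
            f"class '{class_name}': need >= {k} profiles, got {p.shape[0]}"
        )
    # principal directions of the normalised profile set (uncentred SVD, so
    # a set of collinear profiles yields exactly their common direction)
    _, s, vt = np.linalg.svd(p, full_matrices=False)
    rank = int(np.sum(s > max(s[0], _EPS) * 1e-10)) if s.size else 0
    if rank < k:
        raise ValueError(
            f"class '{class_name}': profile set is rank-deficient "
            f"(rank {rank} < {k} requested components)"
        )
    return vt[:k]


def build_class_bases(
    normal_profiles: np.ndarray,
    tumour_profiles: np.ndarray,
    spec: ProfileFeatureSpec,
) -> ClassBases:
    """Leading principal directions of each class's normalised profile set."""
    for name, p in (("normal", normal_profiles), ("tumour", tumour_profiles)):
        if np.asarray(p).shape[-1] != spec.profile_length:
            raise ValueError(
                f"{name} profiles have length {np.asarray(p).shape[-1]}, "
                f"expected profile_length={spec.profile_length}"
            )
    k = spec.n_components_per_basis
    return ClassBases(
        normal_basis=_class_basis(np.asarray(normal_profiles), k, "normal"),
        tumour_basis=_class_basis(np.asarray(tumour_profiles), k, "tumour"),
    )


def _windowed_profiles(magnitude: np.ndarray, length: int) -> np.ndarray:
    """Depth windows centred on every voxel, reflected at the depth edges.

    Input has depth on axis 0; output appends a window axis of ``length``.
    """
    depth = magnitude.shape[0]
    if length > depth:
        raise ValueError(f"profile_length {length} exceeds volume depth {depth}")
    before = length // 2
    after = length - 1 - before
    pad = [(before, after)] + [(0, 0)] * (magnitude.ndim - 1)
    padded = np.pad(magnitude, pad, mode="reflect")
    windows = sliding_window_view(padded, length, axis=0)
    return windows


def extract_profiles(magnitude: np.ndarray, spec: ProfileFeatureSpec) -> np.ndarray:
    """Normalised local reflectivity profiles for every voxel (window axis last)."""
    return _normalize_profiles(_windowed_profiles(magnitude, spec.profile_length))


def extract_features(
    magnitude: np.ndarray, spec: ProfileFeatureSpec, bases: ClassBases
) -> np.ndarray:
    """Project each voxel's normalised profile onto both class bases.

    Returns an array shaped like ``magnitude`` with a trailing feature axis
    of ``2 * n_components_per_basis`` (normal-basis coefficients first).
    Windows that would exceed the depth range use reflected padding.
    """
    profiles = extract_profiles(np.asarray(magnitude, dtype=float), spec)
    return profiles @ bases.stacked.T


def train_segmenter(
    features: np.ndarray,
    labels: np.ndarray,
    n_estimators: int = 100,
    seed: int = 0,
    heldout_fraction: float = 0.25,
) -> tuple[RandomForestClassifier, float]:
    """Fit the random forest; returns the model and its held-out accuracy.

    The accuracy is measured on a stratified held-out split with identical
    hyper-parameters, after which the returned model is refit on all data.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError(f"training labels contain a single class: {classes}")
    x_tr, x_te, y_tr, y_te = train_test_split(
        features, labels, test_size=heldout_fraction, random_state=seed, stratify=labels
    )
    probe = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    probe.fit(x_tr, y_tr)
    heldout = float(probe.score(x_te, y_te))
    final = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    final.fit(features, labels)
    return final, heldout


def build_segmentation_model(
    normal_profiles: np.ndarray,
    tumour_profiles: np.ndarray,
    spec: ProfileFeatureSpec | None = None,
    n_estimators: int = 100,
    seed: int = 0,
    log_scale: bool = True,
) -> SegmentationModel:
    """Convenience trainer: bases from the labelled profiles, then the forest."""
    spec = spec or ProfileFeatureSpec()
    normal_profiles = np.asarray(normal_profiles, dtype=float)
    tumour_profiles = np.asarray(tumour_profiles, dtype=float)
    if log_scale:
        normal_profiles = np.log(normal_profiles + _EPS)
        tumour_profiles = np.log(tumour_profiles + _EPS)
    bases = build_class_bases(normal_profiles, tumour_profiles, spec)
    feats = np.vstack(
        [
            _normalize_profiles(normal_profiles) @ bases.stacked.T,
            _normalize_profiles(tumour_profiles) @ bases.stacked.T,
        ]
    )
    labels = np.concatenate(
        [np.zeros(len(normal_profiles), dtype=int), np.ones(len(tumour_profiles), dtype=int)]
    )
    clf, heldout = train_segmenter(feats, labels, n_estimators=n_estimators, seed=seed)
    return SegmentationModel(
        bases=bases, spec=spec, classifier=clf, heldout_accuracy=heldout, log_scale=log_scale
    )


def segment_volume(
    vol: ComplexOCTVolume,
    model: SegmentationModel,
    closing_radius_px: int = 2,
    min_region_px: int = 8,
) -> TumourMask:
    """Classify every voxel and collapse to one filled en-face tumour region.

    Depth-resolved labels are reduced by majority vote over depth, then the
    2D mask is post-processed (morphological closing, largest connected
    component of at least ``min_region_px`` pixels, hole filling).  If no
    tumour region is detected an empty mask is returned with a warning (a
    valid outcome for normal tissue).
    """
    magnitude = vol.magnitude()
    if model.log_scale:
        magnitude = np.log(magnitude + _EPS)
    nz, ny, nx = magnitude.shape
    feats = extract_features(magnitude, model.spec, model.bases)
    labels = model.classifier.predict(feats.reshape(-1, feats.shape[-1]))
    labels3d = labels.reshape(nz, ny, nx).astype(bool)
    mask2d = labels3d.mean(axis=0) > 0.5

    if closing_radius_px > 0:
        mask2d = morphology.closing(mask2d, morphology.disk(closing_radius_px))
    sizes = np.bincount(measure.label(mask2d).ravel())[1:] if mask2d.any() else np.array([])
    if sizes.size == 0 or sizes.max() < min_region_px:
        logger.warning("segmentation found no tumour region; returning empty mask")
        return TumourMask(
            mask2d=np.zeros_like(mask2d), border=[], pixel_size=float(vol.voxel_size[1])
        )
    comp = measure.label(mask2d)
    largest = int(np.argmax(np.bincount(comp.ravel())[1:])) + 1
    mask2d = binary_fill_holes(comp == largest)
    border = measure.find_contours(mask2d.astype(float), 0.5)
    return TumourMask(mask2d=mask2d, border=border, pixel_size=float(vol.voxel_size[1]))
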