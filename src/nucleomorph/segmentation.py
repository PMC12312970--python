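"""Two-step instance segmentation of nuclei.

Step 1 separates nuclei from background with a Random-Forest voxel
classifier (200 trees by default) over the per-voxel feature bank; the
thresholded probability map is hole-filled into a binary mask.  Step 2
splits touching nuclei by shape: local maxima of the Euclidean distance
transform seed a marker-controlled watershed, and any two seeds closer
than 10 voxels are merged so that adjacent nuclei below that separation
are deliberately not split.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from sklearn.ensemble import RandomForestClassifier

from .core import LabelMask, PipelineConfig, VoxelGrid
from .features import FeatureStack, compute_features

log = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

BACKGROUND, NUCLEUS = 1, 2  # annotation codes; 0 = unannotated


@dataclass
class VoxelClassifier:
    """Trained tree-ensemble voxel classifier with its training metadata."""

    model: RandomForestClassifier
    feature_names: Tuple[str, ...]
    n_trees: int
    seed: int
    format_version: int = MODEL_FORMAT_VERSION

    def predict_proba_nucleus(self, features: FeatureStack) -> np.ndarray:
        """Per-voxel probability of the nucleus class, shaped like the image."""
        if features.names != self.feature_names:
            raise ValueError(
                "feature names do not match the classifier's training features"
            )
        proba = self.model.predict_proba(features.as_table())
        nucleus_col = list(self.model.classes_).index(NUCLEUS)
        return proba[:, nucleus_col].reshape(features.features.shape[1:])

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "VoxelClassifier":
        with open(path, "rb") as fh:
            clf = pickle.load(fh)
        if clf.format_version != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {clf.format_version}")
        return clf


def train_classifier(
    features: FeatureStack,
    annotations: np.ndarray,
    n_trees: int = 200,
    seed: int = 0,
    n_threads: int = 1,
    max_samples_per_class: Optional[int] = None,
) -> VoxelClassifier:
    """Fit the Random-Forest voxel classifier on sparse annotations.

    Parameters
    ----------
    features
        Feature bank of the training image.
    annotations
        Integer array shaped like the image: 0 = unannotated,
        1 = background, 2 = nucleus.  Both classes must be present.
    n_trees, seed, n_threads
        Forest size, RNG seed (training is deterministic given the seed)
        and worker threads.
    max_samples_per_class
        Optional per-class subsampling of annotated voxels (deterministic
        given the seed), to bound training cost on dense annotations.
    """
    annotations = np.asarray(annotations)
    if annotations.shape != features.features.shape[1:]:
        raise ValueError("annotation shape does not match the feature maps")
    labelled = annotations > 0
    y = annotations[labelled]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("annotations must contain both background and nucleus")
    X = features.as_table()[labelled.ravel()]
    if max_samples_per_class is not None:
        rng = np.random.default_rng(seed)
        keep = np.zeros(y.size, dtype=bool)
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            if idx.size > max_samples_per_class:
                idx = rng.choice(idx, size=max_samples_per_class, replace=False)
            keep[idx] = True
        X, y = X[keep], y[keep]
    model = RandomForestClassifier(
        n_estimators=n_trees, n_jobs=n_threads, random_state=seed
    )
    model.fit(X, y)
    log.info("trained %d-tree forest on %d annotated voxels", n_trees, y.size)
    return VoxelClassifier(
        model=model, feature_names=features.names, n_trees=n_trees, seed=seed
    )


def predict_mask(
    clf: VoxelClassifier, features: FeatureStack, p_threshold: float = 0.5
) -> np.ndarray:
    """Binary nucleus mask: probability >= threshold, then 3D hole filling."""
    proba = clf.predict_proba_nucleus(features)
    mask = proba >= p_threshold
    if mask.any():
        mask = ndimage.binary_fill_holes(mask)
    log.info("mask voxels: %d of %d", int(mask.sum()), mask.size)
    return mask


def _merge_close_seeds(peaks: np.ndarray, min_separation: float) -> np.ndarray:
    """Union-find grouping of seed points closer than ``min_separation``.

    Distances are Euclidean in isotropic voxel units (the merge rule is
    stated in voxels).  Returns a group id per peak.
    """
    n = len(peaks)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    diffs = peaks[:, None, :] - peaks[None, :, :]
    dist = np.sqrt((diffs.astype(float) ** 2).sum(axis=-1))
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] < min_separation:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    roots = np.array([find(i) for i in range(n)])
    _, groups = np.unique(roots, return_inverse=True)
    return groups


def split_touching(
    mask: np.ndarray,
    img: Optional[VoxelGrid] = None,
    seed_threshold: float = 2.0,
    min_separation: float = 10.0,
) -> LabelMask:
    """Split touching nuclei by marker-controlled watershed on shape.

    Seeds are local maxima of the Euclidean distance transform of the mask
    with height at least ``seed_threshold`` voxels; any two seeds closer
    than ``min_separation`` voxels (Euclidean, voxel units) are merged into
    a single marker, so nuclei closer than that are not separated.  The
    watershed floods the inverted distance transform within the mask,
    partitioning every mask voxel; labels are contiguous 1..K.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot split an empty mask")
    edt = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        edt, threshold_abs=seed_threshold, exclude_border=False, labels=mask
    )
    if len(peaks) == 0:
        # mask thinner than the seed threshold everywhere: single instance
        comp, n = ndimage.label(mask)
        log.info("no seeds above %.3g voxels; labelling %d components", seed_threshold, n)
        return LabelMask(comp.astype(np.int32))
    groups = _merge_close_seeds(peaks, min_separation)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for (coord, grp) in zip(peaks, groups):
        markers[tuple(coord)] = grp + 1
    labels = watershed(-edt, markers=markers, mask=mask)
    return LabelMask.from_array(labels)


def segment(
    img: VoxelGrid,
    clf: VoxelClassifier,
    config: Optional[PipelineConfig] = None,
) -> LabelMask:
    """Full two-step segmentation: features → mask → instance splitting."""
    config = config or PipelineConfig()
    features = compute_features(img, config.feature_scales)
    mask = predict_mask(clf, features, config.p_threshold)
    if config.min_object_size > 0 and mask.any():
        comp, n = ndimage.label(mask)
        sizes = np.bincount(comp.ravel())
        small = np.flatnonzero(sizes < config.min_object_size)
        mask &= ~np.isin(comp, small[small > 0])
        log.info("mask voxels after size filter: %d", int(mask.sum()))
    if not mask.any():
        return LabelMask(np.zeros(img.shape, dtype=np.int32))
    labels = split_touching(
        mask,
        img,
        seed_threshold=config.seed_threshold,
        min_separation=config.min_seed_separation,
    )
    log.info("segmented %d nuclei", labels.n_labels)
    return labels
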