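"""Voxel-classification and watershed-splitting contracts."""

import numpy as np
import pytest
from scipy import ndimage

from nucleomorph import (
    LabelMask,
    PipelineConfig,
    VoxelGrid,
    compute_features,
    generate_touching_pair,
    predict_mask,
    segment,
    split_touching,
    train_classifier,
)
from nucleomorph.segmentation import BACKGROUND, NUCLEUS, VoxelClassifier


@pytest.fixture(scope="module")
def trained_on_noisy(noisy_nucleus):
    grid, mask, _ = noisy_nucleus
    feats = compute_features(grid, (1, 2))
    ann = np.where(mask.labels > 0, NUCLEUS, BACKGROUND)
    clf = train_classifier(feats, ann, n_trees=50, seed=0,
                           max_samples_per_class=4000)
    return grid, mask, feats, clf


def best_jaccard(truth_mask: np.ndarray, labels: LabelMask) -> float:
    best = 0.0
    for lab in labels.ids:
        pred = labels.labels == lab
        best = max(best, (truth_mask & pred).sum() / (truth_mask | pred).sum())
    return best


class TestTrainClassifier:
    def test_single_class_annotations_rejected(self, noisy_nucleus):
        grid, _, _ = noisy_nucleus
        feats = compute_features(grid, (1,))
        ann = np.full(grid.shape, BACKGROUND)
        with pytest.raises(ValueError, match="both"):
            train_classifier(feats, ann, n_trees=10, seed=0)

    def test_annotation_shape_must_match(self, noisy_nucleus):
        grid, _, _ = noisy_nucleus
        feats = compute_features(grid, (1,))
        with pytest.raises(ValueError, match="shape"):
            train_classifier(feats, np.zeros((2, 2, 2), int), n_trees=10, seed=0)

    def test_training_deterministic_given_seed(self, trained_on_noisy):
        grid, mask, feats, clf = trained_on_noisy
        ann = np.where(mask.labels > 0, NUCLEUS, BACKGROUND)
        clf2 = train_classifier(feats, ann, n_trees=50, seed=0,
                                max_samples_per_class=4000)
        p1 = clf.predict_proba_nucleus(feats)
        p2 = clf2.predict_proba_nucleus(feats)
        np.testing.assert_array_equal(p1, p2)

    def test_heldout_accuracy_on_noisefree_phantom(self, sphere_phantom):
        # linearly separable intensities: near-perfect voxel accuracy
        grid, mask, _ = sphere_phantom
        feats = compute_features(grid, (1, 2))
        ann = np.where(mask.labels > 0, NUCLEUS, BACKGROUND)
        rng = np.random.default_rng(0)
        train = np.zeros(grid.data.size, bool)
        train[rng.choice(grid.data.size, 8000, replace=False)] = True
        ann_train = np.where(train.reshape(grid.shape), ann, 0)
        clf = train_classifier(feats, ann_train, n_trees=50, seed=0)
        heldout = ~train
        pred = clf.model.predict(feats.as_table()[heldout])
        acc = (pred == ann.ravel()[heldout]).mean()
        assert acc >= 0.99

    def test_model_save_load_round_trip(self, trained_on_noisy, tmp_path):
        grid, _, feats, clf = trained_on_noisy
        path = tmp_path / "clf.pkl"
        clf.save(path)
        back = VoxelClassifier.load(path)
        np.testing.assert_array_equal(
            back.predict_proba_nucleus(feats), clf.predict_proba_nucleus(feats)
        )


class TestPredictMask:
    def test_feature_mismatch_rejected(self, trained_on_noisy):
        grid, _, _, clf = trained_on_noisy
        other = compute_features(grid, (1,))
        with pytest.raises(ValueError, match="feature names"):
            predict_mask(clf, other)

    def test_threshold_zero_gives_all_foreground(self, trained_on_noisy):
        grid, _, feats, clf = trained_on_noisy
        assert predict_mask(clf, feats, p_threshold=0.0).all()

    def test_threshold_above_one_gives_empty_mask(self, trained_on_noisy):
        grid, _, feats, clf = trained_on_noisy
        assert not predict_mask(clf, feats, p_threshold=1.01).any()

    def test_hollow_shell_probability_filled_solid(self, trained_on_noisy):
        # emulate a classifier that only detects the envelope: the filled
        # mask must be the solid object
        grid, mask, feats, clf = trained_on_noisy
        solid = mask.labels > 0
        shell = solid & ~ndimage.binary_erosion(solid, iterations=3)

        class ShellClassifier:
            feature_names = feats.names

            def predict_proba_nucleus(self, f):
                return shell.astype(float)

        filled = predict_mask(ShellClassifier(), feats, p_threshold=0.5)
        assert (filled & solid).sum() / solid.sum() > 0.99


class TestSplitTouching:
    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_touching(np.zeros((8, 8, 8), bool))

    def test_pair_8_voxels_apart_stays_merged(self):
        _, mask, _ = generate_touching_pair(8)
        labels = split_touching(mask.labels > 0)
        assert labels.n_labels == 1

    def test_pair_30_apart_splits_with_jaccard(self):
        # radius 16, separation 30: overlapping spheres with a neck
        grid, gt, _ = generate_touching_pair(30, radius_vox=16)
        labels = split_touching(gt.labels > 0)
        assert labels.n_labels == 2
        for gt_id in (1, 2):
            assert best_jaccard(gt.labels == gt_id, labels) >= 0.8

    def test_single_convex_object_single_label_equals_mask(self, sphere_phantom):
        _, mask, _ = sphere_phantom
        solid = mask.labels > 0
        labels = split_touching(solid)
        assert labels.n_labels == 1
        np.testing.assert_array_equal(labels.labels > 0, solid)

    def test_watershed_partitions_the_mask(self):
        _, gt, _ = generate_touching_pair(14)
        solid = gt.labels > 0
        labels = split_touching(solid)
        # labelled voxels == mask voxels: nothing added, nothing lost
        np.testing.assert_array_equal(labels.labels > 0, solid)
        counts = np.bincount(labels.labels.ravel())[1:]
        assert counts.sum() == solid.sum()

    def test_merge_monotone_in_separation(self):
        n_by_sep = {
            s: split_touching(generate_touching_pair(s)[1].labels > 0).n_labels
            for s in range(2, 21, 2)
        }
        seps = sorted(n_by_sep)
        # once split, stays split at larger separations
        assert all(
            n_by_sep[a] <= n_by_sep[b] for a, b in zip(seps, seps[1:])
        )

    def test_split_boundary_at_default_10(self):
        # "nuclei closer than 10 voxels are not separated", read strictly
        results = {
            s: split_touching(generate_touching_pair(s)[1].labels > 0).n_labels
            for s in (9, 10, 11)
        }
        assert results == {9: 1, 10: 2, 11: 2}

    def test_custom_min_separation_moves_the_boundary(self):
        _, gt, _ = generate_touching_pair(12)
        assert split_touching(gt.labels > 0, min_separation=15).n_labels == 1
        assert split_touching(gt.labels > 0, min_separation=12).n_labels == 2


class TestSegmentPipeline:
    def test_single_nucleus_volume_within_5pc(self, trained_on_noisy):
        grid, gtmask, feats, clf = trained_on_noisy
        cfg = PipelineConfig(feature_scales=(1, 2), n_trees=50,
                             min_object_size=200)
        labels = segment(grid, clf, cfg)
        assert labels.n_labels == 1
        truth_vox = (gtmask.labels > 0).sum()
        assert (labels.labels > 0).sum() == pytest.approx(truth_vox, rel=0.05)

    def test_background_only_phantom_gives_zero_labels(self, trained_on_noisy):
        grid, _, _, clf = trained_on_noisy
        rng = np.random.default_rng(5)
        empty = VoxelGrid(
            np.clip(0.02 + 0.02 * rng.standard_normal(grid.shape), 0, None),
            grid.spacing,
        )
        cfg = PipelineConfig(feature_scales=(1, 2), n_trees=50)
        labels = segment(empty, clf, cfg)
        assert labels.n_labels == 0

    def test_labels_subset_of_predicted_mask(self, trained_on_noisy):
        grid, _, feats, clf = trained_on_noisy
        cfg = PipelineConfig(feature_scales=(1, 2), n_trees=50,
                             min_object_size=0)
        mask = predict_mask(clf, feats, cfg.p_threshold)
        labels = segment(grid, clf, cfg)
        assert not (labels.labels[~mask] > 0).any()
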