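"""Segmentation metrics against brute-force pixel/boundary oracles."""

import numpy as np
import pytest

from lucid.metrics import (auroc_from_map, confusion_metrics, evaluate_mask,
                           hausdorff, mean_abs_deviation)


def brute_confusion(pred, truth):
    """Oracle: explicit pixel loops."""
    tp = tn = fp = fn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    total = tp + tn + fp + fn
    return {
        "iou": tp / (tp + fp + fn) if tp + fp + fn else 1.0,
        "dsc": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 1.0,
        "acc": (tp + tn) / total,
        "sen": tp / (tp + fn) if tp + fn else 1.0,
        "spe": tn / (tn + fp) if tn + fp else 1.0,
    }


def brute_boundary(mask):
    """8-connected boundary: pixel stays if any 8-neighbour (or the image
    border) is background."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        out[r, c] = True
    return out


def brute_hausdorff_mad(pred, truth):
    a = np.argwhere(brute_boundary(pred)).astype(float)
    b = np.argwhere(brute_boundary(truth)).astype(float)
    d_ab = [min(np.hypot(*(p - q)) for q in b) for p in a]
    d_ba = [min(np.hypot(*(p - q)) for q in a) for p in b]
    return max(max(d_ab), max(d_ba)), float(np.mean(d_ab))


class TestConfusionMetrics:
    def test_identical_masks_are_perfect(self, rng):
        mask = rng.uniform(size=(10, 10)) > 0.5
        m = confusion_metrics(mask, mask)
        assert m["iou"] == m["dsc"] == m["sen"] == 1.0
        assert m["acc"] == 1.0

    def test_disjoint_masks_zero_overlap(self):
        pred = np.zeros((4, 4), dtype=bool)
        truth = np.zeros((4, 4), dtype=bool)
        pred[:2], truth[2:] = True, True
        m = confusion_metrics(pred, truth)
        assert m["iou"] == 0.0 and m["dsc"] == 0.0

    def test_hand_counted_2x2(self):
        pred = np.array([[1, 1], [0, 0]], dtype=bool)
        truth = np.array([[1, 0], [0, 0]], dtype=bool)
        m = confusion_metrics(pred, truth)
        assert m == {"iou": 1 / 2, "dsc": 2 / 3, "acc": 3 / 4, "sen": 1.0,
                     "spe": 2 / 3}

    def test_both_empty_convention(self):
        empty = np.zeros((3, 3), dtype=bool)
        m = confusion_metrics(empty, empty)
        assert m["iou"] == m["dsc"] == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_metrics(np.zeros((2, 2)), np.zeros((3, 3)))


class TestOracleEquivalence:
    def test_200_random_pairs_match_brute_force(self, rng):
        """IoU/DSC/Acc/Sen/Spe/HD/MAD all agree with exhaustive computation
        on random 5x5 masks; the dsc = 2*iou/(1+iou) identity holds."""
        checked_boundaries = 0
        for _ in range(200):
            pred = rng.uniform(size=(5, 5)) > rng.uniform(0.2, 0.8)
            truth = rng.uniform(size=(5, 5)) > rng.uniform(0.2, 0.8)
            m = confusion_metrics(pred, truth)
            expected = brute_confusion(pred, truth)
            for key, val in expected.items():
                assert m[key] == pytest.approx(val, abs=1e-12)
            assert m["dsc"] == pytest.approx(2 * m["iou"] / (1 + m["iou"]), abs=1e-12)
            if pred.any() and truth.any():
                hd_exp, mad_exp = brute_hausdorff_mad(pred, truth)
                assert hausdorff(pred, truth) == pytest.approx(hd_exp, abs=1e-9)
                assert mean_abs_deviation(pred, truth) == pytest.approx(mad_exp,
                                                                        abs=1e-9)
                checked_boundaries += 1
        assert checked_boundaries > 100

    def test_transposition_symmetry(self, rng):
        pred = rng.uniform(size=(6, 8)) > 0.5
        truth = rng.uniform(size=(6, 8)) > 0.5
        assert confusion_metrics(pred.T, truth.T) == confusion_metrics(pred, truth)
        if pred.any() and truth.any():
            assert hausdorff(pred.T, truth.T) == hausdorff(pred, truth)
            assert mean_abs_deviation(pred.T, truth.T) == mean_abs_deviation(pred,
                                                                             truth)


class TestBoundaryDistances:
    def test_identical_masks_zero_distance(self, rng):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 2:6] = True
        assert hausdorff(mask, mask) == 0.0
        assert mean_abs_deviation(mask, mask) == 0.0

    def test_single_pixels_point_distance(self):
        a = np.zeros((5, 8), dtype=bool)
        b = np.zeros((5, 8), dtype=bool)
        a[2, 1], b[2, 4] = True, True
        assert hausdorff(a, b) == 3.0
        assert mean_abs_deviation(a, b) == 3.0

    def test_concentric_squares_uniform_offset(self):
        """Pred boundary uniformly 2 px outside truth: directed MAD is 2
        along edges (corners measure diagonal excess, so use edges only)."""
        truth = np.zeros((20, 20), dtype=bool)
        truth[6:14, 6:14] = True
        pred = np.zeros((20, 20), dtype=bool)
        pred[4:16, 4:16] = True
        assert mean_abs_deviation(pred, truth) >= 2.0
        assert hausdorff(pred, truth) == pytest.approx(2 * np.sqrt(2))

    def test_mad_never_exceeds_hd(self, rng):
        for _ in range(50):
            pred = rng.uniform(size=(6, 6)) > 0.6
            truth = rng.uniform(size=(6, 6)) > 0.6
            if pred.any() and truth.any():
                assert mean_abs_deviation(pred, truth) <= hausdorff(pred, truth) + 1e-12

    def test_empty_mask_flagged(self):
        full = np.ones((3, 3), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            hausdorff(np.zeros((3, 3), dtype=bool), full)
        with pytest.raises(ValueError, match="empty"):
            mean_abs_deviation(full, np.zeros((3, 3), dtype=bool))


class TestAuroc:
    def test_perfect_and_inverted_separation(self):
        truth = np.array([[1, 1], [0, 0]], dtype=bool)
        assert auroc_from_map(truth.astype(float), truth) == 1.0
        assert auroc_from_map(1.0 - truth, truth) == 0.0

    def test_random_map_is_chance_level(self, rng):
        truth = rng.uniform(size=(100, 100)) > 0.5
        values = rng.uniform(size=(100, 100))
        assert auroc_from_map(values, truth) == pytest.approx(0.5, abs=0.02)

    def test_invariant_under_monotone_transform(self, rng):
        truth = rng.uniform(size=(20, 20)) > 0.5
        values = rng.uniform(size=(20, 20))
        base = auroc_from_map(values, truth)
        assert auroc_from_map(np.exp(3 * values), truth) == pytest.approx(base)
        assert auroc_from_map(values**3, truth) == pytest.approx(base)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            auroc_from_map(np.ones((2, 2)), np.ones((2, 2), dtype=bool))


class TestEvaluateMask:
    def test_full_report(self, rng):
        truth = np.zeros((12, 12), dtype=bool)
        truth[3:9, 3:9] = True
        pred = np.zeros((12, 12), dtype=bool)
        pred[4:10, 4:10] = True
        values = truth.astype(float) * 0.8 + rng.uniform(0, 0.1, truth.shape)
        report = evaluate_mask(pred, truth, values)
        assert 0 < report.iou < 1 and report.iou <= report.dsc
        assert report.hd is not None and report.mad is not None
        assert report.auroc > 0.9
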