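"""Evaluation metrics against independent oracles.

The brute-force pair oracle enumerates all ordered pairs of *distinct*
voxels (the SNEMI3D contest counting convention); the entropy oracle
computes conditional entropies directly from joint frequencies.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stackmae.metrics import (
    adapted_rand_error,
    average_precision,
    contingency_table,
    evaluate,
    variation_of_information,
)
from stackmae.volumes import LabelVolume


def brute_force_arand(s, t):
    """Pair loop over all ordered pairs of distinct voxels on T != 0."""
    mask = t != 0
    sv, tv = s[mask].ravel(), t[mask].ravel()
    n = len(sv)
    same_s = same_t = same_both = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a = sv[i] == sv[j]
            b = tv[i] == tv[j]
            same_s += a
            same_t += b
            same_both += a and b
    if same_s == 0 and same_t == 0:
        return 0.0
    if same_s == 0 or same_t == 0:
        return 1.0
    precision = same_both / same_s
    recall = same_both / same_t
    if precision + recall == 0:
        return 1.0
    return 1.0 - 2 * precision * recall / (precision + recall)


def brute_force_voi(s, t):
    """Conditional entropies from explicit joint frequencies (nats)."""
    mask = t != 0
    sv, tv = s[mask].ravel(), t[mask].ravel()
    n = len(sv)
    joint = {}
    for a, b in zip(sv.tolist(), tv.tolist()):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    ps, pt = {}, {}
    for (a, b), c in joint.items():
        ps[a] = ps.get(a, 0) + c
        pt[b] = pt.get(b, 0) + c
    h_s_given_t = -sum(
        (c / n) * math.log((c / n) / (pt[b] / n)) for (a, b), c in joint.items()
    )
    h_t_given_s = -sum(
        (c / n) * math.log((c / n) / (ps[a] / n)) for (a, b), c in joint.items()
    )
    return h_s_given_t, h_t_given_s


def _rand_labels(rng, shape=(3, 3, 3), k=4):
    return rng.integers(0, k, size=shape)


def test_identical_labelings_are_perfect(small_labels):
    vs, vm = variation_of_information(small_labels, small_labels)
    assert vs == pytest.approx(0.0, abs=1e-12)
    assert vm == pytest.approx(0.0, abs=1e-12)
    assert adapted_rand_error(small_labels, small_labels) == pytest.approx(0.0, abs=1e-12)
    ap50, ap75 = average_precision(small_labels, small_labels)
    assert ap50 == 1.0 and ap75 == 1.0


def test_relabeling_leaves_metrics_unchanged(small_labels):
    k = int(small_labels.data.max())
    perm = np.zeros(k + 1, dtype=np.int64)
    perm[1:] = np.arange(k, 0, -1)
    permuted = LabelVolume(perm[small_labels.data])
    assert variation_of_information(permuted, small_labels) == pytest.approx((0.0, 0.0), abs=1e-12)
    assert adapted_rand_error(permuted, small_labels) == pytest.approx(0.0, abs=1e-12)


def test_voi_split_for_halved_segment():
    """T one 4-voxel segment, S splits it 2/2: H(S|T) = ln 2, H(T|S) = 0."""
    t = np.full((1, 1, 4), 1, dtype=np.int64)
    s = np.array([[[1, 1, 2, 2]]], dtype=np.int64)
    vs, vm = variation_of_information(LabelVolume(s), LabelVolume(t))
    assert vs == pytest.approx(math.log(2))
    assert vm == pytest.approx(0.0, abs=1e-12)


def test_voi_components_swap_with_arguments(rng):
    s = LabelVolume(_rand_labels(rng) + 1)
    t = LabelVolume(_rand_labels(rng) + 1)
    vs, vm = variation_of_information(s, t, ignore_background=False)
    vs2, vm2 = variation_of_information(t, s, ignore_background=False)
    assert vs == pytest.approx(vm2)
    assert vm == pytest.approx(vs2)


def test_voi_zero_iff_identical_up_to_relabeling(rng):
    s = _rand_labels(rng, k=3) + 1
    t = s.copy()
    t[t == 1] = 7  # bijective relabel
    vs, vm = variation_of_information(LabelVolume(s), LabelVolume(t), ignore_background=False)
    assert vs + vm == pytest.approx(0.0, abs=1e-12)
    t[0, 0, 0] = 99 if t[0, 0, 0] != 99 else 98  # break the bijection
    vs, vm = variation_of_information(LabelVolume(s), LabelVolume(t), ignore_background=False)
    assert vs + vm > 0


def test_arand_single_segment_covering_two_equal_truths():
    t = np.array([[[1, 1, 2, 2]]], dtype=np.int64)
    s = np.ones((1, 1, 4), dtype=np.int64)
    got = adapted_rand_error(LabelVolume(s), LabelVolume(t))
    assert got == pytest.approx(brute_force_arand(s, t))
    # precision 4/12, recall 4/4 -> F = 1/2 -> error 1/2
    assert got == pytest.approx(0.5)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_metrics_match_brute_force_on_small_volumes(seed):
    """Exhaustive pair/entropy oracles on random label volumes <= 100 voxels."""
    rng = np.random.default_rng(seed)
    shape = tuple(int(rng.integers(1, 5)) for _ in range(3))
    s = rng.integers(0, 4, size=shape)
    t = rng.integers(0, 4, size=shape)
    if not (t != 0).any():
        t[0, 0, 0] = 1
    got = adapted_rand_error(LabelVolume(s), LabelVolume(t))
    assert got == pytest.approx(brute_force_arand(s, t), abs=1e-12)
    vs, vm = variation_of_information(LabelVolume(s), LabelVolume(t))
    ref_vs, ref_vm = brute_force_voi(s, t)
    assert vs == pytest.approx(ref_vs, abs=1e-12)
    assert vm == pytest.approx(ref_vm, abs=1e-12)
    assert 0.0 <= got <= 1.0


def test_arand_in_unit_interval_random_sweep():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        s = rng.integers(0, 5, size=(2, 3, 3))
        t = rng.integers(0, 5, size=(2, 3, 3))
        if not (t != 0).any():
            continue
        assert 0.0 <= adapted_rand_error(LabelVolume(s), LabelVolume(t)) <= 1.0


def test_arand_cross_checked_against_skimage(rng):
    """Independent implementation check: skimage's contest-convention
    adapted Rand error, which also ignores truth label 0."""
    from skimage.metrics import adapted_rand_error as sk_are

    for _ in range(5):
        s = _rand_labels(rng, shape=(4, 5, 5), k=5)  # includes background in S
        t = _rand_labels(rng, shape=(4, 5, 5), k=5)
        t[0, 0, 0] = 1
        are, _, _ = sk_are(t, s)
        assert adapted_rand_error(LabelVolume(s), LabelVolume(t)) == pytest.approx(
            are, abs=1e-10
        )


def test_shape_mismatch_and_empty_mask_errors():
    with pytest.raises(ValueError, match="shape mismatch"):
        contingency_table(np.zeros((2, 2, 2), dtype=int), np.zeros((2, 2, 3), dtype=int))
    with pytest.raises(ValueError, match="empty"):
        contingency_table(np.zeros((2, 2, 2), dtype=int), np.zeros((2, 2, 2), dtype=int))


def test_ap_missed_instance_halves_ap50():
    t = np.zeros((1, 2, 8), dtype=np.int64)
    t[0, :, :3] = 1
    t[0, :, 5:] = 2
    s = np.zeros_like(t)
    s[0, :, :3] = 9  # instance 1 found exactly, instance 2 missed
    ap50, ap75 = average_precision(LabelVolume(s), LabelVolume(t))
    assert ap50 == pytest.approx(0.5)
    assert ap75 == pytest.approx(0.5)


def test_ap_iou_threshold_separates_50_from_75():
    t = np.zeros((1, 1, 10), dtype=np.int64)
    t[0, 0, :10] = 1
    s = np.zeros_like(t)
    s[0, 0, :6] = 1  # IoU 0.6: counts at 0.5, not at 0.75
    ap50, ap75 = average_precision(LabelVolume(s), LabelVolume(t))
    assert ap50 == 1.0
    assert ap75 == 0.0


def test_ap_undefined_without_truth_instances():
    s = np.ones((1, 2, 2), dtype=np.int64)
    t = np.zeros((1, 2, 2), dtype=np.int64)
    ap50, ap75 = average_precision(LabelVolume(s), LabelVolume(t))
    assert math.isnan(ap50) and math.isnan(ap75)


def test_ap_greedy_matching_is_one_to_one():
    t = np.zeros((1, 1, 8), dtype=np.int64)
    t[0, 0, :4] = 1
    s = np.zeros_like(t)
    s[0, 0, :4] = 1
    s[0, 0, 4:] = 2  # spurious prediction overlapping nothing
    ap50, _ = average_precision(LabelVolume(s), LabelVolume(t))
    # ranked list: both size 4 (tie broken by id): TP then FP -> AP = 1.0
    assert ap50 == pytest.approx(1.0)


def test_evaluate_report_fields(small_labels):
    rep = evaluate(small_labels, small_labels)
    d = rep.as_dict()
    assert set(d) == {"voi_split", "voi_merge", "a_rand", "ap50", "ap75"}
    assert d["a_rand"] == pytest.approx(0.0, abs=1e-12)
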