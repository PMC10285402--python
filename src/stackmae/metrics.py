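"""Segmentation evaluation: VI split/merge, adapted Rand error, instance AP.

All pairwise metrics are computed from a voxel-count contingency table
between the predicted segmentation S and the ground truth T.  Following
the SNEMI3D convention, evaluation is restricted to truth-foreground
voxels (T != 0) unless ``ignore_background=False``.

* Variation of information: VI(S, T) = H(S|T) + H(T|S), entropies in nats.
  H(S|T) quantifies over-segmentation (split, Voi-S); H(T|S) quantifies
  under-segmentation (merge, Voi-M).
* Adapted Rand error: 1 − F, where F is the F-score of pair-classification
  precision/recall over distinct voxel pairs
  (precision = (Σ n_ij² − n) / (Σ s_i² − n), recall over Σ t_j² − n),
  the convention of the SNEMI3D contest evaluation.
  Lower is better; 0 iff the partitions agree up to relabeling.
* AP-50 / AP-75: predicted instances ranked by voxel count, matched
  greedily one-to-one to truth instances at IoU ≥ threshold; AP is the
  area under the resulting precision-recall curve.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass
class ContingencyTable:
    """Joint voxel counts over (predicted segment, truth segment)."""

    counts: np.ndarray  # (n_pred_segments, n_truth_segments), integer
    pred_ids: np.ndarray
    truth_ids: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def pred_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def truth_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class MetricsReport:
    voi_split: float
    voi_merge: float
    a_rand: float
    ap50: float
    ap75: float

    def as_dict(self) -> dict:
        return asdict(self)


def _label_data(vol) -> np.ndarray:
    if isinstance(vol, np.ndarray):
        return vol
    return np.asarray(vol.data) if hasattr(vol, "data") else np.asarray(vol)


def contingency_table(S, T, ignore_background: bool = True) -> ContingencyTable:
    """Voxel-count contingency table between two label volumes."""
    s = _label_data(S)
    t = _label_data(T)
    if s.shape != t.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {t.shape}")
    if ignore_background:
        mask = t != 0
        if not mask.any():
            raise ValueError("evaluation mask is empty (ground truth all background)")
        s, t = s[mask], t[mask]
    else:
        s, t = s.ravel(), t.ravel()
    pred_ids, si = np.unique(s, return_inverse=True)
    truth_ids, ti = np.unique(t, return_inverse=True)
    counts = np.zeros((len(pred_ids), len(truth_ids)), dtype=np.int64)
    np.add.at(counts, (si, ti), 1)
    return ContingencyTable(counts, pred_ids, truth_ids)


def variation_of_information(S, T, ignore_background: bool = True) -> tuple[float, float]:
    """(voi_split, voi_merge) = (H(S|T), H(T|S)) in nats."""
    table = S if isinstance(S, ContingencyTable) else contingency_table(S, T, ignore_background)
    n = table.n
    p = table.counts / n
    ps = table.pred_marginals / n
    pt = table.truth_marginals / n
    nz = p > 0
    pij = p[nz]
    # joint entropy and marginal entropies
    h_joint = float(-(pij * np.log(pij)).sum())
    h_s = float(-(ps[ps > 0] * np.log(ps[ps > 0])).sum())
    h_t = float(-(pt[pt > 0] * np.log(pt[pt > 0])).sum())
    voi_split = max(0.0, h_joint - h_t)  # H(S|T)
    voi_merge = max(0.0, h_joint - h_s)  # H(T|S)
    return voi_split, voi_merge


def adapted_rand_error(S, T, ignore_background: bool = True) -> float:
    """Adapted Rand error, 1 − F of pair precision/recall (lower is better)."""
    table = S if isinstance(S, ContingencyTable) else contingency_table(S, T, ignore_background)
    n = float(table.n)
    sum_ij = float((table.counts.astype(np.float64) ** 2).sum()) - n
    sum_s = float((table.pred_marginals.astype(np.float64) ** 2).sum()) - n
    sum_t = float((table.truth_marginals.astype(np.float64) ** 2).sum()) - n
    if sum_s <= 0 and sum_t <= 0:
        # every segment is a single voxel in both partitions: identical
        return 0.0
    if sum_s <= 0 or sum_t <= 0:
        return 1.0
    precision = sum_ij / sum_s
    recall = sum_ij / sum_t
    if precision + recall == 0.0:
        return 1.0
    f = 2.0 * precision * recall / (precision + recall)
    return 1.0 - f


def _instance_masks(lab: np.ndarray) -> dict[int, np.ndarray]:
    return {int(i): np.flatnonzero(lab.ravel() == i) for i in np.unique(lab) if i != 0}


def average_precision(
    S, T, iou_thresholds: tuple[float, ...] = (0.5, 0.75)
) -> tuple[float, ...]:
    """Instance-level AP at each IoU threshold (background excluded).

    Predicted instances are scored by voxel count and matched greedily in
    decreasing score, one-to-one, to the best-overlapping unmatched truth
    instance with IoU ≥ threshold.  Returns ``nan`` per threshold when the
    ground truth contains no instances.
    """
    s = _label_data(S)
    t = _label_data(T)
    if s.shape != t.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {t.shape}")
    truth = _instance_masks(t)
    if not truth:
        return tuple(float("nan") for _ in iou_thresholds)
    preds = _instance_masks(s)
    order = sorted(preds, key=lambda i: (-len(preds[i]), i))
    # precompute IoUs pred x truth (sparse loop; instances are few)
    ious: dict[int, list[tuple[float, int]]] = {}
    for pid in order:
        pv = preds[pid]
        cand = []
        for tid, tv in truth.items():
            inter = np.intersect1d(pv, tv, assume_unique=True).size
            if inter:
                iou = inter / (pv.size + tv.size - inter)
                cand.append((iou, tid))
        ious[pid] = sorted(cand, reverse=True)
    results = []
    for thr in iou_thresholds:
        matched: set[int] = set()
        tp_flags = []
        for pid in order:
            hit = False
            for iou, tid in ious[pid]:
                if iou < thr:
                    break
                if tid not in matched:
                    matched.add(tid)
                    hit = True
                    break
            tp_flags.append(hit)
        tp = np.cumsum(tp_flags)
        ranks = np.arange(1, len(tp_flags) + 1)
        precision_at = tp / ranks
        ap = float(sum(p for p, f in zip(precision_at, tp_flags) if f) / len(truth))
        results.append(ap)
    return tuple(results)


def evaluate(S, T, ignore_background: bool = True) -> MetricsReport:
    """Full metrics report for a (prediction, truth) pair."""
    table = contingency_table(S, T, ignore_background)
    voi_split, voi_merge = variation_of_information(table, None)
    a_rand = adapted_rand_error(table, None)
    ap50, ap75 = average_precision(S, T, (0.5, 0.75))
    return MetricsReport(voi_split, voi_merge, a_rand, ap50, ap75)
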