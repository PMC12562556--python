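"""Detection evaluation: precision/recall, AP by PR-curve integration, mAP, confusion matrix.

Matching is greedy in descending score with single use of each ground-truth
box (ties broken by larger IoU, then lower prediction index). AP integrates
the precision envelope on the standard 101-point recall grid — the de-facto
convention behind the mAP@0.5:0.95 metric name — with an exact-envelope
trapezoid rule available behind a flag. TP/FP/FN follow the usual detection
definitions; TN is only meaningful as the background cell of the confusion
matrix and is reported nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectionSet",
    "MatchOutcome",
    "PRCurve",
    "box_iou_matrix",
    "match_detections",
    "precision",
    "recall",
    "pr_curve",
    "average_precision",
    "mean_ap",
    "evaluate_detections",
    "confusion_matrix",
    "pr_curves",
    "export_pr_curves",
]


@dataclass
class DetectionSet:
    """Boxes (xyxy pixels, half-open), integer class labels, optional scores."""

    boxes: np.ndarray
    labels: np.ndarray
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=np.float64).reshape(-1)
        if len(self.boxes) and np.any(
            (self.boxes[:, 2] <= self.boxes[:, 0]) | (self.boxes[:, 3] <= self.boxes[:, 1])
        ):
            raise ValueError("boxes must satisfy x_min < x_max and y_min < y_max")

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass
class MatchOutcome:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    # score of each TP/FP prediction, for PR sweeps
    tp_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    scores: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    class_label: int
    iou_thr: float


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two xyxy box arrays (Na x Nb)."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    ix = np.maximum(
        0.0,
        np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0]),
    )
    iy = np.maximum(
        0.0,
        np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1]),
    )
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def match_detections(pred: DetectionSet, gt: DetectionSet, iou_thr: float = 0.5) -> MatchOutcome:
    """Greedy class-aware matching at one IoU threshold.

    Predictions are visited in descending score; each claims the unclaimed
    same-class ground-truth box of highest IoU >= ``iou_thr`` (larger IoU,
    then lower prediction index, break ties). Unmatched predictions are FP,
    unmatched ground truths FN.
    """
    if not (0.0 < iou_thr < 1.0 or iou_thr == 1.0):
        raise ValueError("iou_thr must be in (0, 1]")
    scores = pred.scores if pred.scores is not None else np.ones(len(pred))
    order = np.argsort(-scores, kind="stable")
    iou = box_iou_matrix(pred.boxes, gt.boxes) if len(pred) and len(gt) else np.zeros((len(pred), len(gt)))
    gt_used = np.zeros(len(gt), dtype=bool)
    tp_flags = np.zeros(len(pred), dtype=bool)
    for i in order:
        best_j, best_iou = -1, -1.0
        for j in range(len(gt)):
            if gt_used[j] or gt.labels[j] != pred.labels[i]:
                continue
            if iou[i, j] >= iou_thr and iou[i, j] > best_iou:
                best_j, best_iou = j, iou[i, j]
        if best_j >= 0:
            gt_used[best_j] = True
            tp_flags[i] = True
    tp = int(tp_flags.sum())
    return MatchOutcome(
        tp=tp,
        fp=len(pred) - tp,
        fn=len(gt) - tp,
        tp_flags=tp_flags[order],
        scores=scores[order],
    )


def precision(tp: int, fp: int) -> float:
    """TP / (TP + FP); 0 by convention when the denominator is 0."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be nonnegative")
    return tp / (tp + fp) if tp + fp > 0 else 0.0


def recall(tp: int, fn: int) -> float:
    """TP / (TP + FN); 0 by convention when the denominator is 0."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be nonnegative")
    return tp / (tp + fn) if tp + fn > 0 else 0.0


def pr_curve(
    tp_flags: np.ndarray, scores: np.ndarray, n_gt: int, class_label: int = 0, iou_thr: float = 0.5
) -> PRCurve:
    """Precision/recall along the descending-score sweep."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    flags = np.asarray(tp_flags, dtype=bool)[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    rec = tp_cum / n_gt if n_gt > 0 else np.zeros_like(tp_cum, dtype=float)
    prec = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    return PRCurve(recall=rec, precision=prec, class_label=class_label, iou_thr=iou_thr)


def average_precision(curve: PRCurve, method: str = "101point") -> float:
    """Integral of precision over recall.

    ``101point``: mean of the interpolated precision max_{r' >= r} p(r') on
    the grid r = 0, 0.01, ..., 1. ``trapezoid``: exact trapezoid rule on the
    monotone precision envelope.
    """
    rec, prec = np.asarray(curve.recall, float), np.asarray(curve.precision, float)
    if rec.size == 0:
        import warnings

        warnings.warn("empty PR curve; AP = 0")
        return 0.0
    # monotone non-increasing precision envelope
    env = np.maximum.accumulate(prec[::-1])[::-1]
    if method == "101point":
        grid = np.linspace(0.0, 1.0, 101)
        # for each grid recall, the envelope at the first sweep point with rec >= r
        idx = np.searchsorted(rec, grid, side="left")
        vals = np.where(idx < rec.size, env[np.minimum(idx, rec.size - 1)], 0.0)
        return float(vals.mean())
    if method == "trapezoid":
        r = np.concatenate([[0.0], rec])
        p = np.concatenate([[env[0]], env])
        return float(np.sum(np.diff(r) * (p[1:] + p[:-1]) / 2.0))
    raise ValueError(f"unknown method {method!r}")


def mean_ap(per_class_ap: dict | np.ndarray) -> float:
    """Flat average of category-level APs."""
    vals = np.asarray(list(per_class_ap.values()) if isinstance(per_class_ap, dict) else per_class_ap, float)
    if vals.size == 0:
        raise ValueError("need at least one class")
    return float(vals.mean())


IOU_GRID_50_95 = np.round(np.arange(0.50, 0.96, 0.05), 2)


def evaluate_detections(
    preds: list[DetectionSet],
    gts: list[DetectionSet],
    class_ids: list[int],
    iou_thrs: np.ndarray | None = None,
    method: str = "101point",
) -> dict:
    """Dataset-level evaluation.

    Returns per-class AP at each IoU threshold, ``mAP50`` and ``mAP50_95``,
    and per-class P/R at IoU 0.5 over all emitted detections.
    """
    iou_thrs = IOU_GRID_50_95 if iou_thrs is None else np.atleast_1d(iou_thrs)
    per_class: dict[int, dict] = {}
    ap_table = np.zeros((len(class_ids), len(iou_thrs)))
    for ci, cls in enumerate(class_ids):
        n_gt = sum(int((g.labels == cls).sum()) for g in gts)
        for ti, thr in enumerate(iou_thrs):
            flags, scores = [], []
            for p, g in zip(preds, gts):
                pm = p.labels == cls
                gm = g.labels == cls
                sub_p = DetectionSet(p.boxes[pm], p.labels[pm],
                                     p.scores[pm] if p.scores is not None else None)
                sub_g = DetectionSet(g.boxes[gm], g.labels[gm])
                out = match_detections(sub_p, sub_g, float(thr))
                flags.append(out.tp_flags)
                scores.append(out.scores)
            flags = np.concatenate(flags) if flags else np.zeros(0, bool)
            scores = np.concatenate(scores) if scores else np.zeros(0)
            curve = pr_curve(flags, scores, n_gt, cls, float(thr))
            ap_table[ci, ti] = average_precision(curve, method=method)
        # operating point: all detections, IoU 0.5
        i50 = int(np.argmin(np.abs(iou_thrs - 0.5)))
        tp = fp = fn = 0
        for p, g in zip(preds, gts):
            pm, gm = p.labels == cls, g.labels == cls
            out = match_detections(
                DetectionSet(p.boxes[pm], p.labels[pm], p.scores[pm] if p.scores is not None else None),
                DetectionSet(g.boxes[gm], g.labels[gm]),
                0.5,
            )
            tp, fp, fn = tp + out.tp, fp + out.fp, fn + out.fn
        per_class[cls] = {
            "AP50": float(ap_table[ci, i50]),
            "AP50_95": float(ap_table[ci].mean()),
            "P": precision(tp, fp),
            "R": recall(tp, fn),
        }
    i50 = int(np.argmin(np.abs(iou_thrs - 0.5)))
    return {
        "per_class": per_class,
        "mAP50": float(ap_table[:, i50].mean()) if len(class_ids) else 0.0,
        "mAP50_95": float(ap_table.mean()) if len(class_ids) else 0.0,
        "iou_thrs": [float(t) for t in iou_thrs],
    }


def confusion_matrix(
    preds: list[DetectionSet],
    gts: list[DetectionSet],
    class_ids: list[int],
    iou_thr: float = 0.5,
    score_thr: float = 0.3,
    normalize: bool = True,
) -> np.ndarray:
    """(K+1) x (K+1) matrix, rows true grade (+background), columns predicted.

    A ground truth matched (IoU >= thr) by a kept prediction lands at
    (true, predicted); unmatched ground truths in the background column;
    unmatched predictions in the background row. Rows are normalized to sum
    to 1 where defined.
    """
    K = len(class_ids)
    idx = {c: i for i, c in enumerate(class_ids)}
    M = np.zeros((K + 1, K + 1))
    for p, g in zip(preds, gts):
        keep = (p.scores >= score_thr) if p.scores is not None else np.ones(len(p), bool)
        pb, pl = p.boxes[keep], p.labels[keep]
        ps = p.scores[keep] if p.scores is not None else np.ones(int(keep.sum()))
        iou = box_iou_matrix(pb, g.boxes) if len(pb) and len(g) else np.zeros((len(pb), len(g)))
        gt_used = np.zeros(len(g), dtype=bool)
        pred_used = np.zeros(len(pb), dtype=bool)
        for i in np.argsort(-ps, kind="stable"):
            cand = [j for j in range(len(g)) if not gt_used[j] and iou[i, j] >= iou_thr]
            if cand:
                j = max(cand, key=lambda j: iou[i, j])
                gt_used[j] = True
                pred_used[i] = True
                M[idx[int(g.labels[j])], idx[int(pl[i])]] += 1
        for i in range(len(pb)):
            if not pred_used[i]:
                M[K, idx[int(pl[i])]] += 1  # background predicted as class
        for j in range(len(g)):
            if not gt_used[j]:
                M[idx[int(g.labels[j])], K] += 1  # missed target
    if normalize:
        sums = M.sum(axis=1, keepdims=True)
        M = np.divide(M, sums, out=np.zeros_like(M), where=sums > 0)
    return M


def pr_curves(
    preds: list[DetectionSet],
    gts: list[DetectionSet],
    class_ids: list[int],
    iou_thr: float = 0.5,
) -> list[PRCurve]:
    """Per-class PR curves plus a pooled all-classes curve (class label -1)."""
    curves = []
    all_flags, all_scores, all_gt = [], [], 0
    for cls in class_ids:
        flags, scores = [], []
        n_gt = sum(int((g.labels == cls).sum()) for g in gts)
        for p, g in zip(preds, gts):
            pm, gm = p.labels == cls, g.labels == cls
            out = match_detections(
                DetectionSet(p.boxes[pm], p.labels[pm],
                             p.scores[pm] if p.scores is not None else None),
                DetectionSet(g.boxes[gm], g.labels[gm]),
                iou_thr,
            )
            flags.append(out.tp_flags)
            scores.append(out.scores)
        flags = np.concatenate(flags) if flags else np.zeros(0, bool)
        scores = np.concatenate(scores) if scores else np.zeros(0)
        curves.append(pr_curve(flags, scores, n_gt, cls, iou_thr))
        all_flags.append(flags)
        all_scores.append(scores)
        all_gt += n_gt
    curves.append(pr_curve(np.concatenate(all_flags), np.concatenate(all_scores),
                           all_gt, -1, iou_thr))
    return curves


def export_pr_curves(curves: list[PRCurve], out_dir, png: bool = True) -> None:
    """Write each curve as CSV (recall, precision) and an overview PNG."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for c in curves:
        name = "all_classes" if c.class_label == -1 else f"class_{c.class_label}"
        arr = np.stack([c.recall, c.precision], axis=1)
        header = f"recall,precision (IoU={c.iou_thr})"
        np.savetxt(out / f"pr_{name}.csv", arr, delimiter=",", header=header, comments="")
    if png:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for c in curves:
            label = "all classes" if c.class_label == -1 else f"class {c.class_label}"
            ax.plot(c.recall, c.precision, label=f"{label} (AP={average_precision(c):.3f})")
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1.05)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "pr_curves.png", dpi=120)
        plt.close(fig)
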