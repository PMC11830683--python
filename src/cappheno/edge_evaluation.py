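"""Correspondence-based edge scoring: precision/recall/F, ODS, OIS, AP.

Predicted edge pixels are matched one-to-one to ground-truth edge pixels
within a Euclidean distance tolerance (default 0.75% of the image diagonal,
the convention of the BSDS benchmark) by maximum-cardinality bipartite
matching.  Matched pixels are true positives; unmatched predictions are
false positives and unmatched truth pixels false negatives.

Dataset summaries follow the standard definitions: ODS (optimal dataset
scale) is the F-score at the one threshold maximising pooled-count F over
the whole dataset; OIS (optimal image scale) averages each image's own
best-threshold F; AP is the area under the recall-sorted, monotone-
interpolated precision curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "MatchCounts",
    "PRPoint",
    "EdgeEvalResult",
    "default_tolerance",
    "match_edge_maps",
    "precision_recall_f",
    "evaluate_dataset",
]


@dataclass
class MatchCounts:
    tp: int
    fp: int
    fn: int

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class PRPoint:
    threshold: float
    precision: float
    recall: float
    f: float


@dataclass
class EdgeEvalResult:
    ods: float
    ois: float
    ap: float
    curve: list[PRPoint] = field(default_factory=list)
    ods_threshold: float = float("nan")


def default_tolerance(shape: tuple[int, int]) -> float:
    """Match tolerance: 0.75% of the image diagonal, in pixels."""
    return 0.0075 * float(np.hypot(*shape))


def match_edge_maps(pred: np.ndarray, gt: np.ndarray, tol: float) -> MatchCounts:
    """One-to-one matching of edge pixels within ``tol``.

    TP is the size of the maximum-cardinality matching of the bipartite
    tolerance graph (prediction pixels vs truth pixels, an edge where the
    Euclidean distance is <= tol) — the benchmark convention, computed here
    with Hopcroft-Karp.  The count is symmetric in the two maps.
    """
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    p_coords = np.argwhere(pred)
    g_coords = np.argwhere(gt)
    n_p, n_g = len(p_coords), len(g_coords)
    if n_p == 0 or n_g == 0:
        return MatchCounts(tp=0, fp=n_p, fn=n_g)

    tree = cKDTree(g_coords)
    neighbour_lists = tree.query_ball_point(p_coords, r=tol + 1e-9)
    rows, cols = [], []
    for i, neighbours in enumerate(neighbour_lists):
        rows.extend([i] * len(neighbours))
        cols.extend(neighbours)
    if not rows:
        return MatchCounts(tp=0, fp=n_p, fn=n_g)
    graph = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n_p, n_g)
    )
    matching = sparse.csgraph.maximum_bipartite_matching(graph, perm_type="column")
    tp = int((matching >= 0).sum())
    return MatchCounts(tp=tp, fp=n_p - tp, fn=n_g - tp)


def precision_recall_f(m: MatchCounts) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F = harmonic mean; zero denominators
    give 0 by convention."""
    if min(m.tp, m.fp, m.fn) < 0:
        raise ValueError("counts must be non-negative")
    p = m.tp / (m.tp + m.fp) if m.tp + m.fp > 0 else 0.0
    r = m.tp / (m.tp + m.fn) if m.tp + m.fn > 0 else 0.0
    f = 2.0 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f


def _binarize(pred: np.ndarray, t: float) -> np.ndarray:
    if pred.dtype == bool:
        return pred
    return np.asarray(pred, dtype=float) > t


def evaluate_dataset(
    preds: list[np.ndarray],
    gts: list[np.ndarray],
    thresholds: list[float] | None = None,
    tol: float | None = None,
) -> EdgeEvalResult:
    """Score a dataset of edge predictions against ground truth.

    ``preds`` may be probability maps in [0, 1] (swept over 99 evenly spaced
    thresholds by default) or boolean maps (evaluated at the single implicit
    threshold).  ``tol`` defaults to 0.75% of each image's diagonal.
    """
    if len(preds) == 0 or len(preds) != len(gts):
        raise ValueError("need equally many (>=1) predictions and truths")
    all_binary = all(np.asarray(p).dtype == bool for p in preds)
    if thresholds is None:
        thresholds = [0.5] if all_binary else [i / 100.0 for i in range(1, 100)]
    if not all(0.0 < t < 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")

    n_img = len(preds)
    counts = np.empty((len(thresholds), n_img), dtype=object)
    for ti, t in enumerate(thresholds):
        for i, (pr, gt) in enumerate(zip(preds, gts)):
            tol_i = tol if tol is not None else default_tolerance(np.asarray(gt).shape)
            counts[ti, i] = match_edge_maps(_binarize(pr, t), gt, tol_i)

    curve: list[PRPoint] = []
    pooled_f = []
    for ti, t in enumerate(thresholds):
        pooled = MatchCounts(0, 0, 0)
        for i in range(n_img):
            pooled = pooled + counts[ti, i]
        p, r, f = precision_recall_f(pooled)
        curve.append(PRPoint(threshold=t, precision=p, recall=r, f=f))
        pooled_f.append(f)
    best_ti = int(np.argmax(pooled_f))
    ods = pooled_f[best_ti]

    ois_terms = []
    for i in range(n_img):
        per_image_f = [precision_recall_f(counts[ti, i])[2] for ti in range(len(thresholds))]
        ois_terms.append(max(per_image_f))
    ois = float(np.mean(ois_terms))

    ap = _average_precision(curve)
    return EdgeEvalResult(
        ods=ods, ois=ois, ap=ap, curve=curve, ods_threshold=thresholds[best_ti]
    )


def _average_precision(curve: list[PRPoint]) -> float:
    """Trapezoidal area under the recall-sorted precision envelope."""
    pts = sorted(((pt.recall, pt.precision) for pt in curve))
    recalls = np.array([r for r, _ in pts])
    precisions = np.array([p for _, p in pts])
    # monotone interpolation: precision envelope from the high-recall side
    env = np.maximum.accumulate(precisions[::-1])[::-1]
    r_ext = np.concatenate([[0.0], recalls])
    p_ext = np.concatenate([[env[0]], env])
    return float(np.trapezoid(p_ext, r_ext))
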