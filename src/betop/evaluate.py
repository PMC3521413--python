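"""Evaluation: residue-level confusion metrics, AUC, epitope non-planarity,
multi-epitope ground-truth construction, and G-test feature association.

Non-planarity of a residue patch is the RMS perpendicular distance of its
surface atoms from the total-least-squares plane; flat epitopes score around
1 A, protrusive ones 3 A and above.  Epitope similarity S_XY = |X n Y| /
min(|X|, |Y|) merges redundant epitopes observed across complexes of the same
antigen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, f-score, accuracy); 0/0 ratios are 0.

    sen = TP/(TP+FN); spe = TN/(TN+FP); f = 2*pre*sen/(pre+sen);
    acc = (TP+TN)/total.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    f = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else 0.0
    return sen, spe, f, acc


def confusion_from_sets(
    predicted: set, truth: set, universe: set
) -> ConfusionCounts:
    """Residue-level confusion counts over a scoring universe."""
    return ConfusionCounts(
        tp=len(predicted & truth),
        fp=len((predicted & universe) - truth),
        fn=len((truth & universe) - predicted),
        tn=len(universe - predicted - truth),
    )


def auc(scores: dict, truth: set) -> float:
    """Rank-based AUC of per-residue scores against epitope membership."""
    from sklearn.metrics import roc_auc_score

    keys = sorted(scores)
    y = np.array([1 if k in truth else 0 for k in keys])
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    s = np.array([scores[k] for k in keys], dtype=float)
    return float(roc_auc_score(y, s))


def non_planarity(coords: np.ndarray) -> float:
    """RMS distance of atoms from their best-fit (total-least-squares) plane.

    The plane normal is the smallest principal axis of the centered
    coordinates.  Returns Angstrom; 0 for exactly coplanar input; collinear
    atoms give 0 with a warning (the plane is not unique).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 3:
        raise ValueError("need at least 3 atoms with xyz coordinates")
    centered = coords - coords.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9:
        logger.warning("collinear atoms: best-fit plane is not unique")
        return 0.0
    normal = vt[-1]
    dist = centered @ normal
    return float(np.sqrt(np.mean(dist**2)))


def epitope_similarity(x: set, y: set) -> float:
    """Overlap of two epitopes relative to the smaller one."""
    if not x or not y:
        raise ValueError("epitope sets must be non-empty")
    return len(x & y) / min(len(x), len(y))


def build_multi_epitope_truth(
    epitopes: list[tuple[set, float]], link_threshold: float = 0.5
) -> list[set]:
    """Representative epitopes of one antigen across several complexes.

    ``epitopes`` is a list of (residue set, resolution) from different
    complexes of the same antigen.  Epitopes are single-linkage clustered at
    S_XY >= ``link_threshold``; each cluster is represented by the epitope
    from the best (lowest) resolution structure.
    """
    n = len(epitopes)
    if n == 0:
        return []
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if epitope_similarity(epitopes[i][0], epitopes[j][0]) >= link_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    reps = []
    for members in groups.values():
        best = min(members, key=lambda i: (
            epitopes[i][1] if epitopes[i][1] is not None else math.inf, i))
        reps.append(set(epitopes[best][0]))
    return reps


def g_test(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """G statistic of feature presence vs class on the 2x2 table
    G = 2 * sum O * ln(O/E), zero-observation cells contributing 0."""
    a = np.asarray(values_a)
    b = np.asarray(values_b)
    obs = np.array([
        [(a > 0).sum(), (a <= 0).sum()],
        [(b > 0).sum(), (b <= 0).sum()],
    ], dtype=float)
    grand = obs.sum()
    if grand == 0:
        return 0.0
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        return 0.0
    expected = row * col / grand
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    return float(2.0 * terms.sum())


def g_test_counts(observed: np.ndarray, expected: np.ndarray) -> float:
    """G statistic directly from observed/expected cell counts."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(o > 0, o * np.log(o / e), 0.0)
    return float(2.0 * terms.sum())
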