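"""Morisita-Horn dissimilarity per image and the decision-tree baseline.

The Morisita-Horn (MH) index measures the overlap of two count
distributions over spatial quadrats:

    MH(x, y) = 2 * sum_i x_i y_i / ((lambda_x + lambda_y) * X * Y)

with X = sum x_i, lambda_x = sum x_i^2 / X^2 (and likewise for y).  It is
1 for identical distributions, 0 for disjoint supports, and invariant to
separately rescaling x or y.  Dissimilarity = 1 - similarity.

As a whole-image feature the pattern's window is divided into a gx-by-gy
quadrat grid, each phenotype group is reduced to its per-quadrat counts,
and one MH dissimilarity is computed between the configured pair of groups
(default: epithelium versus pooled CTL+Treg immune cells).  A depth-limited
decision tree on that single scalar is the classical baseline against which
the graph network is compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .io import PointPattern

logger = logging.getLogger(__name__)

#: Default phenotype pairing: tumor compartment vs pooled immune compartment.
DEFAULT_PAIR_POLICY: tuple[tuple[str, ...], tuple[str, ...]] = (
    ("Epithelial",),
    ("CTL", "Treg"),
)


@dataclass
class QuadratCounts:
    """Per-phenotype cell counts over a regular quadrat grid."""

    grid: tuple[int, int]
    counts: dict[str, np.ndarray]  # type -> length gx*gy nonnegative ints


@dataclass
class MHResult:
    similarity: float
    dissimilarity: float
    phenotype_pair: tuple[str, str] = ("x", "y")


def quadrat_counts(pattern: PointPattern, gx: int, gy: int) -> QuadratCounts:
    """Bin cells into a gx-by-gy grid over the pattern's bounding box.

    Quadrats are half-open [left, right) x [bottom, top); the max-edge
    quadrats are closed so every cell lands in exactly one bin.  A phenotype
    with no cells gets an all-zero vector.
    """
    if gx < 1 or gy < 1:
        raise ValueError("grid dimensions must be >= 1")
    xy = pattern.coords
    x0, y0 = xy.min(axis=0)
    x1, y1 = xy.max(axis=0)
    # degenerate extent (all cells collinear/coincident) still bins validly
    wx = (x1 - x0) or 1.0
    wy = (y1 - y0) or 1.0
    ix = np.minimum(((xy[:, 0] - x0) / wx * gx).astype(np.int64), gx - 1)
    iy = np.minimum(((xy[:, 1] - y0) / wy * gy).astype(np.int64), gy - 1)
    bins = ix * gy + iy
    labels = np.asarray(pattern.labels)
    counts = {}
    for t in pattern.label_dictionary:
        counts[t] = np.bincount(bins[labels == t], minlength=gx * gy).astype(np.int64)
    return QuadratCounts(grid=(gx, gy), counts=counts)


def morisita_horn(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    phenotype_pair: tuple[str, str] = ("x", "y"),
) -> MHResult:
    """Morisita-Horn overlap of two equal-length count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("count vectors must be 1-D with equal lengths")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be nonnegative")
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        raise ZeroDivisionError("Morisita-Horn undefined for an all-zero vector")
    lam_x = (x * x).sum() / X**2
    lam_y = (y * y).sum() / Y**2
    sim = 2.0 * (x * y).sum() / ((lam_x + lam_y) * X * Y)
    sim = float(min(max(sim, 0.0), 1.0))  # guard roundoff at the boundaries
    return MHResult(similarity=sim, dissimilarity=1.0 - sim, phenotype_pair=phenotype_pair)


def mh_feature(
    pattern: PointPattern,
    pair_policy: tuple[tuple[str, ...], tuple[str, ...]] = DEFAULT_PAIR_POLICY,
    gx: int = 10,
    gy: int = 10,
) -> float:
    """Single MH dissimilarity per image under a phenotype pairing.

    Each side of ``pair_policy`` is a group of phenotypes whose quadrat
    counts are pooled.  Returns NaN (logged) when either group is empty.
    """
    qc = quadrat_counts(pattern, gx, gy)
    group_a, group_b = pair_policy
    a = sum((qc.counts.get(t, 0) for t in group_a), np.zeros(gx * gy))
    b = sum((qc.counts.get(t, 0) for t in group_b), np.zeros(gx * gy))
    if a.sum() == 0 or b.sum() == 0:
        logger.warning(
            "sample %s: empty phenotype group in %s; MH feature is NaN",
            pattern.sample_id, pair_policy,
        )
        return float("nan")
    res = morisita_horn(a, b, phenotype_pair=("+".join(group_a), "+".join(group_b)))
    return res.dissimilarity


@dataclass
class MHTreeModel:
    """Decision tree on the scalar MH feature of each image."""

    tree: DecisionTreeClassifier
    classes: tuple[str, str]

    def predict(self, features: Sequence[float]) -> np.ndarray:
        return self.tree.predict(np.asarray(features, dtype=float).reshape(-1, 1))

    def predict_proba(self, features: Sequence[float]) -> np.ndarray:
        return self.tree.predict_proba(np.asarray(features, dtype=float).reshape(-1, 1))

    def positive_scores(self, features: Sequence[float]) -> np.ndarray:
        """P(classes[0]) per sample, for ranking metrics."""
        proba = self.predict_proba(features)
        col = list(self.tree.classes_).index(self.classes[0])
        return proba[:, col]


def train_mh_tree(
    features: Sequence[float],
    labels: Sequence[str],
    seed: int = 0,
    max_depth: int = 3,
) -> MHTreeModel:
    """Fit a depth-limited decision tree on per-image MH dissimilarities."""
    f = np.asarray(features, dtype=float).reshape(-1, 1)
    y = np.asarray(labels)
    uniq = sorted(set(y))
    if len(uniq) < 2:
        raise ValueError("need two classes to train the baseline tree")
    keep = np.isfinite(f[:, 0])
    if not keep.all():
        logger.warning("dropping %d samples with missing MH feature", (~keep).sum())
        f, y = f[keep], y[keep]
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    tree.fit(f, y)
    return MHTreeModel(tree=tree, classes=(uniq[0], uniq[1]))
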