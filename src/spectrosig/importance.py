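"""Gini feature-importance attribution, global and category-specific.

A forest's split nodes each reduce Gini impurity; a feature's *global*
importance is the sample-fraction-weighted impurity reduction summed over
every node that splits on it, accumulated over trees and normalized so the
map sums to 1.  The *category-specific* map is built by taking every leaf
whose majority class is the category, walking from the leaf back to the
root, and crediting each split node on the path with its impurity
reduction; this attributes to a category exactly the features its decision
paths consulted.  Maps live on the 146 x 48 spectrotemporal grid and are
compared with Gaussian-fit difference masks (mean + k sigma, default k=4,
tolerating about one false positive among the 7008 cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectral import N_BINS, N_FREQS

MAP_SHAPE = (N_FREQS, N_BINS)


def gini_impurity(class_proportions) -> float:
    """G = sum_i p_i (1 - p_i) over class proportions of a node."""
    p = np.asarray(class_proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    return float(np.sum(p * (1.0 - p)))


def node_importance(
    parent_G: float, child_Gs: tuple[float, float], node_sample_fractions
) -> float:
    """Sample-fraction-weighted impurity reduction of one split.

    ``node_sample_fractions`` is (f_parent, f_left, f_right) with the
    children partitioning the parent's samples;
    I = f_p G_p - f_l G_l - f_r G_r, which is >= 0 for any valid split by
    concavity of the Gini index.
    """
    f_p, f_l, f_r = (float(f) for f in node_sample_fractions)
    if abs((f_l + f_r) - f_p) > 1e-9:
        raise ValueError("children fractions must sum to the parent fraction")
    if f_l > f_p + 1e-12 or f_r > f_p + 1e-12:
        raise ValueError("a child cannot hold more samples than its parent")
    g_l, g_r = child_Gs
    return f_p * parent_G - f_l * g_l - f_r * g_r


@dataclass
class ImportanceMap:
    """Nonnegative 146 x 48 attribution weights."""

    values: np.ndarray
    scope: str = "global"  # global | per-category
    tag: str = ""  # probe_id or aggregate tag
    category: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != MAP_SHAPE:
            raise ValueError(f"importance maps are exactly {MAP_SHAPE}")
        if np.any(self.values < 0):
            raise ValueError("importance weights are nonnegative")

    def flatten(self) -> np.ndarray:
        return self.values.reshape(-1)

    def normalized(self) -> "ImportanceMap":
        total = self.values.sum()
        vals = self.values / total if total > 0 else self.values
        return ImportanceMap(vals, self.scope, self.tag, self.category)


def _tree_node_importances(tree) -> np.ndarray:
    """Per-node weighted impurity reduction, as a fraction of root samples."""
    t = tree.tree_
    total = t.weighted_n_node_samples[0]
    left, right = t.children_left, t.children_right
    imp = np.zeros(t.node_count)
    internal = left != -1
    w = t.weighted_n_node_samples / total
    imp[internal] = (
        w[internal] * t.impurity[internal]
        - w[left[internal]] * t.impurity[left[internal]]
        - w[right[internal]] * t.impurity[right[internal]]
    )
    return imp


def _tree_feature_importance(tree, n_features: int) -> np.ndarray:
    imp = _tree_node_importances(tree)
    t = tree.tree_
    internal = t.children_left != -1
    out = np.zeros(n_features)
    np.add.at(out, t.feature[internal], imp[internal])
    return out


def global_importance(forest, shape=MAP_SHAPE, tag: str = "") -> ImportanceMap:
    """Mean over trees of per-tree (sum-1 normalized) Gini importances.

    Implemented by direct traversal of each tree's node arrays; the result
    is renormalized to sum to 1 and reshaped to the TF grid.
    """
    n_features = int(np.prod(shape))
    acc = np.zeros(n_features)
    any_split = False
    for est in forest.estimators_:
        vec = _tree_feature_importance(est, n_features)
        s = vec.sum()
        if s > 0:
            acc += vec / s
            any_split = True
    if not any_split:
        warnings.warn("forest contains no splits; importance map is all zero")
        return ImportanceMap(np.zeros(shape), "global", tag)
    acc /= len(forest.estimators_)
    acc /= acc.sum()
    return ImportanceMap(acc.reshape(shape), "global", tag)


def _tree_parents(tree) -> np.ndarray:
    t = tree.tree_
    parents = np.full(t.node_count, -1, dtype=int)
    for n in range(t.node_count):
        for child in (t.children_left[n], t.children_right[n]):
            if child != -1:
                parents[child] = n
    return parents


def _leaf_majority_class(tree) -> np.ndarray:
    """Majority training class index of every node (leaves included)."""
    value = np.asarray(tree.tree_.value)  # (n_nodes, 1, n_classes)
    return value[:, 0, :].argmax(axis=1)


def category_importance(
    forest, category, shape=MAP_SHAPE, tag: str = ""
) -> ImportanceMap:
    """Leaf-to-root attribution of importance to one category.

    For every tree, each leaf whose majority class is ``category``
    contributes, for each split node on its path to the root, that node's
    full impurity reduction to the node's split feature.  A feature used at
    several nodes of one path accumulates once per node.  If no leaf of any
    tree is associated with the category the map is zero (with a warning).
    """
    classes = list(forest.classes_)
    if category not in classes:
        raise ValueError(f"category {category!r} unknown to this forest")
    c_idx = classes.index(category)
    n_features = int(np.prod(shape))
    acc = np.zeros(n_features)
    any_leaf = False
    for est in forest.estimators_:
        t = est.tree_
        imp = _tree_node_importances(est)
        parents = _tree_parents(est)
        majority = _leaf_majority_class(est)
        leaves = np.flatnonzero(t.children_left == -1)
        for leaf in leaves:
            if majority[leaf] != c_idx:
                continue
            any_leaf = True
            node = parents[leaf]
            while node != -1:
                acc[t.feature[node]] += imp[node]
                node = parents[node]
    if not any_leaf:
        warnings.warn(f"no leaf predicts category {category!r}; zero map")
    acc /= len(forest.estimators_)
    return ImportanceMap(acc.reshape(shape), "per-category", tag, category=category)


def average_importance(
    maps: list[ImportanceMap], normalize: bool = False, tag: str = "average"
) -> ImportanceMap:
    """Cell-wise mean of importance maps.

    With ``normalize=True`` each map is first rescaled to sum to 1 so that
    probes with large absolute importance do not dominate the average.
    """
    if not maps:
        raise ValueError("need at least one map")
    scope = maps[0].scope
    cats = {m.category for m in maps}
    if any(m.scope != scope for m in maps):
        raise ValueError("cannot average maps of mixed scope")
    stack = np.stack(
        [(m.normalized() if normalize else m).values for m in maps]
    )
    return ImportanceMap(
        stack.mean(axis=0),
        scope,
        tag,
        category=cats.pop() if len(cats) == 1 else None,
    )


@dataclass
class MapComparison:
    """Gaussian-fit difference mask between two maps (D = A - B)."""

    mu: float
    sigma: float
    k: float
    positive: np.ndarray  # D > mu + k sigma  (A exceeds B)
    negative: np.ndarray  # D < mu - k sigma  (B exceeds A)
    z: np.ndarray


def compare_maps(map_a: ImportanceMap, map_b: ImportanceMap, k: float = 4.0) -> MapComparison:
    """Cells where one map significantly exceeds the other.

    A normal distribution is fit to the cell-wise difference over all 7008
    cells; cells beyond mean + k sigma are flagged (the symmetric lower
    tail is reported separately).  k = 4 tolerates on the order of one
    false positive per map under a Gaussian difference field.
    """
    if map_a.values.shape != map_b.values.shape:
        raise ValueError("maps must share a shape")
    d = map_a.values - map_b.values
    mu, sigma = float(d.mean()), float(d.std())
    if sigma == 0:
        z = np.zeros_like(d)
        empty = np.zeros_like(d, dtype=bool)
        return MapComparison(mu, sigma, k, empty, empty.copy(), z)
    z = (d - mu) / sigma
    return MapComparison(mu, sigma, k, z > k, z < -k, z)


@dataclass
class ContrastMap:
    """Tri-state comparison of two probe groups' mean importance maps.

    ``labels``: 0 = neither, 1 = both-important (both groups' own z >= 2),
    2 = group-A dominant, 3 = group-B dominant.  Dominance (difference
    z-score beyond k_diff) overlays the both-important layer.
    """

    labels: np.ndarray
    z_a: np.ndarray
    z_b: np.ndarray
    diff: MapComparison

    NEITHER, BOTH, A_DOMINANT, B_DOMINANT = 0, 1, 2, 3


def group_importance_contrast(
    maps_a: list[ImportanceMap],
    maps_b: list[ImportanceMap],
    k_important: float = 2.0,
    k_diff: float = 4.0,
) -> ContrastMap:
    """Contrast two groups of probes (e.g. mono- vs polypredictive).

    Each group's maps are averaged (per-map sum-1 normalized); each mean
    map is z-scored against its own cell distribution; cells with z >= 2 in
    both groups are 'both-important', and cells where the difference field
    exceeds k_diff sigma are labeled with the dominant group.
    """
    if not maps_a or not maps_b:
        raise ValueError("both groups must be non-empty")
    mean_a = average_importance(maps_a, normalize=True, tag="group_a")
    mean_b = average_importance(maps_b, normalize=True, tag="group_b")

    def zscore(m: ImportanceMap) -> np.ndarray:
        v = m.values
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    z_a, z_b = zscore(mean_a), zscore(mean_b)
    diff = compare_maps(mean_a, mean_b, k=k_diff)
    labels = np.zeros(mean_a.values.shape, dtype=int)
    labels[(z_a >= k_important) & (z_b >= k_important)] = ContrastMap.BOTH
    labels[diff.positive] = ContrastMap.A_DOMINANT
    labels[diff.negative] = ContrastMap.B_DOMINANT
    return ContrastMap(labels, z_a, z_b, diff)
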