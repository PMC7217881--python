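"""Importance-masked activity patterns and their hierarchical clustering.

For a category, each predictive probe's mean baseline-normalized activity
map is filtered by an importance mask (cells whose importance exceeds the
map's mean + 1 SD), keeping only task-relevant activity.  The retained
ratio values, shifted by -1 so increases are positive and suppressions
negative, are clustered with complete-linkage agglomeration under cosine
distance — opposite modulation patterns (increase vs decrease) sit near
the maximal distance 2, so the top clusters separate activity families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .importance import ImportanceMap

logger = logging.getLogger(__name__)


@dataclass
class SignatureMask:
    """Boolean 146 x 48 mask of cells with importance above mean + 1 SD."""

    mask: np.ndarray
    mu: float
    sigma: float
    scope: str  # per-probe | per-category
    category: str | None = None

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def importance_mask(
    imp: ImportanceMap, n_sd: float = 1.0, scope: str | None = None
) -> SignatureMask:
    """Cells whose importance score exceeds mu + n_sd * sigma of the map."""
    v = imp.values
    mu, sigma = float(v.mean()), float(v.std())
    return SignatureMask(
        mask=v > mu + n_sd * sigma,
        mu=mu,
        sigma=sigma,
        scope=scope or ("per-category" if imp.category else "per-probe"),
        category=imp.category,
    )


def category_mean_activity(tfmaps: np.ndarray, labels, category) -> np.ndarray:
    """Cell-wise mean of a probe's TF ratio maps over one category's trials."""
    tfmaps = np.asarray(tfmaps, float)
    labels = np.asarray(labels)
    sel = labels == category
    if not sel.any():
        raise ValueError(f"no trials of category {category!r}")
    return tfmaps[sel].mean(axis=0)


def apply_mask(activity: np.ndarray, mask: SignatureMask) -> np.ndarray:
    """Retained-cell vector (fixed row-major cell order) of a masked map.

    Dropped cells are excluded, not zero-filled, so the clustering geometry
    sees only the task-relevant cells.  An empty mask yields an empty
    vector; callers exclude such probes from clustering.
    """
    activity = np.asarray(activity, float)
    if activity.shape != mask.mask.shape:
        raise ValueError("activity and mask shapes differ")
    return activity[mask.mask]


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """d = 1 - cos(u, v), in [0, 2]; 2 means opposite modulation patterns."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def masked_cluster_vectors(
    activities: dict[str, np.ndarray], mask: SignatureMask
) -> dict[str, np.ndarray]:
    """Importance-masked, ratio-centered vectors for clustering.

    Ratios are shifted by -1 (increase positive, suppression negative);
    probes whose centered vector is all zero are excluded and logged.
    """
    out = {}
    for pid, act in activities.items():
        vec = apply_mask(act, mask) - 1.0
        if vec.size == 0 or not np.any(vec):
            logger.info("probe %s excluded from clustering (empty/zero masked vector)", pid)
            continue
        out[pid] = vec
    return out


@dataclass
class ClusterSummary:
    cluster_id: int
    members: list[str]
    mean_f1: float
    poly_fraction: float
    mean_pattern: np.ndarray


@dataclass
class ClusterResult:
    """Complete-linkage clustering of probes by masked activity pattern."""

    assignments: pd.Series  # probe_id -> cluster_id
    merge_heights: np.ndarray
    linkage_matrix: np.ndarray | None
    summaries: list[ClusterSummary]
    category: str | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.nunique())


def cluster_probes(
    vectors: dict[str, np.ndarray],
    linkage_method: str = "complete",
    cut_distance: float = 0.7,
    n_report: int = 4,
    category: str | None = None,
) -> ClusterResult:
    """Agglomerative clustering under cosine distance.

    Inter-cluster distance is the maximum pairwise cosine distance between
    members (complete linkage).  The tree is cut at ``cut_distance``;
    clusters are numbered 1..k by decreasing size (ties broken by lowest
    member probe_id) and the ``n_report`` most populated are summarized by
    callers.  A single probe forms one trivial cluster.
    """
    pids = sorted(vectors)
    if not pids:
        raise ValueError("no vectors to cluster")
    if len(pids) == 1:
        return ClusterResult(
            assignments=pd.Series({pids[0]: 1}),
            merge_heights=np.array([]),
            linkage_matrix=None,
            summaries=[],
            category=category,
        )
    lengths = {vectors[p].size for p in pids}
    if len(lengths) != 1:
        raise ValueError("all probes must share the same mask cell set")
    X = np.stack([vectors[p] for p in pids])
    Z = linkage(X, method=linkage_method, metric="cosine")
    flat = fcluster(Z, t=cut_distance, criterion="distance")
    # renumber by decreasing size, tie-break on lowest member probe_id
    order = sorted(
        np.unique(flat),
        key=lambda c: (-np.sum(flat == c), min(p for p, f in zip(pids, flat) if f == c)),
    )
    remap = {old: new for new, old in enumerate(order, start=1)}
    assignments = pd.Series({p: remap[f] for p, f in zip(pids, flat)})
    return ClusterResult(
        assignments=assignments,
        merge_heights=Z[:, 2],
        linkage_matrix=Z,
        summaries=[],
        category=category,
    )


def summarize_cluster(
    members: list[str],
    cluster_id: int,
    vectors: dict[str, np.ndarray],
    member_f1: dict[str, float],
    member_status: dict[str, str],
) -> ClusterSummary:
    """Mean F1, polypredictive fraction and mean pattern of one cluster."""
    if not members:
        raise ValueError("a cluster summary needs at least one member")
    mean_f1 = float(np.mean([member_f1[p] for p in members]))
    poly = float(
        np.mean([member_status[p] == "polypredictive" for p in members])
    )
    pattern = np.mean([vectors[p] for p in members], axis=0)
    return ClusterSummary(
        cluster_id=cluster_id,
        members=list(members),
        mean_f1=mean_f1,
        poly_fraction=poly,
        mean_pattern=pattern,
    )


def summarize_top_clusters(
    result: ClusterResult,
    vectors: dict[str, np.ndarray],
    member_f1: dict[str, float],
    member_status: dict[str, str],
    n_report: int = 4,
) -> list[ClusterSummary]:
    """Summaries for the n_report most populated clusters (by renumbering)."""
    summaries = []
    for cid in sorted(result.assignments.unique())[:n_report]:
        members = sorted(result.assignments.index[result.assignments == cid])
        summaries.append(
            summarize_cluster(members, int(cid), vectors, member_f1, member_status)
        )
    result.summaries = summaries
    return summaries
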