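"""Per-probe decision-forest decoding of the 8 stimulus categories.

Each probe is treated as an independent dataset: n trials x 7008
spectrotemporal features (flattened 146 x 48 ratio maps).  A random forest
(Gini splits, bootstrap, sqrt-feature subsampling, default 3000 trees) is
evaluated with stratified 5-fold cross-validation; out-of-fold predictions
are pooled so every trial is predicted exactly once, and per-class F1 is
computed on the pooled predictions.  A probe is *predictive* of a category
when that category's F1 exceeds a permutation-derived threshold (default
0.390278, the 99.999th percentile of per-class F1 under label permutation);
probes predictive of exactly one category are *monopredictive*, of several
*polypredictive*.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .synthdata import CATEGORIES
from .spectral import FREQS, N_BINS, N_FREQS

PERMUTATION_F1_THRESHOLD = 0.390278
"""99.999th percentile of per-class F1 under label permutation (full scale)."""

CHANCE_F1 = 0.125
"""Expected F1 of a uniformly random classifier on 8 balanced classes."""

#: frequency-row masks for the band-restricted comparisons (half-open bands
#: on the integer 4..149 Hz grid)
BANDS = {
    "full": (FREQS >= 4) & (FREQS < 150),
    "low": (FREQS >= 4) & (FREQS < 50),
    "gamma": (FREQS >= 50) & (FREQS < 150),
}


def probe_seed(master_seed: int, probe_id: str) -> int:
    """Stable per-probe RNG seed derived from a master seed and the probe id."""
    digest = hashlib.sha256(f"{master_seed}:{probe_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def f1_score(predictions, truths, label) -> float:
    """Per-class F1: harmonic mean of precision and recall for one label.

    Returns 0 when precision + recall = 0.  If the label never occurs in
    the truths, recall is undefined and F1 is reported as 0 with a warning.
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have the same length")
    n_true = np.sum(truths == label)
    if n_true == 0:
        warnings.warn(f"label {label!r} absent from truths; F1 reported as 0")
        return 0.0
    tp = np.sum((predictions == label) & (truths == label))
    n_pred = np.sum(predictions == label)
    precision = tp / n_pred if n_pred else 0.0
    recall = tp / n_true
    if precision + recall == 0:
        return 0.0
    return float(2.0 * precision * recall / (precision + recall))


def per_class_f1(predictions, truths, labels=CATEGORIES) -> np.ndarray:
    return np.array([f1_score(predictions, truths, c) for c in labels])


@dataclass
class DecodingResult:
    """Cross-validated per-class F1 scores for one probe."""

    probe_id: str
    per_class_f1: np.ndarray
    per_class_f1_sd: np.ndarray
    labels: tuple = CATEGORIES
    n_trees: int = 3000
    cv_folds: int = 5
    seed: int | None = None
    band: str = "full"

    def __post_init__(self) -> None:
        self.per_class_f1 = np.asarray(self.per_class_f1, float)
        if np.any((self.per_class_f1 < 0) | (self.per_class_f1 > 1)):
            raise ValueError("F1 values must lie in [0, 1]")


@dataclass
class ProbePredictivity:
    """Which categories a probe decodes above threshold, and its status."""

    probe_id: str
    predictive_categories: list[str]
    status: str  # none | monopredictive | polypredictive
    threshold: float = PERMUTATION_F1_THRESHOLD


def _as_features(X: np.ndarray, band: str = "full") -> np.ndarray:
    """Flatten (n, 146, 48) maps row-major, optionally row-restricted."""
    X = np.asarray(X)
    if X.ndim == 3:
        if X.shape[1:] != (N_FREQS, N_BINS):
            raise ValueError("expected (n, 146, 48) TF maps")
        if band not in BANDS:
            raise ValueError(f"unknown band {band!r}; use one of {sorted(BANDS)}")
        X = X[:, BANDS[band], :]
        return X.reshape(X.shape[0], -1)
    if X.ndim == 2:
        if band != "full":
            raise ValueError("band restriction needs unflattened (n, 146, 48) maps")
        return X
    raise ValueError("X must be (n, features) or (n, 146, 48)")


def _make_forest(n_trees: int, seed) -> RandomForestClassifier:
    # Gini criterion, bootstrap, sqrt-feature subsampling, unlimited depth:
    # the reference implementation's defaults.
    return RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", random_state=seed, n_jobs=1
    )


def crossval_decode(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 3000,
    folds: int = 5,
    seed: int | None = None,
    probe_id: str = "",
    band: str = "full",
    labels=CATEGORIES,
) -> DecodingResult:
    """Stratified k-fold forest decoding with pooled out-of-fold predictions.

    On 400 balanced trials each fold trains on 320 and predicts 80, so the
    pooled predictions cover every trial exactly once; per-class F1 is
    computed on that pooled set and the fold-wise standard deviation of
    per-class F1 is retained as a noise estimate.
    """
    Xf = _as_features(X, band).astype(np.float32)
    y = np.asarray(y)
    if Xf.shape[0] != y.shape[0]:
        raise ValueError("X and y must agree on the number of trials")
    if Xf.shape[0] < folds:
        raise ValueError("fewer trials than folds")
    _, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < folds:
        raise ValueError(
            f"stratified {folds}-fold CV needs at least {folds} trials per "
            f"class (smallest class has {class_counts.min()})"
        )
    rng_seed = seed if seed is None else int(seed) % (2**31)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    pooled = np.empty(y.shape[0], dtype=y.dtype)
    fold_f1 = []
    for train, test in skf.split(Xf, y):
        clf = _make_forest(n_trees, rng_seed)
        clf.fit(Xf[train], y[train])
        pred = clf.predict(Xf[test])
        pooled[test] = pred
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold_f1.append(per_class_f1(pred, y[test], labels))
    return DecodingResult(
        probe_id=probe_id,
        per_class_f1=per_class_f1(pooled, y, labels),
        per_class_f1_sd=np.std(np.asarray(fold_f1), axis=0, ddof=0),
        labels=tuple(labels),
        n_trees=n_trees,
        cv_folds=folds,
        seed=rng_seed,
        band=band,
    )


def permutation_threshold(
    datasets: list[tuple[np.ndarray, np.ndarray]],
    n_permutations: int,
    percentile: float = 99.999,
    n_trees: int = 3000,
    folds: int = 5,
    seed: int | None = None,
    labels=CATEGORIES,
) -> tuple[float, np.ndarray]:
    """Empirical per-class F1 percentile under random label permutation.

    Each permutation shuffles one dataset's labels and runs the full
    cross-validated decoding; all 8 per-class F1 values of every permutation
    and every dataset enter one pool, whose requested percentile is the
    significance threshold.  Full scale is 1e5 permutations at the 99.999th
    percentile (threshold 0.390278); scaled-down runs (fewer permutations,
    lower percentile) are supported — the returned pool lets callers judge
    the tail resolution actually achieved.
    """
    if not datasets:
        raise ValueError("need at least one null dataset")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    pool = []
    for i in range(n_permutations):
        X, y = datasets[i % len(datasets)]
        yp = np.asarray(y)[rng.permutation(len(y))]
        res = crossval_decode(
            X,
            yp,
            n_trees=n_trees,
            folds=folds,
            seed=int(rng.integers(2**31)),
            labels=labels,
        )
        pool.append(res.per_class_f1)
    pool = np.concatenate(pool)
    return float(np.percentile(pool, percentile)), pool


def classify_predictivity(
    result: DecodingResult, threshold: float = PERMUTATION_F1_THRESHOLD
) -> ProbePredictivity:
    """Strictly-above-threshold rule: 0 categories -> none, 1 -> mono, >=2 -> poly."""
    cats = [c for c, f in zip(result.labels, result.per_class_f1) if f > threshold]
    status = "none" if not cats else ("monopredictive" if len(cats) == 1 else "polypredictive")
    return ProbePredictivity(
        probe_id=result.probe_id,
        predictive_categories=cats,
        status=status,
        threshold=threshold,
    )


def band_restricted_f1(
    X: np.ndarray,
    y: np.ndarray,
    band: str,
    n_trees: int = 3000,
    folds: int = 5,
    seed: int | None = None,
    probe_id: str = "",
) -> DecodingResult:
    """Identical CV protocol on a frequency-row-restricted feature matrix.

    Bands: ``full`` 4-150 Hz (146 rows), ``low`` 4-50 Hz (46 rows),
    ``gamma`` broadband gamma 50-150 Hz (100 rows).
    """
    return crossval_decode(
        X, y, n_trees=n_trees, folds=folds, seed=seed, probe_id=probe_id, band=band
    )


def compare_band_groups(
    f1_full: np.ndarray, f1_low: np.ndarray, f1_gamma: np.ndarray
) -> dict[str, float]:
    """Pairwise two-sided Mann-Whitney U tests, Bonferroni-corrected.

    Compares the per-probe F1 distributions obtained with full-spectrum,
    low-band and gamma-band features; three comparisons, so raw p-values
    are multiplied by 3 (capped at 1).
    """
    groups = {
        "full": np.asarray(f1_full, float),
        "low": np.asarray(f1_low, float),
        "gamma": np.asarray(f1_gamma, float),
    }
    for name, g in groups.items():
        if g.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 probes")
    pairs = [("full", "low"), ("full", "gamma"), ("low", "gamma")]
    out = {}
    for a, b in pairs:
        ga, gb = groups[a], groups[b]
        if ga.size == gb.size and np.array_equal(np.sort(ga), np.sort(gb)) and np.ptp(
            np.concatenate([ga, gb])
        ) == 0:
            p = 1.0
        else:
            p = float(mannwhitneyu(ga, gb, alternative="two-sided").pvalue)
        out[f"{a}_vs_{b}"] = min(1.0, p * len(pairs))
    return out
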