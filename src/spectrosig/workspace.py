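"""Pipeline orchestration, anatomical bounding boxes and configuration.

``run_pipeline`` chains the stages — preprocessing (detrend, 10-sigma
rejection, bipolar derivation), time-frequency featurization and
responsiveness screening, per-probe forest decoding with predictivity
classification, importance attribution, and importance-masked clustering —
over a synthetic (or adapted) cohort, writing CSV/JSON artifacts that each
embed the configuration hash and master seed.

Functional-area membership uses the printed MNI bounding boxes for the
fusiform face area (FFA), visual word form area (VWFA) and parahippocampal
place area (PPA); finer anatomical labelling (e.g. a Brodmann atlas) is a
pluggable interface whose default returns "unmapped".
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import decoding as dec
from . import importance as imp
from . import preprocess as pre
from . import signatures as sig
from . import spectral as spc
from .synthdata import CATEGORIES, Cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FunctionalAreaBox:
    """Axis-aligned MNI bounding box of a category-selective area."""

    name: str  # FFA | VWFA | PPA
    hemisphere: str  # left | right
    x: tuple[float, float]
    y: tuple[float, float]
    z: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (self.x, self.y, self.z):
            if lo > hi:
                raise ValueError("box intervals must satisfy lo <= hi")

    def contains(self, mni: Sequence[float]) -> bool:
        """Closed-interval membership (boundaries inclusive)."""
        x, y, z = mni
        return (
            self.x[0] <= x <= self.x[1]
            and self.y[0] <= y <= self.y[1]
            and self.z[0] <= z <= self.z[1]
        )


DEFAULT_AREAS = [
    FunctionalAreaBox("FFA", "left", (-44, -38), (-61, -50), (-24, -15)),
    FunctionalAreaBox("FFA", "right", (36, 43), (-55, -49), (-25, -13)),
    FunctionalAreaBox("VWFA", "left", (-50, -38), (-61, -50), (-30, -16)),
    FunctionalAreaBox("PPA", "left", (-31, -22), (-55, -49), (-12, -6)),
    FunctionalAreaBox("PPA", "right", (24, 32), (-54, -45), (-12, -6)),
]


def in_functional_area(
    mni: Sequence[float], boxes: Sequence[FunctionalAreaBox] = DEFAULT_AREAS
) -> list[FunctionalAreaBox]:
    """All boxes containing the MNI point."""
    return [b for b in boxes if b.contains(mni)]


def null_brodmann_lookup(mni: Sequence[float]) -> str:
    """Default anatomical labeller: no atlas bundled, everything unmapped."""
    return "unmapped"


def area_predictivity_profile(
    records: pd.DataFrame,
    area: FunctionalAreaBox,
    categories: Sequence[str] = CATEGORIES,
) -> pd.Series:
    """Per-category counts of predictive probes located inside one area.

    ``records`` needs columns mni_x/y/z and ``predictive_categories`` (a
    ';'-joined string or list).  The counts sum to the number of
    (probe, category) predictive pairs within the area.
    """
    counts = {c: 0 for c in categories}
    for _, row in records.iterrows():
        if not area.contains((row["mni_x"], row["mni_y"], row["mni_z"])):
            continue
        cats = row["predictive_categories"]
        if isinstance(cats, str):
            cats = [c for c in cats.split(";") if c]
        for c in cats:
            if c in counts:
                counts[c] += 1
    return pd.Series(counts, name=area.name)


@dataclass
class PipelineConfig:
    """Every stage parameter in one serializable record."""

    seed: int = 0
    artifact_sigma_k: float = 10.0
    bipolar: bool = True
    responsiveness_alpha: float = 0.005
    fdr_method: str = "fdr_bh"
    n_trees: int = 3000
    cv_folds: int = 5
    f1_threshold: float = dec.PERMUTATION_F1_THRESHOLD
    mask_scope: str = "category"  # category | probe
    mask_n_sd: float = 1.0
    linkage: str = "complete"
    cut_distance: float = 0.7
    n_report_clusters: int = 4
    normalize_probe_maps: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    """End-to-end artifacts of one pipeline run."""

    config: PipelineConfig
    exclusions: pd.DataFrame
    responsiveness: pd.DataFrame
    decoding: pd.DataFrame
    importance_maps: dict  # probe_id -> {"global": map, category: map, ...}
    category_masks: dict  # category -> SignatureMask
    clusters: dict  # category -> ClusterResult
    cluster_table: pd.DataFrame
    tfmaps: dict  # probe_id -> (n, 146, 48)
    labels: dict  # probe_id -> (n,)
    counts: dict


def _stamp(df: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.config_hash
    df["master_seed"] = config.seed
    return df


def preprocess_cohort(cohort: Cohort, config: PipelineConfig):
    """Detrend, reject 10-sigma artifacts (monopolar), then derive bipolar probes.

    Returns ``(epochs, labels, mni, exclusions)`` keyed by derived probe id
    when ``config.bipolar`` is set (shafts with one usable contact yield no
    derivation), else by the recorded contact id.
    """
    exclusions = []
    clean: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    meta: dict[str, dict] = {}
    for spec_ in cohort.probe_specs:
        pid = spec_.probe_id
        detrended = pre.detrend_linear(cohort.epochs[pid])
        pes = pre.ProbeEpochSet(pid, detrended, cohort.labels[pid])
        retain, report = pre.reject_artifacts(pes, k=config.artifact_sigma_k)
        exclusions.append(report.to_frame())
        if not report.usable:
            logger.warning("probe %s unusable after artifact rejection", pid)
            continue
        clean[pid] = detrended[retain]
        labels[pid] = cohort.labels[pid][retain]
        meta[pid] = dict(
            subject_id=spec_.subject_id,
            shaft_id=spec_.shaft_id,
            contact_index=spec_.contact_index,
            mni=spec_.mni,
        )
    exclusions = (
        pd.concat(exclusions, ignore_index=True)
        if exclusions
        else pd.DataFrame(columns=["probe_id", "trial_index", "reason"])
    )
    if not config.bipolar:
        mni = {p: meta[p]["mni"] for p in clean}
        return clean, labels, mni, exclusions

    out_epochs: dict[str, np.ndarray] = {}
    out_labels: dict[str, np.ndarray] = {}
    out_mni: dict[str, tuple] = {}
    shafts: dict[tuple, list[str]] = {}
    for pid in clean:
        shafts.setdefault(
            (meta[pid]["subject_id"], meta[pid]["shaft_id"]), []
        ).append(pid)
    for key in sorted(shafts):
        members = shafts[key]
        # bipolar derivation requires a common retained-trial base per shaft
        common = None
        for pid in members:
            lab = labels[pid]
            common = lab if common is None else common
        contacts = [
            dict(
                probe_id=pid,
                contact_index=meta[pid]["contact_index"],
                epochs=clean[pid],
                mni=meta[pid]["mni"],
            )
            for pid in members
            if len(labels[pid]) == len(common) and np.array_equal(labels[pid], common)
        ]
        skipped = set(members) - {c["probe_id"] for c in contacts}
        if skipped:
            logger.warning(
                "shaft %s: contacts %s skipped for bipolar derivation "
                "(unequal retained-trial base)",
                key,
                sorted(skipped),
            )
        for deriv in pre.bipolar_rereference(contacts):
            out_epochs[deriv.probe_id] = deriv.epochs
            out_labels[deriv.probe_id] = common
            out_mni[deriv.probe_id] = deriv.mni
    return out_epochs, out_labels, out_mni, exclusions


def run_pipeline(
    config: PipelineConfig,
    cohort: Cohort,
    outdir=None,
    brodmann_lookup: Callable = null_brodmann_lookup,
) -> PipelineResult:
    """Execute preprocess -> spectral -> decoding -> importance -> clustering."""
    epochs, labels, mni, exclusions = preprocess_cohort(cohort, config)
    logger.info("preprocess: %d usable probes", len(epochs))

    # --- spectral stage ---
    tfmaps: dict[str, np.ndarray] = {}
    resp_rows = []
    responsive: dict[str, bool] = {}
    for pid in sorted(epochs):
        maps, post, base = spc.probe_tf_features(epochs[pid])
        tfmaps[pid] = maps
        res = spc.responsiveness_test(
            post, base, alpha=config.responsiveness_alpha, probe_id=pid
        )
        responsive[pid] = res.responsive
        resp_rows.append(
            dict(
                probe_id=pid,
                n_significant_frequencies=res.n_significant_frequencies,
                responsive=res.responsive,
            )
        )
    responsiveness = pd.DataFrame(resp_rows)

    # --- decoding stage (responsive probes only) ---
    dec_rows = []
    results: dict[str, dec.DecodingResult] = {}
    predictivity: dict[str, dec.ProbePredictivity] = {}
    for pid in sorted(epochs):
        if not responsive.get(pid, False):
            continue
        res = dec.crossval_decode(
            tfmaps[pid],
            labels[pid],
            n_trees=config.n_trees,
            folds=config.cv_folds,
            seed=dec.probe_seed(config.seed, pid),
            probe_id=pid,
        )
        pred = dec.classify_predictivity(res, threshold=config.f1_threshold)
        results[pid] = res
        predictivity[pid] = pred
        row = dict(probe_id=pid, status=pred.status,
                   predictive_categories=";".join(pred.predictive_categories),
                   mni_x=mni[pid][0], mni_y=mni[pid][1], mni_z=mni[pid][2],
                   brodmann=brodmann_lookup(mni[pid]))
        for c, f, s in zip(res.labels, res.per_class_f1, res.per_class_f1_sd):
            row[f"f1_{c}"] = f
            row[f"f1_sd_{c}"] = s
        dec_rows.append(row)
    decoding_df = pd.DataFrame(dec_rows)

    # --- importance stage (predictive probes, forest refit on all trials) ---
    importance_maps: dict[str, dict] = {}
    for pid, pred in sorted(predictivity.items()):
        if pred.status == "none":
            continue
        X = tfmaps[pid].reshape(tfmaps[pid].shape[0], -1).astype(np.float32)
        forest = dec._make_forest(config.n_trees, dec.probe_seed(config.seed, pid))
        forest.fit(X, labels[pid])
        maps = {"global": imp.global_importance(forest, tag=pid)}
        for c in pred.predictive_categories:
            maps[c] = imp.category_importance(forest, c, tag=pid)
        importance_maps[pid] = maps

    # --- clustering stage (per category over its predictive probes) ---
    category_masks: dict[str, sig.SignatureMask] = {}
    clusters: dict[str, sig.ClusterResult] = {}
    cluster_rows = []
    for cat in CATEGORIES:
        members = [
            pid
            for pid, pred in predictivity.items()
            if cat in pred.predictive_categories and pid in importance_maps
        ]
        if len(members) < 2:
            continue
        cat_maps = [importance_maps[p][cat] for p in members]
        if config.mask_scope == "category":
            mean_map = imp.average_importance(
                cat_maps, normalize=config.normalize_probe_maps, tag=f"mean[{cat}]"
            )
            mask = sig.importance_mask(mean_map, n_sd=config.mask_n_sd)
        else:
            # per-probe masks differ per probe; clustering needs one common
            # cell set, so the probe-scope mode unions the per-probe masks
            union = np.zeros(imp.MAP_SHAPE, dtype=bool)
            mus, sigmas = [], []
            for m in cat_maps:
                pm = sig.importance_mask(m, n_sd=config.mask_n_sd)
                union |= pm.mask
                mus.append(pm.mu)
                sigmas.append(pm.sigma)
            mask = sig.SignatureMask(
                union, float(np.mean(mus)), float(np.mean(sigmas)),
                scope="per-probe-union", category=cat,
            )
        if mask.n_cells == 0:
            logger.warning("category %s: empty importance mask; skipped", cat)
            continue
        category_masks[cat] = mask
        activities = {
            p: sig.category_mean_activity(tfmaps[p], labels[p], cat) for p in members
        }
        vectors = sig.masked_cluster_vectors(activities, mask)
        if len(vectors) < 2:
            continue
        cres = sig.cluster_probes(
            vectors,
            linkage_method=config.linkage,
            cut_distance=config.cut_distance,
            n_report=config.n_report_clusters,
            category=cat,
        )
        member_f1 = {
            p: float(results[p].per_class_f1[list(results[p].labels).index(cat)])
            for p in vectors
        }
        member_status = {p: predictivity[p].status for p in vectors}
        sig.summarize_top_clusters(
            cres, vectors, member_f1, member_status, n_report=config.n_report_clusters
        )
        clusters[cat] = cres
        for pid, cid in cres.assignments.items():
            cluster_rows.append(
                dict(probe_id=pid, category=cat, cluster_id=int(cid),
                     f1=member_f1[pid], status=member_status[pid])
            )
    cluster_table = pd.DataFrame(cluster_rows)

    n_probes = len(epochs)
    counts = dict(
        n_probes=n_probes,
        n_responsive=int(sum(responsive.values())),
        responsive_fraction=float(np.mean(list(responsive.values()))) if n_probes else 0.0,
        n_predictive=int(sum(p.status != "none" for p in predictivity.values())),
        n_monopredictive=int(sum(p.status == "monopredictive" for p in predictivity.values())),
        n_polypredictive=int(sum(p.status == "polypredictive" for p in predictivity.values())),
    )
    logger.info("pipeline counts: %s", counts)

    result = PipelineResult(
        config=config,
        exclusions=exclusions,
        responsiveness=responsiveness,
        decoding=decoding_df,
        importance_maps=importance_maps,
        category_masks=category_masks,
        clusters=clusters,
        cluster_table=cluster_table,
        tfmaps=tfmaps,
        labels=labels,
        counts=counts,
    )
    if outdir is not None:
        write_artifacts(result, Path(outdir))
    return result


def write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    cfg.to_json(outdir / "config.json")
    _stamp(result.exclusions, cfg).to_csv(outdir / "exclusions.csv", index=False)
    _stamp(result.responsiveness, cfg).to_csv(outdir / "responsiveness.csv", index=False)
    _stamp(result.decoding, cfg).to_csv(outdir / "decoding.csv", index=False)
    _stamp(result.cluster_table, cfg).to_csv(outdir / "clusters.csv", index=False)
    with open(outdir / "counts.json", "w") as fh:
        json.dump(
            {**result.counts, "config_hash": cfg.config_hash, "master_seed": cfg.seed},
            fh,
            indent=2,
        )
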