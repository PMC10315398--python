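"""k-fold nested cross-validation of SOM classifiers for the nested models.

Profiles are randomly permuted (random permutation sampling) and split into
k non-overlapping near-equal folds.  For each outer fold, a SOM is trained
and its nodes class-labeled on the remaining training+validation data only;
held-out profiles are scored by their BMU's class probabilities.  Because
the three model classes are heavily imbalanced, metrics are micro-averaged:
the one-vs-rest ROC AUC pools every (sample, class) decision, balanced
accuracy is the mean per-class recall, and F1 comes from pooled confusion
counts at the argmax decision.  Confidence bounds are a seeded bootstrap
over folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import balanced_accuracy_score, f1_score, roc_auc_score

from .som import SOMConfig, SOMModel, bmu, probability_maps, train_ksom

logger = logging.getLogger(__name__)

CLASSES = (1, 2, 3)


@dataclass(frozen=True)
class FoldPlan:
    n: int
    k: int
    fold_ids: np.ndarray  # (n,) in 0..k-1
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_ids == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_ids != fold)


@dataclass
class MetricWithCI:
    value: float
    lower: float
    upper: float


@dataclass
class ModalityNCVResult:
    modality_id: str
    auc: MetricWithCI
    balanced_accuracy: MetricWithCI
    f1: MetricWithCI
    n_models_trained: int
    folds_used: int


@dataclass
class NCVReport:
    results: list[ModalityNCVResult] = field(default_factory=list)

    @property
    def total_models_trained(self) -> int:
        return sum(r.n_models_trained for r in self.results)


def split_folds(n: int, k: int = 10, seed: int = 0) -> FoldPlan:
    """Seeded random permutation chunked into k near-equal disjoint folds."""
    if n < k:
        raise ValueError("need at least k samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = np.empty(n, dtype=np.int64)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for fold, size in enumerate(sizes):
        fold_ids[perm[start : start + size]] = fold
        start += size
    return FoldPlan(n=n, k=k, fold_ids=fold_ids, seed=seed)


def multiclass_metrics(scores: np.ndarray, labels: np.ndarray, classes=CLASSES):
    """(micro AUC, balanced accuracy, micro F1) from per-class probability scores.

    The AUC is the one-vs-rest Mann-Whitney statistic on the pooled
    (sample, class) decisions (mid-rank tie handling); classes absent from
    ``labels`` are excluded from the pooling and logged.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    present = [c for c in classes if (labels == c).any()]
    if len(present) < len(classes):
        logger.info("classes absent from labels: %s", set(classes) - set(present))
    cols = [list(classes).index(c) for c in present]
    onehot = np.stack([(labels == c).astype(int) for c in present], axis=1)
    auc = float(roc_auc_score(onehot.ravel(), scores[:, cols].ravel()))
    pred = np.asarray(classes)[np.argmax(scores, axis=1)]
    ba = float(balanced_accuracy_score(labels, pred))
    f1 = float(f1_score(labels, pred, average="micro"))
    return auc, ba, f1


def score_profiles(
    model: SOMModel, prob_maps, profiles: np.ndarray, classes=CLASSES
) -> np.ndarray:
    """Class scores of profiles = class probabilities of their BMU.

    The BMU search is restricted to nodes with at least one training hit:
    zero-hit interpolating nodes carry no class information, so a profile is
    scored by the nearest node (in weight space) that does.
    """
    probs = prob_maps.probabilities
    hit = prob_maps.hit_nodes
    if not hit.any():
        raise ValueError("probability map has no hit node")
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    hit_idx = np.flatnonzero(hit)
    sub = SOMModel(
        weights=model.weights[hit_idx],
        grid=model.grid,
        axial=model.axial[hit_idx],
        grid_distance=model.grid_distance[np.ix_(hit_idx, hit_idx)],
        config=model.config,
    )
    winners = hit_idx[bmu(sub, profiles)]
    return probs[winners]


def run_ncv(
    modalities: dict[str, np.ndarray],
    labels: np.ndarray,
    plan: FoldPlan,
    som_config: SOMConfig | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> NCVReport:
    """Nested cross-validation of every modality on a shared fold plan.

    ``modalities`` maps modality id -> (n, profile_len) matrix; all share
    ``labels`` and the fold plan (so comparisons are paired).  Returns per
    modality micro-averaged AUC / balanced accuracy / F1 with bootstrap
    confidence bounds over folds, plus the count of SOMs trained.
    """
    som_config = som_config or SOMConfig()
    labels = np.asarray(labels)
    report = NCVReport()
    for modality_id, profiles in modalities.items():
        profiles = np.asarray(profiles, dtype=float)
        if profiles.shape[0] != plan.n:
            raise ValueError(f"{modality_id}: profile count does not match fold plan")
        fold_metrics = []
        n_trained = 0
        for fold in range(plan.k):
            tr = plan.train_indices(fold)
            te = plan.test_indices(fold)
            if np.unique(labels[tr]).size < len(CLASSES):
                logger.warning("%s fold %d lacks a class in training; skipped", modality_id, fold)
                continue
            cfg = SOMConfig(
                grid=som_config.grid,
                initial_radius=som_config.initial_radius,
                max_epochs=som_config.max_epochs,
                cover_steps=som_config.cover_steps,
                init=som_config.init,
                seed=som_config.seed + fold,
            )
            model = train_ksom(profiles[tr], cfg)
            n_trained += 1
            pmaps = probability_maps(model, profiles[tr], labels[tr])
            scores = score_profiles(model, pmaps, profiles[te])
            fold_metrics.append(multiclass_metrics(scores, labels[te]))
        if not fold_metrics:
            logger.warning("%s: no usable fold", modality_id)
            continue
        fm = np.asarray(fold_metrics)  # (folds, 3)
        rng = np.random.default_rng(seed)
        boot = np.empty((n_bootstrap, 3))
        for b in range(n_bootstrap):
            pick = rng.integers(0, fm.shape[0], fm.shape[0])
            boot[b] = fm[pick].mean(axis=0)
        lo = np.percentile(boot, 2.5, axis=0)
        hi = np.percentile(boot, 97.5, axis=0)
        point = fm.mean(axis=0)
        report.results.append(
            ModalityNCVResult(
                modality_id=modality_id,
                auc=MetricWithCI(point[0], lo[0], hi[0]),
                balanced_accuracy=MetricWithCI(point[1], lo[1], hi[1]),
                f1=MetricWithCI(point[2], lo[2], hi[2]),
                n_models_trained=n_trained,
                folds_used=fm.shape[0],
            )
        )
    return report
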