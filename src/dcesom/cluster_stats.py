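"""Silhouette threshold-sweep analysis, DSC%, and modality significance tests.

For each information modality, nodes of its trained SOM are labeled with the
model class of maximum probability whenever that probability reaches a
threshold; sweeping the threshold over 100 states (0.01..1.00, step 0.01)
and computing silhouette coefficients of the included node weight vectors
traces the stability of the class separation on the feature space.  The
distinction-power statistic of a feature versus its raw echo is

    DSC% = 100 x (SC_feature / SC_raw - 1)

on the mean silhouette coefficients.  Per-threshold mean-SC samples of a
feature and its raw echo are compared by a mean-centered Levene test for
variance homogeneity, then a two-sample ANOVA (homogeneous) or Welch test
(heterogeneous), with Holm-Bonferroni control across the features of one
echo; a feature is significant when the adjusted p-value is below 0.05 and
its DSC% is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

from .som import NodeProbabilityMaps, SOMModel

DEFAULT_THRESHOLDS = np.round(np.arange(1, 101) * 0.01, 2)


@dataclass
class SilhouetteSweep:
    modality_id: str
    thresholds: np.ndarray
    mean_sc: np.ndarray  # per threshold; NaN where < 2 classes survive
    sd_sc: np.ndarray
    n_nodes: np.ndarray  # included node count per threshold
    per_cluster_mean: list[dict[int, float]] = field(default_factory=list)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.mean_sc)

    @property
    def overall_mean(self) -> float:
        return float(np.nanmean(self.mean_sc)) if self.valid.any() else np.nan


@dataclass
class ModalityComparison:
    modality_id: str
    dsc_percent: float
    levene_p: float
    omnibus_p: float
    omnibus_test: str  # "anova" | "welch"
    adjusted_p: float = np.nan
    significant: bool = False


def silhouette(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette coefficients (Euclidean).

    s(i) = (b - a)/max(a, b) with a the mean intra-cluster distance
    (excluding self) and b the smallest mean distance to another cluster;
    points in singleton clusters score 0 by convention.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least two clusters")
    return silhouette_samples(np.asarray(points, dtype=float), labels)


def threshold_labels(prob_maps: NodeProbabilityMaps, threshold: float):
    """Included-node mask and argmax class labels at one probability threshold.

    A node is included when its maximum class probability reaches the
    threshold; ties go to the lower class id (argmax convention).
    """
    probs = prob_maps.probabilities
    hit = prob_maps.hit_nodes
    with np.errstate(invalid="ignore"):
        pmax = np.where(hit, np.nanmax(np.where(np.isnan(probs), -np.inf, probs), axis=1), -np.inf)
        argmax = np.where(hit, np.nanargmax(np.where(np.isnan(probs), -np.inf, probs), axis=1), -1)
    include = hit & (pmax >= threshold - 1e-12)
    classes = np.asarray(prob_maps.classes)
    labels = np.where(include, classes[np.clip(argmax, 0, None)], 0)
    return include, labels


def threshold_sweep(
    model: SOMModel,
    prob_maps: NodeProbabilityMaps,
    modality_id: str = "",
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
) -> SilhouetteSweep:
    """Silhouette analysis of the SOM node weights at each probability state."""
    mean_sc = np.full(thresholds.size, np.nan)
    sd_sc = np.full(thresholds.size, np.nan)
    n_nodes = np.zeros(thresholds.size, dtype=int)
    per_cluster: list[dict[int, float]] = []
    for i, tau in enumerate(thresholds):
        include, labels = threshold_labels(prob_maps, tau)
        n_nodes[i] = int(include.sum())
        lab = labels[include]
        if np.unique(lab).size < 2:
            per_cluster.append({})
            continue
        sc = silhouette(model.weights[include], lab)
        mean_sc[i] = sc.mean()
        sd_sc[i] = sc.std(ddof=1) if sc.size > 1 else 0.0
        per_cluster.append({int(c): float(sc[lab == c].mean()) for c in np.unique(lab)})
    return SilhouetteSweep(
        modality_id=modality_id,
        thresholds=np.asarray(thresholds, dtype=float),
        mean_sc=mean_sc,
        sd_sc=sd_sc,
        n_nodes=n_nodes,
        per_cluster_mean=per_cluster,
    )


def dsc_percent(sc_modality: float, sc_raw: float) -> float:
    """DSC% = 100 x (SC_modality / SC_raw - 1); undefined for SC_raw = 0."""
    if sc_raw == 0:
        raise ValueError("DSC%% undefined: raw-modality mean SC is zero")
    return 100.0 * (sc_modality / sc_raw - 1.0)


def levene_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Mean-centered Levene test with a guard for degenerate identical spreads."""
    za = np.abs(a - a.mean())
    zb = np.abs(b - b.mean())
    if np.ptp(np.concatenate([za, zb])) == 0:  # all deviations equal -> W = 0
        return 0.0, 1.0
    w, p = stats.levene(a, b, center="mean")
    return float(w), float(p)


def omnibus_test(a: np.ndarray, b: np.ndarray, homogeneous: bool) -> tuple[float, str]:
    """Two-sample ANOVA when variances are homogeneous, else Welch's test."""
    if np.ptp(np.concatenate([a, b])) == 0:  # identical constant samples
        return 1.0, "anova" if homogeneous else "welch"
    if homogeneous:
        _f, p = stats.f_oneway(a, b)
        return float(p), "anova"
    _t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(p), "welch"


def compare_modalities(
    raw_sweep: SilhouetteSweep,
    feature_sweeps: list[SilhouetteSweep],
    alpha: float = 0.05,
    levene_alpha: float = 0.05,
) -> list[ModalityComparison]:
    """Feature-vs-raw comparisons with Holm-Bonferroni multiplicity control.

    Samples are the per-threshold mean silhouette coefficients over the
    thresholds valid for both sweeps.
    """
    results: list[ModalityComparison] = []
    for sweep in feature_sweeps:
        both = raw_sweep.valid & sweep.valid
        if both.sum() < 2:
            continue
        a = sweep.mean_sc[both]
        b = raw_sweep.mean_sc[both]
        _w, lev_p = levene_test(a, b)
        omni_p, which = omnibus_test(a, b, homogeneous=lev_p >= levene_alpha)
        results.append(
            ModalityComparison(
                modality_id=sweep.modality_id,
                dsc_percent=dsc_percent(float(a.mean()), float(b.mean())),
                levene_p=lev_p,
                omnibus_p=omni_p,
                omnibus_test=which,
            )
        )
    if results:
        _rej, adj, *_ = multipletests([r.omnibus_p for r in results], method="holm")
        for r, p_adj in zip(results, adj):
            r.adjusted_p = float(p_adj)
            r.significant = bool(p_adj < alpha and r.dsc_percent > 0)
    return results


def holm_adjust(pvalues) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values."""
    return multipletests(pvalues, method="holm")[1]
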