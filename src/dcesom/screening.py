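"""Normalized contrast-enhancement-ratio (NCER) screening of dynamic modalities.

A dynamic modality (a raw echo series or one radiomics feature's time-stack)
is DCE-informative only if it enhances more over the tumor than over normal
tissue.  For each modality the contrast-enhancement ratio of a region is the
plateau-window regional mean divided by the baseline-window regional mean;
NCER is the tumor CER over the normal CER; modalities are screened on the
study-averaged NCER against a threshold (default 1.2).  Tumor is the union of
the model-2 and model-3 regions of the model-choice map; normal is model 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ModalityNCER:
    modality_id: str
    ncer_per_study: list[float] = field(default_factory=list)
    evaluable: bool = True

    @property
    def mean_ncer(self) -> float:
        vals = [v for v in self.ncer_per_study if np.isfinite(v)]
        return float(np.mean(vals)) if vals else np.nan


def compute_ncer(
    modality: np.ndarray,
    labels: np.ndarray,
    valid: np.ndarray,
    baseline_tp: np.ndarray,
    plateau_tp: np.ndarray,
) -> float:
    """NCER of one modality stack for one study.

    ``modality`` is (x, y, slice, time); ``labels`` the model-choice map;
    ``valid`` the voxels carrying trustworthy modality values;
    ``baseline_tp``/``plateau_tp`` index the time axis of the stack.
    Returns NaN when a regional baseline mean vanishes (non-evaluable).
    """
    labels = np.asarray(labels)
    normal = valid & (labels == 1)
    tumor = valid & ((labels == 2) | (labels == 3))
    if not normal.any() or not tumor.any():
        raise ValueError("model-choice map must provide non-empty normal and tumor regions")

    def cer(region: np.ndarray) -> float:
        base = modality[region][:, baseline_tp].mean()
        plateau = modality[region][:, plateau_tp].mean()
        if base == 0:
            return np.nan
        return plateau / base

    cer_t, cer_n = cer(tumor), cer(normal)
    if not np.isfinite(cer_t) or not np.isfinite(cer_n) or cer_n == 0:
        return np.nan
    return float(cer_t / cer_n)


def screen_features(
    entries: list[ModalityNCER],
    threshold: float = 1.2,
    always_keep: tuple[str, ...] = (),
    top_k: int | None = None,
) -> list[str]:
    """Deterministic retained-modality list.

    Modalities in ``always_keep`` (the raw echoes — the comparison baseline)
    are retained unconditionally.  The rest are retained when their
    study-averaged NCER meets the threshold; with ``top_k`` the retained
    feature list is truncated to the k highest-NCER modalities.
    """
    if not any(e.evaluable for e in entries):
        raise ValueError("no evaluable modality")
    scored = []
    for e in entries:
        if e.modality_id in always_keep:
            continue
        m = e.mean_ncer
        if e.evaluable and np.isfinite(m) and m >= threshold:
            scored.append((m, e.modality_id))
    scored.sort(key=lambda t: (-t[0], t[1]))
    if top_k is not None:
        scored = scored[:top_k]
    retained = list(always_keep) + [mid for _m, mid in scored]
    logger.info("screening retained %d of %d modalities", len(retained), len(entries))
    return retained
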