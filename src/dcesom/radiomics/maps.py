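"""Convolutional (sliding-window) dynamic radiomics feature maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .features import window_features
from .quantize import quantize_fbn
from .registry import categories_for


@dataclass
class DynamicFeatureStack:
    """Per-feature 4-D value maps (x, y, slice, time) plus validity.

    ``valid`` marks voxels whose full analysis window lies inside the mask;
    values elsewhere are 0 and must be ignored via the mask.  ``timepoints``
    records which acquisition indices (0-based) each time slot corresponds
    to, supporting temporally sub-sampled computation.
    """

    maps: dict[str, np.ndarray]
    valid: np.ndarray  # (x, y, slice)
    timepoints: np.ndarray  # 0-based acquisition indices
    window: int = 5
    ng: int = 128
    echo: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.maps)


def valid_centers(mask2d: np.ndarray, window: int) -> np.ndarray:
    """Centers whose full window x window neighborhood lies inside the mask."""
    structure = np.ones((window, window), dtype=bool)
    return ndimage.binary_erosion(mask2d, structure=structure, border_value=0)


def compute_feature_maps(
    series: np.ndarray,
    mask: np.ndarray,
    feature_ids: list[str],
    ng: int = 128,
    window: int = 5,
    timepoints: np.ndarray | None = None,
) -> DynamicFeatureStack:
    """Slide a window x window kernel over every slice/timepoint of a series.

    ``series`` is the plateau-normalized echo series (x, y, slice, time).
    Quantization is fixed-bin-number per slice per timepoint over the mask;
    each feature value is assigned to the central voxel of its window.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be an odd size >= 3")
    series = np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    nx, ny, nz, nt = series.shape
    if mask.shape != (nx, ny, nz):
        raise ValueError("mask must match the spatial grid")
    timepoints = np.arange(nt) if timepoints is None else np.asarray(timepoints)
    cats = categories_for(feature_ids)
    half = window // 2

    valid = np.zeros((nx, ny, nz), dtype=bool)
    for z in range(nz):
        valid[:, :, z] = valid_centers(mask[:, :, z], window)

    out = {fid: np.zeros((nx, ny, nz, timepoints.size)) for fid in feature_ids}
    for z in range(nz):
        centers = np.argwhere(valid[:, :, z])
        if centers.size == 0:
            continue
        for ti, t in enumerate(timepoints):
            img = series[:, :, z, t]
            quant = quantize_fbn(img, ng, mask[:, :, z])
            for cx, cy in centers:
                qwin = quant[cx - half : cx + half + 1, cy - half : cy + half + 1]
                rwin = img[cx - half : cx + half + 1, cy - half : cy + half + 1]
                feats = window_features(qwin, rwin, ng, categories=cats)
                for fid in feature_ids:
                    out[fid][cx, cy, z, ti] = feats[fid]
    return DynamicFeatureStack(
        maps=out, valid=valid, timepoints=timepoints, window=window, ng=ng
    )
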