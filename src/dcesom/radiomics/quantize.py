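"""Series normalization and fixed-bin-number gray-level quantization."""

from __future__ import annotations

import numpy as np


def normalize_series(
    echo1: np.ndarray,
    echo2: np.ndarray,
    mask: np.ndarray,
    tail_len: int = 10,
):
    """Normalize both echo profiles by each voxel's first-echo plateau.

    The last ``tail_len`` timepoints of the first-echo profile (the stable
    plateau) are averaged per voxel; both echo profiles of that voxel are
    divided by this factor.  Voxels whose factor is not positive are flagged
    and excluded.

    Returns ``(norm_echo1, norm_echo2, valid_mask)``.
    """
    if echo1.shape != echo2.shape:
        raise ValueError("echoes must share a shape")
    nt = echo1.shape[-1]
    if nt <= tail_len:
        raise ValueError("series shorter than the normalization tail")
    factor = echo1[..., nt - tail_len :].mean(axis=-1)
    valid = np.asarray(mask, dtype=bool) & (factor > 0)
    safe = np.where(valid, factor, 1.0)[..., None]
    return echo1 / safe, echo2 / safe, valid


def quantize_fbn(image: np.ndarray, ng: int, mask: np.ndarray) -> np.ndarray:
    """Fixed-bin-number quantization of a 2-D image over a mask.

    level = floor(Ng (x - min) / (max - min)) + 1, with the maximum clipped
    to Ng; min/max are taken inside the mask.  A constant image maps to
    level 1 everywhere by convention.  Outside the mask levels are 0.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    out = np.zeros(image.shape, dtype=np.int32)
    if hi == lo:
        out[mask] = 1
        return out
    levels = np.floor(ng * (image[mask] - lo) / (hi - lo)).astype(np.int32) + 1
    out[mask] = np.minimum(levels, ng)
    return out
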