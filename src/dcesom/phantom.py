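"""Digital rat-brain phantoms with nested-model ground truth.

The phantom emulates the tissue taxonomy used for nested-model pharmacokinetic
classification: a normal-vasculature background (model 1, intact blood-brain
barrier), a tumor core with contrast leakage but no measurable back-flux
(model 2), a leaky tumor rim with back-flux (model 3), and a small
"caudate putamen" reference patch whose plasma volume fraction is pinned to
1% so the arterial input function can be normalized against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABEL_BACKGROUND = 0
LABEL_MODEL1 = 1
LABEL_MODEL2 = 2
LABEL_MODEL3 = 3

#: per-voxel draw ranges; rates in 1/min, times in s, M0 in arbitrary units
DEFAULT_PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "vp_normal": (0.006, 0.02),
    "vp_tumor": (0.01, 0.04),
    "ktrans": (0.05, 0.15),
    "kep": (0.3, 0.8),
    "t1pre": (1.7, 2.1),
    "t2star_pre": (0.02, 0.03),
    "m0": (800.0, 1200.0),
}


class PhantomConfigurationError(ValueError):
    """Raised when the requested region geometry is degenerate."""


@dataclass(frozen=True)
class RegionGeometry:
    """Region layout as fractions of the in-plane field of view."""

    brain_semiaxes: tuple[float, float] = (0.42, 0.42)
    tumor_center: tuple[float, float] = (0.62, 0.40)
    tumor_radius: float = 0.16
    core_radius: float = 0.08
    reference_center: tuple[float, float] = (0.32, 0.62)
    reference_halfwidth: float = 0.06


@dataclass
class TissueTruth:
    """Ground-truth label volume and parameter maps for a phantom.

    ``labels`` holds {0: background, 1: model 1, 2: model 2, 3: model 3}.
    ``ktrans`` and ``kep`` are in 1/min; ``t1pre``/``t2star_pre`` in seconds.
    ``kappa`` is the DeltaR2*/DeltaR1 coupling ratio used during signal
    synthesis (0 = pure-T1 synthesis).
    """

    labels: np.ndarray
    vp: np.ndarray
    ktrans: np.ndarray
    kep: np.ndarray
    t1pre: np.ndarray
    t2star_pre: np.ndarray
    m0: np.ndarray
    kappa: float = 0.0
    reference_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def ve(self) -> np.ndarray:
        out = np.zeros_like(self.ktrans)
        pos = self.kep > 0
        out[pos] = self.ktrans[pos] / self.kep[pos]
        return out

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != LABEL_BACKGROUND

    def validate(self) -> None:
        lab = self.labels
        if (self.ktrans[lab == LABEL_MODEL1] != 0).any() or (self.kep[lab == LABEL_MODEL1] != 0).any():
            raise AssertionError("model-1 voxels must have Ktrans = kep = 0")
        if (self.ktrans[lab == LABEL_MODEL2] <= 0).any() or (self.kep[lab == LABEL_MODEL2] != 0).any():
            raise AssertionError("model-2 voxels must have Ktrans > 0 and kep = 0")
        if (self.ktrans[lab == LABEL_MODEL3] <= 0).any() or (self.kep[lab == LABEL_MODEL3] <= 0).any():
            raise AssertionError("model-3 voxels must have Ktrans > 0 and kep > 0")


def _disk(xx: np.ndarray, yy: np.ndarray, center: tuple[float, float], radius: float) -> np.ndarray:
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def make_phantom(
    shape: tuple[int, int, int] = (64, 64, 3),
    region_geometry: RegionGeometry | None = None,
    parameter_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> TissueTruth:
    """Build a deterministic tissue-truth phantom.

    Parameters are drawn per voxel, uniformly within ``parameter_ranges``,
    from a generator seeded with ``seed``; the reference patch is forced to
    model 1 with vp exactly 0.01.
    """
    nx, ny, nz = shape
    if nx < 16 or ny < 16:
        raise PhantomConfigurationError("phantom slices must be at least 16x16")
    geom = region_geometry or RegionGeometry()
    ranges = dict(DEFAULT_PARAMETER_RANGES)
    if parameter_ranges:
        ranges.update(parameter_ranges)
    rng = np.random.default_rng(seed)

    x = (np.arange(nx) + 0.5) / nx
    y = (np.arange(ny) + 0.5) / ny
    xx, yy = np.meshgrid(x, y, indexing="ij")

    ax, ay = geom.brain_semiaxes
    brain = ((xx - 0.5) / ax) ** 2 + ((yy - 0.5) / ay) ** 2 <= 1.0
    tumor = _disk(xx, yy, geom.tumor_center, geom.tumor_radius) & brain
    core = _disk(xx, yy, geom.tumor_center, geom.core_radius) & brain
    rim = tumor & ~core
    cx, cy = geom.reference_center
    # at least ~4x4 voxels in plane so AIF normalization has a usable region
    hw = max(geom.reference_halfwidth, 2.0 / nx, 2.0 / ny)
    ref = (np.abs(xx - cx) <= hw) & (np.abs(yy - cy) <= hw) & brain

    if not tumor.any() or not core.any() or not rim.any():
        raise PhantomConfigurationError("tumor rim/core regions are empty")
    if not ref.any():
        raise PhantomConfigurationError("reference patch lies outside the brain")
    if (ref & tumor).any():
        raise PhantomConfigurationError("reference patch overlaps the tumor")

    labels2d = np.full((nx, ny), LABEL_BACKGROUND, dtype=np.int8)
    labels2d[brain] = LABEL_MODEL1
    labels2d[core] = LABEL_MODEL2
    labels2d[rim] = LABEL_MODEL3

    labels = np.repeat(labels2d[:, :, None], nz, axis=2)
    ref_mask = np.repeat(ref[:, :, None], nz, axis=2)

    def draw(key: str) -> np.ndarray:
        lo, hi = ranges[key]
        return rng.uniform(lo, hi, size=shape)

    vp = np.zeros(shape)
    vp[labels == LABEL_MODEL1] = draw("vp_normal")[labels == LABEL_MODEL1]
    tumor_mask = (labels == LABEL_MODEL2) | (labels == LABEL_MODEL3)
    vp[tumor_mask] = draw("vp_tumor")[tumor_mask]
    vp[ref_mask] = 0.01

    ktrans = np.zeros(shape)
    ktrans[tumor_mask] = draw("ktrans")[tumor_mask]
    kep = np.zeros(shape)
    kep[labels == LABEL_MODEL3] = draw("kep")[labels == LABEL_MODEL3]

    t1pre = draw("t1pre")
    t2star = draw("t2star_pre")
    m0 = draw("m0")
    t1pre[labels == LABEL_BACKGROUND] = ranges["t1pre"][0]
    m0[labels == LABEL_BACKGROUND] = 0.05 * ranges["m0"][0]  # faint background

    truth = TissueTruth(
        labels=labels,
        vp=vp,
        ktrans=ktrans,
        kep=kep,
        t1pre=t1pre,
        t2star_pre=t2star,
        m0=m0,
        reference_mask=ref_mask,
    )
    truth.validate()
    return truth
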