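"""Kohonen self-organizing map: hexagonal lattice, batch training, BMU maps.

The lattice is a 10 x 10 hexagonal grid (axial coordinates, unit spacing).
Batch training assigns every profile to its best matching unit (BMU, minimum
Euclidean distance, ties to the lowest node index) and then replaces each
node's weight by the neighborhood-kernel-weighted mean of all profiles, with
a Gaussian kernel h = exp(-d^2 / (2 sigma^2)) over hexagonal grid distance d
and sigma equal to the current neighborhood radius.  The radius decays
linearly from its initial value to 1 over the ordering phase ("cover steps")
and holds at 1 afterwards.  Training is deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SOMConfig:
    grid: tuple[int, int] = (10, 10)
    initial_radius: float = 3.0
    max_epochs: int = 200
    cover_steps: int = 100  # ordering-phase length (epochs)
    init: str = "sample"  # "sample" | "pca"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_radius < 1:
            raise ValueError("initial radius must be >= 1")
        if self.cover_steps < 1 or self.max_epochs < 1:
            raise ValueError("epochs and cover steps must be positive")


@dataclass
class SOMModel:
    weights: np.ndarray  # (n_nodes, n_features)
    grid: tuple[int, int]
    axial: np.ndarray  # (n_nodes, 2) axial hex coordinates
    grid_distance: np.ndarray  # (n_nodes, n_nodes) hexagonal distances
    config: SOMConfig
    quantization_errors: list[float] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class NodeProbabilityMaps:
    """Per-node hit counts and model-class probabilities from labeled BMUs."""

    hits: np.ndarray  # (n_nodes,) int
    probabilities: np.ndarray  # (n_nodes, n_classes); NaN rows at zero-hit nodes
    classes: tuple[int, ...] = (1, 2, 3)

    @property
    def hit_nodes(self) -> np.ndarray:
        return self.hits > 0


def hex_axial_coordinates(grid: tuple[int, int]) -> np.ndarray:
    """Axial (q, r) coordinates of an odd-r offset hexagonal grid, row-major."""
    rows, cols = grid
    coords = np.empty((rows * cols, 2), dtype=np.int64)
    k = 0
    for r in range(rows):
        for c in range(cols):
            coords[k] = (c - (r - (r & 1)) // 2, r)
            k += 1
    return coords


def hex_distance_matrix(axial: np.ndarray) -> np.ndarray:
    """Pairwise hexagonal grid distance in axial coordinates, unit spacing."""
    dq = axial[:, 0][:, None] - axial[:, 0][None, :]
    dr = axial[:, 1][:, None] - axial[:, 1][None, :]
    return (np.abs(dq) + np.abs(dr) + np.abs(dq + dr)) / 2.0


def bmu(model: SOMModel, profiles: np.ndarray) -> np.ndarray:
    """Best-matching-unit index for each profile (ties -> lowest node index)."""
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if profiles.shape[1] != model.weights.shape[1]:
        raise ValueError("profile length does not match node weights")
    d2 = (
        (profiles**2).sum(axis=1, keepdims=True)
        - 2.0 * profiles @ model.weights.T
        + (model.weights**2).sum(axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def _radius_schedule(config: SOMConfig, epoch: int) -> float:
    if epoch >= config.cover_steps - 1 or config.cover_steps == 1:
        return 1.0
    frac = epoch / (config.cover_steps - 1)
    return config.initial_radius + (1.0 - config.initial_radius) * frac


def train_ksom(profiles: np.ndarray, config: SOMConfig | None = None) -> SOMModel:
    """Batch-train a hexagonal SOM on a (n_profiles, n_features) matrix."""
    config = config or SOMConfig()
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[0] < config.grid[0] * config.grid[1]:
        raise ValueError("need at least as many profiles as lattice nodes")
    if not np.isfinite(x).all():
        raise ValueError("profiles must be finite (no missing values)")
    if np.allclose(x, x[0]):
        logger.warning("all profiles identical: SOM converges trivially")

    axial = hex_axial_coordinates(config.grid)
    gdist = hex_distance_matrix(axial)
    n_nodes = axial.shape[0]
    rng = np.random.default_rng(config.seed)

    if config.init == "sample":
        weights = x[rng.choice(x.shape[0], size=n_nodes, replace=False)].copy()
    elif config.init == "pca":
        center = x.mean(axis=0)
        xc = x - center
        _u, _s, vt = np.linalg.svd(xc, full_matrices=False)
        span1 = np.linspace(-1, 1, config.grid[0])
        span2 = np.linspace(-1, 1, config.grid[1])
        g1, g2 = np.meshgrid(span1, span2, indexing="ij")
        sd = xc.std(axis=0).mean()
        weights = (
            center
            + np.outer(g1.ravel(), vt[0]) * 2 * sd
            + np.outer(g2.ravel(), vt[1] if vt.shape[0] > 1 else 0 * vt[0]) * sd
        )
    else:
        raise ValueError("init must be 'sample' or 'pca'")

    model = SOMModel(
        weights=weights, grid=config.grid, axial=axial, grid_distance=gdist, config=config
    )
    for epoch in range(config.max_epochs):
        winners = bmu(model, x)
        sigma = _radius_schedule(config, epoch)
        kernel = np.exp(-(gdist**2) / (2.0 * sigma**2))  # (n_nodes, n_nodes)
        # numerator_k = sum_j h(k, bmu_j) x_j ; denominator_k = sum_j h(k, bmu_j)
        hit_counts = np.bincount(winners, minlength=n_nodes).astype(float)
        sums = np.zeros_like(model.weights)
        np.add.at(sums, winners, x)
        numer = kernel @ sums
        denom = kernel @ hit_counts
        update = denom > 0
        model.weights[update] = numer[update] / denom[update, None]
        qe = float(np.sqrt(((x - model.weights[winners]) ** 2).sum(axis=1)).mean())
        model.quantization_errors.append(qe)
    return model


def probability_maps(
    model: SOMModel, profiles: np.ndarray, labels: np.ndarray, classes=(1, 2, 3)
) -> NodeProbabilityMaps:
    """Hit counts and per-node class probabilities from labeled profiles.

    Zero-hit nodes carry NaN probabilities (explicit missing, never imputed).
    """
    labels = np.asarray(labels)
    if not np.isin(labels, classes).all():
        raise ValueError(f"labels must lie in {classes}")
    winners = bmu(model, profiles)
    n_nodes = model.n_nodes
    hits = np.bincount(winners, minlength=n_nodes)
    probs = np.full((n_nodes, len(classes)), np.nan)
    for ci, c in enumerate(classes):
        counts_c = np.bincount(winners[labels == c], minlength=n_nodes)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs[:, ci] = np.where(hits > 0, counts_c / np.maximum(hits, 1), np.nan)
    return NodeProbabilityMaps(hits=hits, probabilities=probs, classes=tuple(classes))
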