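"""The 133-feature registry: identities, categories, and aggregation codes.

The registry is shipped as a JSON manifest (``registry.json``) so the feature
set is auditable; the loader validates the per-category counts against the
design (IH 21, IBS 17, GLCM 25, GLRLM 16, GLSZM 16, GLDZM 16, NGTDM 5,
NGLDM 17 — 133 total).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

CATEGORY_INFO = {
    "ih": ("IH", "intensity histogram", "DHQ4"),
    "ibs": ("IBS", "intensity based statistical", "DHQ4"),
    "glcm": ("GLCM", "gray level co-occurrence matrix", "BTW3"),
    "glrlm": ("GLRLM", "gray level run length matrix", "BTW3"),
    "glszm": ("GLSZM", "gray level size zone matrix", "8QNN"),
    "gldzm": ("GLDZM", "gray level distance zone matrix", "8QNN"),
    "ngtdm": ("NGTDM", "neighborhood gray tone difference matrix", "8QNN"),
    "ngldm": ("NGLDM", "neighboring gray level dependence matrix", "8QNN"),
}

EXPECTED_COUNTS = {
    "IH": 21,
    "IBS": 17,
    "GLCM": 25,
    "GLRLM": 16,
    "GLSZM": 16,
    "GLDZM": 16,
    "NGTDM": 5,
    "NGLDM": 17,
}


@dataclass(frozen=True)
class FeatureSpec:
    feature_id: str  # e.g. "glcm_dissimilarity"
    category: str  # e.g. "GLCM"
    name: str  # e.g. "dissimilarity"
    aggregation: str  # DHQ4 | BTW3 | 8QNN

    @property
    def prefix(self) -> str:
        return self.feature_id.split("_", 1)[0]


class RegistryError(ValueError):
    """Raised when the manifest disagrees with the designed category counts."""


def load_registry() -> list[FeatureSpec]:
    """Load and validate the shipped 133-feature manifest."""
    text = resources.files(__package__).joinpath("registry.json").read_text()
    entries = json.loads(text)
    registry = [
        FeatureSpec(e["feature_id"], e["category"], e["name"], e["aggregation"])
        for e in entries
    ]
    counts: dict[str, int] = {}
    for spec in registry:
        counts[spec.category] = counts.get(spec.category, 0) + 1
    if counts != EXPECTED_COUNTS:
        raise RegistryError(f"registry counts {counts} != expected {EXPECTED_COUNTS}")
    expected_agg = {abbr: agg for abbr, _full, agg in CATEGORY_INFO.values()}
    for spec in registry:
        if spec.aggregation != expected_agg[spec.category]:
            raise RegistryError(f"{spec.feature_id}: wrong aggregation {spec.aggregation}")
    return registry


def build_manifest() -> list[dict]:
    """Regenerate the manifest from the feature implementation (dev helper)."""
    import numpy as np

    from .features import window_features

    rng = np.random.default_rng(0)
    probe = window_features(rng.integers(1, 9, (5, 5)), rng.uniform(0, 1, (5, 5)), 8)
    entries = []
    for key in probe:
        prefix, name = key.split("_", 1)
        abbr, _full, agg = CATEGORY_INFO[prefix]
        entries.append(
            {
                "feature_id": key,
                "category": abbr,
                "name": name.replace("_", " "),
                "aggregation": agg,
            }
        )
    return entries


def categories_for(feature_ids) -> tuple[str, ...]:
    """The lowercase category prefixes needed to compute ``feature_ids``."""
    return tuple(sorted({fid.split("_", 1)[0] for fid in feature_ids}))
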