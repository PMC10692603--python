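"""Size-based partition of detected spots into species.

Each species is defined by an equivalent-radius interval ``(radius_min,
radius_max]`` plus the maximal linking distance used later by the tracker.
Boundary values belong to the smaller-radius class (inclusive upper bound,
strict lower bound).  Default thresholds resolve the per-replicate tuning
ranges of the original filters to single values: bacteria ≤ 4.5 µm,
zoospores in (4.5, 10] µm, vorticellae > 10 µm, with maximal linking
distances of 2, 15 and 60 µm respectively.  Spots falling in a configured
gap between rules land in an ``unassigned`` bucket — reported, never
silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class SpeciesRule:
    """Radius band (µm) and tracker linking distance (µm) for one species.

    ``radius_min`` is exclusive, ``radius_max`` inclusive; ``None`` means
    unbounded on that side.
    """

    species: str
    radius_min: float | None
    radius_max: float | None
    max_linking_distance: float

    def __post_init__(self) -> None:
        if self.max_linking_distance <= 0:
            raise ValueError("max_linking_distance must be > 0")
        lo = self.radius_min if self.radius_min is not None else -np.inf
        hi = self.radius_max if self.radius_max is not None else np.inf
        if lo >= hi:
            raise ValueError(f"empty radius band for {self.species}")

    def contains(self, radius: float) -> bool:
        lo = self.radius_min if self.radius_min is not None else -np.inf
        hi = self.radius_max if self.radius_max is not None else np.inf
        return lo < radius <= hi


def default_rules() -> list[SpeciesRule]:
    """Default double-filter scheme for the three-species community."""
    return [
        SpeciesRule("bacterium", None, 4.5, 2.0),
        SpeciesRule("zoospore", 4.5, 10.0, 15.0),
        SpeciesRule("vorticella", 10.0, None, 60.0),
    ]


def validate_rules(rules: list[SpeciesRule]) -> list[SpeciesRule]:
    """Check that radius bands are mutually non-overlapping."""
    if not rules:
        raise ValueError("at least one species rule is required")
    seen = set()
    for r in rules:
        if r.species in seen:
            raise ValueError(f"duplicate rule for species {r.species!r}")
        seen.add(r.species)
    by_lo = sorted(rules, key=lambda r: (r.radius_min
                                         if r.radius_min is not None
                                         else -np.inf))
    for a, b in zip(by_lo, by_lo[1:]):
        a_hi = a.radius_max if a.radius_max is not None else np.inf
        b_lo = b.radius_min if b.radius_min is not None else -np.inf
        if a_hi > b_lo:
            raise ValueError(
                f"rules for {a.species!r} and {b.species!r} overlap")
    return by_lo


def classify_spot(radius: float, rules: list[SpeciesRule]) -> str:
    """Label one spot by its equivalent radius; gaps yield ``unassigned``."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    for r in rules:
        if r.contains(radius):
            return r.species
    return UNASSIGNED


def partition_table(spots: pd.DataFrame,
                    rules: list[SpeciesRule] | None = None
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Add a ``species`` column and return per-species counts.

    Every spot receives exactly one label (a species or ``unassigned``), so
    the counts always sum to the input size.
    """
    if rules is None:
        rules = default_rules()
    rules = validate_rules(rules)
    labeled = spots.copy()
    if len(labeled):
        if (labeled["radius_um"] < 0).any():
            raise ValueError("negative spot radius")
        labels = np.full(len(labeled), UNASSIGNED, dtype=object)
        radii = labeled["radius_um"].to_numpy()
        for i, rad in enumerate(radii):
            labels[i] = classify_spot(float(rad), rules)
        labeled["species"] = labels
    else:
        labeled["species"] = pd.Series(dtype=object)
    counts = {r.species: int((labeled["species"] == r.species).sum())
              for r in rules}
    counts[UNASSIGNED] = int((labeled["species"] == UNASSIGNED).sum())
    assert sum(counts.values()) == len(labeled)
    logger.info("partitioned %d spots: %s", len(labeled), counts)
    return labeled, counts


def species_tables(labeled: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a labeled spot table into one table per species label."""
    return {sp: df.reset_index(drop=True)
            for sp, df in labeled.groupby("species", sort=True)}
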