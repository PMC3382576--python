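"""Geographic summaries: latitude bins, landmasses and depositional environments.

Species are summarised by the modern latitude of their localities (5-degree
half-open bins, south negative), by landmass, and by depositional
environment.  A species with occurrences in several bins or groups
contributes its pooled species-level CCM2 score to each of them, so group
score lists may overlap across groups of the same summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ccm import ENVIRONMENTS, CompletenessScore, SpecimenRecord
from .errors import TableValidationError

LATITUDE_BIN_WIDTH = 5.0


def _score_value(score: CompletenessScore | float) -> float:
    return score.value_percent if isinstance(score, CompletenessScore) else float(score)


def latitude_bin_lower(latitude_deg: float, width: float = LATITUDE_BIN_WIDTH) -> float:
    """Lower edge of the half-open [lower, lower+width) bin holding a latitude.

    Boundary latitudes go to the higher bin; +90 (which would open an empty
    bin beyond the pole) is folded into the northernmost bin.
    """
    if not -90.0 <= latitude_deg <= 90.0:
        raise TableValidationError(f"latitude {latitude_deg} out of [-90, 90]")
    if latitude_deg == 90.0:
        return 90.0 - width
    return float(np.floor(latitude_deg / width) * width)


def latitudinal_summary(
    records: Sequence[SpecimenRecord],
    species_scores: Mapping[str, CompletenessScore | float],
    width: float = LATITUDE_BIN_WIDTH,
) -> pd.DataFrame:
    """Species counts, specimen counts and mean CCM2 per latitudinal bin.

    Returns one row per bin from -90 to +90 (empty bins keep NaN means).  A
    species occupies every bin in which it has at least one specimen and
    counts once per occupied bin.
    """
    edges = np.arange(-90.0, 90.0, width)
    species_in_bin: dict[float, set[str]] = {e: set() for e in edges}
    specimens_in_bin: dict[float, int] = {e: 0 for e in edges}
    for rec in records:
        lower = latitude_bin_lower(rec.latitude_deg, width)
        species_in_bin[lower].add(rec.species)
        specimens_in_bin[lower] += 1

    rows = []
    for lower in edges:
        names = sorted(species_in_bin[lower])
        scores = [_score_value(species_scores[s]) for s in names if s in species_scores]
        rows.append(
            {
                "lat_lower": lower,
                "lat_upper": lower + width,
                "species_count": len(names),
                "specimen_count": specimens_in_bin[lower],
                "mean_ccm2": float(np.mean(scores)) if scores else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupSummary:
    """Per-group species counts, mean CCM2, and the raw score lists.

    ``scores`` keeps the species-level values so group comparisons
    (e.g. Mann-Whitney) can run on the same data the means were taken from.
    """

    grouping: str
    species_count: dict[str, int]
    mean_ccm2: dict[str, float]
    scores: dict[str, list[float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": list(self.species_count),
                "species_count": list(self.species_count.values()),
                "mean_ccm2": [self.mean_ccm2[g] for g in self.species_count],
            }
        )


def group_summary(
    records: Sequence[SpecimenRecord],
    species_scores: Mapping[str, CompletenessScore | float],
    grouping: str = "environment",
) -> GroupSummary:
    """Summarise species CCM2 by depositional environment or landmass.

    A species recorded from several groups contributes its pooled score to
    each of them.  Environment labels are validated against the three
    canonical categories; landmass labels are free-form.
    """
    if grouping not in ("environment", "landmass"):
        raise ValueError("grouping must be 'environment' or 'landmass'")
    membership: dict[str, set[str]] = {}
    for rec in records:
        label = rec.environment if grouping == "environment" else rec.region
        if grouping == "environment" and label not in ENVIRONMENTS:
            raise TableValidationError(
                f"unknown environment {label!r}; allowed: {list(ENVIRONMENTS)}"
            )
        membership.setdefault(label, set()).add(rec.species)

    counts: dict[str, int] = {}
    means: dict[str, float] = {}
    scores: dict[str, list[float]] = {}
    for label in sorted(membership):
        names = sorted(membership[label])
        values = [_score_value(species_scores[s]) for s in names if s in species_scores]
        counts[label] = len(names)
        scores[label] = values
        means[label] = float(np.mean(values)) if values else float("nan")
    return GroupSummary(grouping, counts, means, scores)
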