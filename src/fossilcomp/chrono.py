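"""Substage time bins and per-bin summary series.

Geological stages are split into 'early' and 'late' substages at the stage's
temporal midpoint.  Occurrences of uncertain age are ranged through every
substage their possible age range intersects.  Per-bin summaries report the
mean CCM2 over the species present (each species once per bin), the sample
standard deviation of those species scores, and the number of specimens in
the bin as the sample-size indicator.

Ages are in Ma before present, so a bin's ``start_ma`` exceeds its
``end_ma`` and bins are ordered old to young.  Bin membership of a point age
uses half-open intervals [start_ma, end_ma) with the oldest bin closed at
both ends; a boundary age therefore belongs to the younger bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ccm import CompletenessScore, SpecimenRecord
from .errors import BinLookupError, TableValidationError

_CONTIGUITY_TOL = 1e-6


@dataclass(frozen=True)
class TimeBin:
    stage: str
    half: str  # "early" | "late"
    start_ma: float
    end_ma: float

    @property
    def label(self) -> str:
        return f"{self.half} {self.stage}"

    @property
    def midpoint_ma(self) -> float:
        return (self.start_ma + self.end_ma) / 2.0


@dataclass
class TimeBinTable:
    """Ordered (old -> young), contiguous substage bins."""

    bins: list[TimeBin]

    def __post_init__(self) -> None:
        self._index = {b.label.lower(): i for i, b in enumerate(self.bins)}
        self._stage_index: dict[str, tuple[int, int]] = {}
        for i, b in enumerate(self.bins):
            lo, hi = self._stage_index.get(b.stage.lower(), (i, i))
            self._stage_index[b.stage.lower()] = (min(lo, i), max(hi, i))

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bins]

    def midpoints(self) -> np.ndarray:
        return np.array([b.midpoint_ma for b in self.bins])

    def index(self, label: str) -> int:
        try:
            return self._index[label.strip().lower()]
        except KeyError:
            raise BinLookupError(f"unknown substage label {label!r}") from None

    def resolve(self, identifier: str) -> tuple[int, int]:
        """Resolve a substage or bare-stage identifier to an index range.

        A substage label ('early Aptian') resolves to a single bin; a bare
        stage name ('Aptian') resolves to both of its substages.
        """
        key = identifier.strip().lower()
        if key in self._index:
            i = self._index[key]
            return i, i
        if key in self._stage_index:
            return self._stage_index[key]
        raise BinLookupError(f"unknown stage or substage identifier {identifier!r}")

    def bin_of_age(self, age_ma: float) -> int:
        """Bin containing a point age; boundary ages go to the younger bin."""
        if not self.bins[-1].end_ma <= age_ma <= self.bins[0].start_ma:
            raise BinLookupError(f"age {age_ma} Ma outside the binned interval")
        for i, b in enumerate(self.bins):
            if b.start_ma >= age_ma > b.end_ma:
                return i
        return len(self.bins) - 1  # age equals the youngest boundary


def make_substage_bins(
    stage_boundaries: Sequence[tuple[str, float, float]]
) -> TimeBinTable:
    """Split each stage at its midpoint into early/late substage bins.

    *stage_boundaries* is an ordered (old -> young) sequence of
    ``(stage_name, start_ma, end_ma)`` with ``start_ma > end_ma``; adjacent
    stages must be contiguous.
    """
    if not stage_boundaries:
        raise TableValidationError("no stages supplied")
    bins: list[TimeBin] = []
    prev_end: float | None = None
    for name, start, end in stage_boundaries:
        if start <= end:
            raise TableValidationError(
                f"stage {name!r}: start_ma ({start}) must exceed end_ma ({end}) "
                "(zero or negative duration)"
            )
        if prev_end is not None and abs(prev_end - start) > _CONTIGUITY_TOL:
            raise TableValidationError(
                f"stage {name!r} starts at {start} Ma but the previous stage "
                f"ends at {prev_end} Ma (gap or overlap)"
            )
        mid = (start + end) / 2.0
        bins.append(TimeBin(name, "early", start, mid))
        bins.append(TimeBin(name, "late", mid, end))
        prev_end = end
    return TimeBinTable(bins)


def assign_occurrences(
    records: Sequence[SpecimenRecord], bins: TimeBinTable
) -> pd.DataFrame:
    """Specimen-by-bin incidence (bool DataFrame, specimens x bin labels).

    A specimen is present in every bin intersecting its possible age range;
    a precisely dated specimen occupies exactly one bin.
    """
    incidence = pd.DataFrame(
        False,
        index=pd.Index([r.specimen_id for r in records], name="specimen_id"),
        columns=bins.labels,
    )
    for rec in records:
        try:
            oldest, _ = bins.resolve(rec.age_earliest)
            _, youngest = bins.resolve(rec.age_latest)
        except BinLookupError as exc:
            raise BinLookupError(f"specimen {rec.specimen_id}: {exc}") from None
        if oldest > youngest:
            raise TableValidationError(
                f"specimen {rec.specimen_id}: age_earliest {rec.age_earliest!r} is "
                f"younger than age_latest {rec.age_latest!r}"
            )
        incidence.iloc[incidence.index.get_loc(rec.specimen_id), oldest : youngest + 1] = True
    return incidence


def species_incidence(
    records: Sequence[SpecimenRecord], specimen_incidence: pd.DataFrame
) -> pd.DataFrame:
    """Collapse specimen incidence to species-by-bin incidence."""
    species = pd.Series({r.specimen_id: r.species for r in records}, name="species")
    return specimen_incidence.groupby(species).any()


def bin_assignment_mapping(specimen_incidence: pd.DataFrame) -> dict[str, list[str]]:
    """Specimen -> occupied bin labels, for per-bin CCM2 scoring."""
    return {
        sid: list(specimen_incidence.columns[row.to_numpy()])
        for sid, row in specimen_incidence.iterrows()
    }


@dataclass
class BinSeries:
    """A per-bin series: value, optional spread, and sample count.

    ``value`` is NaN for empty bins (n == 0); ``std_dev`` is defined only
    where at least two observations contributed.
    """

    labels: list[str]
    value: np.ndarray
    std_dev: np.ndarray | None
    n: np.ndarray

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if self.std_dev is not None:
            self.std_dev = np.asarray(self.std_dev, dtype=float)
        lens = {len(self.labels), self.value.size, self.n.size} | (
            {self.std_dev.size} if self.std_dev is not None else set()
        )
        if len(lens) != 1:
            raise TableValidationError("BinSeries vectors must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.labels,
                "value": self.value,
                "std_dev": self.std_dev if self.std_dev is not None else np.nan,
                "n": self.n,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BinSeries":
        required = {"bin", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise TableValidationError(f"bin-series table missing column(s) {sorted(missing)}")
        std = frame["std_dev"].to_numpy(float) if "std_dev" in frame else None
        n = (
            frame["n"].fillna(0).to_numpy(int)
            if "n" in frame
            else (~frame["value"].isna()).astype(int).to_numpy()
        )
        return cls(list(frame["bin"]), frame["value"].to_numpy(float), std, n)


def mean_ccm2_series(
    per_bin_scores: Mapping[tuple[str, str], CompletenessScore | float],
    bins: TimeBinTable,
    specimen_incidence: pd.DataFrame,
) -> BinSeries:
    """Per-bin mean and SD of species CCM2, with specimen counts as n.

    The mean averages over species (each species once per bin); ``n`` counts
    specimens, the customary sample-size indicator plotted alongside such
    curves.
    """
    values = np.full(len(bins), np.nan)
    stds = np.full(len(bins), np.nan)
    counts = np.zeros(len(bins), dtype=int)
    by_bin: dict[str, list[float]] = {}
    for (species, label), score in per_bin_scores.items():
        v = score.value_percent if isinstance(score, CompletenessScore) else float(score)
        by_bin.setdefault(label, []).append(v)
    for i, label in enumerate(bins.labels):
        scores = by_bin.get(label)
        if scores:
            values[i] = float(np.mean(scores))
            if len(scores) >= 2:
                stds[i] = float(np.std(scores, ddof=1))
        if label in specimen_incidence.columns:
            counts[i] = int(specimen_incidence[label].sum())
    return BinSeries(bins.labels, values, stds, counts)


def taxic_diversity_series(
    species_by_bin: pd.DataFrame, bins: TimeBinTable
) -> BinSeries:
    """Raw taxic diversity: distinct species counted in every bin they span."""
    counts = np.zeros(len(bins), dtype=int)
    for i, label in enumerate(bins.labels):
        if label in species_by_bin.columns:
            counts[i] = int(species_by_bin[label].sum())
    return BinSeries(bins.labels, counts.astype(float), None, counts)
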