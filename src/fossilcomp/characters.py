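"""Partition of a phylogenetic character list into per-element contributions.

A character completeness analysis starts from a list of phylogenetic
characters compiled for the clade under study.  Every character can be scored
only if a particular skeletal element (or part of an element) is preserved, so
the list induces a partition: element/part -> number of scorable characters.
This module defines that lookup table, the keys into it, and its reader.

Conventions
-----------
* Keys are side-agnostic: a left and a right femur map to the same key,
  because characters are scorable from either side.
* Characters on elongate limb/girdle bones may be split into ``proximal_end``,
  ``distal_end`` and ``shaft`` sets; vertebral-column characters into
  ``single``/``anterior``/``posterior``/``series``/``neural_spine`` sets.
* All internal arithmetic uses raw character counts; percentages are derived
  on demand and rounded only for display.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

from .errors import TableFormatError, TableValidationError, UnknownKeyError

#: Allowed part qualifiers.
PARTS = frozenset(
    {
        "whole",
        "proximal_end",
        "distal_end",
        "shaft",
        "single",
        "anterior",
        "posterior",
        "series",
        "neural_spine",
    }
)

#: Parts valid only for elongate limb/girdle elements.
LIMB_PARTS = frozenset({"proximal_end", "distal_end", "shaft"})

#: Parts valid only for sections of the vertebral column.
VERTEBRAL_PARTS = frozenset({"single", "anterior", "posterior", "series", "neural_spine"})

#: Body-region labels used for coarse summaries.
REGIONS = (
    "skull",
    "vertebral_column_and_ribs",
    "pectoral_girdle",
    "forelimbs",
    "pelvic_girdle",
    "hindlimbs",
    "integument",
)

_SIDE_PREFIX = re.compile(r"^(left|right|l|r)[_\s]+")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at *ndigits* decimals (display convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _normalise_element(name: str) -> str:
    name = name.strip().lower().replace(" ", "_")
    return _SIDE_PREFIX.sub("", name)


@dataclass(frozen=True, order=True)
class ElementPartKey:
    """Side-agnostic identifier of a scorable skeletal element or part.

    ``part`` qualifies which subset of the element's characters is meant;
    ``whole`` stands for the undivided element.
    """

    element: str
    part: str = "whole"

    def __post_init__(self) -> None:
        object.__setattr__(self, "element", _normalise_element(self.element))
        object.__setattr__(self, "part", self.part.strip().lower())
        if not self.element:
            raise TableValidationError("element name must be non-empty")
        if self.part not in PARTS:
            raise TableValidationError(
                f"unknown part {self.part!r}; allowed: {sorted(PARTS)}"
            )
        vertebral = "vertebra" in self.element
        if self.part in VERTEBRAL_PARTS and not vertebral:
            raise TableValidationError(
                f"part {self.part!r} is only valid for vertebral sections, "
                f"got element {self.element!r}"
            )
        if self.part in LIMB_PARTS and vertebral:
            raise TableValidationError(
                f"part {self.part!r} is not valid for vertebral section {self.element!r}"
            )

    @classmethod
    def parse(cls, token: str) -> "ElementPartKey":
        """Parse an ``element`` or ``element:part`` token."""
        element, _, part = token.partition(":")
        return cls(element, part or "whole")

    def __str__(self) -> str:
        return self.element if self.part == "whole" else f"{self.element}:{self.part}"


@dataclass
class CharacterContributionTable:
    """Mapping of element/part keys to scorable-character counts.

    The table declares its total explicitly so that a partial file (counts not
    summing to the declared character-list length) is detectable.
    """

    total_characters: int
    entries: dict[ElementPartKey, int]
    region: dict[ElementPartKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_characters <= 0:
            raise TableValidationError("total_characters must be positive")
        for key, count in self.entries.items():
            if int(count) != count or count < 0:
                raise TableValidationError(
                    f"character count for {key} must be a non-negative integer, got {count!r}"
                )
        total = sum(self.entries.values())
        if total != self.total_characters:
            raise TableValidationError(
                f"entry counts sum to {total}, but the table declares "
                f"{self.total_characters} characters (discrepancy {total - self.total_characters:+d})"
            )
        missing = set(self.entries) - set(self.region)
        if missing:
            raise TableValidationError(f"keys without a region label: {sorted(map(str, missing))}")
        bad = {r for r in self.region.values() if r not in REGIONS}
        if bad:
            raise TableValidationError(
                f"unknown region labels {sorted(bad)}; allowed: {list(REGIONS)}"
            )

    def keys(self) -> Iterable[ElementPartKey]:
        return self.entries.keys()

    def count(self, key: ElementPartKey) -> int:
        try:
            return self.entries[key]
        except KeyError:
            raise UnknownKeyError(
                f"element/part key {key} is not in the contribution table"
            ) from None

    def percent(self, key: ElementPartKey) -> float:
        """Exact percentage contribution of *key* (no rounding)."""
        return self.count(key) / self.total_characters * 100.0

    def percent_rounded(self, key: ElementPartKey, ndigits: int = 2) -> float:
        """Display-rounded percentage contribution (half-up)."""
        return round_half_up(self.percent(key), ndigits)


def region_percentages(table: CharacterContributionTable) -> dict[str, float]:
    """Percentage of characters attributable to each body region.

    Every known region label is present in the result (0.0 when no key maps
    to it); the values sum to 100 exactly before any display rounding.
    """
    counts = {r: 0 for r in REGIONS}
    for key, n in table.entries.items():
        counts[table.region[key]] += n
    return {r: c / table.total_characters * 100.0 for r, c in counts.items()}


_REQUIRED_COLUMNS = ("element", "part", "character_count", "region")


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def load_contribution_table(path: str | Path) -> CharacterContributionTable:
    """Read a contribution table from a delimited text file.

    The file carries a metadata line ``#total=<N>`` before the header, then
    columns ``element,part,character_count,region`` (comma or tab delimited).
    Duplicate element/part keys are rejected, as are counts that do not sum
    to the declared total.
    """
    path = Path(path)
    total: int | None = None
    data_lines: list[str] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                m = re.match(r"#\s*total\s*=\s*(\d+)", stripped)
                if m:
                    total = int(m.group(1))
                continue
            data_lines.append(line)
    if total is None:
        raise TableFormatError(f"{path}: missing '#total=<N>' metadata line")
    if not data_lines:
        raise TableFormatError(f"{path}: no header row found")

    delim = _sniff_delimiter(data_lines[0])
    reader = csv.DictReader(data_lines, delimiter=delim)
    columns = [c.strip() for c in reader.fieldnames or []]
    missing = [c for c in _REQUIRED_COLUMNS if c not in columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")

    entries: dict[ElementPartKey, int] = {}
    region: dict[ElementPartKey, str] = {}
    for i, row in enumerate(reader, start=2):
        key = ElementPartKey(row["element"], (row.get("part") or "whole"))
        raw = (row["character_count"] or "").strip()
        try:
            count = int(raw)
        except ValueError:
            raise TableValidationError(
                f"{path} line {i}: character_count {raw!r} is not an integer"
            ) from None
        if count < 0:
            raise TableValidationError(f"{path} line {i}: negative count for {key}")
        if key in entries:
            raise TableValidationError(f"{path} line {i}: duplicate key {key}")
        entries[key] = count
        region[key] = row["region"].strip().lower()
    return CharacterContributionTable(total_characters=total, entries=entries, region=region)


def write_contribution_table(
    table: CharacterContributionTable, path: str | Path, delimiter: str = ","
) -> None:
    """Write *table* in the format read by :func:`load_contribution_table`."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"#total={table.total_characters}\n")
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_REQUIRED_COLUMNS)
        for key in sorted(table.entries):
            writer.writerow([key.element, key.part, table.entries[key], table.region[key]])
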