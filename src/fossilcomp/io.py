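"""Readers and writers for the package's delimited-text interchange formats.

All tables are UTF-8 delimited text (comma by default, tab auto-detected on
read).  The occurrence table has columns
``specimen_id,species,genus,elements,age_earliest,age_latest,environment,latitude,region``
where ``elements`` is a semicolon-separated list of ``element:part`` tokens
(part defaults to ``whole``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .ccm import SpecimenRecord
from .characters import ElementPartKey, load_contribution_table, write_contribution_table
from .chrono import BinSeries
from .errors import TableFormatError

__all__ = [
    "load_contribution_table",
    "write_contribution_table",
    "read_occurrences",
    "write_occurrences",
    "read_bin_series",
    "write_bin_series",
    "read_stage_boundaries",
    "read_scores",
]

_OCCURRENCE_COLUMNS = (
    "specimen_id",
    "species",
    "elements",
    "age_earliest",
    "age_latest",
    "environment",
    "latitude",
    "region",
)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")


def read_occurrences(path: str | Path) -> list[SpecimenRecord]:
    """Parse an occurrence table into specimen records."""
    frame = _read_table(path)
    missing = [c for c in _OCCURRENCE_COLUMNS if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: occurrence table missing column(s) {missing}")
    records = []
    for _, row in frame.iterrows():
        tokens = [t for t in str(row["elements"]).split(";") if t.strip() and t != "nan"]
        inventory = frozenset(ElementPartKey.parse(t) for t in tokens)
        records.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]),
                species=str(row["species"]),
                genus=str(row.get("genus", "") or ""),
                inventory=inventory,
                age_earliest=str(row["age_earliest"]),
                age_latest=str(row["age_latest"]),
                environment=str(row["environment"]),
                latitude_deg=float(row["latitude"]),
                region=str(row["region"]),
            )
        )
    return records


def write_occurrences(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    rows = [
        {
            "specimen_id": r.specimen_id,
            "species": r.species,
            "genus": r.genus,
            "elements": ";".join(str(k) for k in sorted(r.inventory)),
            "age_earliest": r.age_earliest,
            "age_latest": r.age_latest,
            "environment": r.environment,
            "latitude": r.latitude_deg,
            "region": r.region,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["specimen_id", "species", "genus", "elements",
                                "age_earliest", "age_latest", "environment",
                                "latitude", "region"]).to_csv(path, index=False)


def read_bin_series(path: str | Path) -> BinSeries:
    """Read a per-bin series (columns ``bin,value[,std_dev,n]``)."""
    return BinSeries.from_frame(_read_table(path))


def write_bin_series(series: BinSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_stage_boundaries(path: str | Path) -> list[tuple[str, float, float]]:
    """Read stage boundaries from delimited text or YAML.

    Delimited files need columns ``stage,start_ma,end_ma``; YAML files hold a
    list of ``{stage, start_ma, end_ma}`` mappings.  Order must be old to
    young.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text(encoding="utf-8"))
        try:
            return [(str(d["stage"]), float(d["start_ma"]), float(d["end_ma"])) for d in data]
        except (KeyError, TypeError) as exc:
            raise TableFormatError(f"{path}: malformed stage list ({exc})") from None
    frame = _read_table(path)
    missing = [c for c in ("stage", "start_ma", "end_ma") if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: stage table missing column(s) {missing}")
    return [
        (str(r["stage"]), float(r["start_ma"]), float(r["end_ma"]))
        for _, r in frame.iterrows()
    ]


def read_scores(path: str | Path) -> list[float]:
    """Read a one-column list of scores (header ``score`` optional)."""
    path = Path(path)
    values = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower() == "score":
            continue
        values.append(float(line))
    return values


def default_stage_boundaries() -> list[tuple[str, float, float]]:
    """The packaged Tithonian–Maastrichtian stage boundaries (Gradstein et al. 2004)."""
    return read_stage_boundaries(
        Path(__file__).parent / "data" / "stage_boundaries_gradstein2004.csv"
    )
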