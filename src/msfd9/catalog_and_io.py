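"""Regulatory catalog, measurement file IO and record-level quality control.

The catalog holds one entry per regulated (contaminant, foodstuff) category
of the EU maximum-level legislation (Reg. 1881/2006/CE and updates); each
entry carries the maximum permitted concentration in the edible tissue,
expressed on a wet-weight basis. Measurements are individual georeferenced
concentration records tagged with a category code, the observed values of
the lognormal concentration variable the acceptance statistics model.

Files are plain delimited text (comma or semicolon separated, UTF-8, header
row). A decimal-comma dialect is accepted on input; output is always
canonical decimal-point.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "UNITS",
    "ANALYTES",
    "RegulatoryCategory",
    "Catalog",
    "load_catalog",
    "Measurement",
    "ParseError",
    "load_measurements",
    "write_measurements",
    "QCConfig",
    "QCReport",
    "qc_filter",
    "apply_loq_policy",
    "LOQ_POLICIES",
]

#: Closed set of concentration units used by the regulation (wet weight).
UNITS = frozenset({"mg/kg w.w.", "µg/kg w.w.", "pg/g w.w."})

#: Regulated analytes (or regulated sums of analytes).
ANALYTES = frozenset(
    {
        "Cd",
        "Hg",
        "Pb",
        "dioxins",
        "sum dioxins and dl-PCBs",
        "benzo(a)pyrene",
        "sum of 4 PAHs",
    }
)

_CODE_PREFIX_TO_ANALYTE = {
    "Cd": "Cd",
    "Hg": "Hg",
    "Pb": "Pb",
    "Dioxins": "dioxins",
    "Sum dioxins": "sum dioxins and dl-PCBs",
    "Benzo(a)pyrene": "benzo(a)pyrene",
    "Sum PAH": "sum of 4 PAHs",
}


def _analyte_from_code(code: str) -> str:
    for prefix, analyte in _CODE_PREFIX_TO_ANALYTE.items():
        if code.startswith(prefix):
            return analyte
    raise ValueError(f"cannot infer analyte from category code {code!r}")


@dataclass(frozen=True)
class RegulatoryCategory:
    """One row of the regulatory catalog.

    ``limit_value`` is the maximum level in ``limit_unit`` (wet weight)
    permitted for ``analyte`` in the ``foodstuff`` class; ``legislation``
    cites the regulation that sets it.
    """

    code: str
    analyte: str
    foodstuff: str
    limit_value: float
    limit_unit: str
    legislation: str

    def __post_init__(self) -> None:
        if self.limit_value <= 0:
            raise ValueError(
                f"category {self.code!r}: limit_value must be positive, "
                f"got {self.limit_value}"
            )
        if self.limit_unit not in UNITS:
            raise ValueError(
                f"category {self.code!r}: unknown unit {self.limit_unit!r}; "
                f"expected one of {sorted(UNITS)}"
            )
        if self.analyte not in ANALYTES:
            raise ValueError(
                f"category {self.code!r}: unknown analyte {self.analyte!r}"
            )


class Catalog(Mapping[str, RegulatoryCategory]):
    """Immutable mapping from category code to :class:`RegulatoryCategory`."""

    def __init__(self, categories: Iterable[RegulatoryCategory]):
        self._by_code: dict[str, RegulatoryCategory] = {}
        for cat in categories:
            if cat.code in self._by_code:
                raise ValueError(f"duplicate category code {cat.code!r}")
            self._by_code[cat.code] = cat

    def __getitem__(self, code: str) -> RegulatoryCategory:
        return self._by_code[code]

    def __iter__(self):
        return iter(self._by_code)

    def __len__(self) -> int:
        return len(self._by_code)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Catalog({len(self)} categories)"


_CATALOG_COLUMNS = ["code", "legislation", "foodstuff", "limit_value", "limit_unit"]


def _sniff_delimiter(header_line: str) -> str:
    return ";" if header_line.count(";") > header_line.count(",") else ","


def _parse_float(text: str, decimal: str = ".") -> float:
    if decimal == ",":
        text = text.replace(",", ".")
    return float(text)


def load_catalog(
    source: Union[str, Path] = "builtin", decimal: str = "."
) -> Catalog:
    """Load a regulatory catalog from a delimited-text file.

    ``source="builtin"`` loads the packaged catalog of EU maximum levels
    (17 categories covering Cd, Hg, Pb, dioxins, dioxin-like PCB sums,
    benzo(a)pyrene and the 4-PAH sum). Duplicate codes, non-positive limits
    and unknown units are hard errors.
    """
    if source == "builtin":
        text = (
            resources.files("msfd9.data")
            .joinpath("regulatory_catalog.csv")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(source).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        return Catalog([])
    delim = _sniff_delimiter(lines[0])
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    missing = set(_CATALOG_COLUMNS) - set(reader.fieldnames or [])
    if missing:
        raise ValueError(f"catalog file missing columns: {sorted(missing)}")
    cats = []
    for row in reader:
        cats.append(
            RegulatoryCategory(
                code=row["code"].strip(),
                analyte=_analyte_from_code(row["code"].strip()),
                foodstuff=row["foodstuff"].strip(),
                limit_value=_parse_float(row["limit_value"], decimal),
                limit_unit=row["limit_unit"].strip(),
                legislation=row["legislation"].strip(),
            )
        )
    return Catalog(cats)


@dataclass
class Measurement:
    """One concentration record at a monitoring station.

    ``concentration`` is in the unit of the record's regulatory category
    (wet-weight basis). ``below_loq`` flags values reported as below the
    limit of quantification; such records must carry ``loq``.
    Coordinates are ETRS89 geographic decimal degrees.
    """

    station_id: str
    lon: float
    lat: float
    year: int
    species: str
    tissue: str
    category_code: str
    concentration: float
    unit: str
    below_loq: bool = False
    loq: Optional[float] = None
    subregion: Optional[str] = None

    def validate(self, catalog: Optional[Catalog] = None) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat {self.lat} outside [-90, 90]")
        if self.concentration < 0:
            raise ValueError(f"negative concentration {self.concentration}")
        if self.below_loq and self.loq is None:
            raise ValueError("below_loq record without loq")
        if self.loq is not None and self.loq < 0:
            raise ValueError(f"negative loq {self.loq}")
        if catalog is not None and self.category_code not in catalog:
            raise ValueError(f"unknown category code {self.category_code!r}")


@dataclass(frozen=True)
class ParseError:
    """A rejected input row: its 1-based data-row number, the violated rule
    and a human-readable message."""

    row: int
    rule: str
    message: str


MEASUREMENT_COLUMNS = [
    "station_id",
    "lon",
    "lat",
    "year",
    "species",
    "tissue",
    "category_code",
    "concentration",
    "unit",
    "below_loq",
    "loq",
    "subregion",
]
_REQUIRED_COLUMNS = MEASUREMENT_COLUMNS[:-1]  # subregion is optional

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean {text!r}")


def load_measurements(
    path: Union[str, Path],
    catalog: Catalog,
    decimal: str = ".",
) -> tuple[list[Measurement], list[ParseError]]:
    """Read a measurement file, validating every record.

    Returns the well-formed measurements and a list of :class:`ParseError`
    for rejected rows (malformed numbers, invariant violations, category
    codes absent from ``catalog``). Rows are never silently dropped. A
    missing required column is a hard error.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty measurement file")
    delim = _sniff_delimiter(lines[0])
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    missing = set(_REQUIRED_COLUMNS) - set(reader.fieldnames or [])
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    measurements: list[Measurement] = []
    errors: list[ParseError] = []
    for i, row in enumerate(reader, start=1):
        try:
            loq_text = (row.get("loq") or "").strip()
            m = Measurement(
                station_id=row["station_id"].strip(),
                lon=_parse_float(row["lon"], decimal),
                lat=_parse_float(row["lat"], decimal),
                year=int(row["year"]),
                species=row["species"].strip(),
                tissue=row["tissue"].strip(),
                category_code=row["category_code"].strip(),
                concentration=_parse_float(row["concentration"], decimal),
                unit=row["unit"].strip(),
                below_loq=_parse_bool(row.get("below_loq") or "false"),
                loq=_parse_float(loq_text, decimal) if loq_text else None,
                subregion=(row.get("subregion") or "").strip() or None,
            )
            m.validate(catalog)
        except (ValueError, KeyError) as exc:
            errors.append(ParseError(row=i, rule="invalid_record", message=str(exc)))
            continue
        measurements.append(m)
    return measurements, errors


def _fmt(value) -> str:
    # repr() gives the shortest string that round-trips the float exactly,
    # which the lossless write->read property relies on.
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_measurements(
    measurements: Sequence[Measurement], path: Union[str, Path]
) -> None:
    """Write measurements in the canonical dialect (comma-separated,
    decimal point, UTF-8, ``\\n`` line endings)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(MEASUREMENT_COLUMNS) + "\n")
        for m in measurements:
            fh.write(
                ",".join(
                    _fmt(getattr(m, col)) for col in MEASUREMENT_COLUMNS
                )
                + "\n"
            )


@dataclass
class QCConfig:
    """Enables/disables the record-level quality-control predicates.

    bbox
        ``(min_lon, min_lat, max_lon, max_lat)`` of the assessment area;
        records outside are removed. ``None`` disables the rule.
    check_unit
        Remove records whose unit differs from their category's unit.
    check_loq
        Remove below-LOQ records whose quantification limit exceeds the
        regulatory limit (such records cannot inform the compliance test).
    year_range
        ``(first, last)`` inclusive assessment window; ``None`` disables.
    """

    bbox: Optional[tuple[float, float, float, float]] = None
    check_unit: bool = True
    check_loq: bool = True
    year_range: Optional[tuple[int, int]] = None


@dataclass
class QCReport:
    """Accounting of a QC pass: every removal is attributed to one rule and
    ``n_input == n_kept + sum(removed_by_rule.values())`` always holds."""

    n_input: int
    n_kept: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    loq_substitution: str = "half_loq"

    def check(self) -> None:
        assert self.n_input == self.n_kept + sum(self.removed_by_rule.values())


def qc_filter(
    measurements: Sequence[Measurement],
    catalog: Catalog,
    qc: Optional[QCConfig] = None,
    loq_substitution: str = "half_loq",
) -> tuple[list[Measurement], QCReport]:
    """Apply the enabled QC predicates; return kept records and a report.

    Filtering is total: invalid records are removed and counted, never an
    error. A record is attributed to the first rule it fails (rule order:
    bbox, unit, loq, year).
    """
    qc = qc or QCConfig()
    removed: dict[str, int] = {"bbox": 0, "unit": 0, "loq": 0, "year": 0}
    kept: list[Measurement] = []
    for m in measurements:
        if qc.bbox is not None:
            lo_x, lo_y, hi_x, hi_y = qc.bbox
            if not (lo_x <= m.lon <= hi_x and lo_y <= m.lat <= hi_y):
                removed["bbox"] += 1
                continue
        cat = catalog.get(m.category_code)
        if qc.check_unit and cat is not None and m.unit != cat.limit_unit:
            removed["unit"] += 1
            continue
        if (
            qc.check_loq
            and cat is not None
            and m.below_loq
            and m.loq is not None
            and m.loq > cat.limit_value
        ):
            removed["loq"] += 1
            continue
        if qc.year_range is not None:
            first, last = qc.year_range
            if not first <= m.year <= last:
                removed["year"] += 1
                continue
        kept.append(m)
    report = QCReport(
        n_input=len(measurements),
        n_kept=len(kept),
        removed_by_rule={k: v for k, v in removed.items() if v},
        loq_substitution=loq_substitution,
    )
    report.check()
    return kept, report


LOQ_POLICIES = ("half_loq", "loq", "zero", "drop")


def apply_loq_policy(
    measurements: Sequence[Measurement], policy: str = "half_loq"
) -> list[Measurement]:
    """Substitute a usable concentration for below-LOQ records.

    half_loq (default)
        concentration := loq / 2, the common monitoring convention.
    loq / zero
        concentration := loq, respectively 0.
    drop
        below-LOQ records are discarded.
    """
    if policy not in LOQ_POLICIES:
        raise ValueError(f"unknown LOQ policy {policy!r}; choose from {LOQ_POLICIES}")
    out: list[Measurement] = []
    for m in measurements:
        if not m.below_loq:
            out.append(m)
            continue
        if policy == "drop":
            continue
        if m.loq is None:
            raise ValueError(
                f"below-LOQ record at station {m.station_id!r} has no loq"
            )
        value = {"half_loq": m.loq / 2.0, "loq": m.loq, "zero": 0.0}[policy]
        out.append(replace(m, concentration=value))
    return out
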