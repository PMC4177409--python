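"""Code assignment and precautionary integration of assessment results.

Every measurement is coded 1 (within the regulatory limit, mapped green) or
2 (exceeding, mapped red). Codes are then integrated upward — data within a
station, stations within a grid cell, the same cell across years — with a
single rule applied identically at every level: the majority code wins and
an exact tie yields code 2, in compliance with the precautionary principle.
A unit with no data is "no data", never coded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .catalog_and_io import Measurement, RegulatoryCategory

__all__ = [
    "code_datum",
    "integrate_codes",
    "StationAssessment",
    "assess_station",
    "CellAssessment",
    "assess_cell",
]

WITHIN = 1  #: within the regulatory limit (green)
EXCEEDING = 2  #: above the regulatory limit (red)


def code_datum(measurement: Measurement, category: RegulatoryCategory) -> int:
    """1 if the concentration does not exceed the category limit, else 2.

    "Not exceeding" includes equality: a value exactly at the limit codes 1.
    A unit mismatch between record and category is a hard error (never a
    silent conversion).
    """
    if measurement.category_code != category.code:
        raise ValueError(
            f"measurement category {measurement.category_code!r} does not "
            f"match {category.code!r}"
        )
    if measurement.unit != category.limit_unit:
        raise ValueError(
            f"unit mismatch for {category.code!r}: record in "
            f"{measurement.unit!r}, limit in {category.limit_unit!r}"
        )
    return WITHIN if measurement.concentration <= category.limit_value else EXCEEDING


def integrate_codes(codes: Iterable[int]) -> int:
    """Majority code of a non-empty multiset of {1, 2}; ties integrate
    to 2 (precautionary principle)."""
    counts = Counter(codes)
    unexpected = set(counts) - {WITHIN, EXCEEDING}
    if unexpected:
        raise ValueError(f"codes must be 1 or 2, got {sorted(unexpected)}")
    n1, n2 = counts[WITHIN], counts[EXCEEDING]
    if n1 + n2 == 0:
        raise ValueError("cannot integrate an empty set of codes")
    return EXCEEDING if n2 >= n1 else WITHIN


@dataclass(frozen=True)
class StationAssessment:
    """Integrated result of one station (or station-year) for one category."""

    station_id: str
    category_code: str
    years: tuple[int, ...]
    code: int
    n_data: int
    n_exceed: int


def assess_station(
    measurements: Sequence[Measurement], category: RegulatoryCategory
) -> StationAssessment:
    """Integrate all data of one station for one category.

    Data of different species in the same regulatory category are pooled at
    the datum level before coding. The same majority/tie rule used for
    cells applies.
    """
    if not measurements:
        raise ValueError("no measurements: a station with no data is uncoded")
    stations = {m.station_id for m in measurements}
    if len(stations) > 1:
        raise ValueError(f"mixed stations {sorted(stations)} in one assessment")
    cats = {m.category_code for m in measurements}
    if len(cats) > 1:
        raise ValueError(f"mixed categories {sorted(cats)} in one assessment")
    codes = [code_datum(m, category) for m in measurements]
    return StationAssessment(
        station_id=measurements[0].station_id,
        category_code=category.code,
        years=tuple(sorted({m.year for m in measurements})),
        code=integrate_codes(codes),
        n_data=len(codes),
        n_exceed=sum(1 for c in codes if c == EXCEEDING),
    )


@dataclass(frozen=True)
class CellAssessment:
    """Integrated result of one grid cell for one category."""

    cell_id: tuple[int, int]
    category_code: str
    code: int
    n_stations_code1: int
    n_stations_code2: int


def assess_cell(
    station_assessments: Sequence[StationAssessment],
    cell_id: tuple[int, int],
    station_cells: Sequence[tuple[int, int]] | None = None,
) -> CellAssessment:
    """Integrate station results falling in one cell.

    In whole-period mode the caller passes one assessment per station-year,
    so a station sampled in three years contributes three votes. If
    ``station_cells`` is given it must place every assessment in
    ``cell_id`` (mixed cells are a hard error).
    """
    if not station_assessments:
        raise ValueError("no station results: a cell with no data is uncoded")
    if station_cells is not None:
        wrong = {c for c in station_cells if c != cell_id}
        if wrong:
            raise ValueError(
                f"station results from cells {sorted(wrong)} mixed into "
                f"cell {cell_id}"
            )
    cats = {a.category_code for a in station_assessments}
    if len(cats) > 1:
        raise ValueError(f"mixed categories {sorted(cats)} in one cell")
    codes = [a.code for a in station_assessments]
    return CellAssessment(
        cell_id=cell_id,
        category_code=station_assessments[0].category_code,
        code=integrate_codes(codes),
        n_stations_code1=sum(1 for c in codes if c == WITHIN),
        n_stations_code2=sum(1 for c in codes if c == EXCEEDING),
    )
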