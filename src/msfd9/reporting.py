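"""Summary statistics, map export and the end-to-end assessment pipeline.

Produces, per subregion and regulatory category, the spatial coverage and
the percentages of data, stations and grid cells within/outside regulatory
limits, plus green/red GeoJSON cell maps. Percentages are printed to one
decimal, rounded half-up; counts are never rounded; categories without data
render as "-" and are excluded from denominators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional, Sequence, Union

from .catalog_and_io import Catalog, Measurement, apply_loq_policy
from .integration import (
    EXCEEDING,
    WITHIN,
    CellAssessment,
    StationAssessment,
    assess_cell,
    assess_station,
    code_datum,
    integrate_codes,
)
from .spatial_grid import SubregionGrid, cell_of

__all__ = [
    "round_half_up",
    "spatial_coverage",
    "exceedance_frequency",
    "SummaryRow",
    "summarize",
    "render_maps",
    "render_png",
    "AssessmentResult",
    "run_assessment",
    "write_summary_csv",
    "format_summary_table",
    "write_geojson",
    "CONTAMINANT_CLASSES",
    "class_totals",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (0.05 at 1 decimal rounds to 0.1)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def spatial_coverage(n_cells_with_data: int, n_total_cells: int) -> float:
    """Percentage of subregion cells holding at least one assessed datum."""
    if n_total_cells < 1:
        raise ValueError("total cell count must be >= 1")
    if not 0 <= n_cells_with_data <= n_total_cells:
        raise ValueError(
            f"cells with data ({n_cells_with_data}) outside "
            f"[0, {n_total_cells}]"
        )
    return round_half_up(100.0 * n_cells_with_data / n_total_cells)


def exceedance_frequency(codes: Sequence[int]) -> tuple[int, float]:
    """Number of exceedances (code 2) and their percentage of all data —
    the frequency-of-exceedance indicator."""
    if not codes:
        raise ValueError("exceedance frequency of empty data")
    n_exceed = sum(1 for c in codes if c == EXCEEDING)
    return n_exceed, round_half_up(100.0 * n_exceed / len(codes))


@dataclass
class SummaryRow:
    """One subregion x category row of the summary table."""

    subregion: str
    category_code: str
    spatial_coverage_pct: Optional[float]
    pct_data_within: Optional[float]
    pct_data_outside: Optional[float]
    pct_stations_within: Optional[float]
    pct_stations_outside: Optional[float]
    pct_cells_within: Optional[float]
    pct_cells_outside: Optional[float]
    n_data: int
    n_stations: int
    n_cells_with_data: int
    n_total_cells: int

    @property
    def no_data(self) -> bool:
        return self.n_data == 0


def _pct_pair(n_within: int, n_total: int) -> tuple[float, float]:
    return (
        round_half_up(100.0 * n_within / n_total),
        round_half_up(100.0 * (n_total - n_within) / n_total),
    )


def summarize(
    grid: SubregionGrid,
    subregion: str,
    datum_codes: dict[str, list[int]],
    station_codes: dict[str, dict[str, int]],
    cell_assessments: dict[str, dict[tuple[int, int], CellAssessment]],
    categories: Sequence[str],
) -> list[SummaryRow]:
    """Build one :class:`SummaryRow` per category.

    ``datum_codes`` maps category -> per-datum codes, ``station_codes``
    category -> {station (or station-year) key: integrated code},
    ``cell_assessments`` category -> {cell_id: assessment}. Categories
    absent from the data are emitted as "no data" rows.
    """
    rows: list[SummaryRow] = []
    total_cells = grid.total_cells
    for code in categories:
        codes = datum_codes.get(code, [])
        if not codes:
            rows.append(
                SummaryRow(
                    subregion=subregion,
                    category_code=code,
                    spatial_coverage_pct=None,
                    pct_data_within=None,
                    pct_data_outside=None,
                    pct_stations_within=None,
                    pct_stations_outside=None,
                    pct_cells_within=None,
                    pct_cells_outside=None,
                    n_data=0,
                    n_stations=0,
                    n_cells_with_data=0,
                    n_total_cells=total_cells,
                )
            )
            continue
        st = station_codes[code]
        cells = cell_assessments[code]
        n_data = len(codes)
        d_within = sum(1 for c in codes if c == WITHIN)
        s_within = sum(1 for c in st.values() if c == WITHIN)
        c_within = sum(1 for a in cells.values() if a.code == WITHIN)
        pd_in, pd_out = _pct_pair(d_within, n_data)
        ps_in, ps_out = _pct_pair(s_within, len(st))
        pc_in, pc_out = _pct_pair(c_within, len(cells))
        rows.append(
            SummaryRow(
                subregion=subregion,
                category_code=code,
                spatial_coverage_pct=spatial_coverage(len(cells), total_cells),
                pct_data_within=pd_in,
                pct_data_outside=pd_out,
                pct_stations_within=ps_in,
                pct_stations_outside=ps_out,
                pct_cells_within=pc_in,
                pct_cells_outside=pc_out,
                n_data=n_data,
                n_stations=len(st),
                n_cells_with_data=len(cells),
                n_total_cells=total_cells,
            )
        )
    return rows


_COLOR = {WITHIN: "green", EXCEEDING: "red"}


def render_maps(
    cell_assessments: dict[tuple[int, int], CellAssessment],
    grid: SubregionGrid,
    include_no_data: bool = False,
) -> dict:
    """GeoJSON FeatureCollection of assessed cells.

    Each feature carries properties ``code`` and ``color`` (green for 1,
    red for 2). With ``include_no_data`` the remaining subregion cells are
    emitted with ``code: null`` and ``color: "none"``. An assessment
    referencing a cell outside the subregion grid is a hard error.
    """
    from .spatial_grid import cell_bounds  # local to avoid cycle at import

    dangling = set(cell_assessments) - set(grid.in_subregion)
    if dangling:
        raise ValueError(
            f"assessments reference cells outside the grid: {sorted(dangling)}"
        )
    features = []
    for cell_id in sorted(grid.in_subregion):
        assessed = cell_id in cell_assessments
        if not assessed and not include_no_data:
            continue
        lon0, lat0, lon1, lat1 = cell_bounds(grid.fishnet, *cell_id)
        props: dict = {"row": cell_id[0], "col": cell_id[1]}
        if assessed:
            a = cell_assessments[cell_id]
            props.update(
                code=a.code,
                color=_COLOR[a.code],
                category_code=a.category_code,
                n_stations_code1=a.n_stations_code1,
                n_stations_code2=a.n_stations_code2,
            )
        else:
            props.update(code=None, color="none")
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [
                            [lon0, lat0],
                            [lon1, lat0],
                            [lon1, lat1],
                            [lon0, lat1],
                            [lon0, lat0],
                        ]
                    ],
                },
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def render_png(
    cell_assessments: dict[tuple[int, int], CellAssessment],
    grid: SubregionGrid,
    path: Union[str, Path],
) -> None:
    """Raster companion of :func:`render_maps`: subregion outline, grey
    no-data cells, green/red assessed cells."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    from .spatial_grid import cell_bounds

    dangling = set(cell_assessments) - set(grid.in_subregion)
    if dangling:
        raise ValueError(
            f"assessments reference cells outside the grid: {sorted(dangling)}"
        )
    fig, ax = plt.subplots(figsize=(7, 6))
    for cell_id in sorted(grid.in_subregion):
        lon0, lat0, lon1, lat1 = cell_bounds(grid.fishnet, *cell_id)
        a = cell_assessments.get(cell_id)
        face = "0.9" if a is None else {WITHIN: "tab:green", EXCEEDING: "tab:red"}[a.code]
        ax.add_patch(
            Rectangle((lon0, lat0), lon1 - lon0, lat1 - lat0,
                      facecolor=face, edgecolor="0.6", linewidth=0.3)
        )
    boundary = grid.polygon.boundary
    geoms = getattr(boundary, "geoms", [boundary])
    for line in geoms:
        xs, ys = line.xy
        ax.plot(xs, ys, color="k", linewidth=1.0)
    ax.set_xlabel("longitude (°E, ETRS89)")
    ax.set_ylabel("latitude (°N, ETRS89)")
    ax.set_aspect("equal")
    ax.autoscale_view()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class AssessmentResult:
    """Everything the pipeline computes for one subregion."""

    subregion: str
    grid: SubregionGrid
    datum_codes: dict[str, list[int]]
    station_year_assessments: dict[str, list[StationAssessment]]
    station_codes: dict[str, dict[str, int]]
    cell_assessments: dict[str, dict[tuple[int, int], CellAssessment]]
    summary: list[SummaryRow]


def run_assessment(
    measurements: Sequence[Measurement],
    catalog: Catalog,
    grid: SubregionGrid,
    subregion: str,
    mode: str = "whole_period",
    year: Optional[int] = None,
    loq_policy: str = "half_loq",
    station_denominator: str = "unique",
) -> AssessmentResult:
    """Run the full datum -> station -> cell integration for one subregion.

    ``mode="whole_period"`` pools station-year results as separate votes in
    each cell (a station sampled in three years contributes three codes);
    ``mode="single_year"`` restricts the assessment to ``year``. The
    station-level percentages use unique stations by default
    (``station_denominator="station_years"`` counts station-years instead).
    """
    if mode not in ("whole_period", "single_year"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "single_year":
        if year is None:
            raise ValueError("single_year mode requires a year")
        measurements = [m for m in measurements if m.year == year]
    ms = apply_loq_policy(measurements, loq_policy)

    by_cat: dict[str, list[Measurement]] = {}
    for m in ms:
        by_cat.setdefault(m.category_code, []).append(m)

    datum_codes: dict[str, list[int]] = {}
    sy_assessments: dict[str, list[StationAssessment]] = {}
    station_codes: dict[str, dict[str, int]] = {}
    cell_assessments: dict[str, dict[tuple[int, int], CellAssessment]] = {}

    for code, records in sorted(by_cat.items()):
        category = catalog[code]
        datum_codes[code] = [code_datum(m, category) for m in records]

        by_station_year: dict[tuple[str, int], list[Measurement]] = {}
        for m in records:
            by_station_year.setdefault((m.station_id, m.year), []).append(m)
        sy = [
            assess_station(group, category)
            for _, group in sorted(by_station_year.items())
        ]
        sy_assessments[code] = sy

        per_station: dict[str, list[int]] = {}
        for a in sy:
            per_station.setdefault(a.station_id, []).append(a.code)
        if station_denominator == "unique":
            station_codes[code] = {
                sid: integrate_codes(codes) for sid, codes in per_station.items()
            }
        elif station_denominator == "station_years":
            station_codes[code] = {
                f"{a.station_id}:{a.years[0]}": a.code for a in sy
            }
        else:
            raise ValueError(
                f"unknown station denominator {station_denominator!r}"
            )

        by_cell: dict[tuple[int, int], list[StationAssessment]] = {}
        for a in sy:
            group = by_station_year[(a.station_id, a.years[0])]
            lon, lat = group[0].lon, group[0].lat
            cid = cell_of(grid.fishnet, lon, lat)
            if cid is None:
                raise ValueError(
                    f"station {a.station_id!r} at ({lon}, {lat}) falls "
                    "outside the fishnet"
                )
            by_cell.setdefault(cid, []).append(a)
        cell_assessments[code] = {
            cid: assess_cell(group, cid)
            for cid, group in sorted(by_cell.items())
        }

    categories = list(catalog)
    summary = summarize(
        grid, subregion, datum_codes, station_codes, cell_assessments, categories
    )
    return AssessmentResult(
        subregion=subregion,
        grid=grid,
        datum_codes=datum_codes,
        station_year_assessments=sy_assessments,
        station_codes=station_codes,
        cell_assessments=cell_assessments,
        summary=summary,
    )


_CSV_FIELDS = [
    "subregion",
    "category_code",
    "spatial_coverage_pct",
    "pct_data_within",
    "pct_data_outside",
    "pct_stations_within",
    "pct_stations_outside",
    "pct_cells_within",
    "pct_cells_outside",
    "n_data",
    "n_stations",
    "n_cells_with_data",
    "n_total_cells",
]


def write_summary_csv(rows: Sequence[SummaryRow], path: Union[str, Path]) -> None:
    """Delimited-text summary, one row per category; "-" marks no data."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_CSV_FIELDS) + "\n")
        for r in rows:
            d = asdict(r)
            fh.write(
                ",".join(
                    "-" if d[f] is None else str(d[f]) for f in _CSV_FIELDS
                )
                + "\n"
            )


_TABLE_ROWS = [
    ("% of spatial coverage", "spatial_coverage_pct"),
    ("% of data within the limits", "pct_data_within"),
    ("% of data outside the limits", "pct_data_outside"),
    ("% of station within the limits", "pct_stations_within"),
    ("% of station outside the limits", "pct_stations_outside"),
    ("% of cells within the limits", "pct_cells_within"),
    ("% of cells outside the limits", "pct_cells_outside"),
]


def format_summary_table(rows: Sequence[SummaryRow]) -> str:
    """Human-readable fixed-width table, categories as columns."""
    if not rows:
        return "(no categories)\n"
    header = f"{rows[0].subregion} (total cells {rows[0].n_total_cells})"
    label_w = max(len(lbl) for lbl, _ in _TABLE_ROWS + [(header, "")]) + 2
    col_w = max(max(len(r.category_code) for r in rows) + 2, 8)

    def cell(value) -> str:
        return ("-" if value is None else f"{value:g}").rjust(col_w)

    lines = [
        header.ljust(label_w)
        + "".join(r.category_code.rjust(col_w) for r in rows)
    ]
    for label, attr in _TABLE_ROWS:
        lines.append(
            label.ljust(label_w) + "".join(cell(getattr(r, attr)) for r in rows)
        )
    return "\n".join(lines) + "\n"


def write_geojson(obj: dict, path: Union[str, Path]) -> None:
    """Write GeoJSON with deterministic formatting (sorted keys)."""
    Path(path).write_text(
        json.dumps(obj, sort_keys=True, separators=(",", ":")) + "\n",
        encoding="utf-8",
    )


#: Contaminant classes used in the record-count bookkeeping of the
#: Mediterranean initial assessment (HOCs = halogenated organic compounds,
#: i.e. dioxins and dioxin-like PCB sums).
CONTAMINANT_CLASSES = {
    "Cd": "metals",
    "Hg": "metals",
    "Pb": "metals",
    "benzo(a)pyrene": "pahs",
    "sum of 4 PAHs": "pahs",
    "dioxins": "hocs",
    "sum dioxins and dl-PCBs": "hocs",
}


def class_totals(
    rows: Sequence[SummaryRow], catalog: Catalog
) -> dict[str, int]:
    """Record counts per contaminant class plus the grand total; the class
    counts always sum to the total (the bookkeeping identity)."""
    totals = {"metals": 0, "pahs": 0, "hocs": 0}
    for r in rows:
        cls = CONTAMINANT_CLASSES[catalog[r.category_code].analyte]
        totals[cls] += r.n_data
    totals["total"] = sum(totals.values())
    return totals
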