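"""Synthetic monitoring-data generator.

Emulates the statistical and spatial structure the assessment assumes:
per-category lognormal concentration distributions (median = geometric
mean, dispersion given as a natural-scale coefficient of variation) at
stations scattered over a subregion polygon, optionally biased toward the
coast where real monitoring effort concentrates. The target exceedance
fraction of a category is dialled by solving the lognormal median so that
P(Y > TL) equals the target.

Three stylized subregion polygons are packaged (synthetic stand-ins for
undeposited assessment boundaries): ``elongated_basin``, ``boot_coast``
and ``island_mix``. Output uses exactly the measurement-file dialect of
:mod:`msfd9.catalog_and_io`; a sidecar records the generating truth per
category for parameter-recovery tests. Identical scenario + seed gives
byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .catalog_and_io import Catalog, Measurement, write_measurements
from .spatial_grid import load_polygon

__all__ = [
    "FIXTURE_POLYGON_NAMES",
    "fixture_polygon",
    "gen_stations",
    "gen_concentrations",
    "solve_gm_for_exceedance",
    "expected_exceedance",
    "CategoryPlan",
    "Scenario",
    "default_scenario",
    "gen_dataset",
    "write_sidecar",
]

FIXTURE_POLYGON_NAMES = ("elongated_basin", "boot_coast", "island_mix")

_SPECIES_BY_FOODSTUFF = {
    "Bivalve molluscs": ("Mytilus galloprovincialis", "soft tissue"),
    "Crustaceans": ("Parapenaeus longirostris", "muscle"),
    "Cephalopods": ("Octopus vulgaris", "muscle"),
}
_DEFAULT_SPECIES = ("Mullus barbatus", "muscle")


def fixture_polygon(name: str) -> BaseGeometry:
    """Load one of the packaged stylized subregion polygons."""
    if name not in FIXTURE_POLYGON_NAMES:
        raise ValueError(
            f"unknown fixture polygon {name!r}; choose from "
            f"{FIXTURE_POLYGON_NAMES}"
        )
    with resources.as_file(
        resources.files("msfd9.data").joinpath(f"{name}.geojson")
    ) as p:
        return load_polygon(p)


def gen_stations(
    polygon: BaseGeometry,
    n: int,
    seed: int,
    coastal_bias: bool = False,
) -> list[tuple[float, float]]:
    """Draw ``n`` station positions inside the polygon (lon, lat).

    Rejection sampling from the bounding box; with ``coastal_bias`` points
    are additionally thinned toward the interior so density concentrates
    near the boundary, mimicking coastal monitoring effort.
    """
    if n < 1:
        raise ValueError("need at least one station")
    if polygon.is_empty or polygon.area == 0:
        raise ValueError("degenerate subregion polygon")
    rng = np.random.default_rng(seed)
    min_x, min_y, max_x, max_y = polygon.bounds
    # decay scale ~ one tenth of the linear extent of the subregion
    scale = 0.1 * math.sqrt(polygon.area)
    points: list[tuple[float, float]] = []
    while len(points) < n:
        lon = rng.uniform(min_x, max_x)
        lat = rng.uniform(min_y, max_y)
        pt = Point(lon, lat)
        if not polygon.covers(pt):
            continue
        if coastal_bias:
            accept_p = math.exp(-polygon.boundary.distance(pt) / scale)
            if rng.uniform() > accept_p:
                continue
        points.append((lon, lat))
    return points


def gen_concentrations(
    gm: float, cv: float, n: int, seed_or_rng: Union[int, np.random.Generator]
) -> np.ndarray:
    """Lognormal draws with median ``gm`` and natural-scale SD ``cv * gm``
    (log-scale sigma = sqrt(ln(1 + cv^2)))."""
    if gm <= 0:
        raise ValueError("gm must be positive")
    if cv <= 0:
        raise ValueError("cv must be positive")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=math.log(gm), sigma=sigma, size=n)


def solve_gm_for_exceedance(tl: float, fraction: float, cv: float) -> float:
    """Median gm such that P(Y > tl) = fraction for the cv-lognormal.

    Closed form: gm = tl * exp(-z_(1-fraction) * sigma). Fractions 0 and 1
    are mapped to six sigma below/above the threshold (practically never /
    always exceeding).
    """
    if tl <= 0:
        raise ValueError("tl must be positive")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("exceedance fraction must be in [0, 1]")
    sigma = math.sqrt(math.log1p(cv * cv))
    if fraction <= 0.0:
        z = 6.0
    elif fraction >= 1.0:
        z = -6.0
    else:
        z = float(stats.norm.ppf(1.0 - fraction))
    return tl * math.exp(-z * sigma)


def expected_exceedance(gm: float, cv: float, tl: float) -> float:
    """P(Y > tl) under the cv-lognormal with median gm."""
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(stats.norm.sf((math.log(tl) - math.log(gm)) / sigma))


@dataclass(frozen=True)
class CategoryPlan:
    """Generation plan for one regulatory category.

    Exactly one of ``gm`` / ``target_exceedance_fraction`` fixes the
    lognormal median (the fraction solves it against the category limit).
    ``n_per_station`` is records per station per year.
    """

    category_code: str
    gm: Optional[float] = None
    cv: float = 0.2
    target_exceedance_fraction: Optional[float] = None
    n_per_station: int = 1
    years: tuple[int, ...] = (2006, 2007, 2008, 2009, 2010, 2011, 2012)

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if self.n_per_station < 1:
            raise ValueError("n_per_station must be >= 1")
        if (self.gm is None) == (self.target_exceedance_fraction is None):
            raise ValueError(
                "give exactly one of gm / target_exceedance_fraction"
            )
        if self.target_exceedance_fraction is not None and not (
            0.0 <= self.target_exceedance_fraction <= 1.0
        ):
            raise ValueError("target_exceedance_fraction must be in [0, 1]")

    def resolve_gm(self, limit_value: float) -> float:
        if self.gm is not None:
            return self.gm
        return solve_gm_for_exceedance(
            limit_value, self.target_exceedance_fraction, self.cv
        )


@dataclass(frozen=True)
class Scenario:
    """A full synthetic monitoring campaign over one subregion."""

    polygon: str = "elongated_basin"  # fixture name or path to GeoJSON
    n_stations: int = 60
    plans: tuple[CategoryPlan, ...] = ()
    seed: int = 0
    coastal_bias: bool = False
    subregion_label: str = "SYN"

    def geometry(self) -> BaseGeometry:
        if self.polygon in FIXTURE_POLYGON_NAMES:
            return fixture_polygon(self.polygon)
        return load_polygon(self.polygon)


def default_scenario(seed: int = 0) -> Scenario:
    """A realistic mostly-compliant campaign over the elongated basin.

    Mirrors the qualitative pattern of the Mediterranean initial
    assessment at desk scale: metals monitored most densely with sporadic
    mercury/lead exceedances, PAHs and dioxin sums compliant and measured
    in mussels, everything sampled yearly 2006-2012.
    """
    return Scenario(
        polygon="elongated_basin",
        n_stations=60,
        plans=(
            CategoryPlan("Hg 3.3.1", target_exceedance_fraction=0.03),
            CategoryPlan("Cd 3.2.9", target_exceedance_fraction=0.0),
            CategoryPlan("Pb 3.1.5", target_exceedance_fraction=0.07),
            CategoryPlan("Benzo(a)pyrene 6.1.6", target_exceedance_fraction=0.0),
            CategoryPlan(
                "Sum dioxins and dioxin like PCBs 5.3",
                target_exceedance_fraction=0.0,
            ),
        ),
        seed=seed,
    )


def gen_dataset(
    scenario: Scenario,
    catalog: Catalog,
    out_path: Optional[Union[str, Path]] = None,
    sidecar_path: Optional[Union[str, Path]] = None,
) -> tuple[list[Measurement], dict[str, dict[str, float]]]:
    """Generate the scenario's measurements and ground truth.

    Returns the measurement list and a truth map
    ``{category_code: {gm, cv, sigma_log, tl, expected_exceedance, n}}``;
    optionally writes the measurement file and the key-value sidecar.
    """
    polygon = scenario.geometry()
    stations = gen_stations(
        polygon, scenario.n_stations, scenario.seed, scenario.coastal_bias
    )
    measurements: list[Measurement] = []
    truth: dict[str, dict[str, float]] = {}
    for plan_i, plan in enumerate(scenario.plans):
        category = catalog[plan.category_code]
        gm = plan.resolve_gm(category.limit_value)
        sigma = math.sqrt(math.log1p(plan.cv * plan.cv))
        species, tissue = _SPECIES_BY_FOODSTUFF.get(
            category.foodstuff, _DEFAULT_SPECIES
        )
        # one independent stream per category so plans do not perturb
        # each other's draws
        rng = np.random.default_rng(
            np.random.SeedSequence([scenario.seed, plan_i])
        )
        n_cat = 0
        for s_i, (lon, lat) in enumerate(stations):
            for year in plan.years:
                values = gen_concentrations(
                    gm, plan.cv, plan.n_per_station, rng
                )
                for v in values:
                    measurements.append(
                        Measurement(
                            station_id=f"ST{s_i:04d}",
                            lon=lon,
                            lat=lat,
                            year=year,
                            species=species,
                            tissue=tissue,
                            category_code=category.code,
                            concentration=float(v),
                            unit=category.limit_unit,
                            below_loq=False,
                            loq=None,
                            subregion=scenario.subregion_label,
                        )
                    )
                n_cat += plan.n_per_station
        truth[category.code] = {
            "gm": gm,
            "cv": plan.cv,
            "sigma_log": sigma,
            "tl": category.limit_value,
            "expected_exceedance": expected_exceedance(
                gm, plan.cv, category.limit_value
            ),
            "n": float(n_cat),
        }
    if out_path is not None:
        write_measurements(measurements, out_path)
    if sidecar_path is not None:
        write_sidecar(truth, sidecar_path)
    return measurements, truth


def write_sidecar(
    truth: dict[str, dict[str, float]], path: Union[str, Path]
) -> None:
    """Tab-separated key-value sidecar: category, field, value."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for code in sorted(truth):
            for key in sorted(truth[code]):
                fh.write(f"{code}\t{key}\t{repr(truth[code][key])}\n")


def read_sidecar(path: Union[str, Path]) -> dict[str, dict[str, float]]:
    """Inverse of :func:`write_sidecar`."""
    truth: dict[str, dict[str, float]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        code, key, value = line.split("\t")
        truth.setdefault(code, {})[key] = float(value)
    return truth
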