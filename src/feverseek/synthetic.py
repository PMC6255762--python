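"""Synthetic study generator.

Builds a complete self-contained study — a gridded landscape (land class,
elevation, roads, under-5 population), a public health-facility list, survey
clusters selected by probability-proportional-to-size (PPS) sampling with
DHS-style coordinate displacement, and child-level two-week fever recall plus
treatment-seeking responses drawn from a three-parameter logistic (3PL)
item-response model with known ground-truth parameters.

Every operation is deterministic given its seed, so the full downstream
pipeline (travel time -> Bayesian fit -> back-calculated probability curves ->
holdout validation -> administrative aggregation) is testable against known
truth without any external microdata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .raster import Raster

__all__ = [
    "LandscapeConfig",
    "TrueParameters",
    "ClusterRecord",
    "ChildRecord",
    "Landscape",
    "generate_landscape",
    "sample_clusters",
    "displace_clusters",
    "simulate_responses",
    "clusters_to_frame",
    "children_to_frame",
]

#: default land-class mix; speeds for these classes live in feverseek.travel
DEFAULT_LAND_FRACTIONS = {
    "builtup": 0.05,
    "agriculture": 0.35,
    "savanna": 0.40,
    "forest": 0.15,
    "water": 0.05,
}

DEFAULT_FACILITIES = {"hospital": 2, "health_centre": 8, "dispensary": 25}

MIN_HOUSEHOLDS, MAX_HOUSEHOLDS = 15, 30


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    Defaults describe a 100 x 100 km study region at 1-km resolution —
    the grid scale of the travel-time surfaces this package emulates.
    """

    grid_width: int = 100
    grid_height: int = 100
    cell_size: float = 1000.0
    land_class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAND_FRACTIONS)
    )
    road_density: float = 0.05
    elevation_relief: float = 800.0
    n_facilities_per_tier: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FACILITIES)
    )
    n_admin_units: int = 4
    total_population_u5: float = 200_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_width <= 0 or self.grid_height <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        total = sum(self.land_class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"land_class_fractions sum to {total}, expected 1")
        if any(v < 0 for v in self.land_class_fractions.values()):
            raise ValueError("land_class_fractions must be non-negative")
        if any(n < 0 for n in self.n_facilities_per_tier.values()):
            raise ValueError("facility counts must be non-negative")
        if not 0 <= self.road_density <= 1:
            raise ValueError("road_density must be in [0, 1]")
        if self.n_admin_units < 1:
            raise ValueError("n_admin_units must be >= 1")


@dataclass
class TrueParameters:
    """Ground-truth generative parameters of the 3PL response model.

    The response probability for a fever case with travel time ``t`` (minutes)
    and residence indicator ``urban`` is

        P = c + (1 - c) * logistic(a * theta - b),
        theta = alpha + beta_time * t + beta_urban * urban.

    ``c`` is the threshold (minimum) probability — the floor the probability
    of seeking treatment decays to at large travel time.
    """

    a: float = 1.0
    b: float = 0.0
    c: float = 0.2
    alpha: float = 0.5
    beta_time: float = -0.01  # per minute of travel time
    beta_urban: float = 0.3
    fever_prevalence: float = 0.25
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("discrimination a must be > 0")
        if not 0 < self.c <= 1:
            raise ValueError("threshold c must be in (0, 1]")
        if not 0 <= self.fever_prevalence <= 1:
            raise ValueError("fever_prevalence must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    def response_probability(self, travel_time_min, urban):
        theta = self.alpha + self.beta_time * np.asarray(travel_time_min) + (
            self.beta_urban * np.asarray(urban)
        )
        return self.c + (1.0 - self.c) * expit(self.a * theta - self.b)


@dataclass
class ClusterRecord:
    cluster_id: int
    true_coords: tuple[float, float]
    published_coords: tuple[float, float]
    residence: str  # "urban" | "rural"
    n_households: int

    def __post_init__(self) -> None:
        if not MIN_HOUSEHOLDS <= self.n_households <= MAX_HOUSEHOLDS:
            raise ValueError(
                f"n_households must be in [{MIN_HOUSEHOLDS}, {MAX_HOUSEHOLDS}]"
            )
        if self.residence not in ("urban", "rural"):
            raise ValueError(f"unknown residence {self.residence!r}")


@dataclass
class ChildRecord:
    child_id: int
    cluster_id: int
    fever: int  # two-week recall indicator
    response: float  # 1/0 sought public treatment; NaN when missing or no fever
    item_id: str
    travel_time_min: float
    urban: int


@dataclass
class Landscape:
    """Co-registered rasters plus the facility list and admin partition."""

    land_class: Raster  # integer codes into ``land_classes``
    elevation: Raster
    road_mask: Raster  # 0/1
    population: Raster  # under-5 persons per cell
    admin_partition: Raster  # integer admin-unit label per cell
    facilities: pd.DataFrame  # columns: id, x, y, tier
    land_classes: list[str]


def _smooth_field(shape, sigma, rng) -> np.ndarray:
    """Standardised smoothed Gaussian noise field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _draw_roads(shape, density, rng) -> np.ndarray:
    """Straight segments between random edge points until coverage >= density."""
    nrows, ncols = shape
    mask = np.zeros(shape, dtype=bool)
    target = int(round(density * nrows * ncols))
    guard = 0
    while mask.sum() < target and guard < 1000:
        guard += 1
        if rng.random() < 0.5:  # west-east
            r0, r1 = rng.integers(0, nrows, size=2)
            c0, c1 = 0, ncols - 1
        else:  # north-south
            c0, c1 = rng.integers(0, ncols, size=2)
            r0, r1 = 0, nrows - 1
        n = max(abs(r1 - r0), abs(c1 - c0)) + 1
        rr = np.round(np.linspace(r0, r1, n)).astype(int)
        cc = np.round(np.linspace(c0, c1, n)).astype(int)
        mask[rr, cc] = True
    return mask


def _admin_tiling(shape, k) -> np.ndarray:
    """Regular block tiling of the grid into k admin units (labels 0..k-1)."""
    nrows, ncols = shape
    kr = int(math.floor(math.sqrt(k)))
    while k % kr:
        kr -= 1
    kc = k // kr
    row_lab = np.minimum((np.arange(nrows) * kr) // nrows, kr - 1)
    col_lab = np.minimum((np.arange(ncols) * kc) // ncols, kc - 1)
    return (row_lab[:, None] * kc + col_lab[None, :]).astype(float)


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate co-registered landscape rasters, facilities and admin units.

    Land classes are assigned by thresholding a smooth random field at the
    configured class fractions (spatially coherent patches); elevation is a
    smooth field scaled to ``elevation_relief``; under-5 population is a
    log-Gaussian surface concentrated around built-up patches; facilities are
    placed preferentially in high-population cells (probability proportional
    to cell population, without replacement).
    """
    if sum(config.n_facilities_per_tier.values()) == 0:
        raise ValueError("no sources for cost distance: zero facilities requested")
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_height, config.grid_width)
    ncells = shape[0] * shape[1]

    # land class: threshold one smooth field at the cumulative class fractions
    classes = list(config.land_class_fractions)
    fracs = np.array([config.land_class_fractions[c] for c in classes])
    f = _smooth_field(shape, sigma=3.0, rng=rng)
    qs = np.cumsum(fracs)[:-1]
    cuts = np.quantile(f, qs) if len(classes) > 1 else np.array([])
    land = np.searchsorted(cuts, f, side="left").astype(float)

    elev = _smooth_field(shape, sigma=5.0, rng=rng)
    elev = (elev - elev.min()) * (
        config.elevation_relief / max(float(np.ptp(elev)), 1e-12)
    )

    roads = _draw_roads(shape, config.road_density, rng).astype(float)

    # population: log-Gaussian field plus a boost on built-up cells
    logpop = 1.2 * _smooth_field(shape, sigma=4.0, rng=rng)
    if "builtup" in classes:
        logpop = logpop + 2.0 * (land == classes.index("builtup"))
    if "water" in classes:
        logpop[land == classes.index("water")] = -np.inf
    pop = np.exp(logpop)
    pop *= config.total_population_u5 / pop.sum()

    # facilities: PPS placement over cells, distinct cells per tier draw
    cell_p = (pop / pop.sum()).ravel()
    rows = []
    fid = 0
    for tier, n in config.n_facilities_per_tier.items():
        if n == 0:
            continue
        idx = rng.choice(ncells, size=min(n, (cell_p > 0).sum()), replace=False,
                         p=cell_p)
        for i in idx:
            r, c = divmod(int(i), shape[1])
            x = (c + 0.5) * config.cell_size
            y = (r + 0.5) * config.cell_size
            rows.append({"id": fid, "x": x, "y": y, "tier": tier})
            fid += 1
    facilities = pd.DataFrame(rows, columns=["id", "x", "y", "tier"])

    admin = _admin_tiling(shape, config.n_admin_units)

    cs = config.cell_size
    return Landscape(
        land_class=Raster(land, cs),
        elevation=Raster(elev, cs),
        road_mask=Raster(roads, cs),
        population=Raster(pop, cs),
        admin_partition=Raster(admin, cs),
        facilities=facilities,
        land_classes=classes,
    )


def sample_clusters(
    population: Raster,
    n_clusters: int,
    urban_threshold: float,
    seed: int,
) -> list[ClusterRecord]:
    """PPS selection of survey clusters over population cells.

    Cell selection probability is proportional to cell population; sampling is
    without replacement so cluster locations are distinct. Residence is urban
    iff the cell's population is at least ``urban_threshold`` people. Household
    counts are uniform on [15, 30], the range typical of DHS/MIS/MICS clusters.
    """
    pop = population.data
    if np.nanmin(pop) < 0 or np.nansum(pop) <= 0:
        raise ValueError("population raster must be non-negative with positive total")
    if n_clusters == 0:
        return []
    flat = np.nan_to_num(pop.ravel(), nan=0.0)
    populated = int((flat > 0).sum())
    if n_clusters > populated:
        raise ValueError(
            f"n_clusters={n_clusters} exceeds {populated} populated cells"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n_clusters, replace=False, p=flat / flat.sum())
    clusters = []
    for cid, i in enumerate(idx):
        r, c = divmod(int(i), pop.shape[1])
        xy = population.coords_of(r, c)
        residence = "urban" if flat[i] >= urban_threshold else "rural"
        n_hh = int(rng.integers(MIN_HOUSEHOLDS, MAX_HOUSEHOLDS + 1))
        clusters.append(ClusterRecord(cid, xy, xy, residence, n_hh))
    return clusters


def displace_clusters(
    clusters: list[ClusterRecord],
    seed: int,
    urban_max_km: float = 2.0,
    rural_max_km: float = 5.0,
    rural_far_fraction: float = 0.01,
    rural_far_km: float = 10.0,
    extent: tuple[float, float] | None = None,
    valid_raster: Raster | None = None,
) -> list[ClusterRecord]:
    """Apply DHS-convention coordinate displacement for confidentiality.

    Displacement is uniform in angle and uniform in distance up to the class
    maximum (urban <= 2 km, rural <= 5 km, with a 1% share of rural clusters
    displaced up to 10 km). True coordinates are retained on the record for
    oracle testing only. With ``extent`` given, displacements leaving the
    study region are redrawn; with ``valid_raster`` given, displacements
    landing on its nodata cells are redrawn too (rejection, preserving the
    law on the admissible region — displaced survey points stay on
    inhabitable land).
    """
    rng = np.random.default_rng(seed)
    out = []
    for cl in clusters:
        if cl.residence == "urban":
            max_km = urban_max_km
        elif rng.random() < rural_far_fraction:
            max_km = rural_far_km
        else:
            max_km = rural_max_km
        for _ in range(10_000):
            angle = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0, max_km * 1000.0)
            px = cl.true_coords[0] + dist * np.cos(angle)
            py = cl.true_coords[1] + dist * np.sin(angle)
            if extent is not None and not (
                0 <= px < extent[0] and 0 <= py < extent[1]
            ):
                continue
            if valid_raster is not None:
                try:
                    if np.isnan(valid_raster.value_at(px, py)):
                        continue
                except ValueError:
                    continue
            break
        else:  # pragma: no cover - admissible region smaller than radius
            px, py = cl.true_coords
        out.append(
            ClusterRecord(
                cl.cluster_id, cl.true_coords, (px, py), cl.residence, cl.n_households
            )
        )
    return out


def simulate_responses(
    clusters: list[ClusterRecord],
    travel_time: Raster,
    params: TrueParameters,
    seed: int,
    item_id: str = "public",
    children_per_household: int = 1,
) -> list[ChildRecord]:
    """Draw child-level fever and treatment responses from the 3PL model.

    Each sampled household contributes ``children_per_household`` under-5
    children. Fever is Bernoulli(``fever_prevalence``); for fever cases, the
    treatment-seeking response is Bernoulli of the 3PL probability at the
    cluster's travel time (minutes, read from ``travel_time`` at the published
    coordinates) and residence. A ``missing_rate`` share of fever-case
    responses is set missing (don't-know answers); children without fever are
    never asked and carry no response.
    """
    rng = np.random.default_rng(seed)
    children: list[ChildRecord] = []
    cid = 0
    for cl in clusters:
        try:
            t = travel_time.value_at(*cl.published_coords)
        except ValueError as exc:
            raise ValueError(
                f"cluster {cl.cluster_id} outside travel-time raster: {exc}"
            ) from exc
        if np.isnan(t):
            raise ValueError(
                f"cluster {cl.cluster_id} falls on a nodata travel-time cell"
            )
        urban = int(cl.residence == "urban")
        p = float(params.response_probability(t, urban))
        for _ in range(cl.n_households * children_per_household):
            fever = int(rng.random() < params.fever_prevalence)
            if fever:
                y = float(rng.random() < p)
                if rng.random() < params.missing_rate:
                    y = np.nan
            else:
                y = np.nan
            children.append(
                ChildRecord(cid, cl.cluster_id, fever, y, item_id, float(t), urban)
            )
            cid += 1
    return children


def clusters_to_frame(clusters: list[ClusterRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "true_x": [c.true_coords[0] for c in clusters],
            "true_y": [c.true_coords[1] for c in clusters],
            "x": [c.published_coords[0] for c in clusters],
            "y": [c.published_coords[1] for c in clusters],
            "residence": [c.residence for c in clusters],
            "n_households": [c.n_households for c in clusters],
        }
    )


def children_to_frame(children: list[ChildRecord]) -> pd.DataFrame:
    """Child-level analysis table (one row per child; y is NaN when missing)."""
    return pd.DataFrame(
        {
            "child_id": [c.child_id for c in children],
            "cluster_id": [c.cluster_id for c in children],
            "fever": [c.fever for c in children],
            "y": [c.response for c in children],
            "item_id": [c.item_id for c in children],
            "travel_time_min": [c.travel_time_min for c in children],
            "urban": [c.urban for c in children],
        }
    )
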