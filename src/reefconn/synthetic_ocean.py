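"""Synthetic ocean, reef and gene-flow generators.

Every input the dispersal pipeline needs can be generated here: analytic
surface-velocity fields (uniform flow, solid-body rotation, the classic
double gyre), reef grids with named reef groups, spawning calendars
restricted to a spawning season, and planted-structure site-to-site
migration-rate ("gene flow") matrices of the kind produced by Bayesian
assignment methods.

All generators are pure functions of their parameters and a seed: calling
one twice with identical arguments yields byte-identical output.  A single
master seed can be split deterministically per generator with
:func:`split_seed`.

Geometry is flat Cartesian metres by default; velocities are in m s^-1 and
times in days.  Land is represented as zero-velocity cells plus a boolean
mask, and reef cells are always ocean cells.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0

#: Reference date that maps calendar dates onto the field's numeric time
#: axis ("days since epoch").
EPOCH = pd.Timestamp("2000-01-01")

__all__ = [
    "SECONDS_PER_DAY",
    "EPOCH",
    "split_seed",
    "GridSpec",
    "VelocityField",
    "ReefGrid",
    "SpawningCalendar",
    "GeneFlowMatrix",
    "make_uniform_field",
    "make_solid_body_rotation",
    "make_double_gyre",
    "make_reef_grid",
    "make_spawning_calendar",
    "make_synthetic_geneflow",
]


def split_seed(master_seed: int, name: str) -> int:
    """Derive a per-generator child seed from a single master seed.

    The child is a deterministic function of ``(master_seed, name)`` and is
    kept below 2**31 so it is safe for any downstream RNG.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# Grid specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Rectangular cell grid: ``nx`` x ``ny`` cells over a Cartesian box.

    Coordinates are metres unless ``geometry='spherical'``, in which case the
    axes are degrees longitude/latitude and velocity-to-displacement
    conversion applies the standard cos(latitude) metric.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    nx: int
    ny: int
    geometry: str = "cartesian"

    def __post_init__(self):
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("grid extent must be non-degenerate and increasing")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")
        if self.geometry not in ("cartesian", "spherical"):
            raise ValueError(f"unknown geometry {self.geometry!r}")

    @property
    def x_edges(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.nx + 1)

    @property
    def y_edges(self) -> np.ndarray:
        return np.linspace(self.y_min, self.y_max, self.ny + 1)

    @property
    def x_centres(self) -> np.ndarray:
        e = self.x_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def y_centres(self) -> np.ndarray:
        e = self.y_edges
        return 0.5 * (e[:-1] + e[1:])

    def cell_area(self) -> np.ndarray:
        """Cell areas in m^2, shape (ny, nx)."""
        if self.geometry == "cartesian":
            dx = np.diff(self.x_edges)
            dy = np.diff(self.y_edges)
            return np.outer(dy, dx)
        # Spherical: A = R^2 * dlam * (sin(phi2) - sin(phi1))
        r_earth = 6371000.0
        dlam = np.deg2rad(np.diff(self.x_edges))
        sinphi = np.sin(np.deg2rad(self.y_edges))
        dphi = np.diff(sinphi)
        return r_earth**2 * np.outer(dphi, dlam)


def _check_axes(x_edges: np.ndarray, y_edges: np.ndarray) -> None:
    for name, e in (("lon_edges", x_edges), ("lat_edges", y_edges)):
        if e.ndim != 1 or len(e) < 2 or not np.all(np.diff(e) > 0):
            raise ValueError(f"{name} must be 1-D, length >= 2 and strictly increasing")


# ---------------------------------------------------------------------------
# Velocity fields
# ---------------------------------------------------------------------------


@dataclass
class VelocityField:
    """Gridded surface currents u, v on (time, lat, lon) in m s^-1.

    ``times`` are days since :data:`EPOCH`.  For steady fields a single time
    slice is stored.  If ``time_periodic`` is set, the field repeats with
    ``period`` days and query times are wrapped modulo the period.
    Velocities are zero on land cells.
    """

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    land: np.ndarray  # bool (ny, nx)
    geometry: str = "cartesian"
    time_periodic: bool = False
    period: float | None = None

    def __post_init__(self):
        self.lon_edges = np.asarray(self.lon_edges, dtype=float)
        self.lat_edges = np.asarray(self.lat_edges, dtype=float)
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        _check_axes(self.lon_edges, self.lat_edges)
        ny, nx = len(self.lat_edges) - 1, len(self.lon_edges) - 1
        expect = (len(self.times), ny, nx)
        if self.u.shape != expect or self.v.shape != expect:
            raise ValueError(
                f"u/v shape {self.u.shape} inconsistent with axes {expect}"
            )
        if self.land.shape != (ny, nx):
            raise ValueError("land mask shape inconsistent with axes")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
                raise ValueError("time step must be uniform")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("velocity fields must be finite everywhere")
        if np.any(self.u[:, self.land] != 0) or np.any(self.v[:, self.land] != 0):
            raise ValueError("velocity must be zero on land cells")
        if self.time_periodic and (self.period is None or self.period <= 0):
            raise ValueError("time_periodic fields need a positive period")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.lat_edges) - 1, len(self.lon_edges) - 1)

    @property
    def lon_centres(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    @property
    def lat_centres(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    # -- NetCDF round trip --------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            data_vars={
                "u": (("time", "lat", "lon"), self.u),
                "v": (("time", "lat", "lon"), self.v),
                "land": (("lat", "lon"), self.land.astype(np.int8)),
                "lon_edges": (("lon_edge",), self.lon_edges),
                "lat_edges": (("lat_edge",), self.lat_edges),
            },
            coords={
                "time": self.times,
                "lat": self.lat_centres,
                "lon": self.lon_centres,
            },
            attrs={
                "geometry": self.geometry,
                "time_periodic": int(self.time_periodic),
                "period": -1.0 if self.period is None else float(self.period),
                "time_units": f"days since {EPOCH.date()}",
                "velocity_units": "m s-1",
            },
        )
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "VelocityField":
        period = float(ds.attrs["period"])
        return cls(
            lon_edges=ds["lon_edges"].values,
            lat_edges=ds["lat_edges"].values,
            times=ds["time"].values,
            u=ds["u"].values,
            v=ds["v"].values,
            land=ds["land"].values.astype(bool),
            geometry=str(ds.attrs["geometry"]),
            time_periodic=bool(int(ds.attrs["time_periodic"])),
            period=None if period < 0 else period,
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "VelocityField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def _empty_land(grid: GridSpec) -> np.ndarray:
    return np.zeros((grid.ny, grid.nx), dtype=bool)


def make_uniform_field(
    speed: float,
    bearing: float,
    grid: GridSpec,
    land: np.ndarray | None = None,
) -> VelocityField:
    """Spatially and temporally constant flow.

    ``bearing`` follows the compass convention: 0 deg = northward (+v),
    90 deg = eastward (+u).  Land cells (if given) are forced to zero.
    """
    if speed < 0:
        raise ValueError("speed must be >= 0")
    land = _empty_land(grid) if land is None else np.asarray(land, dtype=bool)
    theta = np.deg2rad(bearing)
    u0, v0 = speed * np.sin(theta), speed * np.cos(theta)
    u = np.full((1, grid.ny, grid.nx), u0)
    v = np.full((1, grid.ny, grid.nx), v0)
    u[:, land] = 0.0
    v[:, land] = 0.0
    return VelocityField(
        grid.x_edges, grid.y_edges, np.array([0.0]), u, v, land, grid.geometry
    )


def make_solid_body_rotation(
    omega: float,
    centre: tuple[float, float],
    grid: GridSpec,
) -> VelocityField:
    """Solid-body rotation about ``centre``: u = -omega*(y-y0), v = omega*(x-x0).

    ``omega`` is the angular velocity in rad day^-1 (stored velocities are
    converted to m s^-1); a particle at radius r orbits with period
    2*pi/omega days.  Useful as an analytic orbit oracle: trajectories are
    circles and the streamfunction is omega*r^2/2.
    """
    x0, y0 = centre
    xc, yc = np.meshgrid(grid.x_centres, grid.y_centres)
    u = (-omega * (yc - y0) / SECONDS_PER_DAY)[None, :, :]
    v = (omega * (xc - x0) / SECONDS_PER_DAY)[None, :, :]
    land = _empty_land(grid)
    return VelocityField(
        grid.x_edges, grid.y_edges, np.array([0.0]), u, v, land, grid.geometry
    )


def _double_gyre_uv(
    amplitude: float,
    perturbation: float,
    grid: GridSpec,
    t_days: np.ndarray,
    period: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the double-gyre velocity at cell centres for given times.

    Streamfunction psi = (U*Ly/pi) sin(pi f(xs, t)) sin(pi ys) on the unit
    rectangle xs in [0, 2], ys in [0, 1], with
    f = eps*sin(wt)*xs^2 + (1 - 2 eps sin(wt)) xs.  ``amplitude`` is the
    maximum zonal speed U in m s^-1.  eps = 0 gives two steady
    counter-rotating cells separated by an impermeable mid-domain line.
    """
    lx = grid.x_max - grid.x_min
    ly = grid.y_max - grid.y_min
    xs = 2.0 * (grid.x_centres - grid.x_min) / lx  # [0, 2]
    ys = (grid.y_centres - grid.y_min) / ly  # [0, 1]
    xg, yg = np.meshgrid(xs, ys)
    w = 2.0 * np.pi / period
    u = np.empty((len(t_days), grid.ny, grid.nx))
    v = np.empty_like(u)
    for k, t in enumerate(t_days):
        s = perturbation * np.sin(w * t)
        f = s * xg**2 + (1.0 - 2.0 * s) * xg
        dfdx = 2.0 * s * xg + (1.0 - 2.0 * s)
        u[k] = -amplitude * np.sin(np.pi * f) * np.cos(np.pi * yg)
        v[k] = amplitude * (2.0 * ly / lx) * dfdx * np.cos(np.pi * f) * np.sin(np.pi * yg)
    return u, v


def make_double_gyre(
    amplitude: float,
    perturbation: float,
    grid: GridSpec,
    period: float = 10.0,
    n_time: int = 40,
) -> VelocityField:
    """Two counter-rotating gyres with an optionally leaky separatrix.

    With ``perturbation`` = 0 the field is steady and the mid-domain line is
    an exact transport barrier (closed streamlines either side); with
    ``perturbation`` > 0 the separatrix oscillates with ``period`` days and
    a weak inter-gyre exchange appears.  The field is divergence-free (it
    derives from a streamfunction).

    ``amplitude`` must be > 0; use it as the peak speed in m s^-1.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if perturbation == 0:
        times = np.array([0.0])
        u, v = _double_gyre_uv(amplitude, 0.0, grid, times, period)
        return VelocityField(
            grid.x_edges, grid.y_edges, times, u, v, _empty_land(grid), grid.geometry
        )
    times = np.arange(n_time) * (period / n_time)
    u, v = _double_gyre_uv(amplitude, perturbation, grid, times, period)
    return VelocityField(
        grid.x_edges,
        grid.y_edges,
        times,
        u,
        v,
        _empty_land(grid),
        grid.geometry,
        time_periodic=True,
        period=period,
    )


# ---------------------------------------------------------------------------
# Reef grid
# ---------------------------------------------------------------------------


@dataclass
class ReefGrid:
    """Per-cell reef fraction F_r, cell area A_i and reef-group labels.

    ``group_id`` is -1 on non-reef cells and a non-negative integer on reef
    cells; F_r = 0 exactly where group_id = -1.  Shares the spatial axes of
    the :class:`VelocityField` it accompanies.
    """

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    reef_fraction: np.ndarray  # (ny, nx) in [0, 1]
    cell_area: np.ndarray  # (ny, nx) m^2, > 0
    group_id: np.ndarray  # (ny, nx) int, -1 = non-reef
    geometry: str = "cartesian"

    def __post_init__(self):
        _check_axes(self.lon_edges, self.lat_edges)
        fr, gid = self.reef_fraction, self.group_id
        if fr.shape != gid.shape or fr.shape != self.cell_area.shape:
            raise ValueError("reef arrays must share one shape")
        if np.any((fr < 0) | (fr > 1)):
            raise ValueError("reef_fraction must lie in [0, 1]")
        if np.any(self.cell_area <= 0):
            raise ValueError("all cell areas must be positive")
        if not np.array_equal(fr > 0, gid >= 0):
            raise ValueError("F_r > 0 exactly on cells with group_id >= 0")
        if len(self.group_ids()) < 1:
            raise ValueError("reef grid must contain at least one reef group")

    def group_ids(self) -> np.ndarray:
        gids = np.unique(self.group_id)
        return gids[gids >= 0]

    def reef_cells(self) -> np.ndarray:
        """(n_cells, 2) array of (iy, ix) indices of reef cells, row-major order."""
        return np.argwhere(self.reef_fraction > 0)

    def group_of_cells(self, cells: np.ndarray) -> np.ndarray:
        return self.group_id[cells[:, 0], cells[:, 1]]

    def group_centroids(self) -> pd.DataFrame:
        """Unweighted mean of member cell centres per group (columns x, y)."""
        xc = 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])
        yc = 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])
        rows = []
        for g in self.group_ids():
            iy, ix = np.nonzero(self.group_id == g)
            rows.append((int(g), float(np.mean(xc[ix])), float(np.mean(yc[iy]))))
        return pd.DataFrame(rows, columns=["group", "x", "y"]).set_index("group")

    def group_areas(self) -> pd.Series:
        """Total source-cell area per group (the release weight rho*A_i sums over)."""
        out = {}
        for g in self.group_ids():
            mask = self.group_id == g
            out[int(g)] = float(self.cell_area[mask].sum())
        return pd.Series(out, name="area")

    def to_dataset(self) -> xr.Dataset:
        xc = 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])
        yc = 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])
        return xr.Dataset(
            data_vars={
                "reef_fraction": (("lat", "lon"), self.reef_fraction),
                "cell_area": (("lat", "lon"), self.cell_area),
                "group_id": (("lat", "lon"), self.group_id.astype(np.int32)),
                "lon_edges": (("lon_edge",), self.lon_edges),
                "lat_edges": (("lat_edge",), self.lat_edges),
            },
            coords={"lat": yc, "lon": xc},
            attrs={"geometry": self.geometry, "area_units": "m2"},
        )

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "ReefGrid":
        return cls(
            lon_edges=ds["lon_edges"].values,
            lat_edges=ds["lat_edges"].values,
            reef_fraction=ds["reef_fraction"].values,
            cell_area=ds["cell_area"].values,
            group_id=ds["group_id"].values.astype(int),
            geometry=str(ds.attrs["geometry"]),
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "ReefGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def make_reef_grid(
    cluster_centres: list[tuple[float, float]],
    cells_per_cluster: int,
    grid: GridSpec,
    seed: int,
    fr_beta: tuple[float, float] = (2.0, 2.0),
    land: np.ndarray | None = None,
) -> ReefGrid:
    """Plant reef-cell clusters around the given centres.

    Each cluster claims the ``cells_per_cluster`` ocean cells nearest its
    centre; reef fractions are drawn from a Beta(*fr_beta*) distribution on
    (0, 1].  If two clusters claim a common cell their groups are merged
    (with a logged warning).  Deterministic under ``seed``.
    """
    if len(cluster_centres) == 0:
        raise ValueError("at least one reef cluster is required")
    if cells_per_cluster < 1:
        raise ValueError("cells_per_cluster must be >= 1")
    land = _empty_land(grid) if land is None else np.asarray(land, dtype=bool)
    xc, yc = np.meshgrid(grid.x_centres, grid.y_centres)
    rng = np.random.default_rng(seed)

    for cx, cy in cluster_centres:
        if not (grid.x_min <= cx <= grid.x_max and grid.y_min <= cy <= grid.y_max):
            raise ValueError(f"cluster centre ({cx}, {cy}) lies outside the domain")

    group_id = np.full((grid.ny, grid.nx), -1, dtype=int)
    merged_into: dict[int, int] = {}
    for g, (cx, cy) in enumerate(cluster_centres):
        d2 = (xc - cx) ** 2 + (yc - cy) ** 2
        d2[land] = np.inf
        order = np.argsort(d2, axis=None, kind="stable")[:cells_per_cluster]
        iy, ix = np.unravel_index(order, d2.shape)
        target = g
        taken = group_id[iy, ix]
        clash = taken[taken >= 0]
        if clash.size:
            target = int(np.min(clash))
            logger.warning(
                "reef clusters overlap: merging group %d into group %d", g, target
            )
            merged_into[g] = target
        group_id[iy, ix] = np.where(taken >= 0, np.minimum(taken, target), target)

    reef = group_id >= 0
    fr = np.zeros((grid.ny, grid.nx))
    a, b = fr_beta
    draws = rng.beta(a, b, size=int(reef.sum()))
    fr[reef] = np.maximum(draws, 1e-6)  # keep F_r strictly positive on reef cells
    return ReefGrid(
        grid.x_edges, grid.y_edges, fr, grid.cell_area(), group_id, grid.geometry
    )


# ---------------------------------------------------------------------------
# Spawning calendar
# ---------------------------------------------------------------------------

#: October-March: the austral spawning season used for seasonal subsetting.
SPAWNING_MONTHS = (10, 11, 12, 1, 2, 3)


@dataclass
class SpawningCalendar:
    """Release dates, all falling within the allowed spawning months."""

    dates: pd.DatetimeIndex
    months_allowed: tuple[int, ...] = SPAWNING_MONTHS

    def __post_init__(self):
        self.dates = pd.DatetimeIndex(self.dates)
        if len(self.dates) == 0:
            raise ValueError("calendar contains no dates")
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValueError("dates must be strictly increasing")
        bad = set(self.dates.month) - set(self.months_allowed)
        if bad:
            raise ValueError(f"dates fall in disallowed months: {sorted(bad)}")

    def offsets(self, epoch: pd.Timestamp = EPOCH) -> np.ndarray:
        """Days since ``epoch`` for each date."""
        return ((self.dates - epoch) / pd.Timedelta(days=1)).to_numpy(float)

    def to_yaml_dict(self) -> dict:
        return {
            "dates": [d.strftime("%Y-%m-%d") for d in self.dates],
            "months_allowed": list(self.months_allowed),
        }

    @classmethod
    def from_yaml_dict(cls, d: dict) -> "SpawningCalendar":
        return cls(
            pd.DatetimeIndex([pd.Timestamp(s) for s in d["dates"]]),
            tuple(d["months_allowed"]),
        )


def make_spawning_calendar(
    start: str,
    end: str,
    months_allowed: tuple[int, ...] = SPAWNING_MONTHS,
    every: int = 1,
) -> SpawningCalendar:
    """Daily spawning dates between ``start`` and ``end`` (inclusive),
    restricted to ``months_allowed``; ``every`` thins to every n-th date."""
    all_days = pd.date_range(start, end, freq="D")
    keep = all_days[all_days.month.isin(months_allowed)]
    if every > 1:
        keep = keep[::every]
    return SpawningCalendar(keep, tuple(months_allowed))


# ---------------------------------------------------------------------------
# Gene-flow matrices
# ---------------------------------------------------------------------------


@dataclass
class GeneFlowMatrix:
    """Site-by-site per-generation migration rates.

    ``m[i, j]`` is the fraction of population i derived from population j
    per generation (BayesAss orientation); rows sum to 1 and the diagonal is
    self-recruitment.
    """

    site_names: list[str]
    m: np.ndarray

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        n = len(self.site_names)
        if self.m.shape != (n, n):
            raise ValueError("matrix shape must match the number of sites")
        if np.any((self.m < 0) | (self.m > 1)):
            raise ValueError("migration rates must lie in [0, 1]")
        if not np.allclose(self.m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each row must sum to 1 within 1e-6")

    @property
    def self_recruitment(self) -> np.ndarray:
        return np.diag(self.m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.m, index=self.site_names, columns=self.site_names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="site")

    @classmethod
    def from_csv(cls, path) -> "GeneFlowMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        if list(df.index) != list(df.columns):
            raise ValueError("gene-flow CSV must have identical row/column site names")
        return cls(list(df.index), df.to_numpy(float))


def make_synthetic_geneflow(
    n_sites: int,
    self_recruitment: float,
    structure: np.ndarray | list[int] | None = None,
    noise: float = 0.0,
    seed: int = 0,
    within_between_ratio: float = 4.0,
    site_names: list[str] | None = None,
) -> GeneFlowMatrix:
    """Planted-structure migration-rate matrix.

    The diagonal is ``self_recruitment`` (high self-recruitment, 0.77-0.84,
    is typical of assignment-based estimates on reef corals); the remaining
    row mass is spread over the other sites, biased by
    ``within_between_ratio`` towards pairs sharing a block of ``structure``
    (a length-``n_sites`` partition labelling).  ``noise`` perturbs the
    off-diagonal weights multiplicatively (log-normal with sigma = noise)
    before each row is renormalised to sum exactly to 1.
    """
    if not (0.0 < self_recruitment < 1.0):
        raise ValueError("self_recruitment must lie strictly in (0, 1)")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    if n_sites < 2:
        raise ValueError("need at least two sites")
    labels = (
        np.zeros(n_sites, dtype=int)
        if structure is None
        else np.asarray(structure, dtype=int)
    )
    if labels.shape != (n_sites,):
        raise ValueError("structure must be one block label per site")
    rng = np.random.default_rng(seed)
    same = labels[:, None] == labels[None, :]
    w = np.where(same, within_between_ratio, 1.0).astype(float)
    np.fill_diagonal(w, 0.0)
    if noise > 0:
        w *= np.exp(noise * rng.standard_normal(w.shape))
    off = (1.0 - self_recruitment) * w / w.sum(axis=1, keepdims=True)
    m = off + np.diag(np.full(n_sites, self_recruitment))
    names = site_names or [f"site_{i:02d}" for i in range(n_sites)]
    return GeneFlowMatrix(list(names), m)
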