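"""Lagrangian advection of passive surface particles.

Virtual larvae are modelled as positively buoyant, otherwise passive
surface drifters: each particle is released at a reef cell and integrated
through the gridded velocity field with fixed-step fourth-order
Runge-Kutta, bilinear interpolation in space (between cell centres, edge
values clamped) and linear interpolation in time.

Boundary policy: a particle whose occupied cell is land sticks there with
zero velocity (its fate dynamics keep running); a particle leaving the open
domain boundary is frozen at its last position and flagged, and the rest of
its series is treated as off-reef.  Cell occupancy uses 0-based indices and
half-open intervals [edge_k, edge_{k+1}) on both axes.

All of this is deterministic given (field, release set, dt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .synthetic_ocean import EPOCH, SECONDS_PER_DAY, ReefGrid, VelocityField

__all__ = [
    "ReleaseSet",
    "TrajectorySet",
    "release_from_reefs",
    "advect",
    "occupied_cells",
    "sample_reef_fraction",
]


# ---------------------------------------------------------------------------
# Releases
# ---------------------------------------------------------------------------


@dataclass
class ReleaseSet:
    """Particles to release on one spawning date.

    ``source_cells`` holds one (iy, ix) row per particle (a cell releasing N
    particles appears N times); ``positions`` the matching start positions.
    """

    source_cells: np.ndarray  # (n, 2) int (iy, ix)
    positions: np.ndarray  # (n, 2) float (x, y)
    particles_per_cell: int
    release_date: pd.Timestamp

    def __post_init__(self):
        self.source_cells = np.asarray(self.source_cells, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.particles_per_cell < 1:
            raise ValueError("particles_per_cell must be >= 1")
        if len(self.source_cells) != len(self.positions):
            raise ValueError("one position per particle required")

    @property
    def n_particles(self) -> int:
        return len(self.positions)


def release_from_reefs(
    reef: ReefGrid,
    n_per_cell: int,
    release_date,
    jitter: float = 0.0,
    seed: int | None = None,
) -> ReleaseSet:
    """Release ``n_per_cell`` particles from every reef cell.

    Default positions are cell centres; ``jitter`` in (0, 1] spreads them
    uniformly over that fraction of the cell (seeded, reproducible).
    """
    cells = reef.reef_cells()
    if len(cells) == 0:
        raise ValueError("reef grid has no reef cells")
    xc = 0.5 * (reef.lon_edges[:-1] + reef.lon_edges[1:])
    yc = 0.5 * (reef.lat_edges[:-1] + reef.lat_edges[1:])
    cells_rep = np.repeat(cells, n_per_cell, axis=0)
    pos = np.column_stack([xc[cells_rep[:, 1]], yc[cells_rep[:, 0]]])
    if jitter > 0:
        rng = np.random.default_rng(seed)
        dx = np.diff(reef.lon_edges)[cells_rep[:, 1]]
        dy = np.diff(reef.lat_edges)[cells_rep[:, 0]]
        pos[:, 0] += jitter * dx * (rng.random(len(pos)) - 0.5)
        pos[:, 1] += jitter * dy * (rng.random(len(pos)) - 0.5)
    return ReleaseSet(cells_rep, pos, n_per_cell, pd.Timestamp(release_date))


# ---------------------------------------------------------------------------
# Velocity sampling
# ---------------------------------------------------------------------------


def _interp_axis(
    centres: np.ndarray, q: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bracketing index pair and weight for 1-D linear interpolation with
    clamped ends; a single-cell axis degenerates to nearest sampling."""
    if len(centres) == 1:
        z = np.zeros(len(q), dtype=int)
        return z, z, np.zeros(len(q))
    i = np.searchsorted(centres, q) - 1
    i = np.clip(i, 0, len(centres) - 2)
    w = (q - centres[i]) / (centres[i + 1] - centres[i])
    return i, i + 1, np.clip(w, 0.0, 1.0)


class _FieldSampler:
    """Vectorised velocity sampler returning m/day displacement rates."""

    def __init__(self, field: VelocityField):
        self.f = field
        self.xc = field.lon_centres
        self.yc = field.lat_centres
        self.nt = len(field.times)

    def _time_bracket(self, t_abs: float) -> tuple[int, int, float]:
        f = self.f
        if self.nt == 1:
            return 0, 0, 0.0
        if f.time_periodic:
            tq = (t_abs - f.times[0]) % f.period + f.times[0]
            step = f.times[1] - f.times[0]
            k = int((tq - f.times[0]) // step)
            k = min(k, self.nt - 1)
            w = (tq - f.times[k]) / step
            return k, (k + 1) % self.nt, float(np.clip(w, 0.0, 1.0))
        tq = np.clip(t_abs, f.times[0], f.times[-1])
        k = int(np.searchsorted(f.times, tq, side="right")) - 1
        k = min(max(k, 0), self.nt - 2)
        w = (tq - f.times[k]) / (f.times[k + 1] - f.times[k])
        return k, k + 1, float(w)

    def velocity(self, t_abs: float, pos: np.ndarray) -> np.ndarray:
        """(n, 2) velocity in metres per day at absolute time ``t_abs`` days."""
        k0, k1, wt = self._time_bracket(t_abs)
        ix0, ix1, wx = _interp_axis(self.xc, pos[:, 0])
        iy0, iy1, wy = _interp_axis(self.yc, pos[:, 1])

        def bilinear(a):
            return (
                a[iy0, ix0] * (1 - wx) * (1 - wy)
                + a[iy0, ix1] * wx * (1 - wy)
                + a[iy1, ix0] * (1 - wx) * wy
                + a[iy1, ix1] * wx * wy
            )

        out = np.empty_like(pos)
        for comp, arr in ((0, self.f.u), (1, self.f.v)):
            plane = bilinear(arr[k0])
            if wt > 0.0:
                plane = (1 - wt) * plane + wt * bilinear(arr[k1])
            out[:, comp] = plane
        if not np.isfinite(out).all():
            bad = np.argwhere(~np.isfinite(out))[0, 0]
            raise FloatingPointError(
                f"NaN velocity encountered at position {pos[bad]} (cell "
                f"iy={np.searchsorted(self.f.lat_edges, pos[bad, 1], 'right') - 1}, "
                f"ix={np.searchsorted(self.f.lon_edges, pos[bad, 0], 'right') - 1})"
            )
        return out * SECONDS_PER_DAY


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class TrajectorySet:
    """Fixed-step trajectories for one release.

    ``times`` are days since release (uniform step ``dt``); ``positions``
    has shape (n_particles, n_steps + 1, 2).  ``exit_step[p]`` is the step
    index at which particle p left the open boundary (or n_steps if it never
    did): positions from there on are frozen and the series counts as
    off-reef.  ``stuck_step`` records first contact with land, with the same
    sentinel.
    """

    times: np.ndarray
    positions: np.ndarray
    source_cells: np.ndarray
    release_date: pd.Timestamp
    dt: float
    exit_step: np.ndarray
    stuck_step: np.ndarray
    particles_per_cell: int

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_steps(self) -> int:
        return len(self.times) - 1

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            data_vars={
                "x": (("particle", "step"), self.positions[:, :, 0]),
                "y": (("particle", "step"), self.positions[:, :, 1]),
                "source_iy": (("particle",), self.source_cells[:, 0].astype(np.int32)),
                "source_ix": (("particle",), self.source_cells[:, 1].astype(np.int32)),
                "exit_step": (("particle",), self.exit_step.astype(np.int32)),
                "stuck_step": (("particle",), self.stuck_step.astype(np.int32)),
            },
            coords={"step": np.arange(len(self.times)), "time_days": ("step", self.times)},
            attrs={
                "dt_days": self.dt,
                "t_max_days": float(self.times[-1]),
                "release_date": self.release_date.strftime("%Y-%m-%d"),
                "particles_per_cell": self.particles_per_cell,
            },
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "TrajectorySet":
        pos = np.stack([ds["x"].values, ds["y"].values], axis=-1)
        return cls(
            times=ds["time_days"].values,
            positions=pos,
            source_cells=np.column_stack(
                [ds["source_iy"].values, ds["source_ix"].values]
            ).astype(int),
            release_date=pd.Timestamp(ds.attrs["release_date"]),
            dt=float(ds.attrs["dt_days"]),
            exit_step=ds["exit_step"].values.astype(int),
            stuck_step=ds["stuck_step"].values.astype(int),
            particles_per_cell=int(ds.attrs["particles_per_cell"]),
        )

    @classmethod
    def from_netcdf(cls, path) -> "TrajectorySet":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def occupied_cells(
    positions: np.ndarray, lon_edges: np.ndarray, lat_edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell indices (iy, ix) occupied by each position; half-open intervals.

    Returns (iy, ix, inside) where ``inside`` flags positions within the
    domain.  Out-of-domain positions get index -1.
    """
    ix = np.searchsorted(lon_edges, positions[..., 0], side="right") - 1
    iy = np.searchsorted(lat_edges, positions[..., 1], side="right") - 1
    inside = (
        (ix >= 0)
        & (ix < len(lon_edges) - 1)
        & (iy >= 0)
        & (iy < len(lat_edges) - 1)
    )
    return np.where(inside, iy, -1), np.where(inside, ix, -1), inside


def advect(
    field: VelocityField,
    release: ReleaseSet,
    dt: float = 0.02,
    t_max: float = 120.0,
) -> TrajectorySet:
    """Integrate all particles of a release through the field.

    ``dt`` and ``t_max`` are in days (defaults: 0.02 d step, 120 d drift).
    Classic RK4; the absolute field time of trajectory time t is
    ``(release_date - epoch) + t`` days, wrapped for periodic fields.
    """
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be positive")
    n_steps = int(round(t_max / dt))
    sampler = _FieldSampler(field)
    pos = release.positions.copy()

    _, _, inside0 = occupied_cells(pos, field.lon_edges, field.lat_edges)
    if not inside0.all():
        bad = np.argwhere(~inside0)[0, 0]
        raise ValueError(f"release position {pos[bad]} lies outside the domain")

    t0 = (release.release_date - EPOCH) / pd.Timedelta(days=1)
    times = np.arange(n_steps + 1) * dt
    out = np.empty((release.n_particles, n_steps + 1, 2))
    out[:, 0] = pos
    sentinel = n_steps
    exit_step = np.full(release.n_particles, sentinel, dtype=int)
    stuck_step = np.full(release.n_particles, sentinel, dtype=int)
    active = np.ones(release.n_particles, dtype=bool)

    def land_contact(p: np.ndarray) -> np.ndarray:
        iy, ix, inside = occupied_cells(p, field.lon_edges, field.lat_edges)
        hit = np.zeros(len(p), dtype=bool)
        hit[inside] = field.land[iy[inside], ix[inside]]
        return hit

    stuck = land_contact(pos)
    stuck_step[stuck] = 0
    active &= ~stuck

    for k in range(n_steps):
        t = t0 + times[k]
        if active.any():
            idx = np.nonzero(active)[0]
            p = pos[idx]
            k1 = sampler.velocity(t, p)
            k2 = sampler.velocity(t + dt / 2, p + 0.5 * dt * k1)
            k3 = sampler.velocity(t + dt / 2, p + 0.5 * dt * k2)
            k4 = sampler.velocity(t + dt, p + dt * k3)
            newp = p + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

            _, _, inside = occupied_cells(newp, field.lon_edges, field.lat_edges)
            exited = ~inside
            newp[exited] = p[exited]  # freeze at last in-domain position
            exit_step[idx[exited]] = k + 1
            pos[idx] = newp
            active[idx[exited]] = False

            still = idx[~exited]
            if len(still):
                hit = land_contact(pos[still])
                stuck_step[still[hit]] = k + 1
                active[still[hit]] = False
        out[:, k + 1] = pos

    return TrajectorySet(
        times=times,
        positions=out,
        source_cells=release.source_cells,
        release_date=release.release_date,
        dt=dt,
        exit_step=exit_step,
        stuck_step=stuck_step,
        particles_per_cell=release.particles_per_cell,
    )


def sample_reef_fraction(traj: TrajectorySet, reef: ReefGrid) -> np.ndarray:
    """Reef fraction F_r of the occupied cell, per particle and step.

    Off-reef and out-of-domain steps return 0; steps after a particle has
    exited the open boundary return 0 (its drift is truncated there).
    Shape (n_particles, n_steps + 1).
    """
    iy, ix, inside = occupied_cells(traj.positions, reef.lon_edges, reef.lat_edges)
    fr = np.zeros(traj.positions.shape[:2])
    fr[inside] = reef.reef_fraction[iy[inside], ix[inside]]
    step_idx = np.arange(fr.shape[1])[None, :]
    fr[step_idx > traj.exit_step[:, None]] = 0.0
    return fr


def occupied_cell_flat(traj: TrajectorySet, reef: ReefGrid) -> np.ndarray:
    """Flat cell index (iy * nx + ix) per particle/step; -1 out of domain or
    after boundary exit.  Used to split settling events on cell change."""
    iy, ix, inside = occupied_cells(traj.positions, reef.lon_edges, reef.lat_edges)
    nx = len(reef.lon_edges) - 1
    flat = np.where(inside, iy * nx + ix, -1)
    step_idx = np.arange(flat.shape[1])[None, :]
    flat[step_idx > traj.exit_step[:, None]] = -1
    return flat
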