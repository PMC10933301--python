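"""Potential-connectivity matrices and the stochastic bootstrap ensemble.

Settling events are accumulated into a source-by-destination matrix per
spawning date: C[i, j] is the probability that a larva produced at reef
unit i (cell or reef group) settles at unit j during one spawning event.
Dated matrices are subset to the spawning season (October-March by
default), then resampled into a bootstrap ensemble of short-term
connectivity matrices, each the arithmetic mean of k randomly chosen
spawning events.  Two summaries of a matrix are provided: the
distance-decay table, and a generations-to-common-ancestor bound derived
from the thresholded connectivity graph.

Matrix orientation is fixed throughout as C[source, destination] and every
file written carries an explicit axis attribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.sparse.csgraph import shortest_path

from .advection import ReleaseSet
from .synthetic_ocean import SPAWNING_MONTHS, ReefGrid

__all__ = [
    "ConnectivityMatrix",
    "BootstrapEnsemble",
    "accumulate",
    "aggregate_to_groups",
    "seasonal_subset",
    "bootstrap_ensemble",
    "distance_decay",
    "generations_to_common_ancestor",
]


@dataclass
class ConnectivityMatrix:
    """Source x destination settlement probabilities for one spawning date.

    ``labels`` are flat cell indices (level='cell') or group ids
    (level='group'); rows sum to at most 1 (a source cannot settle more
    larvae than it released).
    """

    values: np.ndarray
    labels: np.ndarray
    level: str
    spawning_date: pd.Timestamp

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square on its labels")
        if np.any(self.values < 0):
            raise ValueError("connectivity entries must be >= 0")
        if np.any(self.values.sum(axis=1) > 1 + 1e-9):
            raise ValueError("row sums exceed 1: settled cannot exceed released")
        if self.level not in ("cell", "group"):
            raise ValueError("level must be 'cell' or 'group'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = f"source_{self.level}"
        df.to_csv(path)


def accumulate(
    events: pd.DataFrame,
    release: ReleaseSet,
    reef: ReefGrid,
    level: str = "group",
    rho: float = 1.0,
) -> ConnectivityMatrix:
    """Aggregate one spawning date's settling events into C[i, j].

    C[i, j] = sum of S_j over particles released at i and settling at j,
    divided by the larvae released at i (rho * A_i summed over the source
    cells of unit i).  Deterministic.  At group level every reef cell of a
    group contributes to the release normalisation whether or not any of
    its particles settled.
    """
    nx = len(reef.lon_edges) - 1
    cells = reef.reef_cells()
    cell_flat = cells[:, 0] * nx + cells[:, 1]

    if level == "cell":
        labels = cell_flat
        released = rho * reef.cell_area[cells[:, 0], cells[:, 1]]
        src_key = lambda iy, ix: iy * nx + ix
        dst_key = src_key
    elif level == "group":
        labels = reef.group_ids()
        released = rho * reef.group_areas().loc[labels].to_numpy()
        src_key = lambda iy, ix: reef.group_id[iy, ix]
        dst_key = src_key
    else:
        raise ValueError("level must be 'cell' or 'group'")

    index = {lab: k for k, lab in enumerate(labels)}
    c = np.zeros((len(labels), len(labels)))
    if len(events):
        for (siy, six, diy, dix), s in (
            events.groupby(["source_iy", "source_ix", "dest_iy", "dest_ix"])["S"].sum().items()
        ):
            i = index[src_key(siy, six)]
            dst = dst_key(diy, dix)
            if dst not in index:  # settled on a reef cell outside labelled units
                continue
            c[i, index[dst]] += s
    c /= released[:, None]
    return ConnectivityMatrix(c, np.asarray(labels), level, release.release_date)


def aggregate_to_groups(matrix: ConnectivityMatrix, reef: ReefGrid) -> ConnectivityMatrix:
    """Area-weighted aggregation of a cell-level matrix to reef groups.

    Row weights are the released larvae (proportional to A_i), so group
    totals conserve the cell-level totals exactly and the result equals
    direct group-level accumulation.
    """
    if matrix.level != "cell":
        raise ValueError("input must be a cell-level matrix")
    nx = len(reef.lon_edges) - 1
    cells = reef.reef_cells()
    gids = reef.group_of_cells(cells)
    areas = reef.cell_area[cells[:, 0], cells[:, 1]]
    groups = reef.group_ids()
    gindex = {g: k for k, g in enumerate(groups)}
    n_g = len(groups)
    # map matrix labels (flat cell ids) onto group indices
    flat_to_pos = {f: k for k, f in enumerate(cells[:, 0] * nx + cells[:, 1])}
    order = [flat_to_pos[f] for f in matrix.labels]
    row_g = np.array([gindex[g] for g in gids[order]])
    w = areas[order]

    c_g = np.zeros((n_g, n_g))
    wsum = np.zeros(n_g)
    np.add.at(wsum, row_g, w)
    weighted = matrix.values * w[:, None]
    tmp = np.zeros((n_g, matrix.values.shape[1]))
    np.add.at(tmp, row_g, weighted)
    np.add.at(c_g.T, row_g, tmp.T)  # collapse destination cells into groups
    c_g /= wsum[:, None]
    return ConnectivityMatrix(c_g, groups, "group", matrix.spawning_date)


def seasonal_subset(
    matrices: list[ConnectivityMatrix],
    months: tuple[int, ...] = SPAWNING_MONTHS,
) -> list[ConnectivityMatrix]:
    """Keep only matrices whose spawning month falls in ``months``.

    Raises if nothing survives (the calendar should then be checked).
    """
    kept = [m for m in matrices if m.spawning_date.month in months]
    if not kept:
        raise ValueError(
            f"no spawning dates fall in months {sorted(months)}; check the calendar"
        )
    return kept


@dataclass
class BootstrapEnsemble:
    """Ensemble of short-term connectivity matrices.

    Each replicate is the arithmetic mean of exactly k member matrices
    drawn (with replacement by default) from the seasonal date pool,
    sampling the stochastic oceanographic variability of short-term
    connectivity.
    """

    matrices: np.ndarray  # (n_rep, n, n)
    labels: np.ndarray
    level: str
    member_dates: list[list[pd.Timestamp]]
    seed: int

    @property
    def n_replicates(self) -> int:
        return self.matrices.shape[0]

    def mean(self) -> np.ndarray:
        return self.matrices.mean(axis=0)

    def to_dataset(self) -> xr.Dataset:
        dates = np.array(
            [[d.strftime("%Y-%m-%d") for d in row] for row in self.member_dates]
        )
        return xr.Dataset(
            data_vars={
                "connectivity": (("replicate", "source", "destination"), self.matrices),
                "member_dates": (("replicate", "member"), dates.astype("S10")),
            },
            coords={
                "replicate": np.arange(self.n_replicates),
                "source": self.labels,
                "destination": self.labels,
            },
            attrs={
                "axis_order": "C[source, destination]",
                "level": self.level,
                "seed": self.seed,
            },
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "BootstrapEnsemble":
        raw = ds["member_dates"].values
        dates = [
            [pd.Timestamp(x.decode() if isinstance(x, bytes) else str(x)) for x in row]
            for row in raw
        ]
        return cls(
            matrices=ds["connectivity"].values,
            labels=ds["source"].values,
            level=str(ds.attrs["level"]),
            member_dates=dates,
            seed=int(ds.attrs["seed"]),
        )

    @classmethod
    def from_netcdf(cls, path) -> "BootstrapEnsemble":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def bootstrap_ensemble(
    matrices: list[ConnectivityMatrix],
    n_rep: int = 1000,
    k: int = 10,
    seed: int = 0,
    replace: bool = True,
) -> BootstrapEnsemble:
    """Resample dated matrices into ``n_rep`` mean-of-``k`` replicates.

    Sampling is with replacement across the full date pool (the standard
    bootstrap) unless ``replace=False``, which requires a pool of at least
    k dates.  Seeded and reproducible.
    """
    if not matrices:
        raise ValueError("empty matrix pool")
    if not replace and len(matrices) < k:
        raise ValueError("pool smaller than k with replacement disabled")
    base = matrices[0]
    for m in matrices:
        if m.level != base.level or not np.array_equal(m.labels, base.labels):
            raise ValueError("all matrices must share level and labels")
    stack = np.stack([m.values for m in matrices])
    rng = np.random.default_rng(seed)
    out = np.empty((n_rep, stack.shape[1], stack.shape[2]))
    member_dates = []
    for r in range(n_rep):
        idx = rng.choice(len(matrices), size=k, replace=replace)
        out[r] = stack[idx].mean(axis=0)
        member_dates.append([matrices[i].spawning_date for i in idx])
    return BootstrapEnsemble(out, base.labels.copy(), base.level, member_dates, seed)


def distance_decay(matrix: ConnectivityMatrix, reef: ReefGrid) -> pd.DataFrame:
    """Long-format (source, destination, distance, connectivity) table.

    Distances are symmetric Euclidean separations between group centroids
    (great-circle if the grid is spherical); connectivity stays directed.
    Off-diagonal ordered pairs only.
    """
    if matrix.level != "group":
        raise ValueError("distance decay is defined on group-level matrices")
    cent = reef.group_centroids()
    rows = []
    for a, ga in enumerate(matrix.labels):
        for b, gb in enumerate(matrix.labels):
            if a == b:
                continue
            pa = cent.loc[int(ga)]
            pb = cent.loc[int(gb)]
            if reef.geometry == "spherical":
                d = _great_circle(pa["x"], pa["y"], pb["x"], pb["y"])
            else:
                d = float(np.hypot(pa["x"] - pb["x"], pa["y"] - pb["y"]))
            rows.append((int(ga), int(gb), d, float(matrix.values[a, b])))
    return pd.DataFrame(
        rows, columns=["source", "destination", "distance", "connectivity"]
    )


def _great_circle(lon1, lat1, lon2, lat2) -> float:
    r = 6371000.0
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dl = np.deg2rad(lon2 - lon1)
    x = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    return float(r * np.arccos(np.clip(x, -1.0, 1.0)))


def generations_to_common_ancestor(
    matrix: ConnectivityMatrix, eps: float
) -> pd.DataFrame:
    """Generations until pairs of reef units could share a common ancestor.

    The matrix is read as a per-generation colonisation graph with a
    directed edge source -> destination wherever C[source, destination]
    >= eps.  For a candidate ancestor k, d(k, i) is the BFS step count
    k -> i, with the convention that k is its own ancestor at lag 0 only
    through self-recruitment (C[k, k] >= eps); otherwise d(k, k) is the
    shortest return cycle through k (infinite if none).  Then

        g(i, j) = min over k of max(d(k, i), d(k, j)),

    infinite for pairs with no common reachable source.  Returns a long
    table (i, j, generations) over all ordered pairs.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    adj = (matrix.values >= eps).astype(float)
    n = adj.shape[0]
    dist = shortest_path(adj, method="D", unweighted=True, directed=True)
    # ancestor-of-self distance: 0 with a self-loop, else shortest cycle
    d_self = np.full(n, np.inf)
    for k in range(n):
        if adj[k, k]:
            d_self[k] = 0.0
        else:
            succ = np.nonzero(adj[k])[0]
            if len(succ):
                d_self[k] = 1.0 + dist[succ, k].min()
    d_anc = dist.copy()
    d_anc[np.arange(n), np.arange(n)] = d_self

    rows = []
    for i in range(n):
        for j in range(n):
            g = np.min(np.maximum(d_anc[:, i], d_anc[:, j]))
            rows.append((matrix.labels[i], matrix.labels[j], float(g)))
    return pd.DataFrame(rows, columns=["i", "j", "generations"])
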