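"""Spatial substrate: habitat patches on a branching river network.

A riverscape is a set of habitat patches — natal (headwater spawning)
patches and migratory (mainstem overwintering) patches — together with a
matrix of pairwise along-network distances in kilometres.  Carrying
capacity of each patch is a density-dependent function of patch area at a
fixed fish density (default one individual per 100 m², i.e. 0.01 per m²).

Real riverscapes come from GIS hydrography; this module also provides a
synthetic generator that emulates the qualitative structure of a natural
system: a mainstem of migratory patches with natal patches hanging off it
as headwater tips of a random tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Patch",
    "Riverscape",
    "generate_riverscape",
    "read_riverscape",
    "write_riverscape",
    "DEFAULT_DENSITY",
]

#: individuals per m²: one individual per 100 m².
DEFAULT_DENSITY = 0.01

NATAL = "natal"
MIGRATORY = "migratory"
_ROLES = (NATAL, MIGRATORY)


@dataclass(frozen=True)
class Patch:
    """A habitat patch.

    Parameters
    ----------
    patch_id : str
        Unique identifier.
    role : {"natal", "migratory"}
        Natal patches are spawning/rearing habitat; migratory patches are
        overwintering habitat.
    area : float
        Patch area in m²; must be positive.
    carrying_capacity : int
        Maximum sustainable number of individuals, ``floor(area * density)``
        but at least 1.
    coordinate : tuple of float
        Planar (x, y) position, used only for plotting/serialization.
    """

    patch_id: str
    role: str
    area: float
    carrying_capacity: int
    coordinate: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown patch role {self.role!r} for patch {self.patch_id!r}")
        if not self.area > 0:
            raise ValueError(f"patch {self.patch_id!r}: area must be positive, got {self.area}")
        if self.carrying_capacity < 1:
            raise ValueError(f"patch {self.patch_id!r}: carrying capacity must be >= 1")


def capacity_from_area(area: float, density: float = DEFAULT_DENSITY) -> int:
    """Carrying capacity = floor(area × density), floored at one individual."""
    return max(1, math.floor(area * density))


@dataclass
class Riverscape:
    """Patches plus the pairwise along-network distance matrix (km).

    ``distances[i, j]`` is the network distance between ``patches[i]`` and
    ``patches[j]``.  The matrix must be symmetric with a zero diagonal.
    """

    patches: list[Patch]
    distances: np.ndarray
    density: float = DEFAULT_DENSITY
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        ids = [p.patch_id for p in self.patches]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patch ids: {dupes}")
        n = len(self.patches)
        if self.distances.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {self.distances.shape} does not match {n} patches"
            )
        if not np.allclose(self.distances, self.distances.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.distances), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.distances < 0).any():
            raise ValueError("distance matrix has negative entries")
        if not self.natal_indices.size:
            raise ValueError("riverscape needs at least one natal patch")
        if not self.migratory_indices.size:
            raise ValueError("riverscape needs at least one migratory patch")
        self._index = {pid: i for i, pid in enumerate(ids)}

    # -- convenience views -------------------------------------------------
    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def patch_ids(self) -> list[str]:
        return [p.patch_id for p in self.patches]

    @property
    def roles(self) -> np.ndarray:
        return np.array([p.role for p in self.patches])

    @property
    def natal_indices(self) -> np.ndarray:
        return np.flatnonzero(np.array([p.role == NATAL for p in self.patches]))

    @property
    def migratory_indices(self) -> np.ndarray:
        return np.flatnonzero(np.array([p.role == MIGRATORY for p in self.patches]))

    @property
    def carrying_capacities(self) -> np.ndarray:
        return np.array([p.carrying_capacity for p in self.patches], dtype=int)

    def index_of(self, patch_id: str) -> int:
        return self._index[patch_id]

    def total_capacity(self) -> int:
        return int(self.carrying_capacities.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patch_id": self.patch_ids,
                "role": [p.role for p in self.patches],
                "area_m2": [p.area for p in self.patches],
                "K": [p.carrying_capacity for p in self.patches],
                "x": [p.coordinate[0] for p in self.patches],
                "y": [p.coordinate[1] for p in self.patches],
            }
        )


def generate_riverscape(
    n_natal: int,
    n_migratory: int,
    area_range: tuple[float, float] = (5_000.0, 50_000.0),
    branching_factor: int = 2,
    seed: int | np.random.Generator = 0,
    density: float = DEFAULT_DENSITY,
    edge_length_range: tuple[float, float] = (1.0, 8.0),
) -> Riverscape:
    """Generate a synthetic branching riverscape.

    The network is a random tree: migratory patches form a mainstem chain
    (root-ward), and natal patches attach as headwater tips, each natal tip
    connected either to a mainstem node or to another natal node (creating
    tributary branches, up to ``branching_factor`` children per node).
    Pairwise distances are shortest-path sums of random edge lengths (km),
    so they satisfy the triangle inequality with equality along paths.

    Areas are drawn log-uniformly from ``area_range`` (m²); carrying
    capacities are ``floor(area * density)``.

    The function is a pure function of ``seed``.
    """
    if n_natal < 1 or n_migratory < 1:
        raise ValueError("need at least one natal and one migratory patch")
    lo, hi = area_range
    if not (0 < lo <= hi):
        raise ValueError(f"degenerate area range {area_range}")
    if branching_factor < 1:
        raise ValueError("branching_factor must be >= 1")
    rng = np.random.default_rng(seed)

    g = nx.Graph()
    mig_ids = [f"M{i:02d}" for i in range(n_migratory)]
    nat_ids = [f"N{i:02d}" for i in range(n_natal)]

    def edge_len() -> float:
        return float(rng.uniform(*edge_length_range))

    # mainstem chain of migratory patches
    for i, pid in enumerate(mig_ids):
        g.add_node(pid)
        if i > 0:
            g.add_edge(mig_ids[i - 1], pid, length=edge_len())

    # natal patches attach to the mainstem or to already-placed natal patches
    children: dict[str, int] = {pid: 0 for pid in mig_ids}
    for pid in nat_ids:
        candidates = [p for p, c in children.items() if c < branching_factor]
        if not candidates:  # everything saturated: relax onto mainstem
            candidates = mig_ids
        parent = candidates[rng.integers(len(candidates))]
        g.add_node(pid)
        g.add_edge(parent, pid, length=edge_len())
        children[parent] = children.get(parent, 0) + 1
        children[pid] = 0

    order = mig_ids + nat_ids
    spl = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    n = len(order)
    dist = np.zeros((n, n))
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            dist[i, j] = spl[a][b]

    # planar coordinates purely for plotting: mainstem along x, tips jittered
    pos = {pid: (float(dist[0, i]), 0.0) for i, pid in enumerate(mig_ids)}
    for j, pid in enumerate(nat_ids):
        i = order.index(pid)
        pos[pid] = (float(dist[0, i]), float(rng.uniform(0.5, 3.0)))

    patches = []
    for pid in order:
        area = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        patches.append(
            Patch(
                patch_id=pid,
                role=MIGRATORY if pid.startswith("M") else NATAL,
                area=area,
                carrying_capacity=capacity_from_area(area, density),
                coordinate=pos[pid],
            )
        )
    return Riverscape(patches=patches, distances=dist, density=density)


# -- I/O -------------------------------------------------------------------

def write_riverscape(riverscape: Riverscape, patch_table_path, distance_matrix_path) -> None:
    """Write the patch table and distance matrix as CSV.

    Patch table columns: ``patch_id,role,area_m2,K,x,y``.  The distance
    matrix is written with patch ids as both index and header, in km.
    """
    riverscape.to_frame().to_csv(patch_table_path, index=False)
    pd.DataFrame(
        riverscape.distances, index=riverscape.patch_ids, columns=riverscape.patch_ids
    ).to_csv(distance_matrix_path)


def read_riverscape(patch_table_path, distance_matrix_path, density: float = DEFAULT_DENSITY) -> Riverscape:
    """Read a riverscape written by :func:`write_riverscape`.

    ``K`` may be omitted from the patch table, in which case it is computed
    from ``area_m2`` at ``density``.  All structural invariants (unique ids,
    known roles, symmetric zero-diagonal matrix) are re-validated.
    """
    table = pd.read_csv(patch_table_path, dtype={"patch_id": str})
    required = {"patch_id", "role"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"patch table missing columns: {sorted(missing)}")

    patches = []
    for row_number, row in table.iterrows():
        area = row.get("area_m2")
        k = row.get("K")
        has_area = area is not None and not pd.isna(area)
        has_k = k is not None and not pd.isna(k)
        if not has_area and not has_k:
            raise ValueError(
                f"patch table row {row_number} (patch {row['patch_id']!r}): "
                "needs area_m2 or K"
            )
        if not has_area:
            # area backed out of K so Patch invariants still hold
            area = float(k) / density
        if not has_k:
            k = capacity_from_area(float(area), density)
        patches.append(
            Patch(
                patch_id=str(row["patch_id"]),
                role=str(row["role"]),
                area=float(area),
                carrying_capacity=int(k),
                coordinate=(float(row.get("x", 0.0) or 0.0), float(row.get("y", 0.0) or 0.0)),
            )
        )

    mat = pd.read_csv(distance_matrix_path, index_col=0)
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    ids = [p.patch_id for p in patches]
    if set(mat.index) != set(ids) or set(mat.columns) != set(ids):
        raise ValueError("distance matrix ids do not match patch table ids")
    dist = mat.loc[ids, ids].to_numpy(dtype=float)
    return Riverscape(patches=patches, distances=dist, density=density)
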