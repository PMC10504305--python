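"""Over-ocean shortest-path distances on a land-masked raster grid.

The globe is a plate carrée raster (default 400 x 800, ~0.45°; row 0 at the
90°N edge, column 0 at the 180°W edge). Ocean cells form a graph with
16-neighbor connectivity by default (8 compass moves plus knight moves,
configurable down to {4, 8}) and great-circle (haversine, R = 6371 km) edge
weights between cell centers; longitude wraps across the antimeridian by
default. Knight moves keep the shortest-path overestimate of true
great-circle distance within a few percent, where plain 8-neighbor paths
can exceed 8% on unfavourable headings. Sample coordinates that rasterize onto land are snapped to the
nearest ocean cell. The pairwise matrix is collapsed to one continuous axis
with 1-D non-metric MDS (Kruskal stress-1, isotonic regression), restarted
from the classical-MDS axis plus random jitters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .formats import DistanceMatrix, ValidationError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between coordinate arrays (degrees)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class OceanGrid:
    """Plate carrée raster with a boolean land mask (True = land)."""

    land: np.ndarray
    wrap_longitude: bool = True

    def __post_init__(self):
        self.land = np.asarray(self.land, dtype=bool)
        if self.land.ndim != 2:
            raise ValidationError("land mask must be 2-D")
        if not (~self.land).any():
            raise ValidationError("grid has no ocean cell")

    @classmethod
    def default(cls, rows: int = 400, cols: int = 800,
                wrap_longitude: bool = True) -> "OceanGrid":
        return cls(land=np.zeros((rows, cols), dtype=bool),
                   wrap_longitude=wrap_longitude)

    @property
    def rows(self) -> int:
        return self.land.shape[0]

    @property
    def cols(self) -> int:
        return self.land.shape[1]

    @property
    def cell_size_deg(self) -> tuple[float, float]:
        return 180.0 / self.rows, 360.0 / self.cols

    def cell_center(self, r, c) -> tuple[np.ndarray, np.ndarray]:
        dlat, dlon = self.cell_size_deg
        lat = 90.0 - (np.asarray(r) + 0.5) * dlat
        lon = -180.0 + (np.asarray(c) + 0.5) * dlon
        return lat, lon

    def containing_cell(self, lat: float, lon: float) -> tuple[int, int]:
        dlat, dlon = self.cell_size_deg
        r = min(int((90.0 - lat) / dlat), self.rows - 1)
        c = min(int((lon + 180.0) / dlon), self.cols - 1)
        return max(r, 0), max(c, 0)


def snap_to_ocean(lat: float, lon: float, grid: OceanGrid) -> tuple[int, int]:
    """Containing cell if ocean, else the nearest ocean cell by great circle.

    Ties between equidistant ocean cells break to the smaller (row, col).
    """
    r, c = grid.containing_cell(lat, lon)
    if not grid.land[r, c]:
        return r, c
    ocean_r, ocean_c = np.nonzero(~grid.land)
    clat, clon = grid.cell_center(ocean_r, ocean_c)
    d = haversine_km(lat, lon, clat, clon)
    i = int(np.argmin(d))  # row-major order => smallest (row, col) on ties
    logger.info("snapped (%.3f, %.3f) to ocean cell (%d, %d), %.1f km",
                lat, lon, ocean_r[i], ocean_c[i], d[i])
    return int(ocean_r[i]), int(ocean_c[i])


# moves per connectivity level (upper half; symmetry supplies the rest).
# 16-connectivity adds knight moves, whose straighter headings keep the
# shortest-path overestimate of great-circle distance within a few percent;
# each knight move must not cut across land, so its two intermediate cells
# are required to be ocean.
_MOVES = {
    4: [((-1, 0), ()), ((0, 1), ())],
    8: [((-1, -1), ()), ((-1, 0), ()), ((-1, 1), ()), ((0, 1), ())],
    16: [((-1, -1), ()), ((-1, 0), ()), ((-1, 1), ()), ((0, 1), ()),
         ((-1, -2), ((0, -1), (-1, -1))), ((-1, 2), ((0, 1), (-1, 1))),
         ((-2, -1), ((-1, 0), (-1, -1))), ((-2, 1), ((-1, 0), (-1, 1))),
         ((-2, -2), ((-1, -1),)), ((-2, 2), ((-1, 1),))],
}


def _ocean_graph(grid: OceanGrid, connectivity: int = 16):
    """Sparse symmetric graph over ocean cells with haversine edge weights."""
    rows, cols = grid.rows, grid.cols
    idx = -np.ones((rows, cols), dtype=np.int64)
    ocean = ~grid.land
    n_ocean = int(ocean.sum())
    idx[ocean] = np.arange(n_ocean)
    if connectivity not in _MOVES:
        raise ValidationError("connectivity must be 4, 8 or 16")
    src, dst, w = [], [], []
    r_grid, c_grid = np.mgrid[0:rows, 0:cols]

    def shifted_ocean(dr, dc):
        """Boolean grid: cell (r, c) has an ocean cell at offset (dr, dc)."""
        r2 = r_grid + dr
        c2 = c_grid + dc
        if grid.wrap_longitude:
            c2 = c2 % cols
            valid = (r2 >= 0) & (r2 < rows)
        else:
            valid = (r2 >= 0) & (r2 < rows) & (c2 >= 0) & (c2 < cols)
        c2v = np.where(valid, c2, 0)
        return valid & ocean[r2 % rows, c2v], r2, c2v

    for (dr, dc), intermediates in _MOVES[connectivity]:
        ok, r2, c2v = shifted_ocean(dr, dc)
        ok = ok & ocean
        for idr, idc in intermediates:
            mid_ok, _, _ = shifted_ocean(idr, idc)
            ok = ok & mid_ok
        ra, ca = r_grid[ok], c_grid[ok]
        rb, cb = r2[ok], c2v[ok]
        lat_a, lon_a = grid.cell_center(ra, ca)
        lat_b, lon_b = grid.cell_center(rb, cb)
        src.append(idx[ra, ca])
        dst.append(idx[rb, cb])
        w.append(haversine_km(lat_a, lon_a, lat_b, lon_b))
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    w = np.concatenate(w)
    graph = coo_matrix((w, (src, dst)), shape=(n_ocean, n_ocean)).tocsr()
    return graph, idx


def pairwise_ocean_distance(samples: pd.DataFrame, grid: OceanGrid,
                            connectivity: int = 16) -> DistanceMatrix:
    """Shortest over-ocean path (km) between all sample pairs.

    Disconnected ocean basins yield +inf entries, which are reported and
    rejected by downstream statistics.
    """
    graph, idx = _ocean_graph(grid, connectivity)
    cells = [snap_to_ocean(row["latitude"], row["longitude"], grid)
             for _, row in samples.iterrows()]
    nodes = np.array([idx[r, c] for r, c in cells])
    unique_nodes, inverse = np.unique(nodes, return_inverse=True)
    dist_from = dijkstra(graph, directed=False, indices=unique_nodes)
    d = dist_from[inverse][:, nodes]
    d = 0.5 * (d + d.T)  # enforce exact symmetry against float jitter
    np.fill_diagonal(d, 0.0)
    n_inf = int(np.isinf(d).sum())
    if n_inf:
        logger.warning("%d sample pair(s) lie in disconnected basins (+inf)",
                       n_inf // 2)
    return DistanceMatrix(list(samples.index.astype(str)), d,
                          metric_name="ocean_km")


# ---------------------------------------------------------------------------
# 1-D non-metric MDS
# ---------------------------------------------------------------------------

def _kruskal_stress1(d_flat: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a 1-D configuration against target dissimilarities."""
    emb = np.abs(coords[:, None] - coords[None, :])
    iu = np.triu_indices(len(coords), k=1)
    dhat = emb[iu]
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    disp = iso.fit_transform(d_flat, dhat)
    denom = float((dhat ** 2).sum())
    if denom == 0:
        return np.inf
    return float(np.sqrt(((dhat - disp) ** 2).sum() / denom))


def _classical_mds_axis(d: np.ndarray) -> np.ndarray:
    n = len(d)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (d ** 2) @ J
    vals, vecs = np.linalg.eigh(G)
    axis = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    return axis


def nmds_1d(d: DistanceMatrix, n_restarts: int = 20, max_iter: int = 300,
            tol: float = 1e-9, seed: int | None = None
            ) -> tuple[pd.Series, float]:
    """Collapse a distance matrix to one continuous axis by non-metric MDS.

    Minimizes Kruskal stress-1 over 1-D configurations using SMACOF
    majorization with monotone (isotonic) regression, restarting from the
    classical-MDS first axis plus random jitters; the best-stress solution
    is returned, centered at 0. Deterministic given the seed.
    """
    n = len(d.ids)
    if n < 3:
        raise ValidationError("nmds_1d needs >=3 samples")
    if not np.isfinite(d.d).all():
        raise ValidationError("nmds_1d requires finite distances")
    iu = np.triu_indices(n, k=1)
    d_flat = d.d[iu]
    rng = np.random.default_rng(seed)
    base = _classical_mds_axis(d.d)
    scale = np.std(base) if np.std(base) > 0 else 1.0
    best_coords, best_stress = base, _kruskal_stress1(d_flat, base)
    for restart in range(n_restarts):
        init = base.copy() if restart == 0 else \
            base + rng.normal(0, 0.3 * scale, size=n)
        coords, _ = smacof(d.d, metric=False, n_components=1,
                           init=init[:, None], n_init=1, max_iter=max_iter,
                           eps=tol, normalized_stress=True,
                           random_state=np.random.RandomState(
                               int(rng.integers(2**31))))
        coords = coords[:, 0]
        stress = _kruskal_stress1(d_flat, coords)
        if stress < best_stress:
            best_coords, best_stress = coords, stress
    best_coords = best_coords - best_coords.mean()
    return pd.Series(best_coords, index=d.ids, name="nmds1"), best_stress
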