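"""Pairwise predictor distance matrices.

Geographic distances come in three flavours: straight-line Euclidean,
least-cost over a resistance raster (single optimal route), and circuit
effective resistance (all routes, via the weighted graph Laplacian).  The
raster is turned into an undirected 8-neighbour graph whose edge
conductance is the arithmetic mean of the two cells' conductances and whose
edge length is the cell size (x sqrt(2) on diagonals).  Least-cost edges
weigh length/conductance; effective resistance uses edge conductance
directly, so a single edge of conductance c has resistance distance 1/c.

Environmental distances are per-variable absolute differences at the
collection locations; host association distance is binary (same host 0,
different host 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import pdist, squareform

from ._core import (
    DistanceMatrix,
    MothscapeError,
    ResistanceSurface,
    logger,
    validate_sample_table,
)

__all__ = [
    "euclidean_dm",
    "RasterGraph",
    "build_graph",
    "least_cost_dm",
    "resistance_dm",
    "env_and_host_dms",
]


def euclidean_dm(samples: pd.DataFrame) -> DistanceMatrix:
    """Straight-line pairwise distances from planar km coordinates."""
    validate_sample_table(samples)
    xy = samples[["x_km", "y_km"]].to_numpy(float)
    return DistanceMatrix(ids=list(samples["id"].astype(str)),
                          values=squareform(pdist(xy)),
                          label="euclidean", kind="geographic")


# ---------------------------------------------------------------------------
# Raster graph
# ---------------------------------------------------------------------------

@dataclass
class RasterGraph:
    """Undirected graph over non-missing raster cells.

    ``node_of`` maps (row, col) to node index (-1 for missing cells); edges
    are stored as parallel arrays of endpoints, conductances, and lengths.
    """

    node_of: np.ndarray
    cells: np.ndarray            # (n_nodes, 2) row/col per node
    edges_u: np.ndarray
    edges_v: np.ndarray
    conductance: np.ndarray
    length: np.ndarray
    cell_size: float
    x0: float = 0.0
    y0: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.cells.shape[0]

    def cost_matrix(self) -> sparse.csr_matrix:
        """Sparse symmetric traversal-cost matrix (length / conductance)."""
        w = self.length / self.conductance
        n = self.n_nodes
        m = sparse.coo_matrix(
            (np.r_[w, w], (np.r_[self.edges_u, self.edges_v],
                           np.r_[self.edges_v, self.edges_u])), shape=(n, n))
        return m.tocsr()

    def laplacian(self) -> sparse.csr_matrix:
        """Graph Laplacian with edge conductances as weights."""
        n = self.n_nodes
        w = self.conductance
        A = sparse.coo_matrix(
            (np.r_[w, w], (np.r_[self.edges_u, self.edges_v],
                           np.r_[self.edges_v, self.edges_u])), shape=(n, n)).tocsr()
        deg = np.asarray(A.sum(axis=1)).ravel()
        return sparse.diags(deg) - A

    def to_edge_list(self, path) -> None:
        """Export edges as comma-delimited (node1, node2, conductance, length)."""
        pd.DataFrame({"node1": self.edges_u, "node2": self.edges_v,
                      "conductance": self.conductance,
                      "length": self.length}).to_csv(path, index=False)

    def sample_nodes(self, samples: pd.DataFrame) -> np.ndarray:
        """Node index of each sample's containing cell (error if missing)."""
        col = np.floor((samples["x_km"].to_numpy(float) - self.x0)
                       / self.cell_size).astype(int)
        row = np.floor((samples["y_km"].to_numpy(float) - self.y0)
                       / self.cell_size).astype(int)
        rows, cols = self.node_of.shape
        if ((row < 0) | (row >= rows) | (col < 0) | (col >= cols)).any():
            bad = samples["id"][(row < 0) | (row >= rows) | (col < 0) | (col >= cols)]
            raise MothscapeError(f"samples outside raster extent: {list(bad)}")
        nodes = self.node_of[row, col]
        if (nodes < 0).any():
            bad = samples["id"][nodes < 0]
            raise MothscapeError(f"samples on missing cells: {list(bad)}")
        return nodes


def build_graph(resistance: ResistanceSurface, connectivity: int = 8,
                edge_mean: str = "arithmetic") -> RasterGraph:
    """Build the conductance-weighted raster graph.

    Edge conductance is the arithmetic (or harmonic) mean of the two cells'
    conductances; edge length is cell_size for rook moves and
    sqrt(2) x cell_size for diagonals.  Missing cells get no edges.
    """
    if connectivity not in (4, 8):
        raise MothscapeError("connectivity must be 4 or 8")
    cond = resistance.conductance
    valid = np.isfinite(cond)
    rows, cols = cond.shape
    node_of = np.full((rows, cols), -1, dtype=int)
    rr, cc = np.nonzero(valid)
    node_of[rr, cc] = np.arange(rr.size)
    cells = np.column_stack([rr, cc])

    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if connectivity == 8:
        offsets += [(1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]

    eu, ev, ec, el = [], [], [], []
    for dr, dc, mult in offsets:
        r2 = rr + dr
        c2 = cc + dc
        ok = (r2 >= 0) & (r2 < rows) & (c2 >= 0) & (c2 < cols)
        ok[ok] &= valid[r2[ok], c2[ok]]
        u = node_of[rr[ok], cc[ok]]
        v = node_of[r2[ok], c2[ok]]
        g1 = cond[rr[ok], cc[ok]]
        g2 = cond[r2[ok], c2[ok]]
        if edge_mean == "arithmetic":
            g = 0.5 * (g1 + g2)
        elif edge_mean == "harmonic":
            g = 2.0 / (1.0 / g1 + 1.0 / g2)
        else:
            raise MothscapeError(f"unknown edge_mean '{edge_mean}'")
        eu.append(u)
        ev.append(v)
        ec.append(g)
        el.append(np.full(u.size, mult * resistance.cell_size))
    return RasterGraph(
        node_of=node_of, cells=cells,
        edges_u=np.concatenate(eu), edges_v=np.concatenate(ev),
        conductance=np.concatenate(ec), length=np.concatenate(el),
        cell_size=resistance.cell_size, x0=resistance.x0, y0=resistance.y0,
        meta={"connectivity": connectivity, "edge_mean": edge_mean})


def _flag_infinite(values: np.ndarray, label: str) -> np.ndarray:
    inf = ~np.isfinite(values) & ~np.eye(values.shape[0], dtype=bool)
    if inf.any():
        logger.warning("%s: %d disconnected pairs set to NaN", label,
                       int(inf.sum() // 2))
        values = values.copy()
        values[inf] = np.nan
    return values


def least_cost_dm(graph: RasterGraph, samples: pd.DataFrame) -> DistanceMatrix:
    """Pairwise shortest-path traversal cost between sample cells."""
    nodes = graph.sample_nodes(samples)
    uniq, inv = np.unique(nodes, return_inverse=True)
    dist = dijkstra(graph.cost_matrix(), directed=False, indices=uniq)
    values = dist[:, uniq][inv][:, inv]
    np.fill_diagonal(values, 0.0)
    values = _flag_infinite(values, "least_cost_dm")
    return DistanceMatrix(ids=list(samples["id"].astype(str)), values=values,
                          label="least_cost", kind="geographic",
                          meta=dict(graph.meta))


def effective_resistance(laplacian: sparse.spmatrix,
                         nodes: np.ndarray) -> np.ndarray:
    """Effective resistance between the given nodes of a weighted graph.

    Solves grounded Laplacian systems per connected component;
    cross-component pairs are infinite.
    """
    L = laplacian.tocsr()
    _, labels = connected_components(L, directed=False)
    m = nodes.size
    R = np.full((m, m), np.inf)
    np.fill_diagonal(R, 0.0)
    for comp in np.unique(labels[nodes]):
        members = np.nonzero(labels == comp)[0]
        sel = np.nonzero(labels[nodes] == comp)[0]
        if sel.size < 2:
            continue
        local = {g: i for i, g in enumerate(members)}
        idx = np.array([local[g] for g in nodes[sel]])  # local sample indices
        # ground local node 0; with x = Lg^-1 (grounded Laplacian inverse):
        # R_ij = x_ii + x_jj - 2 x_ij, entries involving the ground being 0.
        keep = np.arange(1, members.size)
        pos = np.r_[-1, np.arange(keep.size)]  # local -> grounded index
        rhs_cols = [i for i in idx if i != 0]
        E = np.zeros((keep.size, len(rhs_cols)))
        for k, i in enumerate(rhs_cols):
            E[pos[i], k] = 1.0
        Lsub = L[np.ix_(members, members)]
        Lg = Lsub[np.ix_(keep, keep)]
        if members.size <= 1500:
            V = np.linalg.solve(Lg.toarray(), E)
        else:
            solver = sparse.linalg.factorized(Lg.tocsc())
            V = np.column_stack([solver(E[:, k]) for k in range(E.shape[1])])
        col_of = {i: k for k, i in enumerate(rhs_cols)}

        def x(i: int, j: int) -> float:
            if i == 0 or j == 0:
                return 0.0
            return float(V[pos[j], col_of[i]])

        for a, i in enumerate(idx):
            for b, j in enumerate(idx):
                if a != b:
                    R[sel[a], sel[b]] = x(i, i) + x(j, j) - x(i, j) - x(j, i)
    return R


def resistance_dm(graph: RasterGraph, samples: pd.DataFrame) -> DistanceMatrix:
    """Circuit-theoretic effective resistance between sample cells."""
    nodes = graph.sample_nodes(samples)
    uniq, inv = np.unique(nodes, return_inverse=True)
    R = effective_resistance(graph.laplacian(), uniq)
    values = R[inv][:, inv]
    np.fill_diagonal(values, 0.0)
    values = _flag_infinite(values, "resistance_dm")
    return DistanceMatrix(ids=list(samples["id"].astype(str)), values=values,
                          label="resistance", kind="geographic",
                          meta=dict(graph.meta))


# ---------------------------------------------------------------------------
# Environmental and host distances
# ---------------------------------------------------------------------------

def env_and_host_dms(samples: pd.DataFrame,
                     variables: list[str] | None = None,
                     ) -> list[DistanceMatrix]:
    """Absolute-difference matrices per continuous variable plus binary host.

    Host distance is 0 for pairs collected on the same host species, 1
    otherwise.
    """
    validate_sample_table(samples)
    if variables is None:
        variables = [c for c in samples.columns if c.startswith("env")]
    ids = list(samples["id"].astype(str))
    out = []
    for name in variables:
        if name not in samples.columns:
            raise MothscapeError(f"unknown variable '{name}'")
        v = samples[name].to_numpy(float)
        out.append(DistanceMatrix(ids=ids, values=np.abs(v[:, None] - v[None, :]),
                                  label=name, kind="environmental"))
    host = samples["host"].to_numpy()
    out.append(DistanceMatrix(ids=ids,
                              values=(host[:, None] != host[None, :]).astype(float),
                              label="host", kind="host"))
    return out
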