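"""Random geometric graphs of habitat patches and their Laplacians.

Patches are placed uniformly at random in the unit square and connected
whenever their Euclidean distance falls below a threshold radius.  Draws
that are not a single connected component are rejected.  The graph
Laplacian (degree matrix minus adjacency) encodes net diffusive flux
between patches and enters the metacommunity Jacobian through a
Kronecker product with the dispersal matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "SpatialNetwork",
    "generate_rgg",
    "laplacian_spectrum",
    "build_spatial_network",
    "to_networkx",
    "from_networkx",
    "write_graphml",
    "read_graphml",
    "write_laplacian_csv",
]

DEFAULT_N_PATCHES = 10
DEFAULT_RADIUS = 0.32
DEFAULT_ATTEMPT_BUDGET = 10_000


class InfeasibleLandscapeError(RuntimeError):
    """No connected random geometric graph found within the attempt budget."""


@dataclass(frozen=True)
class SpatialNetwork:
    """A connected habitat-patch graph.

    ``adjacency[k, l]`` is True iff the Euclidean distance between
    patches ``k`` and ``l`` is strictly below ``radius`` (k != l).  The
    Laplacian has node degrees on the diagonal and -1 for each edge, so
    every row sums to zero and the matrix is symmetric positive
    semidefinite with a simple zero eigenvalue on connected graphs.
    """

    N: int
    coords: np.ndarray
    radius: float
    adjacency: np.ndarray
    laplacian: np.ndarray
    seed: int | None = None

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def build_spatial_network(
    coords: np.ndarray, radius: float, *, require_connected: bool = True,
    seed: int | None = None,
) -> SpatialNetwork:
    """Assemble adjacency and Laplacian for given patch coordinates."""
    coords = np.asarray(coords, dtype=float)
    N = coords.shape[0]
    dist = squareform(pdist(coords))
    adjacency = dist < radius
    np.fill_diagonal(adjacency, False)
    if require_connected and not _connected(adjacency):
        raise ValueError("patch graph is not a single connected component")
    laplacian = np.diag(adjacency.sum(axis=1).astype(float)) - adjacency.astype(float)
    return SpatialNetwork(
        N=N, coords=coords, radius=float(radius), adjacency=adjacency,
        laplacian=laplacian, seed=seed,
    )


def _connected(adjacency: np.ndarray) -> bool:
    n_comp, _ = connected_components(csr_matrix(adjacency), directed=False)
    return n_comp == 1


def generate_rgg(
    N: int = DEFAULT_N_PATCHES,
    radius: float = DEFAULT_RADIUS,
    rng: np.random.Generator | None = None,
    *,
    max_attempts: int = DEFAULT_ATTEMPT_BUDGET,
    seed: int | None = None,
) -> SpatialNetwork:
    """Draw a connected random geometric graph in the unit square.

    Coordinates are uniform on [0, 1]^2; patches closer than ``radius``
    are linked; disconnected draws are discarded and redrawn, which
    conditions the RGG distribution on connectivity.
    """
    if N < 2:
        raise ValueError("need at least two patches")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if rng is None:
        rng = np.random.default_rng()
    for _ in range(max_attempts):
        coords = rng.uniform(0.0, 1.0, size=(N, 2))
        try:
            return build_spatial_network(coords, radius, seed=seed)
        except ValueError:
            continue
    raise InfeasibleLandscapeError(
        f"no connected RGG for N={N}, radius={radius} within {max_attempts} attempts"
    )


def laplacian_spectrum(net: SpatialNetwork) -> np.ndarray:
    """Sorted real eigenvalues of the patch-graph Laplacian.

    The smallest is 0 (uniform eigenvector); the second-smallest is
    positive exactly when the graph is connected.
    """
    return np.linalg.eigvalsh(net.laplacian)


# ---------------------------------------------------------------------------
# I/O

def to_networkx(net: SpatialNetwork):
    """Export as an undirected :class:`networkx.Graph` with coordinates."""
    import networkx as nx

    g = nx.Graph(radius=net.radius)
    for k in range(net.N):
        g.add_node(k, x=float(net.coords[k, 0]), y=float(net.coords[k, 1]))
    ks, ls = np.nonzero(np.triu(net.adjacency))
    g.add_edges_from(zip(ks.tolist(), ls.tolist()))
    return g


def from_networkx(g) -> SpatialNetwork:
    """Rebuild a :class:`SpatialNetwork` from a graph written by us."""
    nodes = sorted(g.nodes)
    coords = np.array([[g.nodes[k]["x"], g.nodes[k]["y"]] for k in nodes])
    return build_spatial_network(coords, float(g.graph["radius"]))


def write_laplacian_csv(net: SpatialNetwork, path) -> None:
    """Write the Laplacian as a plain CSV matrix (no header)."""
    np.savetxt(path, net.laplacian, fmt="%.1f", delimiter=",")


def write_graphml(net: SpatialNetwork, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(net), path)


def read_graphml(path) -> SpatialNetwork:
    import networkx as nx

    g = nx.read_graphml(path)
    g = nx.relabel_nodes(g, {n: int(n) for n in g.nodes})
    return from_networkx(g)
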