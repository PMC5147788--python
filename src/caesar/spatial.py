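"""Spatial structure and the distance-dependent CRP partition machinery.

The dd-CRP places a prior over partitions indirectly: each node n draws a
single outgoing link lambda_n to one of its spatial neighbours (or to
itself), with probability proportional to a decay-weighted distance
A[n, m] = f(d(n, m)).  Clusters are the connected components of the
undirected link graph, so resampling one link implicitly splits or merges
clusters.  The decay function used here is the hard cutoff f(d) = 1 for
d <= cutoff, 0 otherwise; f(0) (the self-link weight) plays the role of a
concentration-like parameter: large values favour many small clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AdjacencyGraph",
    "LinkState",
    "SizePrior",
    "build_grid_adjacency",
    "build_mesh_adjacency",
    "link_log_prior",
    "partition_from_links",
    "size_log_prior",
]


class InvalidLinkError(ValueError):
    """A link target outside the node's admissible neighbourhood."""


@dataclass
class AdjacencyGraph:
    """Admissible link targets and their dd-CRP weights.

    ``neighbor_lists[n]`` holds the non-self targets node ``n`` may link to;
    ``weights[n]`` the aligned nonnegative weights A[n, m] = f(d(n, m)).
    ``self_weight`` is f(0), shared by every node.  ``log_norm[n]`` caches
    log(self_weight + sum of row weights) for the row-normalised link prior.
    """

    n_nodes: int
    neighbor_lists: list[np.ndarray]
    weights: list[np.ndarray]
    self_weight: float = 1.0
    log_norm: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("graph needs at least one node")
        if self.self_weight < 0:
            raise ValueError("self_weight must be nonnegative")
        norms = np.empty(self.n_nodes)
        for n in range(self.n_nodes):
            w = np.asarray(self.weights[n], dtype=float)
            if np.any(w < 0):
                raise ValueError("negative link weight")
            self.weights[n] = w
            norms[n] = self.self_weight + w.sum()
        if np.any(norms <= 0):
            raise ValueError(
                "every node needs at least one admissible target with "
                "positive weight (possibly itself)"
            )
        self.log_norm = np.log(norms)

    def candidates(self, node: int) -> np.ndarray:
        """All admissible targets of ``node`` including the self-link."""
        return np.concatenate([self.neighbor_lists[node], [node]])

    def candidate_log_priors(self, node: int) -> np.ndarray:
        """Log link prior for each entry of :meth:`candidates`."""
        w = self.weights[node]
        with np.errstate(divide="ignore"):
            logw = np.log(np.append(w, self.self_weight))
        return logw - self.log_norm[node]


def build_grid_adjacency(
    rows: int, cols: int, cutoff: float = 1.0, self_weight: float = 1.0
) -> AdjacencyGraph:
    """Regular 2-D grid with unit spacing and a hard distance cutoff.

    With ``cutoff=1`` each interior node may link only to its four nearest
    neighbours, the constraint used for grid simulations.
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be positive")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = rows * cols
    xs, ys = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    # hard cutoff keeps the neighbourhood local; search a bounded window
    reach = int(np.floor(cutoff))
    offsets = [
        (di, dj)
        for di in range(-reach, reach + 1)
        for dj in range(-reach, reach + 1)
        if (di, dj) != (0, 0) and np.hypot(di, dj) <= cutoff
    ]
    nbrs: list[np.ndarray] = []
    wts: list[np.ndarray] = []
    for i in range(rows):
        for j in range(cols):
            targets = [
                (i + di) * cols + (j + dj)
                for di, dj in offsets
                if 0 <= i + di < rows and 0 <= j + dj < cols
            ]
            targets.sort()
            nbrs.append(np.asarray(targets, dtype=np.int64))
            wts.append(np.ones(len(targets)))
    graph = AdjacencyGraph(n, nbrs, wts, self_weight)
    graph.coords = coords  # type: ignore[attr-defined] # grid positions, used by region growing
    return graph


def build_mesh_adjacency(
    triangles: np.ndarray, self_weight: float = 1.0, n_nodes: int | None = None
) -> AdjacencyGraph:
    """Adjacency from a triangle mesh: nodes sharing a triangle edge.

    Mesh hop distance stands in for the geodesic, so the hard cutoff at
    distance 1 admits only immediate mesh neighbours — at most six non-self
    targets on a regular triangulation.
    """
    tri = np.asarray(triangles, dtype=np.int64)
    if tri.ndim != 2 or tri.shape[1] != 3:
        raise ValueError("triangles must be an (m, 3) array of node indices")
    if tri.size and tri.min() < 0:
        raise ValueError("negative node index in triangle list")
    n = int(tri.max()) + 1 if tri.size else 0
    if n_nodes is not None:
        if tri.size and n_nodes <= tri.max():
            raise ValueError("triangle index out of range for n_nodes")
        n = n_nodes
    adj: list[set[int]] = [set() for _ in range(n)]
    for a, b, c in tri:
        for u, v in ((a, b), (b, c), (a, c)):
            adj[u].add(int(v))
            adj[v].add(int(u))
    nbrs = [np.asarray(sorted(s), dtype=np.int64) for s in adj]
    wts = [np.ones(len(s)) for s in adj]
    return AdjacencyGraph(n, nbrs, wts, self_weight)


def link_log_prior(graph: AdjacencyGraph, node: int, target: int) -> float:
    """Log probability of the single link lambda_node = target.

    Row-normalised decay weight; the normaliser includes the self weight.
    """
    if target == node:
        if graph.self_weight <= 0:
            raise InvalidLinkError(f"self-link of node {node} has zero weight")
        return float(np.log(graph.self_weight) - graph.log_norm[node])
    row = graph.neighbor_lists[node]
    pos = np.searchsorted(row, target)
    if pos >= len(row) or row[pos] != target:
        raise InvalidLinkError(f"{target} is not an admissible target of {node}")
    return float(np.log(graph.weights[node][pos]) - graph.log_norm[node])


@dataclass
class SizePrior:
    """Improper soft lower bound on cluster sizes.

    Each cluster of size s < d contributes exp(-(d - s)^2 / (2 w^2)); clusters
    at or above the bound contribute 1.  ``d`` sets the scale of the desired
    parcels, ``w`` how sharply undersized clusters are penalised.
    """

    d: int = 200
    w: float = 5.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("size-prior lower bound d must be >= 1")
        if self.w <= 0:
            raise ValueError("size-prior width w must be positive")


def size_log_prior(sizes: np.ndarray, prior: SizePrior | None) -> float:
    """Sum of per-cluster log size-prior terms; 0 when disabled."""
    if prior is None or not prior.enabled:
        return 0.0
    s = np.asarray(sizes, dtype=float)
    deficit = np.maximum(prior.d - s, 0.0)
    return float(-np.sum(deficit**2) / (2.0 * prior.w**2))


def partition_from_links(links: np.ndarray, graph: AdjacencyGraph) -> "LinkState":
    """Connected components of the undirected link graph {(n, lambda_n)}."""
    return LinkState.from_links(links, graph)


class LinkState:
    """Link vector lambda and the partition it induces, kept in sync.

    Mutations go through :meth:`remove_link` / :meth:`set_link`, which update
    the connected components incrementally (split on removal, merge on
    insertion).  Every ``audit_every`` mutations the partition is recomputed
    from scratch and compared — a cheap guard on the incremental bookkeeping.
    Cluster ids are the smallest member index, assigned on (re)labelling.
    """

    audit_every = 100

    def __init__(self, links: np.ndarray, graph: AdjacencyGraph):
        links = np.asarray(links, dtype=np.int64).copy()
        if links.shape != (graph.n_nodes,):
            raise ValueError("links must have one entry per node")
        for n, m in enumerate(links):
            if m != n:
                row = graph.neighbor_lists[n]
                pos = np.searchsorted(row, m)
                if pos >= len(row) or row[pos] != m:
                    raise InvalidLinkError(f"lambda_{n}={m} inadmissible")
        self.graph = graph
        self.links = links
        # incoming[n]: nodes m != n with lambda_m = n
        self.incoming: list[set[int]] = [set() for _ in range(graph.n_nodes)]
        for n, m in enumerate(links):
            if m != n:
                self.incoming[m].add(n)
        self._relabel_full()
        self._mutations = 0

    @classmethod
    def from_links(cls, links: np.ndarray, graph: AdjacencyGraph) -> "LinkState":
        return cls(links, graph)

    # -- queries ---------------------------------------------------------

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> np.ndarray:
        return np.asarray([len(v) for v in self.clusters.values()])

    def labels(self) -> np.ndarray:
        """Per-node cluster labels (cluster id = smallest member index)."""
        return self.cluster_of.copy()

    def component_of(self, node: int) -> set[int]:
        """Undirected link-graph component containing ``node`` (traversal)."""
        seen = {node}
        stack = [node]
        while stack:
            u = stack.pop()
            nxt = self.incoming[u] | {int(self.links[u])}
            for v in nxt:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    # -- mutations -------------------------------------------------------

    def remove_link(self, node: int) -> tuple[int, int | None]:
        """Point ``node`` at itself, possibly splitting its cluster.

        Returns ``(cluster_id_of_node, split_off_id)`` where ``split_off_id``
        is the id now carried by the old link target's component, or None if
        the cluster did not split (target still reachable from ``node``).
        """
        old = int(self.links[node])
        if old == node:
            return int(self.cluster_of[node]), None
        self.incoming[old].discard(node)
        self.links[node] = node
        comp = self.component_of(node)
        if old in comp:
            self._tick()
            return int(self.cluster_of[node]), None
        # split: relabel both halves by their smallest member
        cid = int(self.cluster_of[node])
        members = self.clusters.pop(cid)
        other = members - comp
        new_a = min(comp)
        new_b = min(other)
        self.clusters[new_a] = comp
        self.clusters[new_b] = other
        for m in comp:
            self.cluster_of[m] = new_a
        for m in other:
            self.cluster_of[m] = new_b
        self._tick()
        return new_a, new_b

    def set_link(self, node: int, target: int) -> tuple[int, int | None]:
        """Set lambda_node = target (node must currently self-link).

        Returns ``(resulting_cluster_id, absorbed_id)`` where ``absorbed_id``
        is the id of the cluster that was merged away, or None for a self-link
        or a within-cluster link.
        """
        if int(self.links[node]) != node:
            raise InvalidLinkError("set_link requires a prior remove_link")
        if target == node:
            self._tick()
            return int(self.cluster_of[node]), None
        self.links[node] = target
        self.incoming[target].add(node)
        a = int(self.cluster_of[node])
        b = int(self.cluster_of[target])
        if a == b:
            self._tick()
            return a, None
        ma, mb = self.clusters.pop(a), self.clusters.pop(b)
        merged = ma | mb
        cid = min(a, b)
        self.clusters[cid] = merged
        gone = max(a, b)
        for m in ma if gone == a else mb:
            self.cluster_of[m] = cid
        self._tick()
        return cid, gone

    # -- internals -------------------------------------------------------

    def _relabel_full(self) -> None:
        n = self.graph.n_nodes
        rows = np.arange(n)
        m = csr_matrix(
            (np.ones(n), (rows, self.links)), shape=(n, n)
        )
        _, comp = connected_components(m, directed=False)
        clusters: dict[int, set[int]] = {}
        cluster_of = np.empty(n, dtype=np.int64)
        for label in np.unique(comp):
            members = set(np.flatnonzero(comp == label).tolist())
            cid = min(members)
            clusters[cid] = members
            for mm in members:
                cluster_of[mm] = cid
        self.clusters = clusters
        self.cluster_of = cluster_of

    def _tick(self) -> None:
        self._mutations += 1
        if self._mutations % self.audit_every == 0:
            self.audit()

    def audit(self) -> None:
        """Full recompute; raises if incremental bookkeeping has drifted."""
        saved_of, saved_cl = self.cluster_of, self.clusters
        self._relabel_full()
        if not np.array_equal(saved_of, self.cluster_of) or saved_cl != self.clusters:
            raise AssertionError("incremental partition bookkeeping drifted")

    def copy(self) -> "LinkState":
        new = object.__new__(LinkState)
        new.graph = self.graph
        new.links = self.links.copy()
        new.incoming = [set(s) for s in self.incoming]
        new.clusters = {k: set(v) for k, v in self.clusters.items()}
        new.cluster_of = self.cluster_of.copy()
        new._mutations = self._mutations
        return new
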