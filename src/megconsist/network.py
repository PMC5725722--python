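"""Phase lag index connectivity and graph-theoretical network metrics.

Connectivity between two reconstructed ROI series is the phase lag index

    PLI = | < sign( sin( dphi(t_k) ) ) >_k |,

the asymmetry of the instantaneous phase-difference distribution around zero.
Exactly zero-lag samples (sign 0) contribute nothing, which makes the index
insensitive to volume conduction / leakage.

The per-epoch, per-band ROI x ROI PLI matrix feeds: the weighted clustering
coefficient (triple-product form), the weighted characteristic path length
(Dijkstra on 1/w edge lengths), Newman modularity maximized by simulated
annealing and averaged over runs, and the Kruskal minimum spanning tree on
1/PLI lengths with its degree sequence, leaf fraction and diameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy.signal import hilbert
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra

__all__ = [
    "AdjacencyMatrix",
    "SpanningTree",
    "NetworkMetrics",
    "instantaneous_phase",
    "pli",
    "pli_adjacency",
    "weighted_clustering",
    "weighted_path_length",
    "newman_q",
    "modularity",
    "minimum_spanning_tree",
    "mst_metrics",
    "network_metrics",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyMatrix:
    """Symmetric, zero-diagonal ROI x ROI PLI matrix for one epoch and band."""

    weights: np.ndarray
    band: str = ""
    epoch_id: int = -1
    condition_tag: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any((w < 0) | (w > 1)):
            raise ValueError("PLI weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def global_mean(self) -> float:
        """Mean PLI over the upper triangle (the paper's 'average PLI')."""
        iu = np.triu_indices(self.n_nodes, 1)
        return float(self.weights[iu].mean())

    def node_mean(self) -> np.ndarray:
        """Per-node mean connectivity (row mean excluding the diagonal)."""
        r = self.n_nodes
        return self.weights.sum(axis=1) / (r - 1)


@dataclass
class SpanningTree:
    """Tree over R nodes: exactly R-1 edges, connected, acyclic."""

    edges: list          # [(i, j, pli_weight), ...]
    n_nodes: int

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError("a spanning tree has exactly R-1 edges")
        adj = self.adjacency_list()
        seen = _bfs_dists(adj, 0)
        if np.any(seen < 0):
            raise ValueError("edges do not connect all nodes")

    def adjacency_list(self) -> list:
        adj: list = [[] for _ in range(self.n_nodes)]
        for i, j, _ in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass
class NetworkMetrics:
    """Scalar summary of one adjacency matrix."""

    cw: float
    lw: float
    q: float
    n_modules: float
    mst_degree: np.ndarray
    leaf_fraction: float
    diameter: int


# ---------------------------------------------------------------------------
# phase and PLI
# ---------------------------------------------------------------------------

def instantaneous_phase(series: np.ndarray, axis: int = -1) -> np.ndarray:
    """Phase of the analytic (Hilbert) signal, wrapped to (-pi, pi].

    Input should already be band-limited. Raises on a constant series
    ("no oscillation").
    """
    x = np.asarray(series, float)
    if x.shape[axis] < 16:
        raise ValueError("series too short for a meaningful analytic signal")
    if np.ptp(x, axis=axis).min() == 0:
        raise ValueError("no oscillation: constant series")
    phase = np.angle(hilbert(x, axis=axis))
    # np.angle returns (-pi, pi]; -pi can appear from rounding
    phase = np.where(phase <= -np.pi, phase + 2 * np.pi, phase)
    return phase


def pli(delta_phi: np.ndarray) -> float:
    """Phase lag index of a phase-difference series.

    ``|mean_k sign(sin(dphi_k))|``; sign(0) = 0, so exactly zero-lag samples
    are neutral. Always in [0, 1].
    """
    d = np.asarray(delta_phi, float)
    if d.size == 0:
        raise ValueError("empty phase-difference series")
    return float(np.abs(np.mean(np.sign(np.sin(d)))))


def pli_adjacency(
    roi_series: np.ndarray,
    band: str = "",
    epoch_id: int = -1,
    condition_tag: str = "",
) -> AdjacencyMatrix:
    """PLI between every unordered ROI pair for one epoch.

    ``roi_series`` is (R, N), band-filtered. Phases are extracted once per
    ROI; the matrix is symmetric with zero diagonal.
    """
    x = np.asarray(roi_series, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 ROI series")
    phases = instantaneous_phase(x, axis=1)          # (R, N)
    sin_d = np.sin(phases[:, None, :] - phases[None, :, :])
    w = np.abs(np.sign(sin_d).mean(axis=2))
    np.fill_diagonal(w, 0.0)
    w = 0.5 * (w + w.T)  # symmetric up to float noise; sin is antisymmetric
    return AdjacencyMatrix(weights=w, band=band, epoch_id=epoch_id,
                           condition_tag=condition_tag)


# ---------------------------------------------------------------------------
# weighted graph measures
# ---------------------------------------------------------------------------

def weighted_clustering(adj: AdjacencyMatrix | np.ndarray) -> float:
    """Mean weighted clustering coefficient (triple-product form).

    Per node i: sum_{k!=l} w_ik w_il w_kl / sum_{k!=l} w_ik w_il, defined as
    0 when the denominator vanishes; averaged over nodes.
    """
    w = adj.weights if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, float)
    num = np.diag(w @ w @ w)                          # ordered (k, l) triples
    s = w.sum(axis=1)
    den = s ** 2 - (w ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(ci.mean())


def weighted_path_length(adj: AdjacencyMatrix | np.ndarray) -> float:
    """Mean weighted shortest path length, edge length = 1/weight.

    All-pairs Dijkstra; the mean is over connected ordered pairs. If any
    pair is disconnected the harmonic-mean convention is used:
    ``Lw = (mean over pairs of 1/d_ij)^-1`` with 1/inf = 0.
    """
    w = adj.weights if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, float)
    r = w.shape[0]
    if r < 2:
        raise ValueError("path length needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = _dijkstra(csr_matrix(lengths), directed=False)
    off = ~np.eye(r, dtype=bool)
    dij = d[off]
    if np.all(np.isfinite(dij)):
        return float(dij.mean())
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dij), 1.0 / dij, 0.0)
    mean_inv = inv.mean()
    return float(np.inf) if mean_inv == 0 else float(1.0 / mean_inv)


# ---------------------------------------------------------------------------
# Newman modularity by simulated annealing
# ---------------------------------------------------------------------------

def newman_q(w: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman modularity of a partition.

    ``Q = (1/2m) sum_ij (w_ij - s_i s_j / 2m) delta(c_i, c_j)`` with node
    strengths s and total weight 2m = sum_ij w_ij.
    """
    w = np.asarray(w, float)
    labels = np.asarray(labels)
    s = w.sum(axis=1)
    two_m = s.sum()
    if two_m <= 0:
        raise ValueError("empty graph: all-zero adjacency")
    same = labels[:, None] == labels[None, :]
    return float(((w - np.outer(s, s) / two_m) * same).sum() / two_m)


@njit(cache=True)
def _anneal_run(w, seed, t0, cooling, t_min, stall_limit):  # pragma: no cover
    np.random.seed(seed)
    r = w.shape[0]
    s = np.zeros(r)
    for i in range(r):
        for j in range(r):
            s[i] += w[i, j]
    two_m = s.sum()

    comm = np.empty(r, np.int64)
    for i in range(r):
        comm[i] = np.random.randint(0, r)
    size = np.zeros(r, np.int64)
    strength = np.zeros(r)
    for i in range(r):
        size[comm[i]] += 1
        strength[comm[i]] += s[i]

    # initial Q
    q = 0.0
    for i in range(r):
        for j in range(r):
            if comm[i] == comm[j]:
                q += w[i, j] - s[i] * s[j] / two_m
    q /= two_m

    best_q = q
    best_comm = comm.copy()

    t = t0
    stall = 0
    cand = np.empty(r + 1, np.int64)
    while t >= t_min and stall < stall_limit:
        v = np.random.randint(0, r)
        a = comm[v]
        # candidate modules: those of v's neighbors, plus one empty module
        n_cand = 0
        for j in range(r):
            if w[v, j] > 0.0:
                c = comm[j]
                if c != a:
                    dup = False
                    for q_i in range(n_cand):
                        if cand[q_i] == c:
                            dup = True
                            break
                    if not dup:
                        cand[n_cand] = c
                        n_cand += 1
        if size[a] > 1:  # moving to a fresh singleton module
            for c in range(r):
                if size[c] == 0:
                    cand[n_cand] = c
                    n_cand += 1
                    break
        if n_cand == 0:
            t *= cooling
            stall += 1
            continue
        b = cand[np.random.randint(0, n_cand)]

        k_va = 0.0
        k_vb = 0.0
        for j in range(r):
            if j != v:
                if comm[j] == a:
                    k_va += w[v, j]
                elif comm[j] == b:
                    k_vb += w[v, j]
        dq = 2.0 * (k_vb - k_va) / two_m \
            - 2.0 * s[v] * (strength[b] - strength[a] + s[v]) / (two_m * two_m)

        accept = dq > 0.0 or np.random.random() < np.exp(dq / t)
        if accept:
            comm[v] = b
            size[a] -= 1
            size[b] += 1
            strength[a] -= s[v]
            strength[b] += s[v]
            q += dq
            stall = 0
            if q > best_q:
                best_q = q
                best_comm[:] = comm
        else:
            stall += 1
        t *= cooling

    return best_comm


def modularity(
    adj: AdjacencyMatrix | np.ndarray,
    n_runs: int = 100,
    seed: int = 0,
    t0: float = 1.0,
    cooling: float = 0.995,
    t_min: float = 1e-4,
) -> tuple[float, float]:
    """Averaged annealed Newman modularity: (mean Q, mean module count).

    Each run starts from a random partition and proposes single-node moves to
    a neighboring or fresh module, accepted by the Metropolis rule under a
    geometric cooling schedule (T0, cooling factor, floor ``t_min``, stall
    stop after 100*R consecutive rejections). The best partition per run is
    kept; Q and the module count are averaged over ``n_runs`` runs.
    Deterministic for a fixed seed.
    """
    w = adj.weights if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, float)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if w.sum() <= 0:
        raise ValueError("empty graph: all-zero adjacency")
    r = w.shape[0]
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2 ** 31)
    qs = np.empty(n_runs)
    mods = np.empty(n_runs)
    for i in range(n_runs):
        labels = _anneal_run(np.ascontiguousarray(w, dtype=np.float64),
                             int(run_seeds[i]), t0, cooling, t_min, 100 * r)
        qs[i] = newman_q(w, labels)
        mods[i] = np.unique(labels).size
        if qs[i] < 0.0:
            # the single-module partition (Q = 0) is always admissible
            qs[i] = 0.0
            mods[i] = 1
    return float(qs.mean()), float(mods.mean())


# ---------------------------------------------------------------------------
# minimum spanning tree (Kruskal on 1/PLI lengths)
# ---------------------------------------------------------------------------

def minimum_spanning_tree(adj: AdjacencyMatrix | np.ndarray) -> SpanningTree:
    """Kruskal MST with edge length 1/PLI.

    Zero-weight pairs carry no edge; a disconnected positive-weight graph is
    an error. Ties between equal lengths break by (smaller node id, larger
    node id), so the tree is deterministic.
    """
    w = adj.weights if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, float)
    r = w.shape[0]
    iu, ju = np.triu_indices(r, 1)
    keep = w[iu, ju] > 0
    iu, ju = iu[keep], ju[keep]
    lengths = 1.0 / w[iu, ju]
    order = np.lexsort((ju, iu, lengths))

    parent = list(range(r))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j, float(w[i, j])))
            if len(edges) == r - 1:
                break
    if len(edges) != r - 1:
        raise ValueError("disconnected graph: no spanning tree exists")
    return SpanningTree(edges=edges, n_nodes=r)


def _bfs_dists(adj_list: list, start: int) -> np.ndarray:
    n = len(adj_list)
    dist = np.full(n, -1, int)
    dist[start] = 0
    queue = [start]
    while queue:
        nxt = []
        for u in queue:
            for v in adj_list[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        queue = nxt
    return dist


def mst_metrics(tree: SpanningTree) -> tuple[np.ndarray, float, int]:
    """Degree sequence, leaf fraction, and hop-count diameter of a tree.

    The diameter uses the two-pass breadth-first search (exact on trees).
    """
    deg = tree.degrees()
    leaf_fraction = float((deg == 1).sum() / tree.n_nodes)
    adj = tree.adjacency_list()
    d0 = _bfs_dists(adj, 0)
    far = int(np.argmax(d0))
    d1 = _bfs_dists(adj, far)
    diameter = int(d1.max())
    return deg, leaf_fraction, diameter


def network_metrics(adj: AdjacencyMatrix | np.ndarray, modularity_runs: int = 100,
                    seed: int = 0) -> NetworkMetrics:
    """All scalar network metrics of one adjacency matrix."""
    a = adj if isinstance(adj, AdjacencyMatrix) else AdjacencyMatrix(np.asarray(adj, float))
    q, n_mod = modularity(a, n_runs=modularity_runs, seed=seed)
    tree = minimum_spanning_tree(a)
    deg, leaf, diam = mst_metrics(tree)
    return NetworkMetrics(
        cw=weighted_clustering(a),
        lw=weighted_path_length(a),
        q=q,
        n_modules=n_mod,
        mst_degree=deg,
        leaf_fraction=leaf,
        diameter=diam,
    )
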