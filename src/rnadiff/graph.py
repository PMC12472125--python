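"""Per-atom interaction graph with typed edges and geometric features.

Nodes are the atoms of the coarse 5-atom model.  Static edges (covalent
bonds and user-constrained canonical pairs) are coordinate-independent;
dynamic edges are distance-gated: local contacts within 5 A and long-range
interactions in (5, 16] A, each node capped at its 20 mutual nearest
neighbors per class.  Close-contact edges carry distances plus one-hop
angles theta and two-hop angles phi, expanded in 16 radial (spherical
Bessel) and 7 angular (Legendre) basis functions; long-range edges carry
distances only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import RnaStructure, SecondaryStructure, COARSE_ATOMS

LOCAL_CUTOFF = 5.0
GLOBAL_CUTOFF = 16.0
K_MAX = 20
N_RADIAL = 16
N_SPHERICAL = 7

COVALENT, PAIRING, LOCAL, GLOBAL = "covalent", "pairing", "local", "global"
#: edge classes aggregated by the local (close-contact) branch
CLOSE_CLASSES = (COVALENT, PAIRING, LOCAL)


@dataclass(frozen=True)
class Edge:
    i: int
    j: int
    cls: str

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("self-edges are not allowed")


@dataclass
class NodeInfo:
    atom_name: str
    element: str          # C, P or N in the coarse model
    residue_index: int    # global residue index
    base: str
    is_c4: bool


@dataclass
class EdgeFeatures:
    d: float
    thetas: np.ndarray          # one-hop angles at the source node
    phis: np.ndarray            # two-hop angles
    rbf: np.ndarray             # (N_RADIAL,)
    sbf: np.ndarray | None      # (N_SPHERICAL, N_RADIAL) for close edges


@dataclass
class RnaGraph:
    nodes: list[NodeInfo]
    edges: list[Edge]                       # undirected, i < j
    node_features: np.ndarray | None = None
    edge_features: dict[tuple[int, int], EdgeFeatures] = field(default_factory=dict)

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def edges_of_class(self, *classes: str) -> list[Edge]:
        return [e for e in self.edges if e.cls in classes]


# ---------------------------------------------------------------------------
# Node enumeration
# ---------------------------------------------------------------------------

def enumerate_nodes(structure: RnaStructure) -> tuple[list[NodeInfo], np.ndarray]:
    """Atoms in structure order with coordinates; coarse atom order per residue."""
    nodes: list[NodeInfo] = []
    coords: list[np.ndarray] = []
    ridx = 0
    for res in structure.residues():
        for name in COARSE_ATOMS[res.base]:
            atom = res.get(name)
            if atom is None:
                continue
            nodes.append(NodeInfo(name, atom.element, ridx, res.base,
                                  name == "C4'"))
            coords.append(atom.coord)
        ridx += 1
    return nodes, np.asarray(coords, float)


def _atom_index_map(structure: RnaStructure) -> dict[tuple[int, str], int]:
    out = {}
    k = 0
    ridx = 0
    for res in structure.residues():
        for name in COARSE_ATOMS[res.base]:
            if res.get(name) is None:
                continue
            out[(ridx, name)] = k
            k += 1
        ridx += 1
    return out


# ---------------------------------------------------------------------------
# Static edges
# ---------------------------------------------------------------------------

def build_static_edges(structure: RnaStructure,
                       ss: SecondaryStructure | None = None) -> list[Edge]:
    """Covalent and pairing edges, fixed regardless of coordinates.

    Per residue: P-C4', C4'-anchor and the three base-triangle edges; the
    backbone link C4'(i)-P(i+1) joins consecutive residues of a chain.  Each
    constrained canonical pair contributes two pairing edges, anchor-anchor
    and C2-C2, which fix both the distance and the relative twist of the
    pair.
    """
    amap = _atom_index_map(structure)
    residues = structure.residue_list()
    edges: list[Edge] = []

    def add(cls, ri, ni, rj, nj):
        a, b = amap.get((ri, ni)), amap.get((rj, nj))
        if a is None or b is None:
            return
        edges.append(Edge(min(a, b), max(a, b), cls))

    ridx = 0
    for chain in structure.chains:
        for pos, res in enumerate(chain):
            anchor, c2n, third = COARSE_ATOMS[res.base][2:]
            add(COVALENT, ridx, "P", ridx, "C4'")
            add(COVALENT, ridx, "C4'", ridx, anchor)
            add(COVALENT, ridx, anchor, ridx, c2n)
            add(COVALENT, ridx, c2n, ridx, third)
            add(COVALENT, ridx, third, ridx, anchor)
            if pos + 1 < len(chain):
                add(COVALENT, ridx, "C4'", ridx + 1, "P")
            ridx += 1

    if ss is not None:
        n = len(residues)
        for i, j in ss.pairs:
            if not (0 <= i < n and 0 <= j < n):
                raise IndexError(f"pair ({i},{j}) outside residue range 0..{n-1}")
            anchor_i = residues[i].anchor_name
            anchor_j = residues[j].anchor_name
            add(PAIRING, i, anchor_i, j, anchor_j)
            add(PAIRING, i, "C2", j, "C2")

    # dedupe while preserving order
    seen: set[tuple[int, int, str]] = set()
    out = []
    for e in edges:
        key = (e.i, e.j, e.cls)
        if key not in seen:
            seen.add(key)
            out.append(e)
    return out


# ---------------------------------------------------------------------------
# Dynamic edges
# ---------------------------------------------------------------------------

def build_dynamic_edges(coords: np.ndarray, static_edges: list[Edge],
                        k_max: int = K_MAX,
                        local_cutoff: float = LOCAL_CUTOFF,
                        global_cutoff: float = GLOBAL_CUTOFF) -> list[Edge]:
    """Distance-gated edges between atoms without an existing static edge.

    Distance <= ``local_cutoff`` -> local class; in (local, global] ->
    global class.  Per node and class only the ``k_max`` nearest neighbors
    are retained (ties broken by lower node index); an undirected edge
    survives only when both endpoints retain it, which caps every node's
    dynamic degree at ``k_max`` per class.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    if n < 2:
        return []
    if n <= 2000:
        dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    else:
        tree = cKDTree(coords)
        dmat = np.full((n, n), np.inf)
        pairs = tree.query_pairs(global_cutoff, output_type="ndarray")
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        dmat[pairs[:, 0], pairs[:, 1]] = d
        dmat[pairs[:, 1], pairs[:, 0]] = d
    blocked = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(blocked, True)
    for e in static_edges:
        blocked[e.i, e.j] = blocked[e.j, e.i] = True
    blocked |= dmat == 0.0

    edges: list[Edge] = []
    for cls, lo, hi in ((LOCAL, 0.0, local_cutoff),
                        (GLOBAL, local_cutoff, global_cutoff)):
        cand = (dmat > lo) & (dmat <= hi) & ~blocked
        if not cand.any():
            continue
        masked = np.where(cand, dmat, np.inf)
        # per-row k nearest (stable sort: ties resolved by lower index)
        order = np.argsort(masked, axis=1, kind="stable")[:, :k_max]
        keep = np.zeros((n, n), dtype=bool)
        rows = np.repeat(np.arange(n), order.shape[1])
        keep[rows, order.ravel()] = True
        keep &= cand
        mutual = keep & keep.T
        ii, jj = np.nonzero(np.triu(mutual, 1))
        edges.extend(Edge(int(i), int(j), cls) for i, j in zip(ii, jj))
    edges.sort(key=lambda e: (e.i, e.j, e.cls))
    return edges


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _angle(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length edge vector (coincident atoms)")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(c))


def edge_geometry(graph: RnaGraph, coords: np.ndarray) -> RnaGraph:
    """Fill distance/angle/basis features on every directed edge.

    For a close-contact edge (j -> i): theta entries are the angles at j
    between (i - j) and every other close neighbor k of j; phi entries are
    the planar angles between (j -> i) and each two-hop edge (k -> m) with
    m a close neighbor of k (DimeNet-style torsion surrogate).  Long-range
    edges receive the distance expansion only.
    """
    coords = np.asarray(coords, float)
    close_adj: dict[int, set[int]] = {}
    for e in graph.edges_of_class(*CLOSE_CLASSES):
        close_adj.setdefault(e.i, set()).add(e.j)
        close_adj.setdefault(e.j, set()).add(e.i)

    feats: dict[tuple[int, int], EdgeFeatures] = {}
    for e in graph.edges:
        for j, i in ((e.i, e.j), (e.j, e.i)):   # directed j -> i
            vec = coords[i] - coords[j]
            dist = float(np.linalg.norm(vec))
            if dist == 0.0:
                raise ValueError(f"coincident atoms {i}, {j}")
            if e.cls == GLOBAL:
                rbf, _ = basis_expand(dist, None, GLOBAL_CUTOFF)
                feats[(j, i)] = EdgeFeatures(dist, np.empty(0), np.empty(0),
                                             rbf, None)
                continue
            thetas = []
            for k in sorted(close_adj.get(j, ())):
                if k == i:
                    continue
                thetas.append(_angle(vec, coords[k] - coords[j]))
            phis = []
            for k in sorted(close_adj.get(j, ())):
                if k == i:
                    continue
                for m in sorted(close_adj.get(k, ())):
                    if m == j:
                        continue
                    phis.append(_angle(-vec, coords[m] - coords[k]))
            thetas = np.asarray(thetas)
            phis = np.asarray(phis)
            rbf, sbf = basis_expand(dist, thetas if len(thetas) else None,
                                    LOCAL_CUTOFF)
            if sbf is None:
                sbf = np.zeros((N_SPHERICAL, N_RADIAL))
                sbf[0] = rbf  # l=0 harmonic only when j has no other neighbor
            feats[(j, i)] = EdgeFeatures(dist, thetas, phis, rbf, sbf)
    graph.edge_features = feats
    return graph


# ---------------------------------------------------------------------------
# Basis functions
# ---------------------------------------------------------------------------

def _envelope(x: np.ndarray, p: int = 5) -> np.ndarray:
    """Smooth polynomial envelope, 1 at x=0 and 0 at x=1 (C^1 at the cutoff)."""
    a = -(p + 1) * (p + 2) / 2.0
    b = float(p * (p + 2))
    c = -p * (p + 1) / 2.0
    return 1.0 + a * x**p + b * x**(p + 1) + c * x**(p + 2)


def radial_basis(d: float, cutoff: float, n_radial: int = N_RADIAL,
                 envelope: bool = True) -> np.ndarray:
    """Spherical-Bessel (order 0) radial basis on [0, cutoff].

    b_n(d) = sqrt(2/c) * sin(n pi d / c) / d, orthonormal on [0, c] with the
    r^2 measure; multiplied by a smooth envelope vanishing at the cutoff.
    Finite at d -> 0 and identically zero for d >= cutoff.
    """
    if d <= 0:
        raise ValueError("distance must be positive")
    if d >= cutoff:
        return np.zeros(n_radial)
    n = np.arange(1, n_radial + 1)
    arg = n * np.pi * d / cutoff
    vals = np.sqrt(2.0 / cutoff) * np.sin(arg) / d
    if envelope:
        vals = vals * _envelope(np.array(d / cutoff))
    return vals


def radial_basis_vec(d: np.ndarray, cutoff: float,
                     n_radial: int = N_RADIAL) -> np.ndarray:
    """Vectorized :func:`radial_basis` over an array of distances."""
    d = np.asarray(d, float)
    n = np.arange(1, n_radial + 1)
    inside = d < cutoff
    safe = np.where(inside, d, cutoff / 2.0)
    vals = (np.sqrt(2.0 / cutoff) * np.sin(np.outer(safe, n) * np.pi / cutoff)
            / safe[:, None])
    vals *= _envelope(safe / cutoff)[:, None]
    vals[~inside] = 0.0
    return vals


def angular_basis(theta: np.ndarray, n_spherical: int = N_SPHERICAL) -> np.ndarray:
    """Zonal harmonics P_l(cos theta), l = 0..n_spherical-1, shape (L, len(theta))."""
    x = np.cos(np.atleast_1d(theta))
    out = np.empty((n_spherical, len(x)))
    out[0] = 1.0
    if n_spherical > 1:
        out[1] = x
    for l in range(2, n_spherical):
        out[l] = ((2 * l - 1) * x * out[l - 1] - (l - 1) * out[l - 2]) / l
    return out


def basis_expand(d: float, theta: np.ndarray | None, cutoff: float,
                 n_radial: int = N_RADIAL, n_spherical: int = N_SPHERICAL
                 ) -> tuple[np.ndarray, np.ndarray | None]:
    """Radial expansion of d, and (for close edges) the angular-radial product.

    The spherical part sums the zonal harmonics over the supplied one-hop
    angles and takes the outer product with the radial expansion, giving a
    fixed (n_spherical, n_radial) feature regardless of neighbor count.
    """
    rbf = radial_basis(d, cutoff, n_radial)
    if theta is None:
        return rbf, None
    harm = angular_basis(theta, n_spherical).sum(axis=1)
    return rbf, np.outer(harm, rbf)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

_ELEMENT_ORDER = ("C", "P", "N")
_BASE_ORDER = ("A", "G", "C", "U")
SEQ_EMB_DIM = 256
TIME_EMB_DIM = 16


def node_feature_matrix(nodes: list[NodeInfo], seq_embeddings: np.ndarray,
                        t_embedding: np.ndarray) -> np.ndarray:
    """Concatenate atom one-hot, C4' flag, residue one-hot, sequence and
    time embeddings into one (n_nodes, 3+1+4+256+16) feature matrix."""
    if t_embedding.shape != (TIME_EMB_DIM,):
        raise ValueError("time embedding must have length 16")
    n = len(nodes)
    feats = np.zeros((n, 3 + 1 + 4 + SEQ_EMB_DIM + TIME_EMB_DIM))
    for k, node in enumerate(nodes):
        feats[k, _ELEMENT_ORDER.index(node.element)] = 1.0
        feats[k, 3] = float(node.is_c4)
        feats[k, 4 + _BASE_ORDER.index(node.base)] = 1.0
        feats[k, 8:8 + SEQ_EMB_DIM] = seq_embeddings[node.residue_index]
        feats[k, 8 + SEQ_EMB_DIM:] = t_embedding
    return feats


def assemble_graph(structure: RnaStructure, ss: SecondaryStructure | None,
                   seq_embeddings: np.ndarray, t_embedding: np.ndarray,
                   coords: np.ndarray | None = None,
                   with_geometry: bool = True) -> RnaGraph:
    """Full graph: nodes in structure order, static then dynamic edges.

    ``seq_embeddings`` is (n_residues, 256): every atom of residue r carries
    residue r's embedding.  Edge geometry is computed on unscaled angstrom
    coordinates (``coords`` overrides the structure's own, e.g. for noisy
    diffusion states).
    """
    nodes, own_coords = enumerate_nodes(structure)
    coords = own_coords if coords is None else np.asarray(coords, float)
    if len(coords) != len(nodes):
        raise ValueError("coordinate/node count mismatch")
    if len(seq_embeddings) != structure.n_residues:
        raise ValueError("embedding/residue count mismatch")
    static = build_static_edges(structure, ss)
    dynamic = build_dynamic_edges(coords, static)
    graph = RnaGraph(nodes=nodes, edges=static + dynamic)
    graph.node_features = node_feature_matrix(nodes, np.asarray(seq_embeddings),
                                              np.asarray(t_embedding))
    if with_geometry:
        edge_geometry(graph, coords)
    return graph


def directed_edge_arrays(edges: list[Edge], classes: tuple[str, ...]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Both directions of every edge in the given classes: (src, dst) arrays."""
    src, dst = [], []
    for e in edges:
        if e.cls in classes:
            src.extend((e.i, e.j))
            dst.extend((e.j, e.i))
    return np.asarray(src, dtype=int), np.asarray(dst, dtype=int)


def close_edge_feature_matrix(edges: list[Edge], coords: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized features for all directed close-contact edges.

    Returns (src, dst, features) where features has one row per directed
    edge (j -> i): [rbf (16) | summed theta-harmonics x rbf (7*16) | summed
    phi-harmonics (7)].  Equivalent to :func:`edge_geometry` aggregates but
    computed with array ops so it can run inside the training loop.
    """
    coords = np.asarray(coords, float)
    src, dst = directed_edge_arrays(edges, CLOSE_CLASSES)
    ne = len(src)
    feats = np.zeros((ne, N_RADIAL + N_SPHERICAL * N_RADIAL + N_SPHERICAL))
    if ne == 0:
        return src, dst, feats
    vec = coords[dst] - coords[src]
    dists = np.linalg.norm(vec, axis=1)
    if np.any(dists == 0.0):
        raise ValueError("coincident atoms on a close edge")
    rbf = radial_basis_vec(dists, LOCAL_CUTOFF)

    # grouped adjacency over directed close edges, sorted by source node
    n_nodes = int(max(src.max(), dst.max())) + 1
    order = np.argsort(src, kind="stable")
    nbr_flat = dst[order]                      # concatenated neighbor lists
    deg = np.bincount(src, minlength=n_nodes)
    off = np.concatenate([[0], np.cumsum(deg)])

    def grouped_expand(anchor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """For each row r, emit (r, m) for every neighbor m of anchor[r]."""
        reps = deg[anchor]
        total = int(reps.sum())
        if total == 0:
            return np.empty(0, int), np.empty(0, int)
        rows = np.repeat(np.arange(len(anchor)), reps)
        starts = np.repeat(off[anchor], reps)
        pos = np.arange(total) - np.repeat(np.cumsum(reps) - reps, reps) + starts
        return rows, nbr_flat[pos]

    # one-hop triplets (edge e = j->i, neighbor k of j, k != i)
    rows, ks = grouped_expand(src)
    keep = ks != dst[rows]
    trip_e, trip_k = rows[keep], ks[keep]
    harm_sum = np.zeros((ne, N_SPHERICAL))
    if len(trip_e):
        u = vec[trip_e]
        w = coords[trip_k] - coords[src[trip_e]]
        cosang = np.einsum("ij,ij->i", u, w) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1))
        cosang = np.clip(cosang, -1.0, 1.0)
        np.add.at(harm_sum, trip_e, _legendre_all(cosang).T)
    has_nb = harm_sum[:, 0] > 0
    sbf = np.einsum("el,er->elr", harm_sum, rbf)
    # edges whose source has no other close neighbor: l=0 harmonic only
    sbf[~has_nb, 0, :] = rbf[~has_nb]

    # two-hop chains i <- j <- k -> m, m != j
    phi_sum = np.zeros((ne, N_SPHERICAL))
    if len(trip_e):
        trows, ms = grouped_expand(trip_k)
        qe, qk, qm = trip_e[trows], trip_k[trows], ms
        keep = qm != src[qe]
        qe, qk, qm = qe[keep], qk[keep], qm[keep]
        if len(qe):
            u = -vec[qe]
            w = coords[qm] - coords[qk]
            cosang = np.einsum("ij,ij->i", u, w) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1))
            cosang = np.clip(cosang, -1.0, 1.0)
            np.add.at(phi_sum, qe, _legendre_all(cosang).T)

    feats[:, :N_RADIAL] = rbf
    feats[:, N_RADIAL:N_RADIAL + N_SPHERICAL * N_RADIAL] = sbf.reshape(ne, -1)
    feats[:, N_RADIAL + N_SPHERICAL * N_RADIAL:] = phi_sum
    return src, dst, feats


def _legendre_all(x: np.ndarray, n: int = N_SPHERICAL) -> np.ndarray:
    out = np.empty((n, len(x)))
    out[0] = 1.0
    if n > 1:
        out[1] = x
    for l in range(2, n):
        out[l] = ((2 * l - 1) * x * out[l - 1] - (l - 1) * out[l - 2]) / l
    return out


def global_edge_feature_matrix(edges: list[Edge], coords: np.ndarray
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (src, dst, rbf) for all directed long-range edges."""
    coords = np.asarray(coords, float)
    src, dst = directed_edge_arrays(edges, (GLOBAL,))
    if len(src) == 0:
        return src, dst, np.zeros((0, N_RADIAL))
    dists = np.linalg.norm(coords[dst] - coords[src], axis=1)
    rbf = radial_basis_vec(dists, GLOBAL_CUTOFF)
    return src, dst, rbf


def dump_edges(graph: RnaGraph, path) -> None:
    """Deterministic delimited edge list (i, j, class, d) for diffing."""
    lines = ["i\tj\tclass\td\n"]
    for e in sorted(graph.edges, key=lambda e: (e.i, e.j, e.cls)):
        f = graph.edge_features.get((e.i, e.j))
        d = f.d if f else float("nan")
        lines.append(f"{e.i}\t{e.j}\t{e.cls}\t{d:.6f}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
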