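"""Community phylogeny and ancestral (Steiner) pathway inference.

A neighbor-joining tree is built over the k deconvolved communities from
Euclidean distances between their pathway columns.  The unrooted binary tree
has k leaves (extant communities) and k−2 internal Steiner nodes; edge
weights are inverse branch lengths.  Each pathway dimension i of the Steiner
nodes is inferred independently by minimizing the elastic energy

    U(x, y; W) = Σ_{(u,v)∈E, v Steiner} ½ w_uv (x_u − x_v)²
               + Σ_{(u,v)∈E, v extant } ½ w_uv (x_u − y_v)²,

a positive-definite quadratic form whose unique minimizer solves the linear
system P x = −q, where P is the weighted graph Laplacian restricted to the
Steiner nodes plus the extant-edge weight diagonal, and q collects the
−w·y terms of Steiner–extant edges.

Node indexing: Steiner nodes take indices 0..k−3, extant nodes k−2..2k−3
(extant index k−2+j corresponds to community column j of C); every edge is
stored as (u, v) with u < v, so u is always a Steiner node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

__all__ = [
    "CommunityTree",
    "SteinerSystem",
    "EdgeReport",
    "CommunityLabels",
    "community_distances",
    "nj_tree",
    "build_Pq",
    "steiner_solve",
    "infer_steiner_pathways",
    "edge_perturbations",
    "classify_communities",
    "tree_to_newick",
]

D_FLOOR = 1e-6  # floor on branch lengths inside weights; keeps P finite


@dataclass
class CommunityTree:
    """Unrooted binary tree over k communities with k−2 Steiner nodes."""

    k: int
    extant_names: list
    edges: list  # (u, v) with u < v; u always Steiner
    lengths: dict  # (u, v) → branch length ≥ 0
    extant_matrix: np.ndarray | None = None  # C, m × k
    steiner_matrix: np.ndarray | None = None  # X, m × (k−2)
    row_names: list | None = None
    d_floor: float = D_FLOOR

    def __post_init__(self):
        ns = self.n_steiner
        if len(self.edges) != 2 * self.k - 3:
            raise ValueError(
                f"expected {2 * self.k - 3} edges for k={self.k}, got {len(self.edges)}"
            )
        deg = {}
        for u, v in self.edges:
            if not (u < v and u < ns):
                raise ValueError(f"edge ({u},{v}) violates the indexing convention")
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        for s in range(ns):
            if deg.get(s, 0) != 3:
                raise ValueError(f"Steiner node {s} has degree {deg.get(s, 0)} != 3")
        for e in range(ns, ns + self.k):
            if deg.get(e, 0) != 1:
                raise ValueError(f"extant node {e} has degree {deg.get(e, 0)} != 1")

    @property
    def n_steiner(self) -> int:
        return self.k - 2

    @property
    def steiner_ids(self) -> list:
        return list(range(self.n_steiner))

    @property
    def extant_ids(self) -> list:
        return list(range(self.n_steiner, self.n_steiner + self.k))

    def weight(self, u, v) -> float:
        d = self.lengths[(min(u, v), max(u, v))]
        return 1.0 / max(d, self.d_floor)

    def node_name(self, node: int) -> str:
        if node < self.n_steiner:
            return f"S{node + 1}"
        return str(self.extant_names[node - self.n_steiner])

    def node_vector(self, node: int) -> np.ndarray:
        """Pathway profile of a node (extant column of C or Steiner column of X)."""
        if node < self.n_steiner:
            if self.steiner_matrix is None:
                raise ValueError("Steiner matrix not inferred yet")
            return self.steiner_matrix[:, node]
        if self.extant_matrix is None:
            raise ValueError("extant matrix not set")
        return self.extant_matrix[:, node - self.n_steiner]

    def adjacency(self) -> dict:
        adj = {}
        for u, v in self.edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        return adj


@dataclass
class SteinerSystem:
    """Quadratic program ½xᵀPx + qᵀx for one pathway dimension."""

    P: np.ndarray
    q: np.ndarray
    dimension: int = 0
    y: np.ndarray | None = None
    x: np.ndarray | None = None


@dataclass
class EdgeReport:
    edge: tuple  # (parent name, child name), oriented away from the root
    delta: np.ndarray  # child − parent on the reported pathway rows
    top_gained: list  # up to 5 names, |delta| descending
    top_lost: list
    large_changes: list  # names with |delta| > magnitude threshold


@dataclass
class CommunityLabels:
    component_labels: list  # per component: primary | metastatic | neutral
    delta: np.ndarray  # per component mean fraction change (metastatic − primary)
    presence: dict  # patient → boolean array over components
    patient_case: dict  # patient → 1|2|3|4|"other"
    presence_threshold: float
    change_threshold: float


def community_distances(C: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between community pathway columns."""
    C = np.asarray(C, float)
    k = C.shape[1]
    if k < 3:
        raise ValueError("need at least 3 communities for a phylogeny")
    diff = C[:, :, None] - C[:, None, :]
    return np.sqrt((diff**2).sum(axis=0))


def nj_tree(
    D: np.ndarray,
    names: list | None = None,
    extant_matrix: np.ndarray | None = None,
    row_names: list | None = None,
    d_floor: float = D_FLOOR,
) -> CommunityTree:
    """Neighbor joining on a symmetric distance matrix.

    Negative estimated branch lengths are clamped to zero; weights floor the
    clamped lengths at ``d_floor`` so they stay finite.
    """
    D = np.asarray(D, float)
    k = D.shape[0]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if k < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    names = [f"C{i + 1}" for i in range(k)] if names is None else list(names)
    tree = _skbio_nj(DistanceMatrix(D, ids=[str(n) for n in names]))

    # convert the skbio TreeNode (root = trifurcating internal node) to the
    # flat indexing convention: Steiner 0..k−3, extant k−2..2k−3
    internals = [n for n in tree.traverse() if n.children]
    leaves = {n.name: n for n in tree.tips()}
    assert len(internals) == k - 2, "unexpected NJ topology"
    index = {}
    for i, node in enumerate(internals):
        index[id(node)] = i
    for j, name in enumerate(names):
        index[id(leaves[str(name)])] = (k - 2) + j
    edges, lengths = [], {}
    for node in tree.traverse():
        if node.parent is None:
            continue
        u, v = index[id(node.parent)], index[id(node)]
        u, v = min(u, v), max(u, v)
        edges.append((u, v))
        lengths[(u, v)] = max(float(node.length or 0.0), 0.0)
    return CommunityTree(
        k=k,
        extant_names=names,
        edges=sorted(edges),
        lengths=lengths,
        extant_matrix=None if extant_matrix is None else np.asarray(extant_matrix, float),
        row_names=row_names,
        d_floor=d_floor,
    )


def build_Pq(tree: CommunityTree, y: np.ndarray, dimension: int = 0) -> SteinerSystem:
    """Accumulate the quadratic form for one pathway dimension.

    A Steiner–Steiner edge of weight w adds w to both diagonal entries and
    −w off-diagonal; a Steiner–extant edge adds w to the Steiner diagonal
    and −w·y_v to q.
    """
    y = np.asarray(y, float)
    if y.shape != (tree.k,):
        raise ValueError(f"y must have length k={tree.k}")
    ns = tree.n_steiner
    P = np.zeros((ns, ns))
    q = np.zeros(ns)
    for u, v in tree.edges:
        w = tree.weight(u, v)
        if v < ns:  # Steiner–Steiner
            P[u, u] += w
            P[v, v] += w
            P[u, v] -= w
            P[v, u] -= w
        else:  # Steiner–extant
            P[u, u] += w
            q[u] -= w * y[v - ns]
    return SteinerSystem(P=P, q=q, dimension=dimension, y=y)


def steiner_solve(system: SteinerSystem) -> np.ndarray:
    """Closed-form minimizer x* = −P⁻¹q of the elastic energy."""
    P, q = system.P, system.q
    try:
        x = np.linalg.solve(P, -q)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular Steiner system (disconnected tree or zero weights)"
        ) from exc
    residual = np.abs(P @ x + q).max()
    if residual >= 1e-9:
        raise FloatingPointError(f"stationarity residual {residual:.2e} too large")
    system.x = x
    return x


def elastic_energy(tree: CommunityTree, x: np.ndarray, y: np.ndarray) -> float:
    """U(x, y; W): weighted sum of squared differences along edges."""
    ns = tree.n_steiner
    U = 0.0
    for u, v in tree.edges:
        w = tree.weight(u, v)
        xv = x[v] if v < ns else y[v - ns]
        U += 0.5 * w * (x[u] - xv) ** 2
    return U


def infer_steiner_pathways(tree: CommunityTree) -> CommunityTree:
    """Solve all m pathway dimensions independently; fills steiner_matrix."""
    if tree.extant_matrix is None:
        raise ValueError("extant_matrix must be set before inference")
    C = tree.extant_matrix
    X = np.empty((C.shape[0], tree.n_steiner))
    for i in range(C.shape[0]):
        X[i] = steiner_solve(build_Pq(tree, C[i], dimension=i))
    tree.steiner_matrix = X
    return tree


def _orient_from(tree: CommunityTree, root: int):
    """Directed (parent, child) edges away from the root, BFS order."""
    adj = tree.adjacency()
    if root not in adj:
        raise ValueError(f"root node {root} is not in the tree")
    seen = {root}
    order = [root]
    directed = []
    for node in order:
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                order.append(nb)
                directed.append((node, nb))
    return directed


def edge_perturbations(
    tree: CommunityTree,
    root,
    pathway_rows=None,
    top: int = 5,
    magnitude: float = 1.0,
) -> list[EdgeReport]:
    """Per-edge pathway changes along trajectories directed away from a root.

    ``root`` may be a node index or an extant community name.  ``delta`` is
    child minus parent restricted to ``pathway_rows`` (defaults to all rows);
    the top gained (positive) and lost (negative) rows are ranked by
    |delta| descending, and ``large_changes`` lists rows with
    |delta| > ``magnitude``.
    """
    if tree.steiner_matrix is None:
        raise ValueError("infer Steiner pathways before edge perturbation analysis")
    if isinstance(root, str):
        if root not in tree.extant_names:
            raise ValueError(f"root community {root!r} not found")
        root = tree.n_steiner + tree.extant_names.index(root)
    m = tree.extant_matrix.shape[0]
    rows = np.arange(m) if pathway_rows is None else np.asarray(pathway_rows, int)
    if tree.row_names is not None:
        row_labels = [tree.row_names[i] for i in rows]
    else:
        row_labels = [f"row{i}" for i in rows]
    reports = []
    for parent, child in _orient_from(tree, root):
        delta = tree.node_vector(child)[rows] - tree.node_vector(parent)[rows]
        order = np.argsort(-np.abs(delta), kind="stable")
        gained = [row_labels[i] for i in order if delta[i] > 0][:top]
        lost = [row_labels[i] for i in order if delta[i] < 0][:top]
        large = [row_labels[i] for i in order if abs(delta[i]) > magnitude]
        reports.append(
            EdgeReport(
                edge=(tree.node_name(parent), tree.node_name(child)),
                delta=delta,
                top_gained=gained,
                top_lost=lost,
                large_changes=large,
            )
        )
    return reports


DEFAULT_CASE_MAP = {2: 0, 3: 1, 4: 4}  # case → missing component index


def classify_communities(
    F: np.ndarray,
    sample_ids: list,
    annotation: dict,
    change_threshold: float = 0.05,
    presence_threshold: float = 0.01,
    case_map: dict | None = None,
) -> CommunityLabels:
    """Label components primary/metastatic/neutral and type the patients.

    A component is metastatic if its mean fraction change from each patient's
    primary to metastatic sample exceeds +``change_threshold``, primary if it
    falls below −``change_threshold``, neutral otherwise.  A component is
    present in a patient when its fraction exceeds ``presence_threshold`` in
    either of the patient's samples.  A patient is case 1 when all k
    components are present; cases 2–4 when exactly the component designated
    by ``case_map`` is missing; anything else is "other".
    """
    F = np.asarray(F, float)
    k = F.shape[0]
    case_map = DEFAULT_CASE_MAP if case_map is None else case_map
    cols = {}
    for j, s in enumerate(sample_ids):
        if s not in annotation:
            raise ValueError(f"sample {s!r} missing from annotation")
        patient, stage = annotation[s]
        cols.setdefault(patient, {})[stage] = j
    for patient, by_stage in cols.items():
        if set(by_stage) != {"primary", "metastatic"}:
            raise ValueError(
                f"patient {patient!r} lacks a matched primary/metastatic pair"
            )
    patients = sorted(cols)
    pri = np.array([cols[p]["primary"] for p in patients])
    met = np.array([cols[p]["metastatic"] for p in patients])
    delta = (F[:, met] - F[:, pri]).mean(axis=1)
    labels = [
        "metastatic" if d > change_threshold
        else "primary" if d < -change_threshold
        else "neutral"
        for d in delta
    ]
    presence = {
        p: np.maximum(F[:, cols[p]["primary"]], F[:, cols[p]["metastatic"]])
        > presence_threshold
        for p in patients
    }
    cases = {}
    missing_to_case = {v: c for c, v in case_map.items()}
    for p in patients:
        absent = np.flatnonzero(~presence[p])
        if absent.size == 0:
            cases[p] = 1
        elif absent.size == 1 and int(absent[0]) in missing_to_case:
            cases[p] = missing_to_case[int(absent[0])]
        else:
            cases[p] = "other"
    return CommunityLabels(
        component_labels=labels,
        delta=delta,
        presence=presence,
        patient_case=cases,
        presence_threshold=presence_threshold,
        change_threshold=change_threshold,
    )


def tree_to_newick(tree: CommunityTree) -> str:
    """Newick string rooted at Steiner node S1 (trifurcating root).

    Steiner nodes are labeled S1..S{k−2}; branch lengths are the NJ edge
    lengths.
    """
    adj = tree.adjacency()

    def subtree(node, parent):
        children = [nb for nb in adj[node] if nb != parent]
        label = tree.node_name(node)
        if parent is None:
            inner = ",".join(subtree(c, node) for c in children)
            return f"({inner}){label};"
        d = tree.lengths[(min(node, parent), max(node, parent))]
        if not children:
            return f"{label}:{d:g}"
        inner = ",".join(subtree(c, node) for c in children)
        return f"({inner}){label}:{d:g}"

    return subtree(0, None)
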