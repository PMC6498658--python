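"""Advocacy-coalition detection on thresholded discourse networks.

Coalitions are cohesive subgroups of actors with similar argumentative
patterns.  The exploratory detector is Girvan-Newman edge-betweenness
clustering (divisive removal of high-betweenness edges; dendrogram cut at
maximum modularity).  For the bipolarisation measure an ensemble of eleven
clustering techniques, each constrained to k = 2 clusters, is run and the
best modularity among them is taken.

Per the package's convention, clustering operates on the *binarised*
thresholded graph (an edge exists iff the normalised tie weight survived
the threshold), while modularity is scored with the surviving tie weights.
Isolates — actors whose every tie fell below the threshold — are reported
separately, not as singleton coalitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import scipy.linalg
import scipy.spatial.distance

from .errors import ConsistencyError, ParameterError
from .network import ActorNetwork
from .transform import StanceProfile


@dataclass
class Partition:
    """Assignment of actors to coalitions, with provenance.

    Cluster ids are contiguous from 0, numbered by decreasing cluster size
    (ties broken by first appearance in node order).  ``modularity`` is the
    weighted Newman-Girvan Q of this partition on its source network.
    """

    assignment: dict
    k: int
    method: str
    seed: int | None = None
    modularity: float | None = None
    isolates: list = field(default_factory=list)

    def clusters(self) -> dict:
        out: dict = {}
        for actor, cid in self.assignment.items():
            out.setdefault(cid, []).append(actor)
        return out

    def sizes(self) -> list:
        return sorted((len(m) for m in self.clusters().values()), reverse=True)


def _canonical_partition(nodes, labels) -> dict:
    """Relabel clusters 0..k-1 by decreasing size, then first appearance."""
    labels = list(labels)
    counts: dict = {}
    first: dict = {}
    for i, lab in enumerate(labels):
        counts[lab] = counts.get(lab, 0) + 1
        first.setdefault(lab, i)
    order = sorted(counts, key=lambda lab: (-counts[lab], first[lab]))
    remap = {lab: i for i, lab in enumerate(order)}
    return {a: remap[lab] for a, lab in zip(nodes, labels)}


def modularity(n: ActorNetwork, p: Partition | dict, weighted: bool = True) -> float:
    """Newman-Girvan modularity Q = sum_c (e_cc - a_c^2).

    e_cc is the fraction of total edge weight falling within cluster c and
    a_c the fraction of edge endpoints attached to c.  With ``weighted=False``
    surviving ties count 1 each.  Q lies in [-0.5, 1].
    """
    assignment = p.assignment if isinstance(p, Partition) else dict(p)
    missing = [a for a in assignment if a not in n._index]
    if missing:
        raise ConsistencyError(f"actors in partition absent from network: {missing[:5]}")
    covered = set(assignment)
    uncovered = [a for a in n.non_isolates() if a not in covered]
    if uncovered:
        raise ConsistencyError(f"non-isolate actors not assigned: {uncovered[:5]}")
    nodes = [a for a in n.nodes if a in covered]
    idx = [n.index(a) for a in nodes]
    W = n.weights[np.ix_(idx, idx)]
    A = np.where(W > 0, W if weighted else 1.0, 0.0)
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    labels = np.array([assignment[a] for a in nodes])
    q = 0.0
    deg = A.sum(axis=1)
    for cid in np.unique(labels):
        mask = labels == cid
        e_cc = A[np.ix_(mask, mask)].sum() / two_m
        a_c = deg[mask].sum() / two_m
        q += e_cc - a_c**2
    return float(q)


def _igraph_from(net: ActorNetwork, nodes) -> ig.Graph:
    idx = {a: i for i, a in enumerate(nodes)}
    sub = net.weights[np.ix_([net.index(a) for a in nodes], [net.index(a) for a in nodes])]
    ii, jj = np.nonzero(np.triu(sub > 0, k=1))
    g = ig.Graph(n=len(nodes), edges=list(zip(ii.tolist(), jj.tolist())))
    g.vs["name"] = list(nodes)
    return g


def girvan_newman(n: ActorNetwork, stop: str | int = "max-modularity") -> Partition:
    """Girvan-Newman edge-betweenness community detection.

    Edges of the binarised graph are removed in decreasing order of edge
    betweenness; the resulting dendrogram is cut at the maximum-modularity
    level (default) or at a requested cluster count ``stop=k``.  Isolates
    are reported on the partition, not assigned to coalitions.
    """
    members = n.non_isolates()
    isolates = n.isolates()
    if not members:
        warnings.warn("network has no ties; every node is an isolate", stacklevel=2)
        return Partition(assignment={}, k=0, method="girvan_newman", isolates=isolates)
    g = _igraph_from(n, members)
    dendro = g.community_edge_betweenness(directed=False)
    if stop == "max-modularity":
        clustering = dendro.as_clustering()
    elif isinstance(stop, int):
        if stop < 1:
            raise ParameterError(f"stop={stop} must be a positive cluster count")
        # divisive clustering cannot merge pre-existing components: stop=k
        # means k-1 splits beyond the graph's initial components (exactly k
        # clusters on a connected graph)
        n_comp = len(g.connected_components())
        clustering = dendro.as_clustering(n_comp + stop - 1)
    else:
        raise ParameterError(f"unknown stopping rule {stop!r}")
    assignment = _canonical_partition(members, clustering.membership)
    part = Partition(
        assignment=assignment,
        k=len(set(assignment.values())),
        method="girvan_newman",
        isolates=isolates,
    )
    part.modularity = modularity(n, part)
    return part


# ---------------------------------------------------------------------------
# k = 2 clustering ensemble
# ---------------------------------------------------------------------------


def _gn_k2(nodes, A, G, net, rng):
    g = _igraph_from(net, nodes)
    dendro = g.community_edge_betweenness(directed=False)
    return dendro.as_clustering(2).membership


def _leading_eigenvector(nodes, A, G, net, rng):
    # Newman's spectral bisection on the modularity matrix B = A - kk^T/2m
    deg = A.sum(axis=1)
    two_m = deg.sum()
    B = A - np.outer(deg, deg) / two_m
    vals, vecs = scipy.linalg.eigh(B)
    v = vecs[:, -1]
    labels = (v >= 0).astype(int)
    if labels.min() == labels.max():
        raise ValueError("leading eigenvector does not split the graph")
    return labels


def _fiedler_bisection(nodes, A, G, net, rng):
    # sign split of the Fiedler vector of the combinatorial Laplacian
    deg = A.sum(axis=1)
    L = np.diag(deg) - A
    vals, vecs = scipy.linalg.eigh(L)
    v = vecs[:, 1]
    labels = (v >= np.median(v)).astype(int)
    if labels.min() == labels.max():
        labels = (v >= 0).astype(int)
    if labels.min() == labels.max():
        raise ValueError("Fiedler vector does not split the graph")
    return labels


def _greedy_modularity_k2(nodes, A, G, net, rng):
    comms = nx.community.greedy_modularity_communities(G, cutoff=2, best_n=2)
    lookup = {a: i for i, com in enumerate(comms) for a in com}
    return [lookup[a] for a in nodes]


def _walktrap_medoids(nodes, A, G, net, rng, t: int = 3, max_iter: int = 30):
    # t-step random-walk profiles; 2-medoids on Euclidean profile distance
    deg = A.sum(axis=1)
    P = A / deg[:, None]
    X = np.linalg.matrix_power(P, t)
    D = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(X))
    # farthest-pair initialisation (deterministic)
    m0, m1 = np.unravel_index(np.argmax(D), D.shape)
    medoids = [int(m0), int(m1)]
    labels = np.zeros(len(nodes), dtype=int)
    for _ in range(max_iter):
        labels = (D[:, medoids[1]] < D[:, medoids[0]]).astype(int)
        new = []
        for cid in (0, 1):
            members = np.flatnonzero(labels == cid)
            if members.size == 0:
                raise ValueError("empty medoid cluster")
            within = D[np.ix_(members, members)].sum(axis=1)
            new.append(int(members[np.argmin(within)]))
        if new == medoids:
            break
        medoids = new
    if labels.min() == labels.max():
        raise ValueError("medoids collapse to one cluster")
    return labels


def _spectral_kmeans(nodes, A, G, net, rng):
    from sklearn.cluster import KMeans

    deg = A.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(deg)
    L_sym = np.eye(len(nodes)) - d_isqrt[:, None] * A * d_isqrt[None, :]
    vals, vecs = scipy.linalg.eigh(L_sym)
    emb = vecs[:, :2]
    norms = np.linalg.norm(emb, axis=1)
    emb = emb / np.where(norms > 0, norms, 1.0)[:, None]
    seed = int(rng.integers(2**31 - 1))
    km = KMeans(n_clusters=2, n_init=4, random_state=seed)
    return km.fit_predict(emb)


def _kernighan_lin(nodes, A, G, net, rng):
    seed = int(rng.integers(2**31 - 1))
    side_a, side_b = nx.community.kernighan_lin_bisection(G, seed=seed)
    return [0 if a in side_a else 1 for a in nodes]


DEFAULT_K2_METHODS = (
    ("girvan_newman_k2", _gn_k2),
    ("leading_eigenvector", _leading_eigenvector),
    ("fiedler_bisection", _fiedler_bisection),
    ("greedy_modularity_k2", _greedy_modularity_k2),
    ("walktrap_2medoids", _walktrap_medoids),
    ("spectral_kmeans_1", _spectral_kmeans),
    ("spectral_kmeans_2", _spectral_kmeans),
    ("spectral_kmeans_3", _spectral_kmeans),
    ("kernighan_lin_1", _kernighan_lin),
    ("kernighan_lin_2", _kernighan_lin),
    ("kernighan_lin_3", _kernighan_lin),
)


def cluster_k2_ensemble(n: ActorNetwork, methods=None, seed: int | None = None) -> list:
    """Run the k = 2 clustering ensemble (default: 11 techniques).

    Each method yields a :class:`Partition` with its weighted modularity;
    stochastic methods draw their seeds deterministically from ``seed``.
    A method failing on a degenerate graph is recorded as a warning and
    skipped — the ensemble never aborts.
    """
    members = n.non_isolates()
    if len(members) < 2:
        raise ParameterError("k=2 ensemble needs at least 2 non-isolate actors")
    isolates = n.isolates()
    idx = [n.index(a) for a in members]
    W = n.weights[np.ix_(idx, idx)]
    A = (W > 0).astype(float)
    G = nx.Graph()
    G.add_nodes_from(members)
    ii, jj = np.nonzero(np.triu(A, k=1))
    G.add_edges_from((members[i], members[j]) for i, j in zip(ii.tolist(), jj.tolist()))

    methods = list(methods) if methods is not None else list(DEFAULT_K2_METHODS)
    master = np.random.default_rng(seed)
    partitions = []
    for name, fn in methods:
        rng = np.random.default_rng(master.integers(2**31 - 1))
        try:
            labels = fn(members, A, G, n, rng)
        except Exception as e:  # degenerate graphs: record and move on
            warnings.warn(f"k=2 method {name!r} failed: {e}", stacklevel=2)
            continue
        assignment = _canonical_partition(members, labels)
        part = Partition(
            assignment=assignment,
            k=len(set(assignment.values())),
            method=name,
            seed=seed,
            isolates=isolates,
        )
        part.modularity = modularity(n, part)
        partitions.append(part)
    return partitions


def label_coalitions(p: Partition, profile: StanceProfile, pro_concepts) -> dict:
    """Label each coalition supportive / sceptical / other of the policy.

    A cluster is *supportive* iff its members' mean stance over the given
    pro-policy concepts is positive, *sceptical* iff negative, *other* on a
    tie or when no member mentions any of the concepts.
    """
    pro = set(pro_concepts)
    if not pro:
        raise ParameterError("pro_concepts must be non-empty")
    known = {c for (_a, c) in profile.stance}
    if not pro & known:
        raise ParameterError("none of the pro_concepts appear in the stance profile")
    labels = {}
    for cid, members in p.clusters().items():
        values = [
            profile.stance[(a, c)]
            for a in members
            for c in pro
            if (a, c) in profile.stance
        ]
        if not values:
            warnings.warn(f"cluster {cid}: no member mentions any pro-policy concept", stacklevel=2)
            labels[cid] = "other"
            continue
        mean = float(np.mean(values))
        labels[cid] = "supportive" if mean > 0 else "sceptical" if mean < 0 else "other"
    return labels
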