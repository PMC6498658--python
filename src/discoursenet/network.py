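"""Weighted actor x actor networks.

The same container carries a network through every stage of the pipeline:
raw congruence/conflict counts, the subtract-transformed and
activity-normalised weights, and the thresholded graph on which coalitions
are detected.  ``stage`` records which of these the weights represent;
``threshold_used`` records the tie-weight cut-off once one has been applied.
Matrices loaded from external files (e.g. exports of the DNA coding
software) carry ``stage="unknown"`` because their provenance — pre- or
post-threshold, pre- or post-normalisation — is not recoverable from the
file itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import MatrixFormatError, ParameterError

STAGES = ("congruence", "conflict", "subtract_raw", "normalised", "thresholded", "unknown")

_SYMMETRY_TOL = 1e-9


@dataclass
class ActorNetwork:
    """Symmetric weighted actor network.

    Parameters
    ----------
    nodes : list of str
        Ordered actor labels (order is the row/column order of ``weights``).
    weights : (n, n) ndarray
        Symmetric tie-weight matrix with zero diagonal.
    stage : str
        One of :data:`STAGES`.
    threshold_used : float, optional
        The tie-weight threshold, once applied.
    org_type : dict, optional
        actor -> stakeholder-type label.
    citation_count : dict, optional
        actor -> number of coded statements (drives node size in figures).
    """

    nodes: list
    weights: np.ndarray
    stage: str = "unknown"
    threshold_used: float | None = None
    org_type: dict = field(default_factory=dict)
    citation_count: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = list(self.nodes)
        w = np.asarray(self.weights, dtype=float)
        n = len(self.nodes)
        if w.shape != (n, n):
            raise MatrixFormatError(
                f"weight matrix shape {w.shape} does not match {n} node labels"
            )
        if len(set(self.nodes)) != n:
            raise MatrixFormatError("duplicate actor labels")
        if self.stage not in STAGES:
            raise ParameterError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        asym = np.abs(w - w.T).max(initial=0.0)
        if asym > _SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
            raise MatrixFormatError(
                f"asymmetric weights: ({self.nodes[i]!r}, {self.nodes[j]!r}) "
                f"differ by {asym:.3g}"
            )
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w
        self._index = {a: i for i, a in enumerate(self.nodes)}

    # -- basic queries -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, actor) -> int:
        return self._index[actor]

    def weight(self, a, b) -> float:
        return float(self.weights[self._index[a], self._index[b]])

    def degrees(self) -> dict:
        """Binary degree (number of positive-weight ties) per actor."""
        deg = (self.weights > 0).sum(axis=1)
        return {a: int(deg[i]) for i, a in enumerate(self.nodes)}

    def isolates(self) -> list:
        deg = (self.weights > 0).sum(axis=1)
        return [a for i, a in enumerate(self.nodes) if deg[i] == 0]

    def non_isolates(self) -> list:
        deg = (self.weights > 0).sum(axis=1)
        return [a for i, a in enumerate(self.nodes) if deg[i] > 0]

    # -- conversions ---------------------------------------------------

    def to_networkx(self, binary: bool = False) -> nx.Graph:
        """Positive-weight ties as a networkx graph (all nodes retained)."""
        g = nx.Graph()
        for a in self.nodes:
            g.add_node(
                a,
                org_type=self.org_type.get(a, ""),
                citation_count=int(self.citation_count.get(a, 0)),
            )
        ii, jj = np.nonzero(np.triu(self.weights > 0, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            if binary:
                g.add_edge(self.nodes[i], self.nodes[j])
            else:
                g.add_edge(self.nodes[i], self.nodes[j], weight=float(self.weights[i, j]))
        return g

    def subnetwork(self, nodes) -> "ActorNetwork":
        nodes = list(nodes)
        idx = [self._index[a] for a in nodes]
        return ActorNetwork(
            nodes=nodes,
            weights=self.weights[np.ix_(idx, idx)],
            stage=self.stage,
            threshold_used=self.threshold_used,
            org_type={a: self.org_type[a] for a in nodes if a in self.org_type},
            citation_count={a: self.citation_count[a] for a in nodes if a in self.citation_count},
        )

    # -- I/O -----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.nodes, columns=self.nodes)

    def write_matrix(self, path) -> None:
        """CSV adjacency with actor labels in the first row and column."""
        self.to_frame().to_csv(path)

    def write_graphml(self, path, partition=None) -> None:
        """GraphML export with org_type / citation_count, and coalition labels
        when a partition (mapping actor -> label) is supplied."""
        g = self.to_networkx()
        if partition is not None:
            for a in g.nodes:
                g.nodes[a]["coalition"] = str(partition.get(a, ""))
        nx.write_graphml(g, path)


def read_matrix(path, org_type=None) -> ActorNetwork:
    """Read a square labelled CSV adjacency matrix.

    Row and column labels must match as sets; asymmetries beyond 1e-9 are
    rejected; the diagonal is ignored.  The returned network carries
    ``stage="unknown"`` — whether the exported matrix was thresholded or
    normalised cannot be inferred from the file.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.shape[0] != df.shape[1]:
        raise MatrixFormatError(f"non-square matrix: {df.shape[0]} rows x {df.shape[1]} columns")
    rows, cols = set(df.index), set(df.columns)
    if rows != cols:
        offenders = sorted(rows.symmetric_difference(cols))
        raise MatrixFormatError(f"row/column label mismatch: {offenders[:10]}")
    df = df.loc[df.index, df.index]  # align column order to row order
    try:
        w = df.to_numpy(dtype=float)
    except ValueError as e:
        raise MatrixFormatError(f"non-numeric cell: {e}") from e
    return ActorNetwork(
        nodes=list(df.index), weights=w, stage="unknown", org_type=dict(org_type or {})
    )
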