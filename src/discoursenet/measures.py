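"""Descriptive network statistics for whole networks and coalitions.

All tie counting here is on the binarised thresholded graph: a tie exists
iff the normalised weight survived the threshold.  Reported measures:

* size — node count;
* density — surviving ties over the theoretical maximum n(n-1)/2;
* centralisation — Freeman degree centralisation,
  sum_i (d_max - d_i) / ((n-1)(n-2)), i.e. how far the degree distribution
  is skewed towards a single hub (1.0 for a star, 0 for any regular graph);
* external ratio — per actor, ties to the opposing coalition over all ties,
  averaged over actors; actors without any tie are excluded from the mean
  (their ratio is undefined) and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError
from .coalitions import Partition
from .network import ActorNetwork


class RatioResult(NamedTuple):
    value: float
    n_actors: int
    n_excluded: int


@dataclass
class CoalitionMeasures:
    label: str
    size: int
    centralisation: float | None
    density: float | None
    external_ratio: float | None = None
    by_type_external_ratio: dict = field(default_factory=dict)


def _binary_submatrix(n: ActorNetwork, node_set) -> tuple[np.ndarray, list]:
    nodes = [a for a in n.nodes if a in set(node_set)]
    if len(nodes) != len(set(node_set)):
        missing = sorted(set(node_set) - set(nodes))
        raise ConsistencyError(f"actors not in network: {missing[:5]}")
    idx = [n.index(a) for a in nodes]
    return (n.weights[np.ix_(idx, idx)] > 0).astype(int), nodes


def density(n: ActorNetwork, node_set=None) -> float:
    """Ties within node_set over the theoretical maximum."""
    node_set = list(node_set) if node_set is not None else list(n.nodes)
    if len(node_set) < 2:
        raise ParameterError("density needs at least 2 nodes")
    A, nodes = _binary_submatrix(n, node_set)
    m = A.sum() / 2
    possible = len(nodes) * (len(nodes) - 1) / 2
    return float(m / possible)


def centralisation(n: ActorNetwork, node_set=None) -> float:
    """Freeman degree centralisation of the induced binarised subgraph,
    as a fraction in [0, 1] (multiply by 100 for the percentage form)."""
    node_set = list(node_set) if node_set is not None else list(n.nodes)
    if len(node_set) < 3:
        raise ParameterError("centralisation needs at least 3 nodes")
    A, nodes = _binary_submatrix(n, node_set)
    deg = A.sum(axis=1)
    nn = len(nodes)
    return float((deg.max() - deg).sum() / ((nn - 1) * (nn - 2)))


def actor_external_ratios(n: ActorNetwork, p: Partition) -> dict:
    """Per-actor external ratio: extra-coalition ties / all ties.

    Only assigned actors appear; actors with zero ties map to None
    (undefined ratio)."""
    assignment = p.assignment
    out = {}
    for a in assignment:
        if a not in n._index:
            raise ConsistencyError(f"actor {a!r} in partition absent from network")
    for a, cid in assignment.items():
        row = n.weights[n.index(a)] > 0
        neighbours = [n.nodes[j] for j in np.flatnonzero(row)]
        total = len(neighbours)
        if total == 0:
            out[a] = None
            continue
        external = sum(1 for b in neighbours if assignment.get(b, None) != cid)
        out[a] = external / total
    return out


def external_ratio(
    n: ActorNetwork, p: Partition, cluster=None, org_type=None, registry=None
) -> RatioResult:
    """Mean external ratio over a scope.

    ``cluster`` restricts to one coalition's members; ``org_type`` (with a
    ``registry`` mapping actor -> type, defaulting to the network's) restricts
    to actors of that stakeholder type, each evaluated within their own
    coalition.  Zero-tie actors are excluded from the mean and counted in
    ``n_excluded``.
    """
    ratios = actor_external_ratios(n, p)
    registry = registry if registry is not None else n.org_type
    scoped = list(ratios)
    if cluster is not None:
        scoped = [a for a in scoped if p.assignment[a] == cluster]
    if org_type is not None:
        scoped = [a for a in scoped if registry.get(a) == org_type]
    values = [ratios[a] for a in scoped if ratios[a] is not None]
    excluded = sum(1 for a in scoped if ratios[a] is None)
    if not values:
        import warnings

        warnings.warn("external ratio scope is empty after exclusions", stacklevel=2)
        return RatioResult(float("nan"), 0, excluded)
    return RatioResult(float(np.mean(values)), len(values), excluded)


def by_type_external_ratio(n: ActorNetwork, p: Partition, registry=None) -> dict:
    """Mean external ratio per stakeholder type (actors evaluated within
    their own coalitions), as in the per-type openness comparison."""
    registry = registry if registry is not None else n.org_type
    types = sorted({registry.get(a, "") for a in p.assignment})
    out = {}
    for t in types:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = external_ratio(n, p, org_type=t, registry=registry)
        out[t] = res.value
    return out


def summarise(n: ActorNetwork, p: Partition, registry=None) -> pd.DataFrame:
    """One row of measures per coalition plus a full-network row.

    Columns: size, centralisation (%), density, external ratio; per-type
    external ratios are available via :func:`by_type_external_ratio`.
    Isolates are excluded from coalition rows (they belong to none) but
    counted in the full-network size.
    """
    registry = registry if registry is not None else n.org_type
    rows = []

    def row(label, nodes, ext):
        size = len(nodes)
        cent = centralisation(n, nodes) if size >= 3 else None
        dens = density(n, nodes) if size >= 2 else None
        rows.append(
            CoalitionMeasures(
                label=label,
                size=size,
                centralisation=cent,
                density=dens,
                external_ratio=ext,
            )
        )

    row("full network", list(n.nodes), None)
    for cid, members in sorted(p.clusters().items()):
        res = external_ratio(n, p, cluster=cid)
        row(f"coalition {cid}", members, res.value)

    df = pd.DataFrame(
        [
            {
                "scope": r.label,
                "size": r.size,
                "centralisation_pct": None if r.centralisation is None else round(100 * r.centralisation, 1),
                "density": None if r.density is None else round(r.density, 2),
                "external_ratio": None if r.external_ratio is None else round(r.external_ratio, 2),
            }
            for r in rows
        ]
    )
    df.attrs["isolates"] = len(p.isolates)
    df.attrs["raw"] = rows
    return df
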