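"""From coded statements to actor congruence networks.

The tie weight between two actors is the number of concepts on which they
hold identical stances minus the number on which they hold opposing stances
(the *subtract* transformation: argumentative similarity in excess of
disagreement), divided by the average number of distinct concepts the two
actors mention (*average activity normalisation*, which removes the effect
of how often an actor is quoted).  A tie-weight threshold then keeps only
robust argumentative similarity:

    w_ij = (c_ij - d_ij) / ((|C_i| + |C_j|) / 2),   kept iff w_ij >= tau.

Stances are aggregated per (actor, concept): an actor who both agrees and
disagrees with a concept equally often is *ambivalent* on it, contributing
to neither the congruence count c_ij nor the conflict count d_ij (but still,
by default, to the activity |C_i| — the actor does mention the concept).
Because stances, not statements, enter the weights, repeating a statement
does not change the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError, ParameterError
from .network import ActorNetwork
from .statements import StatementSet

DEFAULT_THRESHOLD = 0.4


@dataclass
class StanceProfile:
    """Per-(actor, concept) aggregated stances.

    Attributes
    ----------
    mentions : dict
        (actor, concept) -> (n_agree, n_disagree).
    stance : dict
        (actor, concept) -> +1, -1 or 0 (ambivalent: equal counts).
    activity : dict
        actor -> number of distinct concepts mentioned, |C_i|.
    statement_count : dict
        actor -> total coded statements (citation frequency).
    org_type : dict
        actor -> stakeholder-type label.
    """

    mentions: dict = field(default_factory=dict)
    stance: dict = field(default_factory=dict)
    activity: dict = field(default_factory=dict)
    statement_count: dict = field(default_factory=dict)
    org_type: dict = field(default_factory=dict)

    @property
    def actors(self) -> list:
        return sorted(self.activity)

    def concepts_of(self, actor) -> list:
        return sorted(c for (a, c) in self.stance if a == actor)


def build_stances(s: StatementSet, count_ambivalent: bool = True) -> StanceProfile:
    """Aggregate a statement set into per-(actor, concept) stances.

    ``count_ambivalent`` controls whether concepts on which an actor is
    ambivalent still count towards the actor's activity |C_i| (default:
    they do — the actor mentions the concept).
    """
    if len(s) == 0:
        raise ConsistencyError("cannot build stances from an empty statement set")
    mentions: dict = {}
    statement_count: dict = {}
    for st in s:
        key = (st.organisation, st.concept)
        a, d = mentions.get(key, (0, 0))
        mentions[key] = (a + 1, d) if st.agreement else (a, d + 1)
        statement_count[st.organisation] = statement_count.get(st.organisation, 0) + 1

    stance = {k: int(np.sign(a - d)) for k, (a, d) in mentions.items()}
    activity: dict = {}
    for (actor, _concept), sgn in stance.items():
        if sgn != 0 or count_ambivalent:
            activity[actor] = activity.get(actor, 0) + 1
    # actors whose every stance is ambivalent and excluded would vanish;
    # keep them registered with zero activity so the caller can decide
    for actor in statement_count:
        activity.setdefault(actor, 0)
    return StanceProfile(
        mentions=mentions,
        stance=stance,
        activity=activity,
        statement_count=statement_count,
        org_type=dict(s.actor_registry),
    )


def congruence_conflict(p: StanceProfile, actors=None) -> tuple[np.ndarray, np.ndarray, list]:
    """Congruence and conflict count matrices.

    c_ij counts concepts on which actors i and j hold the same non-ambivalent
    stance; d_ij counts concepts on which their stances oppose.  Ambivalent
    stances contribute to neither.

    Returns
    -------
    (c, d, actors) : integer matrices over the given (default: sorted) actor order.
    """
    actors = list(actors) if actors is not None else p.actors
    index = {a: i for i, a in enumerate(actors)}
    concepts = sorted({c for (_a, c) in p.stance})
    cindex = {c: j for j, c in enumerate(concepts)}
    # stance matrix S in {-1, 0, +1}; 0 = ambivalent or not mentioned
    S = np.zeros((len(actors), len(concepts)), dtype=np.int64)
    for (a, c), sgn in p.stance.items():
        if a in index:
            S[index[a], cindex[c]] = sgn
    pos = (S > 0).astype(np.int64)
    neg = (S < 0).astype(np.int64)
    c = pos @ pos.T + neg @ neg.T
    d = pos @ neg.T + neg @ pos.T
    np.fill_diagonal(c, 0)
    np.fill_diagonal(d, 0)
    return c, d, actors


def subtract_normalise(
    c: np.ndarray, d: np.ndarray, p: StanceProfile, actors=None
) -> ActorNetwork:
    """Subtract transformation with average activity normalisation.

    w_ij = (c_ij - d_ij) / ((|C_i| + |C_j|) / 2).  Weights are bounded in
    [-1, 1] because |c_ij - d_ij| cannot exceed min(|C_i|, |C_j|).
    """
    actors = list(actors) if actors is not None else p.actors
    act = np.array([p.activity.get(a, 0) for a in actors], dtype=float)
    if np.any(act <= 0):
        bad = [a for a, v in zip(actors, act) if v <= 0]
        raise ConsistencyError(f"actors with zero activity in matrix: {bad[:5]}")
    mean_act = (act[:, None] + act[None, :]) / 2.0
    w = (np.asarray(c, dtype=float) - np.asarray(d, dtype=float)) / mean_act
    np.fill_diagonal(w, 0.0)
    return ActorNetwork(
        nodes=actors,
        weights=w,
        stage="normalised",
        org_type={a: p.org_type.get(a, "") for a in actors},
        citation_count={a: p.statement_count.get(a, 0) for a in actors},
    )


def apply_threshold(n: ActorNetwork, tau: float = DEFAULT_THRESHOLD) -> ActorNetwork:
    """Keep tie weights >= tau (inclusive); replace all others — including
    every negative weight — by 0.  Nodes left without ties remain as
    isolates."""
    if not 0 < tau <= 1:
        raise ParameterError(f"threshold tau={tau} outside (0, 1]")
    if n.stage not in ("normalised", "unknown"):
        raise ConsistencyError(f"threshold expects a normalised network, got stage={n.stage!r}")
    w = np.where(n.weights >= tau, n.weights, 0.0)
    return ActorNetwork(
        nodes=n.nodes,
        weights=w,
        stage="thresholded",
        threshold_used=tau,
        org_type=dict(n.org_type),
        citation_count=dict(n.citation_count),
    )


def build_network(
    s: StatementSet, tau: float = DEFAULT_THRESHOLD, count_ambivalent: bool = True
) -> ActorNetwork:
    """Statements -> stances -> subtract/normalise -> threshold."""
    p = build_stances(s, count_ambivalent=count_ambivalent)
    active = [a for a in p.actors if p.activity[a] > 0]
    c, d, actors = congruence_conflict(p, actors=active)
    return apply_threshold(subtract_normalise(c, d, p, actors=actors), tau=tau)
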