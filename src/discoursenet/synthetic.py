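"""Synthetic two-coalition policy debates with known ground truth.

The generator emulates the statistical structure of a polarised media
debate: two latent advocacy coalitions (supportive / sceptical of the
policy) with opposed per-concept stance polarity, a small set of
intermediary actors with unpolarised stances that blur the coalition
boundary, a heavy-tailed (power-law) distribution of statement activity so
that a few actors dominate the coverage, and a date stream over which the
probability of an on-message statement — and hence the network's
bipolarisation — can vary.

Defaults mirror the scale of the UK sugar-tax newspaper debate that
motivates the package: 95 supportive + 65 sceptical organisations plus 16
intermediaries (176 actors), 47 concepts, 3883 statements over May 2015 to
November 2016.

What the generator does *not* emulate: article-level clustering of
statements, concept topicality drift, actor entry/exit over time, or
persuasion dynamics between actors.  Stances are emitted independently
given the schedule.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .coalitions import Partition
from .errors import ConsistencyError, ParameterError
from .statements import Statement, StatementSet

SUPPORTIVE_TYPES = ("Health charity", "Campaign group", "Advisory body", "NHS", "Professional association")
SCEPTICAL_TYPES = ("Soft drinks industry", "Food and drink industry", "Think tank/Analyst", "Retailer/Retail association")
INTERMEDIARY_TYPES = ("University/Academic", "Political party", "Government department")


@dataclass
class DebateConfig:
    """Generative parameters of a synthetic debate.

    ``p_on_message`` is the probability that an actor's held stance on a
    concept follows the coalition polarity (and hence that an emitted
    statement is on-message; 1 - stance noise); intermediaries ignore it
    and hold uniform random stances.
    ``polarisation_schedule`` optionally replaces the constant
    ``p_on_message`` with piecewise values over the date range: a list of
    (fraction_of_range_start, p) pairs, first fraction 0.0.
    ``activity_skew`` is the exponent of the power-law statement-count
    distribution across actors (activity of rank r is proportional to
    r**-skew).
    """

    n_actors_per_coalition: tuple = (95, 65)
    n_intermediaries: int = 16
    n_concepts: int = 47
    p_on_message: float = 0.9
    activity_skew: float = 1.5
    n_statements: int = 3883
    date_range: tuple = (dt.date(2015, 5, 1), dt.date(2016, 11, 30))
    polarisation_schedule: list | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_concepts < 1:
            raise ParameterError("need at least 1 concept")
        if self.n_statements < 1:
            raise ParameterError("need at least 1 statement")
        if min(self.n_actors_per_coalition) < 1:
            raise ParameterError("each coalition needs at least 1 actor")
        if self.n_intermediaries < 0:
            raise ParameterError("n_intermediaries must be >= 0")
        if not 0 <= self.p_on_message <= 1:
            raise ParameterError("p_on_message must be a probability")
        start, end = self.date_range
        if start >= end:
            raise ParameterError("empty date range")
        if self.polarisation_schedule is not None:
            fracs = [f for f, _p in self.polarisation_schedule]
            if fracs[0] != 0.0 or sorted(fracs) != fracs:
                raise ParameterError("schedule must start at 0.0 and be sorted")
            if any(not 0 <= p <= 1 for _f, p in self.polarisation_schedule):
                raise ParameterError("schedule probabilities must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure behind a generated debate.

    ``stance_tables`` holds, per schedule segment, the (actor x concept)
    array of held stances actually emitted; ``actors`` / ``concepts`` give
    its row/column order and ``segment_starts`` the fraction-of-range
    breakpoints.
    """

    coalition_of: dict  # actor -> supportive | sceptical | intermediary
    polarity: dict  # concept -> stance of the supportive coalition (+1/-1)
    config: DebateConfig = field(repr=False, default=None)
    actors: list = field(default_factory=list)
    concepts: list = field(default_factory=list)
    stance_tables: list = field(default_factory=list, repr=False)
    segment_starts: list = field(default_factory=list)

    def planted_labels(self, actors) -> dict:
        """0/1 labels over the given actors, excluding intermediaries."""
        return {
            a: 0 if self.coalition_of[a] == "supportive" else 1
            for a in actors
            if self.coalition_of.get(a) in ("supportive", "sceptical")
        }


def _segments(cfg: DebateConfig) -> list:
    """(start_frac, p) pieces covering [0, 1]."""
    if cfg.polarisation_schedule is None:
        return [(0.0, cfg.p_on_message)]
    return list(cfg.polarisation_schedule)


def generate_debate(cfg: DebateConfig) -> tuple[StatementSet, GroundTruth]:
    """Draw a complete synthetic debate. Fully reproducible from cfg.seed.

    Statement dates are uniform over the date range (then sorted); actors
    are drawn with power-law weights; concepts uniformly per statement.
    Stances are *positions*, not per-statement coin flips: within each
    schedule segment an actor holds a fixed stance on each concept — the
    coalition's preferred polarity with probability p_on_message, the
    opposite otherwise (so the expected off-message statement rate is
    1 - p_on_message) — and every statement emits it consistently.
    Intermediaries hold uniform random stances.  Persistent heterodox
    positions are what blur the coalition boundary: a per-statement flip
    would be averaged away by stance aggregation and leave the network's
    polarisation insensitive to the noise level.
    """
    rng = np.random.default_rng(cfg.seed)
    n_sup, n_sce = cfg.n_actors_per_coalition
    actors, coalition_of, org_type = [], {}, {}
    for i in range(n_sup):
        a = f"Supportive org {i + 1:03d}"
        actors.append(a)
        coalition_of[a] = "supportive"
        org_type[a] = SUPPORTIVE_TYPES[i % len(SUPPORTIVE_TYPES)]
    for i in range(n_sce):
        a = f"Sceptical org {i + 1:03d}"
        actors.append(a)
        coalition_of[a] = "sceptical"
        org_type[a] = SCEPTICAL_TYPES[i % len(SCEPTICAL_TYPES)]
    for i in range(cfg.n_intermediaries):
        a = f"Intermediary org {i + 1:03d}"
        actors.append(a)
        coalition_of[a] = "intermediary"
        org_type[a] = INTERMEDIARY_TYPES[i % len(INTERMEDIARY_TYPES)]

    concepts = [f"concept_{j + 1:02d}" for j in range(cfg.n_concepts)]
    polarity = {c: int(rng.choice([-1, 1])) for c in concepts}

    # heavy-tailed activity: weight of activity-rank r is r**-skew, ranks
    # shuffled over actors so prominence is independent of coalition
    ranks = rng.permutation(len(actors)) + 1
    weights = ranks.astype(float) ** -cfg.activity_skew
    weights /= weights.sum()

    start, end = cfg.date_range
    span_days = (end - start).days
    day_offsets = np.sort(rng.integers(0, span_days + 1, size=cfg.n_statements))
    actor_draws = rng.choice(len(actors), size=cfg.n_statements, p=weights)
    concept_draws = rng.integers(0, cfg.n_concepts, size=cfg.n_statements)

    # one stance table per schedule segment: stance[actor, concept] in {-1, +1}
    segments = _segments(cfg)
    pol = np.array([polarity[c] for c in concepts])
    side_sign = np.array(
        [1 if coalition_of[a] == "supportive" else -1 for a in actors]
    )
    inter = np.array([coalition_of[a] == "intermediary" for a in actors])
    tables = []
    for _frac, p in segments:
        preferred = side_sign[:, None] * pol[None, :]
        flip = np.where(rng.random(preferred.shape) < p, 1, -1)
        table = preferred * flip
        table[inter] = rng.choice([-1, 1], size=(inter.sum(), cfg.n_concepts))
        tables.append(table)
    seg_starts = np.array([f for f, _p in segments])

    statements = []
    for k in range(cfg.n_statements):
        a = actors[actor_draws[k]]
        c = concepts[concept_draws[k]]
        date = start + dt.timedelta(days=int(day_offsets[k]))
        frac = day_offsets[k] / span_days if span_days else 0.0
        seg = int(np.searchsorted(seg_starts, frac, side="right") - 1)
        stance = int(tables[seg][actor_draws[k], concept_draws[k]])
        statements.append(
            Statement(
                person="",
                organisation=a,
                org_type=org_type[a],
                concept=c,
                agreement=stance > 0,
                date=date,
                article_id=f"article_{k + 1:05d}",
            )
        )
    truth = GroundTruth(
        coalition_of=coalition_of,
        polarity=polarity,
        config=cfg,
        actors=actors,
        concepts=concepts,
        stance_tables=tables,
        segment_starts=list(seg_starts),
    )
    return StatementSet(statements=statements), truth


def evaluate_recovery(truth: GroundTruth, p: Partition) -> float:
    """Adjusted Rand index between the planted coalitions and a detected
    partition, over their shared actors (intermediaries excluded)."""
    planted = truth.planted_labels(p.assignment)
    common = sorted(planted)
    if not common:
        raise ConsistencyError("partition shares no coalition actors with the ground truth")
    true_labels = [planted[a] for a in common]
    found_labels = [p.assignment[a] for a in common]
    return float(adjusted_rand_score(true_labels, found_labels))
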