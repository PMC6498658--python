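import datetime as dt

import numpy as np
import pytest

from discoursenet.network import ActorNetwork
from discoursenet.statements import Statement, StatementSet


def make_statement(org, concept, agree, date="2016-01-10", person="", org_type="", article="a1"):
    return Statement(
        person=person,
        organisation=org,
        org_type=org_type,
        concept=concept,
        agreement=agree,
        date=dt.date.fromisoformat(date),
        article_id=article,
    )


def random_statement_set(rng, n_actors=6, n_concepts=4, n_statements=40):
    """Small random debate for oracle comparisons (no planted structure)."""
    statements = []
    base = dt.date(2016, 1, 1)
    for k in range(n_statements):
        statements.append(
            Statement(
                person="",
                organisation=f"org{rng.integers(n_actors)}",
                org_type="T",
                concept=f"c{rng.integers(n_concepts)}",
                agreement=bool(rng.integers(2)),
                date=base + dt.timedelta(days=int(rng.integers(60))),
                article_id=f"a{k}",
            )
        )
    return StatementSet(statements=statements)


def block_network(sizes, weight=1.0, bridges=()):
    """Disjoint cliques of the given sizes, plus optional bridge edges
    given as ((block_i, member), (block_j, member)) index pairs."""
    n = sum(sizes)
    labels = []
    offsets = []
    pos = 0
    for b, size in enumerate(sizes):
        offsets.append(pos)
        labels.extend(f"b{b}n{i}" for i in range(size))
        pos += size
    W = np.zeros((n, n))
    pos = 0
    for size in sizes:
        W[pos : pos + size, pos : pos + size] = weight
        pos += size
    np.fill_diagonal(W, 0.0)
    for (bi, mi), (bj, mj) in bridges:
        i, j = offsets[bi] + mi, offsets[bj] + mj
        W[i, j] = W[j, i] = weight
    return ActorNetwork(nodes=labels, weights=W, stage="thresholded", threshold_used=0.4)


def star_network(n_leaves=4):
    n = n_leaves + 1
    W = np.zeros((n, n))
    W[0, 1:] = W[1:, 0] = 1.0
    return ActorNetwork(
        nodes=["hub"] + [f"leaf{i}" for i in range(n_leaves)],
        weights=W,
        stage="thresholded",
    )


def cycle_network(n=6):
    W = np.zeros((n, n))
    for i in range(n):
        W[i, (i + 1) % n] = W[(i + 1) % n, i] = 1.0
    return ActorNetwork(nodes=[f"v{i}" for i in range(n)], weights=W, stage="thresholded")


@pytest.fixture
def two_cliques():
    """Two disconnected 4-cliques."""
    return block_network([4, 4])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent brute-force oracles (never call package internals)
# ---------------------------------------------------------------------------


def brute_force_pipeline(statements, tau=0.4, count_ambivalent=True):
    """From-scratch recomputation of stances -> subtract/normalise -> threshold
    using plain dict/loop arithmetic."""
    mentions = {}
    for s in statements:
        key = (s.organisation, s.concept)
        a, d = mentions.get(key, (0, 0))
        mentions[key] = (a + 1, d) if s.agreement else (a, d + 1)
    stance = {}
    for (actor, concept), (a, d) in mentions.items():
        stance[(actor, concept)] = 1 if a > d else (-1 if d > a else 0)
    activity = {}
    for (actor, concept), sg in stance.items():
        if sg != 0 or count_ambivalent:
            activity[actor] = activity.get(actor, 0) + 1
    actors = sorted(activity)
    concepts = sorted({c for (_a, c) in stance})
    w = {}
    for i, ai in enumerate(actors):
        for aj in actors[i + 1 :]:
            c = d = 0
            for concept in concepts:
                si = stance.get((ai, concept), 0)
                sj = stance.get((aj, concept), 0)
                if si == 0 or sj == 0:
                    continue
                if si == sj:
                    c += 1
                else:
                    d += 1
            weight = (c - d) / ((activity[ai] + activity[aj]) / 2)
            w[(ai, aj)] = weight if weight >= tau else 0.0
    return {"stance": stance, "activity": activity, "mentions": mentions, "weights": w, "actors": actors}


def modularity_double_sum(W, labels, weighted=True):
    """Direct (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j)."""
    A = np.where(W > 0, W if weighted else 1.0, 0.0)
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    k = A.sum(axis=1)
    q = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - k[i] * k[j] / two_m
    return q / two_m


def exhaustive_max_bipartition_q(W):
    """Max weighted modularity over all 2^(n-1) bipartitions (n <= 14)."""
    A = np.where(W > 0, W, 0.0)
    two_m = A.sum()
    k = A.sum(axis=1)
    B = A - np.outer(k, k) / two_m
    n = W.shape[0]
    best = -1.0
    for mask in range(2 ** (n - 1)):
        s = np.array([(mask >> i) & 1 for i in range(n - 1)] + [0], dtype=float)
        q = (s @ B @ s + (1 - s) @ B @ (1 - s)) / two_m
        best = max(best, q)
    return best
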