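# Methods

This note records the scientific and numerical choices behind
`discoursenet`: the network construction, the clustering and measurement
conventions, what the synthetic debate generator does and does not
emulate, and the problem sizes the test suite and acceptance script use.

## Statement model and ingestion

The unit of analysis is the coded statement: *(person, organisation,
concept, agreement, date, article)*. The organisation is the actor;
individuals without an affiliation (e.g. a celebrity campaigner) are
registered as their own organisation-level actor, so they appear as nodes
in their own right. Statement tables are long-format CSV/TSV read through
a column-mapping configuration (`columns.*`, `agreement.true_values` /
`false_values`); dates are ISO 8601 and all time windows are half-open
`[start, end)`, which makes period splits unambiguous. The default
before/after boundary for two-period analyses is 2016-01-15
("mid-January"), configurable. Malformed rows are collected and reported
with their 1-based file line numbers rather than silently dropped.

Externally supplied adjacency matrices (labelled square CSV) are accepted
as networks of stage `unknown`: whether such an export was already
normalised or thresholded cannot be recovered from the file, so nothing is
assumed and downstream code may analyse both accountings.

## From stances to tie weights

Stances aggregate statements per (actor, concept) to the sign of net
agreement; an exact tie is *ambivalent*. Ambivalent stances contribute to
neither the congruence count `c_ij` nor the conflict count `d_ij`, but by
default still count toward the activity `|C_i|` (the actor does mention
the concept); `activity.count_ambivalent=False` switches to the stricter
reading. Because weights depend only on stances,

    w_ij = (c_ij − d_ij) / ((|C_i| + |C_j|)/2),

duplicating statements never changes the network, which is the point of
the activity normalisation: argumentative similarity, not quotation rate.
`|c_ij − d_ij| ≤ min(|C_i|, |C_j|)` bounds every weight in [−1, 1]. The
threshold τ = 0.4 is inclusive (`w ≥ τ` kept) and rejects all negative
weights; actors left without ties remain in the network as isolates, so
reported network sizes always refer to the full actor roster.

## Clustering conventions

All graph clustering operates on the **binarised** thresholded graph (an
edge exists iff the weight survived τ): the descriptive measures are tie
counts, and binarisation keeps the clustering consistent with them.
Modularity, in contrast, is scored with the surviving tie weights
(`weighted=False` available), since Q's weighted form is the standard
definition and reduces to the binary one on 0/1 weights.

Girvan–Newman edge betweenness is delegated to igraph's C implementation;
the dendrogram is cut at maximum modularity by default. A divisive
algorithm cannot merge components, so `stop=k` is interpreted as k−1
splits beyond the graph's initial components — exactly k clusters on a
connected graph. Isolates are reported separately, never as singleton
coalitions.

The bipolarisation ensemble runs eleven k = 2 techniques (the count is
conventional; the composition is this package's choice): GN cut at two,
leading-eigenvector sign bisection of the modularity matrix, Fiedler
(Laplacian) bisection, greedy modularity agglomeration stopped at two,
3-step random-walk profiles with 2-medoids, normalised-Laplacian spectral
embedding with 2-means (three seeded restarts), and Kernighan–Lin
bisection (three seeded restarts). Stochastic members draw their seeds
deterministically from the master seed. A member that fails on a
degenerate graph (e.g. GN-at-2 on a graph with three components, or a
spectral split that refuses to separate a complete graph) is recorded as a
warning and skipped; the ensemble never aborts, and the bipolarisation of
a network with fewer than two tied actors is a missing value, not an
error. Since bipolarisation is the maximum modularity over the members, it
is monotone non-decreasing in the number of methods and bounded above by
the exhaustive max over all bipartitions (asserted on small graphs in the
tests).

Coalitions are labelled supportive/sceptical by the sign of members' mean
stance over a caller-supplied set of pro-policy concepts; ties and
clusters that never mention those concepts are labelled `other`.

## Measures

Density is surviving ties over `n(n−1)/2`; centralisation is Freeman
degree centralisation on the binarised (sub)graph, reported as a
percentage to one decimal; external ratios are per-actor (external
ties / all ties) averaged unweighted over the scope — a coalition, or the
actors of one stakeholder type evaluated within their own coalitions.
Actors with zero ties have an undefined ratio; they are excluded from the
mean and counted alongside the result. Table outputs round percentages to
one decimal and ratios to two; raw values are retained on the result
object (`df.attrs["raw"]`).

## Temporal bipolarisation

The series slides a fixed window (default 200 statements, always stepping
one statement) over the stream sorted by (date, article id, input order) —
the tertiary key makes tied dates deterministic. Each window is rebuilt
into a thresholded network and scored by the ensemble; the point is dated
at the window's median (100th of 200) statement. Degenerate windows stay
in the series as gaps. LOESS smoothing (statsmodels `lowess`, locally
linear, span default 0.3) is fitted over window index rather than calendar
time, matching the equal-statement (not equal-duration) windows; gaps are
excluded from the fit. Locally linear fitting reproduces constant and
linear series exactly, which the tests assert; a locally quadratic option
is not provided.

A caveat that matters when reading the curve: max-k2-modularity of a
*sparse, fragmented* graph is high (~0.5) regardless of how the fragments
relate, because any balanced two-grouping of components scores well. The
measure discriminates blended from segregated structure only while the
windowed networks stay reasonably dense. Window sizes should therefore be
chosen large relative to the number of active actors and concepts; the
dose-response analyses below use dense small-debate windows for exactly
this reason.

## Synthetic debates

The generator emulates a polarised media debate: two latent coalitions
with opposed per-concept polarity, intermediaries, a power-law
distribution of statement activity (exponent 1.5 by default, so a few
actors dominate coverage), uniform statement dates, uniform concept
choice, and an on-message probability `p_on_message` that may vary over
time through a piecewise schedule. Defaults mirror the scale of the UK
sugar-tax newspaper debate: 95 + 65 coalition actors, 16 intermediaries,
47 concepts, 3883 statements over May 2015 – November 2016, p = 0.9.

Stance noise is drawn **per (actor, concept) within each schedule
segment**, not per statement: an actor holds the coalition's stance with
probability p (the opposite otherwise) and emits it consistently;
intermediaries hold uniform random stances. Held positions are the
Advocacy-Coalition reading of beliefs, and they are what makes blur
visible in the network — per-statement coin flips would be averaged away
by the net-sign stance aggregation, leaving intermediaries as isolates and
the network's polarisation insensitive to the noise level. The expected
off-message *statement* rate is still `1 − p`; the calibration test
asserts the exact binomial property at the stance-table level plus exact
statement/table consistency.

What the generator does **not** emulate: skewed concept popularity
(uniform concept choice makes the synthetic actor–concept overlap, and
hence network density, lower than in real coded debates — at study scale
the synthetic thresholded network is markedly sparser than a real debate's
network of the same size), article-level clustering of statements, actor
entry and exit, and persuasion dynamics. Passing tests therefore
demonstrate correctness of the pipeline's computations and its behaviour
under controlled structure, not that real debates of a given scale will
yield equally clean coalitions.

A consequence of the heavy-tailed activity worth knowing: actors in the
power-law tail mention one or two concepts, and a single heterodox stance
can leave such an actor with cross-coalition ties only. No clustering of
the thresholded graph can then place them with their planted coalition —
recovery of the planted split is information-limited at high skew, which
the recovery analyses in the test suite make visible.

## Problem sizes used

The suite and acceptance script keep simulations small and seeded:
exhaustive-oracle checks on ≤ 14-node graphs (2¹³ bipartitions);
brute-force pipeline equivalence on ≤ 10-actor debates; recovery at
40 + 40 actors / 20 concepts / 3000 statements over 20 seeds; dose-response
at 12 + 12 actors, 2 intermediaries, 8 concepts, 800 statements, window
400, 10 seeds per p ∈ {0.6, 0.8, 0.95}; the acceptance script runs the
study-scale debate once plus one 800-statement windowed series. The full
suite runs in a few minutes on one CPU.
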