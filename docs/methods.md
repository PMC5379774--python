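# Methods

## Model and assumptions

`diffppin` analyses *presence/absence* of protein–protein interactions.
Each input sample is a contextualized subnetwork of a shared reference
interactome: the edge set of interactions plausible in that sample given
its expressed transcripts, optionally with the major isoform recorded per
expressed protein. Edge weights, if present in the input, are ignored —
the upstream contextualization adjusts presence, not confidence, and the
discretized representation keeps the state space small and deflates
noisy expression values.

Edges are undirected with canonical lexicographic identity; self-loops
are rejected by default (they can be enabled with a flag, but nothing in
the model treats them specially). A protein is *present* in a sample iff
it is an endpoint of some edge or listed in the sample's isoform table;
there is no separate abundance input.

### Differential network

All N = n₁·n₂ inter-group sample pairs are compared (the method does not
assume matched samples; a matched design is simply the special case where
the informative pairs dominate). Per pair, gained edges (group-2 sample
only) count +1 and lost edges −1; the per-edge sum Δ(u,v) over all pairs
is the cumulative differential network, with null-sum edges removed.
Opposing observations therefore cancel rather than being tracked
separately — an edge must change *consistently* to accumulate a large
|Δ|. Comparisons are indexed row-major over (group-1 order, group-2
order) so that results are stable for a given input ordering.

### Significance

The background rewiring probability P_rew is the arithmetic mean of the
per-pair Jaccard distances between edge sets. The union-based
normalization keeps every per-pair value in [0,1] for groups of unequal
network sizes. Each candidate edge is tested one-tailed:
p = P(X ≥ |Δ|) with X ~ Binomial(N, P_rew), computed through the
binomial survival function rather than 1 − CDF so far-tail p-values for
N up to ~10⁴ do not lose precision. The BH family is exactly the
candidate set (edges present in Δ after null-sum removal), and events
pass with *strictly* adjusted p < FDR (default 0.05). The reported
obs_s is the empirical minimum |Δ| among significant events — it is a
description of what passed, not an analytic threshold.

**Known limitation — small groups.** The binomial null assumes the N
pairwise observations of an edge are independent, but the same n₁ + n₂
samples are reused across all pairs. With n₁ = n₂ = 3, a single
sample-level presence change flips the edge in 3 of the 9 comparisons at
once, so the null distribution of |Δ| is clumped in multiples of the
group size while the binomial model spreads it smoothly; at drop-out
noise around 5% the tail P(X ≥ 3 | Bin(9, P_rew)) sits just below 0.05
and sporadic single-sample changes are routinely called significant.
The test is therefore anti-conservative at minimal group sizes, and the
replicate-level false-positive behaviour reported by
`scripts/acceptance.py` (`null_replicate_positive_rate`) quantifies
this honestly. Consequences for practice: treat results from 3-sample
groups as enriched-candidate lists rather than calibrated discoveries,
prefer larger groups where available, and note that planted-signal
recall and cause attribution (which concern strong, consistent events
with |Δ| near N) are unaffected.

### Cause attribution

For an edge rewired between samples a and b, each endpoint is checked
independently: presence differs → DE; present in both with different
major isoforms → AS; otherwise unaltered. The multiset of endpoint
alterations gives the observation's combined type (DE, AS, DE/DE, DE/AS,
AS/AS). Double alterations are deliberately not reduced to a single
sufficient cause: co-deregulation of both partners is biologically
meaningful (e.g. coexpression of complex partners). If isoform tables
are missing, AS silently degrades to "no alteration" and a warning is
emitted once.

An observation with no altered endpoint is labelled UNEXPLAINED. This
cannot happen for networks derived by isoform-determined
contextualization (an edge can only change if an endpoint's presence or
isoform changed) but does happen for arbitrary user input and for the
synthetic generator's edge-level noise. UNEXPLAINED observations are
counted in a diagnostics field, excluded from share normalization, and
excluded from the set-cover universe; an event whose observations are
all unexplained is reported in the edge table but not covered.

Aggregated cause tables weight every event equally (per-event shares are
normalized before averaging). The *proportional* tally averages the
per-event type shares; the *exclusive* tally assigns each event its
single observed type or "mixed", and reports per pure type the absolute
loss (proportional − exclusive share) and relative loss (loss /
proportional share) incurred by the stricter notion.

### Reduced set (weighted set cover)

One candidate reason per distinct (protein, DE|AS) alteration observed in
any significant event's cause annotations. pw_i counts the distinct
comparisons in which the alteration was implicated in at least one
significant event — not all comparisons in which the protein changed —
because reasons are enumerated from the cause annotations of significant
events; this is the one genuinely open reading of the scoring and is the
narrower, data-supported one. rw_i is the number of significant events
affected; s_i = pw_i·rw_i; w_i = s_max − s_i with s_max = max(s_i) + 1
(the +1 keeps every weight ≥ 1 and preserves information in the ratio).
The greedy loop selects the reason minimizing w_i / (newly covered
events), with the ratio compared as an exact rational to avoid
floating-point tie instability, ties broken towards higher s and then
lexicographically by (protein, kind), so solutions are run-to-run
stable. Coverage sets are fixed before the loop (standard set cover);
the classical H_d guarantee applies, d being the largest coverage size.
Exact ILP solving is intentionally absent — a brute-force optimum exists
only as a test oracle on small instances.

## Synthetic data generator

`diffppin.synthetic` emulates the regime the method targets: a uniform
random reference network (default 100 proteins / 300 edges — large
enough for stable P_rew estimates, small enough that hundreds of
replicates run in seconds), two groups of 3 samples (the smallest
recommended group size), per-sample edge drop-out ε = 0.05 as
within-group heterogeneity, and 20 planted events (10 gains, 10 losses;
half DE, half AS). Planted events use dedicated alteration proteins so
the ground truth is unambiguous: a DE event removes the altered protein
from one group entirely; an AS event keeps it present everywhere and
switches its isoform between groups. Partners are drawn from reference
proteins with degree ≥ 1, because an edgeless partner would be present
only through the planted edge itself and the planted alteration would no
longer be the sole cause. All sampling comes from one seeded generator
in a fixed documented order, so outputs are reproducible across
platforms.

What the generator does *not* emulate: realistic degree distributions,
domain-resolved isoform effects (an isoform switch toggles exactly one
planted interaction, never a protein's whole neighbourhood), and
isoform-consistent noise (dropped edges have unaltered endpoints and are
thus UNEXPLAINED, where real contextualized data would always carry a
cause). Passing tests on this generator show the machinery is correct
and calibrated *with respect to its own contracts*; they do not show
that real contextualized networks satisfy the binomial independence
assumption (see the small-group limitation above) nor that cause labels
on real data reach the synthetic recovery rates.

## Bundled transition summary table

`diffppin/data/hematopoietic_transitions.tsv` holds published
per-transition summary statistics for ten developmental transitions of
human blood cells (interactome size changes, P_rew, obs_s/obs_all,
rew₊/rew₋). It serves as the worked example for
`evaluation.transition_table_statistics`, which recomputes Pearson
correlations among the columns and the σ-deviation of the net
significant change |rew₊ − rew₋ − Δn| / σ(Δn) per transition.

## Numerical and formatting choices

- Binomial and hypergeometric tails via scipy survival functions; exact
  agreement with rational-arithmetic oracles is asserted to 10⁻¹².
- BH via statsmodels `multipletests(method="fdr_bh")`.
- Set-cover ratios as `fractions.Fraction`; never floats.
- UPGMA via scipy average-linkage on the condensed normalized Hamming
  matrix; identical samples merge at height 0.
- Output tables: TSV, UTF-8, rows sorted by canonical keys, floats
  formatted `%.6g` — two runs on identical inputs are byte-identical.
- Degenerate inputs: Jaccard distance of two empty edge sets is 0; an
  empty candidate set yields an empty event list with obs_s undefined
  (written as NA); an empty cover universe yields an empty solution.
- Pathway size bounds (default 15–1000 connections) are applied to the
  pathway's edge count in the input file, i.e. before restriction to the
  reference network; maps are not re-filtered after mapping.

## Problem sizes used in the self-checks

The automated checks run with: binomial oracle N ≤ 50 over a 5-point
p-grid; hypergeometric backgrounds ≤ 20; 500 random set-cover instances
with ≤ 12 reasons and ≤ 10 universe elements against brute force; 200
null replicates and 10+10 planted-signal replicates of the default
generator profile. These sizes give tight Monte-Carlo error on the
reported rates while keeping the full suite in the low seconds.
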