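"""Minimal-weight explanation of all significant rewiring by greedy set cover.

Candidate explanations are single-protein alterations (protein, DE|AS)
observed in the cause annotations of significant events.  Each reason i
is scored s_i = pw_i × rw_i, where pw_i counts the pairwise comparisons
in which the alteration was implicated in at least one significant event
and rw_i the significant events it affected.  Scores are converted into
weights w_i = s_max − s_i with s_max = max(s_i) + 1, so that the most
frequently implicated alterations are the cheapest, and a minimum-weight
set covering all significant events is sought.  Set cover is NP-hard; the
classical greedy algorithm (pick the reason with the smallest ratio of
weight to newly covered events until everything is covered) carries the
H_d approximation guarantee, d being the largest coverage size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

from .causes import AS, Alteration, PairCause
from .network_io import EdgeKey

__all__ = [
    "AlterationReason",
    "SetCoverSolution",
    "ProteinFlags",
    "enumerate_reasons",
    "greedy_weighted_set_cover",
    "reduced_protein_set",
]


@dataclass(frozen=True)
class AlterationReason:
    """One candidate cause with its score and set-cover weight."""

    alteration: Alteration
    pw: int  # pairwise comparisons in which it was implicated
    rw: int  # significant events it affected
    covered: frozenset[EdgeKey]
    s: int  # pw * rw
    w: int  # s_max - s  (>= 1 by construction)


@dataclass(frozen=True)
class SetCoverSolution:
    """Greedy cover of the significant events by alteration reasons."""

    selected: tuple[AlterationReason, ...]
    universe: frozenset[EdgeKey]
    newly_covered: tuple[int, ...]  # per selected reason, at selection time

    @property
    def total_weight(self) -> int:
        return sum(r.w for r in self.selected)

    def protein_flags(self) -> dict[str, "ProteinFlags"]:
        """Per-protein summary of the reduced set (node attributes)."""
        flags: dict[str, ProteinFlags] = {}
        for reason in self.selected:
            p = reason.alteration.protein
            prev = flags.get(p)
            if prev is None:
                flags[p] = ProteinFlags(
                    max_score=reason.s, as_only=reason.alteration.kind == AS
                )
            else:
                flags[p] = ProteinFlags(
                    max_score=max(prev.max_score, reason.s),
                    as_only=prev.as_only and reason.alteration.kind == AS,
                )
        return flags


@dataclass(frozen=True)
class ProteinFlags:
    max_score: int
    as_only: bool


def enumerate_reasons(
    pair_causes: Mapping[EdgeKey, Sequence[PairCause]],
) -> list[AlterationReason]:
    """Build the scored reasons from per-event cause annotations.

    ``pair_causes`` maps each significant edge to its cause observations
    (as produced by :func:`diffppin.causes.collect_pair_causes`).  One
    reason is created per distinct (protein, kind) alteration; a single
    global s_max converts scores to weights.
    """
    comparisons: dict[Alteration, set[int]] = {}
    covered: dict[Alteration, set[EdgeKey]] = {}
    for edge, pcs in pair_causes.items():
        for pc in pcs:
            for alt in pc.alterations:
                comparisons.setdefault(alt, set()).add(pc.comparison_index)
                covered.setdefault(alt, set()).add(edge)
    if not comparisons:
        warnings.warn("no explained rewiring observations; no reasons to score",
                      stacklevel=2)
        return []
    scores = {alt: len(comparisons[alt]) * len(covered[alt]) for alt in comparisons}
    s_max = max(scores.values()) + 1
    return [
        AlterationReason(
            alteration=alt,
            pw=len(comparisons[alt]),
            rw=len(covered[alt]),
            covered=frozenset(covered[alt]),
            s=scores[alt],
            w=s_max - scores[alt],
        )
        for alt in sorted(comparisons)
    ]


def greedy_weighted_set_cover(
    reasons: Sequence[AlterationReason], universe: frozenset[EdgeKey] | set[EdgeKey]
) -> SetCoverSolution:
    """Greedy minimum-ratio cover of *universe* by the reasons' coverage sets.

    At each step the reason with the smallest w / (newly covered) ratio is
    selected (ratios compared exactly, avoiding float ties); ties break
    towards the higher score s, then lexicographically by (protein, kind),
    making the output run-to-run stable.
    """
    universe = frozenset(universe)
    coverable = frozenset(e for r in reasons for e in r.covered)
    uncoverable = universe - coverable
    if uncoverable:
        raise ValueError(
            f"universe cannot be covered; uncovered edges: {sorted(uncoverable)}"
        )

    remaining = set(universe)
    available = list(reasons)
    selected: list[AlterationReason] = []
    newly_counts: list[int] = []
    while remaining:
        best = None
        best_key = None
        best_new = 0
        for r in available:
            new = len(r.covered & remaining)
            if new == 0:
                continue
            # exact rational ratio; ties towards higher s, then (protein, kind)
            key = (Fraction(r.w, new), -r.s, r.alteration.protein, r.alteration.kind)
            if best is None or key < best_key:
                best, best_key, best_new = r, key, new
        selected.append(best)
        newly_counts.append(best_new)
        remaining -= best.covered
        available.remove(best)

    solution = SetCoverSolution(
        selected=tuple(selected),
        universe=universe,
        newly_covered=tuple(newly_counts),
    )
    assert frozenset().union(*(r.covered for r in selected), frozenset()) >= universe
    return solution


def reduced_protein_set(solution: SetCoverSolution) -> dict[str, ProteinFlags]:
    """Proteins of the selected reasons with AS-only flag and max score."""
    return solution.protein_flags()


def write_solution_table(solution: SetCoverSolution, path) -> None:
    """TSV: rank, protein, kind, pw, rw, s, w, newly covered count."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tprotein\tkind\tpw\trw\ts\tw\tnewly_covered\n")
        for rank, (reason, new) in enumerate(
            zip(solution.selected, solution.newly_covered), start=1
        ):
            alt = reason.alteration
            fh.write(
                f"{rank}\t{alt.protein}\t{alt.kind}\t{reason.pw}\t{reason.rw}\t"
                f"{reason.s}\t{reason.w}\t{new}\n"
            )
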