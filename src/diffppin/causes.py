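"""Attribute each observed rewiring to transcriptomic alterations of its
interactors.

An interaction can change between two samples for two elementary reasons
per endpoint: the protein is present in one sample but not the other
(differential expression, DE), or it is present in both with a different
major isoform whose domain composition changes what it can bind
(alternative splicing, AS).  Per pairwise comparison the observed
combination of endpoint alterations is one of DE, AS, DE/DE, DE/AS or
AS/AS; redundant double alterations are deliberately kept visible because
co-deregulation of both partners is itself informative.

Over all comparisons in which a significant edge rewired, the per-type
observation counts form the event's cause distribution.  Two tallies are
used downstream: *proportional*, weighting each type by its share of the
event's observations, and *exclusive*, labelling the event with its single
cause type or "mixed" when several types were observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .diffcore import PairwiseDiff
from .network_io import EdgeKey, SampleNetwork
from .significance import RewiringEvent

__all__ = [
    "Alteration",
    "PairCause",
    "CauseDistribution",
    "CAUSE_TYPES",
    "MIXED",
    "UNEXPLAINED",
    "attribute_pair_cause",
    "collect_pair_causes",
    "annotate_event_causes",
    "tabulate_cause_shares",
]

DE = "DE"
AS = "AS"
MIXED = "mixed"
UNEXPLAINED = "UNEXPLAINED"

#: Fixed reporting order of the combined cause types.
CAUSE_TYPES = ("DE", "AS", "DE/DE", "DE/AS", "AS/AS")

_COMBINED = {
    ("DE",): "DE",
    ("AS",): "AS",
    ("DE", "DE"): "DE/DE",
    ("AS", "DE"): "DE/AS",
    ("AS", "AS"): "AS/AS",
    (): UNEXPLAINED,
}


@dataclass(frozen=True, order=True)
class Alteration:
    """A single-protein transcriptomic alteration (candidate cause)."""

    protein: str
    kind: str  # DE or AS

    def __post_init__(self):
        if self.kind not in (DE, AS):
            raise ValueError(f"alteration kind must be DE or AS, got {self.kind!r}")


@dataclass(frozen=True)
class PairCause:
    """Cause annotation of one rewired edge in one pairwise comparison."""

    edge: EdgeKey
    comparison_index: int
    alterations: frozenset[Alteration]
    combined: str


@dataclass(frozen=True)
class CauseDistribution:
    """Per-type observation counts of one event across its comparisons."""

    counts: Mapping[str, int]
    unexplained: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def shares(self) -> dict[str, float]:
        """Proportional shares over explained observations (sum to 1)."""
        total = self.total
        if total == 0:
            return {}
        return {t: c / total for t, c in self.counts.items() if c > 0}

    @property
    def exclusive(self) -> str:
        """The single observed type, or ``mixed`` when several occurred."""
        observed = [t for t, c in self.counts.items() if c > 0]
        if not observed:
            return UNEXPLAINED
        return observed[0] if len(observed) == 1 else MIXED

    def serialize(self) -> str:
        """``TYPE:fraction`` pairs joined by ';' in fixed type order."""
        shares = self.shares
        parts = [
            f"{t}:{shares[t]:.6g}" for t in CAUSE_TYPES if shares.get(t, 0) > 0
        ]
        if self.unexplained:
            parts.append(f"{UNEXPLAINED}:{self.unexplained}")
        return ";".join(parts)


def _endpoint_alteration(
    protein: str, a: SampleNetwork, b: SampleNetwork
) -> Optional[Alteration]:
    in_a = protein in a.proteins
    in_b = protein in b.proteins
    if in_a != in_b:
        return Alteration(protein, DE)
    if in_a and in_b and a.major_isoform is not None and b.major_isoform is not None:
        iso_a = a.major_isoform.get(protein)
        iso_b = b.major_isoform.get(protein)
        if iso_a is not None and iso_b is not None and iso_a != iso_b:
            return Alteration(protein, AS)
    return None


def attribute_pair_cause(
    edge: EdgeKey, a: SampleNetwork, b: SampleNetwork, comparison_index: int = 0
) -> PairCause:
    """Explain why *edge* differs between samples *a* and *b*.

    For each endpoint: DE if its presence differs between the samples,
    else AS if both samples assign it different major isoforms.  An edge
    rewired with neither endpoint altered is possible only for
    user-supplied networks that were not derived from the transcriptome;
    it is labelled UNEXPLAINED and tracked separately downstream.
    """
    if (edge in a.edges) == (edge in b.edges):
        raise ValueError(f"edge {edge} is not rewired between {a.sample_id} and {b.sample_id}")
    alterations = frozenset(
        alt
        for p in set(edge)
        if (alt := _endpoint_alteration(p, a, b)) is not None
    )
    kinds = tuple(sorted(alt.kind for alt in alterations))
    return PairCause(
        edge=edge,
        comparison_index=comparison_index,
        alterations=alterations,
        combined=_COMBINED[kinds],
    )


def collect_pair_causes(
    edges: Iterable[EdgeKey],
    comparisons: Sequence[PairwiseDiff],
    samples: Mapping[str, SampleNetwork],
) -> dict[EdgeKey, list[PairCause]]:
    """Attribute every (edge, comparison) rewiring observation.

    ``samples`` maps sample ids to their networks; each comparison names
    the two samples it compared.
    """
    edges = set(edges)
    no_isoforms = any(samples[c.sample_a_id].major_isoform is None
                      or samples[c.sample_b_id].major_isoform is None
                      for c in comparisons)
    if no_isoforms:
        warnings.warn(
            "isoform maps missing for some samples; alternative-splicing "
            "causes cannot be detected there",
            stacklevel=2,
        )
    out: dict[EdgeKey, list[PairCause]] = {e: [] for e in edges}
    for comp in comparisons:
        a = samples[comp.sample_a_id]
        b = samples[comp.sample_b_id]
        for edge in edges & comp.rewired:
            out[edge].append(attribute_pair_cause(edge, a, b, comp.index))
    return out


def _distribution(pair_causes: Sequence[PairCause]) -> CauseDistribution:
    counts = {t: 0 for t in CAUSE_TYPES}
    unexplained = 0
    for pc in pair_causes:
        if pc.combined == UNEXPLAINED:
            unexplained += 1
        else:
            counts[pc.combined] += 1
    return CauseDistribution(counts=counts, unexplained=unexplained)


def annotate_event_causes(
    events: Sequence[RewiringEvent],
    comparisons: Sequence[PairwiseDiff],
    samples: Mapping[str, SampleNetwork] | Sequence[SampleNetwork],
) -> list[RewiringEvent]:
    """Fill the cause distribution of every significant event."""
    if not isinstance(samples, Mapping):
        samples = {s.sample_id: s for s in samples}
    pair_causes = collect_pair_causes((ev.edge for ev in events), comparisons, samples)
    return [ev.with_causes(_distribution(pair_causes[ev.edge])) for ev in events]


def tabulate_cause_shares(
    events: Sequence[RewiringEvent],
    mode: str = "proportional",
    group_by: str = "none",
) -> pd.DataFrame:
    """Aggregate cause shares over events, as percentages.

    Each event contributes equally (its shares are normalized before
    averaging).  ``mode='proportional'`` averages the per-event type
    shares; ``mode='exclusive'`` assigns each event wholly to its single
    cause type or to ``mixed``, and additionally reports per pure type the
    absolute loss (proportional − exclusive share) and the relative loss
    (loss / proportional share) incurred by the stricter notion.
    ``group_by='direction'`` splits the table by emerging/vanishing.
    """
    if mode not in ("proportional", "exclusive"):
        raise ValueError(f"unknown mode {mode!r}")
    if group_by not in ("none", "direction"):
        raise ValueError(f"unknown group_by {group_by!r}")

    def _aggregate(evs: Sequence[RewiringEvent]) -> pd.DataFrame:
        explained = [ev for ev in evs if ev.causes is not None and ev.causes.total > 0]
        n = len(explained)
        prop = {t: 0.0 for t in CAUSE_TYPES}
        excl = {t: 0.0 for t in (*CAUSE_TYPES, MIXED)}
        for ev in explained:
            for t, share in ev.causes.shares.items():
                prop[t] += share
            excl[ev.causes.exclusive] += 1.0
        if n:
            prop = {t: 100.0 * v / n for t, v in prop.items()}
            excl = {t: 100.0 * v / n for t, v in excl.items()}
        if mode == "proportional":
            return pd.DataFrame(
                {"type": list(CAUSE_TYPES), "share_pct": [prop[t] for t in CAUSE_TYPES]}
            )
        types = [*CAUSE_TYPES, MIXED]
        rows = []
        for t in types:
            if t == MIXED:
                loss = rel = float("nan")
            else:
                loss = prop[t] - excl[t]
                rel = 100.0 * loss / prop[t] if prop[t] > 0 else float("nan")
            rows.append((t, excl[t], loss, rel))
        return pd.DataFrame(
            rows, columns=["type", "share_pct", "absolute_loss_pct", "relative_loss_pct"]
        )

    if group_by == "none":
        return _aggregate(events)
    frames = []
    for direction, label in ((1, "+"), (-1, "-")):
        sub = _aggregate([ev for ev in events if ev.direction == direction])
        sub.insert(0, "direction", label)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)
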