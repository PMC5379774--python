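"""Pairwise differential networks and the cumulative signed differential network.

Each sample of the first group is compared with each sample of the second
group.  For comparison *i*, an interaction found only in the second
group's sample is noted +1 (gained), one found only in the first group's
sample −1 (lost).  The signed observations are summed over all
N = |group1| × |group2| comparisons into Δ(u,v); edges whose
observations cancel to zero are dropped.  The background rewiring
probability P_rew is the mean Jaccard distance of the per-pair edge sets
and later serves as the null rate of the per-edge binomial test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .network_io import EdgeKey, SampleNetwork

__all__ = [
    "PairwiseDiff",
    "DifferentialNetwork",
    "jaccard_rewiring_probability",
    "compare_pair",
    "build_differential_network",
]


@dataclass(frozen=True)
class PairwiseDiff:
    """Result of comparing one group-1 sample with one group-2 sample."""

    index: int
    sample_a_id: str
    sample_b_id: str
    gained: frozenset[EdgeKey]  # edges in b only
    lost: frozenset[EdgeKey]  # edges in a only
    p_rew_i: float

    @property
    def rewired(self) -> frozenset[EdgeKey]:
        return self.gained | self.lost


@dataclass(frozen=True)
class DifferentialNetwork:
    """Cumulative signed differential network over all inter-group pairs."""

    delta: Mapping[EdgeKey, int]
    n_comparisons: int
    p_rew: float
    comparisons: tuple[PairwiseDiff, ...]

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(p for e in self.delta for p in e)


def jaccard_rewiring_probability(edges_a, edges_b) -> float:
    """Jaccard distance between two edge sets; 0.0 when both are empty."""
    a, b = set(edges_a), set(edges_b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return 1.0 - len(a & b) / union


def compare_pair(a: SampleNetwork, b: SampleNetwork, index: int = 0) -> PairwiseDiff:
    """Differential network of a single inter-group sample pair.

    Symmetric under swapping the samples, except that gained and lost
    exchange roles.
    """
    gained = frozenset(b.edges - a.edges)
    lost = frozenset(a.edges - b.edges)
    return PairwiseDiff(
        index=index,
        sample_a_id=a.sample_id,
        sample_b_id=b.sample_id,
        gained=gained,
        lost=lost,
        p_rew_i=jaccard_rewiring_probability(a.edges, b.edges),
    )


def build_differential_network(
    group1: Sequence[SampleNetwork], group2: Sequence[SampleNetwork]
) -> DifferentialNetwork:
    """Compare all inter-group sample pairs and sum the signed observations.

    Comparisons are indexed row-major over (group1 order, group2 order).
    Edges whose gains and losses cancel (null-sum) are removed from the
    cumulative network.  Groups with fewer than three samples are
    accepted with a warning: the test loses calibration and power when a
    handful of samples is reused across all pairs.
    """
    if not group1 or not group2:
        raise ValueError("both groups must contain at least one sample network")
    for name, group in (("group1", group1), ("group2", group2)):
        if len(group) < 3:
            warnings.warn(
                f"{name} has only {len(group)} sample(s); groups with at least "
                "3 samples give meaningful results",
                stacklevel=2,
            )

    comparisons: list[PairwiseDiff] = []
    delta: dict[EdgeKey, int] = {}
    index = 0
    for a in group1:
        for b in group2:
            pd = compare_pair(a, b, index)
            comparisons.append(pd)
            for e in pd.gained:
                delta[e] = delta.get(e, 0) + 1
            for e in pd.lost:
                delta[e] = delta.get(e, 0) - 1
            index += 1

    delta = {e: d for e, d in delta.items() if d != 0}
    n = len(comparisons)
    p_rew = sum(c.p_rew_i for c in comparisons) / n
    return DifferentialNetwork(
        delta=delta,
        n_comparisons=n,
        p_rew=p_rew,
        comparisons=tuple(comparisons),
    )
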