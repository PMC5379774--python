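"""Binomial significance test for rewiring events with BH-FDR control.

Each candidate edge of the cumulative differential network is tested
one-tailed against the background rewiring probability P_rew: the p-value
is P(X >= |Δ(u,v)|) for X ~ Binomial(N, P_rew), i.e. the chance of seeing
at least the observed number of consistent rewiring observations across
the N pairwise comparisons if the edge rewired at the background rate.
The family of tests is exactly the candidate set (edges surviving
null-sum removal), adjusted with Benjamini–Hochberg; events strictly
below the FDR threshold are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffcore import DifferentialNetwork
from .network_io import EdgeKey

__all__ = [
    "RewiringEvent",
    "TransitionSummary",
    "binomial_tail_pvalue",
    "benjamini_hochberg",
    "call_significant",
]

DEFAULT_FDR = 0.05


@dataclass(frozen=True)
class RewiringEvent:
    """One significantly rewired interaction."""

    edge: EdgeKey
    count: int  # |Δ(u,v)|, number of consistent observations
    direction: int  # +1 emerging, -1 vanishing
    n_comparisons: int
    p: float
    p_adj: float
    causes: Optional["CauseDistribution"] = None  # filled by the causes module

    def with_causes(self, causes) -> "RewiringEvent":
        return replace(self, causes=causes)


@dataclass(frozen=True)
class TransitionSummary:
    """Per-transition headline numbers (one row of a summary table)."""

    rew_plus: int
    rew_minus: int
    obs_s: Optional[int]  # min observations among significant events
    obs_all: int  # N, number of pairwise comparisons
    p_rew: float
    fdr: float
    n_candidates: int

    @property
    def net_change(self) -> int:
        return self.rew_plus - self.rew_minus


def binomial_tail_pvalue(count: int, n: int, p_rew: float) -> float:
    """Upper-tail binomial probability P(X >= count), X ~ Binomial(n, p_rew).

    Uses the survival function, which stays accurate in the far tail
    where the textbook 1-CDF subtraction would lose all precision.
    """
    if not 0 <= count <= n:
        raise ValueError(f"count must be in [0, n]; got count={count}, n={n}")
    if not 0.0 <= p_rew <= 1.0:
        raise ValueError(f"p_rew must be in [0, 1]; got {p_rew}")
    if count == 0:
        return 1.0
    return float(stats.binom.sf(count - 1, n, p_rew))


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """BH step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def call_significant(
    diffnet: DifferentialNetwork, fdr: float = DEFAULT_FDR
) -> tuple[list[RewiringEvent], TransitionSummary]:
    """Test every candidate edge and keep events with adjusted p < fdr.

    Returns the significant events sorted by edge key together with the
    transition summary (rew+/rew−, the minimum significant observation
    count obs_s, N, P_rew).
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError(f"fdr must be in (0, 1); got {fdr}")

    edges = sorted(diffnet.delta)
    n = diffnet.n_comparisons
    raw = [
        binomial_tail_pvalue(abs(diffnet.delta[e]), n, diffnet.p_rew) for e in edges
    ]
    adj = benjamini_hochberg(raw)

    events = [
        RewiringEvent(
            edge=e,
            count=abs(diffnet.delta[e]),
            direction=1 if diffnet.delta[e] > 0 else -1,
            n_comparisons=n,
            p=p,
            p_adj=pa,
        )
        for e, p, pa in zip(edges, raw, adj)
        if pa < fdr
    ]

    summary = TransitionSummary(
        rew_plus=sum(1 for ev in events if ev.direction > 0),
        rew_minus=sum(1 for ev in events if ev.direction < 0),
        obs_s=min((ev.count for ev in events), default=None),
        obs_all=n,
        p_rew=diffnet.p_rew,
        fdr=fdr,
        n_candidates=len(edges),
    )
    return events, summary
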