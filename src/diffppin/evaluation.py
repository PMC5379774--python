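"""Downstream analyses of detected rewiring.

Covers hypergeometric enrichment of protein sets and of pathway-mapped
interactions (with per-source BH adjustment), direction-consistent
connected components among the reduced protein set, sample clustering by
normalized Hamming distance over the significantly rewired interactions,
and the self-consistency statistics of a per-transition summary table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

from .network_io import EdgeKey, SampleNetwork, edge_key
from .significance import RewiringEvent, benjamini_hochberg

__all__ = [
    "PathwayEdgeMap",
    "EnrichmentResult",
    "hypergeometric_enrichment",
    "pathway_edge_enrichment",
    "load_pathway_edge_file",
    "direction_consistent_components",
    "interactome_clustering",
    "load_transition_table",
    "transition_table_statistics",
]


@dataclass(frozen=True)
class PathwayEdgeMap:
    """Interactions of one pathway, restricted to the reference network."""

    name: str
    source: str  # e.g. the pathway database the map came from
    edges: frozenset[EdgeKey]


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    overlap: int
    query_size: int
    set_size: int
    background_size: int
    p: float
    p_adj: Optional[float] = None


def hypergeometric_enrichment(query, target, background) -> EnrichmentResult:
    """Upper-tail hypergeometric overrepresentation of *target* in *query*.

    p = P(X >= overlap) for X ~ Hypergeometric(|background|, |target|,
    |query|).  Both query and target must be subsets of the background.
    """
    query, target, background = set(query), set(target), set(background)
    if not query <= background:
        raise ValueError("query is not a subset of the background")
    if not target <= background:
        raise ValueError("target is not a subset of the background")
    overlap = len(query & target)
    m, n_target, n_query = len(background), len(target), len(query)
    p = 1.0 if overlap == 0 else float(
        stats.hypergeom.sf(overlap - 1, m, n_target, n_query)
    )
    return EnrichmentResult(
        set_id="",
        overlap=overlap,
        query_size=n_query,
        set_size=n_target,
        background_size=m,
        p=min(p, 1.0),
    )


def pathway_edge_enrichment(
    rewired_edges: Iterable[EdgeKey],
    maps: Sequence[PathwayEdgeMap],
    background_edges: Iterable[EdgeKey],
    subset: Optional[Iterable[EdgeKey]] = None,
) -> list[EnrichmentResult]:
    """Interaction-centric pathway enrichment.

    One hypergeometric test per pathway over edges; BH adjustment runs
    separately per pathway source.  ``subset`` optionally restricts the
    query to a filtered portion of the rewired edges (e.g. one direction
    or one cause type).
    """
    background = set(background_edges)
    query = set(rewired_edges) & background
    if subset is not None:
        query &= set(subset)
    results: list[EnrichmentResult] = []
    for pmap in maps:
        edges = pmap.edges & background
        base = hypergeometric_enrichment(query, edges, background)
        results.append(
            EnrichmentResult(
                set_id=pmap.name,
                overlap=base.overlap,
                query_size=base.query_size,
                set_size=base.set_size,
                background_size=base.background_size,
                p=base.p,
            )
        )
    adjusted: list[EnrichmentResult] = []
    by_source: dict[str, list[int]] = {}
    for idx, pmap in enumerate(maps):
        by_source.setdefault(pmap.source, []).append(idx)
    adj = [None] * len(results)
    for indices in by_source.values():
        padj = benjamini_hochberg([results[i].p for i in indices])
        for i, a in zip(indices, padj):
            adj[i] = a
    for r, a in zip(results, adj):
        adjusted.append(
            EnrichmentResult(
                set_id=r.set_id,
                overlap=r.overlap,
                query_size=r.query_size,
                set_size=r.set_size,
                background_size=r.background_size,
                p=r.p,
                p_adj=a,
            )
        )
    return adjusted


def load_pathway_edge_file(
    path: str | Path,
    background_edges: Iterable[EdgeKey] | None = None,
    *,
    min_edges: int = 15,
    max_edges: int = 1000,
) -> list[PathwayEdgeMap]:
    """Read a pre-mapped pathway edge TSV (source, pathway, proteinA, proteinB).

    The size bounds (defaults 15..1000 connections) apply to the pathway's
    edge count in the file, i.e. before restriction to the reference
    network, mirroring the usual practice of filtering pathway databases
    before interactome mapping.
    """
    raw: dict[tuple[str, str], set[EdgeKey]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 columns "
                    "(source, pathway, proteinA, proteinB)"
                )
            raw.setdefault((cols[0], cols[1]), set()).add(edge_key(cols[2], cols[3]))
    background = None if background_edges is None else set(background_edges)
    maps = []
    for (source, name), edges in sorted(raw.items()):
        if not (min_edges <= len(edges) <= max_edges):
            continue
        if background is not None:
            edges = edges & background
        maps.append(PathwayEdgeMap(name=name, source=source, edges=frozenset(edges)))
    return maps


@dataclass(frozen=True)
class DirectedComponent:
    proteins: frozenset[str]
    direction: int  # +1 emerging, -1 vanishing

    @property
    def size(self) -> int:
        return len(self.proteins)


def direction_consistent_components(
    reduced_proteins: Iterable[str],
    events: Sequence[RewiringEvent],
    min_size: int = 3,
) -> list[DirectedComponent]:
    """Connected components of reduced-set proteins per rewiring direction.

    For each direction separately, the subgraph induced by the reduced
    set on the significant edges of that direction is decomposed into
    connected components; components smaller than ``min_size`` proteins
    are dropped.
    """
    reduced = set(reduced_proteins)
    out: list[DirectedComponent] = []
    for direction in (1, -1):
        g = nx.Graph()
        for ev in events:
            if ev.direction != direction:
                continue
            u, v = ev.edge
            if u in reduced and v in reduced:
                g.add_edge(u, v)
        for comp in nx.connected_components(g):
            if len(comp) >= min_size:
                out.append(DirectedComponent(frozenset(comp), direction))
    out.sort(key=lambda c: (-c.direction, -c.size, sorted(c.proteins)))
    return out


def interactome_clustering(
    samples: Sequence[SampleNetwork], feature_edges: Iterable[EdgeKey]
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """UPGMA clustering of samples by interactome dissimilarity.

    Each sample becomes a boolean presence vector over ``feature_edges``
    (typically the significantly rewired interactions); the pairwise
    distance is the normalized Hamming distance and agglomeration uses
    average linkage.  Returns (linkage matrix, sample ids in input order,
    condensed distance vector).
    """
    features = sorted(set(feature_edges))
    if not features:
        raise ValueError("feature edge set must be non-empty")
    if len(samples) < 2:
        raise ValueError("need at least two samples to cluster")
    matrix = np.array(
        [[e in s.edges for e in features] for s in samples], dtype=float
    )
    condensed = []
    n = len(samples)
    for i in range(n):
        for j in range(i + 1, n):
            condensed.append(np.mean(matrix[i] != matrix[j]))
    condensed = np.asarray(condensed)
    link = linkage(condensed, method="average")
    return link, [s.sample_id for s in samples], condensed


# ---------------------------------------------------------------------------
# Transition summary table statistics

_TABLE_RESOURCE = "hematopoietic_transitions.tsv"


def load_transition_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a per-transition summary table (bundled blood-development one
    by default) and derive the fraction obs_s/obs_all and the net change."""
    if path is None:
        source = resources.files("diffppin.data") / _TABLE_RESOURCE
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    df["obs_fraction"] = df["obs_s"] / df["obs_all"]
    df["net_change"] = df["rew_plus"] - df["rew_minus"]
    df["sigma_deviation"] = (
        (df["net_change"] - df["delta_n"]).abs() / df["sigma_delta_n"]
    )
    return df


def transition_table_statistics(df: pd.DataFrame) -> dict[str, float]:
    """Self-consistency statistics of a transition summary table.

    Pearson correlations between the summary columns, plus the deviation
    of the net significant change from the mean net interactome-size
    difference, expressed in units of its standard deviation.
    """
    return {
        "pearson_p_rew_vs_sigma_delta_n": float(
            np.corrcoef(df["p_rew"], df["sigma_delta_n"])[0, 1]
        ),
        "pearson_obs_fraction_vs_p_rew": float(
            np.corrcoef(df["obs_fraction"], df["p_rew"])[0, 1]
        ),
        "pearson_obs_fraction_vs_obs_all": float(
            np.corrcoef(df["obs_fraction"], df["obs_all"])[0, 1]
        ),
        "max_sigma_deviation": float(df["sigma_deviation"].max()),
        "mean_sigma_deviation": float(df["sigma_deviation"].mean()),
    }
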