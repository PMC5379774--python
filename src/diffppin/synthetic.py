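"""Synthetic grouped interactomes with planted, cause-labelled rewiring.

The generator emulates the data regime the method is built for: a shared
reference interactome, per-sample subnetworks with within-group
heterogeneity, and consistent between-group gains/losses with a known
transcriptomic cause per planted event.  Heterogeneity is modelled by
independently dropping each reference edge with probability ε per sample.
Planted events are realized on dedicated alteration proteins so their
ground truth is unambiguous:

* a DE-planted event removes the altered protein (and hence its planted
  interaction) entirely from one group's samples — presence change;
* an AS-planted event keeps the altered protein present in all samples
  but switches its major isoform between groups, with the planted
  interaction present only where the binding-competent isoform is.

Every sample carries an isoform map covering exactly its present
proteins, so re-deriving causes from the emitted networks reproduces the
ground-truth record.  All sampling is drawn from a single seeded
generator in a fixed documented order, making runs reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .network_io import (
    ISOFORM_SUFFIX,
    EdgeKey,
    SampleNetwork,
    edge_key,
    write_isoform_map,
    write_sample_network,
)

__all__ = [
    "SimulationProfile",
    "PlantedEvent",
    "GroundTruth",
    "generate_reference",
    "generate_groups",
    "write_simulation",
]


@dataclass(frozen=True)
class SimulationProfile:
    """Study conditions for one simulated two-group comparison.

    Defaults reflect a small-group regime: two groups of three samples
    each, a few hundred reference interactions, 5% per-sample edge
    drop-out as within-group heterogeneity, and twenty planted
    consistent rewiring events split evenly between gains and losses and
    between DE and AS causes.
    """

    n_proteins: int = 100
    n_edges: int = 300
    n1: int = 3
    n2: int = 3
    epsilon: float = 0.05
    n_gains: int = 10
    n_losses: int = 10
    de_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError(f"epsilon must be in [0, 0.5); got {self.epsilon}")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be >= 1")


@dataclass(frozen=True)
class PlantedEvent:
    edge: EdgeKey
    direction: int  # +1 gained in group 2, -1 lost in group 2
    cause_kind: str  # DE or AS
    altered_protein: str


@dataclass(frozen=True)
class GroundTruth:
    reference: SampleNetwork
    planted: tuple[PlantedEvent, ...]

    @property
    def planted_edges(self) -> frozenset[EdgeKey]:
        return frozenset(ev.edge for ev in self.planted)


def _protein_name(i: int) -> str:
    return f"P{i:04d}"


def generate_reference(
    n_proteins: int, n_edges: int, seed: int | np.random.Generator
) -> SampleNetwork:
    """Uniformly random simple undirected graph with exactly ``n_edges``."""
    max_edges = n_proteins * (n_proteins - 1) // 2
    if n_edges > max_edges:
        raise ValueError(
            f"cannot place {n_edges} edges among {n_proteins} proteins "
            f"(max {max_edges})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(max_edges, size=n_edges, replace=False)
    proteins = [_protein_name(i) for i in range(n_proteins)]
    # unrank the flat indices of the upper triangle
    edges = set()
    for flat in sorted(int(c) for c in chosen):
        i = int((2 * n_proteins - 1 - np.sqrt((2 * n_proteins - 1) ** 2 - 8 * flat)) // 2)
        j = flat - i * (2 * n_proteins - i - 1) // 2 + i + 1
        edges.add(edge_key(proteins[i], proteins[j]))
    assert len(edges) == n_edges
    return SampleNetwork(
        sample_id="reference",
        edges=frozenset(edges),
        proteins=frozenset(proteins),
        major_isoform=None,
    )


def _baseline_isoform(protein: str) -> str:
    return f"{protein}-T1"


def _switched_isoform(protein: str) -> str:
    return f"{protein}-T2"


def generate_groups(
    profile: SimulationProfile,
) -> tuple[list[SampleNetwork], list[SampleNetwork], GroundTruth]:
    """Simulate both sample groups plus the planted ground truth.

    Sampling order (fixed so runs are reproducible): reference edges,
    planted-event partner proteins, per-event cause kinds, then the
    per-sample edge drop-outs, group 1 before group 2, samples in index
    order.
    """
    rng = np.random.default_rng(profile.seed)
    reference = generate_reference(profile.n_proteins, profile.n_edges, rng)
    ref_edges = sorted(reference.edges)
    ref_proteins = sorted(reference.proteins)

    n_planted = profile.n_gains + profile.n_losses
    # partners must be constitutively expressed (reference degree >= 1);
    # otherwise their own presence would change with the planted edge and
    # the planted alteration would no longer be the event's sole cause
    connected = sorted({p for e in ref_edges for p in e})
    if n_planted > len(connected):
        raise ValueError(
            f"cannot plant {n_planted} events: only {len(connected)} connected "
            "reference proteins available as partners"
        )
    partners = [
        connected[i]
        for i in rng.choice(len(connected), size=n_planted, replace=False)
    ]
    n_de = int(round(profile.de_fraction * n_planted))
    kinds = np.array(["DE"] * n_de + ["AS"] * (n_planted - n_de))
    rng.shuffle(kinds)

    planted: list[PlantedEvent] = []
    for k in range(n_planted):
        altered = f"A{k:04d}"  # dedicated alteration protein, not in reference
        direction = 1 if k < profile.n_gains else -1
        planted.append(
            PlantedEvent(
                edge=edge_key(altered, partners[k]),
                direction=direction,
                cause_kind=str(kinds[k]),
                altered_protein=altered,
            )
        )

    def make_sample(group: int, idx: int) -> SampleNetwork:
        keep = rng.random(len(ref_edges)) >= profile.epsilon
        edges = {e for e, k in zip(ref_edges, keep) if k}
        isoforms: dict[str, str] = {}
        for ev in planted:
            # planted edge present iff the sample's group matches the direction
            edge_here = (ev.direction > 0) == (group == 2)
            if ev.cause_kind == "DE":
                if edge_here:
                    edges.add(ev.edge)  # altered protein expressed here
            else:  # AS: protein present everywhere, isoform differs by group
                present_iso = (
                    _switched_isoform(ev.altered_protein)
                    if group == 2
                    else _baseline_isoform(ev.altered_protein)
                )
                isoforms[ev.altered_protein] = present_iso
                if edge_here:
                    edges.add(ev.edge)
        present = {p for e in edges for p in e} | set(isoforms)
        for p in present:
            isoforms.setdefault(p, _baseline_isoform(p))
        return SampleNetwork(
            sample_id=f"g{group}_s{idx}",
            edges=frozenset(edges),
            proteins=frozenset(isoforms),
            major_isoform=isoforms,
        )

    group1 = [make_sample(1, i) for i in range(profile.n1)]
    group2 = [make_sample(2, i) for i in range(profile.n2)]
    return group1, group2, GroundTruth(reference=reference, planted=tuple(planted))


def write_simulation(
    outdir: str | Path,
    group1: Sequence[SampleNetwork],
    group2: Sequence[SampleNetwork],
    truth: Optional[GroundTruth] = None,
) -> None:
    """Write both groups (and the ground truth) in the tool's input format."""
    outdir = Path(outdir)
    for name, group in (("group1", group1), ("group2", group2)):
        gdir = outdir / name
        gdir.mkdir(parents=True, exist_ok=True)
        for sample in group:
            write_sample_network(sample, gdir / f"{sample.sample_id}.tsv")
            if sample.major_isoform is not None:
                write_isoform_map(
                    sample, gdir / f"{sample.sample_id}{ISOFORM_SUFFIX}"
                )
    if truth is not None:
        with open(outdir / "ground_truth.tsv", "w", encoding="utf-8") as fh:
            fh.write("protein1\tprotein2\tdirection\tcause\taltered_protein\n")
            for ev in sorted(truth.planted, key=lambda e: e.edge):
                fh.write(
                    f"{ev.edge[0]}\t{ev.edge[1]}\t"
                    f"{'+' if ev.direction > 0 else '-'}\t"
                    f"{ev.cause_kind}\t{ev.altered_protein}\n"
                )
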