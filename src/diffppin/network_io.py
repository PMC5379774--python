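"""Reading sample interactomes and writing Cytoscape-importable result tables.

A sample network is a tab-separated edge list (protein A, protein B,
optional weight; weights are ignored because presence is all the method
uses).  An optional companion file maps each expressed protein to its
major transcript isoform, which is what makes alternative-splicing causes
detectable downstream.  Lines starting with ``#`` are comments; files are
UTF-8; no header is expected.

All result tables are plain TSV with a header row, sorted
deterministically, so that two runs on identical input are byte-identical
and the files load directly into network viewers as node/edge attribute
tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "EdgeKey",
    "SampleNetwork",
    "ParseError",
    "edge_key",
    "read_sample_network",
    "read_group_directory",
    "write_sample_network",
    "write_isoform_map",
    "write_edge_attribute_table",
    "write_node_attribute_table",
]

#: An undirected interaction, stored as a lexicographically ordered pair.
EdgeKey = tuple[str, str]


class ParseError(ValueError):
    """Malformed input file; message carries file name and line number."""


def edge_key(a: str, b: str, *, allow_self_loops: bool = False) -> EdgeKey:
    """Canonical undirected edge identity for proteins *a* and *b*.

    Self-interactions are rejected by default; pass
    ``allow_self_loops=True`` to permit them.
    """
    for p in (a, b):
        if not p or "\t" in p or "\n" in p:
            raise ValueError(f"invalid protein identifier: {p!r}")
    if a == b and not allow_self_loops:
        raise ValueError(f"self-interaction {a!r}-{b!r} not allowed")
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SampleNetwork:
    """One sample's contextualized interactome.

    ``proteins`` is the set of expressed proteins: endpoints of the edges
    plus any edgeless proteins listed in the isoform file.  A protein is
    "present" in a sample iff it is a member of ``proteins``.
    """

    sample_id: str
    edges: frozenset[EdgeKey]
    proteins: frozenset[str]
    major_isoform: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        endpoint_proteins = {p for e in self.edges for p in e}
        if not endpoint_proteins <= self.proteins:
            missing = sorted(endpoint_proteins - self.proteins)
            raise ValueError(f"edge endpoints missing from protein set: {missing}")
        if self.major_isoform is not None:
            extra = set(self.major_isoform) - self.proteins
            if extra:
                raise ValueError(
                    f"isoform map lists proteins outside the network: {sorted(extra)}"
                )


def _data_lines(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_sample_network(
    path: str | Path,
    isoform_path: str | Path | None = None,
    *,
    sample_id: str | None = None,
    allow_self_loops: bool = False,
) -> SampleNetwork:
    """Read one sample network (and optionally its major-isoform map).

    Edges are canonicalized and deduplicated; a duplicate edge with a
    different weight column is still the same edge.  The protein set is
    the union of edge endpoints and isoform-file proteins.  Conflicting
    duplicate isoform assignments raise :class:`ParseError`.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    edges: set[EdgeKey] = set()
    for lineno, cols in _data_lines(path):
        if len(cols) < 2:
            raise ParseError(f"{path}:{lineno}: expected >=2 tab-separated columns")
        try:
            edges.add(edge_key(cols[0].strip(), cols[1].strip(),
                               allow_self_loops=allow_self_loops))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc

    isoforms: dict[str, str] | None = None
    if isoform_path is not None:
        isoform_path = Path(isoform_path)
        isoforms = {}
        for lineno, cols in _data_lines(isoform_path):
            if len(cols) < 2:
                raise ParseError(
                    f"{isoform_path}:{lineno}: expected >=2 tab-separated columns"
                )
            protein, transcript = cols[0].strip(), cols[1].strip()
            if not protein or not transcript:
                raise ParseError(f"{isoform_path}:{lineno}: empty field")
            previous = isoforms.get(protein)
            if previous is not None and previous != transcript:
                raise ParseError(
                    f"{isoform_path}:{lineno}: conflicting isoform for {protein}: "
                    f"{previous} vs {transcript}"
                )
            isoforms[protein] = transcript

    proteins = {p for e in edges for p in e}
    if isoforms:
        proteins |= set(isoforms)
    if not edges and not proteins:
        warnings.warn(f"{path}: empty network (0 edges, 0 proteins)", stacklevel=2)
    return SampleNetwork(
        sample_id=sample_id,
        edges=frozenset(edges),
        proteins=frozenset(proteins),
        major_isoform=isoforms,
    )


#: Suffix of a companion isoform file for sample file ``<stem>.tsv``.
ISOFORM_SUFFIX = ".isoforms.tsv"


def read_group_directory(
    directory: str | Path,
    *,
    use_isoforms: bool = True,
    allow_self_loops: bool = False,
) -> list[SampleNetwork]:
    """Read every sample of a group from one directory.

    Every ``*.tsv`` file that is not an isoform companion file is one
    sample; ``<stem>.isoforms.tsv``, if present, supplies its major
    isoforms.  Samples are ordered by file name.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"group directory not found: {directory}")
    samples = []
    for path in sorted(directory.glob("*.tsv")):
        if path.name.endswith(ISOFORM_SUFFIX):
            continue
        iso = path.with_name(path.stem + ISOFORM_SUFFIX)
        iso_path = iso if (use_isoforms and iso.exists()) else None
        samples.append(
            read_sample_network(path, iso_path, allow_self_loops=allow_self_loops)
        )
    if not samples:
        raise FileNotFoundError(f"no sample networks (*.tsv) in {directory}")
    return samples


def _fmt(x: float) -> str:
    """Fixed 6-significant-digit float formatting for table output."""
    return format(x, ".6g")


def write_sample_network(network: SampleNetwork, path: str | Path) -> None:
    """Write the edge list of a sample network (round-trips with reader)."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")
        # edgeless proteins cannot be expressed in an edge list; they
        # survive a round trip only through the isoform companion file


def write_isoform_map(network: SampleNetwork, path: str | Path) -> None:
    if network.major_isoform is None:
        raise ValueError(f"sample {network.sample_id} has no isoform map")
    with open(path, "w", encoding="utf-8") as fh:
        for protein in sorted(network.major_isoform):
            fh.write(f"{protein}\t{network.major_isoform[protein]}\n")


EDGE_TABLE_COLUMNS = (
    "protein1",
    "protein2",
    "direction",
    "observations",
    "comparisons",
    "p_value",
    "p_value_adj",
    "causes",
)


def write_edge_attribute_table(events, path: str | Path) -> None:
    """Write significant rewiring events as a Cytoscape edge-attribute table.

    One row per event: endpoints, direction (+/-), the number of pairwise
    observations |Δ(u,v)| out of N comparisons, raw and adjusted p-value,
    and the serialized cause distribution.  Rows are sorted by edge key.
    """
    rows = sorted(events, key=lambda ev: ev.edge)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EDGE_TABLE_COLUMNS) + "\n")
        for ev in rows:
            causes = "" if ev.causes is None else ev.causes.serialize()
            fh.write(
                "\t".join(
                    (
                        ev.edge[0],
                        ev.edge[1],
                        "+" if ev.direction > 0 else "-",
                        str(ev.count),
                        str(ev.n_comparisons),
                        _fmt(ev.p),
                        _fmt(ev.p_adj),
                        causes,
                    )
                )
                + "\n"
            )


NODE_TABLE_COLUMNS = ("protein", "in_reduced_set", "importance_score", "as_only")


def write_node_attribute_table(proteins, solution, path: str | Path) -> None:
    """Write one row per differential-network protein.

    ``importance_score`` is the maximum score s of the selected reasons
    touching the protein (0 if the protein is not in the reduced set);
    ``as_only`` marks proteins whose every selected reason is an
    alternative-splicing event (drawn with a distinct node shape in
    network viewers).
    """
    flags = solution.protein_flags() if solution is not None else {}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(NODE_TABLE_COLUMNS) + "\n")
        for protein in sorted(proteins):
            info = flags.get(protein)
            in_set = info is not None
            score = info.max_score if in_set else 0
            as_only = info.as_only if in_set else False
            fh.write(
                f"{protein}\t{str(in_set).lower()}\t{score}\t{str(as_only).lower()}\n"
            )
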