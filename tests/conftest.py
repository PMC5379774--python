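from __future__ import annotations

import pytest

from diffppin.network_io import SampleNetwork, edge_key


def make_network(sample_id, edges, isoforms=None, extra_proteins=()):
    """Small-fixture helper: build a SampleNetwork from edge tuples."""
    keys = frozenset(edge_key(a, b) for a, b in edges)
    proteins = {p for e in keys for p in e} | set(extra_proteins)
    if isoforms is not None:
        proteins |= set(isoforms)
    return SampleNetwork(
        sample_id=sample_id,
        edges=keys,
        proteins=frozenset(proteins),
        major_isoform=isoforms,
    )


@pytest.fixture
def net_factory():
    return make_network
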