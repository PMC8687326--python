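"""PPI network assembly and compartment subnetwork extraction.

The global network G = (P, E) is a simple undirected :class:`networkx.Graph`
whose nodes are the interaction endpoints.  Each node carries a
``localisations`` attribute mapping compartment labels to scores in [0, 1];
each edge carries a ``score`` attribute.  A compartment subnetwork G_i is the
subgraph induced by the proteins whose localisation score for that compartment
passes the threshold: membership is decided purely by endpoint localisation,
never by filtering edges within a compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io import InteractionRecord, LocalisationRecord

__all__ = [
    "LocalisedProtein",
    "build_network",
    "derive_interaction_score",
    "extract_subnetwork",
]


@dataclass(frozen=True)
class LocalisedProtein:
    """A protein identifier with per-compartment localisation scores.

    An empty localisation map is allowed; such a protein stays in the global
    network but joins no compartment subnetwork.
    """

    id: str
    localisations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for compartment, score in self.localisations.items():
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"localisation score for {self.id!r}/{compartment!r} "
                    f"outside [0, 1]: {score}"
                )


def build_network(
    interactions: Iterable[InteractionRecord],
    localisations: Iterable[LocalisationRecord] = (),
) -> nx.Graph:
    """Assemble the global PPI network from filtered records.

    The node set is exactly the union of interaction endpoints; localisation
    records for proteins that interact with nothing are ignored.  Duplicate
    unordered pairs keep the maximum score (readers already collapse them, but
    in-memory record lists get the same treatment).
    """
    graph = nx.Graph()
    for rec in interactions:
        if rec.protein_a == rec.protein_b:
            continue
        a, b = rec.key
        if graph.has_edge(a, b):
            graph[a][b]["score"] = max(graph[a][b]["score"], rec.score)
        else:
            graph.add_edge(a, b, score=rec.score)
    nx.set_node_attributes(graph, {n: {} for n in graph.nodes}, "localisations")
    for rec in localisations:
        if rec.protein in graph:
            locs = graph.nodes[rec.protein]["localisations"]
            locs[rec.compartment] = max(locs.get(rec.compartment, 0.0), rec.score)
    return graph


def _localisation_map(protein) -> Mapping[str, float]:
    if isinstance(protein, LocalisedProtein):
        return protein.localisations
    if isinstance(protein, Mapping):
        return protein
    raise TypeError(f"expected LocalisedProtein or mapping, got {type(protein).__name__}")


def derive_interaction_score(a, b) -> float:
    """Noisy-OR interaction score from the two proteins' localisation maps.

    Returns ``1 - prod_c (1 - L_a(c) * L_b(c))`` over the shared compartments
    c, i.e. the probability that the pair co-localises in at least one
    compartment when per-compartment co-localisations are independent.  With
    no shared compartment the score is 0.  Accepts :class:`LocalisedProtein`
    instances or plain compartment->score mappings.
    """
    loc_a, loc_b = _localisation_map(a), _localisation_map(b)
    miss = 1.0
    for compartment, score_a in loc_a.items():
        score_b = loc_b.get(compartment)
        if score_b is not None:
            miss *= 1.0 - score_a * score_b
    return 1.0 - miss


def extract_subnetwork(
    network: nx.Graph,
    compartment: str,
    loc_threshold: float = 0.8,
    vocabulary: Sequence[str] | None = None,
) -> nx.Graph:
    """Induced subgraph of proteins localised to *compartment*.

    A protein belongs to the subnetwork iff its localisation score for the
    compartment is strictly greater than *loc_threshold*; the edge set is then
    every global edge with both endpoints inside.  Multi-localised proteins
    appear in every subnetwork whose threshold they pass.  When *vocabulary*
    is given, an unknown compartment label raises ``ValueError``.
    """
    if vocabulary is not None and compartment not in vocabulary:
        raise ValueError(
            f"unknown compartment {compartment!r}; expected one of {sorted(vocabulary)}"
        )
    members = [
        n
        for n, data in network.nodes(data=True)
        if data.get("localisations", {}).get(compartment, 0.0) > loc_threshold
    ]
    subgraph = network.subgraph(members).copy()
    subgraph.graph["compartment"] = compartment
    return subgraph
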