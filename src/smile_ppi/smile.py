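"""The SMILE procedure: per-compartment clustering, overlap scoring and
merging of subcellular modules into super modules.

SMILE (subcellular module identification with localisation expansion) works in
three steps: (i) extract one interaction subnetwork per compartment from the
localisation-annotated PPI network, (ii) detect cohesive clusters in each
subnetwork, (iii) merge highly overlapping clusters — typically multi-localised
variants of the same assembly found in different compartments — into super
modules.  Two modules A and B overlap with score

    omega(A, B) = |A ∩ B|^2 / (|A| · |B|)

which is 1 iff A = B and 0 iff they are disjoint.  Pairs exceeding a threshold
omega_0 (0.5 by default; for near-complete networks 0.75 is recommended) are
connected in an overlap graph, and each connected component becomes one super
module whose member set is the union over its constituents.  Super modules
with best overlap below 0.25 against every baseline (whole-network) module are
classified as novel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
from sklearn.base import BaseEstimator

from .cluster import (
    Cluster,
    GreedyCohesiveClusterer,
    MarkovClusterer,
    filter_by_size,
)
from .io import DEFAULT_COMPARTMENTS
from .network import extract_subnetwork

__all__ = [
    "SubcellularModule",
    "SuperModule",
    "overlap_score",
    "build_overlap_graph",
    "merge_modules",
    "classify_modules",
    "minimum_merge_fraction",
    "SMILE",
    "run_smile",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubcellularModule:
    """A cluster detected within one compartment's subnetwork."""

    members: frozenset[str]
    compartment: str

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SuperModule:
    """Union of one connected component of overlapping subcellular modules."""

    members: frozenset[str]
    constituents: tuple[SubcellularModule, ...]
    compartments: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def overlap_score(a: Iterable[str], b: Iterable[str]) -> float:
    """Overlap score |A∩B|²/(|A|·|B|) between two protein sets.

    Symmetric; 1 iff the sets are identical, 0 iff disjoint.  Undefined
    (raises ``ValueError``) for empty sets.
    """
    set_a, set_b = frozenset(a), frozenset(b)
    if not set_a or not set_b:
        raise ValueError("overlap score is undefined for empty sets")
    inter = len(set_a & set_b)
    return (inter * inter) / (len(set_a) * len(set_b))


def minimum_merge_fraction(omega0: float = 0.5, tol: float = 1e-9) -> float:
    """Smallest shared-member fraction at which two equal-size modules merge.

    For |A| = |B| with shared fraction f the overlap score is f², so the merge
    condition omega(A, B) > omega0 holds from f = sqrt(omega0) upward; the
    default omega0 = 0.5 therefore requires just over 70.7% shared members.
    Computed by bisection on f so the result follows from the score formula
    rather than a closed form.
    """
    if not 0.0 <= omega0 <= 1.0:
        raise ValueError("omega0 must lie in [0, 1]")
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if mid * mid > omega0:
            hi = mid
        else:
            lo = mid
    return hi


def build_overlap_graph(modules: Sequence[SubcellularModule], omega0: float = 0.5) -> nx.Graph:
    """Graph over module indices with an edge where overlap score > *omega0*.

    The comparison is strict: a pair at exactly the threshold is not
    connected.
    """
    if not 0.0 <= omega0 <= 1.0:
        raise ValueError("omega0 must lie in [0, 1]")
    graph = nx.Graph()
    graph.add_nodes_from(range(len(modules)))
    for i in range(len(modules)):
        for j in range(i + 1, len(modules)):
            score = overlap_score(modules[i].members, modules[j].members)
            if score > omega0:
                graph.add_edge(i, j, overlap=score)
    return graph


def merge_modules(
    modules: Sequence[SubcellularModule], omega0: float = 0.5
) -> list[SuperModule]:
    """Merge overlapping subcellular modules into super modules.

    Each connected component of the overlap graph yields one super module
    whose member set is the union over the component, so every input module
    belongs to exactly one super module; modules overlapping nothing pass
    through unchanged as singleton components.
    """
    graph = build_overlap_graph(modules, omega0)
    supers = []
    for component in nx.connected_components(graph):
        constituents = tuple(modules[i] for i in sorted(component))
        members = frozenset().union(*(m.members for m in constituents))
        compartments = frozenset(m.compartment for m in constituents)
        supers.append(SuperModule(members, constituents, compartments))
    supers.sort(key=lambda s: sorted(s.members))
    return supers


def classify_modules(
    super_modules: Sequence[SuperModule],
    global_modules: Sequence[Cluster],
    novelty_threshold: float = 0.25,
) -> tuple[list[str], list[str]]:
    """Label super modules as "novel"/"shared" and baseline modules as
    "global-unique"/"shared".

    A super module is novel iff its best overlap score against every
    whole-network module is strictly below *novelty_threshold* (default 0.25);
    symmetrically a whole-network module is global-unique iff no super module
    reaches the threshold.  With no global modules at all, every super module
    is novel.
    """
    if not 0.0 <= novelty_threshold <= 1.0:
        raise ValueError("novelty_threshold must lie in [0, 1]")
    super_labels = []
    for sm in super_modules:
        best = max(
            (overlap_score(sm.members, gm.members) for gm in global_modules),
            default=0.0,
        )
        super_labels.append("novel" if best < novelty_threshold else "shared")
    global_labels = []
    for gm in global_modules:
        best = max(
            (overlap_score(gm.members, sm.members) for sm in super_modules),
            default=0.0,
        )
        global_labels.append("global-unique" if best < novelty_threshold else "shared")
    return super_labels, global_labels


def _make_backend(method: str, params: dict, source: str):
    if method == "greedy":
        keys = ("penalty", "density_min", "merge_overlap", "weighted")
        kwargs = {k: params[k] for k in keys if k in params}
        kwargs["min_size"] = params.get("seed_min_size", 3)
        return GreedyCohesiveClusterer(source=source, **kwargs)
    if method == "mcl":
        keys = (
            "inflation",
            "expansion",
            "prune_threshold",
            "max_iterations",
            "convergence_tol",
            "weighted",
        )
        return MarkovClusterer(source=source, **{k: params[k] for k in keys if k in params})
    raise ValueError(f"unknown clustering method {method!r}; expected 'greedy' or 'mcl'")


class SMILE(BaseEstimator):
    """Subcellular module identification with localisation expansion.

    Fitting runs the three-step procedure on a localisation-annotated PPI
    network (a :class:`networkx.Graph` as built by
    :func:`smile_ppi.network.build_network`): per-compartment subnetwork
    extraction, backend clustering of each subnetwork with the size filter,
    and the overlap merge.

    Parameters
    ----------
    compartments : sequence of str
        Compartment vocabulary (default: the six ComPPI majors).
    method : {"greedy", "mcl"}
        Clustering backend for the subnetworks.
    omega0 : float, default 0.5
        Merge threshold on the overlap score (strict).
    min_size : int, default 11
        Module size filter applied per subnetwork before merging (the default
        keeps clusters larger than ten).
    loc_threshold : float, default 0.8
        Localisation score a protein must exceed to enter a subnetwork.
    penalty, density_min, merge_overlap, seed_min_size
        Greedy backend parameters (see :class:`GreedyCohesiveClusterer`).
    inflation, expansion
        MCL backend parameters (see :class:`MarkovClusterer`).
    weighted : bool, default True
        Use edge scores as weights in either backend.

    Attributes
    ----------
    subcellular_modules_ : list of SubcellularModule
    super_modules_ : list of SuperModule
    stage_counts_ : dict
        Per-stage bookkeeping: subnetwork sizes, modules per compartment and
        the super-module total.
    """

    def __init__(
        self,
        compartments: Sequence[str] = DEFAULT_COMPARTMENTS,
        method: str = "greedy",
        omega0: float = 0.5,
        min_size: int = 11,
        loc_threshold: float = 0.8,
        penalty: float = 2.0,
        density_min: float = 0.5,
        merge_overlap: float = 0.8,
        seed_min_size: int = 3,
        inflation: float = 2.0,
        expansion: int = 2,
        weighted: bool = True,
    ):
        self.compartments = compartments
        self.method = method
        self.omega0 = omega0
        self.min_size = min_size
        self.loc_threshold = loc_threshold
        self.penalty = penalty
        self.density_min = density_min
        self.merge_overlap = merge_overlap
        self.seed_min_size = seed_min_size
        self.inflation = inflation
        self.expansion = expansion
        self.weighted = weighted

    def fit(self, X: nx.Graph, y=None) -> "SMILE":
        """Run the full procedure on the network *X*."""
        params = self.get_params()
        modules: list[SubcellularModule] = []
        counts: dict = {"compartments": {}, "proteins": X.number_of_nodes(),
                        "edges": X.number_of_edges()}
        for compartment in self.compartments:
            subnetwork = extract_subnetwork(
                X, compartment, self.loc_threshold, vocabulary=self.compartments
            )
            backend = _make_backend(self.method, params, source=compartment)
            clusters = filter_by_size(backend.fit(subnetwork).clusters_, self.min_size)
            modules.extend(SubcellularModule(c.members, compartment) for c in clusters)
            counts["compartments"][compartment] = {
                "proteins": subnetwork.number_of_nodes(),
                "edges": subnetwork.number_of_edges(),
                "modules": len(clusters),
            }
            logger.info(
                "compartment %s: %d proteins, %d edges, %d modules",
                compartment,
                subnetwork.number_of_nodes(),
                subnetwork.number_of_edges(),
                len(clusters),
            )
        self.subcellular_modules_ = modules
        self.super_modules_ = merge_modules(modules, self.omega0) if modules else []
        counts["subcellular_modules"] = len(modules)
        counts["super_modules"] = len(self.super_modules_)
        self.stage_counts_ = counts
        logger.info(
            "%d subcellular modules merged into %d super modules",
            len(modules),
            len(self.super_modules_),
        )
        return self


def run_smile(
    network: nx.Graph,
    compartments: Sequence[str] = DEFAULT_COMPARTMENTS,
    method: str = "greedy",
    omega0: float = 0.5,
    min_size: int = 11,
    loc_threshold: float = 0.8,
    **backend_params,
) -> list[SuperModule]:
    """Functional wrapper over :class:`SMILE`; returns the super modules."""
    estimator = SMILE(
        compartments=compartments,
        method=method,
        omega0=omega0,
        min_size=min_size,
        loc_threshold=loc_threshold,
        **backend_params,
    )
    return estimator.fit(network).super_modules_
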