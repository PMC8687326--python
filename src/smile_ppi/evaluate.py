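"""Quality measures for predicted module sets.

Complex-reference agreement uses the clustering-wise sensitivity (Sn),
positive predictive value (PPV) and their geometric mean Acc, computed from
the match matrix t_ij = |predicted_i ∩ reference_j|.  Biological relevance
uses the one-sided hypergeometric over-representation test per
(module, pathway) pair with Benjamini–Hochberg FDR control, summarised as the
over-representation score (ORS): the fraction of modules significantly
enriched in at least one pathway of a resource.  A composite score sums the
ORS over pathway resources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import sqrt
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .smile import overlap_score

__all__ = [
    "MatchMatrix",
    "EnrichmentResult",
    "QualityReport",
    "match_matrix",
    "sensitivity",
    "ppv",
    "accuracy",
    "hypergeometric_p",
    "bh_adjust",
    "enrich_modules",
    "ors",
    "matched_complex_fraction",
    "quality_report",
]


def _as_sets(modules) -> dict[str, frozenset[str]]:
    """Normalise module input (mapping, or sequence of sets / objects with
    ``members``) to an ordered id -> member-set mapping."""
    if isinstance(modules, Mapping):
        return {str(k): frozenset(v) for k, v in modules.items()}
    out: dict[str, frozenset[str]] = {}
    for i, module in enumerate(modules):
        members = getattr(module, "members", module)
        out[getattr(module, "id", f"M{i:04d}")] = frozenset(members)
    return out


@dataclass
class MatchMatrix:
    """Shared-protein counts between predicted and reference complexes.

    ``t[i, j]`` is the number of proteins in both predicted complex i and
    reference complex j; ``v`` and ``w`` are the predicted and reference
    sizes.
    """

    t: np.ndarray
    v: np.ndarray
    w: np.ndarray
    predicted_ids: tuple[str, ...] = ()
    reference_ids: tuple[str, ...] = ()

    @property
    def r(self) -> int:
        return self.t.shape[0]

    @property
    def s(self) -> int:
        return self.t.shape[1]


def match_matrix(predicted, reference: GeneSetCollection | Mapping) -> MatchMatrix:
    """Build the match matrix between predicted modules and reference sets."""
    pred = _as_sets(predicted)
    ref = reference.sets if isinstance(reference, GeneSetCollection) else dict(reference)
    if not pred or not ref:
        raise ValueError("match_matrix needs non-empty predicted and reference sets")
    pred_ids, ref_ids = tuple(pred), tuple(ref)
    t = np.zeros((len(pred_ids), len(ref_ids)), dtype=int)
    for i, pid in enumerate(pred_ids):
        for j, rid in enumerate(ref_ids):
            t[i, j] = len(pred[pid] & frozenset(ref[rid]))
    v = np.array([len(pred[pid]) for pid in pred_ids])
    w = np.array([len(ref[rid]) for rid in ref_ids])
    return MatchMatrix(t, v, w, pred_ids, ref_ids)


def sensitivity(m: MatchMatrix) -> float:
    """Sn = Σ_j max_i t_ij / Σ_j w_j: the fraction of reference-complex
    membership covered by each complex's best-matching prediction."""
    total = int(m.w.sum())
    if total == 0:
        raise ValueError("sensitivity undefined: all reference complexes are empty")
    return float(m.t.max(axis=0).sum()) / total


def ppv(m: MatchMatrix) -> float:
    """PPV = Σ_i max_j t_ij / Σ_i Σ_j t_ij: how concentrated each prediction's
    reference hits are on its best-matching complex.  Returns 0 with a warning
    when no predicted protein hits any reference."""
    denominator = int(m.t.sum())
    if denominator == 0:
        warnings.warn("PPV denominator is 0 (no predicted/reference overlap); returning 0",
                      stacklevel=2)
        return 0.0
    return float(m.t.max(axis=1).sum()) / denominator


def accuracy(sn: float, ppv_value: float) -> float:
    """Acc, the geometric mean sqrt(Sn * PPV)."""
    for name, value in (("sn", sn), ("ppv", ppv_value)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return sqrt(sn * ppv_value)


def hypergeometric_p(N: int, n: int, T: int, t: int) -> float:
    """P(X >= t) for X hypergeometric: n draws from N proteins of which T are
    annotated.  Computed through the survival function for numerical
    stability; t = 0 gives exactly 1."""
    if not (0 <= t <= n <= N and 0 <= T <= N):
        raise ValueError(f"invalid hypergeometric configuration N={N}, n={n}, T={T}, t={t}")
    if t > min(n, T):
        raise ValueError(f"overlap t={t} exceeds min(n={n}, T={T})")
    if t == 0:
        return 1.0
    return float(hypergeom.sf(t - 1, N, T, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving and
    clipped to 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


@dataclass(frozen=True)
class EnrichmentResult:
    """One module x pathway over-representation test."""

    module_id: str
    pathway_id: str
    overlap: int
    p: float
    p_adjusted: float
    significant: bool


def enrich_modules(
    modules,
    pathways: GeneSetCollection,
    background,
    cutoff: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of every module in every pathway.

    *background* is the statistical universe: either the total protein count N
    of the analysed network, or the explicit protein set (then N is its size,
    module members outside it are dropped with a warning, and pathways are
    restricted to it).  BH adjustment runs across all module x pathway pairs
    of this one resource; a pair is significant when the adjusted p-value is
    below *cutoff*.
    """
    module_sets = _as_sets(modules)
    universe: frozenset[str] | None
    if isinstance(background, (int, np.integer)):
        N, universe = int(background), None
    else:
        universe = frozenset(background)
        N = len(universe)
    pathway_sets = {
        name: (members & universe if universe is not None else members)
        for name, members in pathways.sets.items()
    }
    pathway_sets = {name: m for name, m in pathway_sets.items() if m}

    rows: list[tuple[str, str, int, float]] = []
    for module_id, members in module_sets.items():
        if universe is not None and not members <= universe:
            dropped = members - universe
            warnings.warn(
                f"module {module_id}: {len(dropped)} member(s) outside the background "
                "universe dropped for the test",
                stacklevel=2,
            )
            members = members & universe
        n = len(members)
        if n > N:
            raise ValueError(f"module {module_id} larger than background N={N}")
        for pathway_id, pathway in pathway_sets.items():
            T = len(pathway)
            if T > N:
                raise ValueError(f"pathway {pathway_id} larger than background N={N}")
            t = len(members & pathway)
            p = hypergeometric_p(N, n, T, t) if n else 1.0
            rows.append((module_id, pathway_id, t, p))
    adjusted = bh_adjust([row[3] for row in rows])
    return [
        EnrichmentResult(mid, pid, t, p, p_adj, p_adj < cutoff)
        for (mid, pid, t, p), p_adj in zip(rows, adjusted)
    ]


def ors(enrichments: Sequence[EnrichmentResult], module_count: int) -> float:
    """Over-representation score: the fraction of the *module_count* modules
    with at least one significantly enriched pathway."""
    if module_count < 1:
        raise ValueError("module_count must be >= 1")
    meaningful = {e.module_id for e in enrichments if e.significant}
    return len(meaningful) / module_count


def matched_complex_fraction(
    modules,
    reference: GeneSetCollection | Mapping,
    match_threshold: float = 0.25,
) -> tuple[int, float]:
    """Count and fraction of modules whose best overlap score against the
    reference sets reaches *match_threshold*."""
    module_sets = _as_sets(modules)
    if not module_sets:
        raise ValueError("matched_complex_fraction needs at least one module")
    if not 0.0 <= match_threshold <= 1.0:
        raise ValueError("match_threshold must lie in [0, 1]")
    ref = reference.sets if isinstance(reference, GeneSetCollection) else dict(reference)
    count = 0
    for members in module_sets.values():
        best = max((overlap_score(members, r) for r in ref.values() if r), default=0.0)
        if best >= match_threshold:
            count += 1
    return count, count / len(module_sets)


@dataclass
class QualityReport:
    """Complex-reference agreement plus pathway over-representation summary."""

    sn: float
    ppv: float
    acc: float
    ors_by_resource: dict[str, float] = field(default_factory=dict)
    composite: float = 0.0
    matched_count: int = 0
    matched_fraction: float = 0.0

    def as_dict(self) -> dict:
        return {
            "Sn": self.sn,
            "PPV": self.ppv,
            "Acc": self.acc,
            "ORS": dict(self.ors_by_resource),
            "composite": self.composite,
            "matched_count": self.matched_count,
            "matched_fraction": self.matched_fraction,
        }


def quality_report(
    modules,
    complexes: GeneSetCollection,
    pathway_resources: Mapping[str, GeneSetCollection] | None = None,
    background=None,
    cutoff: float = 0.05,
    match_threshold: float = 0.25,
) -> QualityReport:
    """Full evaluation of a module set: Sn/PPV/Acc and matched fraction
    against reference complexes, plus per-resource ORS (composite = their sum)
    when pathway resources and a background are given."""
    module_sets = _as_sets(modules)
    m = match_matrix(module_sets, complexes)
    sn = sensitivity(m)
    ppv_value = ppv(m)
    report = QualityReport(sn=sn, ppv=ppv_value, acc=accuracy(sn, ppv_value))
    report.matched_count, report.matched_fraction = matched_complex_fraction(
        module_sets, complexes, match_threshold
    )
    if pathway_resources:
        if background is None:
            background = frozenset().union(*module_sets.values())
        for name, resource in pathway_resources.items():
            enrichments = enrich_modules(module_sets, resource, background, cutoff)
            report.ors_by_resource[name] = ors(enrichments, len(module_sets))
        report.composite = float(sum(report.ors_by_resource.values()))
    return report
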