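"""Readers and writers for the plain-text formats the pipeline touches.

Interactions and localisations arrive as three-column TSV files; reference
complexes and pathway resources arrive in GMT.  The confidence filters that
define the analysed network (interaction score >= 0.8 kept, localisation
score > 0.8 kept, complexes with >= 5 members kept) are applied at load time
so that everything downstream sees only the filtered records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DEFAULT_COMPARTMENTS",
    "ParseError",
    "InteractionRecord",
    "LocalisationRecord",
    "GeneSetCollection",
    "Module",
    "read_interactions",
    "read_localisations",
    "read_gmt",
    "write_modules",
    "read_modules",
]

#: The six major compartments of ComPPI-style localisation data.  The
#: "secretory-pathway" label pools Golgi, ER, endosome, peroxisome, lysosome,
#: vacuole and vesicles.
DEFAULT_COMPARTMENTS: tuple[str, ...] = (
    "nucleus",
    "cytosol",
    "mitochondrion",
    "secretory-pathway",
    "membrane",
    "extracellular",
)


class ParseError(ValueError):
    """Raised for a malformed line; carries the 1-based line number."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True)
class InteractionRecord:
    """An undirected, score-annotated protein pair.

    The pair is unordered: ``(a, b)`` and ``(b, a)`` denote the same
    interaction, and readers collapse duplicates keeping the maximum score.
    """

    protein_a: str
    protein_b: str
    score: float

    @property
    def key(self) -> tuple[str, str]:
        """Canonical (sorted) endpoint pair."""
        a, b = self.protein_a, self.protein_b
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class LocalisationRecord:
    """A protein's confidence of residing in one compartment."""

    protein: str
    compartment: str
    score: float


@dataclass
class GeneSetCollection:
    """A named collection of gene/protein sets (one GMT file)."""

    name: str
    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass(frozen=True)
class Module:
    """On-disk form of a module: id, provenance labels, member set."""

    id: str
    provenance: tuple[str, ...]
    members: frozenset[str]


def _check_score_arg(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def _parse_score(path, lineno: int, text: str) -> float:
    try:
        score = float(text)
    except ValueError:
        raise ParseError(path, lineno, f"non-numeric score {text!r}") from None
    if not 0.0 <= score <= 1.0:
        raise ParseError(path, lineno, f"score {score} outside [0, 1]")
    return score


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_interactions(path: str | Path, min_score: float = 0.8) -> list[InteractionRecord]:
    """Read a weighted edge list, keeping interactions with score >= *min_score*.

    Self-loops are dropped and duplicate unordered pairs are collapsed to the
    record with the maximum score.  Interactions below 0.8 are considered
    biologically unlikely under the default threshold.
    """
    _check_score_arg("min_score", min_score)
    best: dict[tuple[str, str], float] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected >=3 tab-separated columns, got {len(fields)}")
        a, b = fields[0].strip(), fields[1].strip()
        score = _parse_score(path, lineno, fields[2].strip())
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        if score > best.get(key, -1.0):
            best[key] = score
    records = [
        InteractionRecord(a, b, s) for (a, b), s in sorted(best.items()) if s >= min_score
    ]
    if not records:
        warnings.warn(f"no interactions with score >= {min_score} in {path}", stacklevel=2)
    return records


def read_localisations(
    path: str | Path,
    min_score: float = 0.8,
    compartments: Sequence[str] | None = DEFAULT_COMPARTMENTS,
) -> list[LocalisationRecord]:
    """Read a protein localisation table, keeping scores strictly > *min_score*.

    Duplicate (protein, compartment) rows collapse to the maximum score.  When
    a compartment vocabulary is configured (the default is the six ComPPI
    majors), unknown labels are rejected; pass ``compartments=None`` to accept
    arbitrary labels.
    """
    _check_score_arg("min_score", min_score)
    vocabulary = set(compartments) if compartments is not None else None
    best: dict[tuple[str, str], float] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected >=3 tab-separated columns, got {len(fields)}")
        protein, compartment = fields[0].strip(), fields[1].strip()
        score = _parse_score(path, lineno, fields[2].strip())
        if vocabulary is not None and compartment not in vocabulary:
            raise ParseError(
                path, lineno,
                f"unknown compartment {compartment!r}; expected one of {sorted(vocabulary)}",
            )
        key = (protein, compartment)
        if score > best.get(key, -1.0):
            best[key] = score
    return [
        LocalisationRecord(p, c, s) for (p, c), s in sorted(best.items()) if s > min_score
    ]


def read_gmt(path: str | Path, min_size: int = 5) -> GeneSetCollection:
    """Read a GMT file, dropping sets with fewer than *min_size* members.

    GMT lines are ``name TAB description TAB member TAB member ...``.  Members
    are de-duplicated; the default size filter keeps complexes with five or
    more members.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    sets: dict[str, frozenset[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, f"GMT line needs >=3 fields, got {len(fields)}")
        name = fields[0].strip()
        if name in sets:
            raise ParseError(path, lineno, f"duplicate gene-set name {name!r}")
        members = frozenset(m.strip() for m in fields[2:] if m.strip())
        if not members:
            raise ParseError(path, lineno, f"gene set {name!r} has no members")
        if len(members) >= min_size:
            sets[name] = members
    return GeneSetCollection(name=Path(path).stem, sets=sets)


def write_modules(modules: Sequence[Module], path: str | Path) -> None:
    """Write modules as ``id TAB provenance TAB member TAB member ...``.

    Provenance labels are comma-joined; members are emitted sorted so that
    identical module sets always produce byte-identical files.
    """
    if modules is None:
        raise ValueError("modules must not be None")
    with open(path, "w") as handle:
        handle.write("#module_id\tprovenance\tmembers...\n")
        for module in modules:
            fields = [module.id, ",".join(module.provenance), *sorted(module.members)]
            handle.write("\t".join(fields) + "\n")


def read_modules(path: str | Path) -> list[Module]:
    """Read modules written by :func:`write_modules`."""
    modules: list[Module] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, f"module line needs >=3 fields, got {len(fields)}")
        provenance = tuple(p for p in fields[1].split(",") if p)
        modules.append(Module(fields[0], provenance, frozenset(fields[2:])))
    return modules
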