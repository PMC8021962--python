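"""Ontology-based neuroanatomy of the developing mouse CNS.

The developing mouse brain reference atlas organises the CNS into a forest of
named structures across thirteen ontological levels: transverse neuromeric
segments (prosomeres, mesomeres, rhombomeres) at level 3, the longitudinal
roof/alar/basal/floor plates at level 5, subpallial strata and nuclei at
levels 8-12, and cortical (area, layer) units in the adult. Every expression
and adhesion computation in this package is indexed by these structures.

The anterior-posterior rank of a transverse segment (``ap_index``) is a
convention of the prosomeric model (rostral secondary prosencephalon first,
rhombomere r11 last) and is therefore stored explicitly rather than inferred
from the graph.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import (
    CycleError,
    DanglingParentError,
    DuplicateAcronymError,
    OntologyParseError,
    UnknownVocabularyError,
)

#: The seven developmental stages covered by the atlas.
AGE_STAGES: tuple[str, ...] = ("E11.5", "E13.5", "E15.5", "E18.5", "P4", "P14", "P56")

PLATES: frozenset[str] = frozenset({"roof", "alar", "basal", "floor", "none"})
STRATA: frozenset[str] = frozenset(
    {"ventricular", "periventricular", "intermediate", "superficial", "none"}
)
#: Topological divisions of the subpallium (free vocabulary; "none" elsewhere).
DIVISIONS: frozenset[str] = frozenset(
    {"septal", "paraseptal", "central", "amygdaloid", "none"}
)

_STRUCTURE_FIELDS = (
    "id",
    "acronym",
    "name",
    "level",
    "parent_id",
    "ap_index",
    "plate",
    "stratum",
    "division",
    "area",
    "layer",
)


@dataclass(frozen=True)
class Structure:
    """One named structure of the reference atlas.

    Parameters
    ----------
    id : str
        Opaque identifier, unique across the graph.
    acronym : str
        Short label used in figures (e.g. ``"r4"``, ``"Put"``); unique within
        an ontological level.
    name : str
        Full anatomical name.
    level : int
        Ontological level, 1-13.
    parent_id : str
        Identifier of the parent structure; empty string for roots.
    ap_index : int or None
        Anterior-posterior rank (lower = more anterior); only meaningful for
        transverse segments and their plate subdivisions.
    plate : str
        Longitudinal plate membership, one of :data:`PLATES`.
    stratum : str
        Radial stratum membership, one of :data:`STRATA`.
    division : str
        Subpallial topological division label ("none" elsewhere).
    area, layer : str, int or None
        Cortical area acronym and layer number for adult isocortex units
        modelled as (area, layer) pairs; ``None``/"none" elsewhere.
    """

    id: str
    acronym: str
    name: str
    level: int
    parent_id: str = ""
    ap_index: int | None = None
    plate: str = "none"
    stratum: str = "none"
    division: str = "none"
    area: str = "none"
    layer: int | None = None

    def __post_init__(self) -> None:
        if self.level < 1:
            raise OntologyParseError(f"structure {self.id!r}: level must be >= 1")
        if self.plate not in PLATES:
            raise UnknownVocabularyError(
                f"structure {self.id!r}: unknown plate {self.plate!r}"
            )
        if self.stratum not in STRATA:
            raise UnknownVocabularyError(
                f"structure {self.id!r}: unknown stratum {self.stratum!r}"
            )


class StructureGraph:
    """A validated forest of :class:`Structure` records.

    Validation enforces: no cycles in the parent relation, no dangling
    ``parent_id``, ``parent.level < child.level``, and acronym uniqueness
    within each level.
    """

    age_stages: tuple[str, ...] = AGE_STAGES

    def __init__(self, structures: Iterable[Structure]):
        self._by_id: dict[str, Structure] = {}
        for s in structures:
            if s.id in self._by_id:
                raise OntologyParseError(f"duplicate structure id {s.id!r}")
            self._by_id[s.id] = s
        self._validate()

    def _validate(self) -> None:
        seen: dict[tuple[int, str], str] = {}
        for s in self._by_id.values():
            key = (s.level, s.acronym)
            if key in seen:
                raise DuplicateAcronymError(
                    f"acronym {s.acronym!r} duplicated at level {s.level} "
                    f"(ids {seen[key]!r}, {s.id!r})"
                )
            seen[key] = s.id
            if s.parent_id:
                parent = self._by_id.get(s.parent_id)
                if parent is None:
                    raise DanglingParentError(
                        f"structure {s.id!r} references missing parent "
                        f"{s.parent_id!r}"
                    )
                if not parent.level < s.level:
                    raise OntologyParseError(
                        f"structure {s.id!r} (level {s.level}) has parent "
                        f"{parent.id!r} at level {parent.level}"
                    )
        # cycle check: follow parents from every node; parent.level < level
        # already rules out cycles among validated edges, but self-parenting
        # and mutually-parenting malformed records must raise CycleError
        # before the level check can be trusted, so walk explicitly.
        for s in self._by_id.values():
            slow = s.id
            visited = {slow}
            cur = s
            while cur.parent_id:
                if cur.parent_id in visited:
                    raise CycleError(
                        f"cycle in parent relation at structure {cur.id!r}"
                    )
                visited.add(cur.parent_id)
                nxt = self._by_id.get(cur.parent_id)
                if nxt is None:  # pragma: no cover - caught above
                    raise DanglingParentError(cur.parent_id)
                cur = nxt

    # -- access --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def __contains__(self, structure_id: str) -> bool:
        return structure_id in self._by_id

    def __getitem__(self, structure_id: str) -> Structure:
        return self._by_id[structure_id]

    def get(self, structure_id: str) -> Structure | None:
        return self._by_id.get(structure_id)

    def by_acronym(self, acronym: str, level: int | None = None) -> Structure:
        """Look up a structure by acronym (optionally restricted to a level)."""
        hits = [
            s
            for s in self._by_id.values()
            if s.acronym == acronym and (level is None or s.level == level)
        ]
        if not hits:
            raise KeyError(acronym)
        if len(hits) > 1:
            raise KeyError(
                f"acronym {acronym!r} is ambiguous across levels "
                f"{sorted(s.level for s in hits)}; pass level="
            )
        return hits[0]

    def segments_at_level(self, level: int) -> list[Structure]:
        """Structures of one ontological level in anterior-posterior order.

        Ordered by ``ap_index`` ascending (anterior first); structures
        without an ``ap_index`` sort after those with one; ties broken by
        acronym for a stable, deterministic ordering. An absent level yields
        an empty list.
        """
        members = [s for s in self._by_id.values() if s.level == level]
        return sorted(
            members,
            key=lambda s: (s.ap_index is None, s.ap_index or 0, s.acronym),
        )

    def select(
        self,
        plate: str | None = None,
        stratum: str | None = None,
        division: str | None = None,
        level: int | None = None,
        area: str | None = None,
        layer: int | None = None,
    ) -> list[Structure]:
        """All and only the structures matching every supplied filter.

        Filter values must come from the enumerated vocabularies
        (:data:`PLATES`, :data:`STRATA`); an unknown value raises
        :class:`~cadhesion.errors.UnknownVocabularyError`. No filters
        returns every structure.
        """
        if plate is not None and plate not in PLATES:
            raise UnknownVocabularyError(f"unknown plate {plate!r}")
        if stratum is not None and stratum not in STRATA:
            raise UnknownVocabularyError(f"unknown stratum {stratum!r}")
        out = []
        for s in sorted(self._by_id.values(), key=lambda s: (s.level, s.acronym)):
            if plate is not None and s.plate != plate:
                continue
            if stratum is not None and s.stratum != stratum:
                continue
            if division is not None and s.division != division:
                continue
            if level is not None and s.level != level:
                continue
            if area is not None and s.area != area:
                continue
            if layer is not None and s.layer != layer:
                continue
            out.append(s)
        return out

    def cortical_units(self) -> list[Structure]:
        """Adult isocortex (area, layer) units, area-major then layer order."""
        units = [s for s in self._by_id.values() if s.area != "none"]
        return sorted(units, key=lambda s: (s.area, s.layer or 0))

    def subpallial_nuclei(self) -> list[Structure]:
        """Named subpallial nuclei (levels 11-12, non-"none" stratum)."""
        nuclei = [
            s
            for s in self._by_id.values()
            if s.level >= 11 and s.stratum != "none" and s.area == "none"
        ]
        return sorted(nuclei, key=lambda s: (s.level, s.stratum, s.acronym))


# -- I/O ----------------------------------------------------------------------


def _structure_from_obj(obj: dict, where: str) -> Structure:
    if not isinstance(obj, dict):
        raise OntologyParseError(f"{where}: expected an object, got {type(obj).__name__}")
    unknown = set(obj) - set(_STRUCTURE_FIELDS)
    if unknown:
        raise OntologyParseError(f"{where}: unknown fields {sorted(unknown)}")
    try:
        kwargs = dict(obj)
        kwargs["level"] = int(kwargs["level"])
        if kwargs.get("ap_index") is not None:
            kwargs["ap_index"] = int(kwargs["ap_index"])
        if kwargs.get("layer") is not None:
            kwargs["layer"] = int(kwargs["layer"])
        return Structure(**kwargs)
    except (KeyError, TypeError, ValueError) as exc:
        raise OntologyParseError(f"{where}: {exc}") from exc


def load_ontology(path: str | Path) -> StructureGraph:
    """Load and validate a structure graph from its JSON file.

    The file holds a list of structure objects (field names as in
    :class:`Structure`); ids are strings, ``parent_id`` empty for roots.
    Raises a distinct named error for parse failures, cycles, duplicate
    acronyms within a level and dangling parent references.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise OntologyParseError(f"cannot parse ontology file {path}: {exc}") from exc
    if isinstance(payload, dict):  # allow {"structures": [...]} wrapping
        payload = payload.get("structures", None)
    if not isinstance(payload, list):
        raise OntologyParseError(f"{path}: expected a JSON list of structures")
    structures = [
        _structure_from_obj(obj, f"{path} entry {i}") for i, obj in enumerate(payload)
    ]
    return StructureGraph(structures)


def write_ontology(graph: StructureGraph, path: str | Path) -> None:
    """Write a graph back to the JSON interchange format (round-trip safe)."""
    rows = [asdict(s) for s in sorted(graph, key=lambda s: (s.level, s.acronym))]
    Path(path).write_text(
        json.dumps(rows, indent=1, ensure_ascii=False) + "\n", encoding="utf-8"
    )


def write_ontology_csv(graph: StructureGraph, path: str | Path) -> None:
    """Companion CSV export, one row per structure, identical columns."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_STRUCTURE_FIELDS)
        writer.writeheader()
        for s in sorted(graph, key=lambda s: (s.level, s.acronym)):
            writer.writerow(asdict(s))


def load_packaged_ontology() -> StructureGraph:
    """The packaged developing-mouse fixture.

    Covers the levels the analyses index: the 19 level-3 transverse
    segments RSP...r11, the level-2 regions, level-5 alar/basal plate
    subdivisions of each segment, the adult isocortex as 9 areas x 6
    layers, and the named subpallial nuclei grouped by stratum.
    """
    ref = resources.files("cadhesion.data").joinpath("ontology_devmouse.json")
    with resources.as_file(ref) as path:
        return load_ontology(path)


def segments_at_level(graph: StructureGraph, level: int) -> list[Structure]:
    """Functional alias for :meth:`StructureGraph.segments_at_level`."""
    return graph.segments_at_level(level)


def select_structures(graph: StructureGraph, **filters) -> list[Structure]:
    """Functional alias for :meth:`StructureGraph.select`."""
    return graph.select(**filters)
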