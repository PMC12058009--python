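"""Cell-type taxonomy for peripheral blood smear (PBS) object detection.

The taxonomy covers 29 object classes routinely annotated on digitized
smears: 10 white-blood-cell (WBC) subtypes, 16 red-blood-cell (RBC)
morphologies (including the nucleated normoblast), platelets, platelet
clumps, and staining/debris artifacts.

Each class carries a *negative cluster*: the set of morphologically
confusable classes used as the negative population when computing
true negatives and specificity for that class.  Restricting negatives to
the confusable cluster (rather than every other object on the slide)
makes specificity a statement about the clinically relevant
discriminations — e.g. a basophil detector is judged against lymphocytes
and neutrophils, the cells it is actually at risk of being confused with.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator


@dataclass(frozen=True)
class CellClass:
    """One cell type: canonical name, broad group, and its negative cluster."""

    name: str
    group: str  # one of {"WBC", "RBC", "PLT", "ARTIFACT"}
    negative_cluster: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.group not in {"WBC", "RBC", "PLT", "ARTIFACT"}:
            raise ValueError(f"unknown group {self.group!r} for class {self.name!r}")


def _norm(name: str) -> str:
    """Normalization key: case/space/punctuation-insensitive."""
    return re.sub(r"[^a-z0-9]", "", name.lower())


# Canonical class list, in the canonical row order that also defines the
# integer class indices of the YOLO text dialect.
_CLASS_DEFS: list[tuple[str, str, tuple[str, ...]]] = [
    ("Basophil", "WBC", ("Lymphocyte", "Neutrophil")),
    ("Neutrophil", "WBC", ("Eosinophil", "Monocyte", "Lymphocyte", "Basophil")),
    ("Lymphocyte", "WBC", ("Neutrophil", "Monocyte", "Basophil", "Eosinophil",
                           "Lymphoblast", "Reactive lymphocyte", "Myeloblast")),
    ("Monocyte", "WBC", ("Lymphoblast", "Reactive lymphocyte", "Lymphocyte")),
    ("Eosinophil", "WBC", ("Neutrophil", "Band neutrophil", "Hypersegmented neutrophil")),
    ("Hypersegmented neutrophil", "WBC", ("Neutrophil", "Band neutrophil", "Eosinophil")),
    ("Band neutrophil", "WBC", ("Neutrophil", "Hypersegmented neutrophil", "Eosinophil")),
    ("Myeloblast", "WBC", ("Lymphocyte", "Lymphoblast", "Monocyte")),
    ("Lymphoblast", "WBC", ("Reactive lymphocyte", "Lymphocyte", "Myeloblast", "Monocyte")),
    ("Reactive lymphocyte", "WBC", ("Lymphoblast", "Lymphocyte", "Myeloblast", "Monocyte")),
    ("Pencil cell", "RBC", ("Sickle cell", "Elliptocyte")),
    ("Stomatocyte", "RBC", ("Elliptocyte",)),
    ("Microcytic RBC", "RBC", ("Spherocyte", "Macrocytic RBC", "Hypochromic RBC")),
    ("Macrocytic RBC", "RBC", ("Reticulocyte", "Microcytic RBC", "Hypochromic RBC")),
    ("Schistocyte", "RBC", ("Bite cell",)),
    ("Bite cell", "RBC", ("Spherocyte", "Schistocyte")),
    ("Spherocyte", "RBC", ("Macrocytic RBC", "Bite cell")),
    ("Teardrop cell", "RBC", ("Elliptocyte",)),
    ("Target cell", "RBC", ("Stomatocyte", "Knizocyte")),
    ("Knizocyte", "RBC", ("Target cell",)),
    ("Elliptocyte", "RBC", ("Teardrop cell", "Stomatocyte")),
    ("Reticulocyte", "RBC", ("Spherocyte", "Macrocytic RBC")),
    ("Hypochromic RBC", "RBC", ("Spherocyte",)),
    ("Echinocyte", "RBC", ("Spherocyte", "Macrocytic RBC", "Microcytic RBC")),
    ("Sickle cell", "RBC", ("Bite cell",)),
    ("Platelets", "PLT", ("Artifact", "Platelet clump")),
    ("Platelet clump", "PLT", ("Platelets", "Artifact")),
    ("Normoblast", "RBC", ("Lymphocyte", "Reactive lymphocyte", "Myeloblast", "Lymphoblast")),
    ("Artifact", "ARTIFACT", ("Platelets", "Platelet clump")),
]

# Spelling variants seen across annotation sources.
_EXTRA_ALIASES: dict[str, str] = {
    "artifacts": "Artifact",
    "platelet": "Platelets",
    "plateletsclump": "Platelet clump",
    "neutrophilband": "Band neutrophil",
    "bandneutrophil": "Band neutrophil",
    "reactivelymphocyte": "Reactive lymphocyte",
    "teardrop": "Teardrop cell",
    "hypersegmentedneutrophil": "Hypersegmented neutrophil",
    "microcyticrbc": "Microcytic RBC",
    "macrocyticrbc": "Macrocytic RBC",
    "hypochromicrbc": "Hypochromic RBC",
}


@dataclass(frozen=True)
class Taxonomy:
    """Ordered collection of :class:`CellClass` with alias resolution.

    Class order is significant: it defines the integer indices used by the
    YOLO-style annotation dialect.
    """

    classes: tuple[CellClass, ...]
    _by_key: dict[str, CellClass] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        by_key: dict[str, CellClass] = {}
        for c in self.classes:
            by_key[_norm(c.name)] = c
        for alias, target in _EXTRA_ALIASES.items():
            if _norm(target) in by_key:
                by_key.setdefault(alias, by_key[_norm(target)])
        object.__setattr__(self, "_by_key", by_key)
        for c in self.classes:
            for neg in c.negative_cluster:
                resolved = self.resolve(neg)
                if resolved == c.name:
                    raise ValueError(f"negative cluster of {c.name!r} includes itself")

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self) -> Iterator[CellClass]:
        return iter(self.classes)

    def __contains__(self, name: str) -> bool:
        return _norm(name) in self._by_key

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.classes)

    def resolve(self, name: str) -> str:
        """Map any recognized spelling to the canonical class name."""
        key = _norm(name)
        if key not in self._by_key:
            raise KeyError(f"unknown cell class {name!r}")
        return self._by_key[key].name

    def get(self, name: str) -> CellClass:
        key = _norm(name)
        if key not in self._by_key:
            raise KeyError(f"unknown cell class {name!r}")
        return self._by_key[key]

    def index_of(self, name: str) -> int:
        canonical = self.resolve(name)
        return self.names.index(canonical)

    def class_at(self, index: int) -> CellClass:
        if not 0 <= index < len(self.classes):
            raise IndexError(f"class index {index} out of range 0..{len(self.classes) - 1}")
        return self.classes[index]


def default_taxonomy() -> Taxonomy:
    """The 29-class PBS taxonomy with its negative clusters."""
    return Taxonomy(tuple(CellClass(n, g, negs) for n, g, negs in _CLASS_DEFS))


DEFAULT_TAXONOMY = default_taxonomy()
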