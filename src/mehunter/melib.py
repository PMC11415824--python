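"""Mobile-element template library: loading, validation, sequence utilities.

Templates are plain FASTA records whose class (Alu, L1, SVA) is derived from
the header by a case-insensitive prefix rule, overridable with an explicit
name->class mapping.  A small built-in synthetic library (one template per
class, 300/600/900 bp) supports tests and simulations without any external
repeat database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ME_CLASSES = ("Alu", "L1", "SVA")

_DNA = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")

#: header prefixes mapped to classes, checked case-insensitively and in order
_PREFIX_RULES = (
    ("ALU", "Alu"),
    ("L1", "L1"),
    ("LINE1", "L1"),
    ("LINE-1", "L1"),
    ("SVA", "SVA"),
)


class LibraryError(ValueError):
    """Raised for malformed or unusable template libraries."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}.

    N maps to N; any other character raises ``ValueError``.
    """
    if not set(seq) <= _DNA:
        bad = sorted(set(seq) - _DNA)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return seq.translate(_COMP)[::-1]


def class_from_header(name: str) -> Optional[str]:
    """Infer the ME class from a FASTA header by the prefix rule, or None."""
    upper = name.upper()
    for prefix, cls in _PREFIX_RULES:
        if upper.startswith(prefix):
            return cls
    return None


@dataclass(frozen=True)
class METemplate:
    """One mobile-element consensus sequence."""

    name: str
    me_class: str
    sequence: str

    def __post_init__(self) -> None:
        if self.me_class not in ME_CLASSES:
            raise LibraryError(f"unknown ME class {self.me_class!r}")
        if not self.sequence:
            raise LibraryError(f"template {self.name!r} has empty sequence")
        if not set(self.sequence) <= _DNA:
            bad = sorted(set(self.sequence) - _DNA)
            raise LibraryError(f"template {self.name!r} has non-ACGTN characters: {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MELibrary:
    """Ordered collection of templates with unique names."""

    templates: list[METemplate] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [t.name for t in self.templates]
        if len(names) != len(set(names)):
            raise LibraryError("template names are not unique")

    @property
    def classes_present(self) -> set[str]:
        return {t.me_class for t in self.templates}

    def by_class(self, me_class: str) -> list[METemplate]:
        return [t for t in self.templates if t.me_class == me_class]

    def __iter__(self):
        return iter(self.templates)

    def __len__(self) -> int:
        return len(self.templates)

    def require_classes(self, classes: Iterable[str]) -> None:
        missing = set(classes) - self.classes_present
        if missing:
            raise LibraryError(f"library has no template for classes: {sorted(missing)}")


def load_templates(
    fasta_path: str | Path,
    class_map: Optional[Mapping[str, str]] = None,
) -> MELibrary:
    """Load an ME template library from FASTA.

    Parameters
    ----------
    fasta_path
        Path to a FASTA file, one record per template.
    class_map
        Optional explicit header->class mapping consulted before the
        prefix rule.

    Raises
    ------
    LibraryError
        If the file is empty, a sequence contains non-ACGTN characters, or a
        header matches neither ``class_map`` nor the prefix rule.
    """
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise LibraryError(f"empty library: no FASTA records in {fasta_path}")
    templates = []
    for rec in records:
        cls = None
        if class_map and rec.id in class_map:
            cls = class_map[rec.id]
        if cls is None:
            cls = class_from_header(rec.id)
        if cls is None:
            raise LibraryError(
                f"unclassifiable template {rec.id!r}: header matches no class rule "
                "and no class_map entry was given"
            )
        templates.append(METemplate(rec.id, cls, str(rec.seq).upper()))
    return MELibrary(templates)


def write_fasta(library: MELibrary, out_path: str | Path) -> None:
    """Serialize a library back to FASTA (wrapped at 60 columns)."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.name, description="") for t in library
    ]
    with open(out_path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


_BUILTIN_SEED = 170224
_BUILTIN_SPECS = (("AluY_sim", "Alu", 300), ("L1HS_sim", "L1", 600), ("SVA_E_sim", "SVA", 900))


def builtin_library() -> MELibrary:
    """The bundled toy library: one synthetic template per class.

    Sequences are i.i.d. uniform DNA generated from a fixed seed, so the
    library is identical in every session without shipping data files.
    """
    rng = np.random.default_rng(_BUILTIN_SEED)
    templates = []
    for name, cls, length in _BUILTIN_SPECS:
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
        templates.append(METemplate(name, cls, seq))
    return MELibrary(templates)


def resolve_library(spec: str, class_map: Optional[Mapping[str, str]] = None) -> MELibrary:
    """Resolve a ``me_library`` config value: ``builtin`` or a FASTA path."""
    if spec == "builtin":
        return builtin_library()
    return load_templates(spec, class_map=class_map)
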