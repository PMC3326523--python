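"""Histone sequences, the PTM mark grammar, and peptide-window extraction.

Numbering convention
--------------------
All residue positions are 1-based on the *mature* chain, i.e. position 1 is
the first residue after cleavage of the initiator methionine.  This is the
convention that makes the community mark names ``H3K4``, ``H3K14``, ``H4K5``
etc. point at actual lysines.  Note that linker-histone (H1) marks are
traditionally numbered counting the initiator Met, so literature H1.4
positions are shifted by one relative to this module (see docs/methods.md).

Mark-string grammar
-------------------
::

    label     := histone [ "(" start "-" end ")" ] mark*
    mark      := residue position modifier        e.g. "K14ac", "S10ph"
               | "p" residue position             e.g. "pS10", "pT3"
    modifier  := "ac" | "me3" | "ph"

Acetylation and trimethylation are only valid on lysine, phosphorylation
only on serine/threonine.  When the window bounds are omitted the window
defaults to ±5 residues around the outermost marks (clipped at the
termini), or to the full chain for an unmodified label.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: valid modification kinds and the residues they may sit on
MOD_KINDS = {"ac": {"K"}, "me3": {"K"}, "ph": {"S", "T"}}

# Canonical mature (initiator-Met-cleaved) human histone chains.  H2A is the
# type-1 consensus (P0C0S8), H2B type 1-K (O60814), H3 the H3.1 chain
# (P68431), H4 P62805 and H1.4 P10412.  The arrays only require the five
# chains below; user FASTA files may override or extend this collection.
CANONICAL_HISTONES: dict[str, str] = {
    "H1.4": (
        "SETAPAAPAAPAPAEKTPVKKKARKSAGAAKRKASGPPVSELITKAVAASKERSGVSLAA"
        "LKKALAAAGYDVEKNNSRIKLGLKSLVSKGTLVQTKGTGASGSFKLNKKAASGEAKPKAK"
        "KAGAAKAKKPAGAAKKPKKATGAATPKKSAKKTPKKAKKPAAAAGAKKAKSPKKAKAAKP"
        "KKAPKSPAKAKAVKPKAAKPKTAKPKAAKPKKAAAKKK"
    ),
    "H2A": (
        "SGRGKQGGKARAKAKTRSSRAGLQFPVGRVHRLLRKGNYAERVGAGAPVYLAAVLEYLTA"
        "EILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGKVTIAQGGVLPNIQAVLLPKKT"
        "ESHHKAKGK"
    ),
    "H2B": (
        "PEPAKSAPAPKKGSKKAVTKAQKKDGKKRKRSRKESYSVYVYKVLKQVHPDTGISSKAMG"
        "IMNSFVNDIFERIAGEASRLAHYNKRSTITSREIQTAVRLLLPGELAKHAVSEGTKAVTK"
        "YTSSK"
    ),
    "H3": (
        "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALREIRRYQKSTEL"
        "LIRKLPFQRLVREIAQDFKTDLRFQSSAVMALQEACEAYLVGLFEDTNLCAIHAKRVTIM"
        "PKDIQLARRIRGERA"
    ),
    "H4": (
        "SGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLKV"
        "FLENVIRDAVTYTEHAKRKTVTAMDVVYALKRQGRTLYGFGG"
    ),
}


class MarkError(ValueError):
    """Raised for malformed or chemically invalid mark strings."""


@dataclass(frozen=True)
class HistoneSequence:
    """A named amino-acid chain with 1-based mature-chain numbering."""

    name: str
    residues: str
    numbering_origin: int = 1

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"{self.name}: non-standard residues {sorted(bad)}")
        if self.numbering_origin != 1:
            raise ValueError("numbering origin is fixed at 1 (mature chain)")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside {self.name} (1-{len(self)})")
        return self.residues[position - 1]

    def lysine_positions(self) -> list[int]:
        return [i + 1 for i, aa in enumerate(self.residues) if aa == "K"]


@dataclass(frozen=True, order=True)
class Modification:
    """A single PTM at a 1-based mature-chain position."""

    position: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MOD_KINDS:
            raise MarkError(f"unknown modification kind {self.kind!r}")
        if self.position < 1:
            raise MarkError("positions are 1-based")

    def validate_on(self, histone: HistoneSequence) -> None:
        aa = histone.residue(self.position)
        if aa not in MOD_KINDS[self.kind]:
            raise MarkError(
                f"{self.kind} not valid on {aa}{self.position} of {histone.name}"
            )


@dataclass(frozen=True)
class ModifiedPeptide:
    """A windowed histone peptide carrying a set of site-addressed marks."""

    parent: str
    start: int
    end: int
    mods: frozenset[Modification] = frozenset()
    collection: Mapping[str, HistoneSequence] | None = field(
        default=None, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        histone = self.histone()
        if not 1 <= self.start <= self.end <= len(histone):
            raise MarkError(
                f"window ({self.start}-{self.end}) outside {self.parent} "
                f"(1-{len(histone)})"
            )
        positions = [m.position for m in self.mods]
        if len(set(positions)) != len(positions):
            raise MarkError("multiple marks on one residue")
        for mod in self.mods:
            if not self.start <= mod.position <= self.end:
                raise MarkError(
                    f"mark at {mod.position} outside window "
                    f"({self.start}-{self.end})"
                )
            mod.validate_on(histone)

    def histone(self) -> HistoneSequence:
        coll = self.collection if self.collection is not None else default_collection()
        try:
            return coll[self.parent]
        except KeyError:
            raise MarkError(f"unknown histone {self.parent!r}") from None

    @property
    def sequence(self) -> str:
        """Unmodified window sequence (marks are annotations, not letters)."""
        return self.histone().residues[self.start - 1 : self.end]

    @property
    def label(self) -> str:
        marks = "".join(
            f"{self.histone().residue(m.position)}{m.position}{m.kind}"
            for m in sorted(self.mods)
        )
        return f"{self.parent}({self.start}-{self.end}){marks}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

    def without_kinds(self, kinds: Iterable[str]) -> "ModifiedPeptide":
        """Copy of this peptide with all marks of the given kinds removed."""
        drop = set(kinds)
        kept = frozenset(m for m in self.mods if m.kind not in drop)
        return ModifiedPeptide(self.parent, self.start, self.end, kept, self.collection)

    def unmodified(self) -> "ModifiedPeptide":
        return ModifiedPeptide(
            self.parent, self.start, self.end, frozenset(), self.collection
        )

    def count(self, kind: str) -> int:
        return sum(1 for m in self.mods if m.kind == kind)


_DEFAULT_COLLECTION: dict[str, HistoneSequence] | None = None


def default_collection() -> dict[str, HistoneSequence]:
    """The five packaged human histone chains, keyed by name."""
    global _DEFAULT_COLLECTION
    if _DEFAULT_COLLECTION is None:
        _DEFAULT_COLLECTION = {
            name: HistoneSequence(name, seq) for name, seq in CANONICAL_HISTONES.items()
        }
    return _DEFAULT_COLLECTION


def read_fasta(path: str | Path) -> dict[str, HistoneSequence]:
    """Load a user histone collection from FASTA (record ids become names)."""
    records = SeqIO.parse(str(path), "fasta")
    out: dict[str, HistoneSequence] = {}
    for rec in records:
        if rec.id in out:
            raise ValueError(f"duplicate sequence name {rec.id!r}")
        out[rec.id] = HistoneSequence(rec.id, str(rec.seq).upper())
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


_LABEL_RE = re.compile(
    r"^(?P<name>[A-Za-z0-9.\-_]+?)" r"(?:\((?P<start>\d+)-(?P<end>\d+)\))?" r"(?P<marks>([A-Z]\d+(ac|me3|ph)|p[ST]\d+)*)$"
)
_MARK_RE = re.compile(r"([A-Z])(\d+)(ac|me3|ph)|p([ST])(\d+)")

#: padding applied around the outermost marks when bounds are omitted
DEFAULT_WINDOW_PAD = 5


def parse_mark(
    label: str, collection: Mapping[str, HistoneSequence] | None = None
) -> ModifiedPeptide:
    """Parse a mark string such as ``"H4(1-11)K5acK8ac"`` into a peptide.

    Without explicit bounds the window pads ``DEFAULT_WINDOW_PAD`` residues
    around the outermost marks (clipped at the termini); an unmodified
    boundless label spans the whole chain.
    """
    coll = collection if collection is not None else default_collection()
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise MarkError(f"malformed mark string {label!r}")
    name = m.group("name")
    if name not in coll:
        raise MarkError(f"unknown histone name {name!r} in {label!r}")
    histone = coll[name]

    mods: list[Modification] = []
    mark_str = m.group("marks") or ""
    consumed = 0
    for token in _MARK_RE.finditer(mark_str):
        consumed += len(token.group(0))
        if token.group(4):  # prefix form pS10 / pT3
            residue, position, kind = token.group(4), int(token.group(5)), "ph"
        else:
            residue, position, kind = (
                token.group(1),
                int(token.group(2)),
                token.group(3),
            )
        actual = histone.residue(position)
        if actual != residue:
            raise MarkError(
                f"{label!r}: residue {position} of {name} is {actual}, not {residue}"
            )
        mod = Modification(position, kind)
        mod.validate_on(histone)
        mods.append(mod)
    if consumed != len(mark_str):
        raise MarkError(f"malformed mark string {label!r}")

    if m.group("start") is not None:
        start, end = int(m.group("start")), int(m.group("end"))
    elif mods:
        positions = [mod.position for mod in mods]
        start = max(1, min(positions) - DEFAULT_WINDOW_PAD)
        end = min(len(histone), max(positions) + DEFAULT_WINDOW_PAD)
    else:
        start, end = 1, len(histone)
    return ModifiedPeptide(name, start, end, frozenset(mods), collection)


def extract_window(
    parent: HistoneSequence, center: int, length: int
) -> tuple[int, int]:
    """Window bounds of ``length`` residues with ``center`` at slot ⌈L/2⌉.

    Windows are truncated (not shifted) at the chain termini, so a window
    near an end can be shorter than requested but the center rule is never
    violated.
    """
    if not 1 <= center <= len(parent):
        raise IndexError(f"center {center} outside {parent.name}")
    if not 5 <= length <= 25:
        raise ValueError("window length must be in [5, 25]")
    offset = math.ceil(length / 2) - 1
    start = center - offset
    end = start + length - 1
    return max(1, start), min(len(parent), end)


def modifiable_sites(peptide: ModifiedPeptide) -> list[tuple[int, frozenset[str]]]:
    """Positions in the window that can carry marks, with their allowed kinds.

    Lysines report {ac, me3}; serines and threonines report {ph}; sorted by
    position.
    """
    out: list[tuple[int, frozenset[str]]] = []
    histone = peptide.histone()
    for position in range(peptide.start, peptide.end + 1):
        aa = histone.residue(position)
        kinds = frozenset(k for k, residues in MOD_KINDS.items() if aa in residues)
        if kinds:
            out.append((position, kinds))
    return out
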