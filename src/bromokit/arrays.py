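"""Deterministic SPOT-membrane layout generation.

Three membrane classes are generated, mirroring the standard designs used
to profile acetyl-lysine reader domains:

* ``single_kac`` — every lysine of every histone as a singly acetylated
  probe with a sequence-identical unmodified control;
* ``crosstalk`` — for each central acetyl-lysine epitope, the Cartesian
  product of flanking modifiable-site states (K: unmod/ac/me3, S/T:
  unmod/ph) within an 11-mer window;
* ``multi_kac`` — every window placement over the N-terminal tails with
  every non-empty subset of window lysines acetylated;
* ``linker_scan`` — Kac-Gly(n)-Kac peptides plus single-residue property
  substitutions in the linker, with paired anchor-Asn-mutant (N→A)
  annotation slots for simulating no-binding membranes.

All designers are pure functions of their parameters: re-running with the
same arguments produces byte-identical layout tables.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .histones import (
    AMINO_ACIDS,
    HistoneSequence,
    Modification,
    ModifiedPeptide,
    default_collection,
    extract_window,
    modifiable_sites,
)

ROLES = ("probe", "unmod_control", "mutant_control")

#: grid width used to lay spots out row-major; purely presentational
GRID_COLUMNS = 20

#: ordered mark states per modifiable residue class (unmod first)
K_STATES: tuple[str | None, ...] = (None, "ac", "me3")
ST_STATES: tuple[str | None, ...] = (None, "ph")


@dataclass(frozen=True)
class Spot:
    row: int
    col: int
    peptide: ModifiedPeptide
    role: str
    control_partner: str | None = None
    replicate_of: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown spot role {self.role!r}")


@dataclass
class ArrayLayout:
    membrane_id: str
    spots: list[Spot]
    design_class: str
    provenance: dict = field(default_factory=dict)
    collection: Mapping[str, HistoneSequence] | None = None

    def __post_init__(self) -> None:
        coords = [(s.row, s.col) for s in self.spots]
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate spot coordinates")
        if coords != sorted(coords):
            raise ValueError("spots must be in row-major order")
        labels = [s.peptide.label for s in self.spots if s.replicate_of is None]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate peptide labels not flagged as replicates")

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def probes(self) -> list[Spot]:
        return [s for s in self.spots if s.role == "probe"]

    @property
    def controls(self) -> list[Spot]:
        return [s for s in self.spots if s.role == "unmod_control"]

    def spot_by_label(self, label: str, role: str = "probe") -> Spot:
        for s in self.spots:
            if s.peptide.label == label and s.role == role:
                return s
        raise KeyError(f"no {role} spot labelled {label!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "membrane_id": self.membrane_id,
                "row": s.row,
                "col": s.col,
                "label": s.peptide.label,
                "role": s.role,
                "control_partner": s.control_partner or "",
                "replicate_of": s.replicate_of or "",
            }
            for s in self.spots
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# design_class={self.design_class}\n")
            fh.write(f"# provenance={json.dumps(self.provenance, sort_keys=True)}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "membrane_id": self.membrane_id,
            "design_class": self.design_class,
            "provenance": self.provenance,
            "spots": self.to_frame().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_layout_tsv(
    path: str | Path, collection: Mapping[str, HistoneSequence] | None = None
) -> ArrayLayout:
    """Rebuild a layout from its TSV export (labels are re-parsed)."""
    from .histones import parse_mark

    header: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        for line in iter(fh.readline, ""):
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                header[key.strip()] = value
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        frame = pd.read_csv(fh, sep="\t", keep_default_na=False)
    spots = [
        Spot(
            int(r.row),
            int(r.col),
            parse_mark(r.label, collection),
            r.role,
            r.control_partner or None,
            r.replicate_of or None,
        )
        for r in frame.itertuples()
    ]
    return ArrayLayout(
        membrane_id=str(frame.membrane_id.iloc[0]) if len(frame) else "empty",
        spots=spots,
        design_class=header.get("design_class", "unknown"),
        provenance=json.loads(header.get("provenance", "{}")),
        collection=collection,
    )


def _grid(n: int) -> tuple[int, int]:
    return divmod(n, GRID_COLUMNS)


class _Placer:
    """Assigns consecutive row-major grid coordinates."""

    def __init__(self) -> None:
        self._n = 0
        self.spots: list[Spot] = []

    def add(self, peptide: ModifiedPeptide, role: str, **kw) -> Spot:
        row, col = _grid(self._n)
        spot = Spot(row, col, peptide, role, **kw)
        self.spots.append(spot)
        self._n += 1
        return spot


def design_single_kac_array(
    histones: Sequence[HistoneSequence] | None = None,
    length: int = 11,
    membrane_id: str = "single_kac",
) -> ArrayLayout:
    """One singly acetylated probe per lysine, preceded by its unmodified
    control over the same window."""
    if not 10 <= length <= 14:
        raise ValueError("single-Kac arrays use peptide lengths 10-14")
    if histones is None:
        histones = list(default_collection().values())
    placer = _Placer()
    for histone in histones:
        for k in histone.lysine_positions():
            start, end = extract_window(histone, k, length)
            control = ModifiedPeptide(histone.name, start, end)
            probe = ModifiedPeptide(
                histone.name, start, end, frozenset({Modification(k, "ac")})
            )
            placer.add(control, "unmod_control")
            placer.add(probe, "probe", control_partner=control.label)
    return ArrayLayout(
        membrane_id,
        placer.spots,
        "single_kac",
        {"length": length, "histones": [h.name for h in histones]},
    )


def _flank_state_sets(
    peptide_sites: list[tuple[int, frozenset[str]]], center: int
) -> list[tuple[int, tuple[str | None, ...]]]:
    """Flanking modifiable sites (excluding the central K) with their
    ordered state alphabets."""
    out = []
    for position, kinds in peptide_sites:
        if position == center:
            continue
        out.append((position, K_STATES if "ac" in kinds else ST_STATES))
    return out


def design_crosstalk_array(
    histone: HistoneSequence | None = None,
    length: int = 11,
    max_flanking_mods: int | None = None,
    membrane_id: str = "crosstalk",
) -> ArrayLayout:
    """Combinatorial flanking-mark contexts around each central Kac epitope.

    The Cartesian product over flanking states includes the all-unmodified
    member, which is exactly the central-Kac-only peptide.  A fully
    unmodified control is placed before each epitope block.
    ``max_flanking_mods=None`` enumerates the full product.
    """
    if histone is None:
        histone = default_collection()["H3"]
    if length != 11:
        warnings.warn(
            "crosstalk arrays are designed as 11-mers; other lengths deviate "
            "from the reference design",
            stacklevel=2,
        )
    placer = _Placer()
    for k in histone.lysine_positions():
        start, end = extract_window(histone, k, length)
        window = ModifiedPeptide(histone.name, start, end)
        flanks = _flank_state_sets(modifiable_sites(window), k)
        control = window
        placer.add(control, "unmod_control")
        center_mod = Modification(k, "ac")
        for states in itertools.product(*(alphabet for _, alphabet in flanks)):
            n_marks = sum(1 for s in states if s is not None)
            if max_flanking_mods is not None and n_marks > max_flanking_mods:
                continue
            mods = {center_mod} | {
                Modification(pos, state)
                for (pos, _), state in zip(flanks, states)
                if state is not None
            }
            probe = ModifiedPeptide(histone.name, start, end, frozenset(mods))
            placer.add(probe, "probe", control_partner=control.label)
    return ArrayLayout(
        membrane_id,
        placer.spots,
        "crosstalk",
        {
            "histone": histone.name,
            "length": length,
            "max_flanking_mods": max_flanking_mods,
        },
    )


def design_multi_kac_array(
    histones: Sequence[HistoneSequence] | None = None,
    length: int = 11,
    tail_length: int = 30,
    membrane_id: str = "multi_kac",
) -> ArrayLayout:
    """Every N-terminal-tail window with every non-empty acetyl-lysine
    subset; one unmodified control per window."""
    if histones is None:
        coll = default_collection()
        histones = [coll["H3"], coll["H4"]]
    placer = _Placer()
    seen: set[str] = set()
    for histone in histones:
        tail_end = min(tail_length, len(histone))
        for start in range(1, tail_end - length + 2):
            end = start + length - 1
            ks = [
                p for p in histone.lysine_positions() if start <= p <= end
            ]
            if not ks:
                continue
            control = ModifiedPeptide(histone.name, start, end)
            if control.label not in seen:
                seen.add(control.label)
                placer.add(control, "unmod_control")
            for r in range(1, len(ks) + 1):
                for subset in itertools.combinations(ks, r):
                    probe = ModifiedPeptide(
                        histone.name,
                        start,
                        end,
                        frozenset(Modification(p, "ac") for p in subset),
                    )
                    if probe.label in seen:
                        continue
                    seen.add(probe.label)
                    placer.add(probe, "probe", control_partner=control.label)
    return ArrayLayout(
        membrane_id,
        placer.spots,
        "multi_kac",
        {
            "length": length,
            "tail_length": tail_length,
            "histones": [h.name for h in histones],
        },
    )


#: default substitution panel spanning small/bulky/hydrophobic/polar/
#: cyclic/acidic/basic residue properties
LINKER_PANEL = ("G", "A", "L", "F", "S", "P", "E", "K")

#: linker lengths whose slots receive single-residue substitutions
SUBSTITUTED_LENGTHS = (2, 3)


def _linker_parent(
    flank_n: str, flank_c: str, linker: str, tag: str
) -> HistoneSequence:
    seq = f"{flank_n}K{linker}K{flank_c}"
    return HistoneSequence(tag, seq)


def design_linker_array(
    flank_n: str = "SGRG",
    flank_c: str = "GLG",
    linker_lengths: Sequence[int] = (0, 1, 2, 3, 4),
    panel: Sequence[str] = LINKER_PANEL,
    panel_positions: Sequence[int] = (1, 2),
    membrane_id: str = "linker_scan",
) -> ArrayLayout:
    """Kac-Gly(n)-Kac spacer series plus linker-residue property scans.

    For each length in ``SUBSTITUTED_LENGTHS`` (∩ requested lengths), each
    panel residue is substituted at each requested 1-based linker slot, one
    substitution at a time.  Substitutions that reproduce the all-Gly base
    peptide (panel residue G) are flagged ``replicate_of``.  Every probe is
    paired with an unmodified control and an anchor-mutant (N→A) annotation
    slot usable for simulating no-binding membranes.
    """
    if not linker_lengths:
        raise ValueError("linker_lengths must be non-empty")
    if any(n < 0 for n in linker_lengths):
        raise ValueError("linker lengths must be >= 0")
    bad = set(panel) - AMINO_ACIDS
    if bad:
        raise ValueError(f"panel residues outside the 20-letter alphabet: {bad}")
    collection: dict[str, HistoneSequence] = {}
    placer = _Placer()

    def add_probe(linker: str, tag: str, replicate_of: str | None) -> None:
        parent = _linker_parent(flank_n, flank_c, linker, tag)
        collection[parent.name] = parent
        k1 = len(flank_n) + 1
        k2 = k1 + len(linker) + 1
        control = ModifiedPeptide(parent.name, 1, len(parent), collection=collection)
        probe = ModifiedPeptide(
            parent.name,
            1,
            len(parent),
            frozenset({Modification(k1, "ac"), Modification(k2, "ac")}),
            collection=collection,
        )
        placer.add(control, "unmod_control")
        placer.add(
            probe, "probe", control_partner=control.label, replicate_of=replicate_of
        )
        # N->A annotation slot: same peptide, flagged as a mutant-null probe
        placer.add(
            probe, "mutant_control", control_partner=control.label,
            replicate_of=probe.label,
        )

    for n in sorted(set(linker_lengths)):
        add_probe("G" * n, f"LNK-G{n}", None)
    base_labels = {
        n: f"LNK-G{n}(1-{len(flank_n) + n + 2 + len(flank_c)})"
        for n in linker_lengths
    }
    for n in sorted(set(SUBSTITUTED_LENGTHS) & set(linker_lengths)):
        for slot in panel_positions:
            if not 1 <= slot <= n:
                raise ValueError(f"panel slot {slot} outside linker of length {n}")
            for residue in panel:
                linker = "G" * (slot - 1) + residue + "G" * (n - slot)
                tag = f"LNK-n{n}s{slot}{residue}"
                replicate = None
                if linker == "G" * n:
                    k1 = len(flank_n) + 1
                    k2 = k1 + n + 1
                    replicate = (
                        base_labels[n].split("(")[0]
                        + f"(1-{len(flank_n) + n + 2 + len(flank_c)})"
                        + f"K{k1}acK{k2}ac"
                    )
                add_probe(linker, tag, replicate)
    layout = ArrayLayout(
        membrane_id,
        placer.spots,
        "linker_scan",
        {
            "flank_n": flank_n,
            "flank_c": flank_c,
            "linker_lengths": sorted(set(linker_lengths)),
            "panel": list(panel),
            "panel_positions": list(panel_positions),
        },
        collection=collection,
    )
    return layout


DESIGNERS = {
    "single_kac": design_single_kac_array,
    "crosstalk": design_crosstalk_array,
    "multi_kac": design_multi_kac_array,
    "linker_scan": design_linker_array,
}
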