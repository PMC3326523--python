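"""Signature-motif scanning, domain-boundary proposal, alignment distances,
neighbor joining, and family assignment for bromodomain-like sequences.

The reader-domain fold carries three sequence signatures used here:

* the N-terminal helix motif ``ϕxx(x*)ϕxxx(x*)ϕ`` (three buried
  hydrophobics with two optional insertion slots),
* the ``PϕD`` motif capping the A helix,
* the long B-helix signature ``ϕxxDϕxxϕϕxNϕxxY/F`` ending just before the
  acetyl-lysine-anchoring asparagine.

ϕ denotes the hydrophobic class {A, C, F, I, L, M, V, W, Y} by default
(configurable); x is any residue.  Patterns are scanned exhaustively,
including overlaps and every optional-insertion variant.

Family assignment is nearest-reference classification under global-
alignment identity distances, with an optional neighbor-joining tree for
reporting.  Distances are d = 1 - identity, which is a dissimilarity, not
a metric: the triangle inequality is not guaranteed and never assumed.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

HYDROPHOBIC = frozenset("ACFILMVWY")

PHI = "phi"
ANY = "any"


@dataclass(frozen=True)
class Insertion:
    """An optional-insertion slot of 0..max_len arbitrary residues."""

    max_len: int = 3


PatternElement = str | frozenset | Insertion


@dataclass(frozen=True)
class MotifPattern:
    """An ordered positional pattern over residue classes.

    Elements: ``PHI`` (hydrophobic class), ``ANY``, a literal residue
    string of length 1, a frozenset choice (e.g. {Y, F}), or an
    :class:`Insertion` slot.
    """

    name: str
    elements: tuple[PatternElement, ...]
    hydrophobic: frozenset = HYDROPHOBIC

    def __post_init__(self) -> None:
        fixed = [e for e in self.elements if not isinstance(e, Insertion)]
        if len(fixed) < 3:
            raise ValueError("patterns need at least 3 fixed positions")

    def variants(self) -> list[str]:
        """All concrete fixed-length regex strings (insertions expanded)."""
        slots = [e.max_len for e in self.elements if isinstance(e, Insertion)]
        out = []
        for lengths in itertools.product(*(range(m + 1) for m in slots)):
            it = iter(lengths)
            parts = []
            for e in self.elements:
                if isinstance(e, Insertion):
                    parts.append("." * next(it))
                elif e == PHI:
                    parts.append("[" + "".join(sorted(self.hydrophobic)) + "]")
                elif e == ANY:
                    parts.append(".")
                elif isinstance(e, frozenset):
                    parts.append("[" + "".join(sorted(e)) + "]")
                else:
                    parts.append(re.escape(e))
            out.append("".join(parts))
        return out


def _p(spec: str, hydrophobic: frozenset = HYDROPHOBIC) -> tuple[PatternElement, ...]:
    """Compact pattern builder: 'f'=ϕ, 'x'=any, '?'=insertion slot,
    '[YF]'=choice, other letters literal."""
    out: list[PatternElement] = []
    i = 0
    while i < len(spec):
        ch = spec[i]
        if ch == "f":
            out.append(PHI)
        elif ch == "x":
            out.append(ANY)
        elif ch == "?":
            out.append(Insertion())
        elif ch == "[":
            j = spec.index("]", i)
            out.append(frozenset(spec[i + 1 : j]))
            i = j
        else:
            out.append(ch)
        i += 1
    return tuple(out)


def default_patterns(hydrophobic: frozenset = HYDROPHOBIC) -> list[MotifPattern]:
    """The three shipped signature patterns."""
    return [
        MotifPattern("alphaZ", _p("fxx?fxxx?f"), hydrophobic),
        MotifPattern("PphiD", _p("PfD"), hydrophobic),
        MotifPattern("alphaB", _p("fxxDfxxffxNfxx[YF]"), hydrophobic),
    ]


@dataclass(frozen=True)
class MotifMatch:
    pattern: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    matched: str


def scan_motifs(
    sequence: str, patterns: Sequence[MotifPattern] | None = None
) -> list[MotifMatch]:
    """All matches of every pattern, overlaps and insertion variants
    included, ordered by (start, pattern name, end)."""
    patterns = list(patterns) if patterns is not None else default_patterns()
    sequence = sequence.upper()
    found: set[MotifMatch] = set()
    for pattern in patterns:
        for variant in pattern.variants():
            rx = re.compile("(?=(" + variant + "))")
            for m in rx.finditer(sequence):
                s = m.start(1) + 1
                e = m.end(1)
                found.add(MotifMatch(pattern.name, s, e, m.group(1)))
    return sorted(found, key=lambda m: (m.start, m.pattern, m.end))


ANCHOR_CLASSES = {"N": "Asn", "T": "Thr", "Y": "Tyr", "D": "Asp"}


@dataclass
class BrdAnnotation:
    """Motif matches plus proposed domain bounds for one sequence."""

    sequence_id: str
    matches: list[MotifMatch]
    domains: list[tuple[int, int]] = field(default_factory=list)
    anchor_positions: list[int] = field(default_factory=list)
    anchor_classes: list[str] = field(default_factory=list)


#: allowed offset of the B-helix motif start after the helix-Z motif start
DOMAIN_SPAN = (30, 120)
#: residues added before the helix-Z motif / after the anchor region
DOMAIN_MARGIN_N = 6
DOMAIN_MARGIN_C = 25


def propose_domain(
    sequence_id: str,
    sequence: str,
    patterns: Sequence[MotifPattern] | None = None,
    span: tuple[int, int] = DOMAIN_SPAN,
    margin_n: int = DOMAIN_MARGIN_N,
    margin_c: int = DOMAIN_MARGIN_C,
) -> BrdAnnotation:
    """Motif-anchored domain proposal.

    A domain requires a helix-Z motif followed, within the spacing
    envelope, by a B-helix motif; bounds run from the helix-Z start minus
    ``margin_n`` to the B-helix end plus ``margin_c`` (clipped).  Multiple
    non-overlapping proposals are made greedily left to right.  Fewer than
    two compatible anchors yields an empty proposal, not an error.  The
    residue immediately after the B-helix motif is reported as the
    acetyl-lysine anchor and classified (Asn/Thr/Tyr/Asp/other).
    """
    matches = scan_motifs(sequence, patterns)
    alphaz = [m for m in matches if m.pattern == "alphaZ"]
    alphab = [m for m in matches if m.pattern == "alphaB"]
    domains: list[tuple[int, int]] = []
    anchors: list[int] = []
    anchor_classes: list[str] = []
    cursor = 0
    for z in alphaz:
        if z.start <= cursor:
            continue
        partner = next(
            (
                b
                for b in alphab
                if span[0] <= b.start - z.start <= span[1] and b.start > cursor
            ),
            None,
        )
        if partner is None:
            continue
        start = max(1, cursor + 1, z.start - margin_n)
        end = min(len(sequence), partner.end + margin_c)
        domains.append((start, end))
        anchor_pos = partner.end + 1
        if anchor_pos <= len(sequence):
            anchors.append(anchor_pos)
            anchor_classes.append(
                ANCHOR_CLASSES.get(sequence[anchor_pos - 1], "other")
            )
        cursor = end
    return BrdAnnotation(sequence_id, matches, domains, anchors, anchor_classes)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def _identity_distance(a: str, b: str, aligner: Align.PairwiseAligner) -> float:
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 0.0
    alignment = aligner.align(a, b)[0]
    sa, sb = str(alignment[0]), str(alignment[1])
    columns = sum(1 for x, y in zip(sa, sb) if not (x == "-" and y == "-"))
    identities = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return 1.0 - identities / columns


def pairwise_distances(
    sequences: Mapping[str, str] | None = None,
    alignment: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Symmetric identity-distance matrix.

    Either unaligned ``sequences`` (global pairwise alignment, BLOSUM62,
    affine gaps 10/0.5) or a user-supplied ``alignment`` (equal-length
    gapped strings; distances computed column-wise, dual-gap columns
    excluded).
    """
    if (sequences is None) == (alignment is None):
        raise ValueError("provide exactly one of sequences / alignment")
    if alignment is not None:
        labels = list(alignment)
        rows = [alignment[k] for k in labels]
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must share one length")
        n = len(labels)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                cols = [
                    (x, y)
                    for x, y in zip(rows[i], rows[j])
                    if not (x == "-" and y == "-")
                ]
                if not cols:
                    raise ValueError("no aligned columns between sequences")
                ident = sum(1 for x, y in cols if x == y and x != "-")
                mat[i, j] = mat[j, i] = 1.0 - ident / len(cols)
        return pd.DataFrame(mat, index=labels, columns=labels)
    labels = list(sequences)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    aligner = _aligner()
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _identity_distance(sequences[labels[i]], sequences[labels[j]], aligner)
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _nj_pick(d: np.ndarray, labels: list[str]) -> tuple[int, int]:
    """Lowest-Q pair with deterministic lowest-label-pair tie-breaking."""
    n = d.shape[0]
    r = d.sum(axis=1)
    best = None
    best_q = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            q = (n - 2) * d[i, j] - r[i] - r[j]
            key = tuple(sorted((labels[i], labels[j])))
            if q < best_q - 1e-12 or (
                abs(q - best_q) <= 1e-12 and (best is None or key < best[2])
            ):
                best_q = q
                best = (i, j, key)
    assert best is not None
    return best[0], best[1]


def nj_tree(distances: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None
            ) -> str:
    """Neighbor-joining tree (newick, unrooted trifurcation at the last
    join) from a symmetric distance matrix.

    Ties in the Q criterion break on the lexicographically lowest leaf-
    label pair; negative branch lengths are clamped to zero with the
    deficit moved to the sibling branch.
    """
    if isinstance(distances, pd.DataFrame):
        labels = list(distances.index)
        d = distances.to_numpy(dtype=float).copy()
    else:
        d = np.asarray(distances, dtype=float).copy()
        if labels is None:
            labels = [f"t{i}" for i in range(d.shape[0])]
        labels = list(labels)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [f"{_escape(l)}" for l in labels]
    # sort-keys: the smallest leaf label under each working node, used for
    # deterministic tie-breaking after the first join
    keys = list(labels)

    while len(nodes) > 3:
        i, j = _nj_pick(d, keys)
        m = d.shape[0]
        r = d.sum(axis=1)
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        vi, vj = _clamp_pair(vi, vj, d[i, j])
        new_node = f"({nodes[i]}:{_fmt(vi)},{nodes[j]}:{_fmt(vj)})"
        new_key = min(keys[i], keys[j])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((len(keep) + 1, len(keep) + 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        nodes = [nodes[k] for k in keep] + [new_node]
        keys = [keys[k] for k in keep] + [new_key]
        d = d_new

    # final unrooted trifurcation via the three-point formulas
    va = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    vb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    vc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    va, vb, vc = (max(v, 0.0) for v in (va, vb, vc))
    return (
        f"({nodes[0]}:{_fmt(va)},{nodes[1]}:{_fmt(vb)},{nodes[2]}:{_fmt(vc)});"
    )


def _clamp_pair(vi: float, vj: float, dij: float) -> tuple[float, float]:
    if vi < 0:
        return 0.0, dij
    if vj < 0:
        return dij, 0.0
    return vi, vj


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def _escape(label: str) -> str:
    if re.search(r"[\s(),:;]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# family assignment
# ---------------------------------------------------------------------------

ROMAN_FAMILIES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


@dataclass
class FamilyAssignment:
    sequence_id: str
    family: str  # Roman numeral or "unassigned"
    nearest_reference: str
    distance: float
    tree: str | None = None


def assign_family(
    query_id: str,
    query_seq: str,
    references: Mapping[str, tuple[str, str]],
    cutoff: float = 0.6,
    with_tree: bool = False,
) -> FamilyAssignment:
    """Nearest-reference family assignment.

    ``references`` maps reference id -> (family label, sequence); every
    family should have at least one reference.  Queries farther than
    ``cutoff`` from every reference are "unassigned".  ``with_tree``
    additionally builds a neighbor-joining tree of the references with the
    query grafted in.
    """
    if not references:
        raise ValueError("no references supplied")
    aligner = _aligner()
    best_id, best_d = None, np.inf
    for ref_id, (_, ref_seq) in references.items():
        dist = _identity_distance(query_seq, ref_seq, aligner)
        if dist < best_d or (dist == best_d and (best_id is None or ref_id < best_id)):
            best_id, best_d = ref_id, dist
    family = references[best_id][0] if best_d <= cutoff else "unassigned"
    tree = None
    if with_tree:
        seqs = {rid: rseq for rid, (_, rseq) in references.items()}
        seqs[query_id] = query_seq
        tree = nj_tree(pairwise_distances(sequences=seqs))
    return FamilyAssignment(query_id, family, best_id, float(best_d), tree)


def distinct_families(references: Mapping[str, tuple[str, str]]) -> int:
    return len({fam for fam, _ in references.values()})
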