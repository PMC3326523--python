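"""Motif scanning, domain proposal, distances, NJ, and family assignment."""

import itertools
import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bromokit.family import (
    HYDROPHOBIC,
    MotifPattern,
    assign_family,
    default_patterns,
    distinct_families,
    nj_tree,
    pairwise_distances,
    propose_domain,
    scan_motifs,
)
from bromokit.synth import family_templates, synth_brd_sequences

AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_matches(sequence, pattern):
    """Independent oracle: expand the written pattern into per-position
    token lists (insertion slots enumerated 0..3) and slide a full-match
    window at every offset."""
    phi = "[" + "".join(sorted(HYDROPHOBIC)) + "]"
    variants = {
        "alphaZ": [
            [phi, ".", "."] + ["."] * a + [phi, ".", ".", "."] + ["."] * b + [phi]
            for a in range(4)
            for b in range(4)
        ],
        "PphiD": [["P", phi, "D"]],
        "alphaB": [
            [phi, ".", ".", "D", phi, ".", ".", phi, phi, ".", "N", phi, ".", ".", "[FY]"]
        ],
    }[pattern]
    out = set()
    for tokens in variants:
        length = len(tokens)
        compiled = re.compile("".join(tokens))
        for start in range(len(sequence) - length + 1):
            if compiled.fullmatch(sequence[start : start + length]):
                out.add((start + 1, start + length))
    return out


class TestScanMotifs:
    def test_alphab_example_matches_exactly_once(self):
        matches = scan_motifs("LAADLAALLANLAAY")
        alphab = [m for m in matches if m.pattern == "alphaB"]
        assert len(alphab) == 1
        assert (alphab[0].start, alphab[0].end) == (1, 15)

    def test_poly_g_matches_nothing(self):
        assert scan_motifs("G" * 80) == []

    @pytest.mark.parametrize("pattern_name", ["alphaZ", "PphiD", "alphaB"])
    def test_agreement_with_expansion_oracle(self, pattern_name):
        rng = np.random.default_rng(42)
        pattern = next(p for p in default_patterns() if p.name == pattern_name)
        for _ in range(300):
            seq = "".join(
                rng.choice(list("LAND" + AA)) for _ in range(rng.integers(20, 60))
            )
            got = {
                (m.start, m.end)
                for m in scan_motifs(seq, [pattern])
            }
            assert got == oracle_matches(seq, pattern_name)

    def test_all_phi_saturated_sequence_counts_match_sliding_window(self):
        """Sequence engineered so D/N/Y align at many offsets; match count
        equals an exhaustive window check."""
        seq = ("LLLDLLLLLLNLLLY" * 4)[:58]
        got = {(m.start, m.end) for m in scan_motifs(seq, default_patterns()[2:])}
        assert got == oracle_matches(seq, "alphaB")
        assert got  # non-trivial

    def test_deterministic_ordering(self):
        seq = "LAADLAALLANLAAYLAADLAALLANLAAY"
        a = scan_motifs(seq)
        b = scan_motifs(seq)
        assert a == b
        starts = [m.start for m in a]
        assert starts == sorted(starts)


class TestProposeDomain:
    def test_template_bounds_contain_all_planted_motifs(self):
        for family, seq in family_templates().items():
            ann = propose_domain(family, seq)
            assert len(ann.domains) == 1
            start, end = ann.domains[0]
            assert start <= 7 and end >= 86  # planted motif span (1-based)

    def test_anchor_classification(self):
        templates = family_templates()
        assert propose_domain("I", templates["I"]).anchor_classes == ["Asn"]
        assert propose_domain("VI", templates["VI"]).anchor_classes == ["Asp"]
        assert propose_domain("VII", templates["VII"]).anchor_classes == ["Thr"]

    def test_single_anchor_yields_no_domain(self):
        # helix-Z-like motif alone, no B-helix signature anywhere
        seq = "G" * 10 + "LKKLEEEL" + "G" * 90
        ann = propose_domain("x", seq)
        assert ann.domains == []

    def test_concatenated_templates_give_two_nonoverlapping_domains(self):
        templates = family_templates()
        ann = propose_domain("cat", templates["I"] + templates["II"])
        assert len(ann.domains) == 2
        (s1, e1), (s2, e2) = ann.domains
        assert e1 < s2  # ordered and disjoint


class TestPairwiseDistances:
    def test_identical_sequences_distance_zero(self):
        d = pairwise_distances(sequences={"a": "MKLVNN", "b": "MKLVNN"})
        assert d.loc["a", "b"] == 0.0

    def test_hand_aligned_example(self):
        d = pairwise_distances(sequences={"a": "AAAA", "b": "AAAT"})
        assert d.loc["a", "b"] == pytest.approx(0.25)

    def test_permutation_equivariance(self):
        seqs = {
            "a": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
            "b": "MKTAYIAKQRNISFVKSHFSRQLEERLGLIEVA",
            "c": "MLTAYIDKQRQISFVKAHFSRQAEERLGLIEVQ",
        }
        d1 = pairwise_distances(sequences=seqs)
        order = ["c", "a", "b"]
        d2 = pairwise_distances(sequences={k: seqs[k] for k in order})
        pd.testing.assert_frame_equal(d1.loc[order, order], d2)

    def test_symmetric_zero_diagonal(self):
        seqs = {f"s{i}": s for i, (_, _, s) in enumerate(
            synth_brd_sequences(n_per_family=1, seed=3)[:4]
        )}
        d = pairwise_distances(sequences=seqs)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_user_alignment_column_wise(self):
        aln = {"a": "AC-GT", "b": "ACAGT", "c": "AC-GA"}
        d = pairwise_distances(alignment=aln)
        # a vs c: dual-gap column excluded -> 4 columns, 3 identical
        assert d.loc["a", "c"] == pytest.approx(0.25)
        # a vs b: 5 columns, one gap mismatch -> 4/5 identity
        assert d.loc["a", "b"] == pytest.approx(0.2)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distances(sequences={"a": "", "b": "AAA"})


def naive_nj(d, labels):
    """Independent O(n^4) neighbor joining with the same conventions:
    recompute Q from scratch each step, tie-break on the lowest label pair,
    clamp negative branch lengths moving the deficit to the sibling."""
    d = {(a, b): d[i][j] for i, a in enumerate(labels) for j, b in enumerate(labels)}
    nodes = {l: l for l in labels}
    keys = {l: l for l in labels}
    active = list(labels)

    def fmt(x):
        return f"{x:.10g}"

    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best, best_q = None, None
        for a, b in itertools.combinations(active, 2):
            q = (n - 2) * d[(a, b)] - r[a] - r[b]
            key = tuple(sorted((keys[a], keys[b])))
            if best_q is None or q < best_q - 1e-12 or (
                abs(q - best_q) <= 1e-12 and key < best
            ):
                best_q, best, pair = q, key, (a, b)
        a, b = pair
        va = 0.5 * d[(a, b)] + (r[a] - r[b]) / (2 * (n - 2))
        vb = d[(a, b)] - va
        if va < 0:
            va, vb = 0.0, d[(a, b)]
        elif vb < 0:
            va, vb = d[(a, b)], 0.0
        new = f"({nodes[a]}:{fmt(va)},{nodes[b]}:{fmt(vb)})"
        for c in active:
            if c in (a, b):
                continue
            d[(new, c)] = d[(c, new)] = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
        d[(new, new)] = 0.0
        nodes[new] = new
        keys[new] = min(keys[a], keys[b])
        active = [c for c in active if c not in (a, b)] + [new]
    x, y, z = active
    vx = 0.5 * (d[(x, y)] + d[(x, z)] - d[(y, z)])
    vy = 0.5 * (d[(x, y)] + d[(y, z)] - d[(x, z)])
    vz = 0.5 * (d[(x, z)] + d[(y, z)] - d[(x, y)])
    vx, vy, vz = (max(v, 0.0) for v in (vx, vy, vz))
    return f"({nodes[x]}:{fmt(vx)},{nodes[y]}:{fmt(vy)},{nodes[z]}:{fmt(vz)});"


def tree_distances_from_newick(newick):
    """Leaf-to-leaf path lengths via scikit-bio (independent reader)."""
    from io import StringIO

    from skbio import TreeNode

    tree = TreeNode.read(StringIO(newick))
    leaves = sorted(t.name for t in tree.tips())
    out = {}
    for a in leaves:
        for b in leaves:
            out[(a, b)] = 0.0 if a == b else tree.find(a).distance(tree.find(b))
    return leaves, out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        newick = nj_tree(d, ["A", "B", "C"])
        assert newick == "(A:1,B:3,C:5);"

    def test_additive_five_taxon_matrix_recovered_exactly(self):
        """The classic additive matrix: NJ must return the generating tree
        with exact branch lengths (checked as leaf-path distances)."""
        labels = ["A", "B", "C", "D", "E"]
        d = np.array(
            [
                [0, 5, 9, 9, 8],
                [5, 0, 10, 10, 9],
                [9, 10, 0, 8, 7],
                [9, 10, 8, 0, 3],
                [8, 9, 7, 3, 0],
            ],
            float,
        )
        newick = nj_tree(d, labels)
        leaves, paths = tree_distances_from_newick(newick)
        assert leaves == labels
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert paths[(a, b)] == pytest.approx(d[i, j], abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_six_taxon_matrices_match_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0.1, 1.0, size=(6, 6))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"t{i}" for i in range(6)]
        assert nj_tree(d, labels) == naive_nj(d.tolist(), labels)

    def test_permutation_invariance_up_to_isomorphism(self):
        labels = ["A", "B", "C", "D", "E"]
        d = np.array(
            [
                [0, 5, 9, 9, 8],
                [5, 0, 10, 10, 9],
                [9, 10, 0, 8, 7],
                [9, 10, 8, 0, 3],
                [8, 9, 7, 3, 0],
            ],
            float,
        )
        perm = [2, 0, 4, 1, 3]
        d2 = d[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        _, paths1 = tree_distances_from_newick(nj_tree(d, labels))
        _, paths2 = tree_distances_from_newick(nj_tree(d2, labels2))
        assert paths1.keys() == paths2.keys()
        for key in paths1:
            assert paths1[key] == pytest.approx(paths2[key], abs=1e-9)

    def test_negative_branch_clamped_to_zero(self):
        # a non-additive matrix known to produce a negative NJ branch
        d = np.array(
            [[0, 1, 10, 10], [1, 0, 10, 10], [10, 10, 0, 0.1], [10, 10, 0.1, 0]],
            float,
        )
        newick = nj_tree(d, ["a", "b", "c", "d"])
        assert "-" not in newick.replace("e-", "")  # no negative lengths

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            nj_tree(d, ["a", "b", "c"])

    def test_agreement_with_skbio_on_additive_matrix(self):
        """Cross-check against the established scikit-bio implementation
        (identical leaf-path metric on an additive matrix)."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        labels = ["A", "B", "C", "D", "E"]
        d = np.array(
            [
                [0, 5, 9, 9, 8],
                [5, 0, 10, 10, 9],
                [9, 10, 0, 8, 7],
                [9, 10, 8, 0, 3],
                [8, 9, 7, 3, 0],
            ],
            float,
        )
        ours = tree_distances_from_newick(nj_tree(d, labels))[1]
        theirs_tree = skbio_nj(DistanceMatrix(d, labels))
        for a in labels:
            for b in labels:
                if a == b:
                    continue
                theirs = theirs_tree.find(a).distance(theirs_tree.find(b))
                assert ours[(a, b)] == pytest.approx(theirs, abs=1e-9)


@pytest.fixture(scope="module")
def references():
    return {f"ref_{fam}": (fam, seq) for fam, seq in family_templates().items()}


class TestAssignFamily:
    def test_reference_maps_to_its_own_family(self, references):
        for ref_id, (fam, seq) in references.items():
            a = assign_family(ref_id, seq, references)
            assert a.family == fam
            assert a.distance == 0.0

    def test_accuracy_on_mutated_families(self, references):
        queries = synth_brd_sequences(n_per_family=6, mutation_rate=0.15, seed=11)
        correct = sum(
            assign_family(sid, seq, references).family == fam
            for sid, fam, seq in queries
        )
        assert correct / len(queries) >= 0.95

    def test_shipped_reference_set_spans_eight_families(self, references):
        assert distinct_families(references) == 8

    def test_distant_query_unassigned(self, references):
        a = assign_family("junk", "G" * 110, references, cutoff=0.6)
        assert a.family == "unassigned"

    def test_grafted_tree_contains_query(self, references):
        small = {k: references[k] for k in list(references)[:4]}
        _, fam, seq = synth_brd_sequences(n_per_family=1, seed=1)[0]
        a = assign_family("query", seq, small, with_tree=True)
        assert a.tree is not None and "query" in a.tree


class TestMotifPattern:
    def test_variants_expand_insertions(self):
        pattern = next(p for p in default_patterns() if p.name == "alphaZ")
        assert len(pattern.variants()) == 16  # 4 x 4 insertion lengths

    def test_too_short_pattern_rejected(self):
        with pytest.raises(ValueError):
            MotifPattern("bad", ("any", "any"))
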