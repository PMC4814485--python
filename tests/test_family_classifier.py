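import io
import itertools
import random

import numpy as np
import pytest
import skbio

from aqpfam.alignment import GAP_EXTEND, GAP_OPEN, blosum62
from aqpfam.family_classifier import (
    SubfamilyAssignment,
    assign_subfamily,
    assign_systematic_names,
    build_nj_tree,
    pairwise_similarity,
)
from aqpfam.synthetic_data import TEMPLATES, mutate_copy, subgroup_base_sequence

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# brute-force affine-gap alignment oracle for tiny sequences


def _enumerate_alignments(a, b):
    """All gapped alignments of two short strings as (colsA, colsB)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ca, cb in _enumerate_alignments(a[1:], b):
            yield a[0] + ca, "-" + cb
    if b:
        for ca, cb in _enumerate_alignments(a, b[1:]):
            yield "-" + ca, b[0] + cb
    if a and b:
        for ca, cb in _enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ca, b[0] + cb


def _affine_score(ca, cb, matrix):
    score, gap_a, gap_b = 0.0, False, False
    for x, y in zip(ca, cb):
        if x == "-":
            score -= GAP_EXTEND if gap_a else GAP_OPEN + GAP_EXTEND
            gap_a, gap_b = True, False
        elif y == "-":
            score -= GAP_EXTEND if gap_b else GAP_OPEN + GAP_EXTEND
            gap_b, gap_a = True, False
        else:
            score += matrix[x, y]
            gap_a = gap_b = False
    return score


def _similarity_of(ca, cb, matrix):
    start, end = 0, len(ca)
    while start < end and (ca[start] == "-" or cb[start] == "-"):
        start += 1
    while end > start and (ca[end - 1] == "-" or cb[end - 1] == "-"):
        end -= 1
    if end <= start:
        return 0.0
    positive = sum(
        1
        for i in range(start, end)
        if ca[i] != "-" and cb[i] != "-" and matrix[ca[i], cb[i]] > 0
    )
    return 100.0 * positive / (end - start)


class TestPairwiseSimilarity:
    def test_identical_sequences_are_100(self):
        seq = "MSKEEVVSGAQSRDYHDPPPAGLWSFVAEFIATLLFVFAGV"
        assert pairwise_similarity(seq, seq) == 100.0
        assert pairwise_similarity("A", "A") == 100.0

    def test_symmetry(self):
        rng = random.Random(1)
        for _ in range(5):
            a = "".join(rng.choice(AA) for _ in range(60))
            b = "".join(rng.choice(AA) for _ in range(55))
            assert pairwise_similarity(a, b) == pytest.approx(
                pairwise_similarity(b, a)
            )

    def test_single_nonpositive_substitution(self):
        # A->G scores 0 in BLOSUM62: 5 positive pairs over 6 columns
        assert pairwise_similarity("ACDEFG", "GCDEFG") == pytest.approx(
            100 * 5 / 6
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_similarity("", "ACD")

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_alignment_oracle(self, seed):
        rng = random.Random(seed)
        a = "".join(rng.choice(AA) for _ in range(5))
        b = "".join(rng.choice(AA) for _ in range(6))
        matrix = blosum62()
        best = max(
            _enumerate_alignments(a, b),
            key=lambda cols: _affine_score(*cols, matrix),
        )
        best_score = _affine_score(*best, matrix)
        optimal_sims = {
            round(_similarity_of(ca, cb, matrix), 9)
            for ca, cb in _enumerate_alignments(a, b)
            if abs(_affine_score(ca, cb, matrix) - best_score) < 1e-9
        }
        assert round(pairwise_similarity(a, b), 9) in optimal_sims


class TestAssignSubfamily:
    def test_exact_panel_copy_gets_its_labels(self, panel):
        ref = panel[0]
        a = assign_subfamily("q", ref.seq, panel)
        assert (a.subfamily, a.subgroup) == (ref.subfamily, ref.subgroup)
        assert a.similarity == 100.0
        assert a.margin > 0

    def test_planted_truth_recovery_at_30pct_divergence(self, panel):
        rng = np.random.default_rng(7)
        groups = list(TEMPLATES)
        hits = 0
        for rep in range(20):
            sg = groups[rep % len(groups)]
            query, _ = mutate_copy(subgroup_base_sequence(sg), rng, 0.30)
            a = assign_subfamily(f"q{rep}", query, panel)
            hits += a.subfamily == TEMPLATES[sg].subfamily
        assert hits >= 19

    def test_random_protein_is_unclassified(self, panel):
        rng = random.Random(23)
        query = "".join(rng.choice(AA) for _ in range(250))
        a = assign_subfamily("rand", query, panel)
        assert not a.classified
        assert a.subfamily is None

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            assign_subfamily("q", "MKV" * 40, [])


# ---------------------------------------------------------------------------
# neighbor joining


def _path_lengths(newick, ids):
    tree = skbio.TreeNode.read(io.StringIO(newick))
    return {
        (x, y): tree.find(x).distance(tree.find(y))
        for x, y in itertools.combinations(ids, 2)
    }


def _random_additive_matrix(seed, n):
    """Distances induced by a random binary tree with positive lengths."""
    rng = random.Random(seed)
    dist = {}
    # iteratively join random clusters, tracking leaf depths
    depth = {f"t{i}": 0.0 for i in range(n)}
    clusters = [[f"t{i}"] for i in range(n)]
    while len(clusters) > 1:
        i, j = rng.sample(range(len(clusters)), 2)
        li, lj = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        for leaf in clusters[i]:
            depth[leaf] += li
        for leaf in clusters[j]:
            depth[leaf] += lj
        for x in clusters[i]:
            for y in clusters[j]:
                dist[frozenset((x, y))] = depth[x] + depth[y]
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    ids = sorted(depth)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = dist[frozenset((ids[a], ids[b]))]
    return ids, d


class TestNeighborJoining:
    def test_quartet_topology_recovered(self):
        # additive matrix of ((A:1,B:2):1,(C:3,D:1))
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        newick = build_nj_tree(ids, d)
        tree = skbio.TreeNode.read(io.StringIO(newick))
        # least-squares brute force over the three quartet topologies picks
        # AB|CD: verify our tree induces that split
        ab = tree.lca([tree.find("A"), tree.find("B")])
        assert {t.name for t in ab.tips()} in ({"A", "B"}, {"C", "D"})
        assert _path_lengths(newick, ids) == pytest.approx(
            {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 3,
             ("B", "C"): 6, ("B", "D"): 4, ("C", "D"): 4}
        )

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        newick = build_nj_tree(["A", "B", "C"], d)
        lengths = _path_lengths(newick, ["A", "B", "C"])
        # (d_AB + d_AC - d_BC)/2 = 1, etc.
        assert lengths[("A", "B")] == pytest.approx(3)
        assert lengths[("A", "C")] == pytest.approx(4)
        assert lengths[("B", "C")] == pytest.approx(5)

    def test_ultrametric_five_taxa_reproduced_exactly(self):
        ids, d = _random_additive_matrix(5, 5)
        newick = build_nj_tree(ids, d)
        lengths = _path_lengths(newick, ids)
        for (x, y), value in lengths.items():
            i, j = ids.index(x), ids.index(y)
            assert abs(value - d[i, j]) < 1e-9

    @pytest.mark.parametrize("seed,n", [(0, 6), (1, 8), (2, 10), (3, 7)])
    def test_additive_matrices_path_lengths_exact(self, seed, n):
        ids, d = _random_additive_matrix(seed, n)
        lengths = _path_lengths(build_nj_tree(ids, d), ids)
        for (x, y), value in lengths.items():
            assert abs(value - d[ids.index(x), ids.index(y)]) < 1e-9

    def test_agrees_with_independent_nj_implementation(self):
        ids, d = _random_additive_matrix(9, 7)
        ours = _path_lengths(build_nj_tree(ids, d), ids)
        theirs_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
        for (x, y), value in ours.items():
            assert value == pytest.approx(
                theirs_tree.find(x).distance(theirs_tree.find(y)), abs=1e-6
            )

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            build_nj_tree(["A", "B", "C"],
                          np.array([[0, 1, 2], [9, 0, 3], [2, 3, 0]], float))
        with pytest.raises(ValueError, match="3 taxa"):
            build_nj_tree(["A", "B"], np.zeros((2, 2)))


class TestSystematicNames:
    @staticmethod
    def _assignment(qid, subgroup, similarity=90.0):
        subfamily = "".join(ch for ch in subgroup if not ch.isdigit())
        return SubfamilyAssignment(qid, subfamily, subgroup, "ref", similarity, 5.0)

    def test_single_member_gets_index_one(self):
        names = assign_systematic_names([self._assignment("q", "PIP1")])
        assert names["q"] == "PIP1;1"

    def test_ortholog_hints_fix_the_order(self):
        assignments = [
            self._assignment("g_late", "TIP2", similarity=99.0),
            self._assignment("g_early", "TIP2", similarity=80.0),
        ]
        hints = {"g_early": "HbTIP2;1", "g_late": "HbTIP2;3"}
        names = assign_systematic_names(assignments, hints)
        assert names == {"g_early": "TIP2;1", "g_late": "TIP2;2"}

    def test_unclassified_query_keeps_no_name(self):
        unknown = SubfamilyAssignment("u", None, None, None, 10.0, 0.0)
        names = assign_systematic_names([unknown])
        assert names["u"] is None

    def test_species_prefix(self):
        names = assign_systematic_names(
            [self._assignment("q", "NIP2")], species_prefix="Jc"
        )
        assert names["q"] == "JcNIP2;1"
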