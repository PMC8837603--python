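import random
import re

import numpy as np
import pytest

from npstpipe import phylogeny

OTHER = {"A": "C", "C": "G", "G": "T", "T": "A"}


# ---------------------------------------------------------------------------
# independent oracles

def nw_oracle(a, b, match=1, mismatch=-1, gap=-2):
    """Plain quadratic Needleman-Wunsch, independent of the package code."""
    la, lb = len(a), len(b)
    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        H[i][0] = gap * i
    for j in range(1, lb + 1):
        H[0][j] = gap * j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
    return H[la][lb]


def aligned_score(row_a, row_b, match=1, mismatch=-1, gap=-2):
    score = 0.0
    for x, y in zip(row_a, row_b):
        if x == "-" and y == "-":
            continue
        if x == "-" or y == "-":
            score += gap
        else:
            score += match if x == y else mismatch
    return score


def parse_newick_leafsets(newick):
    """Tiny independent Newick reader: leaf sets of every internal node."""
    pos = 0

    def parse():
        nonlocal pos
        if newick[pos] == "(":
            pos += 1
            children = [parse()]
            while newick[pos] == ",":
                pos += 1
                children.append(parse())
            assert newick[pos] == ")"
            pos += 1
            # optional label / branch length
            m = re.match(r"[^,():;]*(:[^,();]+)?", newick[pos:])
            pos += m.end()
            leaves = frozenset().union(*children)
            internal.append(leaves)
            return leaves
        m = re.match(r"([^,():;]+)(:[^,();]+)?", newick[pos:])
        label = m.group(1)
        pos += m.end()
        return frozenset([label])

    internal = []
    root = parse()
    return root, internal


def brute_force_novel_clades(newick, label_class):
    all_leaves, internal = parse_newick_leafsets(newick)
    sides = set()
    for s in internal:
        if 0 < len(s) < len(all_leaves):
            sides.add(s)
            sides.add(all_leaves - s)
    cands = [
        s
        for s in sides
        if all(label_class[l] != "reference" for l in s)
        and sum(1 for l in s if label_class[l] == "npst") >= 2
    ]
    return {s for s in cands if not any(s < o for o in cands)}


def random_additive_tree(n, rng):
    """Random binary topology with positive branch lengths; returns
    (labels, distance matrix, set of non-trivial leaf bipartitions)."""
    labels = [f"L{i}" for i in range(n)]
    active = list(range(n))
    # build by random joins, tracking leaf-to-leaf path lengths directly
    D = {(lab, lab): 0.0 for lab in labels}
    members = {i: [labels[i]] for i in range(n)}
    depth = {lab: 0.0 for lab in labels}  # distance from leaf up to its current cluster root
    splits = set()
    nxt = n
    while len(active) > 1:
        i, j = rng.sample(active, 2)
        li = round(rng.uniform(0.05, 0.5), 3)
        lj = round(rng.uniform(0.05, 0.5), 3)
        for a in members[i]:
            for b in members[j]:
                D[(a, b)] = D[(b, a)] = depth[a] + li + depth[b] + lj
        for a in members[i]:
            depth[a] += li
        for b in members[j]:
            depth[b] += lj
        members[nxt] = members[i] + members[j]
        if 2 <= len(members[nxt]) <= n - 2:
            splits.add(frozenset(members[nxt]))
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    M = np.array([[D[(a, b)] for b in labels] for a in labels])
    return labels, M, splits


# ---------------------------------------------------------------------------

class TestAlignProgressive:
    def test_identical_pair_gap_free(self):
        aln = phylogeny.align_progressive([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        assert [s for _, s in aln.rows] == ["ACGTACGT", "ACGTACGT"]

    def test_acgt_act_oracle(self):
        aln = phylogeny.align_progressive([("a", "ACGT"), ("b", "ACT")])
        rows = dict(aln.rows)
        assert len(rows["a"]) == 4
        assert rows["a"].count("-") + rows["b"].count("-") == 1
        # score of the produced alignment equals the exhaustive DP optimum
        assert aligned_score(rows["a"], rows["b"]) == nw_oracle("ACGT", "ACT")

    @pytest.mark.parametrize("seed", range(5))
    def test_pairwise_matches_dp_oracle(self, seed):
        rng = random.Random(seed)
        a = "".join(rng.choice("ACGT") for _ in range(40))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(30, 50)))
        aln = phylogeny.align_progressive([("a", a), ("b", b)])
        rows = dict(aln.rows)
        assert rows["a"].replace("-", "") == a
        assert rows["b"].replace("-", "") == b
        assert aligned_score(rows["a"], rows["b"]) == nw_oracle(a, b)

    def test_input_order_invariance(self):
        seqs = [("c", "ACGTAC"), ("a", "ACGTTC"), ("b", "AGGTAC")]
        aln1 = phylogeny.align_progressive(seqs)
        aln2 = phylogeny.align_progressive(list(reversed(seqs)))
        assert aln1.rows == aln2.rows

    def test_columns_at_least_max_length(self):
        seqs = [("a", "ACGTACGTAA"), ("b", "ACGT"), ("c", "ACGTACG")]
        aln = phylogeny.align_progressive(seqs)
        assert len(aln.rows[0][1]) >= 10

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            phylogeny.align_progressive([("a", "ACGT")])


class TestPDistance:
    def test_symmetry_and_zero_diagonal(self):
        aln = phylogeny.LabeledAlignment(
            [("a", "ACGT-A"), ("b", "ACTTCA"), ("c", "GGGT-A")], {}
        )
        labels, D = phylogeny.p_distance_matrix(aln)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_pairwise_deletion(self):
        aln = phylogeny.LabeledAlignment([("a", "AC-T"), ("b", "ACG-"), ("c", "ACGT")], {})
        labels, D = phylogeny.p_distance_matrix(aln)
        assert D[labels.index("a"), labels.index("b")] == 0.0  # only AC shared

    def test_no_shared_columns_raises(self):
        aln = phylogeny.LabeledAlignment(
            [("a", "AC--"), ("b", "--GT"), ("c", "ACGT")], {}
        )
        with pytest.raises(phylogeny.DistanceError):
            phylogeny.p_distance_matrix(aln)


def _branch_lengths(newick):
    return {
        m.group(1): float(m.group(2))
        for m in re.finditer(r"([A-Za-z0-9_]+):([0-9.eE+-]+)", newick)
    }


class TestNJTree:
    def test_three_taxon_closed_form(self):
        # constructed alignment with p-distances 0.2 / 0.3 / 0.4
        A = "ACGTACGTACGTACGTACGT"
        B, C = list(A), list(A)
        for i in range(4):
            B[i] = OTHER[A[i]]
        for i in (2, 3):
            C[i] = OTHER[OTHER[A[i]]]
        for i in range(4, 8):
            C[i] = OTHER[A[i]]
        aln = phylogeny.LabeledAlignment(
            [("A", A), ("B", "".join(B)), ("C", "".join(C))], {}
        )
        labels, D = phylogeny.p_distance_matrix(aln)
        assert D[0, 1] == pytest.approx(0.2)
        assert D[0, 2] == pytest.approx(0.3)
        assert D[1, 2] == pytest.approx(0.4)
        bl = _branch_lengths(phylogeny.nj_tree(aln))
        assert bl["A"] == pytest.approx((0.2 + 0.3 - 0.4) / 2)
        assert bl["B"] == pytest.approx((0.2 + 0.4 - 0.3) / 2)
        assert bl["C"] == pytest.approx((0.3 + 0.4 - 0.2) / 2)

    def test_four_taxon_additive_recovery(self):
        labels = ["A", "B", "C", "D"]
        # tree ((A:1,B:2):3,(C:4,D:5)) scaled by 1/20
        raw = {
            ("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
            ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9,
        }
        D = np.zeros((4, 4))
        for (a, b), v in raw.items():
            D[labels.index(a), labels.index(b)] = v / 20
            D[labels.index(b), labels.index(a)] = v / 20
        newick = phylogeny.nj_from_distances(labels, D)
        _, internal = parse_newick_leafsets(newick)
        splits = {s for s in internal if 1 < len(s) < 4}
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits
        bl = _branch_lengths(newick)
        assert bl["A"] == pytest.approx(1 / 20)
        assert bl["B"] == pytest.approx(2 / 20)

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrix_topology_recovery(self, seed):
        rng = random.Random(seed)
        n = rng.randint(4, 8)
        labels, D, true_splits = random_additive_tree(n, rng)
        newick = phylogeny.nj_from_distances(labels, D)
        all_leaves, internal = parse_newick_leafsets(newick)
        got = set()
        for s in internal:
            if 1 < len(s) < n:
                got.add(min(s, all_leaves - s, key=sorted))
        expected = {min(s, frozenset(labels) - s, key=sorted) for s in true_splits}
        assert expected <= got

    def test_identical_pair_zero_pendants(self):
        aln = phylogeny.LabeledAlignment(
            [("A", "ACGTACGT"), ("B", "ACGTACGT"), ("C", "GCTAGCTA")], {}
        )
        newick = phylogeny.nj_tree(aln)
        bl = _branch_lengths(newick)
        assert bl["A"] == pytest.approx(0.0)
        assert bl["B"] == pytest.approx(0.0)

    def test_fewer_than_three_rejected(self):
        aln = phylogeny.LabeledAlignment([("a", "AC"), ("b", "AC")], {})
        with pytest.raises(ValueError):
            phylogeny.nj_tree(aln)


class TestCallNovelClades:
    def test_metagenome_only_cherry(self):
        lc = {"n1": "npst", "n2": "npst", "r1": "reference", "r2": "reference"}
        calls = phylogeny.call_novel_clades("((n1:1,n2:1):1,(r1:1,r2:1):1);", lc)
        assert [set(c.clade_leaves) for c in calls] == [{"n1", "n2"}]
        assert calls[0].is_novel

    def test_mixed_cherries_no_calls(self):
        lc = {"n1": "npst", "n2": "npst", "r1": "reference", "r2": "reference"}
        calls = phylogeny.call_novel_clades("((n1:1,r1:1):1,(n2:1,r2:1):1);", lc)
        assert calls == []

    @pytest.mark.parametrize("seed", range(8))
    def test_random_trees_match_bipartition_oracle(self, seed):
        rng = random.Random(seed)
        n = 12
        labels, _, _ = random_additive_tree(n, rng)
        # build a random newick over the labels
        items = [f"{lab}:1" for lab in labels]
        while len(items) > 3:
            i, j = sorted(rng.sample(range(len(items)), 2), reverse=True)
            a, b = items.pop(i), items.pop(j)
            items.append(f"({a},{b}):1")
        newick = f"({items[0]},{items[1]},{items[2]});"
        lc = {lab: ("npst" if rng.random() < 0.5 else "reference") for lab in labels}
        got = {c.clade_leaves for c in phylogeny.call_novel_clades(newick, lc)}
        assert got == brute_force_novel_clades(newick, lc)

    def test_rotation_and_reroot_invariance(self):
        import dendropy

        lc = {
            "n1": "npst", "n2": "npst", "n3": "npst",
            "r1": "reference", "r2": "reference",
        }
        newick = "(((n1:1,n2:1):1,n3:1):1,(r1:1,r2:1):1);"
        base = {c.clade_leaves for c in phylogeny.call_novel_clades(newick, lc)}
        tree = dendropy.Tree.get(data=newick, schema="newick")
        node = tree.find_node_with_taxon_label("r1").parent_node
        tree.reroot_at_node(node)
        rerooted = tree.as_string(schema="newick").strip()
        assert {
            c.clade_leaves for c in phylogeny.call_novel_clades(rerooted, lc)
        } == base

    def test_unlabeled_class_rejected(self):
        with pytest.raises(ValueError):
            phylogeny.call_novel_clades("((a:1,b:1):1,c:1);", {"a": "npst"})
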