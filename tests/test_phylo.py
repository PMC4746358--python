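"""Block selection, distances, neighbor joining, bootstrap, classification."""

import numpy as np
import pytest

from photocoord.phylo import (
    BlockSelectionParams,
    TreeNode,
    UndefinedDistanceError,
    bipartitions,
    bootstrap_supports,
    canonical_split,
    classify_by_clade,
    neighbor_joining,
    nj_tree,
    p_distance_matrix,
    parse_newick,
    select_conserved_blocks,
)
from photocoord.types import MultipleAlignment


def _aln(rows, ids=None, labels=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return MultipleAlignment(ids, rows, labels)


# ---------------------------------------------------------------------------
# block selection

def _oracle_blocks(aln, params):
    """Independent oracle: label each column, drop gap columns and long
    non-conserved runs, trim to flank, filter by length."""
    from collections import Counter

    ncol = aln.n_columns
    labels = []
    for j in range(ncol):
        col = aln.column(j)
        if "-" in col or "N" in col:
            labels.append("G")
            continue
        modal = Counter(col).most_common(1)[0][1]
        if modal >= params.min_seqs_flank:
            labels.append("F")
        elif modal >= params.min_seqs_conserved:
            labels.append("C")
        else:
            labels.append("N")
    keep = [lab != "G" for lab in labels]
    j = 0
    while j < ncol:
        if labels[j] == "N":
            k = j
            while k < ncol and labels[k] == "N":
                k += 1
            if k - j > params.max_contig_nonconserved:
                for t in range(j, k):
                    keep[t] = False
            j = k
        else:
            j += 1
    blocks = []
    j = 0
    while j < ncol:
        if not keep[j]:
            j += 1
            continue
        k = j
        while k < ncol and keep[k]:
            k += 1
        cols = list(range(j, k))
        while cols and labels[cols[0]] != "F":
            cols.pop(0)
        while cols and labels[cols[-1]] != "F":
            cols.pop()
        if len(cols) >= params.min_block_length:
            blocks.append((cols[0], cols[-1] + 1))
        j = k
    return blocks


class TestBlockSelection:
    def test_fully_conserved_alignment_is_one_block(self):
        aln = _aln(["ACGTACGTACGT"] * 15)
        assert select_conserved_blocks(aln) == [(0, 12)]

    def test_gap_column_splits_and_length_filter_removes(self):
        rows = ["ACGTA-CGTACGT"] * 15  # gap at column 5; fragments 5 and 7 < 10
        assert select_conserved_blocks(_aln(rows)) == []

    def test_long_nonconserved_run_splits_block(self):
        rng = np.random.default_rng(0)
        n, left, mid, right = 15, 15, 5, 15
        cols = []
        for _ in range(left):
            cols.append("A" * n)
        for _ in range(mid):  # modal count 15/4 < 8: non-conserved
            bases = "".join(rng.permutation(list("ACGT" * 4))[:n - 1]) + "A"
            cols.append(bases)
        for _ in range(right):
            cols.append("G" * n)
        rows = ["".join(c[i] for c in cols) for i in range(n)]
        aln = _aln(rows)
        params = BlockSelectionParams()
        got = select_conserved_blocks(aln, params)
        assert got == _oracle_blocks(aln, params)
        assert got == [(0, left), (left + mid, left + mid + right)]

    def test_matches_oracle_on_random_alignments(self):
        rng = np.random.default_rng(7)
        params = BlockSelectionParams()
        for _ in range(20):
            n, L = 15, 60
            base = rng.choice(list("ACGT"), size=L)
            rows = []
            for _ in range(n):
                row = base.copy()
                noisy = rng.random(L) < 0.25
                row[noisy] = rng.choice(list("ACGT-"), size=int(noisy.sum()))
                rows.append("".join(row))
            aln = _aln(rows)
            assert select_conserved_blocks(aln, params) == _oracle_blocks(aln, params)

    def test_invariant_to_sequence_order(self):
        rng = np.random.default_rng(8)
        base = rng.choice(list("ACGT"), size=40)
        rows = []
        for _ in range(15):
            row = base.copy()
            noisy = rng.random(40) < 0.2
            row[noisy] = rng.choice(list("ACGT"), size=int(noisy.sum()))
            rows.append("".join(row))
        fwd = select_conserved_blocks(_aln(rows))
        rev = select_conserved_blocks(_aln(rows[::-1]))
        assert fwd == rev

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            select_conserved_blocks(_aln(["ACGT"] * 5))


# ---------------------------------------------------------------------------
# distances

class TestPDistance:
    def test_identical_and_known(self):
        ids, D = p_distance_matrix(_aln(["ACGTACGTAC", "ACGTACGTGG", "ACGTACGTAC"]))
        assert D[0, 2] == 0.0
        assert D[0, 1] == pytest.approx(0.2)  # 2 mismatches / 10 sites

    def test_pairwise_deletion(self):
        # gap in one sequence removes the column for that pair only
        ids, D = p_distance_matrix(_aln(["ACGT", "A-GT", "TCGT"]))
        assert D[0, 1] == 0.0            # 3 comparable, 0 mismatches
        assert D[0, 2] == pytest.approx(0.25)

    def test_matches_per_site_loop_oracle(self):
        rng = np.random.default_rng(9)
        rows = [
            "".join(rng.choice(list("ACGT-N"), size=50)) for _ in range(6)
        ]
        aln = _aln(rows)
        try:
            ids, D = p_distance_matrix(aln)
        except UndefinedDistanceError:
            return
        for i in range(6):
            for j in range(6):
                comp = [
                    (a, b) for a, b in zip(rows[i], rows[j])
                    if a not in "-N" and b not in "-N"
                ]
                exp = sum(a != b for a, b in comp) / len(comp)
                assert D[i, j] == pytest.approx(exp)

    def test_no_comparable_sites_is_an_error(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance_matrix(_aln(["AC--", "--GT", "ACGT"]))


# ---------------------------------------------------------------------------
# neighbor joining

WORKED_D = np.array([
    [0, 3, 5, 6],
    [3, 0, 6, 7],
    [5, 6, 0, 7],
    [6, 7, 7, 0],
], dtype=float)


def _random_additive_tree(n_taxa, rng):
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.5, 2.0)))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[nodes[i], nodes[j]],
                          length=float(rng.uniform(0.5, 2.0)))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [merged]
    return TreeNode(children=nodes)


class TestNeighborJoining:
    def test_worked_four_taxon_matrix(self):
        tree = neighbor_joining(WORKED_D, ["A", "B", "C", "D"])
        lengths = {lf.name: lf.length for lf in tree.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        internal = [nd for nd in tree.walk() if not nd.is_leaf and nd is not tree]
        assert len(internal) == 1 and internal[0].length == pytest.approx(1.0)
        # topology (A,B | C,D)
        parts = set(bipartitions(tree).values())
        assert frozenset({"A", "B"}) in parts
        names, P = tree.path_length_matrix()
        order = [names.index(x) for x in ["A", "B", "C", "D"]]
        np.testing.assert_allclose(P[np.ix_(order, order)], WORKED_D, atol=1e-9)

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(D, ["A", "B", "C"])
        lengths = {lf.name: lf.length for lf in tree.leaves()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7])
    def test_reconstructs_additive_matrices_exactly(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(10):
            true_tree = _random_additive_tree(n_taxa, rng)
            names, D = true_tree.path_length_matrix()
            est = neighbor_joining(D, names)
            names2, P = est.path_length_matrix()
            assert names2 == names
            np.testing.assert_allclose(P, D, atol=1e-9)

    def test_agrees_with_skbio_topology(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(17)
        true_tree = _random_additive_tree(6, rng)
        names, D = true_tree.path_length_matrix()
        mine = neighbor_joining(D, names)
        ref = skbio_nj(DistanceMatrix(D, ids=names))
        all_leaves = frozenset(names)
        ref_parts = {
            canonical_split(frozenset(node.subset()), all_leaves)
            for node in ref.non_tips(include_self=False)
        }
        ref_parts = {p for p in ref_parts if 1 < len(p) < len(names) - 1}
        my_parts = {
            p for p in set(bipartitions(mine).values())
            if 1 < len(p) < len(names) - 1
        }
        assert my_parts == ref_parts

    def test_bad_matrices_rejected(self):
        from photocoord.phylo import MatrixError

        with pytest.raises(MatrixError):
            neighbor_joining(np.array([[0, 1], [1, 0]], dtype=float), ["a", "b"])
        bad = WORKED_D.copy()
        bad[0, 1] = 99
        with pytest.raises(MatrixError):
            neighbor_joining(bad, list("ABCD"))
        neg = WORKED_D.copy()
        neg[0, 1] = neg[1, 0] = -1
        with pytest.raises(MatrixError):
            neighbor_joining(neg, list("ABCD"))


# ---------------------------------------------------------------------------
# bootstrap + classification

def _two_clade_alignment(n_fixed=50, length=1000, seed=0):
    """Two 4-leaf clades separated by n_fixed fixed differences."""
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), size=length)
    other = base.copy()
    idx = rng.choice(length, size=n_fixed, replace=False)
    for i in idx:
        other[i] = "ACGT"[("ACGT".index(base[i]) + 1) % 4]
    rows, ids = [], []
    for k in range(4):
        for name, seq in (("L", base), ("R", other)):
            row = seq.copy()
            noisy = rng.choice(length, size=3, replace=False)  # light noise
            for i in noisy:
                row[i] = "ACGT"[("ACGT".index(row[i]) + 1 + k) % 4]
            rows.append("".join(row))
            ids.append(f"{name}{k}")
    return MultipleAlignment(ids, rows)


class TestBootstrap:
    def test_strong_split_gets_high_support(self):
        aln = _two_clade_alignment()
        tree = bootstrap_supports(aln, n_reps=200, seed=5)
        parts = bipartitions(tree)
        left = frozenset({"L0", "L1", "L2", "L3"})
        supports = {
            node.support
            for node in tree.walk()
            if id(node) in parts and parts[id(node)] == left
        }
        assert supports and min(supports) >= 99

    def test_zero_reps_means_no_supports(self):
        tree = bootstrap_supports(_two_clade_alignment(), n_reps=0, seed=0)
        assert all(nd.support is None for nd in tree.walk())

    def test_deterministic_under_seed(self):
        aln = _two_clade_alignment()
        t1 = bootstrap_supports(aln, n_reps=50, seed=3)
        t2 = bootstrap_supports(aln, n_reps=50, seed=3)
        assert t1.to_newick() == t2.to_newick()


class TestClassification:
    def test_query_joins_reference_clade(self):
        aln = _two_clade_alignment()
        tree = bootstrap_supports(aln, n_reps=100, seed=1)
        labels = {"L0": "C4_ref", "L1": "C4_ref", "R0": "cytosolic_ref",
                  "R1": "cytosolic_ref"}
        classes = classify_by_clade(tree, labels)
        assert classes["L2"] == "C4"
        assert classes["L3"] == "C4"
        assert classes["R2"] == "cytosolic"

    def test_conflicting_references_leave_query_unclassified(self):
        # star-ish tree where the only supported clade holds both classes
        tree = parse_newick("((q:0.1,(a:0.1,b:0.1)100:0.1)100:0.1,c:0.1,d:0.1);")
        labels = {"a": "C4_ref", "b": "cytosolic_ref"}
        classes = classify_by_clade(tree, labels)
        assert classes["q"] == "unclassified"
        assert classes["c"] == "unclassified" and classes["d"] == "unclassified"

    def test_simulated_families_classified_correctly(self):
        """Deep reference clades => >= 95% correct over seeds."""
        from photocoord.pipeline import _demo_reference_tree
        from photocoord.simulate import SeqSimConfig, simulate_alignment

        correct = total = 0
        for seed in range(20):
            tree0 = _demo_reference_tree(n_queries=3, ref_class="C4", n_refs=2)
            aln = simulate_alignment(SeqSimConfig(tree=tree0, seq_length=1200, seed=seed))
            labels = {}
            for leaf in aln.leaf_ids:
                if leaf.startswith("C4_ref"):
                    labels[leaf] = "C4_ref"
                elif leaf.startswith("cyto_ref"):
                    labels[leaf] = "cytosolic_ref"
            tree = bootstrap_supports(aln, n_reps=100, seed=seed + 1)
            classes = classify_by_clade(tree, labels)
            for leaf, cls in classes.items():
                want = "C4" if leaf.startswith("C4_query") else "cytosolic"
                total += 1
                correct += cls == want
        assert correct / total >= 0.95


class TestNewick:
    def test_round_trip_through_dendropy(self):
        tree = neighbor_joining(WORKED_D, list("ABCD"))
        text = tree.to_newick()
        back = parse_newick(text)
        assert sorted(back.leaf_names()) == list("ABCD")
        names, P = back.path_length_matrix()
        order = [names.index(x) for x in "ABCD"]
        np.testing.assert_allclose(P[np.ix_(order, order)], WORKED_D, atol=1e-9)
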