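"""Conserved-block selection, distances, neighbor joining and clade classification.

This stage mirrors the classical candidate-gene workflow: trim a nucleotide
alignment to its conserved blocks, compute pairwise p-distances with pairwise
deletion, build an unrooted neighbor-joining tree, attach bootstrap supports,
and classify unlabeled transcripts by the smallest well-supported clade they
share with reference leaves (C4 orthologs, plastid-targeted Calvin-cycle
enzymes, or cytosolic paralogs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import MultipleAlignment


class UndefinedDistanceError(ValueError):
    """A sequence pair shares no comparable (gap-free, unambiguous) site."""


class MatrixError(ValueError):
    """Distance matrix is not symmetric/non-negative/zero-diagonal."""


# ---------------------------------------------------------------------------
# tree structure

@dataclass
class TreeNode:
    """Node of an unrooted tree stored with an arbitrary (trifurcating) root.

    ``length`` is the branch length of the edge above the node; ``support``
    is the integer bootstrap percentage of that edge (internal edges only).
    """

    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self) -> str:
        return _newick(self) + ";"

    def path_length_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path lengths (tree metric)."""
        names = sorted(self.leaf_names())
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        D = np.zeros((n, n))

        def below(node):
            # returns {leaf: distance to node}; fills D across child subtrees
            if node.is_leaf:
                return {node.name: 0.0}
            acc: dict[str, float] = {}
            for child in node.children:
                sub = {k: v + child.length for k, v in below(child).items()}
                for a, da in acc.items():
                    for b, db in sub.items():
                        D[idx[a], idx[b]] = D[idx[b], idx[a]] = da + db
                acc.update(sub)
            return acc

        below(self)
        return names, D


def _newick(node: TreeNode) -> str:
    if node.is_leaf:
        return f"{node.name}:{node.length:.10g}"
    inner = ",".join(_newick(c) for c in node.children)
    label = "" if node.support is None else str(int(node.support))
    return f"({inner}){label}:{node.length:.10g}"


def parse_newick(text: str) -> TreeNode:
    """Parse a newick string (integer internal labels read as supports)."""
    import dendropy

    dt = dendropy.Tree.get(
        data=text, schema="newick",
        suppress_internal_node_taxa=True, suppress_leaf_node_taxa=False,
    )

    def convert(dnode) -> TreeNode:
        name = dnode.taxon.label if dnode.taxon else (dnode.label or None)
        node = TreeNode(
            name=name if dnode.is_leaf() else None,
            length=dnode.edge.length or 0.0,
        )
        if not dnode.is_leaf() and name is not None:
            try:
                node.support = int(name)
            except ValueError:
                pass
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return convert(dt.seed_node)


def bipartitions(tree: TreeNode) -> dict[int, frozenset[str]]:
    """Canonical leaf-set bipartition of every internal edge.

    Keys are ``id(node)`` of the child node below the edge; values are the
    canonical side (smaller side; lexicographic tie-break) as a frozenset.
    """
    all_leaves = frozenset(tree.leaf_names())
    out: dict[int, frozenset[str]] = {}
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        out[id(node)] = canonical_split(side, all_leaves)
    return out


def canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    comp = all_leaves - side
    key_a = (len(side), tuple(sorted(side)))
    key_b = (len(comp), tuple(sorted(comp)))
    return side if key_a <= key_b else comp


# ---------------------------------------------------------------------------
# conserved-block selection (Gblocks-style stringent criteria)

@dataclass(frozen=True)
class BlockSelectionParams:
    """Stringent block-selection thresholds.

    ``min_seqs_conserved`` (IS) and ``min_seqs_flank`` (FS) are minimum counts
    of the modal residue for a column to rate conserved / flank;
    ``max_contig_nonconserved`` (CP) caps runs of non-conserved columns inside
    a block; ``min_block_length`` (BL) is the minimum block width; no gap
    positions are allowed.
    """

    min_seqs_conserved: int = 8
    min_seqs_flank: int = 12
    max_contig_nonconserved: int = 4
    min_block_length: int = 10

    def __post_init__(self):
        if self.min_seqs_flank < self.min_seqs_conserved:
            raise ValueError("flank threshold must be >= conserved threshold")
        if self.min_block_length < 1:
            raise ValueError("min_block_length must be >= 1")


GAP_CHARS = set("-N")


def _column_status(column: str, params: BlockSelectionParams) -> str:
    """'gap', 'flank', 'conserved' or 'nonconserved' for one column."""
    if any(c in GAP_CHARS for c in column):
        return "gap"
    counts: dict[str, int] = {}
    for c in column:
        counts[c] = counts.get(c, 0) + 1
    modal = max(counts.values())
    if modal >= params.min_seqs_flank:
        return "flank"
    if modal >= params.min_seqs_conserved:
        return "conserved"
    return "nonconserved"


def select_conserved_blocks(
    aln: MultipleAlignment, params: BlockSelectionParams = BlockSelectionParams()
) -> list[tuple[int, int]]:
    """Retained column intervals, 0-based half-open.

    A block is a maximal run with no gap column and no run of more than CP
    contiguous non-conserved columns, trimmed so both ends are flank columns,
    and at least BL columns wide.
    """
    if aln.n_seqs < params.min_seqs_conserved:
        raise ValueError(
            f"{aln.n_seqs} sequences < conserved threshold {params.min_seqs_conserved}"
        )
    ncol = aln.n_columns
    status = [_column_status(aln.column(j), params) for j in range(ncol)]

    # drop gap columns and every column of a non-conserved run longer than CP
    drop = [st == "gap" for st in status]
    j = 0
    while j < ncol:
        if status[j] == "nonconserved":
            k = j
            while k < ncol and status[k] == "nonconserved":
                k += 1
            if k - j > params.max_contig_nonconserved:
                for t in range(j, k):
                    drop[t] = True
            j = k
        else:
            j += 1

    # remaining maximal runs of kept columns, trimmed to flank ends
    blocks: list[tuple[int, int]] = []
    j = 0
    while j < ncol:
        if drop[j]:
            j += 1
            continue
        k = j
        while k < ncol and not drop[k]:
            k += 1
        lo, hi = j, k - 1
        while lo <= hi and status[lo] != "flank":
            lo += 1
        while hi >= lo and status[hi] != "flank":
            hi -= 1
        if hi - lo + 1 >= params.min_block_length:
            blocks.append((lo, hi + 1))
        j = k
    return blocks


# ---------------------------------------------------------------------------
# distances

def p_distance_matrix(
    aln: MultipleAlignment, jukes_cantor: bool = False
) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distance with pairwise deletion of gap/N columns.

    With ``jukes_cantor=True`` applies d = -(3/4) ln(1 - 4p/3).
    """
    if aln.n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    seqs = np.array([list(r) for r in aln.rows])
    valid = ~np.isin(seqs, list(GAP_CHARS))
    n = aln.n_seqs
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise UndefinedDistanceError(
                    f"{aln.leaf_ids[i]} and {aln.leaf_ids[j]} share no comparable site"
                )
            p = float((seqs[i][both] != seqs[j][both]).sum()) / m
            if jukes_cantor:
                if p >= 0.75:
                    raise UndefinedDistanceError(
                        "p-distance >= 0.75: Jukes-Cantor correction undefined"
                    )
                p = -0.75 * math.log1p(-4.0 * p / 3.0)
            D[i, j] = D[j, i] = p
    return list(aln.leaf_ids), D


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(D: np.ndarray, labels: list[str]) -> TreeNode:
    """Saitou-Nei neighbor joining, returned as an unrooted tree with a
    trifurcating root.

    Negative branch lengths are clamped to zero with the deficit transferred
    to the sister branch.  Ties on the Q criterion break to the smallest
    (i, j) index pair in node-creation order.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise MatrixError("distance matrix / label shape mismatch")
    if n < 3:
        raise MatrixError("need at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-12):
        raise MatrixError("matrix not symmetric")
    if (D < 0).any():
        raise MatrixError("negative distances")
    if not np.allclose(np.diag(D), 0.0):
        raise MatrixError("nonzero diagonal")

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n) if i < j}

    def d(a: int, b: int) -> float:
        return 0.0 if a == b else dist[(a, b) if a < b else (b, a)]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d(a, b) for b in active) for a in active}
        best, best_q = None, math.inf
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        dab = d(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        if la < 0:
            lb, la = lb + la, 0.0
        if lb < 0:
            la, lb = la + lb, 0.0
        u = len(nodes)
        na, nb = nodes[a], nodes[b]
        na.length, nb.length = la, lb
        nodes.append(TreeNode(children=[na, nb]))
        for k in active:
            if k in (a, b):
                continue
            duk = 0.5 * (d(a, k) + d(b, k) - dab)
            dist[(min(u, k), max(u, k))] = max(duk, 0.0)
        active = [k for k in active if k not in (a, b)] + [u]

    # join the final three nodes at a trifurcating root (closed form)
    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    for k, lk in ((a, la), (b, lb), (c, lc)):
        nodes[k].length = max(lk, 0.0)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def nj_tree(aln: MultipleAlignment, jukes_cantor: bool = False) -> TreeNode:
    labels, D = p_distance_matrix(aln, jukes_cantor=jukes_cantor)
    return neighbor_joining(D, labels)


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_supports(
    aln: MultipleAlignment,
    n_reps: int = 500,
    seed: int = 0,
    jukes_cantor: bool = False,
) -> TreeNode:
    """NJ tree with integer bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; the support of an
    internal edge is the percentage of usable replicates whose NJ tree contains
    the same bipartition.  Replicates where some pair has no comparable site
    are skipped and counted.
    """
    tree = nj_tree(aln, jukes_cantor=jukes_cantor)
    if n_reps == 0:
        return tree
    rng = np.random.default_rng(seed)
    base_parts = bipartitions(tree)
    counts = {part: 0 for part in base_parts.values()}
    n_used = 0
    n_skipped = 0
    ncol = aln.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(r[j] for j in cols) for r in aln.rows]
        rep = MultipleAlignment(aln.leaf_ids, rows, aln.reference_labels)
        try:
            rep_tree = nj_tree(rep, jukes_cantor=jukes_cantor)
        except UndefinedDistanceError:
            n_skipped += 1
            continue
        n_used += 1
        rep_parts = set(bipartitions(rep_tree).values())
        for part in counts:
            if part in rep_parts:
                counts[part] += 1
    if n_skipped:
        import warnings

        warnings.warn(f"{n_skipped} bootstrap replicates skipped (undefined distances)")
    for node in tree.walk():
        key = id(node)
        if key in base_parts and n_used > 0:
            node.support = int(round(100.0 * counts[base_parts[key]] / n_used))
    return tree


# ---------------------------------------------------------------------------
# clade classification

_LABEL_TO_CLASS = {"C4_ref": "C4", "Calvin_ref": "Calvin", "cytosolic_ref": "cytosolic"}


def classify_by_clade(
    tree: TreeNode,
    reference_labels: dict[str, str],
    min_support: int = 50,
) -> dict[str, str]:
    """Assign each unlabeled leaf the class of the smallest supported clade it
    shares with references of a single class.

    A clade is either side of an internal-edge bipartition whose support is at
    least ``min_support``.  A side holding references of conflicting classes
    cannot classify; a query with no qualifying clade is 'unclassified'.
    """
    all_leaves = frozenset(tree.leaf_names())
    refs = {
        leaf: _LABEL_TO_CLASS[lab]
        for leaf, lab in reference_labels.items()
        if lab in _LABEL_TO_CLASS and leaf in all_leaves
    }
    queries = sorted(all_leaves - set(refs))
    if not refs:
        raise ValueError("no reference leaves on the tree")

    sides: list[frozenset[str]] = []
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        if node.support is None or node.support < min_support:
            continue
        side = frozenset(node.leaf_names())
        sides.append(side)
        sides.append(all_leaves - side)

    result: dict[str, str] = {}
    for q in queries:
        best: tuple[int, tuple, str] | None = None
        for side in sides:
            if q not in side:
                continue
            classes = {refs[r] for r in side if r in refs}
            if len(classes) != 1:
                continue
            key = (len(side), tuple(sorted(side)))
            if best is None or key < best[:2]:
                best = (key[0], key[1], classes.pop())
        result[q] = best[2] if best else "unclassified"
    return result


def terminal_branch_zscores(tree: TreeNode) -> dict[str, float]:
    """Z-score of each terminal branch length within the family.

    A descriptive statistic for 'remarkably long branch' candidates
    (accelerated evolution); never used to gate classification.
    """
    leaves = tree.leaves()
    lengths = np.array([lf.length for lf in leaves])
    mu, sd = lengths.mean(), lengths.std(ddof=1) if len(leaves) > 1 else 0.0
    if sd == 0:
        return {lf.name: 0.0 for lf in leaves}
    return {lf.name: float((lf.length - mu) / sd) for lf in leaves}
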