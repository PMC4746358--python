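"""Cluster-3.0-style preprocessing and centroid-linkage biclustering.

The preprocessing chain is log2 transform (zeros become missing), gene
median-centering, gene normalization (unit sum of squares per row), array
median-centering, array normalization.  Clustering is agglomerative centroid
linkage under correlation distance (1 - Pearson) on either axis, with
Cluster-3.0-compatible CDT/GTR/ATR text output.

Centroid linkage can produce height inversions (a merge lower than an earlier
one); nothing here assumes monotone heights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix

MAX_DISTANCE = 2.0  # 1 - (-1); also the sentinel for incomparable pairs


@dataclass
class PreprocessedMatrix:
    values: pd.DataFrame          # may contain NaN (missing)
    provenance: list[str] = field(default_factory=list)
    excluded_rows: list[str] = field(default_factory=list)
    excluded_cols: list[str] = field(default_factory=list)


def _log2_missing(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[out <= 0] = np.nan
    return np.log2(out)


def _center_rows_median(arr: np.ndarray) -> np.ndarray:
    med = np.nanmedian(arr, axis=1, keepdims=True)
    return arr - med


def _normalize_rows(arr: np.ndarray) -> np.ndarray:
    ss = np.nansum(arr ** 2, axis=1, keepdims=True)
    scale = np.sqrt(ss)
    scale[scale == 0] = 1.0  # zero-vector guard: leave zeros untouched
    return arr / scale


DEFAULT_STEPS = (
    "log2", "center_genes", "normalize_genes", "center_arrays", "normalize_arrays",
)


def preprocess(
    expr: ExpressionMatrix, steps: tuple[str, ...] = DEFAULT_STEPS
) -> PreprocessedMatrix:
    """log2 -> center genes (median) -> normalize genes -> center arrays
    (median) -> normalize arrays, ignoring missing cells throughout.

    FPKM = 0 becomes a missing value (log of zero), mirroring how the
    clustering software treats undetected expression.  Rows or columns that
    end up entirely missing are flagged and excluded.  ``steps`` selects a
    prefix/subset of the transform chain (same order as the default).
    """
    arr = expr.values.to_numpy(dtype=float).copy()
    provenance: list[str] = []
    transforms = {
        "log2": lambda a: _log2_missing(a),
        "center_genes": _center_rows_median,
        "normalize_genes": _normalize_rows,
        "center_arrays": lambda a: _center_rows_median(a.T).T,
        "normalize_arrays": lambda a: _normalize_rows(a.T).T,
    }
    unknown = set(steps) - set(transforms)
    if unknown:
        raise ValueError(f"unknown preprocessing steps {sorted(unknown)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for step in steps:
            arr = transforms[step](arr)
            provenance.append(step)

    df = pd.DataFrame(arr, index=expr.values.index, columns=expr.values.columns)
    excluded_rows = [t for t in df.index if df.loc[t].isna().all()]
    excluded_cols = [s for s in df.columns if df[s].isna().all()]
    return PreprocessedMatrix(df, provenance, excluded_rows, excluded_cols)


# ---------------------------------------------------------------------------
# centroid linkage

@dataclass
class Dendrogram:
    """Agglomeration record: leaves 0..n-1, internal nodes n..2n-2.

    ``merges`` lists (node_a, node_b, height, new_node) in merge order;
    heights are the distances actually used and need not be monotone.
    """

    item_ids: list[str]
    merges: list[tuple[int, int, float, int]]
    axis: str  # 'genes' or 'arrays'

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf order of the final tree."""
        children = {new: (a, b) for a, b, _, new in self.merges}
        roots = set(range(self.n_items)) | {m[3] for m in self.merges}
        for a, b, _, _ in self.merges:
            roots.discard(a)
            roots.discard(b)

        def expand(node: int) -> list[int]:
            if node < self.n_items:
                return [node]
            a, b = children[node]
            return expand(a) + expand(b)

        order: list[int] = []
        for r in sorted(roots):
            order.extend(expand(r))
        return order


def pearson_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - Pearson correlation over shared non-missing positions.

    Pairs with fewer than 2 shared positions, or with zero variance on the
    shared positions, are incomparable and get the maximal distance 2.
    """
    ok = ~(np.isnan(u) | np.isnan(v))
    if ok.sum() < 2:
        return MAX_DISTANCE
    a, b = u[ok], v[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return MAX_DISTANCE
    r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return 1.0 - max(-1.0, min(1.0, r))


def uncentered_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - uncentered correlation (cosine) over shared positions."""
    ok = ~(np.isnan(u) | np.isnan(v))
    if ok.sum() < 2:
        return MAX_DISTANCE
    a, b = u[ok], v[ok]
    na, nb = np.sqrt((a ** 2).sum()), np.sqrt((b ** 2).sum())
    if na == 0 or nb == 0:
        return MAX_DISTANCE
    return 1.0 - float((a * b).sum() / (na * nb))


def centroid_linkage(
    matrix: PreprocessedMatrix,
    axis: str = "genes",
    metric=pearson_distance,
) -> Dendrogram:
    """Agglomerative centroid linkage.

    Items are rows (``axis='genes'``) or columns (``axis='arrays'``); a merged
    cluster is represented by the element-wise mean of its member profiles
    (missing cells ignored).  The closest pair merges first; ties break to the
    smallest (i, j) node-index pair.
    """
    if axis == "genes":
        df = matrix.values.drop(index=matrix.excluded_rows)
        data = df.to_numpy(dtype=float)
        ids = list(df.index)
    elif axis == "arrays":
        df = matrix.values.drop(columns=matrix.excluded_cols)
        data = df.to_numpy(dtype=float).T
        ids = list(df.columns)
    else:
        raise ValueError(f"bad axis {axis!r}")
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")

    profiles: dict[int, np.ndarray] = {i: data[i] for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = list(range(n))
    dist: dict[tuple[int, int], float] = {}
    incomparable = 0
    for ii in range(n):
        for jj in range(ii + 1, n):
            d = metric(profiles[ii], profiles[jj])
            if d == MAX_DISTANCE:
                incomparable += 1
            dist[(ii, jj)] = d
    if incomparable:
        warnings.warn(f"{incomparable} item pairs incomparable; distance set to 2.0")

    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best, best_d = None, np.inf
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                d = dist[(a, b)]
                if d < best_d - 1e-15:
                    best_d, best = d, (a, b)
        a, b = best
        # centroid = element-wise mean over member profiles, missing ignored
        members[next_id] = members[a] + members[b]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            centroid = np.nanmean(data[members[next_id]], axis=0)
        profiles[next_id] = centroid
        merges.append((a, b, best_d, next_id))
        active = [k for k in active if k not in (a, b)]
        for k in active:
            dist[(min(k, next_id), max(k, next_id))] = metric(profiles[k], centroid)
        active.append(next_id)
        next_id += 1
    return Dendrogram(ids, merges, axis)


def cut_branches(dendro: Dendrogram, k: int) -> dict[str, int]:
    """Partition items into k branches by removing the k-1 top merges.

    The top merges are the last k-1 in agglomeration order; under monotone
    heights these are exactly the k-1 highest merges, and unlike a pure
    height criterion they still yield exactly k connected components when
    centroid linkage inverts.  Branches are numbered 1..k in leaf order.
    """
    n = dendro.n_items
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    n_merges = len(dendro.merges)
    removed = set(range(n_merges - (k - 1), n_merges))

    parent = list(range(n + len(dendro.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, _, new) in enumerate(dendro.merges):
        if i in removed:
            continue
        parent[find(a)] = find(new)
        parent[find(b)] = find(new)

    labels: dict[str, int] = {}
    branch_of_root: dict[int, int] = {}
    next_label = 1
    for leaf in dendro.leaf_order():
        root = find(leaf)
        if root not in branch_of_root:
            branch_of_root[root] = next_label
            next_label += 1
        labels[dendro.item_ids[leaf]] = branch_of_root[root]
    return labels


def site_separation_check(
    dendro_arrays: Dendrogram, site_of: dict[str, str]
) -> tuple[bool, float]:
    """Cut the array dendrogram at k=2 and score site purity.

    Purity is the best fraction of samples correctly grouped over the two
    possible branch-to-site assignments; returns (purity == 1, purity).
    """
    labels = cut_branches(dendro_arrays, 2)
    sites = sorted({site_of[s] for s in labels})
    if len(sites) != 2:
        raise ValueError("need exactly two sites")
    n = len(labels)
    match_a = sum(
        1 for s, br in labels.items()
        if (br == 1) == (site_of[s] == sites[0])
    )
    purity = max(match_a, n - match_a) / n
    return purity == 1.0, purity


# ---------------------------------------------------------------------------
# Cluster 3.0 text output (CDT / GTR / ATR)

def _node_names(dendro: Dendrogram, prefix: str) -> dict[int, str]:
    names = {}
    for i in range(dendro.n_items):
        names[i] = f"{prefix}{i}X"
    for j, (_, _, _, new) in enumerate(dendro.merges):
        names[new] = f"NODE{j + 1}X"
    return names


def write_tree_file(dendro: Dendrogram, path) -> None:
    """GTR/ATR format: NODEID, LEFT, RIGHT, CORRELATION (1 - height)."""
    prefix = "GENE" if dendro.axis == "genes" else "ARRY"
    names = _node_names(dendro, prefix)
    with open(path, "w") as fh:
        fh.write("NODEID\tLEFT\tRIGHT\tCORRELATION\n")
        for a, b, height, new in dendro.merges:
            fh.write(f"{names[new]}\t{names[a]}\t{names[b]}\t{1.0 - height:.6f}\n")


def write_cdt(
    matrix: PreprocessedMatrix,
    gene_dendro: Dendrogram | None,
    array_dendro: Dendrogram | None,
    path,
) -> None:
    """Clustered data table with GID/AID ids in dendrogram leaf order."""
    df = matrix.values
    gene_ids = list(df.index)
    array_ids = list(df.columns)
    if gene_dendro is not None:
        gene_ids = [gene_dendro.item_ids[i] for i in gene_dendro.leaf_order()]
    if array_dendro is not None:
        array_ids = [array_dendro.item_ids[i] for i in array_dendro.leaf_order()]
    gnames = _node_names(gene_dendro, "GENE") if gene_dendro else None
    anames = _node_names(array_dendro, "ARRY") if array_dendro else None
    gidx = {t: i for i, t in enumerate(gene_dendro.item_ids)} if gene_dendro else {}
    aidx = {s: i for i, s in enumerate(array_dendro.item_ids)} if array_dendro else {}
    with open(path, "w") as fh:
        header = ["GID", "NAME", "GWEIGHT"] + array_ids
        fh.write("\t".join(header) + "\n")
        if anames:
            fh.write("\t".join(["AID", "", ""] + [anames[aidx[s]] for s in array_ids]) + "\n")
        fh.write("\t".join(["EWEIGHT", "", ""] + ["1"] * len(array_ids)) + "\n")
        for t in gene_ids:
            gid = gnames[gidx[t]] if gnames else t
            vals = [
                "" if np.isnan(v) else f"{v:.6f}"
                for v in df.loc[t, array_ids].to_numpy(dtype=float)
            ]
            fh.write("\t".join([gid, t, "1"] + vals) + "\n")


def dendrogram_to_newick(dendro: Dendrogram) -> str:
    """Newick export; branch length of a child = parent height - child height
    (clamped at 0, since centroid linkage can invert)."""
    height = {i: 0.0 for i in range(dendro.n_items)}
    children = {}
    for a, b, h, new in dendro.merges:
        height[new] = h
        children[new] = (a, b)
    roots = set(range(dendro.n_items)) | set(children)
    for a, b, _, _ in dendro.merges:
        roots.discard(a)
        roots.discard(b)

    def render(node: int, parent_h: float) -> str:
        bl = max(parent_h - height[node], 0.0)
        if node < dendro.n_items:
            return f"{dendro.item_ids[node]}:{bl:.6g}"
        a, b = children[node]
        return f"({render(a, height[node])},{render(b, height[node])}):{bl:.6g}"

    root = sorted(roots)[-1]
    return render(root, height[root]) + ";"
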