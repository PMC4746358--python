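"""Candidate-transcript identification from homology hits.

Stage 1 of the pipeline: filter BLASTN-style hits on e-value and identity,
summarise per query-target pair coverage (union of aligned query intervals
over query length) and similarity (mean identity over hits), assign best
targets, and merge split transcripts — queries hitting disjoint stretches of
the same target are two assembly fragments of one gene, and their expression
is recalculated as the per-sample average of the parts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .types import ExpressionMatrix, HitRecord, MappingError


@dataclass(frozen=True)
class CandidateTranscript:
    transcript_id: str
    best_target_id: str
    coverage: float          # fraction of the query covered by hits, in [0,1]
    similarity: float        # mean percent identity over hits, in [0,100]
    merged_from: tuple[str, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage outside [0,1]")
        if not self.merged_from:
            object.__setattr__(self, "merged_from", (self.transcript_id,))


def filter_hits(
    hits: list[HitRecord],
    evalue_max: float = 1e-60,
    identity_min: float = 85.0,
) -> list[HitRecord]:
    """Keep hits with e_value <= evalue_max and identity >= identity_min."""
    return [
        h for h in hits
        if h.e_value <= evalue_max and h.percent_identity >= identity_min
    ]


def _interval_union_length(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by 1-based inclusive intervals (converted internally
    to 0-based half-open; this is the single conversion point)."""
    half_open = sorted((a - 1, b) for a, b in intervals)
    total, cur_lo, cur_hi = 0, None, None
    for lo, hi in half_open:
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        total += cur_hi - cur_lo
    return total


def pair_statistics(hits: list[HitRecord], query_length: int) -> tuple[float, float]:
    """(coverage, similarity) for all hits of one query-target pair.

    Coverage is the union of aligned query intervals divided by the query
    length (overlapping HSPs cannot push it past 1); similarity is the
    unweighted mean of percent identities.
    """
    if not hits:
        raise ValueError("need at least one hit")
    pairs = {(h.query_id, h.target_id) for h in hits}
    if len(pairs) != 1:
        raise ValueError(f"hits span multiple query-target pairs: {sorted(pairs)}")
    if query_length < 1:
        raise ValueError("query_length must be >= 1")
    max_pos = max(h.query_end for h in hits)
    if query_length < max_pos:
        raise ValueError(
            f"query_length {query_length} < max aligned position {max_pos}"
        )
    covered = _interval_union_length([(h.query_start, h.query_end) for h in hits])
    similarity = sum(h.percent_identity for h in hits) / len(hits)
    return covered / query_length, similarity


def best_hit_assignment(hits: list[HitRecord]) -> dict[str, str]:
    """Per query, the target of the lowest-e-value hit.

    Ties break to the higher bit score, then the lexicographically smaller
    target id.
    """
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key_new = (h.e_value, -h.bit_score, h.target_id)
        key_cur = (cur.e_value, -cur.bit_score, cur.target_id)
        if key_new < key_cur:
            best[h.query_id] = h
    return {q: h.target_id for q, h in best.items()}


def _target_union(hits: list[HitRecord], query: str, target: str) -> list[tuple[int, int]]:
    return [
        (h.target_start, h.target_end)
        for h in hits
        if h.query_id == query and h.target_id == target
    ]


def _overlap_fraction(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> float:
    """Overlap of two interval unions as a fraction of the shorter union."""
    len_a = _interval_union_length(a)
    len_b = _interval_union_length(b)
    inter = len_a + len_b - _interval_union_length(a + b)
    return inter / min(len_a, len_b)


def merge_split_transcripts(
    assignments: dict[str, str],
    hits: list[HitRecord],
    expr: ExpressionMatrix,
    overlap_tol: float = 0.1,
    names: dict[str, str] | None = None,
) -> tuple[dict[str, tuple[str, ...]], ExpressionMatrix]:
    """Merge queries that hit disjoint stretches of one best target.

    Two queries assigned to the same target merge when their aligned target
    intervals overlap by less than ``overlap_tol`` of the shorter interval
    union (near-identical intervals mean alternative candidates, not parts).
    Merged expression is the per-sample arithmetic mean of the member FPKMs;
    the merged id comes from ``names`` (keyed by target) or defaults to
    ``<target>_merged``.

    Returns (merged_id -> member ids, updated ExpressionMatrix).
    """
    names = names or {}
    for q in assignments:
        if q not in expr.values.index:
            raise MappingError(f"transcript {q} absent from expression matrix")

    by_target: dict[str, list[str]] = {}
    for q, t in sorted(assignments.items()):
        by_target.setdefault(t, []).append(q)

    merge_map: dict[str, tuple[str, ...]] = {}
    new_rows: dict[str, pd.Series] = {}
    drop: list[str] = []
    for target, queries in by_target.items():
        if len(queries) < 2:
            continue
        # connected components of the "disjoint on target" graph
        unions = {q: _target_union(hits, q, target) for q in queries}
        parent = {q: q for q in queries}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, qa in enumerate(queries):
            for qb in queries[i + 1:]:
                if not unions[qa] or not unions[qb]:
                    continue
                if _overlap_fraction(unions[qa], unions[qb]) < overlap_tol:
                    parent[find(qa)] = find(qb)
        comps: dict[str, list[str]] = {}
        for q in queries:
            comps.setdefault(find(q), []).append(q)
        for members in comps.values():
            if len(members) < 2:
                continue
            members = sorted(members)
            merged_id = names.get(target, f"{target}_merged")
            merge_map[merged_id] = tuple(members)
            new_rows[merged_id] = expr.values.loc[members].mean(axis=0)
            drop.extend(members)

    values = expr.values.drop(index=drop)
    if new_rows:
        values = pd.concat([values, pd.DataFrame(new_rows).T])
    return merge_map, ExpressionMatrix(values, expr.site_of)


def candidate_table(
    hits: list[HitRecord],
    query_lengths: dict[str, int],
    evalue_max: float = 1e-60,
    identity_min: float = 85.0,
) -> list[CandidateTranscript]:
    """Filter hits and summarise each query against its best target."""
    kept = filter_hits(hits, evalue_max, identity_min)
    assignment = best_hit_assignment(kept)
    out = []
    for query in sorted(assignment):
        target = assignment[query]
        pair_hits = [h for h in kept if h.query_id == query and h.target_id == target]
        cov, sim = pair_statistics(pair_hits, query_lengths[query])
        out.append(
            CandidateTranscript(
                transcript_id=query,
                best_target_id=target,
                coverage=cov,
                similarity=sim,
            )
        )
    return out


def write_candidate_table(candidates: list[CandidateTranscript], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tbest_target_id\tcoverage\tsimilarity\tmerged_from\n")
        for c in candidates:
            fh.write(
                f"{c.transcript_id}\t{c.best_target_id}\t{c.coverage:.4f}\t"
                f"{c.similarity:.2f}\t{','.join(c.merged_from)}\n"
            )
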