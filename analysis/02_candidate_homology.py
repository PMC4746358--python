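#!/usr/bin/env python
"""Stage 1: identify candidate transcripts from homology hits.

Filters hits at e-value <= 1e-60 and identity >= 85%, summarises coverage
(union of aligned query intervals over query length) and similarity (mean
identity), and merges split transcripts whose hits tile disjoint stretches
of one target; merged expression is the per-sample mean of the parts.
"""

import json
from pathlib import Path

import pandas as pd

from photocoord import homology as ho, io

DEMO = Path("results/demo")
OUT = Path("results/homology")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    hits = io.read_hit_table(DEMO / "hits.tsv")
    lengths = pd.read_csv(DEMO / "query_lengths.tsv", sep="\t", index_col=0)["length"].to_dict()
    kept = ho.filter_hits(hits)
    candidates = ho.candidate_table(hits, lengths)
    ho.write_candidate_table(candidates, OUT / "candidates.tsv")
    coverages = [c.coverage for c in candidates]
    similarities = [c.similarity for c in candidates]
    print(f"{len(kept)}/{len(hits)} hits pass the e-value/identity filter")
    print(f"{len(candidates)} candidate transcripts")
    print(f"  {100 * sum(c > 0.7 for c in coverages) / len(coverages):.0f}% "
          "with >70% coverage")
    print(f"  {100 * sum(s > 90 for s in similarities) / len(similarities):.0f}% "
          "with >90% similarity")

    expr = io.read_expression_matrix(DEMO / "raw_expr.tsv", DEMO / "sites.tsv")
    names = pd.read_csv(DEMO / "merge_names.tsv", sep="\t", index_col=0)["merged_id"].to_dict()
    assignment = ho.best_hit_assignment(kept)
    merge_map, merged = ho.merge_split_transcripts(assignment, kept, expr, names=names)
    io.write_expression_matrix(merged, OUT / "expr_merged.tsv")
    with open(OUT / "merge_map.json", "w") as fh:
        json.dump({k: list(v) for k, v in merge_map.items()}, fh, indent=1)
    for merged_id, members in merge_map.items():
        print(f"merged {list(members)} -> {merged_id} (mean FPKM per sample)")


if __name__ == "__main__":
    main()
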