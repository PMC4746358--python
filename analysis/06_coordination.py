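#!/usr/bin/env python
"""Stage 5: the coordination analysis.

Spearman rho for every pair of the 78 pathway transcripts over the 78 pooled
samples; the background b = median |rho| over all pairs; mean |rho| within
and between the nine functional groups; an exact one-sided binomial test of
the count of pairs exceeding b (null rate 1/2); per-transcript centrality;
and the coordinated-set call with its percentage.
"""

import json
from pathlib import Path

import pandas as pd

from photocoord import coordination as co, io

DEMO = Path("results/demo")
HOMOLOGY = Path("results/homology")
CLUSTER = Path("results/cluster")
OUT = Path("results/coordination")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    expr = io.read_expression_matrix(HOMOLOGY / "expr_merged.tsv", DEMO / "sites.tsv")
    ann = io.read_annotation(DEMO / "annotation.tsv")
    groups = co.groups_from_annotations(ann, expr.transcript_ids)
    panel = [t for ms in groups.values() for t in ms]
    corr = co.spearman_matrix(expr.subset(panel))
    report = co.group_relatedness(corr, groups)
    print(f"{len(panel)} transcripts, {len(panel) * (len(panel) - 1) // 2} pairs")
    print(f"background median |rho| b = {report.background:.3f}; "
          f"signed median rho = {report.signed_median:.3f}")

    (OUT / "table1.tsv").write_text(co.table1_report(report))
    print("group relatedness written to table1.tsv "
          "(upper triangle mean |rho|, lower triangle binomial p)")

    cent = co.centrality(corr)
    cent.to_csv(OUT / "centrality.tsv", sep="\t")
    print("most central transcripts:", ", ".join(cent.index[:5]))

    branches = pd.read_csv(CLUSTER / "gene_branches.tsv", sep="\t",
                           index_col=0)["branch"].to_dict()
    call = co.call_coordination(report, ann, branches, alpha=0.05)
    result = {
        "background_median": report.background,
        "signed_median": report.signed_median,
        "coordinated_groups": sorted(call.coordinated_groups),
        "n_coordinated_transcripts": len(call.coordinated_transcripts),
        "n_extra_chloroplast": len(call.extra_chloroplast_members),
        "coordinated_percentage": call.percentage,
    }
    with open(OUT / "coordination.json", "w") as fh:
        json.dump(result, fh, indent=1)
    print(f"coordinated groups: {sorted(call.coordinated_groups)}")
    print(f"coordinated set: {len(call.coordinated_transcripts)} transcripts "
          f"+ {len(call.extra_chloroplast_members)} co-clustered chloroplast "
          f"transcripts = {call.percentage:.1f}% of {call.n_total}")


if __name__ == "__main__":
    main()
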