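#!/usr/bin/env python
"""Stage 3: per-site medians, fold changes, and gene-set tests.

Computes the QG/JH fold change and up/down call per transcript, the
percentage of up-/down-regulated transcripts per functional group, and the
distribution tests: KS for dark vs non-dark expression levels and fold
changes, Wilcoxon for C4 vs Calvin levels and for the ATP-/NADPH-related
fold-change contrasts.
"""

import json
from pathlib import Path

from photocoord import exprstats as es, io

DEMO = Path("results/demo")
HOMOLOGY = Path("results/homology")
OUT = Path("results/exprstats")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    expr = io.read_expression_matrix(HOMOLOGY / "expr_merged.tsv", DEMO / "sites.tsv")
    ann = [a for a in io.read_annotation(DEMO / "annotation.tsv")
           if a.transcript_id in set(expr.transcript_ids)]
    summaries = es.site_summaries(expr)
    with open(OUT / "summaries.tsv", "w") as fh:
        fh.write("transcript_id\tmedian_JH\tmedian_QG\tratio\tdirection\ttwo_fold\n")
        for s in summaries:
            fh.write(f"{s.transcript_id}\t{s.median_JH:.4f}\t{s.median_QG:.4f}\t"
                     f"{s.ratio:.4f}\t{s.direction}\t{s.two_fold}\n")

    directions = es.group_direction_summary(summaries, ann)
    print("up/down-regulation per functional group (QG relative to JH):")
    for group, v in sorted(directions.items()):
        print(f"  {group:8s} n={v['n']:3d}  up {v['pct_up']:5.1f}%  "
              f"down {v['pct_down']:5.1f}%")

    sets = {
        "dark": {a.transcript_id for a in ann if a.reaction_class == "dark"},
        "non_dark": {a.transcript_id for a in ann if a.reaction_class == "non_dark"},
        "C4": {a.transcript_id for a in ann if a.functional_group == "C4"},
        "Calvin": {a.transcript_id for a in ann if a.functional_group == "Calvin"},
        "ATP": {a.transcript_id for a in ann if a.energy_group == "ATP_related"},
        "NADPH": {a.transcript_id for a in ann if a.energy_group == "NADPH_related"},
        "dark_other": {a.transcript_id for a in ann
                       if a.reaction_class == "dark" and a.energy_group == "other"},
    }
    tests = {
        "dark_vs_nondark_median_JH": es.compare_gene_sets(
            summaries, sets["dark"], sets["non_dark"], "median_level", site="JH"),
        "dark_vs_nondark_median_QG": es.compare_gene_sets(
            summaries, sets["dark"], sets["non_dark"], "median_level", site="QG"),
        "dark_vs_nondark_ratio": es.compare_gene_sets(
            summaries, sets["dark"], sets["non_dark"], "ratio"),
        "c4_vs_calvin_median_QG": es.compare_gene_sets(
            summaries, sets["C4"], sets["Calvin"], "median_level", site="QG",
            test="wilcoxon", alternative="greater"),
        "atp_vs_other_ratio": es.compare_gene_sets(
            summaries, sets["ATP"], sets["dark_other"], "ratio",
            test="wilcoxon", alternative="greater"),
        "nadph_vs_other_ratio": es.compare_gene_sets(
            summaries, sets["NADPH"], sets["dark_other"], "ratio",
            test="wilcoxon", alternative="greater"),
    }
    with open(OUT / "tests.json", "w") as fh:
        json.dump({"set_tests": tests, "group_directions": directions}, fh, indent=1)
    print("gene-set tests:")
    for name, res in tests.items():
        print(f"  {name}: {res['test']} stat={res['statistic']:.3f} "
              f"p={res['p_value']:.4g} (n={res['n_a']}/{res['n_b']})")


if __name__ == "__main__":
    main()
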