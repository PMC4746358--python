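"""End-to-end orchestration: demo-data generation and staged pipeline runs.

Stages communicate only via files so each is independently testable and
resumable; a manifest records input hashes, parameters and per-stage record
counts.  All randomness flows from one top-level seed through named
per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import coordination as co
from . import diversity as dv
from . import exprstats as es
from . import homology as ho
from . import io
from . import phylo as ph
from . import simulate as sim
from .types import ConfigError, ExpressionMatrix

logger = logging.getLogger("photocoord")

STAGES = ("homology", "phylo", "exprstats", "cluster", "coordinate", "diversity")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# demo dataset

def _demo_reference_tree(
    n_queries: int = 4, ref_class: str = "C4", n_refs: int = 3
) -> ph.TreeNode:
    """Two deep clades: references + queries of ``ref_class`` vs cytosolic.

    With the defaults each family has 14 leaves, enough for the stringent
    block-selection flank threshold (12 sequences) to be attainable.
    """
    def clade(prefix: str, n_ref: int, n_q: int):
        tips = []
        for i in range(n_ref):
            tips.append(ph.TreeNode(name=f"{prefix}_ref{i+1}", length=0.02))
        for i in range(n_q):
            tips.append(ph.TreeNode(name=f"{prefix}_query{i+1}", length=0.02))
        node = tips[0]
        for t in tips[1:]:
            node = ph.TreeNode(children=[node, t], length=0.015)
        return node

    left = clade(ref_class, n_refs, n_queries)
    right = clade("cyto", n_refs, n_queries)
    left.length = 0.12
    right.length = 0.12
    return ph.TreeNode(children=[left, right])


def make_demo_dataset(out_dir, seed: int = 1) -> dict:
    """Emit a full synthetic fixture bundle mirroring the study shape.

    78 photosynthesis transcripts in the nine functional groups plus 30
    cytosolic paralogs, 39 samples per site, planted fold changes and
    latent-factor structure; a split-transcript pair for the merging stage;
    two sequence families with labeled references; SNP tables for both site
    populations; and a truth file with the planted parameters.
    """
    out = io.ensure_dir(out_dir)
    rng = np.random.default_rng(stage_seed(seed, "demo"))

    transcripts = sim.study_transcript_table(seed=stage_seed(seed, "design"))
    config = sim.PopulationSimConfig(
        transcripts=transcripts,
        n_samples_per_site=39,
        noise_sd=0.5,
        seed=stage_seed(seed, "expression"),
    )
    expr, annotations = sim.simulate_population_expression(config)

    # split one transcript into two assembly fragments for the merge stage
    split_id = "MlCalvin_18"
    frag_a, frag_b = f"{split_id}a", f"{split_id}b"
    raw_values = expr.values.rename(index={split_id: frag_a})
    raw_values.loc[frag_b] = raw_values.loc[frag_a]
    raw_expr = ExpressionMatrix(raw_values, expr.site_of)

    io.write_expression_matrix(raw_expr, out / "raw_expr.tsv", out / "sites.tsv")
    io.write_annotation(annotations, out / "annotation.tsv")

    # homology hits: one hit per transcript; the two fragments hit disjoint
    # halves of the same target
    hits_lines = []
    lengths: dict[str, int] = {}
    for tid in raw_expr.transcript_ids:
        qlen = int(rng.integers(900, 2400))
        lengths[tid] = qlen
        if tid == frag_a:
            target, qs, qe, ts, te = "Sb_FBA_target", 1, qlen, 1, qlen
        elif tid == frag_b:
            target, qs, qe, ts, te = "Sb_FBA_target", 1, qlen, qlen + 100, 2 * qlen + 99
        else:
            target = f"Zm_{tid}_t"
            cov = rng.uniform(0.55, 1.0)
            qs, qe = 1, max(1, int(qlen * cov))
            ts, te = 1, qe
        ident = float(rng.uniform(86.0, 99.8))
        hits_lines.append(
            f"{tid}\t{target}\t{ident:.1f}\t{qe - qs + 1}\t"
            f"{int((qe - qs + 1) * (100 - ident) / 100)}\t0\t{qs}\t{qe}\t{ts}\t{te}\t"
            f"1e-{int(rng.integers(65, 180))}\t{float(rng.uniform(500, 2000)):.1f}\n"
        )
    with open(out / "hits.tsv", "w") as fh:
        fh.writelines(hits_lines)
    with open(out / "query_lengths.tsv", "w") as fh:
        fh.write("transcript_id\tlength\n")
        for tid, ln in lengths.items():
            fh.write(f"{tid}\t{ln}\n")
    with open(out / "merge_names.tsv", "w") as fh:
        fh.write("target_id\tmerged_id\n")
        fh.write(f"Sb_FBA_target\t{split_id}\n")

    # sequence families with known membership
    for fam, ref_class in (("C4_family", "C4"), ("Calvin_family", "Calvin")):
        tree = _demo_reference_tree(ref_class=ref_class)
        aln = sim.simulate_alignment(
            sim.SeqSimConfig(tree=tree, seq_length=1200,
                             seed=stage_seed(seed, f"aln:{fam}"))
        )
        labels = {}
        for leaf in aln.leaf_ids:
            if leaf.startswith(f"{ref_class}_ref"):
                labels[leaf] = f"{ref_class}_ref"
            elif leaf.startswith("cyto_ref"):
                labels[leaf] = "cytosolic_ref"
        aln.reference_labels = labels
        io.write_alignment(aln, out / f"{fam}.fasta")

    # SNP tables: same diversity regime at both sites (pi ~ 0.005)
    pathway_ids = [
        a.transcript_id for a in annotations if a.functional_group != "other"
    ]
    truth_pi: dict[str, dict[str, float]] = {}
    for site in ("JH", "QG"):
        tables = {}
        for tid in pathway_ids:
            target_pi = float(rng.uniform(0.002, 0.008))
            tables[tid] = sim.simulate_snp_table(
                tid, length=lengths.get(tid, 1500), n_alleles=78,
                target_pi=target_pi,
                seed=stage_seed(seed, f"snp:{site}:{tid}"),
            )
            truth_pi.setdefault(tid, {})[site] = target_pi
        io.write_snp_tables(tables, out / f"snps_{site}.tsv")

    truth = {
        "seed": seed,
        "split_transcript": {"merged": split_id, "fragments": [frag_a, frag_b]},
        "group_sizes": sim.STUDY_GROUP_SIZES,
        "n_non_dark": sim.N_NON_DARK,
        "coordinated_groups": list(sim.COORDINATED_GROUPS),
        "transcripts": transcripts.to_dict(orient="records"),
        "target_pi": truth_pi,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth


# ---------------------------------------------------------------------------
# pipeline config + runner

@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    seed: int = 1
    evalue_max: float = 1e-60
    identity_min: float = 85.0
    alpha: float = 0.05
    min_support: int = 50
    k_gene_branches: int = 3
    n_bootstrap: int = 200
    stages: tuple[str, ...] = STAGES

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    REQUIRED_INPUTS = {
        "homology": ("hits.tsv", "query_lengths.tsv", "raw_expr.tsv", "sites.tsv"),
        "phylo": (),
        "exprstats": ("annotation.tsv",),
        "cluster": (),
        "coordinate": ("annotation.tsv",),
        "diversity": ("snps_JH.tsv", "snps_QG.tsv"),
    }

    def validate_inputs(self) -> None:
        ind = Path(self.input_dir)
        missing = [
            f for st in self.stages for f in self.REQUIRED_INPUTS[st]
            if not (ind / f).exists()
        ]
        if missing:
            raise ConfigError(f"missing inputs: {sorted(set(missing))}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and return the manifest."""
    config.validate_inputs()
    ind = Path(config.input_dir)
    outd = io.ensure_dir(config.output_dir)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "evalue_max": config.evalue_max,
            "identity_min": config.identity_min,
            "alpha": config.alpha,
            "min_support": config.min_support,
            "k_gene_branches": config.k_gene_branches,
            "n_bootstrap": config.n_bootstrap,
        },
        "inputs": {},
        "stages": {},
    }
    for f in sorted(ind.glob("*")):
        if f.is_file():
            manifest["inputs"][f.name] = _sha256(f)

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            manifest["stages"][stage] = {"status": "skipped"}
            continue
        logger.info("[%s] running", stage)
        try:
            record = _STAGE_FUNCS[stage](config, ind, outd, state)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(stage, exc) from exc
        record["status"] = "ok"
        manifest["stages"][stage] = record
        logger.info("[%s] done: %s", stage, record)

    with open(outd / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# --- individual stages ------------------------------------------------------

def _load_expression(config: PipelineConfig, ind: Path, outd: Path) -> ExpressionMatrix:
    merged = outd / "expr_merged.tsv"
    if merged.exists():
        return io.read_expression_matrix(merged, ind / "sites.tsv")
    return io.read_expression_matrix(ind / "raw_expr.tsv", ind / "sites.tsv")


def _stage_homology(config, ind, outd, state):
    hits = io.read_hit_table(ind / "hits.tsv")
    lengths = pd.read_csv(ind / "query_lengths.tsv", sep="\t", index_col=0)["length"].to_dict()
    kept = ho.filter_hits(hits, config.evalue_max, config.identity_min)
    candidates = ho.candidate_table(hits, lengths, config.evalue_max, config.identity_min)
    ho.write_candidate_table(candidates, outd / "candidates.tsv")
    expr = io.read_expression_matrix(ind / "raw_expr.tsv", ind / "sites.tsv")
    names = {}
    names_file = ind / "merge_names.tsv"
    if names_file.exists():
        names = pd.read_csv(names_file, sep="\t", index_col=0)["merged_id"].to_dict()
    assignment = ho.best_hit_assignment(kept)
    merge_map, merged_expr = ho.merge_split_transcripts(
        assignment, kept, expr, names=names
    )
    io.write_expression_matrix(merged_expr, outd / "expr_merged.tsv")
    with open(outd / "merge_map.json", "w") as fh:
        json.dump({k: list(v) for k, v in merge_map.items()}, fh, indent=1)
    state["expr"] = merged_expr
    return {
        "n_hits": len(hits), "n_kept": len(kept),
        "n_candidates": len(candidates), "n_merged": len(merge_map),
    }


def _stage_phylo(config, ind, outd, state):
    n_trees = 0
    classes: dict[str, str] = {}
    for fasta in sorted(ind.glob("*_family.fasta")):
        aln = io.read_alignment(fasta)
        blocks = ph.select_conserved_blocks(aln)
        trimmed = aln.slice_columns(blocks) if blocks else aln
        tree = ph.bootstrap_supports(
            trimmed, n_reps=config.n_bootstrap,
            seed=stage_seed(config.seed, f"boot:{fasta.stem}"),
        )
        with open(outd / f"{fasta.stem}.nwk", "w") as fh:
            fh.write(tree.to_newick() + "\n")
        fam_classes = ph.classify_by_clade(
            tree, aln.reference_labels, min_support=config.min_support
        )
        classes.update(fam_classes)
        n_trees += 1
    with open(outd / "classes.tsv", "w") as fh:
        fh.write("leaf\tclass\n")
        for leaf in sorted(classes):
            fh.write(f"{leaf}\t{classes[leaf]}\n")
    return {"n_trees": n_trees, "n_classified": sum(
        1 for c in classes.values() if c != "unclassified"
    ), "n_leaves": len(classes)}


def _stage_exprstats(config, ind, outd, state):
    expr = state.get("expr") or _load_expression(config, ind, outd)
    annotations = io.read_annotation(ind / "annotation.tsv")
    ann = [a for a in annotations if a.transcript_id in set(expr.transcript_ids)]
    summaries = es.site_summaries(expr)
    with open(outd / "summaries.tsv", "w") as fh:
        fh.write("transcript_id\tmedian_JH\tmedian_QG\tratio\tdirection\ttwo_fold\n")
        for s in summaries:
            fh.write(
                f"{s.transcript_id}\t{s.median_JH:.4f}\t{s.median_QG:.4f}\t"
                f"{s.ratio:.4f}\t{s.direction}\t{s.two_fold}\n"
            )
    dark = {a.transcript_id for a in ann if a.reaction_class == "dark"}
    non_dark = {a.transcript_id for a in ann if a.reaction_class == "non_dark"}
    c4 = {a.transcript_id for a in ann if a.functional_group == "C4"}
    calvin = {a.transcript_id for a in ann if a.functional_group == "Calvin"}
    atp = {a.transcript_id for a in ann if a.energy_group == "ATP_related"}
    nadph = {a.transcript_id for a in ann if a.energy_group == "NADPH_related"}
    dark_other = {
        a.transcript_id for a in ann
        if a.reaction_class == "dark" and a.energy_group == "other"
    }
    tests = {}
    if dark and non_dark:
        for site in ("JH", "QG"):
            tests[f"dark_vs_nondark_median_{site}"] = es.compare_gene_sets(
                summaries, dark, non_dark, "median_level", site=site, test="ks"
            )
        tests["dark_vs_nondark_ratio"] = es.compare_gene_sets(
            summaries, dark, non_dark, "ratio", test="ks"
        )
    if c4 and calvin:
        tests["c4_vs_calvin_median_QG"] = es.compare_gene_sets(
            summaries, c4, calvin, "median_level", site="QG", test="wilcoxon",
            alternative="greater",
        )
    if atp and dark_other:
        tests["atp_vs_other_ratio"] = es.compare_gene_sets(
            summaries, atp, dark_other, "ratio", test="wilcoxon",
            alternative="greater",
        )
    if nadph and dark_other:
        tests["nadph_vs_other_ratio"] = es.compare_gene_sets(
            summaries, nadph, dark_other, "ratio", test="wilcoxon",
            alternative="greater",
        )
    directions = es.group_direction_summary(summaries, ann)
    with open(outd / "tests.json", "w") as fh:
        json.dump({"set_tests": tests, "group_directions": directions,
                   "bookkeeping": es.annotation_counts(annotations)}, fh, indent=1)
    state["summaries"] = summaries
    return {"n_transcripts": len(summaries), "n_tests": len(tests)}


def _stage_cluster(config, ind, outd, state):
    expr = state.get("expr") or _load_expression(config, ind, outd)
    annotations = io.read_annotation(ind / "annotation.tsv")
    pathway = [
        a.transcript_id for a in annotations
        if a.functional_group != "other" and a.transcript_id in set(expr.transcript_ids)
    ]
    sub = expr.subset(pathway)
    pre = cl.preprocess(sub)
    genes = cl.centroid_linkage(pre, axis="genes")
    arrays = cl.centroid_linkage(pre, axis="arrays")
    cl.write_cdt(pre, genes, arrays, outd / "clustered.cdt")
    cl.write_tree_file(genes, outd / "clustered.gtr")
    cl.write_tree_file(arrays, outd / "clustered.atr")
    for dendro, name in ((genes, "genes"), (arrays, "arrays")):
        with open(outd / f"cluster_{name}.nwk", "w") as fh:
            fh.write(cl.dendrogram_to_newick(dendro) + "\n")
    branches = cl.cut_branches(genes, config.k_gene_branches)
    with open(outd / "gene_branches.tsv", "w") as fh:
        fh.write("transcript_id\tbranch\n")
        for t, b in branches.items():
            fh.write(f"{t}\t{b}\n")
    separated, purity = cl.site_separation_check(arrays, expr.site_of)
    state["gene_branches"] = branches
    state["site_purity"] = purity
    return {
        "n_genes": genes.n_items, "n_arrays": arrays.n_items,
        "site_purity": purity, "sites_separated": separated,
    }


def _stage_coordinate(config, ind, outd, state):
    expr = state.get("expr") or _load_expression(config, ind, outd)
    annotations = io.read_annotation(ind / "annotation.tsv")
    groups = co.groups_from_annotations(annotations, expr.transcript_ids)
    pathway = [t for ms in groups.values() for t in ms]
    sub = expr.subset(pathway)
    corr = co.spearman_matrix(sub)
    report = co.group_relatedness(corr, groups)
    with open(outd / "table1.tsv", "w") as fh:
        fh.write(co.table1_report(report))
    cent = co.centrality(corr)
    cent.to_csv(outd / "centrality.tsv", sep="\t")
    branches = state.get("gene_branches")
    if branches is None and (outd / "gene_branches.tsv").exists():
        branches = pd.read_csv(
            outd / "gene_branches.tsv", sep="\t", index_col=0
        )["branch"].to_dict()
    call = co.call_coordination(report, annotations, branches, alpha=config.alpha)
    result = {
        "background_median": report.background,
        "signed_median": report.signed_median,
        "n_constant_transcripts": corr.n_constant,
        "coordinated_groups": sorted(call.coordinated_groups),
        "n_coordinated_transcripts": len(call.coordinated_transcripts),
        "n_extra_chloroplast": len(call.extra_chloroplast_members),
        "n_total": call.n_total,
        "coordinated_percentage": call.percentage,
        "cells": {
            f"{a}|{b}": {
                "n_pairs": c.n_pairs, "mean_abs_rho": c.mean_abs_rho,
                "n_exceeding": c.n_exceeding, "p_value": c.p_value,
                "stars": c.stars,
            }
            for (a, b), c in report.cells.items()
        },
    }
    with open(outd / "coordination.json", "w") as fh:
        json.dump(result, fh, indent=1)
    state["coordination"] = result
    return {
        "background_median": report.background,
        "coordinated_percentage": call.percentage,
        "n_groups": len(groups),
    }


def _stage_diversity(config, ind, outd, state):
    results: dict[str, list[dv.DiversityResult]] = {}
    for site in ("JH", "QG"):
        tables = io.read_snp_tables(ind / f"snps_{site}.tsv")
        results[site] = [dv.nei_li_pi(t) for t in tables.values()]
    dv.write_diversity_table(results, outd / "pi.tsv")
    ks = dv.compare_site_diversity(results["JH"], results["QG"])
    with open(outd / "diversity_test.json", "w") as fh:
        json.dump(ks, fh, indent=1)
    state["diversity_ks"] = ks
    return {"n_JH": len(results["JH"]), "n_QG": len(results["QG"]),
            "ks_p": ks["p_value"]}


_STAGE_FUNCS = {
    "homology": _stage_homology,
    "phylo": _stage_phylo,
    "exprstats": _stage_exprstats,
    "cluster": _stage_cluster,
    "coordinate": _stage_coordinate,
    "diversity": _stage_diversity,
}
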