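"""Pooled-population Spearman coordination analysis.

The central procedure: compute the Spearman correlation rho for every
transcript pair over the pooled samples of both sites, take the median of
|rho| over all pairs as the background b, average |rho| within and between
functional groups, and test each group cell with an exact one-sided binomial
test of the count of member pairs exceeding b — the null success probability
is 1/2 because b is the empirical median of the same coefficient population
(the pairs are not independent, so the p-value is an approximation carried
over from the original procedure, not an exact null).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, TranscriptAnnotation

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    transcript_ids: list[str]
    rho: np.ndarray                 # symmetric, unit diagonal; NaN = undefined
    n_constant: int = 0             # transcripts with zero rank variance

    def pair_rho(self, a: str, b: str) -> float:
        i = self.transcript_ids.index(a)
        j = self.transcript_ids.index(b)
        return float(self.rho[i, j])


def spearman_matrix(expr: ExpressionMatrix) -> CorrelationMatrix:
    """Spearman rho for every transcript pair over the pooled samples.

    Ranks use average-rank tie handling; rho is the Pearson correlation of
    the ranks.  Constant transcripts have undefined rho against everything;
    their pairs are recorded as missing (NaN) and excluded downstream.
    """
    values = expr.values.to_numpy(dtype=float)
    n_t, n_s = values.shape
    if n_s < 3:
        raise ValueError("need at least 3 pooled samples")
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    sd = ranks.std(axis=1)
    constant = sd == 0
    n_constant = int(constant.sum())
    if n_constant:
        logger.warning("%d constant transcripts: rho undefined for their pairs", n_constant)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered ** 2).sum(axis=1))
    denom[constant] = 1.0
    normed = centered / denom[:, None]
    rho = normed @ normed.T
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(list(expr.values.index), rho, n_constant)


def _upper_triangle(corr: CorrelationMatrix) -> np.ndarray:
    iu = np.triu_indices(len(corr.transcript_ids), k=1)
    vals = corr.rho[iu]
    return vals[~np.isnan(vals)]


def background_median(corr: CorrelationMatrix) -> tuple[float, float]:
    """(b, signed_median): medians of |rho| and of rho over all distinct
    pairs, missing pairs excluded."""
    vals = _upper_triangle(corr)
    if vals.size == 0:
        raise ValueError("no defined transcript pairs")
    return float(np.median(np.abs(vals))), float(np.median(vals))


def binomial_coordination_test(n_pairs: int, n_exceeding: int) -> float:
    """One-sided exact binomial tail P(X >= n_exceeding), X ~ Bin(n_pairs, 1/2)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not 0 <= n_exceeding <= n_pairs:
        raise ValueError("n_exceeding outside [0, n_pairs]")
    return float(stats.binom.sf(n_exceeding - 1, n_pairs, 0.5))


@dataclass
class RelatednessCell:
    group_a: str
    group_b: str                    # == group_a for a within-group cell
    n_pairs: int
    mean_abs_rho: float             # nan when no defined pairs
    n_exceeding: int
    p_value: float                  # nan when n_pairs == 0

    @property
    def stars(self) -> str:
        if math.isnan(self.p_value):
            return ""
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


@dataclass
class RelatednessReport:
    groups: dict[str, list[str]]    # group -> member transcript ids
    background: float               # b = median |rho| over all pairs
    signed_median: float
    cells: dict[tuple[str, str], RelatednessCell] = field(default_factory=dict)

    def cell(self, a: str, b: str) -> RelatednessCell:
        key = (a, b) if (a, b) in self.cells else (b, a)
        return self.cells[key]


def group_relatedness(
    corr: CorrelationMatrix,
    groups: dict[str, list[str]],
    background: float | None = None,
) -> RelatednessReport:
    """Mean |rho| and binomial exceedance test for every group cell.

    Within-group cells average the g(g-1)/2 member pairs; between-group cells
    the a*b cross pairs.  'Exceeding' means strictly |rho| > b.
    """
    for g, members in groups.items():
        if len(set(members)) != len(members):
            raise ValueError(f"duplicate members in group {g}")
    flat = [t for ms in groups.values() for t in ms]
    if len(flat) != len(set(flat)):
        raise ValueError("a transcript appears in more than one group")

    if background is None:
        background, signed = background_median(corr)
    else:
        _, signed = background_median(corr)
    idx = {t: i for i, t in enumerate(corr.transcript_ids)}
    report = RelatednessReport(groups=groups, background=background, signed_median=signed)

    names = list(groups)
    for i, ga in enumerate(names):
        for gb in names[i:]:
            if ga == gb:
                mem = [idx[t] for t in groups[ga]]
                pairs = [
                    corr.rho[a, b]
                    for k, a in enumerate(mem) for b in mem[k + 1:]
                ]
            else:
                pairs = [
                    corr.rho[idx[a], idx[b]]
                    for a in groups[ga] for b in groups[gb]
                ]
            vals = np.array([v for v in pairs if not math.isnan(v)])
            n_pairs = len(pairs)
            if vals.size:
                mean_abs = float(np.mean(np.abs(vals)))
                n_exc = int((np.abs(vals) > background).sum())
                p = binomial_coordination_test(vals.size, n_exc)
            else:
                mean_abs, n_exc, p = math.nan, 0, math.nan
            report.cells[(ga, gb)] = RelatednessCell(
                ga, gb, n_pairs, mean_abs, n_exc, p
            )
    return report


def centrality(corr: CorrelationMatrix) -> pd.Series:
    """Mean |rho| of each transcript to all others (its network centrality),
    sorted descending; missing pairs excluded."""
    n = len(corr.transcript_ids)
    abs_rho = np.abs(corr.rho.copy())
    np.fill_diagonal(abs_rho, np.nan)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(abs_rho, axis=1)
    s = pd.Series(means, index=corr.transcript_ids, name="centrality")
    return s.sort_values(ascending=False, kind="stable")


@dataclass
class CoordinationCall:
    coordinated_groups: set[str]
    coordinated_transcripts: set[str]
    extra_chloroplast_members: set[str]
    n_total: int

    @property
    def percentage(self) -> float:
        joint = self.coordinated_transcripts | self.extra_chloroplast_members
        return 100.0 * len(joint) / self.n_total


def coordination_percentage(n_coordinated: int, n_extra: int, n_total: int) -> float:
    """Coordinated-set percentage: 100 * (coordinated + extra) / total."""
    return 100.0 * (n_coordinated + n_extra) / n_total


def call_coordination(
    report: RelatednessReport,
    annotations: list[TranscriptAnnotation],
    cluster_branches: dict[str, int] | None = None,
    alpha: float = 0.05,
) -> CoordinationCall:
    """Coordinated groups and the coordinated-set percentage.

    A group is coordinated when its within-group binomial p < alpha or at
    least one of its between-group p < alpha.  Chloroplast-encoded transcripts
    outside coordinated groups join the set when they all fall in one common
    gene-cluster branch (tightly coordinated degradation).
    """
    names = list(report.groups)
    coordinated_groups: set[str] = set()
    for g in names:
        within = report.cell(g, g)
        if not math.isnan(within.p_value) and within.p_value < alpha:
            coordinated_groups.add(g)
            continue
        for other in names:
            if other == g:
                continue
            cell = report.cell(g, other)
            if not math.isnan(cell.p_value) and cell.p_value < alpha:
                coordinated_groups.add(g)
                break

    coordinated_transcripts = {
        t for g in coordinated_groups for t in report.groups[g]
    }
    all_transcripts = {t for ms in report.groups.values() for t in ms}

    extra: set[str] = set()
    if cluster_branches:
        outside_chl = [
            a.transcript_id
            for a in annotations
            if a.compartment == "chloroplast"
            and a.transcript_id in all_transcripts
            and a.transcript_id not in coordinated_transcripts
            and a.transcript_id in cluster_branches
        ]
        if outside_chl:
            branches = {cluster_branches[t] for t in outside_chl}
            if len(branches) == 1:
                extra = set(outside_chl)

    return CoordinationCall(
        coordinated_groups=coordinated_groups,
        coordinated_transcripts=coordinated_transcripts,
        extra_chloroplast_members=extra,
        n_total=len(all_transcripts),
    )


# ---------------------------------------------------------------------------
# Table-1-style rendering

def table1_report(report: RelatednessReport) -> str:
    """TSV matrix: upper triangle + diagonal = mean |rho| (2 decimals, with
    significance stars), lower triangle = binomial p (4 decimals).

    Stars: * p < 0.05, ** p < 0.01, *** p < 0.001 (strict inequalities).
    """
    names = list(report.groups)
    header = [""] + [f"{g} ({len(report.groups[g])})" for g in names]
    lines = ["\t".join(header)]
    for i, ga in enumerate(names):
        row = [f"{ga} ({len(report.groups[ga])})"]
        for j, gb in enumerate(names):
            cell = report.cell(ga, gb)
            if j >= i:  # upper triangle + diagonal: mean |rho| with stars
                if math.isnan(cell.mean_abs_rho):
                    row.append("")
                else:
                    row.append(f"{cell.mean_abs_rho:.2f}{cell.stars}")
            else:       # lower triangle: p-value
                row.append("" if math.isnan(cell.p_value) else f"{cell.p_value:.4f}")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def parse_table1(text: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Recover group names, the mean-|rho| upper triangle and the p-value
    lower triangle from a rendered table (round-trip check)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")[1:]
    names = [h.rsplit(" (", 1)[0] for h in header]
    n = len(names)
    means = np.full((n, n), np.nan)
    ps = np.full((n, n), np.nan)
    for i, ln in enumerate(lines[1:]):
        cells = ln.split("\t")[1:]
        for j, c in enumerate(cells):
            if not c:
                continue
            if j >= i:
                means[i, j] = float(c.rstrip("*"))
            else:
                ps[i, j] = float(c)
    return names, means, ps


def groups_from_annotations(
    annotations: list[TranscriptAnnotation],
    transcript_ids: list[str] | None = None,
) -> dict[str, list[str]]:
    """Functional-group membership map, skipping the catch-all 'other'."""
    keep = set(transcript_ids) if transcript_ids is not None else None
    groups: dict[str, list[str]] = {}
    for a in annotations:
        if a.functional_group == "other":
            continue
        if keep is not None and a.transcript_id not in keep:
            continue
        groups.setdefault(a.functional_group, []).append(a.transcript_id)
    return groups
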