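"""Two-site expression statistics.

Per-transcript site medians, QG/JH fold changes and up/down calls, plus the
two nonparametric tests used to compare gene sets: the two-sample
Kolmogorov-Smirnov test (distribution equality) and the Wilcoxon rank-sum
test (mean-rank shift), with exact small-sample enumeration for the latter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import special, stats

from .types import ExpressionMatrix, TranscriptAnnotation


@dataclass(frozen=True)
class SiteSummary:
    transcript_id: str
    median_JH: float
    median_QG: float
    ratio: float            # median_QG / median_JH; nan when both medians are 0
    direction: str          # 'up', 'down' or 'unchanged'
    two_fold: bool
    ratio_defined: bool = True


def site_summaries(
    expr: ExpressionMatrix,
    jh_label: str = "JH",
    qg_label: str = "QG",
) -> list[SiteSummary]:
    """Median FPKM per site, fold change and direction per transcript.

    'Up-regulated' means the QG median strictly exceeds the JH median; exact
    equality is 'unchanged'.  Two-fold means ratio >= 2 or <= 0.5.
    """
    jh_samples = expr.samples_of_site(jh_label)
    qg_samples = expr.samples_of_site(qg_label)
    out = []
    for tid in expr.transcript_ids:
        row = expr.values.loc[tid]
        m_jh = float(np.median(row[jh_samples]))
        m_qg = float(np.median(row[qg_samples]))
        if m_jh == 0.0 and m_qg == 0.0:
            out.append(SiteSummary(tid, m_jh, m_qg, math.nan, "unchanged", False, False))
            continue
        ratio = math.inf if m_jh == 0.0 else m_qg / m_jh
        if m_qg > m_jh:
            direction = "up"
        elif m_qg < m_jh:
            direction = "down"
        else:
            direction = "unchanged"
        two_fold = ratio >= 2.0 or ratio <= 0.5
        out.append(SiteSummary(tid, m_jh, m_qg, ratio, direction, two_fold))
    return out


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov

def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value.

    D is the supremum ECDF difference; the p-value evaluates the Kolmogorov
    distribution at lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D with
    effective size ne = n*m/(n+m).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / n
    cdf_y = np.searchsorted(y, grid, side="right") / m
    D = float(np.max(np.abs(cdf_x - cdf_y)))
    ne = n * m / (n + m)
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * D
    p = float(min(1.0, max(0.0, special.kolmogorov(lam))))
    return D, p


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum

def _average_ranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def wilcoxon_rank_sum(
    x,
    y,
    alternative: str = "two-sided",
    exact_max: int = 10,
) -> tuple[float, float]:
    """Mann-Whitney U (from summed average ranks of x) and its p-value.

    Exact p by full enumeration of rank assignments when both samples have at
    most ``exact_max`` observations and there are no ties; otherwise a normal
    approximation with tie and continuity corrections.  ``alternative`` is
    'two-sided', 'less' (x shifted below y) or 'greater'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"bad alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    ranks = _average_ranks(pooled)
    r_x = float(ranks[:n].sum())
    u = r_x - n * (n + 1) / 2.0

    has_ties = len(np.unique(pooled)) < n + m
    if n <= exact_max and m <= exact_max and not has_ties:
        p = _exact_rank_sum_p(n, m, u, alternative)
    else:
        p = _normal_rank_sum_p(pooled, n, m, u, alternative)
    return u, p


def _exact_rank_sum_p(n: int, m: int, u_obs: float, alternative: str) -> float:
    """Enumerate all C(n+m, n) placements of x among the ranks 1..n+m."""
    N = n + m
    total = math.comb(N, n)
    base = n * (n + 1) / 2.0
    us = [
        sum(pos) + n - base  # ranks are positions+1; U = R_x - n(n+1)/2
        for pos in combinations(range(N), n)
    ]
    us = np.asarray(us, dtype=float)
    if alternative == "less":
        count = int((us <= u_obs + 1e-9).sum())
        return count / total
    if alternative == "greater":
        count = int((us >= u_obs - 1e-9).sum())
        return count / total
    p_less = int((us <= u_obs + 1e-9).sum()) / total
    p_greater = int((us >= u_obs - 1e-9).sum()) / total
    return min(1.0, 2.0 * min(p_less, p_greater))


def _normal_rank_sum_p(pooled, n: int, m: int, u: float, alternative: str) -> float:
    N = n + m
    mean_u = n * m / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3) - counts).sum())
    var_u = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var_u == 0:
        return 1.0
    sd = math.sqrt(var_u)
    if alternative == "less":
        z = (u - mean_u + 0.5) / sd
        return float(stats.norm.cdf(z))
    if alternative == "greater":
        z = (u - mean_u - 0.5) / sd
        return float(stats.norm.sf(z))
    z = (abs(u - mean_u) - 0.5) / sd
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


# ---------------------------------------------------------------------------
# group-level summaries and gene-set comparisons

def group_direction_summary(
    summaries: list[SiteSummary],
    annotations: list[TranscriptAnnotation],
) -> dict[str, dict[str, float]]:
    """Percentage of up- and down-regulated transcripts per functional group.

    Unchanged transcripts count in the denominator only.
    """
    by_id = {s.transcript_id: s for s in summaries}
    groups: dict[str, list[SiteSummary]] = {}
    for a in annotations:
        if a.transcript_id in by_id:
            groups.setdefault(a.functional_group, []).append(by_id[a.transcript_id])
    out = {}
    for group, members in groups.items():
        n = len(members)
        n_up = sum(1 for s in members if s.direction == "up")
        n_down = sum(1 for s in members if s.direction == "down")
        out[group] = {
            "n": n,
            "pct_up": 100.0 * n_up / n,
            "pct_down": 100.0 * n_down / n,
        }
    return out


def compare_gene_sets(
    summaries: list[SiteSummary],
    set_a: set[str],
    set_b: set[str],
    statistic: str = "median_level",
    site: str = "QG",
    test: str = "ks",
    alternative: str = "two-sided",
) -> dict:
    """Compare two transcript sets on a per-transcript statistic.

    ``statistic`` is 'median_level' (the site median FPKM of ``site``) or
    'ratio' (QG/JH median fold change); ``test`` is 'ks' or 'wilcoxon'.
    """
    by_id = {s.transcript_id: s for s in summaries}

    def value(tid: str) -> float:
        s = by_id[tid]
        if statistic == "median_level":
            return s.median_QG if site == "QG" else s.median_JH
        if statistic == "ratio":
            return s.ratio
        raise ValueError(f"bad statistic {statistic!r}")

    a = [value(t) for t in sorted(set_a)]
    b = [value(t) for t in sorted(set_b)]
    if test == "ks":
        stat, p = ks_two_sample(a, b)
    elif test == "wilcoxon":
        stat, p = wilcoxon_rank_sum(a, b, alternative=alternative)
    else:
        raise ValueError(f"bad test {test!r}")
    return {
        "test": test, "statistic_name": statistic, "site": site,
        "n_a": len(a), "n_b": len(b), "statistic": stat, "p_value": p,
    }


def annotation_counts(annotations: list[TranscriptAnnotation]) -> dict[str, int]:
    """Candidate bookkeeping over an annotation table.

    Counts light-reaction members, dark-reaction members (Calvin + C4),
    non-dark paralogs, and the candidate total.
    """
    n_light = sum(1 for a in annotations if a.reaction_class == "light")
    n_calvin = sum(1 for a in annotations if a.functional_group == "Calvin")
    n_c4 = sum(1 for a in annotations if a.functional_group == "C4")
    n_dark = sum(1 for a in annotations if a.reaction_class == "dark")
    n_non_dark = sum(1 for a in annotations if a.reaction_class == "non_dark")
    return {
        "n_candidates": len(annotations),
        "n_light": n_light,
        "n_dark": n_dark,
        "n_calvin": n_calvin,
        "n_c4": n_c4,
        "n_non_dark": n_non_dark,
        "n_dark_and_non_dark": n_dark + n_non_dark,
    }
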