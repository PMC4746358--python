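"""Nei-Li nucleotide diversity from per-site SNP allele counts.

pi is the average pairwise nucleotide difference per base pair.  From a SNP
table it is computed as the sum over segregating sites of the unbiased
per-site heterozygosity 2*p*(1-p)*n/(n-1), divided by the full transcript
length (monomorphic sites included in the denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .exprstats import ks_two_sample
from .types import SNPTable


@dataclass(frozen=True)
class DiversityResult:
    transcript_id: str
    pi: float
    n_sites_segregating: int
    length: int

    def __post_init__(self):
        if self.pi < 0 or self.pi > 0.75:
            raise ValueError("pi outside the nucleotide bound [0, 0.75]")


def nei_li_pi(snps: SNPTable) -> DiversityResult:
    """Per-bp nucleotide diversity of one transcript.

    Sites with fewer than 2 sampled alleles are skipped with a warning; fixed
    differences (alt_count 0 or n) contribute nothing.
    """
    total = 0.0
    n_seg = 0
    for site in snps.sites:
        n = site.n_alleles
        if n < 2:
            warnings.warn(
                f"{snps.transcript_id} pos {site.position}: fewer than 2 alleles, skipped"
            )
            continue
        p = site.alt_count / n
        h = 2.0 * p * (1.0 - p) * n / (n - 1)
        if h > 0:
            n_seg += 1
        total += h
    return DiversityResult(
        transcript_id=snps.transcript_id,
        pi=total / snps.length,
        n_sites_segregating=n_seg,
        length=snps.length,
    )


def compare_site_diversity(
    results_a: list[DiversityResult],
    results_b: list[DiversityResult],
) -> dict:
    """Two-sample KS test on per-transcript pi between two site populations."""
    pis_a = [r.pi for r in results_a]
    pis_b = [r.pi for r in results_b]
    d, p = ks_two_sample(pis_a, pis_b)
    return {"D": d, "p_value": p, "n_a": len(pis_a), "n_b": len(pis_b)}


def write_diversity_table(results: dict[str, list[DiversityResult]], path) -> None:
    """TSV with one row per (site, transcript)."""
    with open(path, "w") as fh:
        fh.write("site\ttranscript_id\tlength\tn_sites_segregating\tpi\n")
        for site, rows in results.items():
            for r in rows:
                fh.write(
                    f"{site}\t{r.transcript_id}\t{r.length}\t"
                    f"{r.n_sites_segregating}\t{r.pi:.6g}\n"
                )
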