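"""Synthetic-data generators with the statistical structure the analysis assumes.

Three generators cover every pipeline input that would otherwise require the
field RNA-seq data:

* a two-site population FPKM matrix with group-structured correlation
  (log-normal FPKM; one latent factor per functional group, shared across
  sites, plus a planted per-transcript site fold change),
* nucleotide alignments evolved along a known tree under Jukes-Cantor,
* SNP tables planted to a target Nei-Li nucleotide diversity.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import TreeNode
from .types import (
    ConfigError,
    DARK_GROUPS,
    ExpressionMatrix,
    FUNCTIONAL_GROUPS,
    LIGHT_GROUPS,
    MultipleAlignment,
    SNPSite,
    SNPTable,
    TranscriptAnnotation,
)


# ---------------------------------------------------------------------------
# population expression

@dataclass
class PopulationSimConfig:
    """Study-shaped population expression simulation.

    ``transcripts`` has one row per transcript with columns:

    - ``transcript_id``
    - ``group``: functional group (latent-factor unit)
    - ``base_log2``: baseline log2 FPKM
    - ``shift_log2``: planted site fold change, log2(QG/JH)
    - ``loading``: coefficient on the shared group factor (lambda >= 0)

    Optional columns ``compartment``, ``reaction_class`` and ``energy_group``
    override the defaults derived from ``group``.
    """

    transcripts: pd.DataFrame
    n_samples_per_site: int = 39
    noise_sd: float = 0.5
    seed: int = 0
    site_labels: tuple[str, str] = ("JH", "QG")

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.n_samples_per_site < 2:
            raise ConfigError("need at least 2 samples per site")
        required = {"transcript_id", "group", "base_log2", "shift_log2", "loading"}
        missing = required - set(self.transcripts.columns)
        if missing:
            raise ConfigError(f"transcripts table missing columns {sorted(missing)}")
        if (self.transcripts["loading"] < 0).any():
            raise ConfigError("loadings must be >= 0")
        if self.transcripts["transcript_id"].duplicated().any():
            raise ConfigError("duplicate transcript ids")


def _default_reaction_class(group: str) -> str:
    if group in DARK_GROUPS:
        return "dark"
    if group in LIGHT_GROUPS:
        return "light"
    return "non_dark"


def simulate_population_expression(
    config: PopulationSimConfig,
) -> tuple[ExpressionMatrix, list[TranscriptAnnotation]]:
    """Draw FPKM = 2**(base + shift*[site==QG] + loading*f_group + noise).

    One standard-normal latent factor per group per sample induces the
    within-group correlation; transcripts with loading 0 are independent
    given their site.
    """
    rng = np.random.default_rng(config.seed)
    tr = config.transcripts.reset_index(drop=True)
    n_per = config.n_samples_per_site
    jh, qg = config.site_labels
    sample_ids = [f"{jh}_{i+1:02d}" for i in range(n_per)] + [
        f"{qg}_{i+1:02d}" for i in range(n_per)
    ]
    is_qg = np.array([0.0] * n_per + [1.0] * n_per)
    n_samples = 2 * n_per

    groups = list(dict.fromkeys(tr["group"]))  # stable order
    factors = {g: rng.standard_normal(n_samples) for g in groups}

    log2_vals = np.empty((len(tr), n_samples))
    for i, row in tr.iterrows():
        eps = rng.normal(0.0, config.noise_sd, size=n_samples)
        log2_vals[i] = (
            row["base_log2"]
            + row["shift_log2"] * is_qg
            + row["loading"] * factors[row["group"]]
            + eps
        )
    values = pd.DataFrame(
        np.exp2(log2_vals), index=list(tr["transcript_id"]), columns=sample_ids
    )
    site_of = {s: (qg if q else jh) for s, q in zip(sample_ids, is_qg)}
    expr = ExpressionMatrix(values, site_of)

    annotations = []
    known_groups = set(FUNCTIONAL_GROUPS)
    for _, row in tr.iterrows():
        group = row["group"]
        annotations.append(
            TranscriptAnnotation(
                transcript_id=row["transcript_id"],
                compartment=row.get("compartment", "nuclear"),
                reaction_class=row.get("reaction_class", _default_reaction_class(group)),
                functional_group=group if group in known_groups else "other",
                energy_group=row.get("energy_group", "other"),
            )
        )
    return expr, annotations


# ---------------------------------------------------------------------------
# sequence evolution (Jukes-Cantor along a known tree)

BASES = "ACGT"


@dataclass
class SeqSimConfig:
    tree: TreeNode
    seq_length: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.seq_length < 1:
            raise ConfigError("seq_length must be >= 1")
        for node in self.tree.walk():
            if node.length < 0:
                raise ConfigError("negative branch length")


def jc_substitution_probability(d: float) -> float:
    """P(observed substitution) after branch length d (expected subs/site)."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def simulate_alignment(config: SeqSimConfig) -> MultipleAlignment:
    """Evolve a uniform-random root sequence down the tree under Jukes-Cantor.

    Per branch of length d each site substitutes with probability
    p = (3/4)(1 - exp(-4d/3)); a substituting site picks uniformly among the
    three other bases.  Gap-free by construction.
    """
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    root_seq = rng.integers(0, 4, size=L)

    leaf_rows: dict[str, str] = {}

    def descend(node: TreeNode, seq: np.ndarray):
        for child in sorted(node.children, key=lambda c: min(c.leaf_names())):
            p = jc_substitution_probability(child.length)
            child_seq = seq.copy()
            hit = rng.random(L) < p
            if hit.any():
                # uniform among the other three bases
                child_seq[hit] = (child_seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
            if child.is_leaf:
                leaf_rows[child.name] = "".join(BASES[b] for b in child_seq)
            else:
                descend(child, child_seq)

    descend(config.tree, root_seq)
    names = sorted(leaf_rows)
    return MultipleAlignment(names, [leaf_rows[n] for n in names])


# ---------------------------------------------------------------------------
# SNP tables with a target nucleotide diversity

def simulate_snp_table(
    transcript_id: str,
    length: int,
    n_alleles: int,
    target_pi: float,
    seed: int = 0,
) -> SNPTable:
    """Plant segregating sites so the expected Nei-Li pi is ``target_pi``.

    Alternate-allele counts are drawn uniformly from 1..n-1 and sites are
    added until the cumulative per-site heterozygosity reaches
    ``target_pi * length`` (stopping at whichever side of the target is
    closer), so the estimator recovers the target up to the granularity of a
    single site.
    """
    if target_pi < 0:
        raise ConfigError("target_pi must be >= 0")
    if n_alleles < 2:
        raise ConfigError("need at least 2 alleles")
    if target_pi == 0:
        return SNPTable(transcript_id, length, [])
    rng = np.random.default_rng(seed)
    goal = target_pi * length
    # minimum per-site contribution (singleton) bounds the site count
    min_contrib = 2.0 * (1.0 / n_alleles) * (1.0 - 1.0 / n_alleles) * n_alleles / (n_alleles - 1)
    if goal / min_contrib > length:
        raise ConfigError("target_pi implies more segregating sites than positions")

    total = 0.0
    contribs: list[tuple[int, float]] = []  # (alt_count, contribution)
    while total < goal and len(contribs) < length:
        a = int(rng.integers(1, n_alleles))
        p = a / n_alleles
        c = 2.0 * p * (1.0 - p) * n_alleles / (n_alleles - 1)
        if total + c > goal and (total + c - goal) > (goal - total):
            break  # overshoot would be worse than stopping here
        contribs.append((a, c))
        total += c
    positions = rng.choice(length, size=len(contribs), replace=False) + 1
    sites = [
        SNPSite(int(pos), alt, n_alleles)
        for pos, (alt, _) in sorted(zip(positions, contribs))
    ]
    return SNPTable(transcript_id, length, sites)


# ---------------------------------------------------------------------------
# study-shaped default design

# Functional-group sizes of the 78-transcript photosynthesis panel plus the
# 30 non-dark paralogs (cytosolic glycolysis/gluconeogenesis isoforms).
STUDY_GROUP_SIZES: dict[str, int] = {
    "C4": 5,
    "Calvin": 18,
    "Cytb6f": 5,
    "FATPase": 7,
    "PET": 12,
    "Lhca": 5,
    "Psa": 9,
    "Lhcb": 5,
    "Psb": 12,
}
N_NON_DARK = 30

# Groups whose member transcripts ride a strong shared latent factor
# (the coordinated functional units); the rest get a weak factor.
COORDINATED_GROUPS = ("Lhca", "Psa", "Psb", "FATPase", "C4", "Calvin")

# Planted log2(QG/JH) mean shifts per group: dark-reaction transcripts
# mostly up-regulated in the harsh site, most light-reaction complexes down,
# Lhca/PET mildly up, chloroplast-encoded transcripts show increased
# degradation.  Signs are mixed across the panel so that the array
# median-centering step cannot absorb the site signal.
GROUP_SHIFT_MEANS: dict[str, float] = {
    "C4": 1.2,
    "Calvin": 1.0,
    "Cytb6f": -0.8,
    "FATPase": -0.8,
    "PET": 0.4,
    "Lhca": 0.4,
    "Psa": -0.8,
    "Lhcb": -1.0,
    "Psb": -0.9,
    "other": -0.2,
}

GROUP_BASE_MEANS: dict[str, float] = {
    "C4": 10.0,
    "Calvin": 9.5,
    "other": 7.0,
}

# chloroplast-encoded members per light-reaction group (4 Psb, 2 Cyt b6/f,
# 3 Psa, 5 F-ATPase = 14 chloroplast transcripts of the light reaction)
CHLOROPLAST_COUNTS: dict[str, int] = {"Psb": 4, "Cytb6f": 2, "Psa": 3, "FATPase": 5}


def study_transcript_table(
    seed: int = 0,
    group_sizes: dict[str, int] | None = None,
    n_non_dark: int = N_NON_DARK,
    loading_coordinated: float = 1.0,
    loading_other: float = 0.2,
    shift_sd: float = 0.4,
) -> pd.DataFrame:
    """Transcript design table mirroring the study panel.

    78 pathway transcripts in nine functional groups plus ``n_non_dark``
    cytosolic paralogs, with group-level base expression, planted site
    shifts, and latent-factor loadings.
    """
    rng = np.random.default_rng(seed)
    sizes = dict(group_sizes or STUDY_GROUP_SIZES)
    rows = []
    for group, size in sizes.items():
        chl = CHLOROPLAST_COUNTS.get(group, 0)
        for i in range(size):
            base = rng.normal(GROUP_BASE_MEANS.get(group, 8.0), 1.5)
            shift = rng.normal(GROUP_SHIFT_MEANS.get(group, 0.0), shift_sd)
            loading = (
                loading_coordinated if group in COORDINATED_GROUPS else loading_other
            )
            energy = "other"
            if group in DARK_GROUPS:
                # PPDK/PGK/PRK-like members consume ATP; MDH/GAPDH/ME-like
                # members cycle NADP+/NADPH
                if i % 5 == 0:
                    energy = "ATP_related"
                elif i % 5 == 1:
                    energy = "NADPH_related"
            rows.append(
                {
                    "transcript_id": f"Ml{group}_{i+1:02d}",
                    "group": group,
                    "base_log2": base,
                    "shift_log2": shift,
                    "loading": loading,
                    "compartment": "chloroplast" if i < chl else "nuclear",
                    "reaction_class": _default_reaction_class(group),
                    "energy_group": energy,
                }
            )
    for i in range(n_non_dark):
        rows.append(
            {
                "transcript_id": f"MlPara_{i+1:02d}",
                "group": "other",
                "base_log2": rng.normal(GROUP_BASE_MEANS["other"], 1.5),
                "shift_log2": rng.normal(GROUP_SHIFT_MEANS["other"], shift_sd),
                "loading": 0.0,
                "compartment": "nuclear",
                "reaction_class": "non_dark",
                "energy_group": "other",
            }
        )
    return pd.DataFrame(rows)
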