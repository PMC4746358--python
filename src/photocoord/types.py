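"""Shared domain types for the photosynthesis coordination pipeline.

The pipeline consumes five kinds of input: a population FPKM expression
matrix with a sample-to-site map, a transcript annotation table, BLAST-style
tabular homology hits, aligned nucleotide sequence families, and per-transcript
SNP tables.  Each type validates its own invariants on construction so that
downstream stages can assume well-formed data.

FPKM semantics: for nuclear-encoded transcripts the value measures expression
level; for chloroplast-encoded transcripts (polyadenylated degradation
intermediates captured by poly-A selection) it measures degradation level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPARTMENTS = ("nuclear", "chloroplast")
REACTION_CLASSES = ("light", "dark", "non_dark")
FUNCTIONAL_GROUPS = (
    "Lhcb", "Psb", "Lhca", "Psa", "Cytb6f", "PET", "FATPase",
    "C4", "Calvin", "other",
)
ENERGY_GROUPS = ("ATP_related", "NADPH_related", "other")

# functional groups belonging to the light reaction
LIGHT_GROUPS = ("Lhcb", "Psb", "Lhca", "Psa", "Cytb6f", "PET", "FATPase")
DARK_GROUPS = ("C4", "Calvin")


class FormatError(ValueError):
    """Malformed input file (structure, not values)."""


class MappingError(KeyError):
    """An identifier is missing from a required map."""


class ConfigError(ValueError):
    """Invalid simulation or pipeline configuration."""


class ExpressionMatrix:
    """Transcripts x samples FPKM matrix with a sample -> site map.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by transcript id, columns by sample id, non-negative
        FPKM values.
    site_of : dict
        Maps every sample id to one of exactly two site labels
        (``"JH"`` and ``"QG"`` in the study design).
    """

    def __init__(self, values: pd.DataFrame, site_of: dict[str, str]):
        if values.index.duplicated().any():
            raise FormatError("duplicate transcript ids")
        if values.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("missing FPKM values are not permitted on input")
        if (arr < 0).any():
            raise ValueError("negative FPKM values")
        missing = [s for s in values.columns if s not in site_of]
        if missing:
            raise MappingError(f"samples missing from site map: {missing}")
        sites = sorted({site_of[s] for s in values.columns})
        if len(sites) != 2:
            raise ValueError(f"expected exactly two site labels, got {sites}")
        for site in sites:
            n = sum(1 for s in values.columns if site_of[s] == site)
            if n < 2:
                raise ValueError(f"site {site} has fewer than 2 samples")
        self.values = values.astype(float)
        self.site_of = {s: site_of[s] for s in values.columns}
        self.sites = tuple(sites)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of_site(self, site: str) -> list[str]:
        return [s for s in self.values.columns if self.site_of[s] == site]

    def subset(self, transcript_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(transcript_ids)], self.site_of)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.values.equals(other.values)
            and self.site_of == other.site_of
        )

    def __repr__(self) -> str:
        nt, ns = self.values.shape
        return f"ExpressionMatrix({nt} transcripts x {ns} samples, sites={self.sites})"


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Pathway annotation for one transcript."""

    transcript_id: str
    compartment: str = "nuclear"
    reaction_class: str = "light"
    functional_group: str = "other"
    energy_group: str = "other"

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"bad compartment {self.compartment!r}")
        if self.reaction_class not in REACTION_CLASSES:
            raise ValueError(f"bad reaction_class {self.reaction_class!r}")
        if self.functional_group not in FUNCTIONAL_GROUPS:
            raise ValueError(f"bad functional_group {self.functional_group!r}")
        if self.energy_group not in ENERGY_GROUPS:
            raise ValueError(f"bad energy_group {self.energy_group!r}")
        if self.functional_group in DARK_GROUPS and self.reaction_class != "dark":
            raise ValueError(
                f"{self.functional_group} transcripts belong to the dark reaction"
            )


@dataclass(frozen=True)
class HitRecord:
    """One BLAST tabular (outfmt 6) hit, strand-normalized.

    Coordinates are 1-based inclusive.  Reverse-strand target hits
    (tstart > tend in the file) are stored with start < end and
    ``target_reversed=True``.
    """

    query_id: str
    target_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    e_value: float
    bit_score: float
    target_reversed: bool = False

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity outside [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.e_value < 0:
            raise ValueError("negative e-value")
        if self.query_start > self.query_end:
            raise ValueError("query coordinates not normalized")
        if self.target_start > self.target_end:
            raise ValueError("target coordinates not normalized")


@dataclass(frozen=True)
class SNPSite:
    position: int          # 1-based bp within the transcript
    alt_count: int         # copies of the alternate allele observed
    n_alleles: int         # total allele copies sampled at this site


@dataclass
class SNPTable:
    """Segregating sites of one transcript in one site population."""

    transcript_id: str
    length: int
    sites: list[SNPSite] = field(default_factory=list)

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("transcript length must be >= 1")
        seen = set()
        for s in self.sites:
            if not 0 <= s.alt_count <= s.n_alleles:
                raise ValueError(f"alt_count out of range at {s.position}")
            if not 1 <= s.position <= self.length:
                raise ValueError(f"position {s.position} outside transcript")
            if s.position in seen:
                raise ValueError(f"duplicate position {s.position}")
            seen.add(s.position)


REFERENCE_LABELS = ("C4_ref", "Calvin_ref", "cytosolic_ref", "none")


class MultipleAlignment:
    """Aligned nucleotide sequences over {A, C, G, T, -, N}.

    ``reference_labels`` is a partial map leaf -> reference class used by the
    clade classifier; leaves without an entry are unlabeled queries.
    """

    ALPHABET = set("ACGT-N")

    def __init__(
        self,
        leaf_ids: list[str],
        rows: list[str],
        reference_labels: dict[str, str] | None = None,
    ):
        if len(leaf_ids) != len(rows):
            raise FormatError("leaf_ids and rows differ in length")
        if len(set(leaf_ids)) != len(leaf_ids):
            raise FormatError("duplicate leaf ids")
        if rows:
            L = len(rows[0])
            for lid, r in zip(leaf_ids, rows):
                if len(r) != L:
                    raise FormatError(f"ragged alignment: {lid} has length {len(r)} != {L}")
                bad = set(r.upper()) - self.ALPHABET
                if bad:
                    raise FormatError(f"illegal characters in {lid}: {sorted(bad)}")
        self.leaf_ids = list(leaf_ids)
        self.rows = [r.upper() for r in rows]
        labels = dict(reference_labels or {})
        for leaf, lab in labels.items():
            if lab not in REFERENCE_LABELS:
                raise ValueError(f"unknown reference label {lab!r}")
        self.reference_labels = labels

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def slice_columns(self, intervals) -> "MultipleAlignment":
        """Concatenate the 0-based half-open column intervals."""
        rows = [
            "".join(r[a:b] for a, b in intervals) for r in self.rows
        ]
        return MultipleAlignment(self.leaf_ids, rows, self.reference_labels)
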