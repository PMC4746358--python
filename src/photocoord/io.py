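"""Readers and writers for every on-disk format the pipeline touches.

All formats are plain text: expression matrices and site maps are TSV,
homology hits are 12-column BLAST tabular (outfmt 6), alignments are aligned
FASTA with reference labels encoded as ``|C4_ref``-style header suffixes,
SNP tables are long-format TSV.  Every reader has a matching writer and the
pair round-trips exactly (modulo float formatting).
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    ExpressionMatrix,
    FormatError,
    HitRecord,
    MultipleAlignment,
    REFERENCE_LABELS,
    SNPSite,
    SNPTable,
    TranscriptAnnotation,
)


# ---------------------------------------------------------------------------
# expression matrix + site map

def read_site_map(path) -> dict[str, str]:
    """Two-column TSV ``sample<TAB>site`` with a header row."""
    site_of: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise FormatError("site map needs two columns: sample, site")
        for row in reader:
            if not row:
                continue
            if len(row) < 2:
                raise FormatError(f"short site-map row: {row}")
            sample, site = row[0], row[1]
            if sample in site_of:
                raise FormatError(f"duplicate sample {sample!r} in site map")
            site_of[sample] = site
    return site_of


def write_site_map(site_of: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tsite\n")
        for sample, site in site_of.items():
            fh.write(f"{sample}\t{site}\n")


def read_expression_matrix(path, site_map_path) -> ExpressionMatrix:
    """TSV with transcript ids in the first column, sample ids in the header."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise FormatError("duplicate sample ids in expression header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if df.index.has_duplicates:
        raise FormatError("duplicate transcript ids in expression file")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric FPKM value: {exc}") from exc
    site_of = read_site_map(site_map_path)
    return ExpressionMatrix(df, site_of)


def write_expression_matrix(expr: ExpressionMatrix, path, site_map_path=None) -> None:
    df = expr.values.copy()
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t")
    if site_map_path is not None:
        write_site_map(expr.site_of, site_map_path)


# ---------------------------------------------------------------------------
# annotation table

_ANN_COLUMNS = [
    "transcript_id", "compartment", "reaction_class", "functional_group",
    "energy_group",
]


def read_annotation(path) -> list[TranscriptAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ANN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation file missing columns {missing}")
    return [
        TranscriptAnnotation(
            transcript_id=row.transcript_id,
            compartment=row.compartment,
            reaction_class=row.reaction_class,
            functional_group=row.functional_group,
            energy_group=row.energy_group,
        )
        for row in df.itertuples()
    ]


def write_annotation(annotations, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANN_COLUMNS) + "\n")
        for a in annotations:
            fh.write(
                f"{a.transcript_id}\t{a.compartment}\t{a.reaction_class}\t"
                f"{a.functional_group}\t{a.energy_group}\n"
            )


def annotation_index(annotations) -> dict[str, TranscriptAnnotation]:
    return {a.transcript_id: a for a in annotations}


# ---------------------------------------------------------------------------
# BLAST tabular hits (outfmt 6)

def read_hit_table(path) -> list[HitRecord]:
    """Parse a 12-column BLAST tabular file into strand-normalized records.

    Reverse-strand target coordinates (tstart > tend) are swapped and the
    orientation retained on ``target_reversed``.
    """
    records: list[HitRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"line {ln}: expected 12 tab-separated columns, got {len(fields)}"
                )
            (qid, tid, pident, length, mismatch, gapopen,
             qstart, qend, tstart, tend, evalue, bitscore) = fields
            try:
                ts, te = int(tstart), int(tend)
                reversed_ = ts > te
                if reversed_:
                    ts, te = te, ts
                rec = HitRecord(
                    query_id=qid,
                    target_id=tid,
                    percent_identity=float(pident),
                    alignment_length=int(length),
                    mismatches=int(mismatch),
                    gap_opens=int(gapopen),
                    query_start=int(qstart),
                    query_end=int(qend),
                    target_start=ts,
                    target_end=te,
                    e_value=float(evalue),
                    bit_score=float(bitscore),
                    target_reversed=reversed_,
                )
            except ValueError as exc:
                raise ValueError(f"line {ln}: {exc}") from exc
            records.append(rec)
    return records


def write_hit_table(hits, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            ts, te = h.target_start, h.target_end
            if h.target_reversed:
                ts, te = te, ts
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.percent_identity:g}\t"
                f"{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.query_start}\t{h.query_end}\t{ts}\t{te}\t"
                f"{h.e_value:g}\t{h.bit_score:g}\n"
            )


# ---------------------------------------------------------------------------
# aligned FASTA

def read_alignment(path, min_seqs: int = 3) -> MultipleAlignment:
    """Aligned FASTA; a header suffix like ``|C4_ref`` marks a reference leaf."""
    leaf_ids, rows, labels = [], [], {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        label = None
        if "|" in name:
            name, _, tag = name.rpartition("|")
            if tag in REFERENCE_LABELS:
                label = tag
            else:
                name = rec.id  # suffix is part of the id, not a label
        leaf_ids.append(name)
        rows.append(str(rec.seq))
        if label and label != "none":
            labels[name] = label
    if len(rows) < min_seqs:
        raise FormatError(f"alignment has {len(rows)} < {min_seqs} sequences")
    return MultipleAlignment(leaf_ids, rows, labels)


def write_alignment(aln: MultipleAlignment, path) -> None:
    records = []
    for leaf, row in zip(aln.leaf_ids, aln.rows):
        name = leaf
        if leaf in aln.reference_labels:
            name = f"{leaf}|{aln.reference_labels[leaf]}"
        records.append(SeqRecord(Seq(row), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# SNP tables

_SNP_HEADER = ["transcript_id", "length", "position", "alt_count", "n_alleles"]


def read_snp_tables(path) -> dict[str, SNPTable]:
    """Long-format TSV; a transcript with no segregating sites appears as a
    single row with '.' in the position/alt_count/n_alleles columns."""
    tables: dict[str, SNPTable] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _SNP_HEADER:
            raise FormatError(f"SNP table header must be {_SNP_HEADER}")
        for row in reader:
            if not row:
                continue
            tid, length = row[0], int(row[1])
            tbl = tables.get(tid)
            if tbl is None:
                tbl = tables[tid] = SNPTable(tid, length, [])
            elif tbl.length != length:
                raise FormatError(f"inconsistent length for {tid}")
            if row[2] == ".":
                continue
            tbl.sites.append(SNPSite(int(row[2]), int(row[3]), int(row[4])))
    for tbl in tables.values():
        SNPTable(tbl.transcript_id, tbl.length, tbl.sites)  # re-validate
    return tables


def write_snp_tables(tables, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SNP_HEADER) + "\n")
        items = tables.values() if isinstance(tables, dict) else tables
        for tbl in items:
            if not tbl.sites:
                fh.write(f"{tbl.transcript_id}\t{tbl.length}\t.\t.\t.\n")
            for s in tbl.sites:
                fh.write(
                    f"{tbl.transcript_id}\t{tbl.length}\t{s.position}\t"
                    f"{s.alt_count}\t{s.n_alleles}\n"
                )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
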