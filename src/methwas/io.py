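"""Readers and writers for the interchange formats.

Beta and detection-p matrices travel as TSV (probes in rows, samples in
columns), sample sheets as CSV, probe annotation as a BED-compatible TSV
(0-based half-open intervals on disk, 1-based point positions in memory),
amplicon references as FASTA plus a CpG-offset TSV, and reads as
(optionally gzipped) Phred+33 FASTQ via Biopython. Every writer/reader
pair round-trips.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import ANNOTATION_COLUMNS, Amplicon, BetaMatrix, ReadRecord, validate_annotation, validate_sample_sheet

__all__ = [
    "write_beta_matrix",
    "read_beta_matrix",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_annotation",
    "read_annotation",
    "write_fastq",
    "read_fastq",
    "write_panel",
    "read_panel",
]


def write_beta_matrix(beta: BetaMatrix, path, detection_path=None) -> None:
    beta.values.to_csv(path, sep="\t", index_label="probe_id")
    if detection_path is not None and beta.detection_p is not None:
        beta.detection_p.to_csv(detection_path, sep="\t", index_label="probe_id")


def read_beta_matrix(path, detection_path=None) -> BetaMatrix:
    vals = pd.read_csv(path, sep="\t", index_col="probe_id")
    bad = vals.columns[vals.dtypes == object]
    if len(bad):
        raise ValueError(f"non-numeric beta values in columns: {list(bad)}")
    det = pd.read_csv(detection_path, sep="\t", index_col="probe_id") if detection_path else None
    return BetaMatrix(vals, det)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet).to_csv(path, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample_id": str, "rebatch_of": str})
    sheet["rebatch_of"] = sheet["rebatch_of"].fillna("")
    return validate_sample_sheet(sheet)


def write_annotation(annot: pd.DataFrame, path) -> None:
    """BED-compatible TSV: chrom, start (0-based half-open), end, probe_id, strand, flags."""
    validate_annotation(annot)
    out = pd.DataFrame(
        {
            "chrom": annot["chrom"],
            "start": annot["pos"] - 1,  # 1-based point -> 0-based half-open
            "end": annot["pos"],
            "probe_id": annot["probe_id"],
            "strand": annot["strand"],
        }
    )
    for c in ("snp_affected", "sex_chrom", "cpg_context", "promoter", "candidate_region"):
        out[c] = annot[c].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    annot = pd.DataFrame(
        {
            "probe_id": raw["probe_id"],
            "chrom": raw["chrom"],
            "pos": raw["start"] + 1,  # 0-based half-open -> 1-based point
            "strand": raw["strand"],
        }
    )
    for c in ("snp_affected", "sex_chrom", "cpg_context", "promoter", "candidate_region"):
        annot[c] = raw[c].astype(bool)
    if not (raw["end"] - raw["start"] == 1).all():
        raise ValueError("probe intervals must be single-base")
    return validate_annotation(annot[list(ANNOTATION_COLUMNS)])


def write_fastq(records, path) -> None:
    path = str(path)
    seqrecs = []
    for r in records:
        sr = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        sr.letter_annotations["phred_quality"] = list(r.qualities)
        seqrecs.append(sr)
    if path.endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            SeqIO.write(seqrecs, fh, "fastq")
    else:
        SeqIO.write(seqrecs, path, "fastq")


def read_fastq(path) -> list[ReadRecord]:
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    out = []
    with opener(path, "rt") as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
            seq = str(rec.seq)
            quals = rec.letter_annotations["phred_quality"]
            if len(seq) != len(quals):  # pragma: no cover - Biopython enforces this
                raise ValueError(f"record {rec.id} (#{i + 1}): sequence/quality length mismatch")
            out.append(ReadRecord(rec.id, seq, list(quals)))
    return out


def write_panel(panel: list[Amplicon], fasta_path, offsets_path) -> None:
    """Amplicon references as FASTA plus a TSV of CpG offsets and anchors."""
    SeqIO.write(
        [SeqRecord(Seq(a.ref_seq), id=a.amplicon_id, description="") for a in panel],
        str(fasta_path),
        "fasta",
    )
    rows = []
    for a in panel:
        rows.append(
            {
                "amplicon_id": a.amplicon_id,
                "chrom": a.chrom,
                "genomic_start": a.genomic_start,
                "cpg_offsets": ",".join(map(str, a.cpg_offsets)),
                "mvp_offset": "" if a.mvp_offset is None else a.mvp_offset,
            }
        )
    pd.DataFrame(rows).to_csv(offsets_path, sep="\t", index=False)


def read_panel(fasta_path, offsets_path) -> list[Amplicon]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    meta = pd.read_csv(offsets_path, sep="\t", dtype={"mvp_offset": "string"})
    panel = []
    for row in meta.itertuples(index=False):
        mvp = None if pd.isna(row.mvp_offset) or row.mvp_offset == "" else int(row.mvp_offset)
        panel.append(
            Amplicon(
                amplicon_id=row.amplicon_id,
                ref_seq=seqs[row.amplicon_id],
                cpg_offsets=tuple(int(x) for x in str(row.cpg_offsets).split(",")),
                chrom=row.chrom,
                genomic_start=int(row.genomic_start),
                mvp_offset=mvp,
            )
        )
    return panel


def write_mvp_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_mvp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "is_mvp" in df.columns:
        df["is_mvp"] = df["is_mvp"].astype(bool)
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
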