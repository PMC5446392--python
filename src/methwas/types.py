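"""Core containers shared across the pipeline.

The central array object is the :class:`BetaMatrix` (probes x samples
methylation fractions); sample metadata, probe annotation and result
tables are plain :class:`pandas.DataFrame` objects with documented,
validated column contracts so they remain easy to write to and read
from TSV/CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: required columns of a sample sheet
SAMPLE_SHEET_COLUMNS = ("sample_id", "group", "sex", "age", "batch", "rebatch_of", "tissue")

#: required columns of a probe annotation table
ANNOTATION_COLUMNS = (
    "probe_id",
    "chrom",
    "pos",
    "strand",
    "snp_affected",
    "sex_chrom",
    "cpg_context",
    "promoter",
    "candidate_region",
)

#: columns of an MVP (methylation variable position) result table
MVP_COLUMNS = ("probe_id", "chrom", "pos", "effect", "coef", "p_raw", "p_adj", "is_mvp")


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions in [0, 1].

    Parameters
    ----------
    values
        DataFrame indexed by probe_id with sample_id columns; entries are
        beta values (methylated / total signal).
    detection_p
        Optional matrix of per-probe, per-sample detection p-values with
        the same index/columns; high values flag unreliable measurements.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if self.detection_p is not None:
            if not self.detection_p.index.equals(self.values.index) or not self.detection_p.columns.equals(
                self.values.columns
            ):
                raise ValueError("detection_p must share the beta matrix index and columns")
            d = self.detection_p.to_numpy(dtype=float)
            if d.size and (np.nanmin(d) < 0 or np.nanmax(d) > 1):
                raise ValueError("detection p-values must lie in [0, 1]")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        keep = self.values.index.isin(set(probe_ids))
        det = self.detection_p.loc[keep] if self.detection_p is not None else None
        return BetaMatrix(self.values.loc[keep], det)

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        cols = [s for s in self.values.columns if s in set(sample_ids)]
        det = self.detection_p[cols] if self.detection_p is not None else None
        return BetaMatrix(self.values[cols], det)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-sheet column contract and pairing consistency."""
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    ids = set(sheet["sample_id"])
    by_id = sheet.set_index("sample_id")
    for sid, ref in sheet[["sample_id", "rebatch_of"]].itertuples(index=False):
        if pd.isna(ref) or ref == "":
            continue
        if ref not in ids:
            raise ValueError(f"rebatch_of of {sid} names unknown sample {ref}")
        if by_id.loc[ref, "batch"] == by_id.loc[sid, "batch"]:
            raise ValueError(f"re-batch sample {sid} shares batch with its original {ref}")
    return sheet


def validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annot.columns]
    if missing:
        raise ValueError(f"probe annotation missing columns: {missing}")
    if annot["probe_id"].duplicated().any():
        raise ValueError("duplicate probe ids in annotation")
    if (annot["pos"] < 1).any():
        raise ValueError("positions are 1-based and must be >= 1")
    return annot


@dataclass
class BatchMarkerResult:
    """Output of paired batch-marker discovery and covariate selection.

    ``candidate_p`` maps every tested probe to its paired t-test p-value;
    ``candidates`` are the probes below the discovery threshold;
    ``selected_covariates`` is the ordered, loci-independent subset chosen
    by iterative ranking; ``selection_trace`` records, per round, the probe
    chosen and how many candidates remained significant after adjustment.
    """

    candidate_p: pd.Series
    candidates: list[str] = field(default_factory=list)
    selected_covariates: list[str] = field(default_factory=list)
    selection_trace: list[tuple[str, int]] = field(default_factory=list)
    degenerate_probes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Amplicon:
    """One bisulfite-PCR amplicon of the replication panel.

    ``ref_seq`` is the unconverted genomic reference with primers trimmed;
    ``cpg_offsets`` are 0-based offsets of CpG cytosines within it;
    ``mvp_offset`` marks which CpG is the tested MVP.
    """

    amplicon_id: str
    ref_seq: str
    cpg_offsets: tuple[int, ...]
    chrom: str = "chrU"
    genomic_start: int = 1  # 1-based anchor of ref_seq[0]
    mvp_offset: int | None = None

    def __post_init__(self) -> None:
        offs = self.cpg_offsets
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("cpg_offsets must be strictly increasing")
        for o in offs:
            if not 0 <= o < len(self.ref_seq):
                raise ValueError(f"CpG offset {o} outside reference")
            if self.ref_seq[o].upper() != "C":
                raise ValueError(f"reference base at CpG offset {o} is not C")
        if self.mvp_offset is not None and self.mvp_offset not in offs:
            raise ValueError("mvp_offset must be one of cpg_offsets")


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: list[int]
    barcode: str = ""
    assigned_sample: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")


@dataclass
class AlignedRead:
    """A read aligned to its amplicon reference with bisulfite-aware calls.

    ``cpg_calls`` holds one symbol per panel CpG: ``M`` (methylated, C read),
    ``U`` (unmethylated, T read), ``-`` (gap / not covered), ``?`` (other base).
    """

    read_id: str
    amplicon_id: str
    score: float
    identity: float
    conversion_rate: float
    cpg_gap_fraction: float
    cpg_calls: str
    ref_start: int = 0
    ref_end: int = 0
    reverse_complement: bool = False
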