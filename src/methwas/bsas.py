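"""Bisulfite amplicon sequencing (BSAS) quantification.

Demultiplexes barcoded reads, applies a per-read quality filter, aligns
each read to its amplicon reference with a bisulfite-aware semi-global
dynamic program, filters alignments on identity / conversion rate / CpG
gaps, calls per-CpG methylation fractions and compares groups at the
tested MVP sites.

The aligner is a Needleman-Wunsch-style semi-global DP (read aligned
end-to-end, reference overhangs free) with linear gap penalty and
bisulfite-asymmetric matching: a read T opposite a reference C counts as
a match at non-CpG positions (bisulfite conversion), while at CpG offsets
both C (methylated) and T (unmethylated) match and are recorded as calls.
Bisulfite conversions therefore count toward identity — converted reads
could never reach a 90% identity threshold otherwise.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import GroupComparison, welch_t
from .types import AlignedRead, Amplicon, ReadRecord

__all__ = [
    "demultiplex",
    "quality_filter",
    "bisulfite_align",
    "filter_alignments",
    "call_methylation",
    "compare_mvp_sites",
    "run_bsas",
    "BsasFilterLog",
]

MATCH, MISMATCH, GAP = 1.0, -1.0, -2.0
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def demultiplex(reads, barcode_map: dict[str, str]) -> tuple[dict[str, list[ReadRecord]], int]:
    """Exact-prefix barcode splitting.

    Assigns each read to the sample whose barcode is an exact prefix of its
    sequence, trimming the barcode from sequence and qualities; returns
    per-sample read lists and the unassigned count.
    """
    if not barcode_map:
        raise ValueError("empty barcode map")
    if not isinstance(barcode_map, dict):
        pairs = list(barcode_map)
        bcs = [b for b, _ in pairs]
        if len(bcs) != len(set(bcs)):
            raise ValueError("duplicate barcodes")
        barcode_map = dict(pairs)
    lengths = {len(b) for b in barcode_map}
    if len(lengths) != 1:
        raise ValueError("barcodes must share one length")
    blen = lengths.pop()
    out: dict[str, list[ReadRecord]] = defaultdict(list)
    unassigned = 0
    for r in reads:
        prefix = r.sequence[:blen]
        sample = barcode_map.get(prefix)
        if sample is None:
            unassigned += 1
            continue
        out[sample].append(
            ReadRecord(r.read_id, r.sequence[blen:], r.qualities[blen:], barcode=prefix, assigned_sample=sample)
        )
    return dict(out), unassigned


def quality_filter(reads, min_q: int = 30, min_frac: float = 0.5) -> tuple[list[ReadRecord], int]:
    """Keep reads with at least ``min_frac`` of bases strictly above ``min_q``.

    The boundary is strict on quality (Q must exceed min_q) and inclusive on
    the fraction; empty reads are dropped and counted.
    """
    kept: list[ReadRecord] = []
    dropped = 0
    for r in reads:
        if not r.sequence:
            dropped += 1
            continue
        good = sum(1 for q in r.qualities if q > min_q)
        if good / len(r.qualities) >= min_frac:
            kept.append(r)
        else:
            dropped += 1
    return kept, dropped


def _score_matrix(read: str, amp: Amplicon) -> np.ndarray:
    """Bisulfite-asymmetric substitution scores, read x reference."""
    ref = amp.ref_seq.upper()
    cpg = np.zeros(len(ref), dtype=bool)
    cpg[list(amp.cpg_offsets)] = True
    refc = np.frombuffer(ref.encode(), dtype="S1")
    rdc = np.frombuffer(read.upper().encode(), dtype="S1")
    S = np.where(rdc[:, None] == refc[None, :], MATCH, MISMATCH)
    is_c = refc == b"C"
    is_ct = (rdc == b"C") | (rdc == b"T")
    # ref C: read T matches at non-CpG (conversion); at CpG both C and T match
    S[np.ix_(is_ct, is_c)] = MATCH
    # ref C with read not in {C, T} stays a mismatch; at CpG likewise
    bad = ~is_ct
    S[np.ix_(bad, is_c)] = MISMATCH
    del cpg  # CpG and non-CpG C score identically; they differ only in calls
    return S


def _dp_semiglobal(S: np.ndarray) -> np.ndarray:
    """Fill the semi-global DP table (free reference overhangs)."""
    m, n = S.shape
    H = np.empty((m + 1, n + 1))
    H[0, :] = 0.0
    cols = 2.0 * np.arange(n + 1)
    for i in range(1, m + 1):
        d = np.empty(n + 1)
        d[0] = GAP * i
        d[1:] = np.maximum(H[i - 1, :-1] + S[i - 1], H[i - 1, 1:] + GAP)
        # horizontal chain H[j] = max(d[j], H[j-1] + GAP) via prefix max
        H[i] = np.maximum.accumulate(d + cols) - cols
    return H


def bisulfite_align(
    read: ReadRecord | str,
    amp: Amplicon,
    min_read_length: int = 30,
    try_reverse_complement: bool = True,
) -> AlignedRead | None:
    """Align one read to an amplicon reference, bisulfite-aware.

    Both the read and (optionally) its reverse complement are aligned; the
    better score wins, ties preferring the forward orientation and, within
    an orientation, the alignment ending earliest on the reference.
    Returns ``None`` for reads shorter than ``min_read_length``.

    The returned metrics follow the quantification contract: identity is
    matching columns over the aligned reference span (reference bases
    deleted from the read count against it); conversion rate is T/(C+T)
    over aligned non-CpG reference cytosines; the CpG gap fraction counts
    panel CpGs aligned to a gap or not covered by the read.
    """
    if isinstance(read, ReadRecord):
        rid, seq = read.read_id, read.sequence
    else:
        rid, seq = "", read
    seq = seq.upper()
    if len(seq) < min_read_length:
        return None

    variants = [(seq, False)]
    if try_reverse_complement:
        variants.append((_revcomp(seq), True))
    best = None
    for s, is_rc in variants:
        S = _score_matrix(s, amp)
        H = _dp_semiglobal(S)
        j_end = int(np.argmax(H[-1]))  # argmax takes the earliest tie
        score = H[-1, j_end]
        if best is None or score > best[0]:
            best = (score, s, is_rc, S, H, j_end)
    score, s, is_rc, S, H, j_end = best

    # traceback: diagonal preferred, then read-insertion, then read-deletion
    ref = amp.ref_seq.upper()
    i, j = len(s), j_end
    aligned_to: dict[int, str | None] = {}  # ref offset -> read base or None (gap)
    match_cols = 0
    while i > 0:
        if j > 0 and np.isclose(H[i, j], H[i - 1, j - 1] + S[i - 1, j - 1]):
            aligned_to[j - 1] = s[i - 1]
            if S[i - 1, j - 1] == MATCH:
                match_cols += 1
            i, j = i - 1, j - 1
        elif np.isclose(H[i, j], H[i - 1, j] + GAP):
            i -= 1  # read base consumed against a gap (insertion in read)
        elif j > 0 and np.isclose(H[i, j], H[i, j - 1] + GAP):
            aligned_to[j - 1] = None  # reference base deleted from read
            j -= 1
        else:  # pragma: no cover - defensive
            raise RuntimeError("traceback failed")
    ref_start, ref_end = j, j_end  # [start, end) on the reference
    span = ref_end - ref_start
    identity = match_cols / span if span > 0 else 0.0

    cpg_set = set(amp.cpg_offsets)
    n_conv = n_unconv = 0
    for off in range(ref_start, ref_end):
        if ref[off] == "C" and off not in cpg_set:
            base = aligned_to.get(off)
            if base == "T":
                n_conv += 1
            elif base == "C":
                n_unconv += 1
    conversion = n_conv / (n_conv + n_unconv) if (n_conv + n_unconv) else 1.0

    calls = []
    n_gap = 0
    for off in amp.cpg_offsets:
        if not (ref_start <= off < ref_end) or aligned_to.get(off) is None:
            calls.append("-")
            n_gap += 1
        elif aligned_to[off] == "C":
            calls.append("M")
        elif aligned_to[off] == "T":
            calls.append("U")
        else:
            calls.append("?")
    gap_frac = n_gap / len(amp.cpg_offsets)

    return AlignedRead(
        read_id=rid,
        amplicon_id=amp.amplicon_id,
        score=float(score),
        identity=identity,
        conversion_rate=conversion,
        cpg_gap_fraction=gap_frac,
        cpg_calls="".join(calls),
        ref_start=ref_start,
        ref_end=ref_end,
        reverse_complement=is_rc,
    )


@dataclass
class BsasFilterLog:
    """Read-level removal counts, first failing rule attributed."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, rule: str, n: int = 1) -> None:
        self.counts[rule] = self.counts.get(rule, 0) + n

    def total(self) -> int:
        return sum(self.counts.values())


def filter_alignments(
    aligned,
    min_identity: float = 0.9,
    min_conversion: float = 0.9,
    max_cpg_gap: float = 0.1,
    log: BsasFilterLog | None = None,
) -> list[AlignedRead]:
    """Apply the identity / conversion / CpG-gap alignment filters.

    Keeps alignments with identity >= min_identity AND conversion rate >=
    min_conversion AND CpG gap fraction <= max_cpg_gap (all boundaries
    inclusive on the keep side).
    """
    kept: list[AlignedRead] = []
    for a in aligned:
        if a.identity < min_identity:
            if log:
                log.add("identity")
        elif a.conversion_rate < min_conversion:
            if log:
                log.add("conversion")
        elif a.cpg_gap_fraction > max_cpg_gap:
            if log:
                log.add("cpg_gap")
        else:
            kept.append(a)
    return kept


def call_methylation(
    surviving: dict[tuple[str, str], list[AlignedRead]],
    panel: dict[str, Amplicon] | list[Amplicon],
    min_reads: int = 1000,
) -> pd.DataFrame:
    """Per-CpG methylation fractions per sample x amplicon.

    ``surviving`` maps (sample_id, amplicon_id) to filtered alignments. The
    fraction is methylated / (methylated + unmethylated) calls; gap and
    ambiguous calls are excluded from the denominator. Cells backed by fewer
    than ``min_reads`` surviving reads are reported with status
    ``insufficient_reads`` and a missing fraction.
    """
    if isinstance(panel, list):
        panel = {a.amplicon_id: a for a in panel}
    rows = []
    for (sample, amp_id), reads in sorted(surviving.items()):
        amp = panel[amp_id]
        n_cpg = len(amp.cpg_offsets)
        n_reads = len(reads)
        enough = n_reads >= min_reads
        meth = np.zeros(n_cpg, dtype=int)
        unmeth = np.zeros(n_cpg, dtype=int)
        for a in reads:
            c = np.frombuffer(a.cpg_calls.encode(), dtype="S1")
            meth += c == b"M"
            unmeth += c == b"U"
        for ci in range(n_cpg):
            denom = meth[ci] + unmeth[ci]
            if not enough:
                frac, status = np.nan, "insufficient_reads"
            elif denom == 0:
                frac, status = np.nan, "no_calls"
            else:
                frac, status = meth[ci] / denom, "ok"
            rows.append((sample, amp_id, ci, int(meth[ci]), int(unmeth[ci]), frac, n_reads, status))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "amplicon_id", "cpg_index", "n_meth", "n_unmeth", "fraction", "reads_used", "status"],
    )


def compare_mvp_sites(
    calls: pd.DataFrame,
    sheet: pd.DataFrame,
    panel: dict[str, Amplicon] | list[Amplicon],
    pooled: str = "paired",
) -> tuple[pd.DataFrame, dict]:
    """Welch comparisons at the tested MVP CpGs plus a pooled-site test.

    Per MVP CpG: case vs control Welch unpaired two-tailed t-test on the
    per-sample fractions. Pooled: per-site (amplicon x CpG) group means
    across every CpG of every amplicon, compared by a paired-by-site
    two-tailed t-test (``pooled="unpaired"`` switches to Welch).
    """
    if isinstance(panel, list):
        panel = {a.amplicon_id: a for a in panel}
    group_of = dict(zip(sheet["sample_id"], sheet["group"]))
    ok = calls[calls["status"] == "ok"].copy()
    ok["group"] = ok["sample_id"].map(group_of)
    if ok["group"].isna().any():
        raise ValueError("samples in calls missing from sample sheet")

    rows = []
    skipped = []
    for amp_id, amp in panel.items():
        if amp.mvp_offset is None:
            continue
        ci = list(amp.cpg_offsets).index(amp.mvp_offset)
        sub = ok[(ok["amplicon_id"] == amp_id) & (ok["cpg_index"] == ci)]
        a = sub.loc[sub["group"] == "case", "fraction"].to_numpy()
        b = sub.loc[sub["group"] == "control", "fraction"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            skipped.append(amp_id)
            continue
        cmp = welch_t(a, b, site_id=f"{amp_id}:cpg{ci}")
        rows.append(
            (amp_id, ci, cmp.mean_a, cmp.sem_a, cmp.n_a, cmp.mean_b, cmp.sem_b, cmp.n_b, cmp.diff, cmp.t, cmp.df, cmp.p)
        )
    per_mvp = pd.DataFrame(
        rows,
        columns=[
            "amplicon_id",
            "cpg_index",
            "mean_case",
            "sem_case",
            "n_case",
            "mean_control",
            "sem_control",
            "n_control",
            "diff",
            "t",
            "df",
            "p",
        ],
    )

    site_means = (
        ok.pivot_table(index=["amplicon_id", "cpg_index"], columns="group", values="fraction", aggfunc="mean")
        .dropna()
    )
    pooled_result: dict = {"mode": pooled, "n_sites": len(site_means), "skipped_amplicons": skipped}
    if len(site_means) >= 2 and {"case", "control"} <= set(site_means.columns):
        x, y = site_means["case"].to_numpy(), site_means["control"].to_numpy()
        if pooled == "paired":
            t, p = sps.ttest_rel(x, y)
        else:
            t, p = sps.ttest_ind(x, y, equal_var=False)
        pooled_result.update(
            {
                "mean_case": float(x.mean()),
                "sem_case": float(x.std(ddof=1) / np.sqrt(x.size)),
                "mean_control": float(y.mean()),
                "sem_control": float(y.std(ddof=1) / np.sqrt(y.size)),
                "t": float(t),
                "p": float(p),
            }
        )
    return per_mvp, pooled_result


def run_bsas(
    reads,
    barcode_map: dict[str, str],
    panel: list[Amplicon],
    amplicon_of_sample=None,
    min_q: int = 30,
    min_qfrac: float = 0.5,
    min_identity: float = 0.9,
    min_conversion: float = 0.9,
    max_cpg_gap: float = 0.1,
    min_reads: int = 1000,
    min_read_length: int = 30,
) -> tuple[pd.DataFrame, BsasFilterLog, dict]:
    """Full read-to-call chain: demultiplex, filter, align, filter, call.

    Each read is aligned against every panel amplicon and assigned to the
    best-scoring one. Returns the methylation call table, the filter log
    and summary counts.
    """
    log = BsasFilterLog()
    by_sample, unassigned = demultiplex(reads, barcode_map)
    log.add("unassigned_barcode", unassigned)
    surviving: dict[tuple[str, str], list[AlignedRead]] = defaultdict(list)
    for sample, rlist in by_sample.items():
        qreads, ndrop = quality_filter(rlist, min_q=min_q, min_frac=min_qfrac)
        log.add("quality", ndrop)
        aligned = []
        for r in qreads:
            best = None
            for amp in panel:
                a = bisulfite_align(r, amp, min_read_length=min_read_length)
                if a is not None and (best is None or a.score > best.score):
                    best = a
            if best is None:
                log.add("too_short")
            else:
                aligned.append(best)
        kept = filter_alignments(
            aligned, min_identity=min_identity, min_conversion=min_conversion, max_cpg_gap=max_cpg_gap, log=log
        )
        for a in kept:
            surviving[(sample, a.amplicon_id)].append(a)
    calls = call_methylation(dict(surviving), panel, min_reads=min_reads)
    summary = {"unassigned": unassigned, "surviving": int(sum(len(v) for v in surviving.values()))}
    return calls, log, summary
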