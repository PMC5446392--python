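"""Bisulfite amplicon pipeline: demultiplexing, filters, alignment, calling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from methwas.bsas import (
    BsasFilterLog,
    bisulfite_align,
    call_methylation,
    compare_mvp_sites,
    demultiplex,
    filter_alignments,
    quality_filter,
    run_bsas,
)
from methwas.simulate import generate_amplicon_reads, make_barcodes
from methwas.types import AlignedRead, Amplicon, ReadRecord

from conftest import make_sheet

MATCH, MISMATCH, GAP = 1.0, -1.0, -2.0


def _score_pair(rd, rf, cpg, off):
    if rf == "C":
        return MATCH if rd in "CT" else MISMATCH
    return MATCH if rd == rf else MISMATCH


def exhaustive_alignment_oracle(read, amp):
    """Best semi-global score by brute-force recursion (tiny instances only)."""
    ref = amp.ref_seq
    cpg = set(amp.cpg_offsets)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i, j):
        # best score aligning read[i:] given current ref offset j (ref suffix free)
        if i == len(read):
            return 0.0  # remaining reference is a free overhang
        options = [best(i + 1, j) + GAP]  # consume read base against a gap
        if j < len(ref):
            options.append(best(i + 1, j + 1) + _score_pair(read[i], ref[j], cpg, j))
            options.append(best(i, j + 1) + GAP)  # consume ref base against a gap
        return max(options)

    # free leading reference overhang: try every start
    return max(best(0, j0) for j0 in range(len(ref) + 1))


def convert(seq, cpg=(), methylated=False):
    out = []
    for i, b in enumerate(seq):
        if b == "C" and i not in cpg:
            out.append("T")
        elif b == "C":
            out.append("C" if methylated else "T")
        else:
            out.append(b)
    return "".join(out)


class TestDemultiplex:
    def test_exact_prefix_assignment_and_trim(self):
        reads = [ReadRecord("r1", "AAAACCCC" + "ATGT", [30] * 12)]
        out, un = demultiplex(reads, {"AAAACCCC": "S1"})
        assert un == 0
        assert out["S1"][0].sequence == "ATGT"
        assert len(out["S1"][0].qualities) == 4

    def test_non_matching_read_unassigned(self):
        reads = [ReadRecord("r1", "GGGGTTTTATGT", [30] * 12)]
        out, un = demultiplex(reads, {"AAAACCCC": "S1"})
        assert un == 1 and out == {}

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            demultiplex([], [("AAAA", "S1"), ("AAAA", "S2")])

    def test_simulated_allocation_exact(self, toy_amplicon):
        truth = {f"S{i}": {"toy": np.full(len(toy_amplicon.cpg_offsets), 0.5)} for i in range(4)}
        sim = generate_amplicon_reads([toy_amplicon], truth, n_reads=250, seed=3)
        out, un = demultiplex(sim.records, sim.barcode_map)
        assert un == 0
        assert {s: len(r) for s, r in out.items()} == {f"S{i}": 250 for i in range(4)}


class TestQualityFilter:
    def test_boundaries(self):
        hi = ReadRecord("hi", "ACGT", [40] * 4)
        edge = ReadRecord("edge", "ACGT", [30] * 4)  # Q not strictly above 30
        half = ReadRecord("half", "ACGT", [40, 40, 20, 20])  # exactly 50% pass
        kept, dropped = quality_filter([hi, edge, half])
        assert [r.read_id for r in kept] == ["hi", "half"]
        assert dropped == 1

    def test_planted_split_exact(self):
        rng = np.random.default_rng(0)
        reads = []
        for i in range(100):
            q = 40 if i < 51 else 20
            reads.append(ReadRecord(f"r{i}", "ACGTACGT", [q] * 8))
        kept, dropped = quality_filter(reads)
        assert len(kept) == 51 and dropped == 49

    def test_empty_read_dropped(self):
        kept, dropped = quality_filter([ReadRecord("e", "", [])])
        assert kept == [] and dropped == 1


class TestBisulfiteAlign:
    def test_unmethylated_converted_read(self, toy_amplicon):
        read = convert(toy_amplicon.ref_seq, toy_amplicon.cpg_offsets, methylated=False)
        a = bisulfite_align(read, toy_amplicon, min_read_length=10)
        assert a.identity == 1.0
        assert a.conversion_rate == 1.0
        assert a.cpg_calls == "U" * len(toy_amplicon.cpg_offsets)

    def test_methylated_read(self, toy_amplicon):
        read = convert(toy_amplicon.ref_seq, toy_amplicon.cpg_offsets, methylated=True)
        a = bisulfite_align(read, toy_amplicon, min_read_length=10)
        assert a.cpg_calls == "M" * len(toy_amplicon.cpg_offsets)
        assert a.conversion_rate == 1.0

    def test_reverse_complement_recovered(self, toy_amplicon):
        read = convert(toy_amplicon.ref_seq, toy_amplicon.cpg_offsets, methylated=False)
        rc = read.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        a = bisulfite_align(rc, toy_amplicon, min_read_length=10)
        assert a.reverse_complement
        assert a.cpg_calls == "U" * len(toy_amplicon.cpg_offsets)

    def test_hand_checked_substitution_and_deletion(self):
        #          0123456789...            CpGs at 2 and 12
        ref = "ATCGATTAGGATCGATTAGGATTAGGATTAGGATTAGGAT"[:40]
        cpgs = tuple(i for i in range(39) if ref[i : i + 2] == "CG")
        amp = Amplicon("t", ref, cpgs)
        read = convert(ref, cpgs, methylated=True)
        read = read[:20] + read[21:]  # delete one base
        read = "A" + read[1:5] + ("C" if read[5] == "A" else "A") + read[6:]  # one substitution
        a = bisulfite_align(read, amp, min_read_length=10)
        # known optimal alignment: full span, 1 mismatch column + 1 gap column
        assert a.ref_end - a.ref_start == 40
        assert a.identity == pytest.approx((40 - 2) / 40)
        assert a.cpg_calls == "M" * len(cpgs)

    def test_short_read_rejected(self, toy_amplicon):
        assert bisulfite_align("ACGTACGT", toy_amplicon) is None

    @pytest.mark.parametrize("trial", range(40))
    def test_dp_score_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        n_ref = int(rng.integers(8, 17))
        ref = "".join(rng.choice(list("ACGT"), n_ref))
        cpgs = tuple(i for i in range(n_ref - 1) if ref[i : i + 2] == "CG")
        amp = Amplicon("t", ref, cpgs) if cpgs else Amplicon("t", "CG" + ref, (0,))
        read = "".join(rng.choice(list("ACGT"), int(rng.integers(5, 13))))
        a = bisulfite_align(read, amp, min_read_length=1, try_reverse_complement=False)
        assert a.score == pytest.approx(exhaustive_alignment_oracle(read, amp))


class TestFilterAlignments:
    def _mk(self, ident=1.0, conv=1.0, gap=0.0):
        return AlignedRead("r", "a", 0.0, ident, conv, gap, "M")

    def test_boundaries_inclusive(self):
        kept = filter_alignments([self._mk(ident=0.9), self._mk(conv=0.9), self._mk(gap=0.1)])
        assert len(kept) == 3

    def test_first_failing_rule_attributed_and_counts_sum(self):
        log = BsasFilterLog()
        reads = [self._mk(ident=0.5, conv=0.5), self._mk(conv=0.8), self._mk(gap=0.5), self._mk()]
        kept = filter_alignments(reads, log=log)
        assert len(kept) == 1
        assert log.counts == {"identity": 1, "conversion": 1, "cpg_gap": 1}
        assert log.total() == len(reads) - len(kept)

    def test_planted_conversion_failures_removed_at_binomial_rate(self, toy_amplicon):
        # long amplicon with many lone cytosines for a fine-grained estimate
        ref = (toy_amplicon.ref_seq * 3)[:120]
        cpgs = tuple(i for i in range(119) if ref[i : i + 2] == "CG")
        amp = Amplicon("t3", ref, cpgs)
        non_cpg_c = sum(1 for i, b in enumerate(ref) if b == "C" and i not in set(cpgs))
        truth = {"S1": {"t3": np.full(len(cpgs), 0.5)}}
        sim = generate_amplicon_reads([amp], truth, n_reads=400, conversion_failure=0.25, seed=5)
        by, _ = demultiplex(sim.records, sim.barcode_map)
        aligned = [bisulfite_align(r, amp) for r in by["S1"]]
        kept = filter_alignments(aligned)
        from scipy.stats import binom

        # survivors need >= 90% converted lone cytosines
        k_min = int(np.ceil(0.9 * non_cpg_c))
        predicted = binom.sf(k_min - 1, non_cpg_c, 0.75)
        observed = len(kept) / 400
        assert observed < 0.1  # vast majority removed
        assert observed == pytest.approx(predicted, abs=0.04)


class TestCallingAndComparison:
    def test_all_methylated_fraction_one(self, toy_amplicon):
        reads = [
            AlignedRead(f"r{i}", "toy", 0, 1.0, 1.0, 0.0, "M" * len(toy_amplicon.cpg_offsets))
            for i in range(20)
        ]
        calls = call_methylation({("S1", "toy"): reads}, [toy_amplicon], min_reads=10)
        assert (calls["fraction"] == 1.0).all()
        assert (calls["status"] == "ok").all()

    def test_insufficient_reads_marked_missing(self, toy_amplicon):
        reads = [
            AlignedRead(f"r{i}", "toy", 0, 1.0, 1.0, 0.0, "U" * len(toy_amplicon.cpg_offsets))
            for i in range(800)
        ]
        calls = call_methylation({("S1", "toy"): reads}, [toy_amplicon], min_reads=1000)
        assert (calls["status"] == "insufficient_reads").all()
        assert calls["fraction"].isna().all()

    def test_gaps_excluded_from_denominator(self, toy_amplicon):
        n = len(toy_amplicon.cpg_offsets)
        reads = [
            AlignedRead("r1", "toy", 0, 1, 1, 0, "M" + "U" * (n - 1)),
            AlignedRead("r2", "toy", 0, 1, 1, 0, "-" + "U" * (n - 1)),
        ]
        calls = call_methylation({("S1", "toy"): reads}, [toy_amplicon], min_reads=1)
        first = calls[calls["cpg_index"] == 0].iloc[0]
        assert first["fraction"] == 1.0  # 1 methylated / 1 informative call

    def test_identical_groups_give_p_one(self, toy_amplicon):
        amp = Amplicon("toy", toy_amplicon.ref_seq, toy_amplicon.cpg_offsets, mvp_offset=toy_amplicon.cpg_offsets[0])
        rows = []
        for s in ["a1", "a2", "b1", "b2"]:
            for ci in range(len(amp.cpg_offsets)):
                rows.append((s, "toy", ci, 50, 50, 0.5, 2000, "ok"))
        calls = pd.DataFrame(rows, columns=["sample_id", "amplicon_id", "cpg_index", "n_meth", "n_unmeth", "fraction", "reads_used", "status"])
        sheet = make_sheet(["a1", "a2", "b1", "b2"], groups=["case", "case", "control", "control"])
        per_mvp, pooled = compare_mvp_sites(calls, sheet, [amp])
        assert per_mvp["diff"].iloc[0] == 0.0
        assert per_mvp["p"].iloc[0] == 1.0

    def test_read_order_invariance(self, toy_amplicon):
        truth = {"S1": {"toy": np.linspace(0.1, 0.9, len(toy_amplicon.cpg_offsets))}}
        sim = generate_amplicon_reads([toy_amplicon], truth, n_reads=150, base_error=0.003, seed=6)
        bc = sim.barcode_map
        amp = toy_amplicon
        c1, _, _ = run_bsas(sim.records, bc, [amp], min_reads=50)
        rng = np.random.default_rng(1)
        shuffled = list(sim.records)
        rng.shuffle(shuffled)
        c2, _, _ = run_bsas(shuffled, bc, [amp], min_reads=50)
        merged = c1.merge(c2, on=["sample_id", "amplicon_id", "cpg_index"], suffixes=("_1", "_2"))
        assert np.allclose(merged["fraction_1"], merged["fraction_2"], equal_nan=True)

    def test_end_to_end_recovery_matches_planted_states(self, toy_amplicon):
        truth = {"S1": {"toy": np.array([0.1, 0.5, 0.9])}}
        sim = generate_amplicon_reads([toy_amplicon], truth, n_reads=1500, base_error=0.001, conversion_failure=0.02, seed=7)
        calls, log, _ = run_bsas(sim.records, sim.barcode_map, [toy_amplicon], min_reads=1000)
        planted = sim.planted_counts
        ok = calls[calls["status"] == "ok"]
        assert len(ok) == 3
        for _, row in ok.iterrows():
            pl = planted[(planted["cpg_index"] == row["cpg_index"])].iloc[0]
            assert row["fraction"] == pytest.approx(pl["n_meth"] / pl["n_total"], abs=0.01)
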