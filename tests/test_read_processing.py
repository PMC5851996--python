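"""Quality trimming, pair merging, filtering, primer removal, dereplication."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mibird.primer_eval import MIBIRD_U_F, MIBIRD_U_R, Primer, reverse_complement
from mibird.read_processing import (
    DereplicatedUnit,
    MergedRead,
    ProcessingParams,
    ReadRecord,
    accounting_tsv,
    dereplicate,
    filter_merged,
    merge_pair,
    parse_units_fasta,
    process_pairs,
    quality_trim,
    read_fastq_pairs,
    trim_primers,
    write_units_fasta,
)

BASES = "ACGT"


def _read(bases, quals, rid="r1"):
    return ReadRecord(rid, bases, tuple(quals))


def brute_trim(read, cutoff):
    """Enumerate every all-above-cutoff segment; longest, ties leftmost."""
    best = (0, 0)
    for s in range(len(read.bases)):
        for e in range(s, len(read.bases) + 1):
            if all(q >= cutoff for q in read.quals[s:e]) and e - s > best[1] - best[0]:
                best = (s, e)
    return read.bases[best[0] : best[1]]


def brute_merge_choice(f, r, params):
    """Exhaustive offset enumeration oracle: (offset, overlap, mismatches) or None."""
    rc = reverse_complement(r.bases)
    best = None
    for off in range(len(f.bases)):
        ov = min(len(f.bases) - off, len(rc))
        if ov < params.min_overlap:
            continue
        mm = sum(a != b for a, b in zip(f.bases[off : off + ov], rc[:ov]))
        cand = (mm / ov, -ov, off, mm)
        if best is None or cand < best:
            best = cand
    if best is None or best[0] > params.max_mismatch_fraction:
        return None
    return best[2], -best[1], best[3]


class TestQualityTrim:
    def test_all_good_unchanged(self):
        r = _read("ACGTACGT", [30] * 8)
        assert quality_trim(r, 10) == r

    def test_low_quality_tail_removed(self):
        r = _read("A" * 52, [30] * 50 + [2, 2])
        out = quality_trim(r, 10)
        assert out.bases == "A" * 50 and len(out.quals) == 50

    def test_interior_drop_keeps_longest_leftmost(self):
        r = _read("AACCGGTT", [30, 30, 30, 5, 30, 30, 30, 5])
        assert quality_trim(r, 10).bases == "AAC"  # ties -> leftmost

    def test_all_bad_gives_empty(self):
        out = quality_trim(_read("ACGT", [2, 3, 4, 5]), 10)
        assert out.bases == "" and out.quals == ()

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 40), min_size=0, max_size=25))
    def test_matches_exhaustive_segment_oracle(self, quals):
        r = _read("A" * len(quals), quals)
        out = quality_trim(r, 10)
        assert out.bases == brute_trim(r, 10)
        assert all(q >= 10 for q in out.quals)
        assert out.bases in r.bases  # contiguous substring


class TestMergePair:
    @staticmethod
    def _pair_from_amplicon(amplicon, read_len, q=35):
        f = _read(amplicon[:read_len], [q] * read_len, "p/1")
        rseq = reverse_complement(amplicon)[:read_len]
        r = _read(rseq, [q] * read_len, "p/2")
        return f, r

    def test_exact_overlap_length_arithmetic(self, rng):
        amplicon = "".join(rng.choice(list(BASES), 280))
        f, r = self._pair_from_amplicon(amplicon, 150)
        m = merge_pair(f, r)
        assert m is not None
        assert len(m) == 280 and m.overlap_length == 20 and m.overlap_mismatches == 0
        assert m.bases == amplicon

    def test_overlap_below_minimum_unmerged(self, rng):
        amplicon = "".join(rng.choice(list(BASES), 291))  # best overlap 9
        f, r = self._pair_from_amplicon(amplicon, 150)
        params = ProcessingParams(min_overlap=10, max_mismatch_fraction=0.0)
        assert merge_pair(f, r, params) is None

    def test_disagreement_resolved_by_quality(self, rng):
        amplicon = "".join(rng.choice(list(BASES), 260))
        f, _ = self._pair_from_amplicon(amplicon, 150)
        # reverse read covers amplicon[110:260]; corrupt one base inside the
        # 40-base overlap (amplicon positions 110..149) and lower its quality
        rc = list(amplicon[110:260])
        i_rc = 20  # amplicon position 130
        rc[i_rc] = next(b for b in BASES if b != rc[i_rc])
        quals = [35] * 150
        quals[149 - i_rc] = 12  # reverse-read coordinate of the corrupted base
        r2 = _read(reverse_complement("".join(rc)), quals, "p/2")
        m = merge_pair(f, r2, ProcessingParams())
        assert m.overlap_mismatches == 1
        assert m.bases == amplicon  # fwd base (q35) wins over rev (q12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_offset_choice_matches_exhaustive_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        amp_len = data.draw(st.integers(30, 60))
        read_len = data.draw(st.integers(20, min(40, amp_len)))
        amplicon = "".join(rng.choice(list(BASES), amp_len))
        f, r = self._pair_from_amplicon(amplicon, read_len)
        params = ProcessingParams(min_overlap=5)
        oracle = brute_merge_choice(f, r, params)
        m = merge_pair(f, r, params)
        if oracle is None:
            assert m is None
        else:
            off, ov, mm = oracle
            assert (m.overlap_length, m.overlap_mismatches) == (ov, mm)
            assert len(m) == off + ov + (len(r) - ov)

    def test_empty_read_unmerged(self):
        assert merge_pair(_read("", []), _read("ACGTACGTACGT", [30] * 12)) is None


class TestFilterMerged:
    @staticmethod
    def _merged(bases, rid="m1"):
        return MergedRead(rid, bases, tuple([30] * len(bases)), 20, 0)

    def test_reasons_and_conservation(self):
        params = ProcessingParams(length_window=(200, 250))
        reads = [
            self._merged("A" * 220),
            self._merged("A" * 100 + "N" + "A" * 119),
            self._merged("A" * 400),
        ]
        kept, removed = filter_merged(reads, params)
        assert len(kept) == 1
        assert sorted(r for _, r in removed) == ["ambiguous", "length"]
        assert len(kept) + len(removed) == len(reads)

    def test_window_required(self):
        with pytest.raises(ValueError):
            filter_merged([], ProcessingParams())

    def test_default_window_from_primers(self):
        lo, hi = ProcessingParams.default_length_window(MIBIRD_U_F, MIBIRD_U_R)
        assert lo < 23 + 171 + 27 < hi


class TestTrimPrimers:
    @staticmethod
    def _amplicon_read(insert, fwd=MIBIRD_U_F, rev=MIBIRD_U_R, lead="", trail=""):
        bases = lead + fwd.core + insert + reverse_complement(rev.core) + trail
        return MergedRead("m1", bases, tuple([30] * len(bases)), 20, 0)

    def test_exact_primers_removed(self, rng):
        insert = "".join(rng.choice(list(BASES), 171))
        res = trim_primers(self._amplicon_read(insert), MIBIRD_U_F, MIBIRD_U_R)
        assert res.status == "ok" and res.insert == insert and len(res.insert) == 171

    @pytest.mark.parametrize("n_subs,status", [(3, "ok"), (4, "rejected")])
    def test_mismatch_boundary(self, n_subs, status, rng):
        insert = "".join(rng.choice(list(BASES), 171))
        core = list(MIBIRD_U_F.core)
        for i in range(n_subs):
            core[3 * i] = next(b for b in BASES if b != core[3 * i])
        m = MergedRead(
            "m1",
            "".join(core) + insert + reverse_complement(MIBIRD_U_R.core),
            tuple([30] * (23 + 171 + 27)), 20, 0,
        )
        res = trim_primers(m, MIBIRD_U_F, MIBIRD_U_R)
        assert res.status == status
        if status == "ok":
            assert res.insert == insert
        else:
            assert res.reason == "fwd_primer"

    def test_leading_spacer_allowance(self, rng):
        insert = "".join(rng.choice(list(BASES), 100))
        m = self._amplicon_read(insert, lead="TTTTTT", trail="AAAAAA")
        assert trim_primers(m, MIBIRD_U_F, MIBIRD_U_R).status == "rejected"
        params = ProcessingParams(leading_bases=6)
        res = trim_primers(m, MIBIRD_U_F, MIBIRD_U_R, params)
        assert res.status == "ok" and res.insert == insert

    def test_too_short_rejected(self):
        m = MergedRead("m1", "ACGT", (30, 30, 30, 30), 4, 0)
        assert trim_primers(m, MIBIRD_U_F, MIBIRD_U_R).reason == "too_short"


class TestDereplicate:
    def test_identical_reads_single_unit(self):
        units, discarded = dereplicate(["ACGTACGT"] * 12)
        assert len(units) == 1 and units[0].read_count == 12 and not discarded

    def test_rescue_arithmetic(self):
        rep = "A" * 171
        variant = "A" * 170 + "T"  # identity 170/171 ~ 99.4%
        units, discarded = dereplicate([rep] * 15 + [variant] * 9)
        assert len(units) == 1 and units[0].read_count == 24 and not discarded
        assert any(s == variant and c == 9 for s, c, _ in units[0].members)

    def test_below_identity_discarded_with_conservation(self):
        rep = "A" * 171
        far = "A" * 168 + "TTT"  # 3 diffs -> 98.2%
        units, discarded = dereplicate([rep] * 15 + [far] * 9)
        assert len(units) == 1 and units[0].read_count == 15
        assert discarded == [(far, 9)]
        assert sum(u.read_count for u in units) + sum(c for _, c in discarded) == 24

    def test_order_invariance(self, rng):
        pool = (["A" * 50] * 13 + ["A" * 49 + "T"] * 4 + ["C" * 50] * 11
                + ["G" * 25 + "C" * 25] * 3)
        a, da = dereplicate(pool)
        shuffled = list(pool)
        rng.shuffle(shuffled)
        b, db = dereplicate(shuffled)
        assert a == b and sorted(da) == sorted(db)

    def test_matches_brute_force_grouping(self, rng):
        # small instance: recompute the expected grouping independently
        seqs = ["ACGTACGTAC", "ACGTACGTAT", "TTTTTTTTTT", "ACGTACGGAC"]
        counts = [12, 3, 11, 2]
        reads = [s for s, c in zip(seqs, counts) for _ in range(c)]
        params = ProcessingParams(min_reads_representative=10, rescue_identity=0.9)
        units, discarded = dereplicate(reads, params)
        # brute force: reps are seqs with >=10; each rare seq joins its best rep
        assert {u.representative for u in units} == {"ACGTACGTAC", "TTTTTTTTTT"}
        by_rep = {u.representative: u.read_count for u in units}
        assert by_rep["ACGTACGTAC"] == 12 + 3 + 2  # both rare variants at 90%+
        assert by_rep["TTTTTTTTTT"] == 11
        assert not discarded

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            dereplicate(["", "ACGT"])


class TestPipelineAndIO:
    def test_end_to_end_error_free(self, rng, primers):
        fwd, rev = primers
        inserts = ["".join(rng.choice(list(BASES), 171)) for _ in range(3)]
        pairs = []
        for ins in inserts:
            amplicon = fwd.core + ins + reverse_complement(rev.core)
            for j in range(12):
                f = ReadRecord(f"{ins[:4]}{j}/1", amplicon[:150], tuple([35] * 150))
                rseq = reverse_complement(amplicon)[:150]
                pairs.append((f, ReadRecord(f"{ins[:4]}{j}/2", rseq, tuple([35] * 150))))
        units, acct = process_pairs(pairs, fwd, rev)
        assert len(units) == 3
        assert sorted(u.representative for u in units) == sorted(inserts)
        assert acct["input_pairs"] == 36 and acct["reads_in_units"] == 36

    def test_fastq_roundtrip_and_units_fasta(self, tmp_path, rng):
        r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
        r1.write_text("@a/1\nACGT\n+\nIIII\n")
        r2.write_text("@a/2\nTTGG\n+\nII5I\n")
        pairs = read_fastq_pairs(r1, r2)
        assert pairs[0][0].bases == "ACGT"
        assert pairs[0][1].quals == (40, 40, 20, 40)
        units = [DereplicatedUnit("ACGT", 12, (("ACGT", 12, 1.0),))]
        out = tmp_path / "units.fasta"
        write_units_fasta(units, out)
        assert out.read_text() == ">unit1;size=12\nACGT\n"
        assert parse_units_fasta(out) == [("unit1", 12, "ACGT")]

    def test_mismatched_pair_files_error(self, tmp_path):
        r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
        r1.write_text("@a/1\nACGT\n+\nIIII\n")
        r2.write_text("")
        with pytest.raises(ValueError):
            read_fastq_pairs(r1, r2)

    def test_accounting_tsv(self):
        out = accounting_tsv({"input_pairs": 5, "merged": 4})
        assert out.splitlines()[1] == "input_pairs\t5"


class TestReadRecordInvariants:
    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ReadRecord("r", "ACGT", (30, 30))

    def test_phred_range(self):
        with pytest.raises(ValueError):
            ReadRecord("r", "AC", (30, 99))
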