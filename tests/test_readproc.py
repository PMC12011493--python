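"""Filtering cascade: merge geometry, maxEE arithmetic, trimming, ledger
conservation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markerbench.commsim import PRIMERS, build_fragment
from markerbench.iupac import revcomp
from markerbench.readproc import (
    DiscardLedger,
    FilterParams,
    MergedRead,
    ReadPair,
    dereplicate,
    expected_errors,
    filter_cascade,
    merge_pair,
    read_fastq_pairs,
    trim_flanks,
    trim_primers,
)
from markerbench.refdata import Marker

ITS_LIKE = Marker("toy", "multicopy", 50, 300, 0)
CODING_LIKE = Marker("cod", "low_copy", 200, 400, 0)


def pair_from_template(s: str, read_len: int = 250, q: int = 40,
                       read_id: str = "r1") -> ReadPair:
    r1 = s[:read_len]
    r2 = revcomp(s)[:read_len]
    return ReadPair(read_id, r1, r2,
                    np.full(len(r1), q), np.full(len(r2), q))


class TestMergePair:
    def test_full_overlap_geometry(self):
        rng = np.random.default_rng(0)
        s = "".join(rng.choice(list("ACGT"), size=300))
        merged = merge_pair(pair_from_template(s))
        assert merged is not None
        assert merged.sequence == s
        assert merged.overlap_len == 200

    def test_overlap_below_minimum_rejected(self):
        # 24 exact overlap bases: one short of the floor
        rng = np.random.default_rng(1)
        s = "".join(rng.choice(list("ACGT"), size=2 * 250 - 24))
        assert merge_pair(pair_from_template(s)) is None
        # at exactly 25 the same construction merges
        s = "".join(rng.choice(list("ACGT"), size=2 * 250 - 25))
        merged = merge_pair(pair_from_template(s))
        assert merged is not None and merged.overlap_len == 25

    def test_single_mismatch_rejects_at_max_diffs_zero(self):
        rng = np.random.default_rng(2)
        s = "".join(rng.choice(list("ACGT"), size=350))
        pair = pair_from_template(s)
        # corrupt one R1 base inside the overlap region
        pos = 200
        seq = list(pair.r1_seq)
        seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        pair.r1_seq = "".join(seq)
        assert merge_pair(pair, max_diffs=0) is None
        assert merge_pair(pair, max_diffs=1) is not None

    def test_overlap_quality_takes_higher_phred(self):
        s = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30 bp
        r1 = s
        r2 = revcomp(s)
        pair = ReadPair("r", r1, r2, np.full(30, 10), np.full(30, 30))
        merged = merge_pair(pair, min_overlap=25)
        assert merged is not None
        assert np.all(merged.qual == 30)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(300, 470))
    def test_roundtrip_of_errorfree_fragments(self, seed, length):
        """merge_pair inverts the simulator's fragmentation for clean reads."""
        rng = np.random.default_rng(seed)
        s = "".join(rng.choice(list("ACGT"), size=length))
        merged = merge_pair(pair_from_template(s))
        assert merged is not None
        assert merged.sequence == s


class TestExpectedErrors:
    @pytest.mark.parametrize(
        "qual,expected",
        [
            ([20] * 100, 1.0),
            ([2] * 10, 10 * 10 ** (-0.2)),
            ([], 0.0),
        ],
    )
    def test_closed_forms(self, qual, expected):
        assert expected_errors(qual) == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 41), min_size=1, max_size=50),
        st.data(),
    )
    def test_monotone_in_quality(self, quals, data):
        """Lowering any single Phred value never lowers the expected errors."""
        i = data.draw(st.integers(0, len(quals) - 1))
        drop = data.draw(st.integers(0, quals[i]))
        worse = list(quals)
        worse[i] -= drop
        assert expected_errors(worse) >= expected_errors(quals) - 1e-12


class TestTrimming:
    def make_read(self, seq: str) -> MergedRead:
        return MergedRead("r", seq, np.full(len(seq), 40), 30)

    def test_primers_removed_both_ends(self):
        fwd, rev = PRIMERS["ITS1"]
        core = "ACGTACGTACGTACGTACGTACGTACGT"
        read = self.make_read(fwd + core + revcomp(rev))
        out = trim_primers(read, fwd, rev)
        assert out.sequence == core
        assert not out.flags

    def test_absent_primers_flagged_untouched(self):
        core = "ACGTACGTACGTACGTACGTACGTACGT"
        out = trim_primers(self.make_read(core), *PRIMERS["ITS1"])
        assert out.sequence == core
        assert out.flags == {"fwd_primer_missing", "rev_primer_missing"}

    def test_one_mismatch_tolerance(self):
        fwd, rev = "ACGTACGTAA", "TTGGCCAATT"
        core = "GGGGCCCCGGGGCCCCGGGGCCCC"
        mutated = "ACGTACGTAC"  # one mismatch in fwd
        read = self.make_read(mutated + core + revcomp(rev))
        assert trim_primers(read, fwd, rev, max_mismatch=1).sequence == core
        out0 = trim_primers(read, fwd, rev, max_mismatch=0)
        assert out0.sequence.startswith(mutated)
        assert "fwd_primer_missing" in out0.flags

    def test_empty_anchors_pass_through(self):
        read = self.make_read("ACGTACGT")
        assert trim_flanks(read, None).sequence == "ACGTACGT"

    def test_anchor_trimming_extracts_target(self):
        m5, m3 = "GGATCC", "GAATTC"
        target = "ACGTACGTACGTAAATTTCCC"
        read = self.make_read("TTTT" + m5 + target + m3 + "AAAA")
        assert trim_flanks(read, (m5, m3)).sequence == target

    def test_missing_anchor_policy(self):
        read = self.make_read("ACGTACGTACGT")
        kept = trim_flanks(read, ("GGATCC", "GAATTC"), on_missing="keep")
        assert kept is not None and "flank_anchor_missing" in kept.flags
        assert trim_flanks(read, ("GGATCC", "GAATTC"), on_missing="discard") is None


class TestFilterCascade:
    def test_all_clean_pairs_kept(self):
        rng = np.random.default_rng(3)
        pairs = []
        for i in range(10):
            s = "".join(rng.choice(list("ACGT"), size=320))
            pairs.append(pair_from_template(s, read_id=f"r{i}"))
        kept, ledger = filter_cascade(pairs, ITS_LIKE)
        assert ledger.kept == 10 and len(kept) == 10
        assert ledger.total == 10

    def test_short_category_for_coding_marker(self):
        s = "".join(np.random.default_rng(4).choice(list("ACGT"), size=150))
        pair = pair_from_template(s, read_len=100)
        _kept, ledger = filter_cascade([pair], CODING_LIKE,
                                       FilterParams(min_overlap=25))
        assert ledger.short == 1

    def test_constructed_batch_counts(self):
        """3 unmergeable + 2 short + 1 low-quality + 4 clean = (3,2,1,0,0,4)."""
        rng = np.random.default_rng(5)
        pairs = []
        for i in range(3):  # unmergeable: unrelated r1/r2
            a = "".join(rng.choice(list("ACGT"), size=250))
            b = "".join(rng.choice(list("ACGT"), size=250))
            pairs.append(ReadPair(f"u{i}", a, b, np.full(250, 40), np.full(250, 40)))
        for i in range(2):  # short: merged length 150 < 200
            s = "".join(rng.choice(list("ACGT"), size=150))
            pairs.append(pair_from_template(s, read_len=100, read_id=f"s{i}"))
        for i in range(1):  # low quality: Q2 everywhere -> ee >> 1
            s = "".join(rng.choice(list("ACGT"), size=300))
            pairs.append(pair_from_template(s, q=2, read_id=f"q{i}"))
        for i in range(4):  # clean
            s = "".join(rng.choice(list("ACGT"), size=320))
            pairs.append(pair_from_template(s, read_id=f"k{i}"))
        _kept, ledger = filter_cascade(pairs, CODING_LIKE)
        assert ledger.as_dict() == {
            "unmerged": 3, "short": 2, "low_quality": 1,
            "chimeric": 0, "nontarget": 0, "kept": 4,
        }
        assert ledger.total == 10

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 25))
    def test_ledger_conservation_fuzz(self, seed, n_pairs):
        """Category counts sum to the input size for arbitrary read batches."""
        rng = np.random.default_rng(seed)
        pairs = []
        for i in range(n_pairs):
            kind = rng.integers(4)
            if kind == 0:  # unrelated
                a = "".join(rng.choice(list("ACGT"), size=250))
                b = "".join(rng.choice(list("ACGT"), size=250))
                pairs.append(ReadPair(f"x{i}", a, b, np.full(250, 40),
                                      np.full(250, 40)))
            else:
                length = int(rng.integers(60, 470))
                q = int(rng.integers(2, 41))
                s = "".join(rng.choice(list("ACGT"), size=length))
                pairs.append(pair_from_template(
                    s, read_len=min(250, length), q=q, read_id=f"x{i}"))
        _kept, ledger = filter_cascade(pairs, ITS_LIKE)
        assert ledger.total == n_pairs

    def test_cascade_with_primer_trim_recovers_insert(self):
        insert = "".join(np.random.default_rng(6).choice(list("ACGT"), size=280))
        frag = build_fragment(insert, "ITS1", 250)
        pair = pair_from_template(frag)
        kept, ledger = filter_cascade(
            [pair], ITS_LIKE, FilterParams(primers=PRIMERS["ITS1"])
        )
        assert ledger.kept == 1
        assert kept[0].sequence == insert


class TestFastqRoundtrip:
    def test_truncated_record_names_read(self, tmp_path):
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        r1.write_text("@read1\nACGT\n+\nIIII\n@read2\nACGT\n")
        r2.write_text("@read1\nACGT\n+\nIIII\n@read2\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="read2"):
            list(read_fastq_pairs(r1, r2))

    def test_phred33_decoding(self, tmp_path):
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        r1.write_text("@r\nACGT\n+\n!I5#\n")
        r2.write_text("@r\nACGT\n+\nIIII\n")
        (pair,) = read_fastq_pairs(r1, r2)
        assert list(pair.r1_qual) == [0, 40, 20, 2]


def test_dereplicate_orders_by_abundance_then_sequence():
    reads = [
        MergedRead(f"r{i}", seq, np.full(len(seq), 40), 30)
        for i, seq in enumerate(["CCCC", "AAAA", "CCCC", "GGGG", "AAAA", "CCCC"])
    ]
    derep = dereplicate(reads)
    assert [(s, n) for s, n, _ in derep] == [("CCCC", 3), ("AAAA", 2), ("GGGG", 1)]
    assert sorted(i for _, _, ids in derep for i in ids) == sorted(
        r.read_id for r in reads
    )


def test_ledger_reclassify_moves_counts():
    ledger = DiscardLedger(kept=10)
    ledger.reclassify_kept("chimeric", 3)
    ledger.reclassify_kept("nontarget", 2)
    assert ledger.as_dict() == {
        "unmerged": 0, "short": 0, "low_quality": 0,
        "chimeric": 3, "nontarget": 2, "kept": 5,
    }
    with pytest.raises(ValueError):
        ledger.reclassify_kept("chimeric", 6)
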