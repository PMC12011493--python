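"""Read filtering cascade: merge, trim, length and expected-error filters.

Stages run in a fixed order — pair merging (ungapped overlap scan, no
staggered configurations, zero mismatches by default), primer trimming,
length floor, expected-error cap, flank trimming — and every input pair is
accounted for in exactly one discard category or kept, so the ledger always
sums to the input count. Chimera and nontarget counts are filled in by the
downstream detection and assignment stages against the same ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .iupac import mask_array, revcomp
from .refdata import Marker

PHRED_OFFSET = 33
PHRED_MAX = 41


@dataclass
class ReadPair:
    """One paired-end read with Phred qualities (integer vectors)."""

    read_id: str
    r1_seq: str
    r2_seq: str
    r1_qual: np.ndarray
    r2_qual: np.ndarray

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    """A merged pair: consensus sequence, per-base quality, overlap, maxEE."""

    read_id: str
    sequence: str
    qual: np.ndarray
    overlap_len: int
    ee: float = 0.0
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.ee = expected_errors(self.qual)


def expected_errors(qual: Iterable[int]) -> float:
    """Sum of per-base error probabilities 10^(-Q/10) (the maxEE statistic)."""
    q = np.asarray(list(qual) if not isinstance(qual, np.ndarray) else qual, dtype=float)
    if q.size == 0:
        return 0.0
    if np.any(q < 0):
        raise ValueError("negative Phred score")
    return float(np.sum(10.0 ** (-q / 10.0)))


def merge_pair(
    pair: ReadPair,
    min_overlap: int = 25,
    max_diffs: int = 0,
    allow_stagger: bool = False,
) -> MergedRead | None:
    """Merge a pair on the longest ungapped overlap within the mismatch cap.

    R2 is reverse-complemented and slid along R1 without gaps; the longest
    overlap of length >= ``min_overlap`` with <= ``max_diffs`` mismatches is
    accepted. Staggered layouts (R2 extending upstream of R1) are rejected
    unless ``allow_stagger``. In the overlap the higher-quality call wins and
    the merged quality is the larger Phred of the two. Returns None when no
    acceptable overlap exists.
    """
    r2c = revcomp(pair.r2_seq)
    q2 = pair.r2_qual[::-1]
    m1 = mask_array(pair.r1_seq)
    m2 = mask_array(r2c)
    len1, len2 = len(pair.r1_seq), len(r2c)

    # offset of r2c start within r1; smaller offset = longer overlap
    for offset in range(0, len1 - min_overlap + 1):
        ov = min(len1 - offset, len2)
        if ov < min_overlap:
            break
        diffs = int(np.count_nonzero((m1[offset : offset + ov] & m2[:ov]) == 0))
        if diffs <= max_diffs:
            return _build_merged(pair, r2c, q2, offset, ov)
    if allow_stagger:
        for offset in range(1, len2 - min_overlap + 1):
            # r2c starts `offset` bases upstream of r1
            ov = min(len2 - offset, len1)
            if ov < min_overlap:
                break
            diffs = int(np.count_nonzero((m2[offset : offset + ov] & m1[:ov]) == 0))
            if diffs <= max_diffs:
                seq, qual = _consensus(
                    r2c[offset : offset + ov], q2[offset : offset + ov],
                    pair.r1_seq[:ov], pair.r1_qual[:ov],
                )
                return MergedRead(pair.read_id, seq, qual, ov)
    return None


def _consensus(a: str, qa: np.ndarray, b: str, qb: np.ndarray) -> tuple[str, np.ndarray]:
    take_b = qb > qa
    seq = "".join(b[i] if take_b[i] else a[i] for i in range(len(a)))
    return seq, np.maximum(qa, qb)


def _build_merged(pair: ReadPair, r2c: str, q2: np.ndarray, offset: int,
                  ov: int) -> MergedRead:
    head_seq = pair.r1_seq[:offset]
    head_q = pair.r1_qual[:offset]
    ov_seq, ov_q = _consensus(
        pair.r1_seq[offset : offset + ov], pair.r1_qual[offset : offset + ov],
        r2c[:ov], q2[:ov],
    )
    tail_seq = r2c[ov:]
    tail_q = q2[ov:]
    sequence = head_seq + ov_seq + tail_seq
    qual = np.concatenate([head_q, ov_q, tail_q])
    return MergedRead(pair.read_id, sequence, qual, ov)


def _find_motif(read_mask: np.ndarray, motif: str, max_mismatch: int,
                last: bool = False) -> int | None:
    """Offset of an IUPAC-compatible motif occurrence, or None."""
    k = len(motif)
    n = len(read_mask)
    if k == 0 or k > n:
        return None
    pm = mask_array(motif)
    windows = np.lib.stride_tricks.sliding_window_view(read_mask, k)
    mism = np.count_nonzero((windows & pm) == 0, axis=1)
    hits = np.nonzero(mism <= max_mismatch)[0]
    if hits.size == 0:
        return None
    return int(hits[-1] if last else hits[0])


def trim_primers(read: MergedRead, fwd: str, rev: str,
                 max_mismatch: int = 1) -> MergedRead:
    """Trim the forward primer at 5' and reverse-complemented reverse primer
    at 3' (IUPAC-aware, <= ``max_mismatch`` each); a missing primer leaves
    that end untouched and records a flag."""
    if not fwd or not rev:
        raise ValueError("primers must be non-empty")
    mask = mask_array(read.sequence)
    start, stop = 0, len(read.sequence)
    flags = set(read.flags)
    pos = _find_motif(mask, fwd, max_mismatch)
    if pos is not None:
        start = pos + len(fwd)
    else:
        flags.add("fwd_primer_missing")
    rc = revcomp(rev)
    pos = _find_motif(mask, rc, max_mismatch, last=True)
    if pos is not None and pos >= start:
        stop = pos
    else:
        flags.add("rev_primer_missing")
    return MergedRead(read.read_id, read.sequence[start:stop],
                      read.qual[start:stop], read.overlap_len, flags=flags)


def trim_flanks(
    read: MergedRead,
    anchors: tuple[str, str] | None,
    on_missing: str = "keep",
) -> MergedRead | None:
    """Anchor-motif flank trimming (stand-in for an HMM extractor).

    Removes everything up to and including the 5' motif and from the 3' motif
    onward, by exact IUPAC-aware search. Empty anchors pass through (coding
    markers). A missing motif either keeps the read untouched or discards it
    (returns None, routed to the nontarget category) per ``on_missing``.
    """
    if not anchors or (not anchors[0] and not anchors[1]):
        return read
    mask = mask_array(read.sequence)
    start, stop = 0, len(read.sequence)
    missing = False
    if anchors[0]:
        pos = _find_motif(mask, anchors[0], 0)
        if pos is None:
            missing = True
        else:
            start = pos + len(anchors[0])
    if anchors[1]:
        pos = _find_motif(mask, anchors[1], 0, last=True)
        if pos is None or pos < start:
            missing = True
        else:
            stop = pos
    if missing:
        if on_missing == "discard":
            return None
        return replace(read, flags=set(read.flags) | {"flank_anchor_missing"})
    return MergedRead(read.read_id, read.sequence[start:stop],
                      read.qual[start:stop], read.overlap_len, flags=set(read.flags))


@dataclass
class DiscardLedger:
    """Per-category read accounting mirroring the filtering-summary figure."""

    unmerged: int = 0
    short: int = 0
    low_quality: int = 0
    chimeric: int = 0
    nontarget: int = 0
    kept: int = 0

    @property
    def total(self) -> int:
        return (self.unmerged + self.short + self.low_quality + self.chimeric
                + self.nontarget + self.kept)

    def reclassify_kept(self, category: str, n: int) -> None:
        """Move reads from kept to a downstream discard category."""
        if n < 0 or n > self.kept:
            raise ValueError("cannot reclassify more reads than are kept")
        self.kept -= n
        setattr(self, category, getattr(self, category) + n)

    def as_dict(self) -> dict[str, int]:
        return {
            "unmerged": self.unmerged, "short": self.short,
            "low_quality": self.low_quality, "chimeric": self.chimeric,
            "nontarget": self.nontarget, "kept": self.kept,
        }


@dataclass
class FilterParams:
    """Knobs of the filtering cascade (defaults follow the benchmark recipe)."""

    min_overlap: int = 25
    max_diffs: int = 0
    allow_stagger: bool = False
    max_ee: float = 1.0
    primers: tuple[str, str] | None = None
    primer_max_mismatch: int = 1
    anchors: tuple[str, str] | None = None
    on_missing: str = "keep"


def filter_cascade(
    pairs: Iterable[ReadPair], marker: Marker, params: FilterParams | None = None
) -> tuple[list[MergedRead], DiscardLedger]:
    """Run merge -> primer trim -> length -> maxEE -> flank trim over a stream.

    Reads discarded by flank trimming are counted as nontarget; chimera
    counts are added to the returned ledger by the detection stage.
    """
    params = params or FilterParams()
    ledger = DiscardLedger()
    kept: list[MergedRead] = []
    for pair in pairs:
        merged = merge_pair(pair, params.min_overlap, params.max_diffs,
                            params.allow_stagger)
        if merged is None:
            ledger.unmerged += 1
            continue
        if params.primers:
            merged = trim_primers(merged, params.primers[0], params.primers[1],
                                  params.primer_max_mismatch)
        if len(merged.sequence) < marker.min_merged_len:
            ledger.short += 1
            continue
        if merged.ee > params.max_ee:
            ledger.low_quality += 1
            continue
        trimmed = trim_flanks(merged, params.anchors, params.on_missing)
        if trimmed is None:
            ledger.nontarget += 1
            continue
        ledger.kept += 1
        kept.append(trimmed)
    return kept, ledger


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream paired Phred+33 FASTQ files; scores are clamped to [0, 41]."""
    with open(r1_path, encoding="ascii") as f1, open(r2_path, encoding="ascii") as f2:
        while True:
            block1 = [f1.readline() for _ in range(4)]
            block2 = [f2.readline() for _ in range(4)]
            if not block1[0] and not block2[0]:
                return
            if "" in block1 or "" in block2 or not block1[3].strip() or not block2[3].strip():
                rid = (block1[0] or block2[0]).strip().lstrip("@")
                raise ValueError(f"truncated FASTQ record near {rid!r}")
            id1 = block1[0].strip().split()[0].lstrip("@")
            id2 = block2[0].strip().split()[0].lstrip("@")
            if id1 != id2:
                raise ValueError(f"unpaired reads {id1!r} / {id2!r}")
            q1 = np.clip(np.frombuffer(block1[3].strip().encode("ascii"),
                                       dtype=np.uint8).astype(int) - PHRED_OFFSET,
                         0, PHRED_MAX)
            q2 = np.clip(np.frombuffer(block2[3].strip().encode("ascii"),
                                       dtype=np.uint8).astype(int) - PHRED_OFFSET,
                         0, PHRED_MAX)
            yield ReadPair(id1, block1[1].strip().upper(), block2[1].strip().upper(),
                           q1, q2)


def dereplicate(reads: Iterable[MergedRead]) -> list[tuple[str, int, list[str]]]:
    """Collapse identical sequences; returns (sequence, abundance, read_ids)
    sorted by decreasing abundance then sequence."""
    groups: dict[str, list[str]] = {}
    for read in reads:
        groups.setdefault(read.sequence, []).append(read.read_id)
    out = [(seq, len(ids), ids) for seq, ids in groups.items()]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def write_derep_fasta(path: str | Path, derep: list[tuple[str, int, list[str]]]) -> None:
    """Write dereplicated reads with ``;size=N`` abundance annotations."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, (seq, size, _ids) in enumerate(derep, 1):
            fh.write(f">uniq{i:05d};size={size}\n")
            for j in range(0, len(seq), 80):
                fh.write(seq[j : j + 80] + "\n")
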