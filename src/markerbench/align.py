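"""Pairwise global alignment with free end gaps, IUPAC-aware.

One aligner configuration is used everywhere identity matters: match +1 for
IUPAC-compatible symbol pairs, −1 otherwise, −2 per gap column, terminal gaps
free. Identity excludes terminal-gap columns and counts internal gap columns
as mismatches, so a read shorter than its reference is not penalised for
covering less of it, but an internal indel is.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .iupac import EXPANSION, GAP, compatible

_ALPHABET = "ACGTRYSWKMBDHVN"


def _substitution_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            m[a, b] = 1.0 if EXPANSION[a] & EXPANSION[b] else -1.0
    return m


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _substitution_matrix()
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # attribute names moved in Biopython 1.88
        # end gaps are free up to a tie-break epsilon: among co-optimal
        # alignments prefer the one with fewer terminal gaps (an unslid
        # alignment of homologous sequences). 1e-4 per column cannot flip a
        # decision between alignments whose integer scores differ, for
        # sequences up to ~2.5 kb.
        aligner.target_end_gap_score = -1e-4
        aligner.query_end_gap_score = -1e-4
    return aligner


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Optimal global alignment of two IUPAC sequences as two gapped rows."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aln = _aligner().align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _core_span(row_a: str, row_b: str) -> tuple[int, int]:
    """Column span [start, stop) excluding terminal gap runs of either row."""
    n = len(row_a)
    start, stop = 0, n
    for row in (row_a, row_b):
        i = 0
        while i < n and row[i] == GAP:
            i += 1
        start = max(start, i)
        j = n
        while j > 0 and row[j - 1] == GAP:
            j -= 1
        stop = min(stop, j)
    return start, stop


def identity_from_rows(row_a: str, row_b: str) -> float:
    """Percent identity over non-terminal-gap columns of an alignment.

    IUPAC-compatible pairs count as matches; internal gap columns as
    mismatches. The denominator is floored at the shorter sequence's length:
    with free end gaps, two unrelated sequences optimally slide to a short
    perfectly matching core, and without the floor that degenerate core would
    score as high identity. A shorter read fully contained in a longer
    reference is unaffected (its core already spans the whole read).
    """
    start, stop = _core_span(row_a, row_b)
    if stop <= start:
        return 0.0
    matches = sum(
        1 for i in range(start, stop) if compatible(row_a[i], row_b[i])
    )
    min_len = min(
        len(row_a) - row_a.count(GAP), len(row_b) - row_b.count(GAP)
    )
    return 100.0 * matches / max(stop - start, min_len)


def percent_identity(a: str, b: str) -> float:
    """Align two sequences and return percent identity (see identity_from_rows)."""
    row_a, row_b = align_pair(a, b)
    return identity_from_rows(row_a, row_b)
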