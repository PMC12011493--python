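"""Shared fixtures: tiny reference sets and a pure-Python alignment oracle."""

from __future__ import annotations

import numpy as np
import pytest

from markerbench.refdata import (
    Marker,
    ReferenceRecord,
    build_center_star_msa,
)


def nw_free_end(a: str, b: str, match: int = 1, mismatch: int = -1,
                gap: int = -2) -> int:
    """Independent Needleman-Wunsch with free end gaps: optimal score only.

    Plain dynamic programming over exact base equality (used on ACGT-only
    oracles), written without reference to the package's aligner.
    """
    n, m = len(a), len(b)
    full = _nw_matrix(a, b, match, mismatch, gap)
    # free trailing gaps: best score on the bottom/right border
    return max(max(full[n]), max(full[i][m] for i in range(n + 1)))


def _nw_matrix(a: str, b: str, match: int, mismatch: int, gap: int):
    n, m = len(a), len(b)
    f = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        f[i][0] = 0
    for j in range(1, m + 1):
        f[0][j] = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = f[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            f[i][j] = max(sub, f[i - 1][j] + gap, f[i][j - 1] + gap)
    return f


def score_rows(row_a: str, row_b: str, match: int = 1, mismatch: int = -1,
               gap: int = -2) -> int:
    """Score a gapped alignment column-wise with free terminal gaps."""
    n = len(row_a)
    start, stop = 0, n
    for row in (row_a, row_b):
        i = 0
        while i < n and row[i] == "-":
            i += 1
        start = max(start, i)
        j = n
        while j > 0 and row[j - 1] == "-":
            j -= 1
        stop = min(stop, j)
    score = 0
    for i in range(start, stop):
        x, y = row_a[i], row_b[i]
        if x == "-" or y == "-":
            score += gap
        elif x == y:
            score += match
        else:
            score += mismatch
    return score


@pytest.fixture
def toy_marker() -> Marker:
    return Marker("toy", "multicopy", 10, 40, 0)


@pytest.fixture
def three_species_refset(toy_marker):
    base = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
    seqs = {
        "sp1": base,
        "sp2": base[:10] + "T" + base[11:],
        "sp3": base[:30] + "G" + base[31:],
    }
    records = [
        ReferenceRecord.from_sequence(sp, "toy", seq) for sp, seq in seqs.items()
    ]
    return build_center_star_msa(records)


def random_family(rng: np.random.Generator, n: int, length: int,
                  sub_rate: float) -> list[str]:
    """A root sequence plus n-1 mutated relatives (substitutions only)."""
    root = "".join(rng.choice(list("ACGT"), size=length))
    out = [root]
    for _ in range(n - 1):
        chars = list(root)
        for i in np.nonzero(rng.random(length) < sub_rate)[0]:
            chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
        out.append("".join(chars))
    return out
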