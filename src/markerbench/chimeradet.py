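"""Two-parent PCR chimera detection, de novo and reference-based.

A query is modelled as a single-crossover hybrid of two parents: for every
ordered candidate pair the query, parent A and parent B are placed on common
columns (star alignment on the query) and the hybrid A[<k] + B[>=k] is scored
against the query at every internal crossover k. De novo mode only considers
parents already processed at a sufficient abundance skew (PCR chimeras are
rarer than their templates); reference mode considers every reference
regardless of abundance, which is what makes it the more sensitive search.
The per-side gate follows the vote semantics: on each side of the crossover
the parent NOT contributing that side must disagree with the query by at
least ``min_diffs_per_side`` more positions than the contributing parent, so
both segments carry real signal.

This is deliberately a transparent crossover model, not a port of the UCHIME
segment/vote heuristics; the benchmark needs the de novo-versus-reference
contrast with auditable semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import align_pair
from .iupac import compatible
from .refdata import ReferenceSet
from .refdata import _center_insertions, _pad_row  # star-merge helpers


@dataclass(frozen=True)
class ChimeraParams:
    """Detection gates.

    ``min_parent_ratio`` is the minimum parent/query abundance skew in de novo
    mode; ``min_diffs_per_side`` the vote margin each crossover side must
    carry; ``max_model_diffs_*`` the residual diffs the hybrid model may leave
    (0 de novo, 1 in sensitive reference mode).
    """

    min_parent_ratio: float = 16.0
    min_diffs_per_side: int = 3
    max_model_diffs_denovo: int = 0
    max_model_diffs_ref: int = 1

    def __post_init__(self) -> None:
        if self.min_parent_ratio < 1 or self.min_diffs_per_side < 1:
            raise ValueError("invalid chimera params")


@dataclass
class ChimeraModel:
    """Best two-parent decomposition of a query."""

    query_id: str
    parent_a: str
    parent_b: str
    crossover: int
    diffs_model: int
    diffs_best_single: int
    left_margin: int
    right_margin: int
    is_chimeric: bool = False


def _star_on_query(query: str, candidates: list[tuple[str, str]]) -> tuple[str, dict[str, str]]:
    """Merge pairwise query-candidate alignments onto common query columns."""
    ins = [0] * (len(query) + 1)
    pairwise: dict[str, tuple[str, str]] = {}
    for cand_id, seq in candidates:
        row_q, row_c = align_pair(query, seq)
        pairwise[cand_id] = (row_q, row_c)
        for slot, count in enumerate(_center_insertions(row_q)):
            ins[slot] = max(ins[slot], count)
    parts = []
    for slot, base in enumerate(query):
        parts.append("-" * ins[slot] + base)
    parts.append("-" * ins[len(query)])
    query_row = "".join(parts)
    rows = {cid: _pad_row(rq, rc, ins) for cid, (rq, rc) in pairwise.items()}
    return query_row, rows


def best_two_parent_model(
    query: str,
    candidates: list[tuple[str, str, float]],
    query_id: str = "query",
) -> ChimeraModel:
    """Minimum-diff single-crossover model of the query over all ordered
    candidate pairs and internal crossover columns.

    ``candidates`` are (id, sequence, abundance) triples; abundance is not
    gated here (the detect_* policies do that). Ties on model diffs prefer
    the model with the larger worst-side vote margin, then lexicographic
    parents and the smallest crossover, so results are deterministic.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidates")
    query_row, rows = _star_on_query(query, [(c[0], c[1]) for c in candidates])
    n_cols = len(query_row)

    diff_prefix: dict[str, np.ndarray] = {}
    for cid, row in rows.items():
        d = np.fromiter(
            (0 if compatible(a, b) else 1 for a, b in zip(query_row, row)),
            dtype=np.int64, count=n_cols,
        )
        diff_prefix[cid] = np.concatenate([[0], np.cumsum(d)])

    totals = {cid: int(p[-1]) for cid, p in diff_prefix.items()}
    diffs_best_single = min(totals.values())

    best: tuple | None = None
    ids = sorted(rows)
    ks = np.arange(1, n_cols)
    for a in ids:
        pa = diff_prefix[a]
        for b in ids:
            if a == b:
                continue
            pb = diff_prefix[b]
            model = pa[ks] + (totals[b] - pb[ks])
            left_margin = pb[ks] - pa[ks]
            right_margin = (totals[a] - pa[ks]) - (totals[b] - pb[ks])
            worst = np.minimum(left_margin, right_margin)
            order = np.lexsort((ks, -worst, model))
            i = order[0]
            key = (int(model[i]), -int(worst[i]), a, b, int(ks[i]))
            if best is None or key < best[:5]:
                best = key + (int(left_margin[i]), int(right_margin[i]))
    assert best is not None
    diffs_model, _negworst, pa_id, pb_id, k, lm, rm = best
    return ChimeraModel(
        query_id=query_id, parent_a=pa_id, parent_b=pb_id, crossover=k,
        diffs_model=diffs_model, diffs_best_single=diffs_best_single,
        left_margin=lm, right_margin=rm,
    )


def _passes(model: ChimeraModel, max_model_diffs: int, min_side: int) -> bool:
    return (
        model.diffs_model <= max_model_diffs
        and model.left_margin >= min_side
        and model.right_margin >= min_side
    )


def detect_denovo(
    reads: list[tuple[str, str, int]],
    params: ChimeraParams | None = None,
) -> tuple[set[str], list[ChimeraModel]]:
    """Abundance-aware de novo chimera search over dereplicated reads.

    Reads (id, sequence, abundance) are processed in decreasing abundance
    (ties lexicographic by sequence); candidates for a query are the already
    processed reads at >= ``min_parent_ratio`` times its abundance. Returns
    the flagged ids and the models behind every flag.
    """
    params = params or ChimeraParams()
    if any(ab < 1 for _, _, ab in reads):
        raise ValueError("abundances must be >= 1")
    ordered = sorted(reads, key=lambda r: (-r[2], r[1], r[0]))
    flagged: set[str] = set()
    models: list[ChimeraModel] = []
    processed: list[tuple[str, str, int]] = []
    for rid, seq, ab in ordered:
        candidates = [
            (pid, pseq, pab) for pid, pseq, pab in processed
            if pab >= params.min_parent_ratio * ab
        ]
        if len(candidates) >= 2:
            model = best_two_parent_model(seq, candidates, query_id=rid)
            if _passes(model, params.max_model_diffs_denovo,
                       params.min_diffs_per_side):
                model.is_chimeric = True
                flagged.add(rid)
                models.append(model)
        processed.append((rid, seq, ab))
    return flagged, models


def detect_reference(
    reads: list[tuple[str, str, int]],
    refs: ReferenceSet,
    params: ChimeraParams | None = None,
) -> tuple[set[str], list[ChimeraModel]]:
    """Reference-based (sensitive) chimera search: every reference is a
    candidate parent with no abundance gate; reads identical to a reference
    are never flagged."""
    params = params or ChimeraParams()
    if not refs.records:
        raise ValueError("empty reference set")
    candidates = [(r.species_id, r.sequence, 1.0) for r in refs.records]
    flagged: set[str] = set()
    models: list[ChimeraModel] = []
    if len(candidates) < 2:
        return flagged, models
    for rid, seq, _ab in reads:
        model = best_two_parent_model(seq, candidates, query_id=rid)
        if model.diffs_best_single == 0:
            continue
        if _passes(model, params.max_model_diffs_ref, params.min_diffs_per_side):
            model.is_chimeric = True
            flagged.add(rid)
            models.append(model)
    return flagged, models


def compare_detection(denovo: set[str], reference: set[str]) -> float:
    """Percent of reference-detected chimeras also found de novo."""
    if not reference:
        if denovo:
            raise ValueError("de novo detections with empty reference set")
        return 100.0
    return 100.0 * len(denovo & reference) / len(reference)
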