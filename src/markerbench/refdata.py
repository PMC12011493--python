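"""Reference sequence sets for mock-community markers.

A marker's Sanger references (one per species, IUPAC alphabet) are the ground
truth for everything downstream: distinguishing positions separate species,
IUPAC ambiguity codes encode intragenomic sequence variants, and species whose
references are compatible at every aligned column are lumped into a single
unit for scoring. The detection table mirrors the published per-species
relative-abundance / sequence-variant layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .align import align_pair
from .iupac import GAP, ambiguous_indices, compatible, is_iupac

MULTICOPY = "multicopy"
LOW_COPY = "low_copy"


@dataclass(frozen=True)
class Marker:
    """A barcode marker and its filtering geometry.

    ``min_merged_len`` is the post-merge length floor (50 bp for ITS-like
    spacers, 200 bp for protein-coding regions); amplicon lengths are the
    mean/SD of the marker's insert length distribution.
    """

    name: str
    copy_class: str
    min_merged_len: int
    amplicon_len_mean: int
    amplicon_len_sd: int

    def __post_init__(self) -> None:
        if self.copy_class not in (MULTICOPY, LOW_COPY):
            raise ValueError(f"unknown copy_class {self.copy_class!r}")
        if self.min_merged_len <= 0:
            raise ValueError("min_merged_len must be positive")
        if self.amplicon_len_mean <= self.min_merged_len:
            raise ValueError("amplicon_len_mean must exceed min_merged_len")


#: The four markers of the benchmark with their published length profiles:
#: ITS1 short (the Hodophilus ITS1 amplicon is < 200 bp), ITS2 long and
#: length-variable (~405 bp in Russula, with outliers ~465 bp that cannot be
#: merged from 2x250 reads), rpb2 395-400 bp, ef1-a of similar scale.
DEFAULT_MARKERS: dict[str, Marker] = {
    "ITS1": Marker("ITS1", MULTICOPY, 50, 220, 40),
    "ITS2": Marker("ITS2", MULTICOPY, 50, 330, 60),
    "rpb2": Marker("rpb2", LOW_COPY, 200, 398, 8),
    "ef1a": Marker("ef1a", LOW_COPY, 200, 380, 12),
}


@dataclass(frozen=True)
class ReferenceRecord:
    """One species' Sanger reference for one marker."""

    species_id: str
    marker: str
    sequence: str
    ambiguous_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.species_id}: empty sequence")
        expected = frozenset(ambiguous_indices(self.sequence))
        if self.ambiguous_positions != expected:
            object.__setattr__(self, "ambiguous_positions", expected)

    @staticmethod
    def from_sequence(species_id: str, marker: str, sequence: str) -> "ReferenceRecord":
        sequence = sequence.upper()
        for i, symbol in enumerate(sequence):
            if not is_iupac(symbol):
                raise ValueError(
                    f"non-IUPAC character {symbol!r} in record "
                    f"{species_id!r} at offset {i}"
                )
        return ReferenceRecord(species_id, marker, sequence)


@dataclass
class ReferenceSet:
    """References of one marker plus their multiple alignment.

    ``msa`` holds one gapped row per record (equal lengths); ``column_map``
    maps each alignment column to the 0-based sequence index for each record,
    or None at a gap. Ungapping any row reproduces its record's sequence.
    """

    marker: Marker
    records: list[ReferenceRecord]
    msa: list[str]
    column_map: list[list[int | None]]

    def __post_init__(self) -> None:
        widths = {len(row) for row in self.msa}
        if len(widths) > 1:
            raise ValueError("MSA rows differ in length")
        for rec, row in zip(self.records, self.msa):
            if row.replace(GAP, "") != rec.sequence:
                raise ValueError(f"MSA row does not ungap to {rec.species_id}")

    @property
    def species_ids(self) -> list[str]:
        return [r.species_id for r in self.records]

    def row(self, species_id: str) -> str:
        for rec, row in zip(self.records, self.msa):
            if rec.species_id == species_id:
                return row
        raise KeyError(species_id)

    def record(self, species_id: str) -> ReferenceRecord:
        for rec in self.records:
            if rec.species_id == species_id:
                return rec
        raise KeyError(species_id)


@dataclass(frozen=True)
class SpeciesUnit:
    """A set of species indistinguishable in one marker, scored as one taxon."""

    unit_id: str
    member_species: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_species:
            raise ValueError("unit must have members")


def read_reference_fasta(path: str | Path, marker: Marker) -> list[ReferenceRecord]:
    """Parse a reference FASTA; headers carry the species id (first token)."""
    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        species_id = entry.id
        if species_id in seen:
            raise ValueError(f"duplicate species_id {species_id!r} in {path}")
        seen.add(species_id)
        records.append(
            ReferenceRecord.from_sequence(species_id, marker.name, str(entry.seq))
        )
    return records


def write_reference_fasta(path: str | Path, records: Iterable[ReferenceRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.species_id}\n")
            for i in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[i : i + 80] + "\n")


def _center_insertions(row_center: str) -> list[int]:
    """Gap counts between consecutive center bases (slots 0..L inclusive)."""
    n_bases = len(row_center) - row_center.count(GAP)
    ins = [0] * (n_bases + 1)
    slot = 0
    for symbol in row_center:
        if symbol == GAP:
            ins[slot] += 1
        else:
            slot += 1
    return ins


def _pad_row(row_center: str, row_other: str, ins: list[int]) -> str:
    """Re-space one pairwise alignment row onto the merged column layout."""
    own = _center_insertions(row_center)
    out: list[str] = []
    slot = 0
    pending: list[str] = []
    for c_sym, o_sym in zip(row_center, row_other):
        if c_sym == GAP:
            pending.append(o_sym)
        else:
            out.append("".join(pending) + GAP * (ins[slot] - own[slot]))
            out.append(o_sym)
            pending = []
            slot += 1
    out.append("".join(pending) + GAP * (ins[slot] - own[slot]))
    return "".join(out)


def build_center_star_msa(records: list[ReferenceRecord]) -> ReferenceSet:
    """Center-star multiple alignment of one marker's references.

    The center is the longest sequence (ties broken lexicographically by
    species id); every other record is globally aligned to it and the pairwise
    alignments are merged column-wise on center coordinates.
    """
    if not records:
        raise ValueError("no records to align")
    marker_names = {r.marker for r in records}
    if len(marker_names) > 1:
        raise ValueError(f"records span several markers: {sorted(marker_names)}")
    marker = DEFAULT_MARKERS.get(
        records[0].marker,
        Marker(records[0].marker, MULTICOPY, 50, max(len(records[0].sequence), 60), 0),
    )

    center = min(records, key=lambda r: (-len(r.sequence), r.species_id))
    others = [r for r in records if r is not center]

    pairwise: dict[str, tuple[str, str]] = {}
    length = len(center.sequence)
    ins = [0] * (length + 1)
    for rec in others:
        row_c, row_o = align_pair(center.sequence, rec.sequence)
        pairwise[rec.species_id] = (row_c, row_o)
        for slot, count in enumerate(_center_insertions(row_c)):
            ins[slot] = max(ins[slot], count)

    center_row_parts: list[str] = []
    for slot, base in enumerate(center.sequence):
        center_row_parts.append(GAP * ins[slot] + base)
    center_row_parts.append(GAP * ins[length])
    center_row = "".join(center_row_parts)

    rows: dict[str, str] = {center.species_id: center_row}
    for rec in others:
        row_c, row_o = pairwise[rec.species_id]
        rows[rec.species_id] = _pad_row(row_c, row_o, ins)

    msa = [rows[r.species_id] for r in records]
    column_map: list[list[int | None]] = []
    for row in msa:
        mapping: list[int | None] = []
        idx = 0
        for symbol in row:
            if symbol == GAP:
                mapping.append(None)
            else:
                mapping.append(idx)
                idx += 1
        column_map.append(mapping)
    return ReferenceSet(marker, list(records), msa, column_map)


def find_distinguishing_positions(refset: ReferenceSet) -> dict[str, set[int]]:
    """Alignment columns at which a species is IUPAC-incompatible with all others."""
    if len(refset.records) < 2:
        raise ValueError("need at least two records")
    n_cols = len(refset.msa[0])
    result: dict[str, set[int]] = {r.species_id: set() for r in refset.records}
    for col in range(n_cols):
        symbols = [row[col] for row in refset.msa]
        for i, rec in enumerate(refset.records):
            if all(
                not compatible(symbols[i], symbols[j])
                for j in range(len(symbols))
                if j != i
            ):
                result[rec.species_id].add(col)
    return result


def collapse_units(refset: ReferenceSet) -> list[SpeciesUnit]:
    """Lump species compatible at every aligned column into single units.

    Membership is the transitive closure of pairwise whole-row compatibility,
    so the output partitions the species list.
    """
    ids = refset.species_ids
    parent = {s: s for s in ids}

    def find(s: str) -> str:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if all(
                compatible(a, b) for a, b in zip(refset.msa[i], refset.msa[j])
            ):
                parent[find(ids[i])] = find(ids[j])

    groups: dict[str, set[str]] = {}
    for s in ids:
        groups.setdefault(find(s), set()).add(s)
    units = []
    for members in sorted(groups.values(), key=lambda m: sorted(m)[0]):
        unit_id = "+".join(sorted(members)) if len(members) > 1 else next(iter(members))
        units.append(SpeciesUnit(unit_id, frozenset(members)))
    return units


@dataclass
class DetectionTable:
    """Per (genus, species, marker) resampled read count (RA) and variant count (SV)."""

    frame: pd.DataFrame  # columns: genus, species, marker, ra, sv
    depth: int = 5000

    def __post_init__(self) -> None:
        required = {"genus", "species", "marker", "ra", "sv"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"detection table missing columns {sorted(missing)}")
        bad = self.frame[(self.frame.ra >= 1) != (self.frame.sv >= 1)]
        if len(bad):
            raise ValueError("sv >= 1 must hold exactly when ra >= 1")


def load_packaged_detection_table(depth: int = 5000) -> DetectionTable:
    """The packaged transcription of the study's species-representation table."""
    with resources.files("markerbench.data").joinpath(
        "mock_community_detection.tsv"
    ).open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh, sep="\t")
    return DetectionTable(frame, depth=depth)


def summarize_detection_table(
    table: DetectionTable, total_species: int | None = None, min_frac: float = 0.0001
) -> dict:
    """Marker-level summaries of a detection table.

    Returns per-marker multiple-variant percentages (share of the full
    community carrying >= 2 sequence variants, nearest-integer), per-genus RA
    column sums, per-genus detected-species counts, and rows whose resampled
    fraction falls below ``min_frac``.
    """
    frame = table.frame
    if frame.empty:
        raise ValueError("empty detection table")
    if total_species is None:
        total_species = frame[["genus", "species"]].drop_duplicates().shape[0]

    multi = frame[frame.sv >= 2].groupby("marker")["species"].count()
    markers = sorted(frame.marker.unique())
    multivariant_pct = {
        m: int(round(100.0 * multi.get(m, 0) / total_species)) for m in markers
    }
    ra_sums = frame.groupby(["genus", "marker"])["ra"].sum()
    detected = (
        frame[frame.ra >= 1].groupby(["genus", "marker"])["species"].count()
    )
    below = frame[
        (frame.ra >= 1) & (frame.ra / table.depth < min_frac)
    ][["genus", "species", "marker"]]
    return {
        "total_species": total_species,
        "multivariant_pct": multivariant_pct,
        "ra_sums": {k: int(v) for k, v in ra_sums.items()},
        "detected_species": {k: int(v) for k, v in detected.items()},
        "below_min_fraction": [tuple(r) for r in below.itertuples(index=False)],
    }
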