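"""Reference-based taxonomic assignment and variant/noise classification.

Reads are annotated to the best-identity reference at a 97% floor; species
lumped into one unit absorb ties among their references, and ties across
units fall back to distinguishing positions. Differences confined to a
reference's IUPAC ambiguity positions (and compatible with the code) are
intragenomic sequence variants; any other difference is sequencing noise.
The detection table resamples every library to a fixed depth so relative
abundances are comparable across markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import align_pair, percent_identity
from .iupac import GAP, compatible
from .refdata import (
    DetectionTable,
    ReferenceRecord,
    ReferenceSet,
    SpeciesUnit,
    find_distinguishing_positions,
)

logger = logging.getLogger(__name__)

IDENTITY_THRESHOLD = 97.0


@dataclass
class Assignment:
    """Annotation of one read: unit/species, variant or noise, identity."""

    read_id: str
    genus: str
    marker: str
    unit_id: str | None  # None = nontarget
    species_id: str | None = None
    variant_id: int | None = None
    noise: bool = False
    identity: float = 0.0
    ambiguous: bool = False

    @property
    def label(self) -> str | None:
        """Species-level label used for tables and truth comparison."""
        return self.species_id or self.unit_id


def global_identity(a: str, b: str) -> float:
    """Percent identity under free-end-gap global alignment, IUPAC-aware."""
    return percent_identity(a, b)


def classify_variant(
    read_seq: str, ref: ReferenceRecord
) -> tuple[str, tuple[tuple[int, str], ...] | None]:
    """Classify a species-assigned read against its reference.

    Returns ("match", haplotype) when every difference sits at an ambiguous
    reference position and is compatible with the code — the haplotype is the
    tuple of (position, base) resolutions; ("noise", None) when any other
    difference (including an internal indel) is present.
    """
    row_read, row_ref = align_pair(read_seq, ref.sequence)
    n = len(row_read)
    # core span excluding terminal gaps of either row
    start, stop = 0, n
    for row in (row_read, row_ref):
        i = 0
        while i < n and row[i] == GAP:
            i += 1
        start = max(start, i)
        j = n
        while j > 0 and row[j - 1] == GAP:
            j -= 1
        stop = min(stop, j)
    ref_idx = -1
    haplotype: list[tuple[int, str]] = []
    for col in range(n):
        if row_ref[col] != GAP:
            ref_idx += 1
        if col < start or col >= stop:
            continue
        if not compatible(row_read[col], row_ref[col]):
            return "noise", None
        if row_ref[col] != GAP and ref_idx in ref.ambiguous_positions:
            haplotype.append((ref_idx, row_read[col]))
    return "match", tuple(haplotype)


class Annotator:
    """Assignment context for one (genus, marker) library."""

    def __init__(
        self,
        refset: ReferenceSet,
        units: list[SpeciesUnit],
        threshold: float = IDENTITY_THRESHOLD,
    ) -> None:
        self.refset = refset
        self.units = units
        self.threshold = threshold
        self.unit_of = {
            sp: u.unit_id for u in units for sp in u.member_species
        }
        self.distinguishing = (
            find_distinguishing_positions(refset) if len(refset.records) >= 2 else {}
        )

    def annotate(
        self, read_id: str, seq: str, genus: str = "",
        unit_abundance: dict[str, float] | None = None,
    ) -> Assignment:
        marker = self.refset.marker.name
        idents = {
            rec.species_id: percent_identity(seq, rec.sequence)
            for rec in self.refset.records
        }
        best = max(idents.values())
        if best < self.threshold:
            return Assignment(read_id, genus, marker, None, identity=best)
        tied = sorted(s for s, v in idents.items() if v >= best - 1e-9)
        tied_units = sorted({self.unit_of[s] for s in tied})
        ambiguous = False
        if len(tied) == 1:
            species: str | None = tied[0]
            unit = self.unit_of[species]
        elif len(tied_units) == 1:
            unit = tied_units[0]
            species = None  # resolved only to the lumped unit
        else:
            supported = [s for s in tied if self._supports(seq, s)]
            if len(supported) == 1:
                species = supported[0]
                unit = self.unit_of[species]
            else:
                ambiguous = True
                if unit_abundance:
                    unit = max(
                        tied_units, key=lambda u: (unit_abundance.get(u, 0.0), u)
                    )
                else:
                    unit = tied_units[0]
                species = None
                logger.warning(
                    "read %s equidistant between units %s; assigned to %s",
                    read_id, tied_units, unit,
                )
        return Assignment(read_id, genus, marker, unit, species_id=species,
                          identity=best, ambiguous=ambiguous)

    def _supports(self, seq: str, species_id: str) -> bool:
        """Does the read match this species' distinguishing bases somewhere?"""
        cols = self.distinguishing.get(species_id, set())
        if not cols:
            return False
        rec = self.refset.record(species_id)
        row_read, row_ref = align_pair(seq, rec.sequence)
        idx_of: dict[int, int] = {}
        ref_idx = -1
        for col, sym in enumerate(row_ref):
            if sym != GAP:
                ref_idx += 1
                idx_of[ref_idx] = col
        row_idx = self.refset.species_ids.index(species_id)
        col_map = self.refset.column_map[row_idx]
        for msa_col in cols:
            seq_idx = col_map[msa_col]
            if seq_idx is None or seq_idx not in idx_of:
                continue
            c = idx_of[seq_idx]
            if row_read[c] != GAP and compatible(row_read[c], row_ref[c]):
                return True
        return False


def annotate_read(
    read_id: str,
    seq: str,
    refset: ReferenceSet,
    units: list[SpeciesUnit],
    genus: str = "",
    threshold: float = IDENTITY_THRESHOLD,
) -> Assignment:
    """One-shot annotation (see Annotator for batch use)."""
    return Annotator(refset, units, threshold).annotate(read_id, seq, genus)


def assign_library(
    derep: list[tuple[str, int, list[str]]],
    refset: ReferenceSet,
    units: list[SpeciesUnit],
    genus: str,
) -> list[Assignment]:
    """Annotate a dereplicated library and classify variants per species.

    Returns one Assignment per underlying read. Variant ids are indexed per
    species by haplotype abundance (canonical = most abundant = 0); noise
    reads keep their species assignment but carry the noise flag.
    """
    annotator = Annotator(refset, units)
    per_unique: list[tuple[Assignment, list[str], str, tuple | None]] = []
    hap_counts: dict[str, dict[tuple, int]] = {}
    for i, (seq, size, read_ids) in enumerate(derep):
        a = annotator.annotate(f"uniq{i + 1:05d}", seq, genus)
        kind, hap = "nontarget", None
        if a.unit_id is not None:
            # classify against one representative reference of the unit
            ref_sp = a.species_id
            if ref_sp is None:
                unit = next(u for u in units if u.unit_id == a.unit_id)
                ref_sp = sorted(unit.member_species)[0]
            kind, hap = classify_variant(seq, refset.record(ref_sp))
            if kind == "match":
                counts = hap_counts.setdefault(a.label, {})
                counts[hap] = counts.get(hap, 0) + size
        per_unique.append((a, read_ids, kind, hap))

    variant_index: dict[str, dict[tuple, int]] = {}
    for label, counts in hap_counts.items():
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        variant_index[label] = {hap: i for i, (hap, _n) in enumerate(ranked)}

    out: list[Assignment] = []
    for a, read_ids, kind, hap in per_unique:
        vid = None
        noise = False
        if a.unit_id is not None:
            if kind == "noise":
                noise = True
            else:
                vid = variant_index[a.label][hap]
        for rid in read_ids:
            out.append(
                Assignment(rid, genus, a.marker, a.unit_id, a.species_id,
                           vid, noise, a.identity, a.ambiguous)
            )
    return out


def build_detection_table(
    assignments: list[Assignment],
    depth: int = 5000,
    min_frac: float = 0.0001,
    seed: int = 0,
    allow_fewer: bool = False,
    all_species: dict[str, list[str]] | None = None,
) -> DetectionTable:
    """Resample each (genus, marker) library and tabulate RA and SV.

    Resampling is without replacement to ``depth`` reads drawn from the
    non-noise species-assigned reads; RA is the resampled per-species count
    and SV the number of distinct variant ids among the resampled reads.
    Species below ``min_frac`` of the *unresampled* library are flagged.
    Absent species get ra=0, sv=0 rows when ``all_species`` lists them.
    """
    pools: dict[tuple[str, str], list[Assignment]] = {}
    for a in assignments:
        if a.unit_id is None or a.noise:
            continue
        pools.setdefault((a.genus, a.marker), []).append(a)

    rows = []
    for idx, key in enumerate(sorted(pools)):
        genus, marker = key
        pool = pools[key]
        if len(pool) < depth:
            if not allow_fewer:
                raise ValueError(
                    f"{genus}/{marker}: {len(pool)} assigned reads < depth {depth}"
                )
            sample = pool
        else:
            rng = np.random.default_rng([int(seed) % (2**31), idx])
            chosen = rng.choice(len(pool), size=depth, replace=False)
            sample = [pool[i] for i in chosen]
        pre_counts: dict[str, int] = {}
        for a in pool:
            pre_counts[a.label] = pre_counts.get(a.label, 0) + 1
        ra: dict[str, int] = {}
        sv: dict[str, set[int]] = {}
        for a in sample:
            ra[a.label] = ra.get(a.label, 0) + 1
            sv.setdefault(a.label, set()).add(a.variant_id)
        labels = set(pre_counts)
        if all_species and genus in all_species:
            labels |= set(all_species[genus])
        for label in sorted(labels):
            n = ra.get(label, 0)
            rows.append({
                "genus": genus, "species": label, "marker": marker,
                "ra": n, "sv": len(sv.get(label, ())) if n else 0,
                "below_min_frac": bool(
                    pre_counts.get(label, 0)
                    and pre_counts[label] / len(pool) < min_frac
                ),
            })
    frame = pd.DataFrame(
        rows, columns=["genus", "species", "marker", "ra", "sv", "below_min_frac"]
    )
    return DetectionTable(frame, depth=depth)
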