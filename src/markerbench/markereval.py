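"""Marker scoring: correct/partial/mixed OTUs, mistakes, best thresholds,
and the benchmark's summary statistics.

An OTU is *correct* when it holds every read of exactly one species and
nothing else, *partial* when it holds a proper subset of one species' reads,
and *mixed* when two or more species are present. Partial OTUs count one
mistake; a mixed OTU counts one mistake per species it contains. The best
threshold per marker maximises correct OTUs, then minimises mistakes, then
takes the lowest threshold. Read-distribution comparisons use one-way ANOVA
on log counts; abundance- and variant-driven mistake rates use Spearman rank
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .otucluster import OTU, SweepResult
from .refdata import DetectionTable

CORRECT, PARTIAL, MIXED = "correct", "partial", "mixed"


@dataclass(frozen=True)
class OTUAssessment:
    otu_id: str
    label: str
    species_present: frozenset[str]
    mistake_contribution: int

    def __post_init__(self) -> None:
        expected = {CORRECT: 0, PARTIAL: 1}.get(self.label, len(self.species_present))
        if self.mistake_contribution != expected:
            raise ValueError("mistake contribution inconsistent with label")


def assess_otus(
    otus: list[OTU], truth: dict[str, int]
) -> list[OTUAssessment]:
    """Label each OTU correct / partial / mixed against per-species totals.

    ``truth`` maps species label -> total read count in the library.
    """
    out: list[OTUAssessment] = []
    for otu in otus:
        species = {s for s, n in otu.species_counts.items() if n > 0}
        unknown = {s for s in species if s not in truth}
        if unknown:
            raise KeyError(f"species missing from truth: {sorted(unknown)}")
        if len(species) >= 2:
            out.append(OTUAssessment(otu.otu_id, MIXED, frozenset(species),
                                     len(species)))
        else:
            (sp,) = species
            if otu.species_counts[sp] == truth[sp]:
                out.append(OTUAssessment(otu.otu_id, CORRECT, frozenset(species), 0))
            else:
                out.append(OTUAssessment(otu.otu_id, PARTIAL, frozenset(species), 1))
    return out


def count_mistakes(assessments: list[OTUAssessment]) -> int:
    """Total mistakes: 1 per partial OTU, species count per mixed OTU."""
    return sum(a.mistake_contribution for a in assessments)


@dataclass
class SweepCell:
    marker: str
    threshold: float
    n_correct: int
    n_partial: int
    n_mixed: int
    mistakes: int
    assessments: list[OTUAssessment] = field(default_factory=list)


def assess_sweep(
    sweep: SweepResult, truth_by_marker: dict[str, dict[str, int]]
) -> list[SweepCell]:
    """Assess every (marker, threshold) partition of a sweep."""
    cells = []
    for (marker, threshold), otus in sorted(sweep.partitions.items()):
        assessments = assess_otus(otus, truth_by_marker[marker])
        labels = [a.label for a in assessments]
        cells.append(SweepCell(
            marker, threshold,
            labels.count(CORRECT), labels.count(PARTIAL), labels.count(MIXED),
            count_mistakes(assessments), assessments,
        ))
    return cells


def select_best_threshold(cells: list[SweepCell]) -> float:
    """Maximise correct OTUs, then minimise mistakes, then lowest threshold."""
    if not cells:
        raise ValueError("no sweep rows")
    best = min(cells, key=lambda c: (-c.n_correct, c.mistakes, c.threshold))
    return best.threshold


def anova_log_counts(table: DetectionTable, genus: str) -> tuple[float, float]:
    """One-way fixed-effects ANOVA on ln(RA) of detected species, groups =
    markers, within one genus."""
    sub = table.frame[(table.frame.genus == genus) & (table.frame.ra >= 1)]
    groups = [
        np.log(g.ra.to_numpy(dtype=float))
        for _m, g in sub.groupby("marker")
    ]
    if len(groups) < 2:
        raise ValueError("need at least two markers")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each marker needs >= 2 detected species")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def species_mistake_rates(cells: list[SweepCell]) -> dict[str, float]:
    """Per species: fraction of sweep cells in which it sits in a non-correct OTU."""
    seen: dict[str, int] = {}
    bad: dict[str, int] = {}
    for cell in cells:
        present: set[str] = set()
        faulted: set[str] = set()
        for a in cell.assessments:
            present |= a.species_present
            if a.label != CORRECT:
                faulted |= a.species_present
        for sp in present:
            seen[sp] = seen.get(sp, 0) + 1
        for sp in faulted:
            bad[sp] = bad.get(sp, 0) + 1
    n_cells = len({(c.marker, c.threshold) for c in cells})
    return {sp: bad.get(sp, 0) / n_cells for sp in seen}


def spearman_mistake_correlations(
    table: DetectionTable, cells: list[SweepCell], genus: str | None = None
) -> dict[str, tuple[float, float]]:
    """Spearman rho between per-species mistake rate and (a) total RA summed
    over markers, (b) total SV summed over markers. p-values use the
    t-approximation; ties get average ranks."""
    rates = species_mistake_rates(cells)
    frame = table.frame
    if genus is not None:
        frame = frame[frame.genus == genus]
    ra = frame.groupby("species")["ra"].sum()
    sv = frame.groupby("species")["sv"].sum()
    species = sorted(set(rates) & set(ra.index))
    if len(species) < 3:
        raise ValueError("need at least three species")
    rate_v = [rates[s] for s in species]

    def corr(x: list[float]) -> tuple[float, float]:
        if len(set(x)) == 1 or len(set(rate_v)) == 1:
            return float("nan"), float("nan")  # rho undefined on constants
        rho, p = stats.spearmanr(x, rate_v)
        return float(rho), float(p)

    return {
        "abundance": corr([float(ra[s]) for s in species]),
        "sv": corr([float(sv[s]) for s in species]),
    }


@dataclass
class EvaluationReport:
    """Full scoring output for one genus's sweep."""

    genus: str
    cells: list[SweepCell]
    best_threshold: dict[str, float]
    anova: tuple[float, float] | None = None
    spearman: dict[str, tuple[float, float]] | None = None


def evaluate(
    sweep: SweepResult,
    truth_by_marker: dict[str, dict[str, int]],
    table: DetectionTable | None = None,
    genus: str = "",
) -> EvaluationReport:
    """Assess a sweep and, when a detection table is supplied, attach the
    ANOVA and Spearman statistics."""
    cells = assess_sweep(sweep, truth_by_marker)
    markers = sorted({c.marker for c in cells})
    best = {
        m: select_best_threshold([c for c in cells if c.marker == m])
        for m in markers
    }
    report = EvaluationReport(genus, cells, best)
    if table is not None:
        try:
            report.anova = anova_log_counts(table, genus)
        except ValueError:
            report.anova = None
        try:
            report.spearman = spearman_mistake_correlations(table, cells, genus)
        except ValueError:
            report.spearman = None
    return report
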