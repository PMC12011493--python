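"""OTU assessment, mistake counting, best-threshold rule, and statistics
against closed-form and rank-based oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from markerbench.markereval import (
    OTUAssessment,
    SweepCell,
    anova_log_counts,
    assess_otus,
    count_mistakes,
    select_best_threshold,
    species_mistake_rates,
    spearman_mistake_correlations,
)
from markerbench.otucluster import OTU
from markerbench.refdata import DetectionTable

import pandas as pd


def make_otu(otu_id: str, counts: dict[str, int]) -> OTU:
    otu = OTU(otu_id, otu_id, "")
    otu.species_counts = dict(counts)
    otu.abundance = sum(counts.values())
    return otu


class TestAssessOtus:
    def test_complete_single_species_is_correct(self):
        otus = [make_otu("o1", {"sp1": 10})]
        (a,) = assess_otus(otus, {"sp1": 10})
        assert a.label == "correct" and a.mistake_contribution == 0

    def test_split_species_gives_two_partials(self):
        otus = [make_otu("o1", {"sp1": 6}), make_otu("o2", {"sp1": 4})]
        labels = [a.label for a in assess_otus(otus, {"sp1": 10})]
        assert labels == ["partial", "partial"]

    def test_two_species_merge_is_mixed(self):
        otus = [make_otu("o1", {"sp1": 10, "sp2": 8})]
        (a,) = assess_otus(otus, {"sp1": 10, "sp2": 8})
        assert a.label == "mixed"
        assert a.species_present == {"sp1", "sp2"}
        assert a.mistake_contribution == 2

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError):
            assess_otus([make_otu("o1", {"spX": 1})], {"sp1": 1})


class TestCountMistakes:
    def test_all_correct_zero(self):
        a = [OTUAssessment("o1", "correct", frozenset({"s"}), 0)]
        assert count_mistakes(a) == 0

    def test_mixed_counts_per_species(self):
        a = [OTUAssessment("o1", "mixed", frozenset({"a", "b", "c"}), 3)]
        assert count_mistakes(a) == 3

    def test_two_partial_plus_two_species_mixed(self):
        a = [
            OTUAssessment("o1", "partial", frozenset({"a"}), 1),
            OTUAssessment("o2", "partial", frozenset({"b"}), 1),
            OTUAssessment("o3", "mixed", frozenset({"c", "d"}), 2),
        ]
        assert count_mistakes(a) == 4


class TestSelectBestThreshold:
    def cell(self, t, correct, mistakes):
        return SweepCell("m", t, correct, 0, 0, mistakes)

    def test_single_row(self):
        assert select_best_threshold([self.cell(97.0, 5, 1)]) == 97.0

    def test_prefers_more_correct(self):
        cells = [self.cell(96.0, 19, 0), self.cell(97.0, 17, 4)]
        assert select_best_threshold(cells) == 96.0

    def test_tie_takes_lowest_threshold(self):
        cells = [self.cell(99.0, 8, 2), self.cell(98.0, 8, 2)]
        assert select_best_threshold(cells) == 98.0


class TestAnova:
    def table_from_log_groups(self, groups: dict[str, list[float]]):
        rows = []
        for marker, logs in groups.items():
            for i, v in enumerate(logs):
                rows.append({"genus": "G", "species": f"sp{marker}{i}",
                             "marker": marker, "ra": int(round(math.exp(v))),
                             "sv": 1})
        return DetectionTable(pd.DataFrame(rows), depth=5000)

    def test_identical_groups_f_zero(self):
        # pre-log values e^1, e^2, e^3 in both groups
        table = self.table_from_log_groups({"m1": [1, 2, 3], "m2": [1, 2, 3]})
        f, p = anova_log_counts(table, "G")
        assert f == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_closed_form_f_statistic(self):
        """Groups with logs {1,2,3} and {2,3,4}: SSB=1.5, SSW=4 -> F=1.5."""
        table = self.table_from_log_groups({"m1": [1, 2, 3], "m2": [2, 3, 4]})
        f, p = anova_log_counts(table, "G")
        # counts are rounded to integers, so logs are approximate
        assert f == pytest.approx(1.5, rel=0.05)
        from scipy import stats
        assert p == pytest.approx(stats.f.sf(f, 1, 4), rel=1e-9)

    def test_single_marker_rejected(self):
        table = self.table_from_log_groups({"m1": [1, 2, 3]})
        with pytest.raises(ValueError):
            anova_log_counts(table, "G")


def cells_with_rates(rates: dict[str, float], n_cells: int = 10):
    """Synthesise sweep cells so each species is non-correct in the wanted
    fraction of cells."""
    cells = []
    for i in range(n_cells):
        assessments = []
        for sp, rate in rates.items():
            bad = i < round(rate * n_cells)
            assessments.append(OTUAssessment(
                f"o{sp}{i}", "partial" if bad else "correct",
                frozenset({sp}), 1 if bad else 0,
            ))
        cells.append(SweepCell("m", 95.0 + 0.5 * i, 0, 0, 0, 0, assessments))
    return cells


class TestSpearman:
    def table_for(self, ra: dict[str, int], sv: dict[str, int]):
        rows = [
            {"genus": "G", "species": sp, "marker": "m", "ra": ra[sp],
             "sv": sv[sp]}
            for sp in ra
        ]
        return DetectionTable(pd.DataFrame(rows), depth=5000)

    def test_mistake_rates_counted_per_cell(self):
        cells = cells_with_rates({"a": 0.3, "b": 1.0, "c": 0.0})
        rates = species_mistake_rates(cells)
        assert rates == {"a": 0.3, "b": 1.0, "c": 0.0}

    def test_perfect_monotone_gives_rho_one(self):
        rates = {"a": 0.1, "b": 0.5, "c": 0.9}
        cells = cells_with_rates(rates)
        table = self.table_for(
            ra={"a": 10, "b": 100, "c": 1000}, sv={"a": 1, "b": 2, "c": 3}
        )
        result = spearman_mistake_correlations(table, cells)
        assert result["abundance"][0] == pytest.approx(1.0)
        assert result["sv"][0] == pytest.approx(1.0)

    def test_reversed_gives_rho_minus_one(self):
        cells = cells_with_rates({"a": 0.9, "b": 0.5, "c": 0.1})
        table = self.table_for(
            ra={"a": 10, "b": 100, "c": 1000}, sv={"a": 1, "b": 2, "c": 3}
        )
        result = spearman_mistake_correlations(table, cells)
        assert result["abundance"][0] == pytest.approx(-1.0)

    def test_tied_ranks_match_manual_formula(self):
        """Six points with one tie in x, against the average-rank formula."""
        ra = {"a": 10, "b": 20, "c": 20, "d": 40, "e": 50, "f": 60}
        rates = {"a": 0.0, "b": 0.2, "c": 0.4, "d": 0.3, "e": 0.8, "f": 0.9}
        cells = cells_with_rates(rates)
        table = self.table_for(ra=ra, sv={k: 1 for k in ra})
        rho = spearman_mistake_correlations(table, cells)["abundance"][0]

        def avg_ranks(vals):
            order = sorted(range(len(vals)), key=lambda i: vals[i])
            ranks = [0.0] * len(vals)
            i = 0
            while i < len(order):
                j = i
                while j + 1 < len(order) and vals[order[j + 1]] == vals[order[i]]:
                    j += 1
                for k in range(i, j + 1):
                    ranks[order[k]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        species = sorted(ra)
        rx = avg_ranks([ra[s] for s in species])
        ry = avg_ranks([rates[s] for s in species])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, rel=1e-9)

    def test_rho_invariant_under_monotone_transform(self):
        rates = {"a": 0.1, "b": 0.2, "c": 0.6, "d": 0.7}
        cells = cells_with_rates(rates)
        t1 = self.table_for(ra={"a": 2, "b": 8, "c": 4, "d": 16},
                            sv={k: 1 for k in rates})
        t2 = self.table_for(ra={"a": 4, "b": 64, "c": 16, "d": 256},  # squared
                            sv={k: 1 for k in rates})
        r1 = spearman_mistake_correlations(t1, cells)["abundance"][0]
        r2 = spearman_mistake_correlations(t2, cells)["abundance"][0]
        assert r1 == pytest.approx(r2)

    def test_fewer_than_three_species_rejected(self):
        cells = cells_with_rates({"a": 0.1, "b": 0.2})
        table = self.table_for(ra={"a": 1, "b": 2}, sv={"a": 1, "b": 1})
        with pytest.raises(ValueError):
            spearman_mistake_correlations(table, cells)
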