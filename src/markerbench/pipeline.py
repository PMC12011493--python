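"""End-to-end orchestration of the benchmark over a working directory.

Stages communicate through plain-text files (FASTA/FASTQ/TSV/JSON) so each
stage is independently runnable and swappable for real sequencing data:
simulate -> filter -> chimera -> assign -> cluster -> evaluate. Every stage
logs read counts in and out, and the discard ledger stays conserved across
the whole cascade.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import commsim, readproc
from .chimeradet import ChimeraParams, compare_detection, detect_denovo, detect_reference
from .commsim import QualityModel, SimulationConfig
from .otucluster import DEFAULT_GRID, ClusterRead, threshold_sweep
from .refdata import (
    DEFAULT_MARKERS,
    Marker,
    collapse_units,
    load_packaged_detection_table,
    read_reference_fasta,
    build_center_star_msa,
    summarize_detection_table,
    write_reference_fasta,
)
from .taxassign import assign_library, build_detection_table

logger = logging.getLogger(__name__)


class QualityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    q_start: float = 38.0
    q_slope: float = 0.05
    q_noise_sd: float = 2.0
    r2_penalty: float = 3.0
    inject_errors: bool = True


class ChimeraConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_parent_ratio: float = 16.0
    min_diffs_per_side: int = 3
    max_model_diffs_denovo: int = 0
    max_model_diffs_ref: int = 1


class SimulationOverrides(BaseModel):
    model_config = ConfigDict(extra="forbid")
    divergence: dict[str, float] | None = None
    intragenomic_variant_rate: dict[str, float] | None = None
    copy_number_range: dict[str, tuple[int, int]] | None = None
    chimera_rate: dict[str, float] | None = None
    nontarget_fraction: dict[str, float] | None = None
    species_weight: dict[str, float] = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Schema-validated run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    communities: list[tuple[str, int]] = Field(
        default_factory=lambda: [("Dermoloma", 19), ("Hodophilus", 11), ("Russula", 11)]
    )
    markers: list[str] = Field(
        default_factory=lambda: ["ITS1", "ITS2", "rpb2", "ef1a"]
    )
    read_len: int = 250
    depth_per_marker: int = 5000
    depth: int = 5000
    min_frac: float = 0.0001
    grid: list[float] = Field(default_factory=lambda: list(DEFAULT_GRID))
    quality: QualityConfig = Field(default_factory=QualityConfig)
    chimera: ChimeraConfig = Field(default_factory=ChimeraConfig)
    anchors: dict[str, tuple[str, str]] = Field(default_factory=dict)
    primer_trim: bool = True
    simulation: SimulationOverrides = Field(default_factory=SimulationOverrides)

    def marker_objects(self) -> list[Marker]:
        return [DEFAULT_MARKERS[name] for name in self.markers]

    def simulation_config(self) -> SimulationConfig:
        sim = SimulationConfig(
            seed=self.seed,
            communities=[tuple(c) for c in self.communities],
            markers=self.marker_objects(),
            read_len=self.read_len,
            depth_per_marker=self.depth_per_marker,
            quality=QualityModel(**self.quality.model_dump()),
        )
        for name in ("divergence", "intragenomic_variant_rate",
                     "copy_number_range", "chimera_rate", "nontarget_fraction"):
            override = getattr(self.simulation, name)
            if override:
                getattr(sim, name).update(override)
        sim.species_weight = dict(self.simulation.species_weight)
        return sim

    def chimera_params(self) -> ChimeraParams:
        return ChimeraParams(**self.chimera.model_dump())


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return RunConfig.model_validate(json.load(fh))


class Pipeline:
    """File-based pipeline over a working directory."""

    def __init__(self, config: RunConfig, workdir: str | Path) -> None:
        self.config = config
        self.workdir = Path(workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)
        self._log_path = self.workdir / "pipeline_log.jsonl"

    # ------------------------------------------------------------------ utils
    def _log(self, stage: str, **fields) -> None:
        entry = {"stage": stage, **fields}
        logger.info("%s: %s", stage, fields)
        with open(self._log_path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(entry) + "\n")

    def _libraries(self) -> list[tuple[str, Marker]]:
        return [
            (genus, marker)
            for genus, _n in self.config.communities
            for marker in self.config.marker_objects()
        ]

    def _refs_path(self, genus: str, marker: str) -> Path:
        return self.workdir / f"refs_{genus}_{marker}.fasta"

    def _load_refset(self, genus: str, marker: Marker):
        records = read_reference_fasta(self._refs_path(genus, marker.name), marker)
        return build_center_star_msa(records)

    # ----------------------------------------------------------------- stages
    def simulate(self) -> None:
        """Generate references, amplicon pools and paired reads."""
        sim = self.config.simulation_config()
        refsets = commsim.simulate_references(sim)
        for gi, (genus, _n) in enumerate(self.config.communities):
            for marker in self.config.marker_objects():
                refset = refsets[(genus, marker.name)]
                write_reference_fasta(self._refs_path(genus, marker.name),
                                      refset.records)
                pool = commsim.simulate_amplicon_pool(refset, sim, genus, gi)
                lib = commsim.simulate_read_pairs(
                    pool, sim.quality, sim, marker, genus, self.workdir, gi
                )
                self._log("simulate", genus=genus, marker=marker.name,
                          templates=len(pool), reads=sim.depth_per_marker,
                          r1=str(lib.r1_path))

    def filter(self) -> None:
        """Merge, trim and quality-filter every library; write ledgers."""
        rows = []
        for genus, marker in self._libraries():
            prefix = f"{genus}_{marker.name}"
            r1 = self.workdir / f"{prefix}_R1.fastq"
            r2 = self.workdir / f"{prefix}_R2.fastq"
            if not r1.exists() or not r2.exists():
                raise FileNotFoundError(f"missing FASTQ for {prefix}")
            params = readproc.FilterParams(
                primers=commsim.PRIMERS[marker.name] if self.config.primer_trim else None,
                anchors=self.config.anchors.get(marker.name),
            )
            kept, ledger = readproc.filter_cascade(
                readproc.read_fastq_pairs(r1, r2), marker, params
            )
            derep = readproc.dereplicate(kept)
            self._write_derep(prefix, derep)
            rows.append({"genus": genus, "marker": marker.name, **ledger.as_dict()})
            self._log("filter", genus=genus, marker=marker.name,
                      input=ledger.total, kept=ledger.kept,
                      discards=ledger.as_dict())
        pd.DataFrame(rows).to_csv(self.workdir / "ledger.tsv", sep="\t", index=False)

    def _write_derep(self, prefix: str, derep) -> None:
        readproc.write_derep_fasta(self.workdir / f"{prefix}_derep.fasta", derep)
        with open(self.workdir / f"{prefix}_derep.tsv", "w", encoding="utf-8") as fh:
            fh.write("uniq_id\tsize\tsequence\tread_ids\n")
            for i, (seq, size, ids) in enumerate(derep, 1):
                fh.write(f"uniq{i:05d}\t{size}\t{seq}\t{','.join(ids)}\n")

    def _read_derep(self, prefix: str) -> list[tuple[str, int, list[str]]]:
        path = self.workdir / f"{prefix}_derep.tsv"
        out = []
        with open(path, encoding="utf-8") as fh:
            fh.readline()
            for line in fh:
                _uid, size, seq, ids = line.rstrip("\n").split("\t")
                out.append((seq, int(size), ids.split(",")))
        return out

    def chimera(self) -> None:
        """De novo and reference chimera removal; updates the ledger."""
        ledger_path = self.workdir / "ledger.tsv"
        ledger = pd.read_csv(ledger_path, sep="\t")
        report_rows = []
        rates = {}
        for genus, marker in self._libraries():
            prefix = f"{genus}_{marker.name}"
            derep = self._read_derep(prefix)
            reads = [(f"uniq{i + 1:05d}", seq, size)
                     for i, (seq, size, _ids) in enumerate(derep)]
            params = self.config.chimera_params()
            refset = self._load_refset(genus, marker)
            denovo, models_d = detect_denovo(reads, params)
            reference, models_r = detect_reference(reads, refset, params)
            flagged = denovo | reference
            rates[prefix] = compare_detection(denovo, reference)
            for model, mode in [(m, "denovo") for m in models_d] + [
                (m, "reference") for m in models_r
            ]:
                report_rows.append({
                    "genus": genus, "marker": marker.name, "query": model.query_id,
                    "parent_a": model.parent_a, "parent_b": model.parent_b,
                    "crossover": model.crossover, "diffs_model": model.diffs_model,
                    "diffs_best_single": model.diffs_best_single, "mode": mode,
                })
            n_removed = sum(
                size for (seq, size, _ids), (uid, _s, _a) in zip(derep, reads)
                if uid in flagged
            )
            kept = [d for d, (uid, _s, _a) in zip(derep, reads) if uid not in flagged]
            self._write_derep(prefix, kept)
            mask = (ledger.genus == genus) & (ledger.marker == marker.name)
            ledger.loc[mask, "chimeric"] += n_removed
            ledger.loc[mask, "kept"] -= n_removed
            self._log("chimera", genus=genus, marker=marker.name,
                      denovo=len(denovo), reference=len(reference),
                      reads_removed=n_removed,
                      denovo_vs_reference_pct=rates[prefix])
        ledger.to_csv(ledger_path, sep="\t", index=False)
        pd.DataFrame(report_rows).to_csv(self.workdir / "chimera_report.tsv",
                                         sep="\t", index=False)
        with open(self.workdir / "chimera_rates.json", "w", encoding="utf-8") as fh:
            json.dump(rates, fh, indent=2)

    def assign(self) -> None:
        """Annotate reads, classify variants, build the detection table."""
        ledger_path = self.workdir / "ledger.tsv"
        ledger = pd.read_csv(ledger_path, sep="\t")
        all_assignments = []
        rows = []
        for genus, marker in self._libraries():
            prefix = f"{genus}_{marker.name}"
            derep = self._read_derep(prefix)
            refset = self._load_refset(genus, marker)
            units = collapse_units(refset)
            assignments = assign_library(derep, refset, units, genus)
            n_nontarget = sum(1 for a in assignments if a.unit_id is None)
            mask = (ledger.genus == genus) & (ledger.marker == marker.name)
            ledger.loc[mask, "nontarget"] += n_nontarget
            ledger.loc[mask, "kept"] -= n_nontarget
            kept_assignments = [a for a in assignments if a.unit_id is not None]
            all_assignments.extend(kept_assignments)
            for a in assignments:
                rows.append({
                    "read_id": a.read_id, "genus": genus, "marker": marker.name,
                    "unit": a.unit_id or "nontarget", "species": a.species_id or "",
                    "variant": "" if a.variant_id is None else a.variant_id,
                    "noise": int(a.noise), "identity": round(a.identity, 3),
                })
            self._log("assign", genus=genus, marker=marker.name,
                      assigned=len(kept_assignments), nontarget=n_nontarget)
        ledger.to_csv(ledger_path, sep="\t", index=False)
        pd.DataFrame(rows).to_csv(self.workdir / "assignments.tsv", sep="\t",
                                  index=False)
        table = build_detection_table(
            all_assignments, depth=self.config.depth,
            min_frac=self.config.min_frac, seed=self.config.seed,
            allow_fewer=True,
        )
        table.frame.to_csv(self.workdir / "detection_table.tsv", sep="\t",
                           index=False)

    def cluster(self) -> None:
        """Threshold sweep of greedy centroid clustering per library."""
        assignments = pd.read_csv(self.workdir / "assignments.tsv", sep="\t",
                                  keep_default_na=False)
        rows = []
        for genus, _n in self.config.communities:
            reads_by_marker = {}
            for marker in self.config.marker_objects():
                prefix = f"{genus}_{marker.name}"
                derep = self._read_derep(prefix)
                sub = assignments[(assignments.genus == genus)
                                  & (assignments.marker == marker.name)]
                label_of = {}
                for rec in sub.itertuples(index=False):
                    label = rec.species or rec.unit
                    if label != "nontarget":
                        label_of[rec.read_id] = (
                            label, None if rec.variant == "" else int(rec.variant)
                        )
                cluster_reads = []
                for i, (seq, _size, ids) in enumerate(derep):
                    members: dict = {}
                    for rid in ids:
                        if rid not in label_of:
                            continue
                        members[label_of[rid]] = members.get(label_of[rid], 0) + 1
                    if not members:
                        continue  # nontarget unique, discarded upstream
                    cluster_reads.append(ClusterRead(
                        f"uniq{i + 1:05d}", seq, sum(members.values()), members
                    ))
                if cluster_reads:
                    reads_by_marker[marker.name] = cluster_reads
            if not reads_by_marker:
                continue
            sweep = threshold_sweep(reads_by_marker, tuple(self.config.grid))
            for (marker, threshold), otus in sorted(sweep.partitions.items()):
                for otu in otus:
                    rows.append({
                        "genus": genus, "marker": marker, "threshold": threshold,
                        "otu_id": otu.otu_id, "centroid_id": otu.centroid_id,
                        "abundance": otu.abundance,
                        "species_counts": json.dumps(
                            {str(k): v for k, v in sorted(otu.species_counts.items())}
                        ),
                        "reads": ",".join(otu.reads),
                    })
            self._log("cluster", genus=genus,
                      markers=sorted(reads_by_marker),
                      cells=len(sweep.partitions))
        pd.DataFrame(rows).to_csv(self.workdir / "otu_sweep.tsv", sep="\t",
                                  index=False)

    def evaluate(self) -> dict:
        """Score every sweep cell and write the evaluation report."""
        from .markereval import SweepCell, assess_otus, count_mistakes, \
            select_best_threshold, spearman_mistake_correlations, anova_log_counts
        from .otucluster import OTU
        from .refdata import DetectionTable

        sweep_frame = pd.read_csv(self.workdir / "otu_sweep.tsv", sep="\t")
        table = DetectionTable(
            pd.read_csv(self.workdir / "detection_table.tsv", sep="\t"),
            depth=self.config.depth,
        )
        report_rows = []
        summary: dict = {"best_threshold": {}, "statistics": {}}
        for genus, _n in self.config.communities:
            gsub = sweep_frame[sweep_frame.genus == genus]
            if gsub.empty:
                continue
            cells = []
            for (marker, threshold), cell_rows in gsub.groupby(["marker", "threshold"]):
                otus = []
                truth: dict[str, int] = {}
                for rec in cell_rows.itertuples(index=False):
                    otu = OTU(rec.otu_id, rec.centroid_id, "",
                              rec.abundance)
                    otu.species_counts = {
                        k: v for k, v in json.loads(rec.species_counts).items()
                    }
                    otus.append(otu)
                    for sp, n in otu.species_counts.items():
                        truth[sp] = truth.get(sp, 0) + n
                assessments = assess_otus(otus, truth)
                labels = [a.label for a in assessments]
                cells.append(SweepCell(
                    marker, float(threshold), labels.count("correct"),
                    labels.count("partial"), labels.count("mixed"),
                    count_mistakes(assessments), assessments,
                ))
            for marker in sorted({c.marker for c in cells}):
                mcells = [c for c in cells if c.marker == marker]
                summary["best_threshold"][f"{genus}/{marker}"] = \
                    select_best_threshold(mcells)
            for c in cells:
                report_rows.append({
                    "genus": genus, "marker": c.marker, "threshold": c.threshold,
                    "n_correct": c.n_correct, "n_partial": c.n_partial,
                    "n_mixed": c.n_mixed, "mistakes": c.mistakes,
                })
            stats_entry: dict = {}
            try:
                f, p = anova_log_counts(table, genus)
                stats_entry["anova"] = {"F": f, "p": p}
            except ValueError as exc:
                stats_entry["anova"] = {"error": str(exc)}
            try:
                stats_entry["spearman"] = {
                    k: {"rho": v[0], "p": v[1]}
                    for k, v in spearman_mistake_correlations(
                        table, cells, genus
                    ).items()
                }
            except ValueError as exc:
                stats_entry["spearman"] = {"error": str(exc)}
            summary["statistics"][genus] = stats_entry
            self._log("evaluate", genus=genus,
                      best=summary["best_threshold"])
        pd.DataFrame(report_rows).to_csv(self.workdir / "evaluation.tsv",
                                         sep="\t", index=False)
        with open(self.workdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2)
        return summary

    def run_all(self) -> dict:
        self.simulate()
        self.filter()
        self.chimera()
        self.assign()
        self.cluster()
        return self.evaluate()


def fixture_check() -> dict:
    """Summarise the packaged species-representation table."""
    table = load_packaged_detection_table()
    return summarize_detection_table(table)
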