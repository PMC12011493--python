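"""Synthetic mock communities: references, PCR pools, and MiSeq-style reads.

The generator emulates the benchmark's study design: three genus-level
communities of closely related species (19/11/11 by default) pooled at equal
genomic DNA proportions, amplified for two multicopy spacers and two low-copy
protein-coding markers, and sequenced as 2x250 bp paired reads with 3' quality
decay. Species are derived from a per-genus ancestor on a star phylogeny, so
the expected pairwise divergence has a closed form: two species mutated
independently at per-site rate d differ at a site with probability
1 - (1-d)^2 - d^2/3.

Intragenomic sequence variants are encoded as IUPAC ambiguity codes in the
references; the amplicon pool realises each copy's haplotype by sampling an
expansion base, so the reads carry concrete variant bases while the reference
keeps the code — the evidence structure the assignment stage exploits. PCR
chimeras join two parents at a single crossover, with parent pairs weighted by
abundance and sequence identity (chimera formation is more likely between
related templates). Nontarget contamination is random sequence at the
marker's length profile, calibrated heavy for the low-copy markers (~44% of
reads) and negligible for the spacers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .align import align_pair, identity_from_rows
from .iupac import CODE_FOR, EXPANSION, GAP, revcomp
from .refdata import (
    DEFAULT_MARKERS,
    LOW_COPY,
    MULTICOPY,
    Marker,
    ReferenceRecord,
    ReferenceSet,
    build_center_star_msa,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: Fixed synthetic primer pairs per marker (forward, reverse), and the fixed
#: primer+spacer context used to pad fragments shorter than the read length.
PRIMERS: dict[str, tuple[str, str]] = {
    "ITS1": ("TCCGTAGGTGAACCTGCGG", "GCTGCGTTCTTCATCGATGC"),
    "ITS2": ("GCATCGATGAAGAACGCAGC", "TCCTCCGCTTATTGATATGC"),
    "rpb2": ("ATGGGYAAYGARATGGCYAC", "CCCATRGCTTGYTTRCCCAT"),
    "ef1a": ("GGTCACTTGATCTACAAGTGC", "CCRATCTTGTAGACRTCCTG"),
}
PAD_CONTEXT = "CTGTCTCTTATACACATCTCCGAGCCCACGAGACTAAGGCGAATCTCGTATGCCGTCTTC"


@dataclass(frozen=True)
class QualityModel:
    """Linear 3'-decay Phred model with Gaussian jitter.

    ``q_start`` is the 5' quality, ``q_slope`` the per-base decline,
    ``r2_penalty`` an extra drop for the reverse read; emitted scores are
    clamped to [2, 41]. With ``inject_errors`` base calls are flipped at the
    probability 10^(-Q/10) implied by the emitted score.
    """

    q_start: float = 38.0
    q_slope: float = 0.05
    q_noise_sd: float = 2.0
    r2_penalty: float = 3.0
    inject_errors: bool = True


NOISE_FREE = QualityModel(
    q_start=41.0, q_slope=0.0, q_noise_sd=0.0, r2_penalty=0.0, inject_errors=False
)


@dataclass(frozen=True)
class TruthLabel:
    """Ground truth for a template or read: target, chimera, or nontarget."""

    kind: str
    species_id: str | None = None
    variant_id: int | None = None
    parents: tuple[str, str] | None = None
    crossover: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "chimera" and (self.parents is None or self.crossover is None):
            raise ValueError("chimera label requires parents and crossover")
        if self.kind == "target" and self.species_id is None:
            raise ValueError("target label requires species_id")


@dataclass(frozen=True)
class Template:
    """One distinct amplicon sequence in the PCR pool with its copy abundance."""

    sequence: str
    abundance: int
    truth: TruthLabel

    def __post_init__(self) -> None:
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror the mock-community design: communities of 19/11/11
    species; interspecific divergence a few percent for the spacers and
    around one percent for the coding markers; roughly a third of species
    carrying intragenomic variants (1-4 polymorphic positions in multicopy,
    1-2 in low-copy markers); ribosomal copy numbers spanning 14 to 1000
    against 1-3 for low-copy genes; chimera rates of a few percent for the
    spacers; and nontarget contamination dominating only the low-copy
    libraries (~44% of reads, versus <0.05% for ITS).
    """

    seed: int = 0
    communities: list[tuple[str, int]] = field(
        default_factory=lambda: [("Dermoloma", 19), ("Hodophilus", 11), ("Russula", 11)]
    )
    markers: list[Marker] = field(
        default_factory=lambda: list(DEFAULT_MARKERS.values())
    )
    divergence: dict[str, float] = field(
        default_factory=lambda: {"ITS1": 0.04, "ITS2": 0.05, "rpb2": 0.010, "ef1a": 0.015}
    )
    intragenomic_variant_rate: dict[str, float] = field(
        default_factory=lambda: {MULTICOPY: 0.36, LOW_COPY: 0.25}
    )
    copy_number_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {MULTICOPY: (14, 1000), LOW_COPY: (1, 3)}
    )
    chimera_rate: dict[str, float] = field(
        default_factory=lambda: {MULTICOPY: 0.03, LOW_COPY: 0.006}
    )
    nontarget_fraction: dict[str, float] = field(
        default_factory=lambda: {MULTICOPY: 0.0005, LOW_COPY: 0.44}
    )
    read_len: int = 250
    depth_per_marker: int = 5000
    quality: QualityModel = field(default_factory=QualityModel)
    #: optional per-species abundance multiplier (DNA degradation hook)
    species_weight: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, n in self.communities:
            if n < 2:
                raise ValueError(f"community {name} needs >= 2 species")
        for cls, (lo, hi) in self.copy_number_range.items():
            if lo > hi or lo < 1:
                raise ValueError(f"bad copy_number_range for {cls}")
        for d in (self.chimera_rate, self.nontarget_fraction):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("rates must be in [0, 1]")


def _rng(config: SimulationConfig, *tags: int) -> np.random.Generator:
    """Independent deterministic stream per (seed, structural position)."""
    return np.random.default_rng([int(config.seed) % (2**31), *tags])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def expected_pairwise_divergence(rate: float) -> float:
    """Expected per-site difference between two star-phylogeny tips."""
    return 1.0 - (1.0 - rate) ** 2 - rate**2 / 3.0


def simulate_references(
    config: SimulationConfig,
) -> dict[tuple[str, str], ReferenceSet]:
    """Per (genus, marker) reference sets derived from random ancestors.

    Species substitute independently from the ancestor at the marker's
    divergence rate; a subset of species carries IUPAC-encoded intragenomic
    variant positions. Identical seed gives identical output.
    """
    out: dict[tuple[str, str], ReferenceSet] = {}
    for gi, (genus, n_species) in enumerate(config.communities):
        for mi, marker in enumerate(config.markers):
            rng = _rng(config, 1, gi, mi)
            length = max(60, int(round(rng.normal(marker.amplicon_len_mean,
                                                  marker.amplicon_len_sd))))
            ancestor = _random_seq(rng, length)
            rate = config.divergence[marker.name]
            var_rate = config.intragenomic_variant_rate[marker.copy_class]
            max_var = 4 if marker.copy_class == MULTICOPY else 2
            records = []
            for si in range(n_species):
                seq = _mutate(rng, ancestor, rate)
                if rng.random() < var_rate:
                    n_var = int(rng.integers(1, max_var + 1))
                    positions = rng.choice(length, size=min(n_var, length), replace=False)
                    chars = list(seq)
                    for p in positions:
                        current = chars[p]
                        other = [b for b in "ACGT" if b != current][rng.integers(3)]
                        chars[p] = CODE_FOR[frozenset({current, other})]
                    seq = "".join(chars)
                records.append(
                    ReferenceRecord.from_sequence(
                        f"{genus}_sp{si + 1:02d}", marker.name, seq
                    )
                )
            seqs = [r.sequence for r in records]
            if len(set(seqs)) < len(seqs):
                logger.warning(
                    "identical references in %s/%s: species will be lumped",
                    genus, marker.name,
                )
            out[(genus, marker.name)] = build_center_star_msa(records)
    return out


def _haplotypes(rng: np.random.Generator, record: ReferenceRecord,
                copies: int) -> dict[str, int]:
    """Realise each copy's haplotype by resolving ambiguity codes.

    Variant positions are linked: a species carries two discrete haplotypes
    (one expansion base per code versus the other), and each copy samples one
    of the two at a species-level mixture weight. Linked resolution keeps the
    realised variant count per species at the low values seen in real
    amplicon data instead of free-recombining 2^k haplotypes.
    """
    positions = sorted(record.ambiguous_positions)
    if not positions:
        return {record.sequence: copies}
    low = list(record.sequence)
    high = list(record.sequence)
    for p in positions:
        bases = sorted(EXPANSION[record.sequence[p]])
        low[p] = bases[0]
        high[p] = bases[-1]
    weight = rng.uniform(0.2, 0.8)
    n_low = int(rng.binomial(copies, weight))
    out: dict[str, int] = {}
    if n_low:
        out["".join(low)] = n_low
    if copies - n_low:
        out["".join(high)] = copies - n_low
    return out


def simulate_amplicon_pool(
    refs: ReferenceSet, config: SimulationConfig, genus: str = "", genus_index: int = 0
) -> list[Template]:
    """PCR pool for one (genus, marker) library.

    Template abundance is the species' drawn copy number (equal DNA input x
    copies per genome); chimeric copies replace target copies at the
    configured rate with identity-weighted parent choice; nontarget templates
    top the pool up to the configured contamination fraction.
    """
    if not refs.records:
        raise ValueError("empty reference set")
    marker = refs.marker
    mi = [m.name for m in config.markers].index(marker.name) if marker.name in [
        m.name for m in config.markers
    ] else 0
    rng = _rng(config, 2, genus_index, mi)

    lo, hi = config.copy_number_range[marker.copy_class]
    templates: list[Template] = []
    species_abundance: dict[str, int] = {}
    species_canonical: dict[str, str] = {}
    for rec in refs.records:
        copies = int(rng.integers(lo, hi + 1))
        weight = config.species_weight.get(rec.species_id, 1.0)
        copies = max(1, int(round(copies * weight)))
        species_abundance[rec.species_id] = copies
        haps = _haplotypes(rng, rec, copies)
        ranked = sorted(haps.items(), key=lambda kv: (-kv[1], kv[0]))
        species_canonical[rec.species_id] = ranked[0][0]
        for vid, (seq, n) in enumerate(ranked):
            templates.append(
                Template(seq, n, TruthLabel("target", species_id=rec.species_id,
                                            variant_id=vid))
            )

    total = sum(t.abundance for t in templates)
    chim_rate = config.chimera_rate[marker.copy_class]
    n_chimeric = int(rng.binomial(total, chim_rate)) if chim_rate > 0 else 0
    if n_chimeric:
        ids = refs.species_ids
        sim = np.ones((len(ids), len(ids)))
        for i in range(len(ids)):
            for j in range(len(ids)):
                if i != j:
                    sim[i, j] = identity_from_rows(refs.msa[i], refs.msa[j]) / 100.0
        ab = np.array([species_abundance[s] for s in ids], dtype=float)
        pair_w = np.outer(ab, ab) * sim
        np.fill_diagonal(pair_w, 0.0)
        flat = pair_w.ravel() / pair_w.sum()
        # deplete target copies that became chimeric
        removal = rng.multinomial(n_chimeric, np.array(
            [t.abundance for t in templates], dtype=float) / total)
        kept: list[Template] = []
        for t, r in zip(templates, removal):
            remaining = t.abundance - int(r)
            if remaining >= 1:
                kept.append(replace(t, abundance=remaining))
        templates = kept
        pair_counts: dict[tuple[int, int], int] = {}
        draws = rng.choice(len(flat), size=n_chimeric, p=flat)
        for d in draws:
            key = (int(d) // len(ids), int(d) % len(ids))
            pair_counts[key] = pair_counts.get(key, 0) + 1
        aln_cache: dict[tuple[int, int], tuple[str, str]] = {}
        chim_counts: dict[tuple[str, tuple[str, str], int], int] = {}
        for (i, j), n in pair_counts.items():
            if (i, j) not in aln_cache:
                aln_cache[(i, j)] = align_pair(
                    species_canonical[ids[i]], species_canonical[ids[j]]
                )
            row_a, row_b = aln_cache[(i, j)]
            n_cols = len(row_a)
            for _ in range(n):
                k = int(rng.integers(1, n_cols - 1))
                seq = (row_a[:k] + row_b[k:]).replace(GAP, "")
                key = (seq, (ids[i], ids[j]), k)
                chim_counts[key] = chim_counts.get(key, 0) + 1
        for (seq, parents, k), n in sorted(chim_counts.items()):
            templates.append(
                Template(seq, n, TruthLabel("chimera", parents=parents, crossover=k))
            )

    nt_frac = config.nontarget_fraction[marker.copy_class]
    if nt_frac > 0:
        total = sum(t.abundance for t in templates)
        n_nontarget = int(round(nt_frac / (1.0 - nt_frac) * total))
        for _ in range(n_nontarget):
            length = max(60, int(round(rng.normal(marker.amplicon_len_mean,
                                                  marker.amplicon_len_sd))))
            templates.append(
                Template(_random_seq(rng, length), 1, TruthLabel("nontarget"))
            )
    return templates


def build_fragment(template: str, marker_name: str, read_len: int) -> str:
    """Sequenced fragment: primers flank the insert; short fragments are
    padded 3' with a fixed primer+spacer context so reads are uniform."""
    fwd, rev = PRIMERS[marker_name]
    frag = fwd + template + revcomp(rev)
    if len(frag) < read_len:
        pad = (PAD_CONTEXT * (read_len // len(PAD_CONTEXT) + 1))[: read_len - len(frag)]
        frag += pad
    return frag


def _phred_profile(rng: np.random.Generator, qm: QualityModel, n: int,
                   penalty: float) -> np.ndarray:
    pos = np.arange(n)
    q = qm.q_start - qm.q_slope * pos - penalty
    if qm.q_noise_sd > 0:
        q = q + rng.normal(0.0, qm.q_noise_sd, size=n)
    return np.clip(np.round(q), 2, 41).astype(int)


def _call_bases(rng: np.random.Generator, seq: str, quals: np.ndarray,
                inject: bool) -> str:
    if not inject:
        return seq
    p_err = 10.0 ** (-quals / 10.0)
    hits = np.nonzero(rng.random(len(seq)) < p_err)[0]
    if not len(hits):
        return seq
    arr = list(seq)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


@dataclass
class SimulatedLibrary:
    """File outputs of one simulated library plus its truth map."""

    r1_path: Path
    r2_path: Path
    truth_path: Path
    truth: dict[str, TruthLabel]


def simulate_read_pairs(
    pool: list[Template],
    qm: QualityModel,
    config: SimulationConfig,
    marker: Marker,
    genus: str,
    out_dir: str | Path,
    genus_index: int = 0,
) -> SimulatedLibrary:
    """Sample paired 2 x read_len reads from the pool, abundance-weighted.

    R1 reads the fragment 5'->3', R2 is the reverse complement of its last
    ``read_len`` bases; per-base Phred scores follow the quality model and
    base-call errors are injected at the implied probability. A truth sidecar
    maps every read id to its template's label.
    """
    if not pool:
        raise ValueError("empty template pool")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mi = [m.name for m in config.markers].index(marker.name) if marker.name in [
        m.name for m in config.markers
    ] else 0
    rng = _rng(config, 3, genus_index, mi)

    abundances = np.array([t.abundance for t in pool], dtype=float)
    draws = rng.multinomial(config.depth_per_marker, abundances / abundances.sum())

    prefix = f"{genus}_{marker.name}"
    r1_path = out_dir / f"{prefix}_R1.fastq"
    r2_path = out_dir / f"{prefix}_R2.fastq"
    truth_path = out_dir / f"{prefix}_truth.tsv"
    truth: dict[str, TruthLabel] = {}

    read_no = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2, \
            open(truth_path, "w") as ft:
        ft.write("read_id\tkind\tspecies_id\tvariant_id\tparents\tcrossover\n")
        for template, n_reads in zip(pool, draws):
            if n_reads == 0:
                continue
            frag = build_fragment(template.sequence, marker.name, config.read_len)
            for _ in range(int(n_reads)):
                read_no += 1
                read_id = f"{prefix}_read{read_no:06d}"
                r1_tmpl = frag[: config.read_len]
                r2_tmpl = revcomp(frag)[: config.read_len]
                q1 = _phred_profile(rng, qm, len(r1_tmpl), 0.0)
                q2 = _phred_profile(rng, qm, len(r2_tmpl), qm.r2_penalty)
                r1 = _call_bases(rng, r1_tmpl, q1, qm.inject_errors)
                r2 = _call_bases(rng, r2_tmpl, q2, qm.inject_errors)
                f1.write(f"@{read_id}\n{r1}\n+\n"
                         f"{''.join(chr(q + 33) for q in q1)}\n")
                f2.write(f"@{read_id}\n{r2}\n+\n"
                         f"{''.join(chr(q + 33) for q in q2)}\n")
                t = template.truth
                ft.write(
                    f"{read_id}\t{t.kind}\t{t.species_id or ''}\t"
                    f"{'' if t.variant_id is None else t.variant_id}\t"
                    f"{','.join(t.parents) if t.parents else ''}\t"
                    f"{'' if t.crossover is None else t.crossover}\n"
                )
                truth[read_id] = t
    return SimulatedLibrary(r1_path, r2_path, truth_path, truth)


def load_truth(path: str | Path) -> dict[str, TruthLabel]:
    """Read a truth sidecar TSV back into labels."""
    truth: dict[str, TruthLabel] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        assert header.startswith("read_id")
        for line in fh:
            rid, kind, sp, vid, parents, cross = line.rstrip("\n").split("\t")
            truth[rid] = TruthLabel(
                kind,
                species_id=sp or None,
                variant_id=int(vid) if vid else None,
                parents=tuple(parents.split(",")) if parents else None,
                crossover=int(cross) if cross else None,
            )
    return truth
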