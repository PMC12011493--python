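# Methods

## The benchmark in one paragraph

Mock communities — known species pooled at equal DNA proportions — are the
standard instrument for measuring what an amplicon pipeline does to species
composition. This package builds that instrument in software: it simulates
genus-level communities of closely related fungal species for four barcode
markers, pushes the reads through the same cascade a practitioner would run
(merge, trim, filter, remove chimeras, assign, cluster), and scores each
marker by how well OTU partitions across a similarity-threshold sweep recover
the known species. Because the generator carries ground-truth labels for
every read, detection rates, false-positive rates and clustering mistakes are
measurable exactly rather than estimated.

## Sequence model

**References.** Each community derives from a random ancestor per (genus,
marker) on a star phylogeny: every species substitutes independently at the
marker's divergence rate *d* per site, so two species differ per site with
probability 1 − (1−d)² − d²/3 — a closed form used as the generator's own
calibration oracle. Defaults: 4–5% for the spacers (ITS1/ITS2), 1–1.5% for
the coding markers (rpb2/ef1-α), reflecting the order-of-magnitude gap
between the marker classes. Amplicon lengths are Normal per marker: ITS1
220±40 bp (short, as in communities where ITS1 runs under 200 bp), ITS2
330±60 bp (long and length-variable; draws beyond ~435 bp exceed what 2×250
bp reads can merge at a 25 bp overlap, reproducing the known failure mode of
long spacers), rpb2 398±8 bp, ef1-α 380±12 bp.

**Intragenomic variants.** A species carries variants with probability 0.36
(multicopy) or 0.25 (low-copy); 1–4 positions (multicopy) or 1–2 (low-copy)
become two-base IUPAC codes in the reference. At the amplicon level the
positions are resolved as two *linked* haplotypes (all-first-base versus
all-second-base) mixed at a species-level weight drawn from U(0.2, 0.8).
Independent per-position resolution would free-recombine up to 2^k
haplotypes per species, inflating sequence-variant counts far beyond what
real per-species tables show (1–3 variants); linked resolution keeps the
realised count at 2. The reference keeps the code while reads carry concrete
bases — the evidence structure that lets assignment separate variants from
noise.

**Pools and reads.** Template abundance = copy number drawn uniformly per
copy class (14–1000 multicopy, 1–3 low-copy) times an optional per-species
weight (a hook for DNA-degradation scenarios; the study design attributes
most missing species to degraded DNA, but states no model for it, so the
default weight is 1). Chimeras replace a Binomial(total copies, rate) number
of copies; parent pairs are sampled ∝ abundance × pairwise identity (chimera
formation rises with template relatedness) with a uniform crossover over the
internal columns of the parents' pairwise alignment. Nontarget templates are
random sequence at the marker's length profile, topped up to 0.05% of
multicopy pools and 44% of low-copy pools — the contamination asymmetry
characteristic of low-copy primer systems. Reads are 2×250 bp; fragments
shorter than the read length are padded 3′ with a fixed primer+spacer
context that primer trimming later removes. Quality follows a linear 3′
decay (Q38 start, −0.05/base, SD 2, R2 −3) clamped to [2, 41], and base
calls are flipped at the 10^(−Q/10) probability implied by the emitted
score, so the empirical error rate is testable against the Phred scale.
Substitution errors only: no indel, index-hopping or PCR-cycle model.

## Filtering cascade

Stages run in fixed order: merge → primer trim → length floor → maxEE →
flank trim. Merging scans ungapped overlaps longest-first and accepts the
first with ≤ max_diffs mismatches (defaults: min overlap 25, max diffs 0,
staggered layouts rejected); overlap quality takes the higher Phred of the
two calls — with zero allowed mismatches there is no disagreement to
resolve. Expected errors EE = Σ 10^(−Q/10); reads above EE 1 are discarded
as low quality, reads shorter than the marker floor (50 bp spacers, 200 bp
coding) as short. Flank trimming is deterministic anchor-motif search (the
cascade position and ledger effect of an HMM extractor, without its
machinery); a missing anchor either keeps the read or routes it to the
nontarget category. The discard ledger (unmerged / short / low-quality /
chimeric / nontarget / kept) is conserved by construction and fuzz-tested;
chimera and nontarget counts are filled by the downstream stages against the
same ledger.

## Chimera model

A query is explained as A[<k] + B[≥k] for an ordered parent pair and a
single crossover k. All candidates are star-aligned onto the query's
columns; per-candidate diff prefix sums make the scan over all ordered pairs
and crossovers exact and fast. De novo mode processes reads in decreasing
abundance and only admits parents ≥ 16× the query's abundance (PCR chimeras
are rarer than their templates); reference mode admits every reference with
no abundance gate, which is what makes it more sensitive — the contrast the
benchmark measures via |denovo ∩ reference| / |reference|. A model counts as
chimeric when its residual diffs are ≤ 0 (de novo) or ≤ 1 (reference) and
each side of the crossover carries a vote margin ≥ 3: the parent *not*
contributing a side must disagree with the query by at least 3 more
positions than the contributing parent. (Comparing against the single best
parent on both sides would make even a perfect chimera unflaggable on the
side that parent contributes.) Ties between equal-diff models prefer the
larger worst-side margin, then lexicographic parents, then the smaller
crossover, so detection is order-invariant and deterministic. This is a
transparent crossover model, not a reimplementation of segment/vote
heuristics of any particular tool.

## Identity, assignment, variants

All identity questions use one aligner: global alignment with free end gaps,
+1 for IUPAC-compatible pairs (nonempty expansion-set intersection; gap
compatible only with gap), −1 otherwise, −2 per gap column. Identity is
matching columns over non-terminal-gap columns, with two numerical guards:

- **terminal-gap epsilon**: end gaps cost −10⁻⁴ per column rather than 0, so
  among co-optimal alignments the one with fewer end gaps wins (an unslid
  alignment of homologous sequences); the epsilon cannot flip a decision
  between alignments whose integer scores differ for sequences under ~2.5 kb;
- **denominator floor** at the shorter sequence's ungapped length: under
  free end gaps two *unrelated* sequences optimally slide to a short perfect
  core, and without the floor that degenerate core would score near 100%
  identity and defeat the 97% annotation threshold. A shorter read fully
  contained in its reference is unaffected.

Assignment takes the best-identity reference at a 97% floor; below it a read
is nontarget. Ties within a lumped unit resolve to the unit; ties across
units fall back to distinguishing positions (alignment columns where one
species is IUPAC-incompatible with every other); remaining ties go
deterministically to the first unit (or most abundant, when abundances are
supplied) with a logged warning. Species whose references are compatible at
every aligned column are lumped into units by transitive closure — the
low-divergence scenario where a marker simply cannot separate sister
species. Reads whose only differences from their reference sit at ambiguity
positions (and within the code) are sequence variants, indexed per species by
haplotype abundance (canonical = 0); any other difference is sequencing
noise. The detection table resamples each library without replacement to a
fixed depth (default 5000) from non-noise assigned reads; the
below-0.01%-presence flag derives from *unresampled* fractions, since a
species can be flagged while still appearing in the resampled counts.

## Clustering and scoring

Greedy centroid clustering processes dereplicated reads in decreasing
abundance (ties lexicographic by sequence); a read joins the best-identity
centroid at or above the threshold — identity ties go to the more abundant,
then older centroid — or founds a new one. Best-hit assignment with explicit
tie-breaks is a documented divergence from first-accept greedy tools, chosen
so an independent step-by-step oracle is well defined; equivalence is tested
on hundreds of random instances. The sweep runs each threshold of the
95–99.5/0.5 grid independently.

An OTU is correct (all reads of exactly one species), partial (a proper
subset of one species' reads) or mixed (≥ 2 species). Mistakes: partial = 1,
mixed = one per species present — a mixed OTU containing a complete species
still counts that species, since merged species misinform downstream ecology
regardless of completeness. Best threshold per marker: maximise correct
OTUs, then minimise mistakes, then take the lowest threshold.

Statistics: one-way fixed-effects ANOVA on ln(read count) of detected
species (groups = markers; undetected species excluded rather than
pseudo-counted; F is log-base invariant), and Spearman rank correlations
(average ranks for ties, t-approximation for p) between a species'
mistake rate and its total abundance or variant count. A species' mistake
rate — not defined by the scoring metric itself — is taken as the fraction
of (marker, threshold) cells in which it occurs in a non-correct OTU, the
only species-level quantity consistent with correlating abundance against
clustering errors; correlations are reported pooled and per genus.

## Packaged fixture

`data/mock_community_detection.tsv` transcribes the study's per-species
representation table (41 species × 4 markers, resampled read count RA and
sequence-variant count SV; absent entries as 0/0). Two truncated rows were
resolved by the conservation law that every genus × marker column sums to
the 5000-read resampling depth: *R. mattiroloana*'s third printed value pair
belongs to rpb2 (the column sums to 4900 without it and exactly 5000 with
it) with ef1-α missing, and *R. globispora*'s two pairs are ITS1/ITS2. With
this reading all 12 columns sum to exactly 5000. The multiple-variant
percentages computed from the fixture over the 41-species denominator are
ITS2 34%, rpb2 15%, ef1-α 34%; ITS1 computes to 37 (15/41 = 36.6%) and is
checked to ±1 point because the printed value 36 rounds inconsistently with
the other three.

## Problem sizes and what the tests show

Test and acceptance experiments are scaled for a desk machine: the
parameter-recovery run uses one 12-species community at 5000 noise-free read
pairs per marker over ITS1/rpb2/ef1-α — markers whose fragment mean + 3 SD +
primers stays below the 2×250−25 merge ceiling, so merge geometry is
guaranteed by construction rather than by seed; ITS2's length profile
deliberately violates it. The noisy chimera experiment uses one 8-species
community at 2500 pairs. Passing tests therefore demonstrate correctness of
the machinery and calibration of the generator, not field performance:
real libraries differ in error structure (indels, motif-dependent quality),
primer-site variation, length heterogeneity within a marker, and chimera
mechanisms beyond two-parent single crossovers. Headline read-level numbers
from any real sequencing run (total depths, chimera detection ratios,
per-genus best thresholds) are reproduced here qualitatively — the marker
contrasts, not the exact values.

## Known limitations

- Star phylogeny only: no shared internal branches, so clade structure
  within a community (and its effect on chimera parentage) is not modelled.
- Two-parent, single-crossover chimeras; multi-parent products register as
  nontarget.
- No denoising/exact-sequence-variant route; the pipeline is OTU-based.
- The center-star MSA is a heuristic: pairwise-optimal against the center
  only; distinguishing positions and unit lumping are defined on its
  columns, matching how reference alignments are curated in practice, but a
  different MSA could shift column indices.
- Flank trimming is anchor-based; libraries whose flanks genuinely need
  profile-HMM extraction are outside the generator's scope.
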