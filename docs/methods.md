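# Methods

This note documents the models, algorithms and numerical choices behind
`bacpool`, in the spirit of a methods supplement: what each stage assumes,
which parameters matter, what the synthetic data do and do not emulate, and
where the design was genuinely open.

## Synthetic genome truth

The generator produces a single chromosome segment intended to stand in for
a sequenced QTL region of a teleost genome.  Bases are drawn i.i.d. with a
configurable AT fraction (default 0.594, matching the composition reported
for the assembled target region); interspersed repeats are a small number of
families (default 5, unit length 0.5–3 kb) whose copies are written over the
background with 1–5% per-copy divergence, up to a target repeat fraction
(default 5.6%).  Genes are non-overlapping intervals placed outside repeats;
SSR marker loci carry an (AC)₈ tract and a ~300 bp amplicon template that is
guaranteed unique (forward and reverse-complement) by rejection sampling, so
a PCR screen has exactly one true template per marker.  Bi-allelic SNPs are
placed inside genes; roughly a third carry additive trait effects.

Genetic map positions are linear in physical position at 3.4 cM/Mb.  This is
deliberately simplistic — no recombination hot/cold spots — because the only
downstream consumer is unit-conversion arithmetic.

Determinism: one global seed drives a per-stage seed sequence
(`seed·1000003 + crc32(stage) mod 2³¹`), so any stage can be re-run in
isolation and full runs are byte-reproducible.

What is *not* modelled: GC isochores, tandem repeat expansions beyond the
SSR tracts, segmental duplications, inverted repeat copies (all copies of a
family share one orientation), and gene structure (genes are intervals, not
exon models).  Consequences are noted per stage below.

## Clone library and physical map

Cloning is a partial digest: every *Hind*III site is retained independently
with probability 0.03 per simulated digest round, and fragments inside the
size-selection window (80–120 kb, mean ≈ 98 kb) enter the library until the
requested clone count (default 6 genome equivalents) is reached.  Clone
boundaries therefore always sit on genuine restriction sites.

Fingerprints are the multiset of complete-digest fragment sizes of the
insert for a second enzyme, binned at ±3 bp.  The default fingerprinting
motif is a 5-mer with three G/C letters; at the default AT fraction its mean
spacing is ~1.3 kb, which makes the number of *distinct* bands in a contig
calibrate to roughly 1.36 kb per consensus band — the same kb/CB constant
used in the physical-map arithmetic — and keeps the CB-derived span estimate
within 25% of truth.

Contig building is single-linkage clustering on shared-band counts.  The
join threshold default is **20 shared bands**.  A lower threshold (10) was
found by simulation to admit false joins: complete-digest fragment sizes are
roughly exponential, so two *unrelated* ~98 kb clones already collide on
6–15 binned bands.  At 20, disjoint clones stay separate while adjacent
clones (overlaps of tens of kb, ≈ 1 true shared band per 1.3 kb of overlap)
join reliably at ≥5x clone coverage.  No Sulston-score probability model is
used; the abstraction is count-based by design.

The minimum tiling path is the classical greedy interval cover over truth
coordinates (simulation mode): repeatedly take, among clones starting inside
covered territory, the one reaching furthest right; ties prefer the leftmost
start so that selected neighbours overlap generously (useful for BES
validation).  On gap-free instances greedy interval cover is provably
minimum; the test suite confirms equality with exhaustive search on all
random instances up to 12 clones.  Disconnected clone sets raise an error
listing the gaps.

## 3D pooling, screening, deconvolution

Pools are presence/absence sets: a pool is truly positive iff at least one
member clone's insert fully contains the marker amplicon.  Observed calls
flip independently per pool with false-negative/false-positive rates
(defaults 0).  Deconvolution intersects the Cartesian product of positive
plate/row/column indices with occupied library addresses; a candidate is
auto-confirmed only when all three dimensions are singletons.  Otherwise a
confirmation plan orders candidates by how many pools they share with other
candidates (most-constraining first).  Confirmation execution applies one
logical inference — a positive pool whose other candidates have all tested
negative must contain the remaining one — which is sound when confirmation
PCR is error-free (the default assumption; a noisy-confirmation flag exists
but is off).  Inconsistent screens (some dimensions positive, empty
intersection) produce a structured warning and an empty result rather than
an exception, mirroring markers that amplify in pools but cannot be
localized.

## Read simulation and preprocessing

Short reads: inward paired 2x250 bp from normal(475, 50) fragments, uniform
substitution errors at 0.2% (a typical post-filter MiSeq rate; the study
design fixes read length, fragment size and 130x per-clone coverage but not
the error rate), flat Q39 qualities.  Long reads: lognormal lengths (median
8 kb) clipped to 0.5–31.4 kb, 1% residual substitution error, representing
*self-corrected* single-molecule reads; raw-error long reads are out of
scope.  Neither platform gets indel errors — a deliberate simplification
that lets all internal alignment be gapless (see below).  Power analyses on
this simulator therefore do not speak to indel-induced assembly artefacts.

Trimming follows the LEADING:3 TRAILING:6 SLIDINGWINDOW:4:15 MINLEN:150
semantics; when one mate is dropped the survivor is kept unpaired, which
maximizes usable coverage.  K-mer normalization (k = 25) is the streaming
median-abundance filter; for speed the abundance table samples every 4th
k-mer position per read with a proportionally scaled threshold, which
reproduces the target (100x) within the +-20% band the pipeline needs.  The
k-mer hash is a fixed-coefficient linear hash over bytes, so results are
identical across processes.

## Greedy overlap assembly

Reads are stored in a canonical orientation (lexicographic min of the read
and its reverse complement), which makes assembly of a reverse-complemented
read set byte-identical.  Both orientations are indexed by their 5' k-mer
(k = min(31, min_overlap)).  A contig seeds from the first unused read and
extends by repeatedly adopting the unused read with the longest overlap that
verifies at 97% identity (mismatch budget covers 2x the read error rate plus
slack); fully contained reads are absorbed.  Left extension is right
extension of the reverse complement.

Repeat handling is the core of the design: at every step all candidate
extensions (they all start at the current contig end) are clustered by
agreement over their first 40 bases (≤2 mismatches joins a cluster).  Two
clusters with ≥2 supporting reads each mean the contig end sits at an
unresolvable branch — in practice an interspersed repeat longer than the
read span — and the contig terminates without consuming the competing
reads, so the other branch remains assemblable.  Requiring two supporters
per cluster makes single-read sequencing errors unable to break contigs.
Contigs contained in longer contigs at ≥95% identity (artifacts of seeding
from reads with corrupted 5' k-mers) are removed afterwards.

## Internal alignment

All read/contig placement uses a k-mer-seeded (k = 15), strictly gapless
verify-on-diagonal aligner; long queries are mapped in 200 bp chunks chained
by (reference, strand, diagonal).  Because the simulator introduces only
substitutions, gapless alignment is exact for everything the pipeline maps;
it would *not* be adequate for real indel-bearing data, and that limitation
is inherited by every stage.  Genuinely gapped comparison — counting
substitutions and indels between two assemblies — goes through edlib's
global Needleman–Wunsch alignment instead.

## Hybrid scaffolding

Long reads are mined by mapping against the short-read contigs at the
permissive thresholds (aligned length fraction 0.2, similarity 0.9).  Edge
construction is stricter: only blocks at ≥97% identity may define a
junction, because 1–5%-diverged repeat copies otherwise generate spurious
contig pairings that pass 0.9.  Each edge's supports are clustered by their
implied gap (±200 bp) and only the majority cluster is kept.

Linearization is greedy chain merging in descending support order, and every
join must verify at the base level before it is accepted: a negative gap
(overlap) is refined by scanning ±48 bp around the projected overlap for the
shift minimizing mismatches over a 400 bp probe, and accepted only if that
probe meets the 99% merge identity (plus a 3-mismatch floor for coverage-1
contig ends); a positive gap requires a recorded spanning read, whose
junction segment (reverse-complemented as needed) becomes the fill — N runs
only when no spanning sequence exists.  Edges whose endpoints are interior
to a chain, whose orientation conflicts with an established chain, or whose
junction fails verification are skipped and logged.  Because chains only
ever merge, the scaffold count never exceeds the contig count; because every
junction is sequence-verified, a wrong graph cannot corrupt a scaffold —
at worst it leaves two chains unmerged.  Projected overlaps are exact only
to a few bases (contig termini are single-coverage), hence the refinement
step; without it, merges fail on off-by-one junctions and validation then
shatters the scaffold.

## Read-back validation

All pool reads (short and long) are re-mapped at 0.95 length-fraction /
0.95 similarity; coverage counts only accepted placements (long reads
contribute their chained block intervals).  Maximal internal zero-coverage
runs split a scaffold; terminal zero runs are trimmed; every output piece
carries its coverage slice and has minimum coverage ≥1.  The operation is
idempotent.  Note the outermost few bases of any template are genuinely
uncovered by full-length-mapping reads, so validation may trim scaffold tips
by a few bases — this is expected behavior of the 0.95 threshold, not a
defect.

## Anchoring

Marker amplicons and simulated BAC-end sequences (854 bp, per-end success
probability 0.972) are placed with the same gapless mapper and classified
full (≥90% aligned), partial (≥25%) or absent, with strand.  A BES pair on
one scaffold in convergent orientation implies the clone's span and
orientation; spans come out within the insert-length range when the scaffold
is correct.

## Microsynteny

A block is a maximal run of genes adjacent in the query (same FPC contig,
≤1 missing gene between consecutive members) whose best hits co-locate on
one target chromosome within 5 gene ranks and 1 Mb of some block member —
co-location, *not* collinearity, so internally shuffled or inverted runs
still count.  The homologous chromosome call reports the argmax chromosome
plus any chromosome with ≥25% of the maximal hit count, which
operationalizes the informal "high number of hits" rule and captures
two-chromosome homology patterns (e.g. against genomes that underwent an
extra duplication-era fission).  The adjacency gap thresholds are declared
defaults, not values inherited from any particular study.

## Association and expression

Genotypes come from a Mendelian multi-family cross (two parents per family
drawing alleles at the population frequency; configurable uneven family
contributions, default 62.1/27.3/… matching a mass-cross batch structure).
Traits are `μ + family effect + Σ additive·(alt count) + N(0, σ)`.

Testing: two genotype classes → pooled-variance two-sample t-test (Welch
behind a flag; pooled matches the classical default of the era's GUI
statistics packages); three classes → one-way ANOVA, and when F is
significant, Tukey HSD with a compact letter display built by greedy clique
cover of the non-significance graph (groups share a letter iff their pair is
non-significant; verified exhaustively on 3-group instances).  α = 0.05
throughout and **no multiple-testing correction** across SNP x trait
combinations — the report carries the test count so users can correct
downstream.  Per-family replication re-runs the test within each family
above a size threshold and flags concordance of the genotype-mean ordering
with the pooled analysis.  Calibration is part of acceptance: type-I error
0.05 ± 0.015 over 2,000 testable null simulations at n = 96, and >95% power
for a 1-SD additive effect at n = 570.  Simulated draws where the SNP does
not segregate (possible with two-parent families) are excluded — one cannot
test a monomorphic marker.

qPCR: the efficiency-corrected ratio `E_t^ΔCt_t / E_r^ΔCt_r` with ΔCt fixed
as calibrator − sample (the convention is stated because the field's usage
is ambiguous); group contrasts are t-tests on log₂ ratios.

## Problem sizes

Default test and acceptance workloads are sized for a single core: the
pipeline smoke test uses a 0.5 Mb genome; the end-to-end assembly check uses
one three-clone FPC pool (~300 kb region) at the full 130x/24x study
coverage; exhaustive deconvolution uses a 4x4x4 design with ≤3 positives;
tiling-path minimality is checked against brute force on ≤12 clones.  All
sizes are configuration, not constants; the same code runs multi-Mb genomes.

## Known limitations

* Substitution-only error model; no indels, no chimeric reads, no
  quality-score correlation.
* Gapless internal alignment (exact here, inadequate for real data).
* Repeat copies are never inverted, so fold-back misassemblies are not
  exercised.
* The physical-map abstraction has no band-calling noise model beyond size
  binning; kb/CB calibration depends on the fingerprint motif density.
* Pool screening models DNA presence, not template titration or primer
  competition.
* The homology table for synteny is simulated (block structure + uniform
  noise), standing in for a BLASTX/best-hit pipeline that is out of scope.
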