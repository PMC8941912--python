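# Methods

`mockqc` quantifies how well a sequencing-based measurement of a defined
mock bacterial community reproduces the community's known composition, and
derives simulation-based acceptance criteria for such measurements. This
note documents the statistical model behind each component, the parameters
that matter, the synthetic-data generators used for testing and
demonstration, and the numerical choices made where the design was open.

## The reference registry

The package ships a registry of 20 gut-associated bacterial strains
(`src/mockqc/data/mock_registry.tsv`): NBRC culture-collection accession,
species name, genome size, genomic GC content (31.5–62.3%), 16S rRNA gene
copy number (3–10), Gram type (+/−/±) and the relative abundance assigned
to each strain when the two communities were formulated. The DNA mock
contains all 20 strains at 3.6–6.9%; the whole-cell mock omits
*M. massiliensis* and *M. funiformis* and is even at 5.6% per strain.

Abundances are stored as printed, rounded to one decimal, so the 18-strain
even community sums to 100.8 rather than 100; the registry validator
accepts sums within ±1.5 percentage points, and all downstream code closes
profiles to exactly 100% before analysis. Consequently the cumulative
Gram-positive abundance of the even cell mock is 67.2% in registry units
(12 × 5.6, the published expected value) and 66.67% (12/18) after closure;
both numbers appear in the code base and tests, each in its own context.

Gram-variable strains (± — *A. caccae*) belong to neither Gram subset by
default: only the 12 strictly Gram-positive strains reproduce the 67.2%
total. `gram_subset(..., include_variable=True)` overrides this.

## Compositional statistics

Species profiles carry only relative information, so all comparisons use
the Aitchison geometry of the simplex:

* **clr transform**: `clr(x)_i = ln(x_i / g(x))` with `g` the geometric
  mean; rows sum to zero.
* **Aitchison distance**: Euclidean distance between clr images — the
  primary dissimilarity, scale-invariant and subcompositionally coherent.
* **Bray-Curtis**: `sum|a_i − b_i| / sum(a_i + b_i)` on closed percent
  vectors; reported as a similarity (100 × (1 − dissimilarity)) where a
  percent agreement is more natural.
* **gmAFD** (geometric mean of absolute fold differences):
  `exp(mean_i |ln(a_i/b_i)|)`. A value of 1.0 means identical profiles;
  1.2 means a typical strain is off by 1.2-fold in either direction. Used
  as the headline accuracy number because it weighs a 2× overcall and a 2×
  undercall equally.
* **qmCV**: per species, the coefficient of variation (sd/mean × 100)
  across all replicate profiles around the grand mean; qmCV is the
  quadratic mean of the species-wise CVs. Sample (n−1) standard deviation
  is used because replicate counts are small (tens); this is switchable.

**Zero handling.** Log-ratio operations are undefined at zero. Before any
log, zeros in a closed vector are multiplicatively replaced: each zero
becomes δ = 0.5 × (smallest nonzero part) and the nonzero parts are scaled
down proportionally so the total is preserved. δ's factor is configurable.
This is standard compositional practice and keeps profiles with undetected
species comparable; it does mean distances involving many zeros depend
mildly on δ. Species whose mean abundance across replicates is exactly
zero carry no information for qmCV and are dropped with a warning.

## Acceptance simulation (allowable errors)

A measurement is judged against two uncertainty sources:

1. **Formulation uncertainty.** Each strain's assigned abundance m_i is
   treated as normal with mean m_i and standard deviation `rel_sd × m_i`,
   with `rel_sd` = 0.05 for the DNA mock (fluorometric total-DNA
   quantification) and 0.10 for the cell mock (adenine-content
   quantification of whole cells). Negative draws are redrawn rather than
   truncated, preserving the near-normal shape at these small CVs; each
   draw is then closed. The "5%/10% standard deviation" is interpreted as
   a *relative* sd: five absolute percentage points would exceed most
   assigned abundances and make the model meaningless.
2. **Measurement uncertainty.** Replicate measured profiles are modelled
   as logistic-normal: multivariate normal in clr coordinates with mean
   `clr(center)` and *diagonal* covariance (the per-part clr variances of
   the replicates; off-diagonals set to zero), mapped back by
   exponentiation and closure. The clr parameterization was chosen over
   alr; with a diagonal matrix the two differ and clr treats all parts
   symmetrically.

From 10^5 draws per arm, 10^5 random (formulated, measured) pairs are
sampled uniformly with replacement, one member from each arm. The
**allowable gmAFD** is the 95th percentile (linear-interpolation empirical
quantile, pinned by a full-sort oracle test) of the pairwise gmAFD
distribution. **Strain-wise acceptance ranges** are the formulated
abundance ± the 95th percentile of the absolute strain-wise abundance
difference over the same pair sample, floored at zero. Using the same
sample for both keeps the two criteria consistent; by construction, 95% of
the pair sample falls at or below the gmAFD threshold.

Two numerical facts worth knowing:

* A diagonal matrix is not a valid clr covariance (valid ones have
  zero-sum rows). Sampling independent normals in clr coordinates and
  projecting onto the simplex shrinks each part's realized clr variance by
  exactly (1 − 1/D) — for D = 20, about 5%. Parameter-recovery tests
  assert against the projected value; the same shrinkage occurs in the
  standard R implementation of logistic-normal sampling on the simplex
  when given a diagonal clr covariance.
* Closure similarly shrinks the realized per-strain CV of the formulated
  arm slightly below `rel_sd`; recovery tests allow 8% relative slack.

## Profile evaluation

Observed profiler output (mpa-format reports, wide/long TSV, or
per-replicon count tables) is reduced to a strain composition. Count
tables mimic pseudo-alignment quantification output: per replicon,
`est_count / effective_length` gives a coverage, coverages add across a
strain's chromosome and plasmids, and closed coverages are the abundance.

Observed taxon names are matched to expected strains by case-sensitive
substring search (grep semantics) using each strain's species name with
subspecies epithets removed, plus three strain-specific alternations for
taxa whose database names differ: "Blautia producta" (NBRC 113351),
"Bacteroides uniformis|Bacteroides rodentium/uniformis" (NBRC 113350) and
"Enterocloster clostridioformis|Clostridium clostridioforme"
(NBRC 113352). A name matching two strains is an error, except the two
*B. longum* strains, which are indistinguishable at species level and form
a collapse group; `collapse_longum` merges them into one bucket (on by
default for amplicon-style species-level comparisons, off for
genome-resolved quantification).

`evaluate_profile` reports: total abundance of expected species, per-strain
abundances (undetected strains reported missing at zero), false positives
sorted by abundance (explicitly "unassigned"/"unclassified" buckets are
tallied separately, but unannotated taxa such as "Pseudomonas sp." count
as false positives), Bray-Curtis similarity and gmAFD against the assigned
composition. Expected + false-positive + unassigned abundance sums to
100% by construction. `species_count_curve` counts taxa at or above each
abundance threshold — the precision-versus-threshold curve on which
k-mer classifiers show false-positive proliferation at low thresholds
while marker-gene profilers stay flat. `protocol_dispersion` emits all
pairwise Aitchison distances annotated within/between laboratory and
protocol group (repeatability vs reproducibility); `gram_bias_summary`
reports cumulative Gram-positive abundance per profile and pairwise
distances within the Gram-positive and Gram-negative subcompositions
separately, exploiting subcompositional coherence: a uniform extraction
bias against Gram-positives moves the Gram totals but leaves each class's
internal subcomposition unchanged.

## Amplicon quantification and primer editing

Reference V4 sequence variants are extracted from 16S gene sequences by
locating the 515F locus part (GTGYCAGCMGCCGCGGTAA) and the reverse
complement of the 806R part (GGACTACNVGGGTWTCTAAT) with IUPAC-degenerate
matching, allowing up to `floor(0.2 × primer length)` mismatches, no
indels, both strands searched. The insert between the primer sites is
kept, deduplicated per strain; identical inserts shared between strains
are flagged.

Merged reads are annotated to the best-identity variant at a ≥97%
threshold. Identity is matches over alignment columns of an end-gap-free
global alignment; since V4 amplicons are near-fixed-length, equal-length
pairs use the exact Hamming shortcut (tested equivalent). Reads tied
between variants of two or more strains at the best identity are counted
ambiguous and excluded rather than fractionally split — conservative, and
at species level the only systematic tie (the two *B. longum* strains)
collapses anyway. Per-strain counts are divided by 16S copy number and
closed, converting gene-level counts to a genome-level composition.

Read-quality filtering for amplicons reduces to the expected-error
statistic `EE = sum_j 10^(−Q_j/10)` with truncation-length and max-EE
thresholds (defaults 200/180 nt and 4/6 for forward/reverse) applied by
the synthetic pipeline driver; pair merging and denoising are out of
scope.

**Primer editing.** Proof-reading polymerases can overwrite
primer-template mismatches, so the primer region of a raw read may read as
the template rather than the synthesized primer. The leading 19 bp
(forward) or 20 bp (reverse) of each raw read is compared by Hamming
distance against (a) the strain's template sequence ("edited") and (b) the
primer with degenerate positions resolved to the template and primer bases
kept at fixed-mismatch positions ("unedited"). Reads with d = 0 to one
expectation are classed edited-perfect or unedited-perfect; an N anywhere
in the prefix forces the mismatch class; when template and resolved primer
coincide, editing is undetectable and perfect reads are reported unedited
with a degenerate flag. The summary statistic is the fraction edited among
perfect calls per strain.

## Read trimming and the GC-bias audit

`trim_pair` applies, per mate and in order: fixed front/tail trims
(defaults 5 and 1 nt), trailing poly-X removal (any single-base 3' run
≥ 10 nt), and — when the window quality threshold is nonzero — a 4-base
sliding window scanned 5'→3' that cuts the read from the start of the
first window whose mean phred falls below the threshold ("cut right"; the
final partial window is evaluated at its actual size). Two filters follow:
the fraction of bases below Q15 must not exceed the unqualified-percent
limit, and the trimmed length must reach the minimum (default 65 nt). A
pair is rejected when either mate fails, keeping mate files synchronized.
Settings are labelled `Q_U_L`, e.g. `15_100_65` (window trimming at Q15)
vs `0_100_65` (no quality trimming). Adapter removal and low-complexity
filtering are deliberately omitted: synthetic reads are adapter-free and
low-complexity filtering is orthogonal to the GC-bias mechanism (the
config stub rejects activation). Window-edge semantics are pinned by unit
fixtures, not by emulating any specific tool byte-for-byte.

`gc_bias_report` closes retained-read counts per strain under two settings
into compositions and reports their Aitchison distance, the per-strain
log-ratio change against genomic GC with its Spearman rank correlation,
and the batch's raw %Q30. When base quality is high the distance is
indistinguishable from multinomial noise; as quality drops, GC-coupled
window cutting removes reads from GC-rich genomes preferentially and the
distance grows.

## Synthetic data generators

The generators supply every input with embedded ground truth; all are
deterministic under a fixed seed.

* **Genomes** are i.i.d. base sequences with P(G) = P(C) = gc/2 at each
  strain's registry GC. They carry no repeat structure, k-mer bias or real
  gene content — sufficient for read-accounting and GC-stratified
  analyses, not for aligner or assembler benchmarking. Tests use 3–5 kb
  stand-ins rather than full genomes; read allocation is per genome copy
  (matching the equal-genome-copy formulation), with length weighting
  behind a flag.
* **Profiles** are logistic-normal around the closed assigned composition
  (clr sd default 0.05, the scale of a well-behaved replicate set), with
  optional per-strain multiplicative bias factors applied before closure —
  e.g. scaling all Gram-positives by 0.5 emulates a non-standard
  extraction with poor Gram-positive lysis, and the biased center is
  available in closed form for oracle tests.
* **Shotgun read pairs** draw strain labels multinomially from the
  composition, fragment start positions uniformly, and per-cycle qualities
  from a plateau (default Q36) minus a positional decay (0.02/cycle) plus
  Gaussian jitter (sd 2), clipped to [2, 40]; an optional abrupt quality
  drop at a configurable cycle emulates mid-read dephasing. The
  `gc_penalty` term (phred offset per unit read GC) couples quality to GC.
  The GC-bias audit uses a three-level plateau ladder (Q30/Q28/Q26,
  gc_penalty −8, jitter sd 4) spanning retention from ~100% down to ~75%
  at stringent settings — the model reproduces the *mechanism*
  (quality-dependent, GC-coupled read loss), not the bimodal quality
  distributions of any real instrument, so its %Q30 values are not
  comparable to platform-reported ones.
* **Amplicon reads** are allocated proportional to composition × 16S copy
  number (the pre-correction truth), each read being a forward primer
  region, a variant insert with i.i.d. substitutions, and the
  reverse-complement reverse primer region. With probability `edit_prob`
  the primer regions match the strain's template; otherwise they are the
  synthesized primer with template-resolved degenerate positions (only
  template-complementary primer variants amplify efficiently; a flag
  restores uniformly random resolution, under which unedited reads at
  degenerate positions are classified as mismatches rather than
  unedited-perfect).

Because generator truth is embedded in read ids (`|strain=ID`) and
provenance records, every downstream module is scorable without external
truth files. Passing tests demonstrate correctness of the accounting and
the qualitative bias structure; they do not validate against real
sequencing artifacts (chimeras, indels, instrument-specific error
profiles), which are declared out of scope.

## Problem sizes and tolerances

Monte-Carlo tests use 10^5 draws/pairs for percentile and
parameter-recovery checks (coverage asserted to ±0.5 percentage points),
1,000 replicates for qmCV recovery (±10% relative), 50,000 reads for the
amplicon round trip (per-strain abundance within 1 percentage point at
a 4-strain, 20–30% composition), and 6,000 read pairs per quality level
for the GC-bias ladder. These sizes put sampling error well below the
asserted tolerances while keeping the full suite under a minute of
simulation time.

## Known limitations

* Distances involving profiles with many zeros depend on the zero
  replacement δ; alternative replacement strategies are not implemented.
* The acceptance simulation treats strains as independent in both arms;
  real formulation errors (pipetting, stock quantification) may be
  correlated across strains.
* Amplicon annotation ignores indel sequencing errors (substitution-only
  generator, Hamming identity on equal lengths); real homopolymer indels
  would slightly depress identities.
* The trimming module implements one window-cut semantic; other tools cut
  differently at window edges, so per-read results are comparable in
  structure, not byte-identical, to any specific preprocessor.
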