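# Methods

`evsmallrna` re-implements, as a tested library and CLI, the computational
analysis of small non-coding RNA (ncRNA) cargo in extracellular vesicles
(EVs) versus their parental cells: read curation, construction of a
unique-sequence ncRNA reference, exact-match read counting under
coverage/length acceptance rules, ncRNA class profiling, negative-binomial
(NB) differential enrichment, and qRT-PCR relative-expression statistics.
Because the underlying study deposited neither raw reads nor patient Ct
data, every stage is exercised against a synthetic-data generator whose
defaults encode the study's design, and validated by property and
parameter-recovery tests rather than by reproducing published per-miRNA
numbers.

## Synthetic study generator

The generator emulates a two-condition small-RNA experiment: 51 nt
single-end reads, two replicates per condition (parental cells, EVs), and a
multi-class ncRNA reference (miRNA, snoRNA, tRNA, rRNA, piRNA, Mt_tRNA,
snRNA).

**Reference.** Each class draws `n_sequences` uniform-random ACGT sequences
in a biologically plausible length range (miRNA 18–25 nt, piRNA 26–32,
snoRNA 60–100, tRNA 70–90, Mt_tRNA 65–75, rRNA 80–160, snRNA 90–150). rRNA
and snRNA deliberately extend past twice the read length so the 50 %
coverage rule rejects some reads by construction. A configurable fraction
(default 10 %) of sequences is copied verbatim into a second source
database, written in lower-case RNA alphabet, to exercise normalization and
deduplication.

**Counts.** Per feature *i*, condition *c*, sample *j*:
`count ~ NB(mean = depth_j · q_ic, dispersion α)` with `Var = μ + αμ²`,
α = 0.1 by default. Within-class relative abundances are log-normal
(σ = 1 — the paper states no within-class abundance law, so this is the
package's baseline and is configurable); class-level masses follow the
published per-class read percentages of the cell and EV libraries.
Per-sample depth varies log-normally (σ = 0.15) around `library_size` to
give the normalization something to do. A chosen number of miRNA features
receives a planted log2 fold change (±2 by default, i.e. four-fold); the EV
abundance vector is then renormalized to unit mass because sequencing depth
is fixed. That renormalization multiplies every feature by one global
constant — exactly the quantity median-of-ratios normalization absorbs — so
the planted per-feature fold change remains the recoverable ground truth.
When the two conditions share a composition, unplanted features have an
exactly zero true fold change; when the published (different) compositions
are used, class-level shifts additionally move whole classes, which is the
intended emulation of the real libraries.

**Reads.** Each counted read is a sense-strand fragment anchored at the
feature's 5′ end (a flag enables random offsets), 3′-extended with a poly-A
run (probability 0.2, length 5–15) and then the NEBNext-style adapter
prefix, truncated to 51 nt. A fraction of reads (default 5 %) gets a
failing quality string (Q2 everywhere, Phred+33); the rest pass at Q37.
There is no base-level sequencing-error model: mapping is 0-mismatch, so an
errored read would simply not map, and the quality flags already exercise
the filter path. Per-read and per-feature truth tables are written next to
every FASTQ.

**Ct tables.** Each sample has a latent input-amount baseline; reference
assays (miR-20a-5p, miR-28-5p) sit at that baseline, targets at baseline +
offset − shift·(group indicator) + technical noise, in triplicate
(cell-line design) or duplicate (plasma design). A shift of *s* log2 units
yields an expected group difference of *s* on the 40−ΔCt scale. Cell-line
defaults plant the study's validated fold changes (3.46×, 2.90×, 1.92×,
0.25×); plasma-mode shifts are not printed in the paper, so the defaults
plant 1.5 log2 for miR-10a-5p, 1.0 for miR-29b-3p and 0 elsewhere, with a
0.3 dropout probability for miR-5701 in the control group to mirror its
partial detectability. Limitations: no amplification-efficiency variation,
no inter-run batch effects.

What passing tests show, and do not show: the generator produces idealized
NB counts, error-free reads and Gaussian Ct noise. Recovery of planted
signal demonstrates correctness of the pipeline's arithmetic and its
statistical calibration under the assumed models, not robustness to real
artifacts (sequencing error, ligation bias, PCR duplicates, efficiency
drift).

## Reference compilation

Sources are normalized (uppercase, U→T) before deduplication, since miRBase
publishes RNA alphabet and genomic databases publish DNA. Records with
ambiguity codes are rejected (exact 0-mismatch matching is undefined on
them) and counted. Identical sequences collapse to one entry; the canonical
id/class comes from the lowest source-priority record, with ties broken by
a configurable class-priority order (miRNA > piRNA > tRNA > Mt_tRNA >
snoRNA > snRNA > rRNA > other — chosen because miRNA is the analytic focus)
and then lexicographic record id, making the result independent of input
order. Class conflicts between databases are always reported, because the
original study does not document how it resolved them.

## Read curation

Steps: 3′ adapter clipping (leftmost exact occurrence of an adapter prefix
of ≥ 3 nt reaching the read's 3′ end, or a full internal occurrence),
poly-A trimming (terminal A-runs of ≥ 5), then quality filtering (≥ 80 % of
bases ≥ Q20, both boundaries inclusive), artifact filtering (> 80 % of one
base), and a 15 nt minimum-length gate. The source study names its tools
but none of their thresholds; these defaults are common small-RNA practice
and are printed in every report header.

A design note on ordering: trimming is iterated to a fixpoint
(adapter ⇄ poly-A) before any filter runs. A single narrative-order pass is
not idempotent — removing a poly-A tail can expose a fresh adapter-prefix
suffix, and a quality fraction computed over bases that are later trimmed
can differ from the fraction over the bases actually kept. Iterating to the
fixpoint and filtering the final retained bases makes curation a projection:
re-curating curated output is exactly a no-op, which the suite asserts
byte-for-byte. Counts conserve exactly (input = output + per-reason drops),
and every retained read is a prefix of its raw read.

## Exact-match mapping

The acceptance rules are: 0 mismatches, the read must cover at least half
of the matched reference sequence, and the read may be at most 1.5 times
the reference length. With end-to-end semantics a read longer than its
target could never match at 0 mismatches, yet the 1.5× rule implies such
reads were considered — so the rules are realized as two containment modes:
read-in-target (with the coverage bound) and target-in-read (with the
length-ratio bound). A strict read-in-target-only mode is available by
flag. Both boundaries are read literally as inclusive ("at least half",
"maximum of 1.5-times") and evaluated in integer arithmetic
(`2·len(read) ≥ len(target)`, `2·len(read) ≤ 3·len(target)`), so
coverage = 0.5 and ratio = 1.5 are accepted without floating-point edge
cases.

Candidates come from a k-mer postings index (k = 12; targets shorter than k
are scanned directly, as are reads shorter than k) and every candidate is
verified base-for-base. The mapper is validated against a brute-force
double-loop containment scan on hundreds of randomized instances.

Multi-mapping resolution is not documented in the original study, so the
default `unique_priority` rule is the package's own: longest match, then
highest target coverage, then class priority, then lexicographically
smallest id — fully deterministic and order-independent. A `fractional`
mode (1/n per hit) exists for reporting; differential analysis uses integer
unique-priority counts because the NB model wants counts. Ambiguity tallies
are always reported so the rule's impact is visible. Mapping is sense-strand
by default (small-RNA libraries are stranded); both-strand mode by flag.

## Class profiles, correlations, detection overlap

Per-sample class counts and percentages are tabulated, with condition
averages computed as arithmetic means of replicate counts and percentages
recomputed from the averaged counts (the construction used in the
published per-class table). Inter-replicate Pearson correlation defaults to
log2(normalized count + 1) — the study does not state its transform; a
raw-scale flag exists. The detection-overlap partition classifies each
feature by whether its per-condition mean count reaches the threshold
(default 100 reads, inclusive ≥) in both, one, or neither condition; the
study does not state whether its "average of 100" is a mean or per-replicate
minimum, so the statistic is configurable with mean as the default.

## Differential enrichment

A self-contained NB Wald engine in the DESeq2 family, deliberately
simplified and documented as such:

* **Size factors** — median-of-ratios over features positive in every
  sample; a poscounts-style pseudo-reference mode exists for sparse
  matrices.
* **Dispersion** — per-feature method-of-moments from pooled within-group
  moments (`Var = μ + αμ²`), then a mean-dispersion trend
  `α_tr(μ) = a/μ + b` fitted by least squares to the positive raw
  estimates (clipped at their 99th percentile). Raw estimates above the
  trend are shrunk to the geometric mean of raw and trend; estimates at or
  below the trend take the trend value. With duplicate designs there are
  only two residual degrees of freedom per feature, and apparently
  sub-trend dispersion is overwhelmingly noise; letting it through makes
  the Wald test anticonservative (measured raw-p type-I ≈ 0.10 instead of
  ≈ 0.05 on the package's own null simulations), while flooring at the
  trend restores calibration (≈ 0.05) at a small, measured cost in power.
  Zero within-group variance yields the floor 1e-8.
* **Wald test** — per-feature NB GLM with log link and a condition
  indicator, fitted by IRLS vectorized across features on *normalized*
  counts (rather than raw counts with a log-offset). Working on the
  normalized scale makes results exactly invariant to rescaling any single
  sample — the size factor absorbs it — which is asserted at 1e-9
  tolerance. log2FC = coefficient/ln 2; p is the two-sided normal tail of
  coefficient/SE. All-zero features, non-converged fits and fits escaping
  to the coefficient cap (20 nats, e.g. a group with no counts) get missing
  p-values.
* **BH adjustment** — step-up with monotonicity enforcement; missing
  p-values are excluded from the test count m. Cross-checked against
  statsmodels.
* **Calls** — enriched/depleted at p < 0.05 with the sign of log2FC,
  four-fold flag at |log2FC| ≥ 2 (inclusive). The study reports both raw
  and FDR-adjusted p; calls gate on raw p by default with a flag for
  adjusted, and both columns are always emitted.

The reference tool's Cox-Reid adjusted likelihood, MAP dispersion
shrinkage, LFC priors and outlier replacement are intentionally absent.
Validation is by properties: label-swap antisymmetry (exact), scaling
invariance, null type-I in [0.03, 0.07], and ≥ 90 % seeded recovery of
planted four-fold features at baseMean ≥ 100 with ≤ 10 % false calls — plus
an independent cross-check of fold-change estimates against pyDESeq2 on a
small simulated matrix. Measured sensitivity under those conditions sits
near 0.9 and fluctuates by a few points across random draws; the
calibration quantities are recomputed at run time by the acceptance script.

## qRT-PCR statistics

Technical replicates are averaged per (sample, target) over detected wells
(Ct present and ≤ 40); fully undetected pairs propagate as undetected and
are excluded, never imputed, with exclusion counts reported. ΔCt subtracts
the arithmetic mean Ct of the two reference miRNAs (equivalent to the
geometric mean of their linear quantities; the combination rule is not
stated in the study). Cell-line comparisons use 2^−ΔΔCt paired within
biological replicate, summarized by default as the mean of per-replicate
folds (exponentiating the mean ΔΔCt is available by flag; the study does
not say which it used) and tested with a two-sided paired t-test on the
ΔCt pairs. Plasma comparisons use 40−ΔCt (one unit = one doubling) with the
Mann-Whitney test — exact when both groups have ≤ 20 observations, normal
approximation with tie correction above. Degenerate inputs are handled
explicitly: all-tied Mann-Whitney input returns p = 1 with a warning;
zero-variance paired differences raise an error rather than returning a
meaningless statistic. No amplification-efficiency correction is applied
(the 2^−ΔΔCt method itself assumes efficiency 2).

## Orchestration, determinism and problem sizes

The CLI stages (simulate, build-ref, curate, map, profile, de, qpcr,
run-all) write TSV artifacts whose commented headers carry the tool
version, seed and configuration hash, and `run-all` finishes with a SHA-256
manifest; two runs from the same configuration are checksum-identical.
All randomness flows from one integer seed through per-stage child seeds.

Problem sizes were chosen so the demo and the full validation suite run
comfortably on a single CPU: the bundled demo uses 30 000 reads per sample
(2 + 2 samples, ~500 reference features), the calibration simulations use
2 000 features at 2 replicates per group, and the mapper/oracle comparison
uses 200 randomized instances. These sizes are large enough that the
binomial/SE tolerances asserted in the tests are meaningful, and the whole
pipeline remains reproducible to the byte.

## Known limitations

* No genome mapping, no SAM/BAM output, no gapped or mismatch-tolerant
  alignment — by design, matching the original exact-match strategy.
* The NB engine supports exactly two groups, no covariates.
* The mapper's acceptance predicate uses fast integer arithmetic only for
  the default 0.5/1.5 bounds; other bounds fall back to float comparisons
  with an epsilon.
* The generator's quality model is binary (pass/fail); there is no
  position-dependent quality decay.
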