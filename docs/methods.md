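# Methods

## Junction-spanning probe design

A spliced transcript is modelled as an upper-case DNA sequence with an
ordered, contiguous, covering exon partition in mRNA coordinates (1-based
inclusive). A junction between exons (l, r) is canonical when r = l + 1 and
skipping when r > l + 1; its context sequence is the last `flank` bases of
exon l followed by the first `flank` bases of exon r, so a skipping
context exists only in the skipped isoform.

Probes are every k-window of the context whose junction point lies at
least `min_overhang` bases from both window ends: exactly
k − 2·min_overhang + 1 candidates per junction per strand (k = 25 and
min_overhang = 1 by default, giving 24). With `strand_mode=both` (the
default) each sense k-mer is paired with its reverse complement, recorded
under the same (junction, offset) with offset measured in transcript
orientation — droplet 3' chemistries differ in which strand the cDNA read
reports, and per-hit strand is retained so a sense-only analysis can be
reproduced with `--strand sense`.

Screening (on by default) removes candidates that would cross-react:
a skipping-junction k-mer occurring anywhere in the unmodified transcript
(either strand) would call skips from unskipped molecules, and a k-mer
occurring in another junction's context cannot be attributed. K-mers
containing N are never emitted, and a k-mer string is never mapped to two
junctions (cross-junction duplicates are dropped with a recorded reason
regardless of the screen flag, preserving the one-label-per-k-mer
invariant). Dropped candidates are retained in the panel's JSON sidecar
for audit.

### The overhang / specificity trade-off

`min_overhang` controls a real sensitivity–specificity dial. A probe with
a 1-base overhang into the downstream exon differs from the corresponding
canonical-junction sequence by a single base whenever the two right exons
begin differently by one base — so a single sequencing error can
manufacture a skip call. At a per-base error rate of ~0.5 % this produces
a visible false-positive floor (~0.3 % of wild-type nuclei in simulation).
Raising `min_overhang` to ~6 requires several coordinated errors and
eliminates the artifact, at the cost of missing molecules whose fragments
clip the junction by fewer than 6 bases (~11 % of junction-overlapping
fragments under uniform placement with 90 nt reads). Error-free data can
use min_overhang = 1; for noisy data the package recommends 6.

## Read scanning

R1 is split positionally into barcode and UMI (16 + 12 for v3 chemistry,
16 + 10 for v2, `custom:<bc>,<umi>` otherwise); only R2 is scanned. Because
every probe shares one length k, exact multi-pattern search is a hash
lookup on each of the |read| − k + 1 windows — contractually identical to
the naive window scan, which the test suite asserts on random reads.
Matching is exact, as befits a presence/absence readout: sequencing errors
cost sensitivity (absorbed by the ~24-fold tiling redundancy) rather than
specificity. Mates are paired by file order with read-id verification at
every record, so a desynchronized pair of files fails immediately instead
of scrambling barcode assignment; memory does not grow with library size.

## Deduplication and classification

Reads sharing (corrected barcode, UMI, junction) collapse to one molecule.
Barcode correction (only when a whitelist is supplied) maps a raw barcode
to itself if listed, otherwise to a *unique* whitelist entry within
Hamming distance 1, otherwise discards the read — ambiguity is never
guessed. Optional directional UMI collapse merges a UMI into an
already-kept UMI at Hamming distance 1, processing UMIs by descending
support with lexicographic tie-break, so amplification-error UMIs fold
into their parent. The dedup key includes the UMI deliberately:
barcode-only collapse would count at most one molecule per junction per
nucleus and undercount expression.

Molecules at skipping junctions count as skipped, at canonical junctions
as unskipped. A single (barcode, UMI) observed at both a skipping and a
canonical junction is biologically impossible for mutually exclusive
isoforms; it is counted once as ambiguous and excluded from both classes
rather than fractionally assigned.

A nucleus is *positive* for a junction when it carries ≥ 1 unique molecule
of it. Percent-positive denominators are all annotated nuclei of the
(condition, cell type) stratum, zero-count nuclei included; annotation
strata can be restricted (e.g. to myonuclei) because junction detection in
non-target lineages is not biologically meaningful. Hit barcodes absent
from the annotation are reported and excluded. Percentages are reported to
2 decimal places.

## Exact Mann–Whitney comparison

Cohorts of a few animals per arm make asymptotic rank tests unreliable, so
the per-cell-type comparison of frequency percentages uses the exact
distribution: counts N(u; n₁, n₂) of rank arrangements with U = u follow
the recursion N(u; n₁, n₂) = N(u − n₂; n₁−1, n₂) + N(u; n₁, n₂−1), summing
to C(n₁+n₂, n₁) and symmetric about n₁n₂/2. The two-sided p is
2·min(P(U ≤ u), P(U ≥ u)) capped at 1 — stated explicitly because
two-sided exact conventions differ. The exact path is used when the data
are untied and n₁ + n₂ ≤ 25 (configurable); otherwise a tie-corrected
normal approximation with continuity correction is used and flagged in
the result, with p = 1 when all observations are identical. Raw p-values
are reported by default; Benjamini–Hochberg adjustment is available as an
added column and never alters the raw values. Reported p-values print at
3 decimals (the floor for 3 vs 8, 2/165, prints as 0.012; U = 2 gives
8/165 → 0.048).

Recovery scoring compares condition centers (means by default, medians by
flag): a cell type "recovered" when |center(treated) − center(WT)| <
|center(disease) − center(WT)|, and is undefined when disease and WT
centers coincide.

## QC filtering

Count matrices are read from the MatrixMarket coordinate trio
(gz-tolerant), with line-numbered errors for malformed or out-of-range
triplets and duplicate entries summed under a warning. Genes detected is
the number of nonzero genes per barcode; total UMI is the column sum.
Filtering order is: optional exclusion list (e.g. externally called
doublets), mitochondrial genes by case-insensitive name prefix (`mt-` by
default), then a strict `<` threshold on the chosen metric — so nuclei
whose counts are mostly mitochondrial correctly fall below the threshold.
The threshold metric defaults to genes detected (< 200) with total UMI
selectable, since both phrasings of this filter circulate in the
literature; the order of operations is recorded in the filter report.
Cohort summaries report both means and medians of genes/UMI per nucleus,
and per-sample/per-group nucleus totals with the mean nuclei per sample
rounded to an integer.

## The simulator

The simulator emulates what the analysis consumes, not transcriptomes in
general. A synthetic transcript (default 6 exons × 120 nt, random sequence
with exon boundary bases forced distinct across exons so minimal-overhang
probes stay junction-specific) hosts one skippable exon: canonical
junctions e2-e3/e3-e4 and skipping junction e2-e4. Per condition, each of
`n_cells` cells draws Poisson(`mean_molecules`) molecules (default mean
8); a molecule overlaps the junction region with probability
`junction_overlap_frac` (default 0.25, i.e. ~2 junction molecules per
cell) and, if so, is skipped with the condition's per-molecule skip
probability. Defaults model a dosing experiment with a 10-fold
molecule-level treatment effect — 0 (WT), 0.02 (untreated disease), 0.2
(treated) — at 700 cells per condition, sizes chosen so per-condition
positivity is estimated from hundreds of positive nuclei while a full
pipeline run stays in seconds.

Junction fragments place the junction point uniformly within the 90 nt
read (≥ 1 base overhang each side); non-overlapping molecules yield reads
from single-exon interiors, which by construction contain no
junction-spanning sequence. Barcodes are drawn without replacement from a
generated whitelist (so correction paths are exercisable), UMIs are unique
within a cell, PCR duplicates replicate a molecule's fragment
Geometric(`dup_geom_p`)-many times (default 0.5 → mean 2 reads/molecule)
with fresh per-base substitution errors (default 0.005; indels are not
modelled because exact matching makes them equivalent to substitutions
for hit/miss purposes). 3' positional bias is deliberately not modelled:
the readout is presence/absence, not coverage. Output is fully determined
by the seed, and the emitted truth records per-cell molecule counts per
junction, per-condition molecule-level skip fractions, and every read's
source molecule.

What passing recovery tests show: the scan–dedup–summarize chain is an
exact inverse of the generative process when reads are error-free, and
degrades only within sampling error under error, duplication, and
barcode/UMI noise. What they do not show: robustness to alignment
artifacts, ambient RNA, doublets, degraded RNA, or non-uniform coverage —
real-data effects outside the simulator's scope.

Frequency cohorts draw per-sample compositions from per-condition
Dirichlet distributions (continuous, hence tie-free, keeping the exact
test on its exact path); an optional multinomial stage adds count-level
discreteness. Count matrices are generated with planted
below-threshold barcodes and mitochondrial genes so filters can be
asserted exactly.

## Numerical and interface choices

- Strict `<` thresholds in QC; percent rounding to 2 decimals; p-value
  printing at 3 decimals; rounded-integer per-sample means in cohort
  summaries.
- UMI-collapse ties (equal support) merge into the lexicographically
  smaller UMI, making dedup order-independent and deterministic.
- Degenerate inputs: empty strata produce null percentages, not errors;
  an all-removed QC filter warns and returns an empty matrix; zero
  denominators in condition ratios are reported as infinite with a flag.
- Exit codes: 0 success, 1 usage/configuration error, 2 data error.
- Every run writes a manifest with resolved parameters, input digests and
  seed; re-running from a manifest reproduces outputs byte-identically.

## Known limitations

- Probe design works in mRNA coordinates from a transcript accession;
  genomic GTF/GFF import is out of scope.
- Exact matching only — no mismatch-tolerant probe expansion; sensitivity
  under high error rates relies on tiling redundancy.
- Presence/absence quantification; no isoform abundance estimation.
- Detected junction frequencies are an under-observation of true skipping
  (3' chemistry samples a minority of molecules per nucleus), so
  percent-positive values are comparable between conditions but are not
  absolute skip rates.
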