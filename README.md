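# skipquant

Targeted detection and quantification of exon-skipped transcripts in
droplet single-nuclei RNA-seq, directly from raw FASTQ.

## The problem

Antisense-oligonucleotide (AON) exon-skipping therapies for Duchenne
muscular dystrophy direct the spliceosome to exclude a mutated or
frame-disrupting exon — in the *mdx* mouse, *Dmd* exon 23 — restoring an
open reading frame. Measuring how many nuclei actually contain the skipped
mRNA is hard: the event is rare, skeletal muscle requires single-*nuclei*
(not single-cell) protocols, and standard droplet pipelines align reads to
an annotated transcriptome that does not contain the therapeutic junction.

`skipquant` sidesteps alignment entirely. The skipped isoform is uniquely
identified by its novel exon–exon junction (e.g. e22–e24 where e23 was
removed), so any read containing a k-mer that spans that junction is direct
evidence of the skipped transcript. The pipeline:

1. **design** — from a spliced transcript sequence and its exon table,
   tile every k-mer (default k = 25) spanning each junction of interest:
   canonical junctions (e22–e23, e23–e24) for the unmodified transcript and
   the skipping junction (e22–e24) for the AON product. K-mers that would
   cross-react with the unmodified transcript or another junction are
   screened out.
2. **count** — stream the paired gzip FASTQ (R1 = 16 bp cell barcode +
   12 bp UMI for 10x 3' v3; R2 = cDNA), exact-match every R2 window against
   the probe panel, optionally correct barcodes against a whitelist
   (unique Hamming-1 neighbour), and collapse PCR duplicates: reads sharing
   (barcode, UMI, junction) are one molecule. Per (condition, cell type,
   junction) the output reports how many annotated nuclei carry ≥ 1
   molecule, as a percentage of *all* nuclei in the stratum.
3. **stats** — compare per-sample cell-type percentages between conditions
   with the **exact Mann–Whitney U test**: U = #{(xᵢ, yⱼ) : xᵢ > yⱼ}, with
   the null distribution of U enumerated over all C(n₁+n₂, n₁) rank
   assignments and the two-sided p = 2·min(P(U ≤ u), P(U ≥ u)) capped at 1.
   For n₁ = 3 vs n₂ = 8 the smallest achievable p is 2/165 ≈ 0.012. Ties
   fall back to a tie-corrected normal approximation, flagged per result.
   Recovery scoring asks whether treatment moved each cell type's mean
   percentage back toward wild type.
4. **qc** — MatrixMarket count-matrix I/O, genes/UMI per nucleus,
   mitochondrial-gene removal, and the strict `< 200` genes-per-nucleus
   (or UMI) nucleus filter.
5. **simulate** — a 10x-style read simulator with per-condition skip
   rates, PCR duplication, and per-base error, emitting full ground truth
   so the entire pipeline is testable without any sequencing download.

## Worked example

Simulate a three-condition cohort (700 nuclei each; per-molecule skip
probability 0 in WT, 0.02 in untreated *mdx*, 0.2 — 10× higher — under
AON treatment), design probes, and count:

```sh
skipquant simulate library --seed 7 --out-dir sim
skipquant design --fasta sim/transcript.fa --exons sim/exons.tsv \
    --junction e2-e3 --junction e3-e4 --junction e2-e4 \
    --min-overhang 6 --out-dir probes
skipquant count --r1 sim/R1.fastq.gz --r2 sim/R2.fastq.gz \
    --kmers probes/kmers.tsv --whitelist sim/whitelist.txt \
    --annotations sim/annotations.tsv --umi-collapse hamming1 \
    --out-dir counts
cat counts/summary.tsv
```

```text
condition	cluster	junction	n_nuclei	n_positive	percent_positive	n_molecules
WT	myonuclei	e3-e4	700	410	58.57	609
WT	myonuclei	e2-e4	700	0	0.0	0
WT	myonuclei	e2-e3	700	383	54.71	570
mdx	myonuclei	e3-e4	700	415	59.29	614
mdx	myonuclei	e2-e4	700	28	4.0	31
mdx	myonuclei	e2-e3	700	404	57.71	586
mdx_e23AON	myonuclei	e3-e4	700	349	49.86	473
mdx_e23AON	myonuclei	e2-e4	700	210	30.0	241
mdx_e23AON	myonuclei	e2-e3	700	342	48.86	492
```

Reading it: e2-e4 is the skipping junction (exon 3 absent). No WT nucleus
contains it; 4.0 % of untreated and 30.0 % of treated nuclei do, and the
canonical junctions appear at similar rates everywhere — the treatment
signal is confined to the junction the AON creates. The simulator's truth
file (`sim/truth.json`) records per-molecule skip fractions of 0.0262 vs
0.2014 for these seeds, a 7.7× ratio the pipeline recovers exactly under
error-free settings (see the acceptance script).

Condition comparison on a simulated 3-vs-8 frequency cohort:

```sh
skipquant simulate cohort --seed 3 --config cohort.yaml --out-dir cohort
skipquant stats --freq-table cohort/frequency_table.tsv \
    --group-a WT --group-b mdx --out stats.tsv
cat stats.tsv
```

```text
cell_type	U	p	method	direction	n1	n2
IIa	24.0	0.012	exact	increase	3	8
IIx	24.0	0.012	exact	increase	3	8
IIb	11.0	0.921	exact	decrease	3	8
fibroblast	0.0	0.012	exact	decrease	3	8
other	0.0	0.012	exact	decrease	3	8
```

`0.012` is the exact floor 2/165 for complete separation at these group
sizes; `direction` is the sign of the mean difference of group A relative
to group B (here: fiber types IIa/IIx are depleted in disease).

Every subcommand writes a `manifest.json` (resolved parameters, input
digests, seed) so runs are reproducible byte-for-byte.

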