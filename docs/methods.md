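# Methods

`retrosilence` re-implements, as a tested pipeline, a consensus-based
computational analysis of retrotransposon silencing in developing male germ
cells, and pairs it with a synthetic multi-omics generator so every stage can
be exercised and validated without any sequencing download.  This note
describes the models, the defaults and their rationale, the numerical
choices, and what the synthetic benchmarks do and do not establish.

## The biological model encoded by the generator

The germ-cell genome is reprogrammed between embryonic primordial germ cells
(E13.5 PGCs, globally hypomethylated) and postnatal stages (prospermatogonia
P0, spermatogonia P7, leptotene/zygotene spermatocytes P21).  Two silencing
systems restrain retrotransposons across this window:

* **Posttranscriptional (perinatal):** PIWI-interacting RNAs (piRNAs,
  24–33 nt) guide endonucleolytic cleavage of retrotransposon RNAs.  The
  `Pld6` knockout disables this pathway: steady-state TE RNA rises with
  little change in transcription, cleaved 5'-monophosphate RNA fragments
  disappear, and TE-derived piRNA pools collapse.  Because cleavage products
  lack the polyA-bearing 3' terminus only transiently, polyA(+) RNA-seq of
  a cleaved transcript shows 5'-depleted coverage; losing cleavage restores
  the 5' end — a positional, not uniform, fold change.
* **Transcriptional (spermatocytes):** de novo DNA methylation established
  perinatally (requiring DNMT3L, and for some elements piRNA guidance)
  silences promoters in meiotic cells.  The `Dnmt3l` knockout leaves
  elements hypomethylated and transcriptionally derepressed in
  spermatocytes — a uniform coverage fold change.  GC-poor (AT-rich)
  genomic regions lose the most methylation.

Activated retrotransposon copies can also fire transcription into nearby
genes (readthrough and antisense-promoter transcripts), upregulating them;
attribution of upregulated genes to activated copies within 100 kb is the
pipeline's final stage.

## Synthetic world

`SimConfig` defaults define the study conditions; the generator is seeded
and byte-deterministic.

* **Genome**: one 40 Mb chromosome of alternating 100-kb AT-rich (GC 0.34)
  and GC-rich (GC 0.52) blocks, with CpG dinucleotides injected at
  block-dependent density.  The 40 Mb size was chosen so that the ±100 kb
  attribution windows of the ~8 genuinely activated copies cover only ~4% of
  the genome — a scaled-down stand-in for the <1% coverage a real mouse
  genome would give — keeping the false-attribution control meaningful.
  The bisulfite benchmarks use a 2 Mb configuration (`small_test_config`),
  which is ample for ~125k CpGs.
* **Consensus library**: six families named in RepeatMasker style (L1Md_A,
  L1Md_T, IAPEz, RLTR10, MMERGLN, B1), 2–3.5 kb, random sequence with a
  CpG-rich 600-bp `5end` sub-region on L1 families (annotated as a
  sub-region of the full-length consensus rather than a separate FASTA
  entry, so full-length reads do not artificially multimap).
* **Copies**: 8 per family, full length, 3% per-base divergence from the
  consensus, placed without overlap.  Only a few copies are
  transcriptionally competent (1 per family plus the driving copies);
  the rest are inert, as most genomic TE copies are.
* **Methylation truth**: per-family beta means per stage/genotype.  E13.5 is
  ~0.03 everywhere; wild type reaches ~0.85–0.88 postnatally.  The
  methylation KO leaves L1 families at ~0.30 (severely affected: de novo
  extent reduced by ≥0.3 relative to WT) and others at 0.55–0.62; its
  genomic background drops to 0.55 (GC-rich) / 0.30 (AT-rich), generating
  the negative methylation-loss-vs-GC correlation.  The piRNA-pathway KO
  hypomethylates only its target families (L1Md_A, L1Md_T, RLTR10; 0.45),
  modelling piRNA-directed de novo methylation.
* **Expression truth**: per-family transcription rates (arbitrary units)
  per stage/genotype.  Perinatally the rates are genotype-flat (silencing
  there is posttranscriptional); in spermatocytes methylation-sensitive
  families rise 6-fold in the methylation KO, and piRNA-target families
  rise 6-fold in the piRNA KO (failed piRNA-directed methylation).
  The absolute rates are free parameters — the source analysis does not
  quantify them — and are chosen to give library compositions in which TE
  reads are a visible minority.
* **Cleavage truth**: piRNA-target families carry an even number of
  cleavage sites (~2/kb) on consensus coordinates, one pinned at 0.85 of
  the element length so the polyA-retained 3' tail is consistently short;
  half the sites (the configured ping-pong fraction) are piRNA-guided.
  Cleavage efficiency is 0.8 (WT) vs 0.05 (piRNA KO), and is gated to the
  perinatal stages — spermatocyte silencing is purely transcriptional, so
  both genotypes are uncleaved there and positional fold changes are flat.
* **piRNA pools**: 24–33 nt (triangular length profile peaking at 28–29 nt),
  70% antisense; antisense 5'-end positions include, for every guided
  cleavage site at p, a ping-pong partner at sense coordinate p+9 with
  elevated abundance (ping-pong-amplified species), plus background
  positions constrained away from the p+9 positions of unguided sites
  (piRNA-independent cleavage is piRNA-free at the overlap position by
  definition).  The piRNA KO shrinks TE-derived piRNAs 20-fold.  The pool
  also contains off-range contaminants and rRNA/tRNA/miRNA decoy reads for
  the blacklist filter.
* **Readthrough / driven pairs**: 5 copy→gene pairs.  One is the canonical
  intronic case — a full-length L1Md_T inserted antisense into a host
  gene's first intron — and the rest sit 5–60 kb upstream of their gene.
  The readthrough RNA is a chimera: the copy, a 1-kb run-on (which raises
  flanking coverage — the recorded evidence flag), and the gene's exons,
  at a rate of 0.5× the copy's family rate.  Driven genes are given a low
  baseline (2 units, vs a lognormal mean of ~8 for ordinary genes): the
  genes whose activation the attribution analysis targets are those mostly
  silent without the TE input.  Readthrough RNAs carrying the copy in sense
  orientation are themselves piRNA cleavage targets.  Driven transcripts
  derive exclusively from one parental allele (the allele carrying the
  insertion), which the allelic-ratio analysis recovers from strain SNPs
  (~1/kb, A/T alternatives so CpGs are never created or destroyed).
* **WGBS**: directional protocol, both strands; unmethylated C reads as T
  with probability `conversion_rate` (default 0.992, within the 99.2–99.3%
  range the protocol achieves); methylated C is protected; non-CpG
  cytosines are never methylated, so their residual C rate estimates the
  conversion rate.  Per-molecule CpG states are Bernoulli draws from the
  site's truth level.
* **polyA(+) rule**: a cleaved molecule contributes only its 3'-terminal
  fragment (the polyA-bearing one); read starts are drawn exactly from the
  resulting outcome distribution (the 3'-most firing site and the eligible
  start positions are enumerated analytically per transcript), not by
  rejection, so read counts conserve the requested library size.

What the generator does **not** model: indels and structural variation,
truncated/5'-deleted copies, paired-end inserts, sequence-composition
biases of real libraries, splice-junction reads mapping across exon
boundaries (they simply fail to align and are dropped symmetrically across
conditions), pachytene piRNA biology beyond pool persistence, and real
mouse sequence content.  Passing benchmarks therefore demonstrate that the
statistics recover the encoded causal structure at realistic depths and
noise levels — not performance on real libraries with their richer artefact
spectrum.

## Alignment

A minimal seed-and-extend aligner stands in for the external short-read
mappers at desk scale: exact k-mer seeding over a sorted-array index,
ungapped full-length extension scored +1/−1 (match/mismatch), and emission
of **all** co-best placements with tie multiplicity k.  "Co-best" is exact
top score; sub-optimal placements are discarded.  With a mismatch cap m and
m+1 non-overlapping seeds per read, the search is exhaustive by pigeonhole —
this is the regime the oracle-equivalence suite checks (cap 2, reads ≥36 nt,
12-mer seeds).  Without a cap the default 4 seeds make it heuristic, like
the tools it replaces.  Bisulfite mode aligns in three-letter space (read
C→T against the C→T genome for the original-top strand; reverse-complement
read G→A against the G→A genome for the original-bottom strand) while
records keep the original bases, oriented to the target's forward strand,
for methylation calling.  Coordinates are 0-based half-open internally;
SAM I/O (1-based, via pysam) carries k as `NH:i`, and imported SAM without
`NH` gets k inferred as the per-read count of co-best records.

Seed lengths in the pipeline: 14 for the 40 Mb genome (cap 2; simulated
reads differ from the genome only by sequencing error), 10 for the ~16 kb
consensus library (cap 4; reads from copies carry ~3% divergence).

## Quantification and statistics

* **Fractional counting**: a read tied across k co-best elements adds 1/k
  to each; sense and antisense tallies are kept separate (stranded
  libraries; sense-only counts enter expression).
* **RPKM/RPM**: RPKM = count / (length-kb × million reads); the per-million
  denominator for consensus TE expression is the library size (total
  reads), and for piRNA RPM the retained-read count (per-million-mapped is
  available as an option).
* **Stabilized fold change**: FC = KO/WT when WT ≥ 1 RPKM; otherwise the
  identical quantity (1 − WT) is added to numerator and denominator so the
  denominator becomes 1, i.e. FC = KO + 1 − WT — continuous at WT = 1 and
  monotone in KO.
* **Replicate tests**: two-sided equal-variance t test on
  log2(value + 0.1) across replicates (Welch optional); the fold change is
  the stabilized FC of replicate means.  Gene-level DE adds
  Benjamini–Hochberg correction (statsmodels) and classes
  up / down / unchanged at >2-fold / <1/2-fold with q < 0.05.
* **Gene DE normalization**: DESeq-style median-of-ratios size factors
  rescale the library totals by default.  Rationale: when a genotype gains
  a large repeat-derived read mass, raw per-million normalization deflates
  every gene's fold change; anchoring on the typical (unchanged) gene
  removes this composition artefact.  Raw totals remain available
  (`normalization="totals"`).  The >3-fold gene set feeding attribution is
  selected on fold change alone, matching how such gene counts are quoted;
  the q-gated classes serve the 2-fold DE tables.
* **Mann–Whitney U**: exact distribution for group sizes ≤20 without ties,
  normal approximation with tie correction otherwise (scipy), cross-checked
  against full enumeration for group sizes ≤8.
* **Fisher exact**: one-sided (enrichment) hypergeometric tail (scipy),
  cross-checked against enumeration for margins ≤12.

## Methylation calling

For each reference CpG covered on the appropriate converted strand, read
C increments methylated and read T unmethylated (G/A on the bottom strand),
pooled onto the C of the dinucleotide; other bases are ignored.  Multi-mapped
records contribute 1/k.  Non-CpG cytosine calls are tallied per target; the
conversion-rate estimate is their unmethylated fraction.  Aggregation pools
raw calls (not site means) over elements, promoters (TSS −1000/+500,
strand-aware, configurable) or 100-kb windows (which also carry GC
fraction); regions without calls are flagged missing, never zero.  No depth
filter is applied by default (the emulated study averaged ~1.7× coverage);
one is available as a knob.  The methylation-loss-vs-GC statistic is the
Pearson correlation between the per-window decrease (WT − KO) and GC
fraction, so GC-poor-biased loss yields a negative R.  De novo extent is
late-stage minus E13.5 level per element; an element is severely affected
when its WT extent exceeds its KO extent by ≥0.3.

## Cleavage and ping-pong

Each adaptor-trimmed 5'-RACE read contributes its alignment start as one
cleavage observation (1/k for ties); antisense alignments are tallied
separately and never merged.  The family share of the cleaved pool is the
family-assigned fraction of mapped cleaved reads.  A cleaved sense read
with 5' end at p carries the ping-pong signature when an antisense piRNA's
5' end sits at sense coordinate p + 9 (10-nt overlap), matched by mapped
coordinate since both are on consensus coordinates; a strict mode verifies
the 10-mer reverse-complement identity from the piRNA sequence.  Reads
shorter than the overlap are excluded from the denominator; a site-level
counting mode is available.

## Attribution

A copy is **activated** when (i) its family is >2-fold up on the consensus
and (ii) its local coverage FC is ≥2, computed from uniquely mapped reads
(fractional shares would smear family-level signal over every copy) with a
minimum mean KO coverage of 5 reads (one or two strays cannot activate an
inert copy).  This operational rule stands in for per-locus browser
inspection; both components are recorded for audit.  A >3-fold upregulated
gene is attributed to the nearest activated copy that is intronic
(sense/antisense by strand) or within 100 kb of the gene span (span-to-span,
inclusive at exactly 100,000 bp).  Enrichment uses the one-sided Fisher test
with, as background, all genes and a genome-wide copy-proximity indicator —
the background construction is a package choice, configurable, and its P
values should be read accordingly.  The neighbor control compares driven
genes' fold changes with those of other genes within 100 kb (U test);
gene-antisense piRNA grouping bins genes by antisense piRNA RPM.  Reads
overlapping annotated repeat copies are excluded from gene exonic counts
(ambiguous origin).

## Read preprocessing

Order of operations: 5' adaptor strip (exact match), fixed 5'/3' trims,
then truncation at the first base of the leftmost run of ≥3 consecutive
bases below the quality threshold (the removal of "low-quality stretches"
is not precisely defined by convention; run length and threshold are
knobs), then optional truncation to a fixed length (e.g. first 50 bp).
Zero-length reads are dropped and counted.  WGBS defaults: trim 6 nt from
the 5' end, 15 nt from the 3' end, Q30.

## Benchmark problem sizes

The validation workflows run at desk scale: bisulfite recovery on a 2 Mb
genome at 5× per genotype (~125k read pairs of calls; element = family-level
pooled copies); positional signatures on 20k-read consensus libraries;
ping-pong recovery from ~10k cleaved reads; attribution on the 40 Mb
default world with 60k reads × 2 genotypes × 2 replicates, pooled over 5
seeds.  Flatness of a positional profile is declared at |Spearman ρ| < 0.5
(≈2.6σ for ~28 windows); a posttranscriptional signature at ρ < 0 with
P < 0.05.

## Known limitations

* Ungapped alignment: indels, splice junctions and structural variants are
  out of scope; junction reads are lost (symmetrically across conditions).
* The aligner is exhaustive only under a mismatch cap with enough seeds;
  uncapped searches are heuristic.
* The Fisher background set and the activation rule are operational
  definitions; their outputs are comparative diagnostics, not calibrated
  P values for real data.
* With two replicates, t-test q values are conservative and noisy;
  conclusions should rest on effect sizes at this design size.
* The generator's absolute transcription rates, piRNA pool composition and
  readthrough strength are free parameters documented above, not measured
  quantities.
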