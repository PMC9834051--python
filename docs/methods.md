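# Methods

This document describes the generative model behind `abclip.simulate`,
the statistical definitions implemented by the analysis modules, the
numerical choices they make, and the known limitations. Quantitative
behaviour (recovery rates, deduplication accuracy, oracle agreement) is
asserted by the test suite and reported by `scripts/acceptance.py`; this
document confines itself to definitions and design rationale.

## 1. Simulator

### Genome and annotation

`make_genome` draws a uniform-random A/C/G/T genome over the configured
chromosome lengths and tiles non-overlapping transcripts onto alternating
strands. Each protein-coding transcript has an exon count drawn from
`exon_count_range`, exon lengths from a normal distribution (mean/sd in
`exon_length`, floor 50 bp) and intron lengths likewise (`intron_length`,
floor 300 bp). A CDS is carved out of the exonic sequence leaving a 5′UTR
of up to 150 bp and a 3′UTR of up to twice that, so every transcript
exposes the full feature vocabulary (UTRs, CDS, splice-site windows,
proximal/distal intron). A configurable fraction of genes
(`histone_fraction`) is generated as short, single-exon "histone-like"
transcripts, mirroring the replication-dependent histone genes that are
the canonical targets of SLBP-class RBPs. Sizing that cannot fit the
requested transcripts raises `SimSizingError` rather than silently
degrading.

All randomness flows through `numpy.random.default_rng` seeded with
`(config.seed, stream_id)` tuples, one stream per concern (genome,
sites, expression, reads, errors), so any component is reproducible in
isolation and insensitive to the order in which others run.

### Expression and binding sites

Per-transcript relative expression is lognormal with unit median and
configurable sigma (`expression_sigma`). `plant_sites` places
`sites_per_rbp` *specific* sites per RBP plus `n_shared_sites` *shared*
intervals bound equally by every RBP (listed once per RBP in the truth
table). Sites are `site_length` bp, restricted to the configured feature
class, separated by at least `site_min_gap`, and carry a read-rate
multiplier λ (`site_enrichment` / `shared_enrichment`). Placement that
cannot satisfy the constraints raises `SitePlacementError`.

### Reads

For each RBP, molecule truncation positions are drawn from a
per-base-pair weight field: transcript expression everywhere, multiplied
by λ inside that RBP's sites. Fragment lengths are normal
(`fragment_length`, floor `fragment_min`) and clipped to the transcript.
The truncation site is the strand-aware 5′ end: `start` on '+', `end−1`
on '−'. PCR duplication gives each molecule `1 + Poisson(d)` copies
(`pcr_duplication = d` is the mean number of *extra* copies), truncated
so the library hits `reads_per_rbp` exactly; copies share UMI,
coordinates and `molecule_id`. FASTQ records are laid out as
`UMI + barcode + reverse-complement(sense fragment)` (or barcode-first),
with i.i.d. uniform substitution errors at `error_rate` over the whole
read, UMI and barcode included. Barcodes default to a generated set with
pairwise Hamming distance ≥ 3.

`generate_expression_background` produces an RNA-seq-style control: the
same expression-proportional field with **no** sites and no duplication.

### Realism and limits

The generator reproduces the properties the analyses actually consume —
strand-aware truncations, expression-driven background, shared versus
specific binding, UMI/barcode read structure, PCR copies, substitution
error — and deliberately omits what they do not: no base-quality model,
no indels, no splice-aware fragments across junctions (fragments are
contiguous in genomic coordinates), no alignment step (reads carry their
true coordinates; the FASTQ route joins demultiplexer assignments back
by read id, standing in for a uniquely-mapping aligner).

## 2. Demultiplexing and UMI deduplication

Reads shorter than `umi_length + barcode_length + 1` are *discarded*;
reads whose barcode field has no unique table entry within
`max_mismatch` are *unassigned*; everything else is assigned, its insert
reverse-complemented into sense orientation. Assigned + unassigned +
discarded always equals the input count (asserted property-based).

Deduplication groups reads by `(rbp, chrom, strand, truncation)` (or the
full interval with `key="interval"`). *Exact* mode counts distinct UMIs
per group. *Directional* mode builds the standard adjacency: UMI `u`
absorbs `v` when they differ at one position and
`count(u) ≥ 2·count(v) − 1`; connected components are collapsed by
union-find and represented by the lexicographically smallest read id.
Directional mode corrects most UMIs altered by sequencing error; the
residual bias has two terms — copies with ≥ 2 UMI errors that escape the
one-mismatch adjacency, and molecules none of whose copies kept a clean
UMI, which splits components — both proportional to duplication depth.
`scripts/acceptance.py` reports the measured relative error at mean
duplication 0.5 and 1.0 with 1% sequencing error. Note the directional
rule is intentionally not idempotent: two singleton UMIs at Hamming
distance 1 satisfy `1 ≥ 2·1−1` and merge.

## 3. Peaks and enrichment

Candidate peaks cluster reads per RBP within a strand, merging clusters
separated by ≤ `merge_gap` bp and keeping those with ≥ `min_reads`
reads. Clustering can anchor on full fragment intervals or, by default
in the pipeline, on truncation sites only: at realistic depth, interval
overlap chains fuse adjacent features into transcript-sized blocks,
whereas truncation clustering preserves site-scale resolution.

Each peak is scored with a 2×2 table
`[[k_ip, N_ip − k_ip], [k_bg, N_bg − k_bg]]` of in-peak versus remaining
usable reads, IP versus background. Backgrounds: **cc** (pool of all
other RBPs in the multiplex), **smi** (size-matched input library) or
**rnaseq** (expression-proportional reads). Fold change is
`(k_ip/N_ip) / (max(k_bg,1)/N_bg)` — the background count is floored at
one read (flagged in the result) so zero-background peaks get a finite,
conservative fold. The p-value uses Yates-corrected chi-squared unless
any observed or expected cell is < 5, in which case the two-sided Fisher
exact test is used. P-values are floored at 10⁻⁸⁸ (chi-squared) and
2.2×10⁻¹⁶ (Fisher) so downstream `−log10(p)` arithmetic stays finite.
Significance is strict: `p < 0.001` **and** `fold > 8`.

The chi-squared path is validated against the closed form
`N(|ad−bc| − N/2)²₊ / (r₁r₂c₁c₂)` with `p = erfc(√(χ²/2))`, and the
Fisher path against exhaustive hypergeometric enumeration in exact
rational arithmetic; the acceptance suite bounds the deviations at 10⁻⁶
relative and 10⁻⁹ absolute respectively over 1,000 random tables.

## 4. Annotation

`derive_features` tiles each transcript into 5′UTR, CDS, 3′UTR (or
noncoding exon), ±100 bp splice-site windows (5′SS at donors, 3′SS at
acceptors, strand-aware), proximal intron (≤ 500 bp from an exon) and
distal intron; the pieces partition the transcript span exactly. Peaks
are assigned the highest-priority overlapping label
(3′UTR > 5′UTR > CDS > 5′SS > 3′SS > proximal > distal > noncoding),
same strand only, else `intergenic`. Motif scanning accepts RNA or DNA
alphabets, reports both genomic strands (or transcript sense strands
when models are supplied), and can be filtered by mean conservation
over a per-base track (missing positions count as 0, threshold strict).
`sample_matched_background` draws length-, feature-class- and
GC-matched non-overlapping control intervals for motif-fraction
comparisons.

## 5. Metagenes and RIC

Truncation profiles are per-base counts in transcript coordinates
(mature or pre-mRNA). Relative information content between an IP
profile `t` and background `b` is `RIC_i = p_i log₂(p_i/q_i)` with
`p = (t+α)/Σ(t+α)`, `q = (b+α)/Σ(b+α)` (additive pseudocount α = 1), so
`Σ RIC = KL(p‖q)` ≥ 0 exactly, and identical profiles give identically
zero. Peak-density metagenes spread each peak uniformly over the
mRNA-coordinate bins (5′UTR/CDS/3′UTR, length-proportional bin counts)
or splice-site offset windows it covers, then normalise the vector to
sum to one; multi-replicate profiles report the standard error of the
mean.

## 6. Splicing maps

A cassette event contributes five regions (upstream exon/intron,
cassette exon, downstream intron/exon, strand-aware). An event overlaps
a region when at least one significant peak has ≥ 50% of its length
inside it (boundary inclusive). Per region and event class, the 2×2
table of overlapping/non-overlapping changed versus background events
yields `OR = (a/b)/(c/d)` with a flagged Haldane +0.5 correction when
any cell is zero, a p-value from the same chi-squared/Fisher rule as
peak enrichment, and tiers `*` p < 0.05, `**` p < 0.001, `***` p < 10⁻⁴.
Background events are sampled uniformly (without replacement when the
pool allows) from unchanged events.

## 7. Comparisons

The overlap coefficient counts the smaller peak set's members (first
argument on ties) that overlap the larger set by ≥ 1 bp on the same
strand. Target ranking orders peaks by (p ascending, fold descending,
peak id) with a stable sort, deduplicates genes keeping the best rank
and accumulates target-gene hits. Complexity curves subsample the read
table without replacement at increasing depths and average the
deduplicated molecule count over several subsampling seeds.

## 8. Limitations

- No sequence alignment; mapping ambiguity, soft-clipping and splice
  junctions are out of scope. SAM/BAM input is supported only as an
  adapter (`reads_from_sam`) onto the aligned-read table.
- The expression-proportional background is an assumption standing in
  for total RNA-seq; real nonspecific background has structure (GC,
  abundance, protein-specific stickiness) the simulator does not model.
- Substitution-only error model with uniform rate; no base-quality
  information is used anywhere downstream.
- The enrichment test treats reads as independent draws; residual PCR
  duplicates that survive deduplication violate this mildly.
- Splicing maps use fabricated cassette events; differential-splicing
  calling from RNA-seq is out of scope.
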