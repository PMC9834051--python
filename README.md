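# abclip

Analysis toolkit for **antibody-barcode multiplexed CLIP** experiments,
with a ground-truth simulator for end-to-end validation.

In antibody-barcode CLIP, several RNA-binding proteins (RBPs) are assayed
in a single immunoprecipitation: each antibody carries a short DNA
barcode, so one sequencing library mixes the binding footprints of all
RBPs and is separated computationally. Each read begins with a unique
molecular identifier (UMI) and the antibody barcode, followed by the
reverse complement of the captured RNA fragment. The strand-aware 5′ end
of an aligned fragment (the *truncation site*) sits next to the
crosslinked nucleotide, so truncation positions pinpoint binding sites at
near-nucleotide resolution.

The key statistical idea the multiplex enables is the **complement
control (CC)**: the background for one RBP is the pooled reads of all the
*other* RBPs in the same reaction. Because those reads passed through the
identical experiment, the CC absorbs shared, nonspecific background
(abundant transcripts, sticky regions) far better than an
expression-proportional control such as total RNA-seq.

## What the package does

| Module | Purpose |
| --- | --- |
| `abclip.simulate` | Synthetic genome/annotation, planted binding sites, multiplexed FASTQ with UMIs, barcodes, PCR duplicates and sequencing error — plus full ground truth |
| `abclip.demux` | UMI extraction, barcode assignment (with mismatch tolerance), read orientation, and exact/directional UMI deduplication into *usable reads* |
| `abclip.enrich` | Candidate peaks from clustered truncation sites; 2×2 enrichment against CC / size-matched input / RNA-seq backgrounds (Yates chi-squared with Fisher fallback); significance filter (p < 0.001, fold > 8) and repeat masking |
| `abclip.annotate` | Transcriptomic feature partition (5′UTR/CDS/3′UTR, splice-site windows, proximal/distal intron), peak-to-region assignment, motif scanning, conservation filtering, matched background sampling |
| `abclip.metagene` | Truncation profiles, relative information content (RIC, per-position p·log₂(p/q)), binned mRNA and splice-site peak-density metagenes |
| `abclip.splicing` | Splicing maps: positional odds ratios of significant peaks around differentially spliced cassette exons vs sampled background events |
| `abclip.compare` | Peak-set overlap coefficients, target-gene ranking curves, background-removal concordance, UMI saturation curves |

Everything is available both as a library and through the `abc` command
line (`abc simulate`, `abc demux`, `abc dedup`, `abc enrich`, `abc
filter`, `abc mask`, `abc annotate`, `abc motif`, `abc metagene`, `abc
splice-map`, `abc compare-overlap`, `abc rank`, `abc complexity`).

## Worked example

Simulate a default 3-plex experiment (50,000 reads per RBP, five specific
sites per RBP at enrichment λ = 20, four sites shared by every RBP, one
expected PCR copy per molecule), push it through FASTQ demultiplexing,
directional UMI deduplication, truncation-anchored candidate peaks and
complement-control enrichment:

```python
from abclip.pipeline import run_pipeline, site_recovery
from abclip.simulate import SimConfig

res = run_pipeline(SimConfig(seed=3), via_fastq=True,
                   backgrounds=("cc", "rnaseq"))
print("reads:", len(res.truth))
print("usable:", {r: len(df) for r, df in res.usable.items()})
print("candidate peaks:", len(res.peaks))
print(res.results["cc"].head(5)[["rbp", "chrom", "start", "end", "k_ip",
                                 "k_bg", "fold", "p_value", "test_used"]]
      .to_string(index=False))
print("enriched (cc):", len(res.enriched["cc"]),
      " (rnaseq):", len(res.enriched["rnaseq"]))
print("recovery cc:", site_recovery(res.sites, res.enriched["cc"]))
print("recovery rnaseq:", site_recovery(res.sites, res.enriched["rnaseq"]))
```

Output (deterministic for this seed):

```text
reads: 150000
usable: {'RBP1': 24916, 'RBP2': 24964, 'RBP3': 24938}
candidate peaks: 198
 rbp chrom  start    end  k_ip  k_bg      fold      p_value  test_used
RBP2  chr1 138173 138383   245    24 20.386406 1.000000e-88 chi2_yates
RBP1  chr3 121053 121249   196    25 15.702026 5.356543e-68 chi2_yates
RBP1  chr3 126883 127088   191    24 15.939025 1.568967e-66 chi2_yates
RBP3  chr3 117285 117509   186    21 17.715706 2.584163e-66 chi2_yates
RBP1  chr2 174449 174687   190    25 15.221352 1.901562e-65 chi2_yates
enriched (cc): 15  (rnaseq): 27
recovery cc: {'shared': 0.0, 'specific': 1.0}
recovery rnaseq: {'shared': 1.0, 'specific': 1.0}
```

Two things are worth reading off this run. First, the top peaks recover
the planted sites with fold changes near the simulated λ = 20 and
p-values down to the chi-squared floor of 10⁻⁸⁸. Second, the complement
control rejects **all** shared (every-RBP) sites while the
expression-proportional background passes every one of them — the
direction-of-effect that motivates the CC in the first place.

The same workflow from the shell:

```console
$ printf 'reads_per_rbp: 10000\nseed: 5\n' > config.yaml
$ abc simulate --config config.yaml --outdir sim
wrote 30000 reads, 60 transcripts, 27 truth sites to sim
$ abc demux --fastq sim/reads.fastq.gz --barcodes sim/barcodes.tsv \
      --umi-len 10 --outdir demux
           rbp  n_reads
          RBP1    10159
          RBP2     9990
          RBP3     9851
__unassigned__        0
 __discarded__        0
```

## Reproduction

Run the test suite (unit, property-based and acceptance tests; the
acceptance tests assert the p-value floors, oracle equivalence of the
statistics, end-to-end planted-site recovery, the CC-vs-RNA-seq
direction of effect over ten seeds, UMI-deduplication accuracy, the
formula-level identities and the demultiplexer partition property):

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

Run the headline computations for any seed and dump the quantities as
JSON:

```bash
python scripts/acceptance.py --seed 3 --out acceptance.json
```

This writes the p-value floor constants, the maximum deviations of the
chi-squared/Fisher implementations from hand-coded oracles over 1,000
random tables, end-to-end site recovery under both backgrounds, exact
and directional deduplication accuracy against planted molecule ids (at
mean PCR duplication 0.5 and 1.0 with 1% sequencing error), the toy
odds-ratio and RIC identities, and the metagene normalisation check.
Typical runtime is about half a minute.

Design and numerical details live in `docs/methods.md`.
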