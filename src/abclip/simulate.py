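"""Synthetic ABC library generator with known ground truth.

The simulator emulates the multiplexed antibody-barcode CLIP design: a
small genome with multi-exon transcripts, per-RBP binding sites with a
configurable read-rate multiplier lambda over local background, shared
(all-RBP) sites, expression-proportional nonspecific background, per-RBP
antibody-efficiency skew, crosslink-truncated fragments sequenced on the
reverse strand behind an inline UMI + barcode, and PCR duplication.

Each generative stage draws from its own child RNG stream of the config
seed, so identical configs give byte-identical outputs regardless of which
stages are invoked.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coords import TranscriptCoords
from .model import READ_COLUMNS, TranscriptModel, TruthSite

_STREAM_GENOME = 0
_STREAM_SITES = 1
_STREAM_EXPRESSION = 2
_STREAM_READS = 3
_STREAM_ERRORS = 4
_STREAM_RNASEQ = 5

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_RC = str.maketrans("ACGTN", "TGCAN")


class SimSizingError(ValueError):
    """Chromosomes too short for the requested transcripts."""


class SitePlacementError(RuntimeError):
    """Could not place the requested sites after bounded retries."""


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def default_barcodes(n: int, length: int = 6, min_dist: int = 3) -> list[str]:
    """Deterministic barcode set with pairwise Hamming distance >= min_dist."""
    chosen: list[str] = []
    for tup in itertools.product("ACGT", repeat=length):
        cand = "".join(tup)
        if all(hamming(cand, c) >= min_dist for c in chosen):
            chosen.append(cand)
            if len(chosen) == n:
                return chosen
    raise ValueError(f"cannot build {n} barcodes of length {length}")


@dataclass
class SimConfig:
    """Study conditions for one simulated multiplexed ABC experiment.

    Defaults describe a 3-plex at 50,000 reads per RBP with 5 specific
    sites per RBP at lambda=20, 4 shared sites bound equally by every RBP,
    and one expected PCR copy per molecule.
    """

    chrom_lengths: tuple[int, ...] = (260_000, 260_000, 260_000)
    n_transcripts: int = 60
    exon_count_range: tuple[int, int] = (2, 8)
    exon_length: tuple[float, float] = (200.0, 80.0)   # mean, sd (bp), min 50
    intron_length: tuple[float, float] = (2250.0, 900.0)  # min 300
    histone_fraction: float = 0.1
    histone_length: int = 400
    n_rbps: int = 3
    rbp_names: tuple[str, ...] = ()
    barcode_length: int = 6
    umi_length: int = 10
    sites_per_rbp: int = 5
    site_length: int = 200
    site_enrichment: float = 20.0     # lambda for specific sites
    site_feature_class: str = "any"   # any | intron | exon | 3utr
    n_shared_sites: int = 4
    shared_enrichment: float = 20.0
    site_min_gap: int = 500
    efficiency: tuple[float, ...] = ()   # relative library share per RBP
    expression_sigma: float = 0.3        # lognormal sd of per-transcript expression
    reads_per_rbp: int = 50_000
    pcr_duplication: float = 1.0         # mean extra copies per molecule
    fragment_length: tuple[float, float] = (60.0, 15.0)
    fragment_min: int = 25
    layout: str = "umi_first"            # umi_first | barcode_first
    error_rate: float = 0.0              # uniform substitution rate
    seed: int = 0
    barcodes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.n_rbps < 1:
            raise ValueError("need at least one RBP")
        if self.site_enrichment < 1 or self.shared_enrichment < 1:
            raise ValueError("site enrichment multiplier lambda must be >= 1")
        if self.reads_per_rbp < 0 or self.pcr_duplication < 0 or self.error_rate < 0:
            raise ValueError("rates and counts must be non-negative")
        if self.layout not in ("umi_first", "barcode_first"):
            raise ValueError(f"unknown read layout {self.layout!r}")
        if not self.rbp_names:
            self.rbp_names = tuple(f"RBP{i + 1}" for i in range(self.n_rbps))
        if len(self.rbp_names) != self.n_rbps:
            raise ValueError("rbp_names length must equal n_rbps")
        if not self.efficiency:
            self.efficiency = (1.0,) * self.n_rbps
        if len(self.efficiency) != self.n_rbps or sum(self.efficiency) <= 0:
            raise ValueError("efficiency must be positive per RBP")
        if not self.barcodes:
            self.barcodes = tuple(default_barcodes(self.n_rbps, self.barcode_length))
        if len(set(self.barcodes)) != self.n_rbps:
            raise ValueError("barcodes must be distinct, one per RBP")
        if any(len(b) != self.barcode_length for b in self.barcodes):
            raise ValueError("barcode length mismatch")
        for a, b in itertools.combinations(self.barcodes, 2):
            if hamming(a, b) < 2:
                raise ValueError("barcodes must be pairwise Hamming distance >= 2")

    def barcode_table(self) -> dict[str, str]:
        return dict(zip(self.barcodes, self.rbp_names))

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Genome and annotation

def make_genome(config: SimConfig) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Random genome plus non-overlapping transcript models.

    Transcripts are laid out sequentially across chromosomes with random
    intergenic gaps and alternating strands; a ``histone_fraction`` subset
    is emitted as short single-exon genes labelled ``histone_like``.
    """
    rng = config._rng(_STREAM_GENOME)
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    genome = {name: _random_seq(rng, L)
              for name, L in zip(chrom_names, config.chrom_lengths)}

    cursors = {name: int(rng.integers(200, 1000)) for name in chrom_names}
    n_hist = int(round(config.histone_fraction * config.n_transcripts))
    models: list[TranscriptModel] = []
    for i in range(config.n_transcripts):
        histone = i < n_hist
        strand = "+" if i % 2 == 0 else "-"
        if histone:
            exon_lens = [config.histone_length]
            intron_lens: list[int] = []
        else:
            n_ex = int(rng.integers(config.exon_count_range[0],
                                    config.exon_count_range[1] + 1))
            exon_lens = np.maximum(
                50, rng.normal(*config.exon_length, n_ex).round()).astype(int).tolist()
            intron_lens = np.maximum(
                300, rng.normal(*config.intron_length, n_ex - 1).round()).astype(int).tolist()
        span = sum(exon_lens) + sum(intron_lens)
        gap = int(rng.integers(500, 2000))

        placed = None
        for chrom in sorted(chrom_names, key=lambda c: cursors[c]):
            limit = config.chrom_lengths[chrom_names.index(chrom)] - 200
            if cursors[chrom] + span <= limit:
                placed = chrom
                break
        if placed is None:
            raise SimSizingError(
                f"chromosomes too short: transcript {i} (span {span} bp) does not fit")
        start = cursors[placed]
        cursors[placed] = start + span + gap

        exons = []
        pos = start
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el + (intron_lens[j] if j < len(intron_lens) else 0)

        model = TranscriptModel(
            gene_id=f"gene{i + 1}", transcript_id=f"tx{i + 1}", chrom=placed,
            strand=strand, exons=exons,
            gene_class="histone_like" if histone else "protein_coding",
        )
        # CDS spans the spliced interior, leaving 5'/3' UTRs.
        coords = TranscriptCoords(model)
        sl = coords.length
        u5 = max(1, min(150, sl // 10))
        u3 = max(1, min(300, sl // 5))
        model.cds = coords.genomic_intervals(u5, sl - u3)
        models.append(model)
    return genome, models


# ---------------------------------------------------------------------------
# Site planting

def _allowed_intervals(model: TranscriptModel, feature_class: str) -> list[tuple[int, int]]:
    if feature_class == "any":
        return [(model.start, model.end)]
    if feature_class == "intron":
        return model.introns
    if feature_class == "exon":
        return list(model.exons)
    if feature_class == "3utr":
        return model.utr3
    raise ValueError(f"unknown site feature class {feature_class!r}")


def plant_sites(models: list[TranscriptModel], config: SimConfig) -> list[TruthSite]:
    """Plant shared and per-RBP specific binding sites.

    All planted intervals (across every RBP) are pairwise separated by at
    least ``site_min_gap`` bp so that candidate-peak clusters stay distinct.
    Shared sites are listed once per RBP with identical coordinates.
    """
    if not models:
        raise ValueError("no transcript models")
    rng = config._rng(_STREAM_SITES)
    occupied: list[tuple[str, int, int]] = []

    def _overlaps_occupied(chrom: str, s: int, e: int) -> bool:
        pad = config.site_min_gap
        return any(c == chrom and s - pad < oe and os_ < e + pad
                   for c, os_, oe in occupied)

    def _place_one(feature_class: str) -> tuple[TranscriptModel, int, int]:
        for _ in range(500):
            m = models[int(rng.integers(len(models)))]
            ivs = [iv for iv in _allowed_intervals(m, feature_class)
                   if iv[1] - iv[0] >= config.site_length]
            if not ivs:
                continue
            s0, e0 = ivs[int(rng.integers(len(ivs)))]
            start = int(rng.integers(s0, e0 - config.site_length + 1))
            end = start + config.site_length
            if not _overlaps_occupied(m.chrom, start, end):
                occupied.append((m.chrom, start, end))
                return m, start, end
        raise SitePlacementError("could not place site after bounded retries")

    sites: list[TruthSite] = []
    for j in range(config.n_shared_sites):
        m, s, e = _place_one(config.site_feature_class)
        for rbp in config.rbp_names:
            sites.append(TruthSite(rbp, m.chrom, s, e, m.strand,
                                   config.shared_enrichment, "shared",
                                   m.transcript_id))
    for rbp in config.rbp_names:
        for j in range(config.sites_per_rbp):
            m, s, e = _place_one(config.site_feature_class)
            sites.append(TruthSite(rbp, m.chrom, s, e, m.strand,
                                   config.site_enrichment, "specific",
                                   m.transcript_id))
    return sites


def transcript_expression(models: list[TranscriptModel], config: SimConfig) -> np.ndarray:
    """Per-transcript relative expression (lognormal, unit median)."""
    rng = config._rng(_STREAM_EXPRESSION)
    return rng.lognormal(0.0, config.expression_sigma, len(models))


# ---------------------------------------------------------------------------
# Read generation

def _umi_strings(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if length == 0:
        return [""] * n
    arr = _BASES[rng.integers(0, 4, (n, length))]
    return [row.tobytes().decode() for row in arr]


def _segments_for_rbp(models, expression, rbp_sites) -> pd.DataFrame:
    """Piecewise-constant sampling weights along every transcript span.

    Background weight is the transcript expression; inside this RBP's
    sites it is multiplied by the site's lambda.
    """
    rows = []
    by_tx: dict[str, list[TruthSite]] = {}
    for s in rbp_sites:
        by_tx.setdefault(s.transcript_id, []).append(s)
    for ti, m in enumerate(models):
        cuts = sorted((s.start, s.end, s.enrichment) for s in by_tx.get(m.transcript_id, []))
        pos = m.start
        for cs, ce, lam in cuts:
            if cs > pos:
                rows.append((ti, pos, cs, expression[ti]))
            rows.append((ti, cs, ce, expression[ti] * lam))
            pos = ce
        if pos < m.end:
            rows.append((ti, pos, m.end, expression[ti]))
    seg = pd.DataFrame(rows, columns=["tx", "start", "end", "rate"])
    seg["weight"] = (seg["end"] - seg["start"]) * seg["rate"]
    return seg


def _fragments(rng, positions, strands, chrom_lens, config):
    n = len(positions)
    L = np.maximum(config.fragment_min,
                   rng.normal(*config.fragment_length, n).round()).astype(np.int64)
    plus = strands == "+"
    starts = np.where(plus, positions, positions + 1 - L)
    ends = np.where(plus, positions + L, positions + 1)
    starts = np.maximum(starts, 0)
    ends = np.minimum(ends, chrom_lens)
    # keep the crosslink inside even at chromosome edges
    starts = np.minimum(starts, positions)
    ends = np.maximum(ends, positions + 1)
    return starts, ends


def generate_reads(models: list[TranscriptModel], sites: list[TruthSite],
                   config: SimConfig) -> pd.DataFrame:
    """Simulate the multiplexed library at alignment level (truth table).

    Each read records its RBP, UMI, genomic interval, strand, crosslink
    truncation site and molecule id; PCR copies share UMI and coordinates.
    Total reads equal ``reads_per_rbp * n_rbps``, split across RBPs by the
    antibody-efficiency weights.
    """
    rng = config._rng(_STREAM_READS)
    expression = transcript_expression(models, config)
    total = config.reads_per_rbp * config.n_rbps
    if total == 0:
        return pd.DataFrame(columns=READ_COLUMNS)
    eff = np.asarray(config.efficiency, dtype=float)
    per_rbp = rng.multinomial(total, eff / eff.sum())

    chrom_len = {f"chr{i + 1}": L for i, L in enumerate(config.chrom_lengths)}
    tx_chrom = np.array([m.chrom for m in models])
    tx_strand = np.array([m.strand for m in models])

    frames = []
    mol_counter = 0
    read_counter = 0
    for r_idx, rbp in enumerate(config.rbp_names):
        n_reads = int(per_rbp[r_idx])
        if n_reads == 0:
            continue
        # molecule copy counts: 1 + Poisson(d), truncated to hit n_reads exactly
        copies = np.array([], dtype=np.int64)
        while copies.sum() < n_reads:
            extra = 1 + rng.poisson(config.pcr_duplication,
                                    max(16, int(n_reads / (1 + config.pcr_duplication))))
            copies = np.concatenate([copies, extra])
        cum = np.cumsum(copies)
        m_idx = int(np.searchsorted(cum, n_reads))
        copies = copies[: m_idx + 1]
        copies[-1] -= int(cum[m_idx] - n_reads)
        if copies[-1] == 0:
            copies = copies[:-1]
        n_mol = len(copies)

        seg = _segments_for_rbp(models, expression,
                                [s for s in sites if s.rbp == rbp])
        w = seg["weight"].to_numpy()
        sel = rng.choice(len(seg), size=n_mol, p=w / w.sum())
        seg_start = seg["start"].to_numpy()[sel]
        seg_len = (seg["end"] - seg["start"]).to_numpy()[sel]
        positions = seg_start + (rng.random(n_mol) * seg_len).astype(np.int64)
        tx = seg["tx"].to_numpy()[sel]
        strands = tx_strand[tx]
        chroms = tx_chrom[tx]
        clens = np.array([chrom_len[c] for c in chroms])
        starts, ends = _fragments(rng, positions, strands, clens, config)
        umis = _umi_strings(rng, n_mol, config.umi_length)
        mol_ids = np.arange(mol_counter, mol_counter + n_mol)
        mol_counter += n_mol

        rep = np.repeat(np.arange(n_mol), copies)
        n_r = len(rep)
        frame = pd.DataFrame({
            "read_id": [f"r{j:08d}" for j in range(read_counter, read_counter + n_r)],
            "rbp": rbp,
            "umi": np.array(umis, dtype=object)[rep],
            "chrom": chroms[rep],
            "start": starts[rep],
            "end": ends[rep],
            "strand": strands[rep],
            "truncation": np.where(strands[rep] == "+", starts[rep], ends[rep] - 1),
            "molecule_id": mol_ids[rep],
        })
        read_counter += n_r
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)[READ_COLUMNS]


def generate_expression_background(models: list[TranscriptModel], config: SimConfig,
                                   n_reads: int) -> pd.DataFrame:
    """RNA-seq-style background: reads proportional to expression only.

    No binding sites, no PCR duplication; every read is its own molecule.
    """
    rng = config._rng(_STREAM_RNASEQ)
    if n_reads == 0:
        return pd.DataFrame(columns=READ_COLUMNS)
    expression = transcript_expression(models, config)
    spans = np.array([m.span for m in models], dtype=float)
    w = spans * expression
    tx = rng.choice(len(models), size=n_reads, p=w / w.sum())
    tx_start = np.array([m.start for m in models])[tx]
    tx_span = spans.astype(np.int64)[tx]
    positions = tx_start + (rng.random(n_reads) * tx_span).astype(np.int64)
    strands = np.array([m.strand for m in models])[tx]
    chroms = np.array([m.chrom for m in models])[tx]
    chrom_len = {f"chr{i + 1}": L for i, L in enumerate(config.chrom_lengths)}
    clens = np.array([chrom_len[c] for c in chroms])
    starts, ends = _fragments(rng, positions, strands, clens, config)
    return pd.DataFrame({
        "read_id": [f"q{j:08d}" for j in range(n_reads)],
        "rbp": "rnaseq",
        "umi": _umi_strings(rng, n_reads, config.umi_length),
        "chrom": chroms, "start": starts, "end": ends, "strand": strands,
        "truncation": np.where(strands == "+", starts, ends - 1),
        "molecule_id": np.arange(n_reads),
    })[READ_COLUMNS]


# ---------------------------------------------------------------------------
# FASTQ emission

def reads_to_fastq_records(genome: dict[str, str], truth: pd.DataFrame,
                           config: SimConfig) -> list[tuple[str, str, str]]:
    """Render truth reads as sequenced records.

    ABC libraries are sequenced on the reverse strand: the insert is the
    reverse complement of the transcribed fragment, behind an inline
    (5') UMI and barcode whose order follows ``config.layout``.
    """
    bc_of = {rbp: bc for bc, rbp in config.barcode_table().items()}
    rng_err = config._rng(_STREAM_ERRORS)
    records = []
    rows = zip(truth["read_id"], truth["rbp"], truth["umi"], truth["chrom"],
               truth["start"], truth["end"], truth["strand"])
    for rid, rbp, umi, chrom, start, end, strand in rows:
        frag = genome[chrom][start:end]
        sense = frag if strand == "+" else reverse_complement(frag)
        insert = reverse_complement(sense)
        if config.layout == "umi_first":
            seq = umi + bc_of[rbp] + insert
        else:
            seq = bc_of[rbp] + umi + insert
        if config.error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hit = np.nonzero(rng_err.random(len(arr)) < config.error_rate)[0]
            if len(hit):
                shift = rng_err.integers(1, 4, len(hit))
                lut = np.zeros(256, dtype=np.uint8)
                for i, b in enumerate(b"ACGT"):
                    lut[b] = i
                arr[hit] = np.frombuffer(b"ACGT", dtype=np.uint8)[
                    (lut[arr[hit]] + shift) % 4]
            seq = arr.tobytes().decode()
        records.append((rid, seq, "I" * len(seq)))
    return records


def generate_multiplex(genome: dict[str, str], models: list[TranscriptModel],
                       sites: list[TruthSite], config: SimConfig,
                       ) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Full simulation: FASTQ records plus the truth aligned-read table."""
    truth = generate_reads(models, sites, config)
    return reads_to_fastq_records(genome, truth, config), truth
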