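"""Core domain types shared across the package.

All genomic coordinates are 0-based half-open (`[start, end)`), matching BED
on disk.  Aligned reads and peaks move between functions as pandas
DataFrames with the fixed column sets below; the dataclasses are the
record-level view used at API edges and in tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

#: Column order of an aligned-read table. ``truncation`` is the strand-aware
#: 5' end of the fragment (crosslink-proximal base): ``start`` on '+',
#: ``end - 1`` on '-'.  ``molecule_id`` is simulator ground truth (-1 when
#: unknown).
READ_COLUMNS = [
    "read_id", "rbp", "umi", "chrom", "start", "end", "strand",
    "truncation", "molecule_id",
]

#: Column order of a peak table (BED6-compatible prefix + the owning RBP).
PEAK_COLUMNS = ["chrom", "start", "end", "peak_id", "score", "strand", "rbp"]


@dataclass(frozen=True)
class AlignedRead:
    """One deduplicable sequencing fragment."""

    read_id: str
    rbp: str
    umi: str
    chrom: str
    start: int
    end: int
    strand: str
    molecule_id: int = -1

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval for {self.read_id}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def truncation(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def reads_to_frame(reads: Iterable[AlignedRead] | pd.DataFrame) -> pd.DataFrame:
    """Coerce an iterable of :class:`AlignedRead` (or a frame) to a read table."""
    if isinstance(reads, pd.DataFrame):
        missing = [c for c in READ_COLUMNS if c not in reads.columns and c != "molecule_id"]
        if missing:
            raise ValueError(f"read table missing columns: {missing}")
        out = reads.copy()
        if "molecule_id" not in out.columns:
            out["molecule_id"] = -1
        return out[READ_COLUMNS]
    rows = [
        (r.read_id, r.rbp, r.umi, r.chrom, r.start, r.end, r.strand,
         r.truncation, r.molecule_id)
        for r in reads
    ]
    return pd.DataFrame(rows, columns=READ_COLUMNS)


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    strand: str
    rbp: str = "."
    peak_id: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("empty peak interval")

    def __len__(self) -> int:
        return self.end - self.start


def peaks_to_frame(peaks: Iterable[Peak] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(peaks, pd.DataFrame):
        out = peaks.copy()
        if "rbp" not in out.columns:
            out["rbp"] = "."
        if "score" not in out.columns:
            out["score"] = 0
        if "peak_id" not in out.columns:
            out["peak_id"] = [f"peak_{i}" for i in range(len(out))]
        return out[PEAK_COLUMNS]
    rows = [
        (p.chrom, p.start, p.end, p.peak_id, 0, p.strand, p.rbp) for p in peaks
    ]
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` and ``cds`` are sorted, non-overlapping genomic intervals.
    UTRs, introns and splice sites are derived on demand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    gene_class: str = "protein_coding"

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for (s, e) in self.exons:
            if not s < e:
                raise ValueError("empty exon")
        for a, b in zip(self.exons, self.exons[1:]):
            if a[1] > b[0]:
                raise ValueError("overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]) if a[1] < b[0]
        ]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def _exonic_outside_cds(self, side: str) -> list[tuple[int, int]]:
        """Exonic intervals 5' ('left' of CDS) or 3' of the CDS in genomic order."""
        if not self.cds:
            return []
        cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
        out: list[tuple[int, int]] = []
        for s, e in self.exons:
            if side == "left" and s < cds_lo:
                out.append((s, min(e, cds_lo)))
            elif side == "right" and e > cds_hi:
                out.append((max(s, cds_hi), e))
        return out

    @property
    def utr5(self) -> list[tuple[int, int]]:
        side = "left" if self.strand == "+" else "right"
        return self._exonic_outside_cds(side)

    @property
    def utr3(self) -> list[tuple[int, int]]:
        side = "right" if self.strand == "+" else "left"
        return self._exonic_outside_cds(side)


@dataclass(frozen=True)
class TruthSite:
    """Simulator ground truth: a planted binding interval."""

    rbp: str
    chrom: str
    start: int
    end: int
    strand: str
    enrichment: float  # read-rate multiplier inside the site (lambda >= 1)
    kind: str = "specific"  # specific | shared
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("empty site")
        if self.enrichment < 1:
            raise ValueError("site enrichment multiplier must be >= 1")


TRUTH_SITE_COLUMNS = [
    "chrom", "start", "end", "rbp", "enrichment", "strand", "kind",
    "transcript_id",
]


def sites_to_frame(sites: Sequence[TruthSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.chrom, s.start, s.end, s.rbp, s.enrichment, s.strand, s.kind,
          s.transcript_id) for s in sites],
        columns=TRUTH_SITE_COLUMNS,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-peak 2x2 enrichment against a background library."""

    peak_id: str
    k_ip: int
    n_ip: int
    k_bg: int
    n_bg: int
    fold: float
    p_value: float
    test_used: str  # chi2_yates | fisher
    bg_kind: str  # cc | smi | rnaseq
    fold_floored: bool = False


#: Cassette-exon region labels in 5'->3' transcript order.
CASSETTE_REGIONS = [
    "upstream_exon", "upstream_intron", "cassette_exon",
    "downstream_intron", "downstream_exon",
]


@dataclass(frozen=True)
class CassetteEvent:
    """A skipped-exon event with its five flanking regions.

    Regions are genomic intervals; 'upstream' means 5' on the transcript
    strand, so on '-' the genomic order is reversed.
    """

    event_id: str
    chrom: str
    strand: str
    upstream_exon: tuple[int, int]
    upstream_intron: tuple[int, int]
    cassette_exon: tuple[int, int]
    downstream_intron: tuple[int, int]
    downstream_exon: tuple[int, int]
    event_class: str = "background"  # included_on_KD | excluded_on_KD | background

    def region(self, label: str) -> tuple[int, int]:
        if label not in CASSETTE_REGIONS:
            raise KeyError(label)
        return getattr(self, label)


@dataclass(frozen=True)
class MotifSite:
    chrom: str
    start: int
    end: int
    strand: str
    motif: str
    mean_conservation: float = float("nan")


@dataclass
class MetageneProfile:
    """A per-position metagene vector.

    ``system`` is one of ``transcript`` (per-base), ``mrna_bins`` (binned
    5'UTR/CDS/3'UTR) or ``splice_window`` (bp offsets around a splice site).
    Density variants sum to 1; RIC variants hold bits.
    """

    system: str
    positions: "pd.Index | list"
    values: "object"  # numpy array
    n_units: int
    se: "object | None" = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"position": list(self.positions), "value": self.values})
        if self.se is not None:
            out["se"] = self.se
        return out
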