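"""Domain types shared across the pipeline.

Coordinate convention: all genomic intervals are 0-based half-open
``[start, end)``.  GTF input (1-based inclusive) is converted at the
parsing boundary and never leaks inward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

Interval = tuple[int, int]


class SpliceForgeError(Exception):
    """Base class for hard errors raised by the pipeline."""


class InvariantError(SpliceForgeError):
    """A domain-type invariant was violated."""


@dataclass
class GenomeSequence:
    """One chromosome: identifier plus uppercase nucleotide string."""

    chrom: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvariantError(f"chromosome {self.chrom!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Return exactly ``end - start`` bases of the 0-based half-open interval."""
        if start < 0 or end > len(self.sequence) or start > end:
            raise SpliceForgeError(
                f"interval [{start}, {end}) outside chromosome {self.chrom!r} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[start:end]


@dataclass
class TranscriptModel:
    """A transcript as an ordered chain of genomic exon intervals.

    ``tsl`` is the Ensembl Transcript Support Level (1 best .. 5 worst,
    ``None`` when unannotated); ``appris`` holds the APPRIS principal/
    alternative tag; ``havana`` marks manual (HAVANA) annotation.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    gene_symbol: str = ""
    biotype: str = ""
    tsl: Optional[int] = None
    appris: Optional[str] = None
    havana: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvariantError(
                f"transcript {self.transcript_id!r}: strand must be '+' or '-'"
            )
        if not self.exons:
            raise InvariantError(f"transcript {self.transcript_id!r} has no exons")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise InvariantError(
                    f"transcript {self.transcript_id!r}: empty exon [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise InvariantError(
                    f"transcript {self.transcript_id!r} has overlapping or "
                    f"unsorted exons"
                )
            prev_end = end
        if self.tsl is not None and not 1 <= self.tsl <= 5:
            raise InvariantError(
                f"transcript {self.transcript_id!r}: TSL {self.tsl} outside 1..5"
            )

    @property
    def length(self) -> int:
        """Spliced transcript length (sum of exon widths), nucleotides."""
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    def exons_tx_order(self) -> list[Interval]:
        """Exons in transcript (5'→3') order: reversed genomic order on '-'."""
        return list(self.exons) if self.strand == "+" else list(reversed(self.exons))


@dataclass
class GeneModel:
    """All transcripts of one gene; one chromosome, one orientation."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise InvariantError(f"gene {self.gene_id!r} has no transcripts")
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise InvariantError(
                    f"gene {self.gene_id!r}: transcript {t.transcript_id!r} on "
                    f"{t.chrom}{t.strand}, gene on {self.chrom}{self.strand} "
                    f"(mixed-strand genes are rejected)"
                )

    @property
    def span(self) -> Interval:
        return (
            min(t.exons[0][0] for t in self.transcripts),
            max(t.exons[-1][1] for t in self.transcripts),
        )


@dataclass
class PslAlignment:
    """One row of a BLAT PSL file (subset of columns the pipeline uses)."""

    query_id: str
    target_chrom: str
    strand: str
    matches: int
    mismatches: int
    q_size: int
    block_count: int
    block_sizes: list[int]
    q_starts: list[int]
    t_starts: list[int]

    def __post_init__(self) -> None:
        if sorted(self.t_starts) != self.t_starts:
            raise InvariantError(
                f"PSL {self.query_id!r}: target block starts not ascending"
            )
        if self.matches + self.mismatches > self.q_size:
            raise InvariantError(
                f"PSL {self.query_id!r}: matches + mismatches exceed query size"
            )

    @property
    def score(self) -> int:
        return self.matches - self.mismatches


@dataclass
class PSMRecord:
    """One peptide-spectrum match row from a search-engine result table."""

    peptide: str
    protein_ids: list[str]
    primary_score: float
    delta_cn: float
    ms1: float

    def __post_init__(self) -> None:
        if not self.peptide:
            raise InvariantError("PSM record with empty peptide")
        if not self.protein_ids:
            raise InvariantError(f"PSM for {self.peptide!r} lists no proteins")


@dataclass
class Proteoform:
    """One in-silico translated splice variant.

    ``orf_start``/``orf_end`` are 0-based cDNA offsets of the coding
    region (stop codon excluded); ``frame`` is ``orf_start % 3``.
    """

    protein_id: str
    gene_id: str
    transcript_id: str
    sequence: str
    frame: int = 0
    orf_start: int = 0
    orf_end: int = 0
    met_corrected: bool = False
    has_stop: bool = False
    translatable: bool = True
    canonical: bool = False
    nmd_target: bool = False

    def __post_init__(self) -> None:
        if self.translatable:
            if (self.orf_end - self.orf_start) % 3:
                raise InvariantError(
                    f"{self.protein_id!r}: ORF length not a multiple of 3"
                )
            if len(self.sequence) != (self.orf_end - self.orf_start) // 3:
                raise InvariantError(
                    f"{self.protein_id!r}: sequence length disagrees with ORF span"
                )
            if self.sequence and not self.sequence.startswith("M"):
                raise InvariantError(
                    f"{self.protein_id!r}: translated sequence must start with M"
                )
        if "*" in self.sequence:
            raise InvariantError(
                f"{self.protein_id!r}: internal stop character in sequence"
            )


@dataclass
class NMDVerdict:
    """Premature-termination-codon call for one transcript."""

    transcript_id: str
    is_target: bool
    stop_tx_pos: Optional[int] = None
    last_junction_tx_pos: Optional[int] = None
    junction_distance: Optional[int] = None
    event: str = "none"


@dataclass
class AlignmentResult:
    """Metrics of one global pairwise protein alignment."""

    query_id: str
    target_id: str
    score: float
    identity_pct: float
    similarity_pct: float
    gap_fraction: float
    query_coverage_pct: float
    target_coverage_pct: float
    aligned_query: str = ""
    aligned_target: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= self.similarity_pct <= 100.0 + 1e-9:
            raise InvariantError("identity/similarity outside [0, 100] ordering")
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise InvariantError("gap fraction outside [0, 1]")


@dataclass
class OrthologPair:
    species_a_protein: str
    species_b_protein: str
    gene_pair: tuple[str, str]
    method: str  # "needle" | "rbh"
    metrics: AlignmentResult

    def key(self) -> tuple[str, str]:
        return self.species_a_protein, self.species_b_protein


@dataclass(frozen=True, order=True)
class OrthologTriad:
    protein_a: str
    protein_b: str
    protein_c: str
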