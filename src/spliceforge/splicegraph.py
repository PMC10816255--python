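"""Per-gene ternary splicing matrices and splice-variant reconstruction.

A gene's transcripts are projected onto a common segmentation of the gene
span: segment boundaries are the union of all exon starts/ends, so every
exon edge of every transcript falls on a segment boundary.  Each
transcript then becomes a row over the alphabet ``{'1', '0', '|'}``:

* ``'1'`` — the segment lies inside an exon of this transcript;
* ``'0'`` — the segment is exonic in at least one other transcript of the
  gene but absent from this one (an alternatively spliced region);
* ``'|'`` — the segment is intronic in every transcript of the gene, so
  the column is constant down the matrix.

Under this encoding the exon chain of every transcript is recoverable as
the maximal genomically contiguous runs of ``'1'`` columns, which makes
the matrix an exact, invertible summary of the gene's splicing patterns.

Transcripts sharing a row string form one splice variant; the most
reliable member (manual HAVANA annotation of a protein-coding biotype,
then lowest TSL, then best APPRIS tag, then longest, then smallest id)
represents the variant in translation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .models import (
    GeneModel,
    GenomeSequence,
    Interval,
    SpliceForgeError,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SegmentPartition:
    """Contiguous segments covering a gene span, labeled exonic/intronic."""

    gene_id: str
    segments: list[Interval]
    exonic: list[bool]  # per segment: inside >=1 transcript's exon?

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class TernaryMatrix:
    gene_id: str
    row_ids: list[str]
    partition: SegmentPartition
    rows: list[str]

    def row(self, transcript_id: str) -> str:
        return self.rows[self.row_ids.index(transcript_id)]

    def as_text(self) -> str:
        return "\n".join(f"{tid}\t{row}" for tid, row in zip(self.row_ids, self.rows))


@dataclass
class SpliceVariant:
    gene_id: str
    pattern: str
    member_ids: list[str]
    representative_id: str = ""
    exons: list[Interval] = field(default_factory=list)
    cdna: str = ""


def segment_gene(gene: GeneModel) -> SegmentPartition:
    """Partition the gene span at the union of all exon boundaries."""
    boundaries: set[int] = set()
    for tx in gene.transcripts:
        for start, end in tx.exons:
            boundaries.add(start)
            boundaries.add(end)
    cuts = sorted(boundaries)
    segments = list(zip(cuts, cuts[1:]))
    exonic = []
    for seg_start, seg_end in segments:
        inside = any(
            s <= seg_start and seg_end <= e
            for tx in gene.transcripts
            for s, e in tx.exons
        )
        exonic.append(inside)
    return SegmentPartition(gene_id=gene.gene_id, segments=segments, exonic=exonic)


def build_ternary_matrix(gene: GeneModel) -> TernaryMatrix:
    """Encode every transcript of the gene as a ternary row string."""
    part = segment_gene(gene)
    rows = []
    for tx in gene.transcripts:
        chars = []
        for (seg_start, seg_end), is_exonic in zip(part.segments, part.exonic):
            if not is_exonic:
                chars.append("|")
            elif any(s <= seg_start and seg_end <= e for s, e in tx.exons):
                chars.append("1")
            else:
                chars.append("0")
        rows.append("".join(chars))
    return TernaryMatrix(
        gene_id=gene.gene_id,
        row_ids=[tx.transcript_id for tx in gene.transcripts],
        partition=part,
        rows=rows,
    )


def exons_from_row(matrix: TernaryMatrix, row: str) -> list[Interval]:
    """Invert one matrix row to its exon chain.

    Exons are the maximal genomically contiguous runs of '1' columns:
    adjacent '1' segments merge into one exon.
    """
    exons: list[Interval] = []
    for (seg_start, seg_end), char in zip(matrix.partition.segments, row):
        if char != "1":
            continue
        if exons and exons[-1][1] == seg_start:
            exons[-1] = (exons[-1][0], seg_end)
        else:
            exons.append((seg_start, seg_end))
    return exons


def cluster_splice_patterns(matrix: TernaryMatrix) -> list[SpliceVariant]:
    """Group transcripts sharing an identical row string into variants."""
    variants: dict[str, SpliceVariant] = {}
    order: list[str] = []
    for tid, row in zip(matrix.row_ids, matrix.rows):
        if row not in variants:
            variants[row] = SpliceVariant(
                gene_id=matrix.gene_id, pattern=row, member_ids=[]
            )
            order.append(row)
        variants[row].member_ids.append(tid)
    return [variants[row] for row in order]


_APPRIS_WORST = 99


def _appris_rank(tag: Optional[str]) -> int:
    """principal1 < ... < principal5 < alternative1 < alternative2 < absent."""
    if not tag:
        return _APPRIS_WORST
    tag = tag.lower()
    for prefix, offset in (("principal", 0), ("alternative", 10)):
        if tag.startswith(prefix):
            suffix = tag[len(prefix) :].lstrip("_:")
            try:
                return offset + int(suffix)
            except ValueError:
                return offset + 9
    return _APPRIS_WORST


def _reliability_key(tx: TranscriptModel) -> tuple:
    coding_havana = tx.biotype == "protein_coding" and tx.havana
    return (
        not coding_havana,
        tx.tsl if tx.tsl is not None else 6,
        _appris_rank(tx.appris),
        -tx.length,
        tx.transcript_id,
    )


def select_representative(
    variant: SpliceVariant, transcripts: Mapping[str, TranscriptModel]
) -> str:
    """Choose the most reliable member transcript of a variant.

    Priority: protein-coding + HAVANA-annotated, then lowest TSL (absent
    ranks below TSL 5), then best APPRIS tag, then greatest spliced
    length, then smallest transcript id.  Deterministic and invariant
    under permutation of the members.
    """
    if not variant.member_ids:
        raise SpliceForgeError(f"variant of {variant.gene_id!r} has no members")
    return min(variant.member_ids, key=lambda tid: _reliability_key(transcripts[tid]))


def consensus_coordinates(gene: GeneModel, mode: str = "tsl") -> Interval:
    """Outer (start, end) genomic coordinates from the gene's reference transcript.

    ``mode='tsl'`` picks the lowest-TSL transcript (human/mouse usage);
    ``mode='appris'`` the best APPRIS tag (rat usage).  When no transcript
    carries the flag, the longest transcript (smallest id on ties) is the
    reference.
    """
    if mode not in ("tsl", "appris"):
        raise SpliceForgeError(f"unknown consensus mode {mode!r}")

    def key(tx: TranscriptModel) -> tuple:
        if mode == "tsl":
            flag = tx.tsl if tx.tsl is not None else float("inf")
        else:
            flag = _appris_rank(tx.appris)
            if flag == _APPRIS_WORST:
                flag = float("inf")
        return (flag, -tx.length, tx.transcript_id)

    ref = min(gene.transcripts, key=key)
    return ref.exons[0][0], ref.exons[-1][1]


def apply_consensus(exons: Sequence[Interval], consensus: Interval) -> list[Interval]:
    """Extend the first/last exon to the consensus outer coordinates.

    Extension only: a consensus narrower than the variant span leaves the
    chain unchanged (logged).  Internal splice junctions are never moved.
    """
    if not exons:
        raise SpliceForgeError("apply_consensus called with empty exon chain")
    outer_start, outer_end = consensus
    adjusted = [tuple(e) for e in exons]
    first_start, first_end = adjusted[0]
    last_start, last_end = adjusted[-1]
    if outer_start < first_start:
        adjusted[0] = (outer_start, first_end)
    elif outer_start > first_start:
        logger.info(
            "consensus start %d inside variant span (first exon at %d); not trimmed",
            outer_start,
            first_start,
        )
    if outer_end > last_end:
        adjusted[-1] = (adjusted[-1][0], outer_end)
    elif outer_end < last_end:
        logger.info(
            "consensus end %d inside variant span (last exon ends %d); not trimmed",
            outer_end,
            last_end,
        )
    return [tuple(e) for e in adjusted]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def reconstruct_cdna(
    exons: Sequence[Interval], chromosome: GenomeSequence, strand: str
) -> str:
    """Splice exon sequences out of the genome; reverse-complement on '-'.

    Exons are given in genomic order; the concatenation is performed in
    genomic order and the whole string reverse-complemented for minus-
    strand transcripts.
    """
    if not exons:
        raise SpliceForgeError("reconstruct_cdna called with empty exon chain")
    parts = [chromosome.fetch(start, end) for start, end in exons]
    cdna = "".join(parts)
    if strand == "-":
        cdna = reverse_complement(cdna)
    return cdna


def build_gene_variants(
    gene: GeneModel,
    genome: Mapping[str, GenomeSequence],
    mode: str = "tsl",
    apply_consensus_adjustment: bool = True,
) -> tuple[TernaryMatrix, list[SpliceVariant]]:
    """Full per-gene reconstruction: matrix, variants, consensus, cDNA."""
    matrix = build_ternary_matrix(gene)
    variants = cluster_splice_patterns(matrix)
    transcripts = {tx.transcript_id: tx for tx in gene.transcripts}
    consensus = consensus_coordinates(gene, mode=mode)
    chromosome = genome[gene.chrom]
    for variant in variants:
        variant.representative_id = select_representative(variant, transcripts)
        exons = exons_from_row(matrix, variant.pattern)
        if apply_consensus_adjustment:
            exons = apply_consensus(exons, consensus)
        variant.exons = exons
        variant.cdna = reconstruct_cdna(exons, chromosome, gene.strand)
    return matrix, variants
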