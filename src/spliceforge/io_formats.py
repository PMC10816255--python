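"""Readers and writers for every external format the pipeline touches.

Formats: genome/proteome FASTA (via Biopython), Ensembl-dialect GTF (via
gffutils, converted to 0-based half-open coordinates at this boundary),
BLAT PSL alignments, and tabular PSM result files (via pandas).

FASTA header dialect for proteoform databases::

    >{record_id}|{gene_id}|{transcript_id}|{canonical|variant}|{nmd|ok}

Reference-matched canonical entries carry the SwissProt accession with a
``-1`` suffix as their record id (e.g. ``>P12345-1|...``), mirroring the
marker convention used for UniProtKB/SwissProt-elected canonicals.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    GeneModel,
    GenomeSequence,
    InvariantError,
    PslAlignment,
    PSMRecord,
    SpliceForgeError,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_NUCLEOTIDES = set("ACGTN")
_FLANK_RE = re.compile(r"^[A-Z*-]\.([A-Z]+)\.[A-Z*-]$")


# ---------------------------------------------------------------------------
# genome FASTA
# ---------------------------------------------------------------------------

def read_genome_fasta(path: Union[str, Path]) -> dict[str, GenomeSequence]:
    """Read a genome FASTA into a mapping of chromosome id -> sequence.

    Record ids are the first whitespace-delimited header token; sequences
    are uppercased.  Duplicate ids and non-ACGTN characters are hard errors.
    """
    genome: dict[str, GenomeSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        chrom = record.id
        if chrom in genome:
            raise SpliceForgeError(f"duplicate chromosome id {chrom!r} in {path}")
        seq = str(record.seq).upper()
        bad = set(seq) - _NUCLEOTIDES
        if bad:
            raise SpliceForgeError(
                f"record {chrom!r} contains non-nucleotide characters: "
                f"{sorted(bad)}"
            )
        genome[chrom] = GenomeSequence(chrom=chrom, sequence=seq)
    return genome


def write_genome_fasta(
    genome: Mapping[str, GenomeSequence], path: Union[str, Path], width: int = 60
) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom].sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_tsl(raw: str) -> Optional[int]:
    # Ensembl writes e.g. "1", "5", "NA", or "1 (assigned to previous version 5)"
    token = raw.strip().split()[0] if raw.strip() else "NA"
    if token.upper() == "NA":
        return None
    try:
        return int(token)
    except ValueError:
        return None


def read_gtf(path: Union[str, Path]) -> list[GeneModel]:
    """Parse exon features from an Ensembl-dialect GTF into gene models.

    GTF 1-based inclusive coordinates become 0-based half-open.  The
    ``transcript_support_level`` attribute maps to ``tsl`` (literal "NA"
    means absent); a tag starting with ``appris`` maps to ``appris``; a
    ``havana`` source column or tag sets ``havana``.  Exons lacking a
    transcript_id are skipped with a warning; a transcript with
    overlapping exons is a hard error.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )

    # accumulate exon chains and attributes per transcript, preserving order
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, dict] = {}
    order: list[str] = []

    # file order preserved: transcript order defines matrix row order
    for feat in db.features_of_type("exon"):
        attrs = feat.attributes
        if "transcript_id" not in attrs or not attrs["transcript_id"][0]:
            logger.warning(
                "skipping exon at %s:%s-%s without transcript_id",
                feat.seqid,
                feat.start,
                feat.end,
            )
            continue
        tid = attrs["transcript_id"][0]
        gid = attrs["gene_id"][0] if "gene_id" in attrs else tid
        if tid not in tx_meta:
            order.append(tid)
            tx_meta[tid] = {
                "gene_id": gid,
                "gene_symbol": attrs.get("gene_name", [""])[0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "biotype": (
                    attrs.get("transcript_biotype", attrs.get("gene_biotype", [""]))
                )[0],
                "tsl": None,
                "appris": None,
                "havana": False,
            }
            tx_exons[tid] = []
        meta = tx_meta[tid]
        # GTF is 1-based inclusive; internal convention is 0-based half-open
        tx_exons[tid].append((feat.start - 1, feat.end))
        if "transcript_support_level" in attrs:
            tsl = _parse_tsl(attrs["transcript_support_level"][0])
            if tsl is not None:
                meta["tsl"] = tsl
        for tag in attrs.get("tag", []):
            if tag.lower().startswith("appris"):
                meta["appris"] = tag.lower().replace("appris_", "")
            if tag.lower() == "havana":
                meta["havana"] = True
        if feat.source.lower() == "havana":
            meta["havana"] = True

    genes: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for tid in order:
        meta = tx_meta[tid]
        exons = sorted(tx_exons[tid])
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise SpliceForgeError(
                    f"transcript {tid!r} has overlapping exons "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=meta["gene_id"],
            gene_symbol=meta["gene_symbol"],
            chrom=meta["chrom"],
            strand=meta["strand"],
            exons=exons,
            biotype=meta["biotype"],
            tsl=meta["tsl"],
            appris=meta["appris"],
            havana=meta["havana"],
        )
        if meta["gene_id"] not in genes:
            gene_order.append(meta["gene_id"])
            genes[meta["gene_id"]] = []
        genes[meta["gene_id"]].append(tx)

    models = []
    for gid in gene_order:
        txs = genes[gid]
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=txs[0].chrom,
                strand=txs[0].strand,
                transcripts=txs,
                gene_symbol=txs[0].gene_symbol,
            )
        )
    return models


def write_gtf(genes: Iterable[GeneModel], path: Union[str, Path], source: str = "spliceforge") -> None:
    """Write gene models back to GTF (1-based inclusive), exon features only."""
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                for start, end in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}";'
                    )
                    fh.write(
                        f"{gene.chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# PSL
# ---------------------------------------------------------------------------

def read_psl(path: Union[str, Path]) -> list[PslAlignment]:
    """Read BLAT PSL rows, skipping any psLayout header block."""
    alignments = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or not line[0].isdigit():
                continue
            cols = line.split("\t")
            if len(cols) < 21:
                raise SpliceForgeError(f"malformed PSL line: {line[:80]!r}")
            ints = lambda s: [int(x) for x in s.rstrip(",").split(",") if x]
            alignments.append(
                PslAlignment(
                    query_id=cols[9],
                    target_chrom=cols[13],
                    strand=cols[8],
                    matches=int(cols[0]),
                    mismatches=int(cols[1]),
                    q_size=int(cols[10]),
                    block_count=int(cols[17]),
                    block_sizes=ints(cols[18]),
                    q_starts=ints(cols[19]),
                    t_starts=ints(cols[20]),
                )
            )
    return alignments


def select_best_psl(alignments: Sequence[PslAlignment]) -> PslAlignment:
    """Pick the single best alignment for one query.

    Ranking: maximize (matches - mismatches); ties broken by fewer blocks,
    then lexicographically smallest target chromosome.  The result is
    invariant under permutation of the input.
    """
    if not alignments:
        raise SpliceForgeError("select_best_psl called with no alignments")
    return min(
        alignments,
        key=lambda a: (
            -(a.matches - a.mismatches),
            a.block_count,
            a.target_chrom,
            a.strand,
            tuple(a.t_starts),
        ),
    )


# ---------------------------------------------------------------------------
# proteoform / protein FASTA
# ---------------------------------------------------------------------------

@dataclass
class ProteinRecord:
    """A protein FASTA record; dialect fields populated when parseable."""

    protein_id: str
    sequence: str
    gene_id: str = ""
    transcript_id: str = ""
    canonical: bool = False
    nmd_target: bool = False
    description: str = ""


def proteoform_header(rec) -> str:
    label = "canonical" if rec.canonical else "variant"
    nmd = "nmd" if rec.nmd_target else "ok"
    return f"{rec.protein_id}|{rec.gene_id}|{rec.transcript_id}|{label}|{nmd}"


def write_proteoform_fasta(records: Iterable, path: Union[str, Path], width: int = 60) -> int:
    """Write proteoforms in the pipeline's FASTA header dialect.

    Records with empty sequences are skipped with a warning.  Returns the
    number of records written.
    """
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            if not rec.sequence:
                logger.warning("skipping empty-sequence record %s", rec.protein_id)
                continue
            fh.write(f">{proteoform_header(rec)}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
            n += 1
    return n


def read_protein_fasta(path: Union[str, Path]) -> list[ProteinRecord]:
    """Read protein FASTA; pipe-delimited dialect headers are decoded.

    Non-dialect headers (e.g. SwissProt ``sp|ACC|NAME``) keep the full
    first token as the record id with empty dialect fields.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        seq = str(rec.seq).upper()
        if (
            len(fields) == 5
            and fields[3] in ("canonical", "variant")
            and fields[4] in ("nmd", "ok")
        ):
            records.append(
                ProteinRecord(
                    protein_id=fields[0],
                    gene_id=fields[1],
                    transcript_id=fields[2],
                    canonical=fields[3] == "canonical",
                    nmd_target=fields[4] == "nmd",
                    sequence=seq,
                    description=rec.description,
                )
            )
        else:
            records.append(
                ProteinRecord(protein_id=rec.id, sequence=seq, description=rec.description)
            )
    return records


_SP_RE = re.compile(r"^sp\|(?P<acc>[^|]+)\|(?P<name>\S+)")
_GN_RE = re.compile(r"\bGN=(\S+)")


def parse_swissprot_header(description: str) -> tuple[Optional[str], Optional[str]]:
    """Return (accession, gene symbol) from a SwissProt-style description."""
    acc = None
    m = _SP_RE.match(description)
    if m:
        acc = m.group("acc")
    gene = None
    mg = _GN_RE.search(description)
    if mg:
        gene = mg.group(1)
    return acc, gene


def reference_canonical_map(records: Iterable[ProteinRecord]) -> dict[str, tuple[str, str]]:
    """Map gene symbol/id -> (SwissProt accession, canonical sequence).

    Built from a reference proteome whose headers carry ``GN=`` gene tags;
    the first entry per gene wins (SwissProt lists the canonical first).
    """
    mapping: dict[str, tuple[str, str]] = {}
    for rec in records:
        acc, gene = parse_swissprot_header(rec.description)
        if acc is None or gene is None:
            continue
        mapping.setdefault(gene, (acc, rec.sequence))
    return mapping


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

DEFAULT_PSM_COLUMNS = {
    "peptide": "peptide",
    "proteins": "proteins",
    "primary_score": "primary_score",
    "delta_cn": "delta_cn",
    "ms1": "ms1",
}


def strip_peptide_flanks(peptide: str) -> str:
    """Strip search-engine flanking annotation: ``K.PEPTIDER.A`` -> ``PEPTIDER``."""
    m = _FLANK_RE.match(peptide)
    return m.group(1) if m else peptide


def read_psm_table(
    path: Union[str, Path],
    columns: Optional[Mapping[str, str]] = None,
) -> list[PSMRecord]:
    """Read a TSV of peptide-spectrum matches.

    ``columns`` maps the logical fields (peptide, proteins, primary_score,
    delta_cn, ms1) to the file's column names.  Rows whose numeric fields
    cannot be parsed are dropped with a logged count.  Protein ids are
    semicolon-separated within the proteins column.
    """
    cols = dict(DEFAULT_PSM_COLUMNS)
    if columns:
        cols.update(columns)
    try:
        # keep_default_na=False so tokens like "n/a" surface as parse
        # failures (dropped rows) rather than silent NaN scores
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise SpliceForgeError(f"PSM table {path} missing columns {missing}")

    records = []
    dropped = 0
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        try:
            score = float(row[cols["primary_score"]])
            dcn = float(row[cols["delta_cn"]])
            ms1 = float(row[cols["ms1"]])
        except (TypeError, ValueError):
            dropped += 1
            continue
        peptide = strip_peptide_flanks(str(row[cols["peptide"]]).strip())
        proteins = [p for p in str(row[cols["proteins"]]).split(";") if p]
        try:
            records.append(
                PSMRecord(
                    peptide=peptide,
                    protein_ids=proteins,
                    primary_score=score,
                    delta_cn=dcn,
                    ms1=ms1,
                )
            )
        except InvariantError:
            dropped += 1
    if dropped:
        logger.warning("dropped %d unparseable PSM rows from %s", dropped, path)
    return records
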