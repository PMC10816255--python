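"""PSM-search-optimized proteoform database and proteotypic peptide filters.

Database construction (the redundancy-purge pipeline):

1. drop proteoforms flagged as NMD targets (for the PSM-search variant of
   the database; the full export keeps them);
2. drop sequences shorter than 10 residues;
3. drop sequences identical to, substrings of, or superstrings of any
   reference (SwissProt) sequence — in every containment case the
   reference sequence is the one that remains;
4. deduplicate within each gene and label exactly one canonical per
   gene: the reference-designated canonical when the gene has a
   SwissProt match (its record id gains the ``-1`` marker), otherwise the
   longest sequence; everything else is a variant.

Proteotypic filtering of PSM result tables:

1. Primary Score >= 2.5 and Delta CN > 0.05 (strict);
2. among duplicate rows sharing (peptide, MS1 value rounded to 4
   decimals) only the highest-scoring one is kept;
3. peptides attributed to more than one protein are dropped.

Peptides surviving all filters in one database but not the other, and
not contained in any reference protein, are the exclusively identified
proteotypic peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .models import Proteoform, PSMRecord, SpliceForgeError

logger = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 10
DEFAULT_PRIMARY_SCORE_MIN = 2.5
DEFAULT_DELTA_CN_MIN = 0.05
MS1_DECIMALS = 4


@dataclass
class PsmDatabase:
    """Per-gene partitioned proteoform records plus purge provenance."""

    records: list[Proteoform]
    removed_short: list[str] = field(default_factory=list)
    removed_reference: dict[str, str] = field(default_factory=dict)  # id -> reason

    def by_gene(self) -> dict[str, list[Proteoform]]:
        genes: dict[str, list[Proteoform]] = {}
        for rec in self.records:
            genes.setdefault(rec.gene_id, []).append(rec)
        return genes


@dataclass
class ProteotypicResult:
    """Peptides surviving the score/redundancy/uniqueness filters."""

    peptides: dict[str, PSMRecord]  # peptide -> winning record (single protein)

    def peptide_set(self) -> set[str]:
        return set(self.peptides)


def purge_short(
    sequences: Iterable[Proteoform], min_len: int = DEFAULT_MIN_LENGTH
) -> tuple[list[Proteoform], list[Proteoform]]:
    """Keep sequences of at least ``min_len`` residues."""
    kept, removed = [], []
    for rec in sequences:
        (kept if len(rec.sequence) >= min_len else removed).append(rec)
    return kept, removed


def purge_vs_reference(
    db_records: Iterable[Proteoform], reference_sequences: Sequence[str]
) -> tuple[list[Proteoform], dict[str, str]]:
    """Remove database sequences redundant with the reference proteome.

    A database sequence is removed when it is identical to, a substring
    of, or a superstring of any reference sequence; the removal reason is
    recorded per record id.
    """
    refs = list(reference_sequences)
    kept: list[Proteoform] = []
    removed: dict[str, str] = {}
    for rec in db_records:
        seq = rec.sequence
        reason = None
        for ref in refs:
            if seq == ref:
                reason = "identical"
                break
            if seq in ref:
                reason = "substring"
                break
            if ref in seq:
                reason = "superstring"
                break
        if reason is None:
            kept.append(rec)
        else:
            removed[rec.protein_id] = reason
    return kept, removed


def label_canonical(
    gene_id: str,
    records: Sequence[Proteoform],
    reference_canonical_map: Optional[Mapping[str, tuple[str, str]]] = None,
) -> list[Proteoform]:
    """Label exactly one canonical proteoform for a gene.

    When the reference designates a canonical for this gene, a record
    carrying the SwissProt accession with the ``-1`` marker and the
    reference sequence is the canonical; novel sequences stay variants.
    Otherwise the longest sequence is canonical (length ties go to the
    lexicographically smallest sequence).
    """
    out: list[Proteoform] = []
    designated = (reference_canonical_map or {}).get(gene_id)
    if designated is not None:
        accession, ref_seq = designated
        canonical = Proteoform(
            protein_id=f"{accession}-1",
            gene_id=gene_id,
            transcript_id="",
            sequence=ref_seq,
            orf_end=3 * len(ref_seq),
            canonical=True,
            translatable=False,
        )
        out.append(canonical)
        for rec in records:
            rec.canonical = False
            out.append(rec)
        return out
    if not records:
        return []
    winner = min(records, key=lambda r: (-len(r.sequence), r.sequence))
    for rec in records:
        rec.canonical = rec is winner
        out.append(rec)
    return out


def build_psm_database(
    proteoforms: Iterable[Proteoform],
    reference_sequences: Sequence[str],
    reference_canonical_map: Optional[Mapping[str, tuple[str, str]]] = None,
    min_len: int = DEFAULT_MIN_LENGTH,
    drop_nmd: bool = True,
) -> PsmDatabase:
    """Run the full redundancy-purge pipeline and label canonicals."""
    pool = [p for p in proteoforms if p.sequence]
    if drop_nmd:
        pool = [p for p in pool if not p.nmd_target]
    pool, short = purge_short(pool, min_len=min_len)
    pool, removed_ref = purge_vs_reference(pool, reference_sequences)

    # deduplicate within each gene, preserving first occurrence
    by_gene: dict[str, list[Proteoform]] = {}
    gene_order: list[str] = []
    for rec in pool:
        if rec.gene_id not in by_gene:
            by_gene[rec.gene_id] = []
            gene_order.append(rec.gene_id)
        if all(rec.sequence != r.sequence for r in by_gene[rec.gene_id]):
            by_gene[rec.gene_id].append(rec)

    # genes whose every novel sequence was purged still get their
    # reference-designated canonical entry
    if reference_canonical_map:
        for gid in reference_canonical_map:
            if gid not in by_gene:
                by_gene[gid] = []
                gene_order.append(gid)

    records: list[Proteoform] = []
    for gid in gene_order:
        records.extend(label_canonical(gid, by_gene[gid], reference_canonical_map))
    return PsmDatabase(
        records=records,
        removed_short=[r.protein_id for r in short],
        removed_reference=removed_ref,
    )


def filter_proteotypic(
    psm_records: Iterable[PSMRecord],
    primary_score_min: float = DEFAULT_PRIMARY_SCORE_MIN,
    delta_cn_min: float = DEFAULT_DELTA_CN_MIN,
) -> ProteotypicResult:
    """Apply the three-stage proteotypic filter to PSM rows.

    Stage 1 keeps rows with Primary Score >= ``primary_score_min`` and
    Delta CN strictly greater than ``delta_cn_min``.  Stage 2 collapses
    rows sharing (peptide, MS1 rounded to 4 decimals) to the highest-
    scoring one.  Stage 3 drops peptides whose surviving rows attribute
    them to more than one protein.
    """
    stage1 = [
        r
        for r in psm_records
        if r.primary_score >= primary_score_min and r.delta_cn > delta_cn_min
    ]

    stage2: dict[tuple[str, float], PSMRecord] = {}
    for rec in stage1:
        key = (rec.peptide, round(rec.ms1, MS1_DECIMALS))
        prev = stage2.get(key)
        if prev is None or rec.primary_score > prev.primary_score:
            stage2[key] = rec

    proteins_per_peptide: dict[str, set[str]] = {}
    best_per_peptide: dict[str, PSMRecord] = {}
    for rec in stage2.values():
        proteins_per_peptide.setdefault(rec.peptide, set()).update(rec.protein_ids)
        prev = best_per_peptide.get(rec.peptide)
        if prev is None or rec.primary_score > prev.primary_score:
            best_per_peptide[rec.peptide] = rec

    surviving = {
        pep: rec
        for pep, rec in best_per_peptide.items()
        if len(proteins_per_peptide[pep]) == 1
    }
    return ProteotypicResult(peptides=surviving)


def exclusive_peptides(
    result_a: ProteotypicResult,
    result_b: ProteotypicResult,
    reference_sequences: Sequence[str],
) -> set[str]:
    """Peptides unique to result A and absent from the reference proteome.

    A peptide qualifies when it survives A's filters, does not survive
    B's, and is not a substring of any reference protein sequence.
    """
    refs = list(reference_sequences)
    out = set()
    for pep in result_a.peptide_set() - result_b.peptide_set():
        if not any(pep in ref for ref in refs):
            out.add(pep)
    return out
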