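"""Three-frame in-silico translation and ORF selection.

Translation uses the standard nuclear codon table; stops are ``'*'`` and
any codon containing a non-ACGT character (e.g. N) translates to ``'X'``.
ORF selection considers, in all three frames of the known gene
orientation, every ORF running from an ATG to the next in-frame stop (or
to the sequence end, open-ended, since variant transcripts may truncate
3' exons) and keeps the longest; ties go to the lowest frame, then the
smallest start offset.

A reference-guided start-methionine correction trims translations whose
chosen initiator disagrees with the annotation-linked reference protein:
the earliest internal methionine whose suffix matches the reference
prefix (over a 20-residue window) becomes the new start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from Bio.Data import CodonTable

from .models import Proteoform, SpliceForgeError

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)

#: residues compared when matching a trimmed start against the reference
MET_MATCH_WINDOW = 20


def translate_frame(cdna: str, frame: int) -> str:
    """Translate one reading frame; trailing partial codon dropped."""
    cdna = cdna.upper()
    out = []
    for i in range(frame, len(cdna) - 2, 3):
        codon = cdna[i : i + 3]
        if codon in _STOPS:
            out.append("*")
        elif codon in _FORWARD:
            out.append(_FORWARD[codon])
        else:
            out.append("X")  # codon containing N or other ambiguity
    return "".join(out)


def translate_three_frames(cdna: str) -> tuple[str, str, str]:
    """Translate all three forward reading frames of the cDNA."""
    return tuple(translate_frame(cdna, f) for f in range(3))


@dataclass
class OrfCall:
    frame: int
    orf_start: int
    orf_end: int  # one past the last full codon; stop codon excluded
    sequence: str
    has_stop: bool
    translatable: bool


def select_orf(cdna: str) -> OrfCall:
    """Pick the longest Met-initiated ORF over all three frames.

    Candidate ORFs run from each ATG to the next in-frame stop, or
    open-ended to the sequence end (trailing partial codon dropped).
    Ties break to the lowest frame, then the smallest start offset.  A
    cDNA without any ATG yields an untranslatable empty call.
    """
    if not cdna:
        raise SpliceForgeError("select_orf called with empty cDNA")
    cdna = cdna.upper()
    best: Optional[OrfCall] = None
    for frame in range(3):
        peptide = translate_frame(cdna, frame)
        for aa_idx, residue in enumerate(peptide):
            if residue != "M":
                continue
            stop_rel = peptide.find("*", aa_idx)
            if stop_rel == -1:
                seq = peptide[aa_idx:]
                has_stop = False
            else:
                seq = peptide[aa_idx:stop_rel]
                has_stop = True
            orf_start = frame + 3 * aa_idx
            call = OrfCall(
                frame=frame,
                orf_start=orf_start,
                orf_end=orf_start + 3 * len(seq),
                sequence=seq,
                has_stop=has_stop,
                translatable=True,
            )
            if (
                best is None
                or len(call.sequence) > len(best.sequence)
                or (
                    len(call.sequence) == len(best.sequence)
                    and (call.frame, call.orf_start) < (best.frame, best.orf_start)
                )
            ):
                best = call
    if best is None:
        return OrfCall(
            frame=0, orf_start=0, orf_end=0, sequence="", has_stop=False,
            translatable=False,
        )
    return best


def translate_variant(
    protein_id: str, gene_id: str, transcript_id: str, cdna: str
) -> Proteoform:
    """Translate one reconstructed splice variant into a proteoform."""
    call = select_orf(cdna)
    return Proteoform(
        protein_id=protein_id,
        gene_id=gene_id,
        transcript_id=transcript_id,
        sequence=call.sequence,
        frame=call.frame,
        orf_start=call.orf_start,
        orf_end=call.orf_end,
        has_stop=call.has_stop,
        translatable=call.translatable,
    )


def correct_start_methionine(proteoform: Proteoform, reference_sequence: str) -> Proteoform:
    """Trim a mischosen initiator Met to match the reference protein start.

    If the translation disagrees with the reference at its start but some
    later methionine begins a suffix whose first ``min(20, len)`` residues
    equal the reference prefix, the sequence is trimmed to that
    methionine and flagged ``met_corrected``.  Otherwise the proteoform
    is returned unchanged (with a log line when no match exists).  The
    output is always a suffix of the input starting with 'M'; the
    correction never lengthens a sequence.
    """
    if not reference_sequence or not proteoform.sequence:
        return proteoform
    seq = proteoform.sequence
    ref = reference_sequence

    def matches_at(i: int) -> bool:
        suffix = seq[i:]
        k = min(MET_MATCH_WINDOW, len(suffix), len(ref))
        return k > 0 and suffix[:k] == ref[:k]

    if matches_at(0):
        return proteoform
    for i in range(1, len(seq)):
        if seq[i] == "M" and matches_at(i):
            return Proteoform(
                protein_id=proteoform.protein_id,
                gene_id=proteoform.gene_id,
                transcript_id=proteoform.transcript_id,
                sequence=seq[i:],
                frame=(proteoform.orf_start + 3 * i) % 3,
                orf_start=proteoform.orf_start + 3 * i,
                orf_end=proteoform.orf_end,
                met_corrected=True,
                has_stop=proteoform.has_stop,
                translatable=proteoform.translatable,
                canonical=proteoform.canonical,
                nmd_target=proteoform.nmd_target,
            )
    logger.info(
        "no internal Met of %s matches the reference start; left unchanged",
        proteoform.protein_id,
    )
    return proteoform
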