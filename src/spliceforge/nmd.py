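"""Nonsense-mediated decay target prediction and AS-event classification.

A transcript is called an NMD target when its stop codon lies at least
``threshold_nt`` (default 50) nucleotides upstream of the last exon-exon
junction — the classic 50-nt rule.  Distances are measured in transcript
coordinates from the base immediately after the stop codon to the
junction, so::

    junction_distance = last_junction_tx_pos - (stop_tx_pos + 3)

Single-exon transcripts have no junction and are never targets; neither
are open-ended ORFs (no stop codon within the reconstructed cDNA).

When a transcript is flagged, the alternative-splicing event that
introduced the premature stop is classified against a non-target
reference transcript of the same gene: intron retention, single/multiple
exon inclusion or exclusion, alternative 3'/5' splice-site use, a purely
UTR-level difference, or a complex combination.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

from .models import Interval, NMDVerdict, Proteoform, SpliceForgeError

logger = logging.getLogger(__name__)

DEFAULT_NMD_THRESHOLD_NT = 50

EVENTS = (
    "A3SS",
    "A5SS",
    "A3SS+A5SS",
    "NMD_in",
    "NMD_ex",
    "multi_NMD_in",
    "multi_NMD_ex",
    "IntronRetention",
    "UTR-related",
    "complex",
    "none",
)


def locate_stop(
    proteoform: Proteoform, exon_lengths_tx_order: Sequence[int]
) -> tuple[Optional[int], Optional[int]]:
    """Transcript coordinates of the stop codon and the last junction.

    ``stop_tx_pos`` is the 0-based position of the stop codon's first
    base (``None`` for open-ended ORFs); ``last_junction_tx_pos`` is the
    cumulative length of all exons but the last (``None`` for single-exon
    transcripts).  Exon lengths must be given in transcript (5'→3') order.
    """
    stop_tx_pos = None
    if proteoform.translatable and proteoform.has_stop:
        stop_tx_pos = proteoform.orf_start + 3 * len(proteoform.sequence)
    last_junction = None
    if len(exon_lengths_tx_order) > 1:
        last_junction = sum(exon_lengths_tx_order[:-1])
    return stop_tx_pos, last_junction


def classify_nmd(
    transcript_id: str,
    proteoform: Proteoform,
    exon_lengths_tx_order: Sequence[int],
    threshold_nt: int = DEFAULT_NMD_THRESHOLD_NT,
) -> NMDVerdict:
    """Apply the 50-nt junction-distance rule to one transcript."""
    stop_tx_pos, last_junction = locate_stop(proteoform, exon_lengths_tx_order)
    if stop_tx_pos is None or last_junction is None:
        return NMDVerdict(
            transcript_id=transcript_id,
            is_target=False,
            stop_tx_pos=stop_tx_pos,
            last_junction_tx_pos=last_junction,
        )
    distance = last_junction - (stop_tx_pos + 3)
    return NMDVerdict(
        transcript_id=transcript_id,
        is_target=distance >= threshold_nt,
        stop_tx_pos=stop_tx_pos,
        last_junction_tx_pos=last_junction,
        junction_distance=distance,
    )


def _introns(exons: Sequence[Interval]) -> list[Interval]:
    return [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])]


def classify_as_event(
    target_exons: Sequence[Interval],
    reference_exons: Sequence[Interval],
    strand: str = "+",
    target_stop_genomic: Optional[int] = None,
    reference_coding_span: Optional[Interval] = None,
) -> str:
    """Classify the splicing difference that distinguishes an NMD target.

    Decision order: (a) intron retention; (b)/(c) single or multiple
    exons present only in the target (inclusion) or only in the reference
    (exclusion); (d) shared exons differing at one boundary, alternative
    3' or 5' splice-site use, or both; (e) identical structure with the
    stop outside the reference coding span (UTR-level); (f) complex.
    """
    t_exons = [tuple(e) for e in target_exons]
    r_exons = [tuple(e) for e in reference_exons]

    # (a) target exon fully covering a reference intron
    for intron_start, intron_end in _introns(r_exons):
        for s, e in t_exons:
            if s <= intron_start and intron_end <= e:
                return "IntronRetention"

    def overlaps_any(exon: Interval, others: Sequence[Interval]) -> bool:
        return any(exon[0] < e and s < exon[1] for s, e in others)

    only_target = [e for e in t_exons if not overlaps_any(e, r_exons)]
    only_ref = [e for e in r_exons if not overlaps_any(e, t_exons)]
    if only_target and only_ref:
        return "complex"
    if len(only_target) == 1:
        return "NMD_in"
    if len(only_ref) == 1:
        return "NMD_ex"
    if len(only_target) >= 2:
        return "multi_NMD_in"
    if len(only_ref) >= 2:
        return "multi_NMD_ex"

    # (d) boundary shifts on overlapping exon pairs.  For a '+' strand
    # exon the acceptor (3' splice site) is its genomic start and the
    # donor (5' splice site) its genomic end; '-' strand mirrors this.
    start_shift = False
    end_shift = False
    if len(t_exons) == len(r_exons):
        for (ts, te), (rs, re) in zip(t_exons, r_exons):
            if ts != rs:
                start_shift = True
            if te != re:
                end_shift = True
        if start_shift or end_shift:
            if strand == "+":
                a3, a5 = start_shift, end_shift
            else:
                a3, a5 = end_shift, start_shift
            if a3 and a5:
                return "A3SS+A5SS"
            return "A3SS" if a3 else "A5SS"
    elif t_exons != r_exons:
        return "complex"

    # (e) identical exon chains: at most a UTR-level difference
    if target_stop_genomic is not None and reference_coding_span is not None:
        cs, ce = reference_coding_span
        if not cs <= target_stop_genomic < ce:
            return "UTR-related"
        return "none"
    return "none"


def strip_id_prefix(
    transcript_ids: Sequence[str], prefix: str = "ENST"
) -> tuple[list[str], dict[str, str]]:
    """Strip a fixed id prefix (for de-novo annotation by external tools).

    Returns the renamed ids and a reversible stripped->original mapping;
    ids not carrying the prefix pass through unchanged.
    """
    renamed = []
    mapping = {}
    for tid in transcript_ids:
        new = tid[len(prefix) :] if tid.startswith(prefix) else tid
        renamed.append(new)
        mapping[new] = tid
    return renamed, mapping


def restore_id_prefix(renamed: Sequence[str], mapping: Mapping[str, str]) -> list[str]:
    return [mapping.get(tid, tid) for tid in renamed]
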