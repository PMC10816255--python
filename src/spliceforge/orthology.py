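"""Cross-species orthologous proteoform detection.

The primary filter aligns every proteoform pair within an ortholog gene
pair by global Needleman-Wunsch with affine gaps in EMBOSS ``needle``
semantics: BLOSUM62, gap of length L costs ``gap_open + L * gap_extend``
(defaults 10.0 / 0.5), and end gaps are unpenalized.  Pairs reaching
similarity >= 80% with a gap fraction <= 0.1 are accepted directly.

Proteoforms left unmatched are rescued by a reciprocal-best-hit (RBH)
pass: a pair is kept when the two proteins are each other's top-scoring
hit and the alignment covers >= 60% of the target and >= 90% of the
query.  The same deterministic global aligner backs both passes, so
repeated runs are byte-identical.

Three-species orthology requires a perfect match across the three
pairwise analyses (a-b, a-c, c-b); triads whose members are all
predicted NMD targets can be intersected with per-species NMD verdicts.

Alignment metrics over the full alignment length: identity counts
identical columns, similarity counts positive-scoring substitution
pairs, the gap fraction counts gap columns, and coverage is the mutually
aligned (non-gap) span over each sequence's length.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Align import substitution_matrices

from .models import (
    AlignmentResult,
    OrthologPair,
    OrthologTriad,
    SpliceForgeError,
)

logger = logging.getLogger(__name__)

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5
DEFAULT_MIN_SIMILARITY = 80.0
DEFAULT_MAX_GAP = 0.1
DEFAULT_RBH_TARGET_COV = 60.0
DEFAULT_RBH_QUERY_COV = 90.0

_NEG = float("-inf")
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _score_fn(matrix):
    alphabet = matrix.alphabet

    def score(x: str, y: str) -> float:
        if x not in alphabet or y not in alphabet:
            raise SpliceForgeError(f"residue pair ({x!r}, {y!r}) outside matrix alphabet")
        return float(matrix[x, y])

    return score


def global_align(
    seq_a: str,
    seq_b: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    matrix=None,
    query_id: str = "",
    target_id: str = "",
) -> AlignmentResult:
    """Global affine-gap alignment with unpenalized end gaps.

    A gap of length L costs ``gap_open + L * gap_extend``.  Tie-breaking
    is fixed (match state preferred over a gap in the target, over a gap
    in the query; trailing end gaps minimized), so the traceback and all
    derived metrics are deterministic.
    """
    if not seq_a or not seq_b:
        raise SpliceForgeError("global_align requires two non-empty sequences")
    sub = matrix if matrix is not None else _BLOSUM62
    score = _score_fn(sub)
    n, m = len(seq_a), len(seq_b)
    go = gap_open + gap_extend  # cost of the first residue of a gap
    ge = gap_extend

    # state M: a[i-1] ~ b[j-1]; X: a[i-1] ~ gap; Y: gap ~ b[j-1]
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # free left end gap in b
    for j in range(1, m + 1):
        Y[0][j] = 0.0  # free left end gap in a

    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = score(ai, seq_b[j - 1])
            Mi[j] = s + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xi[j] = max(Mp[j] - go, Xp[j] - ge, Yp[j] - go)
            Yi[j] = max(Mi[j - 1] - go, Xi[j - 1] - go, Yi[j - 1] - ge)

    def best(i: int, j: int) -> float:
        return max(M[i][j], X[i][j], Y[i][j])

    # free right end gaps: the alignment may end anywhere on the last
    # row/column, with the remaining tail gapped at no cost.  Candidates
    # are scanned in an order that prefers no trailing gap, then shorter
    # trailing gaps, then a trailing gap in the target.
    candidates = [(n, m)]
    candidates += [(i, m) for i in range(n - 1, -1, -1)]
    candidates += [(n, j) for j in range(m - 1, -1, -1)]
    best_cell = None
    best_score = _NEG
    for i, j in candidates:
        v = best(i, j)
        if v > best_score:
            best_score = v
            best_cell = (i, j)

    # traceback (right to left), state preference M > X > Y throughout
    cols_a: list[str] = []
    cols_b: list[str] = []
    i, j = best_cell
    for k in range(n, i, -1):  # trailing gap in b
        cols_a.append(seq_a[k - 1])
        cols_b.append("-")
    for k in range(m, j, -1):  # trailing gap in a
        cols_a.append("-")
        cols_b.append(seq_b[k - 1])

    if M[i][j] == best_score:
        state = "M"
    elif X[i][j] == best_score:
        state = "X"
    else:
        state = "Y"

    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                break
            cols_a.append(seq_a[i - 1])
            cols_b.append(seq_b[j - 1])
            target = M[i][j] - score(seq_a[i - 1], seq_b[j - 1])
            i, j = i - 1, j - 1
            if M[i][j] == target:
                state = "M"
            elif X[i][j] == target:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            if j == 0:  # free left end gap in b
                while i > 0:
                    cols_a.append(seq_a[i - 1])
                    cols_b.append("-")
                    i -= 1
                break
            cols_a.append(seq_a[i - 1])
            cols_b.append("-")
            v = X[i][j]
            i -= 1
            if M[i][j] - go == v:
                state = "M"
            elif X[i][j] - ge == v:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            if i == 0:  # free left end gap in a
                while j > 0:
                    cols_a.append("-")
                    cols_b.append(seq_b[j - 1])
                    j -= 1
                break
            cols_a.append("-")
            cols_b.append(seq_b[j - 1])
            v = Y[i][j]
            j -= 1
            if M[i][j] - go == v:
                state = "M"
            elif X[i][j] - go == v:
                state = "X"
            else:
                state = "Y"

    aligned_a = "".join(reversed(cols_a))
    aligned_b = "".join(reversed(cols_b))
    return _metrics(
        aligned_a, aligned_b, best_score, seq_a, seq_b, sub, query_id, target_id
    )


def _metrics(
    aligned_a: str,
    aligned_b: str,
    dp_score: float,
    seq_a: str,
    seq_b: str,
    sub,
    query_id: str,
    target_id: str,
) -> AlignmentResult:
    alen = len(aligned_a)
    identical = 0
    positive = 0
    gap_cols = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            gap_cols += 1
            continue
        if x == y:
            identical += 1
        if float(sub[x, y]) > 0:
            positive += 1
    both = alen - gap_cols
    return AlignmentResult(
        query_id=query_id,
        target_id=target_id,
        score=dp_score,
        identity_pct=100.0 * identical / alen,
        similarity_pct=100.0 * positive / alen,
        gap_fraction=gap_cols / alen,
        query_coverage_pct=100.0 * both / len(seq_a),
        target_coverage_pct=100.0 * both / len(seq_b),
        aligned_query=aligned_a,
        aligned_target=aligned_b,
    )


# ---------------------------------------------------------------------------
# pair filters
# ---------------------------------------------------------------------------

Protein = tuple[str, str]  # (id, sequence)


def _align_all(
    proteins_a: Sequence[Protein],
    proteins_b: Sequence[Protein],
    gap_open: float,
    gap_extend: float,
) -> dict[tuple[str, str], AlignmentResult]:
    cache = {}
    for aid, aseq in proteins_a:
        for bid, bseq in proteins_b:
            cache[(aid, bid)] = global_align(
                aseq, bseq, gap_open, gap_extend, query_id=aid, target_id=bid
            )
    return cache


def needle_filter(
    proteins_a: Sequence[Protein],
    proteins_b: Sequence[Protein],
    gene_pair: tuple[str, str] = ("", ""),
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    max_gap: float = DEFAULT_MAX_GAP,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    _cache: Optional[dict] = None,
) -> tuple[list[OrthologPair], list[Protein], list[Protein]]:
    """All-vs-all similarity/gap filter within one ortholog gene pair.

    Returns the accepted pairs plus the proteins of each side that
    appear in no accepted pair (the leftovers handed to the RBH rescue).
    """
    cache = (
        _cache
        if _cache is not None
        else _align_all(proteins_a, proteins_b, gap_open, gap_extend)
    )
    pairs: list[OrthologPair] = []
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    for aid, _ in proteins_a:
        for bid, _ in proteins_b:
            res = cache[(aid, bid)]
            if res.similarity_pct >= min_similarity and res.gap_fraction <= max_gap:
                pairs.append(
                    OrthologPair(
                        species_a_protein=aid,
                        species_b_protein=bid,
                        gene_pair=gene_pair,
                        method="needle",
                        metrics=res,
                    )
                )
                matched_a.add(aid)
                matched_b.add(bid)
    leftover_a = [p for p in proteins_a if p[0] not in matched_a]
    leftover_b = [p for p in proteins_b if p[0] not in matched_b]
    return pairs, leftover_a, leftover_b


def rbh_rescue(
    leftover_a: Sequence[Protein],
    leftover_b: Sequence[Protein],
    gene_pair: tuple[str, str] = ("", ""),
    rbh_tcov: float = DEFAULT_RBH_TARGET_COV,
    rbh_qcov: float = DEFAULT_RBH_QUERY_COV,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    _cache: Optional[dict] = None,
) -> list[OrthologPair]:
    """Reciprocal-best-hit rescue of proteins the similarity filter missed.

    Best hits are ranked by alignment score, ties by higher identity and
    then smaller partner id.  A pair is accepted when the hit is mutual
    and the alignment covers >= ``rbh_tcov``% of the target and
    >= ``rbh_qcov``% of the query.
    """
    if not leftover_a or not leftover_b:
        return []
    cache = (
        _cache
        if _cache is not None
        else _align_all(leftover_a, leftover_b, gap_open, gap_extend)
    )

    def best_partner(pid: str, partners: Sequence[Protein], forward: bool) -> str:
        def key(partner: Protein):
            res = cache[(pid, partner[0])] if forward else cache[(partner[0], pid)]
            return (-res.score, -res.identity_pct, partner[0])

        return min(partners, key=key)[0]

    best_for_a = {aid: best_partner(aid, leftover_b, True) for aid, _ in leftover_a}
    best_for_b = {bid: best_partner(bid, leftover_a, False) for bid, _ in leftover_b}

    pairs = []
    for aid, bid in best_for_a.items():
        if best_for_b.get(bid) != aid:
            continue
        res = cache[(aid, bid)]
        if res.target_coverage_pct >= rbh_tcov and res.query_coverage_pct >= rbh_qcov:
            pairs.append(
                OrthologPair(
                    species_a_protein=aid,
                    species_b_protein=bid,
                    gene_pair=gene_pair,
                    method="rbh",
                    metrics=res,
                )
            )
    return pairs


def find_ortholog_pairs(
    clusters: Iterable[tuple[tuple[str, str], Sequence[Protein], Sequence[Protein]]],
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    max_gap: float = DEFAULT_MAX_GAP,
    rbh_tcov: float = DEFAULT_RBH_TARGET_COV,
    rbh_qcov: float = DEFAULT_RBH_QUERY_COV,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[OrthologPair]:
    """Needle filter then RBH rescue, per ortholog gene-pair cluster.

    Proteoforms accepted by the similarity filter never re-enter the RBH
    pass; the two stages partition the accepted pairs by method.
    """
    all_pairs: list[OrthologPair] = []
    for gene_pair, prots_a, prots_b in clusters:
        cache = _align_all(prots_a, prots_b, gap_open, gap_extend)
        accepted, left_a, left_b = needle_filter(
            prots_a,
            prots_b,
            gene_pair,
            min_similarity=min_similarity,
            max_gap=max_gap,
            _cache=cache,
        )
        all_pairs.extend(accepted)
        all_pairs.extend(
            rbh_rescue(
                left_a,
                left_b,
                gene_pair,
                rbh_tcov=rbh_tcov,
                rbh_qcov=rbh_qcov,
                _cache=cache,
            )
        )
    return all_pairs


def _pair_keys(pairs: Iterable) -> set[tuple[str, str]]:
    keys = set()
    for p in pairs:
        if isinstance(p, OrthologPair):
            keys.add(p.key())
        else:
            keys.add(tuple(p))
    return keys


def triad_match(
    pairs_ab: Iterable,
    pairs_ac: Iterable,
    pairs_cb: Iterable,
) -> list[OrthologTriad]:
    """Perfect-match intersection of the three pairwise analyses.

    Emits (a, b, c) iff (a, b), (a, c) and (c, b) all appear in their
    respective pairwise result sets; output deduplicated and sorted.
    """
    ab = _pair_keys(pairs_ab)
    ac = _pair_keys(pairs_ac)
    cb = _pair_keys(pairs_cb)
    triads = set()
    for a, b in ab:
        for a2, c in ac:
            if a2 != a:
                continue
            if (c, b) in cb:
                triads.add(OrthologTriad(protein_a=a, protein_b=b, protein_c=c))
    return sorted(triads)


def nmd_ortholog_triads(
    triads: Iterable[OrthologTriad],
    nmd_flags_a: Mapping[str, bool],
    nmd_flags_b: Mapping[str, bool],
    nmd_flags_c: Mapping[str, bool],
) -> list[OrthologTriad]:
    """Triads whose three members all derive from NMD-flagged transcripts."""
    return [
        t
        for t in triads
        if nmd_flags_a.get(t.protein_a, False)
        and nmd_flags_b.get(t.protein_b, False)
        and nmd_flags_c.get(t.protein_c, False)
    ]
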