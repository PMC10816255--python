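"""Global aligner against an independent affine-gap oracle, threshold
filters, reciprocal-best-hit rescue and triad intersection."""

from __future__ import annotations

import itertools
import random
from functools import lru_cache

import pytest
from Bio.Align import substitution_matrices

from spliceforge import orthology
from spliceforge.models import OrthologPair, OrthologTriad, SpliceForgeError

B62 = substitution_matrices.load("BLOSUM62")
AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_score(a: str, b: str, gap_open=10.0, gap_extend=0.5) -> float:
    """Independent formulation: decompose alignments into substitution
    steps and maximal gap runs (a run of length L costs open + L*extend);
    end runs are free.  Memoized recursion over suffixes."""
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == n or j == m:  # free trailing end gap
            return 0.0
        best = rec(i + 1, j + 1) + float(B62[a[i], b[j]])
        # penalized gap runs (a run reaching a sequence end stays
        # penalized; the free-trailing alternative is the base case)
        for L in range(1, n - i + 1):
            best = max(best, rec(i + L, j) - (gap_open + L * gap_extend))
        for L in range(1, m - j + 1):
            best = max(best, rec(i, j + L) - (gap_open + L * gap_extend))
        return best

    # free leading end gap in exactly one sequence
    return max(
        max(rec(i, 0) for i in range(n + 1)),
        max(rec(0, j) for j in range(m + 1)),
    )


def alignment_score_from_strings(ga: str, gb: str, gap_open=10.0, gap_extend=0.5) -> float:
    """Recompute the score of a concrete alignment, end gaps free."""
    score = 0.0
    runs = []  # (which, start, length)
    col = 0
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            which = "a" if x == "-" else "b"
            if runs and runs[-1][0] == which and runs[-1][1] + runs[-1][2] == col:
                runs[-1] = (which, runs[-1][1], runs[-1][2] + 1)
            else:
                runs.append((which, col, 1))
        else:
            score += float(B62[x, y])
        col += 1
    for which, start, length in runs:
        if start == 0 or start + length == len(ga):
            continue  # end gap, free
        score -= gap_open + length * gap_extend
    return score


class TestGlobalAlign:
    def test_identical_sequences(self):
        r = orthology.global_align("MKLVST", "MKLVST")
        assert (r.identity_pct, r.similarity_pct, r.gap_fraction) == (100.0, 100.0, 0.0)
        assert r.query_coverage_pct == r.target_coverage_pct == 100.0

    def test_single_end_gap_metrics(self):
        r = orthology.global_align("MKV", "MKVA")
        assert r.gap_fraction == 0.25
        assert r.identity_pct == 75.0

    def test_score_symmetric_under_argument_swap(self):
        # the optimal score is symmetric; the traceback (and hence the
        # metrics) need not be when co-optimal alignments exist
        rng = random.Random(21)
        for _ in range(20):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 15)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 15)))
            assert orthology.global_align(a, b).score == orthology.global_align(b, a).score

    def test_empty_sequence_errors(self):
        with pytest.raises(SpliceForgeError):
            orthology.global_align("", "MK")

    def test_score_and_metrics_match_brute_force_oracle(self):
        rng = random.Random(33)
        for _ in range(120):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 12)))
            r = orthology.global_align(a, b)
            assert r.score == pytest.approx(oracle_score(a, b))
            # the emitted alignment is a real alignment of the inputs
            assert r.aligned_query.replace("-", "") == a
            assert r.aligned_target.replace("-", "") == b
            # ... that achieves the optimal score
            assert alignment_score_from_strings(
                r.aligned_query, r.aligned_target
            ) == pytest.approx(r.score)
            # ... and the metrics restate it exactly
            cols = list(zip(r.aligned_query, r.aligned_target))
            alen = len(cols)
            ident = sum(x == y for x, y in cols if "-" not in (x, y))
            gaps = sum("-" in c for c in cols)
            assert r.identity_pct == pytest.approx(100 * ident / alen)
            assert r.gap_fraction == pytest.approx(gaps / alen)
            assert r.identity_pct <= r.similarity_pct <= 100.0

    def test_identity_100_and_no_gaps_implies_equality(self):
        rng = random.Random(4)
        for _ in range(40):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 10)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 10)))
            r = orthology.global_align(a, b)
            if r.identity_pct == 100.0 and r.gap_fraction == 0.0:
                assert a == b


def proteins(*seqs, prefix="p"):
    return [(f"{prefix}{i}", s) for i, s in enumerate(seqs)]


class TestNeedleFilter:
    def test_inclusive_similarity_and_gap_bounds(self):
        a = [("a0", "MKLVSTQWERTYIPAS")]
        b = [("b0", "MKLVSTQWERTYIPAS")]
        res = orthology.global_align(a[0][1], b[0][1])
        accepted, la, lb = orthology.needle_filter(
            a, b, min_similarity=res.similarity_pct, max_gap=res.gap_fraction
        )
        assert len(accepted) == 1 and not la and not lb
        accepted, la, lb = orthology.needle_filter(
            a, b, min_similarity=res.similarity_pct + 0.1
        )
        assert not accepted and la == a and lb == b

    def test_gap_bound_rejects(self):
        a = [("a0", "MKLVSTQWERTY")]
        b = [("b0", "MKLVSTQWERTY" + "A" * 6)]  # 1/3 of columns end-gapped
        res = orthology.global_align(a[0][1], b[0][1])
        assert res.gap_fraction > 0.1
        accepted, la, lb = orthology.needle_filter(a, b)
        assert not accepted

    def test_leftovers_never_reenter_after_acceptance(self):
        seq = "MKLVSTQWERTYIPASDFGH"
        accepted, la, lb = orthology.needle_filter(
            [("a0", seq)], [("b0", seq), ("b1", "WWWWCCCCPPPPHHHH")]
        )
        assert [p.key() for p in accepted] == [("a0", "b0")]
        assert [p[0] for p in la] == []
        assert [p[0] for p in lb] == ["b1"]


class TestRbh:
    def test_mutual_best_with_coverage(self):
        a = [("a0", "MKLVSTQWERTYIPASDFGH")]
        b = [("b0", "MKLVSTQWERTYIPASDFGH")]
        pairs = orthology.rbh_rescue(a, b)
        assert [p.key() for p in pairs] == [("a0", "b0")]
        assert pairs[0].method == "rbh"

    def test_target_coverage_bound(self):
        # target much longer: query fully covered but target is not
        a = [("a0", "MKLVSTQWERTY")]
        b = [("b0", "MKLVSTQWERTY" + "W" * 30)]
        res = orthology.global_align(a[0][1], b[0][1])
        assert res.target_coverage_pct < 60
        assert orthology.rbh_rescue(a, b) == []

    def test_non_reciprocal_hit_yields_no_pair(self):
        # a0 prefers b0; b0 prefers a1 (identical); a1 prefers b0 too
        a = [("a0", "MKLVSTQWERTAIPAS"), ("a1", "MKLVSTQWERTYIPAS")]
        b = [("b0", "MKLVSTQWERTYIPAS")]
        pairs = orthology.rbh_rescue(a, b)
        assert [p.key() for p in pairs] == [("a1", "b0")]

    def test_empty_leftovers(self):
        assert orthology.rbh_rescue([], [("b0", "MK")]) == []


class TestTriads:
    def test_worked_example(self):
        triads = orthology.triad_match(
            [("h1", "m1")], [("h1", "r1")], [("r1", "m1")]
        )
        assert triads == [OrthologTriad("h1", "m1", "r1")]

    def test_missing_third_edge_blocks_triad(self):
        assert orthology.triad_match([("h1", "m1")], [("h1", "r1")], []) == []

    def test_equals_brute_force_triple_enumeration(self):
        rng = random.Random(8)
        hs = [f"h{i}" for i in range(10)]
        ms = [f"m{i}" for i in range(10)]
        rs = [f"r{i}" for i in range(10)]
        for _ in range(20):
            ab = {(rng.choice(hs), rng.choice(ms)) for _ in range(rng.randint(0, 25))}
            ac = {(rng.choice(hs), rng.choice(rs)) for _ in range(rng.randint(0, 25))}
            cb = {(rng.choice(rs), rng.choice(ms)) for _ in range(rng.randint(0, 25))}
            expected = sorted(
                OrthologTriad(h, m, r)
                for h, m, r in itertools.product(hs, ms, rs)
                if (h, m) in ab and (h, r) in ac and (r, m) in cb
            )
            assert orthology.triad_match(ab, ac, cb) == expected

    def test_nmd_triads_require_all_three_flags(self):
        triads = [OrthologTriad("a", "b", "c"), OrthologTriad("x", "y", "z")]
        kept = orthology.nmd_ortholog_triads(
            triads,
            {"a": True, "x": True},
            {"b": True, "y": False},
            {"c": True, "z": True},
        )
        assert kept == [OrthologTriad("a", "b", "c")]
        assert orthology.nmd_ortholog_triads(triads, {}, {}, {}) == []


class TestDeterminism:
    def test_repeated_alignment_identical(self):
        rng = random.Random(2)
        for _ in range(10):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(3, 25)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(3, 25)))
            r1 = orthology.global_align(a, b)
            r2 = orthology.global_align(a, b)
            assert (r1.aligned_query, r1.aligned_target, r1.score) == (
                r2.aligned_query, r2.aligned_target, r2.score)
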