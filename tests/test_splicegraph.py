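"""Ternary matrix construction, inversion, representative selection,
consensus coordinates and cDNA reconstruction."""

from __future__ import annotations

import logging
import random

import pytest

from spliceforge.models import GeneModel, GenomeSequence, TranscriptModel
from spliceforge import splicegraph as sg


def tx(tid, exons, gene="G", strand="+", **kw):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, chrom="c1", strand=strand,
        exons=exons, **kw,
    )


def gene_of(*transcripts, strand="+"):
    return GeneModel(
        gene_id="G", chrom="c1", strand=strand, transcripts=list(transcripts)
    )


@pytest.fixture
def two_tx_gene():
    # T1: [0,100)+[200,300); T2: [0,100)+[150,300)
    return gene_of(
        tx("T1", [(0, 100), (200, 300)]),
        tx("T2", [(0, 100), (150, 300)]),
    )


class TestSegmentation:
    def test_boundary_projection(self, two_tx_gene):
        part = sg.segment_gene(two_tx_gene)
        assert part.segments == [(0, 100), (100, 150), (150, 200), (200, 300)]
        assert part.exonic == [True, False, True, True]

    def test_single_exon_single_segment(self):
        part = sg.segment_gene(gene_of(tx("T", [(0, 50)])))
        assert part.segments == [(0, 50)]
        assert part.exonic == [True]

    def test_identical_transcripts_idempotent(self):
        g1 = gene_of(tx("T1", [(0, 100), (200, 300)]))
        g2 = gene_of(tx("T1", [(0, 100), (200, 300)]),
                     tx("T2", [(0, 100), (200, 300)]))
        assert sg.segment_gene(g1).segments == sg.segment_gene(g2).segments


class TestTernaryMatrix:
    def test_worked_two_transcript_example(self, two_tx_gene):
        m = sg.build_ternary_matrix(two_tx_gene)
        assert m.rows == ["1|01", "1|11"]

    def test_single_transcript_has_no_zero_and_no_pipe_in_exons(self):
        m = sg.build_ternary_matrix(gene_of(tx("T", [(0, 100), (200, 300)])))
        assert m.rows == ["1|1"]

    def test_intron_column_becomes_zero_when_a_transcript_exonifies_it(self, two_tx_gene):
        g = gene_of(
            *two_tx_gene.transcripts,
            tx("T3", [(0, 100), (100, 150), (150, 300)]),
        )
        m = sg.build_ternary_matrix(g)
        # the former '|' column [100,150) is now exonic in T3
        col = [row[1] for row in m.rows]
        assert col == ["0", "0", "1"]

    def test_pipe_columns_are_constant(self, pipeline_run):
        for res in pipeline_run["results"]:
            for j in range(len(res.matrix.rows[0])):
                col = {row[j] for row in res.matrix.rows}
                if "|" in col:
                    assert col == {"|"}

    def test_row_inversion_recovers_exact_exon_chains(self):
        rng = random.Random(42)
        for _ in range(100):
            transcripts = []
            for t in range(rng.randint(1, 6)):
                exons, pos = [], rng.randint(0, 20)
                for _ in range(rng.randint(1, 8)):
                    start = pos + rng.randint(1, 40)
                    end = start + rng.randint(1, 60)
                    exons.append((start, end))
                    pos = end
                transcripts.append(tx(f"T{t}", exons))
            g = gene_of(*transcripts)
            m = sg.build_ternary_matrix(g)
            for t, row in zip(g.transcripts, m.rows):
                assert sg.exons_from_row(m, row) == t.exons


class TestClustering:
    def test_identical_rows_share_a_variant(self):
        g = gene_of(
            tx("T1", [(0, 100), (200, 300)]),
            tx("T2", [(0, 100), (200, 300)]),
            tx("T3", [(0, 100), (150, 300)]),
        )
        variants = sg.cluster_splice_patterns(sg.build_ternary_matrix(g))
        assert len(variants) == 2
        assert variants[0].member_ids == ["T1", "T2"]

    def test_all_distinct_rows_one_variant_each(self, two_tx_gene):
        variants = sg.cluster_splice_patterns(sg.build_ternary_matrix(two_tx_gene))
        assert [v.member_ids for v in variants] == [["T1"], ["T2"]]


class TestRepresentative:
    def members(self, **overrides):
        base = dict(biotype="protein_coding", havana=True)
        a = tx("TA", [(0, 300)], **base, **overrides.get("TA", {}))
        b = tx("TB", [(0, 300)], **base, **overrides.get("TB", {}))
        return {t.transcript_id: t for t in (a, b)}

    def variant(self, members):
        return sg.SpliceVariant(gene_id="G", pattern="1", member_ids=list(members))

    def test_lower_tsl_wins(self):
        members = self.members(TA={"tsl": 5}, TB={"tsl": 1})
        assert sg.select_representative(self.variant(members), members) == "TB"

    def test_havana_protein_coding_outranks_tsl(self):
        members = {
            "TA": tx("TA", [(0, 300)], biotype="protein_coding", havana=True, tsl=5),
            "TB": tx("TB", [(0, 300)], biotype="lncRNA", havana=False, tsl=1),
        }
        assert sg.select_representative(self.variant(members), members) == "TA"

    def test_longest_wins_when_flags_tie(self):
        members = {
            "TA": tx("TA", [(0, 200)], biotype="protein_coding", havana=True),
            "TB": tx("TB", [(0, 350)], biotype="protein_coding", havana=True),
        }
        assert sg.select_representative(self.variant(members), members) == "TB"

    def test_full_tie_smallest_id_and_permutation_invariance(self):
        members = self.members()
        v1 = sg.SpliceVariant(gene_id="G", pattern="1", member_ids=["TB", "TA"])
        v2 = sg.SpliceVariant(gene_id="G", pattern="1", member_ids=["TA", "TB"])
        assert sg.select_representative(v1, members) == "TA"
        assert sg.select_representative(v2, members) == "TA"

    def test_absent_tsl_ranks_below_five(self):
        members = self.members(TA={"tsl": None}, TB={"tsl": 5})
        assert sg.select_representative(self.variant(members), members) == "TB"


class TestConsensus:
    def test_tsl_mode_prefers_lowest_tsl(self):
        g = gene_of(
            tx("T1", [(10, 200)], tsl=2),
            tx("T2", [(0, 300)], tsl=1),
            tx("T3", [(5, 500)]),
        )
        assert sg.consensus_coordinates(g, "tsl") == (0, 300)

    def test_fallback_to_longest_without_flags(self):
        g = gene_of(tx("T1", [(10, 200)]), tx("T2", [(5, 500)]))
        assert sg.consensus_coordinates(g, "tsl") == (5, 500)
        assert sg.consensus_coordinates(g, "appris") == (5, 500)

    def test_appris_mode_prefers_principal_tag(self):
        g = gene_of(
            tx("T1", [(10, 200)], appris="principal_1"),
            tx("T2", [(0, 900)], appris="alternative_2"),
        )
        assert sg.consensus_coordinates(g, "appris") == (10, 200)

    def test_single_transcript_own_span(self):
        g = gene_of(tx("T1", [(7, 77)]))
        assert sg.consensus_coordinates(g, "tsl") == (7, 77)

    def test_apply_extends_outer_exons_only(self):
        adjusted = sg.apply_consensus([(10, 100), (200, 290)], (0, 300))
        assert adjusted == [(0, 100), (200, 300)]

    def test_apply_identity_when_equal(self):
        assert sg.apply_consensus([(0, 100), (200, 300)], (0, 300)) == [
            (0, 100), (200, 300)]

    def test_apply_never_trims(self, caplog):
        with caplog.at_level(logging.INFO, logger="spliceforge.splicegraph"):
            adjusted = sg.apply_consensus([(0, 100), (200, 300)], (20, 250))
        assert adjusted == [(0, 100), (200, 300)]
        assert any("not trimmed" in r.message for r in caplog.records)

    def test_internal_junctions_never_move(self):
        rng = random.Random(3)
        for _ in range(50):
            exons = []
            pos = rng.randint(0, 30)
            for _ in range(rng.randint(2, 6)):
                s = pos + rng.randint(1, 20)
                e = s + rng.randint(5, 40)
                exons.append((s, e))
                pos = e
            consensus = (rng.randint(-50, 50), exons[-1][1] + rng.randint(-50, 50))
            adjusted = sg.apply_consensus(exons, consensus)
            assert [e for _, e in adjusted[:-1]] == [e for _, e in exons[:-1]]
            assert [s for s, _ in adjusted[1:]] == [s for s, _ in exons[1:]]


class TestCdna:
    GENOME = GenomeSequence(chrom="c1", sequence="AAACCCGGGTTT")

    def test_plus_strand_splice(self):
        assert sg.reconstruct_cdna([(0, 3), (9, 12)], self.GENOME, "+") == "AAATTT"

    def test_minus_strand_is_reverse_complement_of_plus(self):
        plus = sg.reconstruct_cdna([(0, 3), (9, 12)], self.GENOME, "+")
        minus = sg.reconstruct_cdna([(0, 3), (9, 12)], self.GENOME, "-")
        # independent reverse-complement oracle via str.translate
        oracle = plus.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert minus == oracle == "AAATTT"[::-1].translate(str.maketrans("ACGT", "TGCA"))

    def test_reverse_complement_is_an_involution(self):
        rng = random.Random(5)
        for _ in range(30):
            seq = "".join(rng.choice("ACGTN") for _ in range(rng.randint(1, 80)))
            assert sg.reverse_complement(sg.reverse_complement(seq)) == seq

    def test_length_is_sum_of_exon_widths(self):
        cdna = sg.reconstruct_cdna([(0, 5), (6, 10)], self.GENOME, "-")
        assert len(cdna) == 9

    def test_out_of_bounds_exon_errors(self):
        with pytest.raises(Exception):
            sg.reconstruct_cdna([(0, 99)], self.GENOME, "+")

    def test_empty_exon_list_errors(self):
        with pytest.raises(Exception):
            sg.reconstruct_cdna([], self.GENOME, "+")
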