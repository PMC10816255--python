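"""Redundancy purge, canonical labeling and the proteotypic filter chain,
checked against naive brute-force oracles."""

from __future__ import annotations

import itertools
import random

import pytest

from spliceforge import psmdb
from spliceforge.fixtures import generate_purge_fixture
from spliceforge.models import Proteoform, PSMRecord


def pf(pid, seq, gene="G"):
    return Proteoform(
        protein_id=pid, gene_id=gene, transcript_id=pid.lower(),
        sequence=seq, orf_end=3 * len(seq), translatable=False,
    )


def psm(pep, prots, score, dcn, ms1=500.0):
    return PSMRecord(
        peptide=pep, protein_ids=prots.split(";"),
        primary_score=score, delta_cn=dcn, ms1=ms1,
    )


class TestPurges:
    def test_short_boundary_at_ten(self):
        kept, removed = psmdb.purge_short([pf("a", "K" * 9), pf("b", "K" * 10)])
        assert [r.protein_id for r in kept] == ["b"]
        assert [r.protein_id for r in removed] == ["a"]

    def test_empty_input_empty_output(self):
        assert psmdb.purge_short([]) == ([], [])

    def test_containment_directions(self):
        refs = ["AMKLVG", "MKLV"]
        kept, removed = psmdb.purge_vs_reference(
            [pf("sub", "MKLV"), pf("sup", "QAMKLVGQ"), pf("novel", "MQQQW"),
             pf("ident", "AMKLVG")],
            refs,
        )
        # reasons reflect the first containment found scanning the
        # reference list in order
        assert removed == {"sub": "substring", "sup": "superstring",
                           "ident": "identical"}
        assert [r.protein_id for r in kept] == ["novel"]

    def test_substring_reason_when_not_identical(self):
        kept, removed = psmdb.purge_vs_reference([pf("x", "MKL")], ["AMKLVG"])
        assert removed == {"x": "substring"}


class TestCanonicalLabeling:
    def test_longest_wins_without_reference(self):
        records = psmdb.label_canonical(
            "G", [pf("a", "K" * 250), pf("b", "M" * 300), pf("c", "L" * 250)]
        )
        flags = {r.protein_id: r.canonical for r in records}
        assert flags == {"a": False, "b": True, "c": False}

    def test_length_tie_smallest_sequence(self):
        records = psmdb.label_canonical("G", [pf("a", "ZZZZZZZZZZ"), pf("b", "AAAAAAAAAA")])
        assert {r.protein_id: r.canonical for r in records} == {"a": False, "b": True}

    def test_reference_designation_overrides_length(self):
        records = psmdb.label_canonical(
            "G", [pf("a", "K" * 300)], {"G": ("P12345", "MSHORT")}
        )
        canonical = [r for r in records if r.canonical]
        assert len(canonical) == 1
        assert canonical[0].protein_id == "P12345-1"
        assert canonical[0].sequence == "MSHORT"
        assert not records[1].canonical

    def test_single_sequence_is_canonical(self):
        (rec,) = psmdb.label_canonical("G", [pf("a", "M" * 20)])
        assert rec.canonical


class TestDatabasePipeline:
    def test_invariants_on_planted_purge_fixture(self):
        for seed in range(5):
            forms, refs, expected_removed, expected_kept = generate_purge_fixture(seed)
            db = psmdb.build_psm_database(forms, refs, min_len=10)
            ids = {r.protein_id for r in db.records}
            assert ids == expected_kept
            # brute-force all-pairs containment oracle
            for rec in db.records:
                assert len(rec.sequence) >= 10
                for ref in refs:
                    assert rec.sequence != ref
                    assert rec.sequence not in ref
                    assert ref not in rec.sequence
            for gene, members in db.by_gene().items():
                seqs = [r.sequence for r in members]
                assert len(seqs) == len(set(seqs))
                assert sum(r.canonical for r in members) == 1
            # recorded reasons agree with the plan (short entries are
            # removed before the reference purge and carry no reason)
            for pid, reason in expected_removed.items():
                if reason == "short":
                    assert pid in db.removed_short
                else:
                    assert db.removed_reference[pid] == reason

    def test_nmd_flagged_records_are_dropped(self):
        a, b = pf("a", "M" * 20), pf("b", "W" * 20)
        b.nmd_target = True
        db = psmdb.build_psm_database([a, b], [])
        assert {r.protein_id for r in db.records} == {"a"}
        full = psmdb.build_psm_database([a, b], [], drop_nmd=False)
        assert {r.protein_id for r in full.records} == {"a", "b"}

    def test_within_gene_deduplication(self):
        db = psmdb.build_psm_database(
            [pf("a", "M" * 20), pf("b", "M" * 20), pf("c", "W" * 20)], []
        )
        assert {r.protein_id for r in db.records} == {"a", "c"}


def brute_force_proteotypic(records, score_min, dcn_min):
    """Literal restatement of the three filters by exhaustive scan."""
    s1 = [r for r in records if r.primary_score >= score_min and r.delta_cn > dcn_min]
    s2 = []
    for r in s1:
        key = (r.peptide, round(r.ms1, 4))
        better = [o for o in s1 if (o.peptide, round(o.ms1, 4)) == key
                  and o.primary_score > r.primary_score]
        if not better and not any(
            (o.peptide, round(o.ms1, 4)) == key and o is not r and
            o.primary_score == r.primary_score and s1.index(o) < s1.index(r)
            for o in s1
        ):
            s2.append(r)
    surviving = set()
    for pep in {r.peptide for r in s2}:
        proteins = set(itertools.chain.from_iterable(
            r.protein_ids for r in s2 if r.peptide == pep))
        if len(proteins) == 1:
            surviving.add(pep)
    return surviving


class TestProteotypicFilter:
    def test_score_boundaries(self):
        records = [
            psm("AAAAK", "P1", 2.4, 0.2),   # fails primary score
            psm("CCCCK", "P1", 2.5, 0.2),   # boundary pass
            psm("DDDDK", "P1", 3.0, 0.05),  # fails strict Delta CN
            psm("EEEEK", "P1", 3.0, 0.051), # boundary pass
        ]
        result = psmdb.filter_proteotypic(records)
        assert result.peptide_set() == {"CCCCK", "EEEEK"}

    def test_multi_protein_peptides_removed(self):
        result = psmdb.filter_proteotypic([psm("AAAAK", "P1;P2", 4.0, 0.2)])
        assert result.peptide_set() == set()

    def test_ms1_duplicates_keep_highest_score(self):
        records = [
            psm("AAAAK", "P1", 3.0, 0.2, ms1=512.1234),
            psm("AAAAK", "P1", 4.5, 0.3, ms1=512.1234),
        ]
        result = psmdb.filter_proteotypic(records)
        assert result.peptides["AAAAK"].primary_score == 4.5

    def test_same_peptide_two_masses_two_proteins_is_not_proteotypic(self):
        records = [
            psm("AAAAK", "P1", 4.0, 0.2, ms1=512.1),
            psm("AAAAK", "P2", 4.2, 0.2, ms1=900.9),
        ]
        assert psmdb.filter_proteotypic(records).peptide_set() == set()

    def test_equals_brute_force_on_random_tables(self):
        rng = random.Random(11)
        peptides = ["PEP%02d" % i for i in range(12)]
        for _ in range(30):
            records = [
                psm(
                    rng.choice(peptides),
                    ";".join(rng.sample(["P1", "P2", "P3"], rng.randint(1, 2))),
                    round(rng.uniform(1.5, 5.0), 2),
                    round(rng.uniform(0.0, 0.3), 3),
                    ms1=round(rng.choice([500.0, 600.0, 700.1234]), 4),
                )
                for _ in range(rng.randint(1, 25))
            ]
            mine = psmdb.filter_proteotypic(records).peptide_set()
            assert mine == brute_force_proteotypic(records, 2.5, 0.05)

    def test_relaxed_score_cutoff_flag(self):
        records = [psm("AAAAK", "P1", 2.1, 0.2)]
        assert psmdb.filter_proteotypic(records).peptide_set() == set()
        relaxed = psmdb.filter_proteotypic(records, primary_score_min=2.0)
        assert relaxed.peptide_set() == {"AAAAK"}


class TestExclusivePeptides:
    def result(self, *peps):
        return psmdb.ProteotypicResult(
            peptides={p: psm(p, "P1", 3.0, 0.2) for p in peps}
        )

    def test_self_difference_is_empty(self):
        a = self.result("AAAAK", "CCCCK")
        assert psmdb.exclusive_peptides(a, a, []) == set()

    def test_reference_substring_excluded(self):
        a, b = self.result("AAAAK", "CCCCK"), self.result()
        assert psmdb.exclusive_peptides(a, b, ["WWAAAAKWW"]) == {"CCCCK"}

    def test_anti_monotone_in_reference_size(self):
        a, b = self.result("AAAAK", "CCCCK", "DDDDK"), self.result("DDDDK")
        refs = ["WWAAAAKWW", "XCCCCKX"]
        for i in range(len(refs) + 1):
            smaller = psmdb.exclusive_peptides(a, b, refs[: i + 1] if i < len(refs) else refs)
            larger = psmdb.exclusive_peptides(a, b, refs[:i])
            assert smaller <= larger
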