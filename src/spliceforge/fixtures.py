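"""Seeded synthetic genome/annotation/proteome/PSM fixture generator.

Every pipeline stage is testable without downloads: the generator plants
gene structures, splicing events, premature stops, PSM rows and mutated
ortholog proteomes with a ground-truth manifest computed constructively
during generation (never by running the pipeline), so the manifest is a
true oracle.

Sequence design guarantees exact ORF control: all background gene
content (exons, introns, spacers) is drawn from the three-letter
alphabet {C, G, T}, and the only adenines are inside explicitly planted
``ATG``/``TAA`` motifs.  Since every stop codon (TAA/TAG/TGA) and the
start codon contain an A, each transcript's cDNA contains exactly the
planted ORFs and nothing else, in any reading frame.  Splicing events
are sized in multiples of three so every variant shares the canonical
reading frame, which makes the expected protein of every variant a
simple slice-and-translate of designed sequence.

Emulated features of real data: multi-exon genes on both strands, TSL/
APPRIS/HAVANA reliability flags, cassette inclusion/exclusion, A3SS/
A5SS, intron retention, premature stops at controlled junction
distances, SwissProt-style reference proteomes, PSM score distributions
with planted decoys, and cross-species proteomes at a configurable
substitution rate.  Not emulated: realistic codon usage, GC content or
splice-site motifs, and read-level sequencing noise.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import ProteinRecord, write_proteoform_fasta
from .models import (
    GeneModel,
    GenomeSequence,
    Interval,
    Proteoform,
    SpliceForgeError,
    TranscriptModel,
)
from .splicegraph import reverse_complement

_BG = "CGT"  # background alphabet: no adenine, hence no unplanned ATG/stop
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_CONSERVATIVE = {
    a: [b for b in _AA20 if b != a and _BLOSUM62[a, b] > 0] or [c for c in _AA20 if c != a]
    for a in _AA20
}

CODING_EVENTS = ("cassette_ex", "cassette_in", "A3SS", "A5SS", "intron_retention")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study; identical spec+seed => identical bytes."""

    seed: int = 0
    n_genes: int = 12
    transcripts_per_gene: tuple[int, int] = (2, 5)
    exon_count: tuple[int, int] = (4, 6)
    exon_length: tuple[int, int] = (90, 180)
    intron_length: tuple[int, int] = (60, 150)
    #: junction distances of planted premature stops, one gene each
    ptc_distances: tuple[int, ...] = (0, 49, 50, 51, 500)
    n_duplicate_pattern_genes: int = 2
    n_met_correction_genes: int = 1
    minus_strand_fraction: float = 0.4
    n_species: int = 1
    mutation_rate: float = 0.05
    n_true_peptides: int = 6
    plant_psm_decoys: bool = True

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SpliceForgeError("infeasible spec: n_genes must be >= 1")
        if self.exon_count[0] < 3:
            raise SpliceForgeError(
                "infeasible spec: exon_count minimum below 3 leaves no room "
                "for internal splicing events"
            )
        if any(d < 0 for d in self.ptc_distances):
            raise SpliceForgeError("infeasible spec: negative PTC junction distance")
        if len(self.ptc_distances) > self.n_genes:
            raise SpliceForgeError(
                "infeasible spec: more planted PTC distances than genes"
            )
        if not 1 <= self.n_species <= 3:
            raise SpliceForgeError("infeasible spec: n_species must be 1..3")
        if not 0.0 <= self.mutation_rate <= 0.4:
            raise SpliceForgeError("infeasible spec: mutation rate outside [0, 0.4]")
        if self.transcripts_per_gene[0] < 1:
            raise SpliceForgeError("infeasible spec: transcripts_per_gene minimum < 1")


@dataclass
class Fixture:
    """In-memory fixture bundle plus the ground-truth manifest."""

    spec: FixtureSpec
    genome: dict[str, GenomeSequence]
    genes: list[GeneModel]
    reference_records: list[ProteinRecord]
    psm_rows_a: list[dict]
    psm_rows_b: list[dict]
    proteome_b: list[ProteinRecord] = field(default_factory=list)
    proteome_c: list[ProteinRecord] = field(default_factory=list)
    gene_pairs_ab: list[tuple[str, str]] = field(default_factory=list)
    gene_pairs_ac: list[tuple[str, str]] = field(default_factory=list)
    gene_pairs_cb: list[tuple[str, str]] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        paths["genome"] = out / "genome.fa"
        with open(paths["genome"], "w") as fh:
            for chrom, rec in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(rec.sequence), 60):
                    fh.write(rec.sequence[i : i + 60] + "\n")

        paths["gtf"] = out / "annotation.gtf"
        _write_fixture_gtf(self.genes, paths["gtf"])

        paths["reference"] = out / "reference_proteome.fa"
        with open(paths["reference"], "w") as fh:
            for rec in self.reference_records:
                fh.write(f">{rec.description}\n")
                for i in range(0, len(rec.sequence), 60):
                    fh.write(rec.sequence[i : i + 60] + "\n")

        for name, rows in (("psm_a", self.psm_rows_a), ("psm_b", self.psm_rows_b)):
            paths[name] = out / f"{name}.tsv"
            with open(paths[name], "w") as fh:
                fh.write("peptide\tproteins\tprimary_score\tdelta_cn\tms1\n")
                for row in rows:
                    fh.write(
                        f"{row['peptide']}\t{row['proteins']}\t"
                        f"{row['primary_score']}\t{row['delta_cn']}\t{row['ms1']}\n"
                    )

        if self.proteome_b:
            paths["proteome_b"] = out / "proteome_b.fa"
            write_proteoform_fasta(self.proteome_b, paths["proteome_b"])
            paths["gene_pairs_ab"] = out / "gene_pairs_ab.tsv"
            _write_pairs(self.gene_pairs_ab, paths["gene_pairs_ab"])
        if self.proteome_c:
            paths["proteome_c"] = out / "proteome_c.fa"
            write_proteoform_fasta(self.proteome_c, paths["proteome_c"])
            paths["gene_pairs_ac"] = out / "gene_pairs_ac.tsv"
            _write_pairs(self.gene_pairs_ac, paths["gene_pairs_ac"])
            paths["gene_pairs_cb"] = out / "gene_pairs_cb.tsv"
            _write_pairs(self.gene_pairs_cb, paths["gene_pairs_cb"])

        paths["manifest"] = out / "manifest.json"
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def _write_pairs(pairs: Sequence[tuple[str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def _write_fixture_gtf(genes: Sequence[GeneModel], path: Path) -> None:
    """GTF writer that round-trips the reliability flags through read_gtf."""
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                source = "havana" if tx.havana else "ensembl"
                for start, end in tx.exons:
                    attrs = [
                        f'gene_id "{gene.gene_id}"',
                        f'transcript_id "{tx.transcript_id}"',
                        f'gene_name "{gene.gene_symbol or gene.gene_id}"',
                        f'transcript_biotype "{tx.biotype}"',
                        f'transcript_support_level "{tx.tsl if tx.tsl is not None else "NA"}"',
                    ]
                    if tx.appris:
                        attrs.append(f'tag "appris_{tx.appris}"')
                    fh.write(
                        f"{gene.chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t"
                        f"{gene.strand}\t.\t" + "; ".join(attrs) + ";\n"
                    )


def _round3(x: int) -> int:
    return 3 * ((x + 2) // 3)


def _bg(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BG) for _ in range(n))


def brute_force_matrix_rows(exon_chains: dict[str, list[Interval]]) -> dict[str, str]:
    """Per-base brute-force ternary encoding (independent matrix oracle).

    Classifies every base of the gene span by exon membership, then
    compresses to segments between the union of exon boundaries.
    """
    span_start = min(s for chain in exon_chains.values() for s, _ in chain)
    span_end = max(e for chain in exon_chains.values() for _, e in chain)
    width = span_end - span_start
    masks = {}
    for tid, chain in exon_chains.items():
        mask = [False] * width
        for s, e in chain:
            for pos in range(s - span_start, e - span_start):
                mask[pos] = True
        masks[tid] = mask
    any_exonic = [any(masks[tid][i] for tid in masks) for i in range(width)]
    cuts = sorted(
        {s for chain in exon_chains.values() for s, _ in chain}
        | {e for chain in exon_chains.values() for _, e in chain}
    )
    rows = {}
    for tid, mask in masks.items():
        chars = []
        for a, b in zip(cuts, cuts[1:]):
            seg = range(a - span_start, b - span_start)
            if not any(any_exonic[i] for i in seg):
                chars.append("|")
            elif all(mask[i] for i in seg):
                chars.append("1")
            else:
                chars.append("0")
        rows[tid] = "".join(chars)
    return rows


# ---------------------------------------------------------------------------
# per-gene construction
# ---------------------------------------------------------------------------

@dataclass
class _GenePlan:
    gene_id: str
    chrom: str
    strand: str
    pre_mrna: str  # sense orientation, introns included
    region_start: int  # genomic offset of the region on its chromosome
    sense_chains: dict[str, list[Interval]]  # tid -> sense exon intervals
    tx_order: list[str]
    flags: dict[str, dict]
    orf_start: int
    met_trim: int  # residues trimmed by start-Met correction (0 = none)
    ptc_distance: Optional[int]
    nmd_tids: list[str]
    planted_events: dict[str, str]


def _plan_gene(
    gidx: int,
    rng: random.Random,
    spec: FixtureSpec,
    ptc_distance: Optional[int],
    make_dup: bool,
    make_met: bool,
) -> _GenePlan:
    gene_id = f"G{gidx:04d}"
    strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
    k = rng.randint(*spec.exon_count)
    lens = [_round3(rng.randint(*spec.exon_length)) for _ in range(k)]
    introns = [_round3(rng.randint(*spec.intron_length)) for _ in range(k - 1)]

    orf_start = rng.randint(6, 20)
    # first exon must hold the 5' UTR plus the first ~22 codons so that
    # every variant shares the reference-matching start of the protein
    lens[0] = max(lens[0], _round3(orf_start + 69))

    base = sum(lens[:-1])  # cDNA offset where the last exon begins
    o = (orf_start - base) % 3 + 3 * rng.randint(0, 3)
    max_d = ptc_distance if ptc_distance is not None else 0
    lens[-1] = max(lens[-1], _round3(o + 3 + max_d + 9))
    stop_tx = base + o
    total = sum(lens)

    cdna = list(_bg(rng, total))
    cdna[orf_start : orf_start + 3] = "ATG"
    cdna[stop_tx : stop_tx + 3] = "TAA"
    cdna[stop_tx + 3] = "C"  # a following T would form a spurious ATG
    met_trim = 0
    if make_met:
        met_trim = rng.randint(4, 8)
        pos = orf_start + 3 * met_trim
        cdna[pos : pos + 3] = "ATG"
    cdna = "".join(cdna)

    # lay exons and introns onto the pre-mRNA (sense orientation)
    sense_exons: list[Interval] = []
    pre_parts: list[str] = []
    pos = 0
    consumed = 0
    for i, ln in enumerate(lens):
        sense_exons.append((pos, pos + ln))
        pre_parts.append(cdna[consumed : consumed + ln])
        consumed += ln
        pos += ln
        if i < k - 1:
            pre_parts.append(_bg(rng, introns[i]))
            pos += introns[i]
    pre_mrna = "".join(pre_parts)

    canonical_tid = f"T{gidx:04d}C"
    chains: dict[str, list[Interval]] = {canonical_tid: list(sense_exons)}
    tx_order = [canonical_tid]
    flags = {
        canonical_tid: dict(
            biotype="protein_coding", tsl=1, appris="principal_1", havana=True
        )
    }
    planted_events: dict[str, str] = {}
    nmd_tids: list[str] = []

    n_tx = rng.randint(*spec.transcripts_per_gene)
    slots = max(n_tx - 1, (1 if ptc_distance is not None else 0) + (1 if make_dup else 0))
    vidx = 0

    def add_variant(chain: list[Interval], event: str, nmd: bool = False) -> str:
        nonlocal vidx
        tid = f"T{gidx:04d}V{vidx}"
        vidx += 1
        chains[tid] = chain
        tx_order.append(tid)
        flags[tid] = dict(
            biotype="protein_coding",
            tsl=rng.choice([2, 3, 4, 5, None]),
            appris=None,
            havana=bool(rng.random() < 0.3),
        )
        planted_events[tid] = event
        if nmd:
            nmd_tids.append(tid)
        return tid

    if ptc_distance is not None:
        # truncate the last exon just downstream of the stop and append a
        # 3'-UTR cassette exon: the stop becomes premature at exactly the
        # requested junction distance, with the ORF untouched
        kept = o + 3 + ptc_distance
        if kept > lens[-1]:
            raise SpliceForgeError(
                f"infeasible spec: PTC distance {ptc_distance} exceeds the "
                f"last exon of {gene_id}"
            )
        last_s, last_e = sense_exons[-1]
        gap, extra_len = 60, 120
        extra = (len(pre_mrna) + gap, len(pre_mrna) + gap + extra_len)
        pre_mrna += _bg(rng, gap + extra_len)
        chain = sense_exons[:-1] + [(last_s, last_s + kept), extra]
        add_variant([iv for iv in chain if iv[0] < iv[1]], "NMD_in", nmd=True)
        slots -= 1

    if make_dup:
        tid = f"T{gidx:04d}D"
        chains[tid] = list(sense_exons)
        tx_order.append(tid)
        flags[tid] = dict(biotype="protein_coding", tsl=5, appris=None, havana=False)
        planted_events[tid] = "duplicate_pattern"
        slots -= 1

    attempts = 0
    while slots > 0 and attempts < 20:
        attempts += 1
        event = rng.choice(CODING_EVENTS)
        chain = None
        if event == "cassette_ex" and k >= 4:
            i = rng.randint(1, k - 2)
            chain = sense_exons[:i] + sense_exons[i + 1 :]
        elif event == "cassette_in":
            i = rng.randint(0, k - 2)
            istart, iend = sense_exons[i][1], sense_exons[i + 1][0]
            ln = min(_round3(rng.randint(24, 60)), _round3(iend - istart - 12))
            if ln >= 12:
                a = istart + 6
                chain = sense_exons[: i + 1] + [(a, a + ln)] + sense_exons[i + 1 :]
        elif event == "A3SS":
            i = rng.randint(1, k - 2)
            d = 3 * rng.randint(1, 4)
            s, e = sense_exons[i]
            if e - (s + d) >= 30:
                chain = sense_exons[:i] + [(s + d, e)] + sense_exons[i + 1 :]
        elif event == "A5SS":
            i = rng.randint(1, k - 2)
            d = 3 * rng.randint(1, 4)
            s, e = sense_exons[i]
            if (e - d) - s >= 30:
                chain = sense_exons[:i] + [(s, e - d)] + sense_exons[i + 1 :]
        elif event == "intron_retention":
            i = rng.randint(0, k - 2)
            merged = (sense_exons[i][0], sense_exons[i + 1][1])
            chain = sense_exons[:i] + [merged] + sense_exons[i + 2 :]
        if chain is None or any(chain == c for c in chains.values()):
            continue
        add_variant(chain, event)
        slots -= 1

    return _GenePlan(
        gene_id=gene_id,
        chrom=f"chr{1 + gidx % 2}",
        strand=strand,
        pre_mrna=pre_mrna,
        region_start=0,  # set during genome assembly
        sense_chains=chains,
        tx_order=tx_order,
        flags=flags,
        orf_start=orf_start,
        met_trim=met_trim,
        ptc_distance=ptc_distance,
        nmd_tids=nmd_tids,
        planted_events=planted_events,
    )


def _sense_to_genomic(
    chain: Sequence[Interval], region_start: int, region_len: int, strand: str
) -> list[Interval]:
    if strand == "+":
        out = [(region_start + s, region_start + e) for s, e in chain]
    else:
        out = [(region_start + region_len - e, region_start + region_len - s) for s, e in chain]
    return sorted(out)


def _variant_cdna(plan: _GenePlan, tid: str) -> str:
    return "".join(plan.pre_mrna[s:e] for s, e in plan.sense_chains[tid])


def _translate_planted(cdna: str, orf_start: int) -> str:
    """Expected protein: translate from the planted ATG to the first stop."""
    coding = cdna[orf_start:]
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate(to_stop=True))


def mutate_orthologs(
    proteome: Sequence[tuple[str, str]], rate: float, seed: int
) -> list[tuple[str, str]]:
    """Simulate an orthologous proteome by per-residue substitution.

    Each residue mutates with probability ``rate``; a mutation is a
    conservative (BLOSUM62-positive) substitution with probability 0.7,
    otherwise a uniform draw over the other residues.  Expected pairwise
    identity is therefore ~``100 * (1 - rate)``.
    """
    if not 0.0 <= rate <= 0.4:
        raise SpliceForgeError("mutation rate outside [0, 0.4]")
    rng = random.Random(seed)
    out = []
    for pid, seq in proteome:
        residues = []
        for aa in seq:
            if rng.random() < rate and aa in _CONSERVATIVE:
                if rng.random() < 0.7:
                    residues.append(rng.choice(_CONSERVATIVE[aa]))
                else:
                    residues.append(rng.choice([c for c in _AA20 if c != aa]))
            else:
                residues.append(aa)
        out.append((pid, "".join(residues)))
    return out


# ---------------------------------------------------------------------------
# fixture assembly
# ---------------------------------------------------------------------------

def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build the full fixture bundle and its ground-truth manifest."""
    spec.validate()
    master = random.Random(spec.seed)

    ptc_assignment: dict[int, int] = {}
    gene_indices = list(range(spec.n_genes))
    ptc_genes = master.sample(gene_indices, len(spec.ptc_distances))
    for gi, d in zip(ptc_genes, spec.ptc_distances):
        ptc_assignment[gi] = d
    dup_genes = set(master.sample(gene_indices, min(spec.n_duplicate_pattern_genes, spec.n_genes)))
    met_genes = set(
        master.sample(
            [g for g in gene_indices if g not in ptc_assignment],
            min(spec.n_met_correction_genes, spec.n_genes - len(ptc_assignment)),
        )
    )

    plans: list[_GenePlan] = []
    for gidx in gene_indices:
        rng = random.Random(master.randrange(2**31))
        plans.append(
            _plan_gene(
                gidx,
                rng,
                spec,
                ptc_assignment.get(gidx),
                gidx in dup_genes,
                gidx in met_genes,
            )
        )

    # genome assembly: genes tiled per chromosome with background spacers
    chrom_parts: dict[str, list[str]] = {}
    chrom_len: dict[str, int] = {}
    spacer_rng = random.Random(master.randrange(2**31))
    genes: list[GeneModel] = []
    manifest_genes: dict[str, dict] = {}

    for plan in plans:
        parts = chrom_parts.setdefault(plan.chrom, [])
        length = chrom_len.setdefault(plan.chrom, 0)
        spacer = _bg(spacer_rng, spacer_rng.randint(100, 200))
        parts.append(spacer)
        length += len(spacer)
        plan.region_start = length
        region = plan.pre_mrna if plan.strand == "+" else reverse_complement(plan.pre_mrna)
        parts.append(region)
        chrom_len[plan.chrom] = length + len(region)

        region_len = len(plan.pre_mrna)
        genomic_chains = {
            tid: _sense_to_genomic(chain, plan.region_start, region_len, plan.strand)
            for tid, chain in plan.sense_chains.items()
        }
        transcripts = [
            TranscriptModel(
                transcript_id=tid,
                gene_id=plan.gene_id,
                gene_symbol=plan.gene_id,
                chrom=plan.chrom,
                strand=plan.strand,
                exons=genomic_chains[tid],
                **plan.flags[tid],
            )
            for tid in plan.tx_order
        ]
        genes.append(
            GeneModel(
                gene_id=plan.gene_id,
                chrom=plan.chrom,
                strand=plan.strand,
                transcripts=transcripts,
                gene_symbol=plan.gene_id,
            )
        )

        # --- constructive expectations -----------------------------------
        matrix_rows = brute_force_matrix_rows(genomic_chains)
        pattern_groups: dict[str, list[str]] = {}
        for tid in plan.tx_order:
            pattern_groups.setdefault(matrix_rows[tid], []).append(tid)

        variants = []
        nmd_expect = {}
        canonical_tid = plan.tx_order[0]
        for pattern, members in pattern_groups.items():
            rep = _expected_representative(members, plan.flags, genomic_chains)
            cdna = _variant_cdna(plan, rep)
            raw = _translate_planted(cdna, plan.orf_start)
            protein = raw[plan.met_trim :] if plan.met_trim else raw
            is_nmd = rep in plan.nmd_tids
            lens = [e - s for s, e in plan.sense_chains[rep]]
            stop_tx = plan.orf_start + 3 * len(raw)
            junction = sum(lens[:-1]) if len(lens) > 1 else None
            distance = None if junction is None else junction - (stop_tx + 3)
            is_target = distance is not None and distance >= 50
            variants.append(
                {
                    "pattern": pattern,
                    "members": members,
                    "representative": rep,
                    "protein_id": f"SP2_{plan.gene_id}_{rep}",
                    "protein": protein,
                    "raw_protein": raw,
                    "met_corrected": bool(plan.met_trim),
                    "nmd_target": is_target,
                    "event": plan.planted_events.get(rep, "none"),
                }
            )
            nmd_expect[rep] = {
                "is_target": is_target,
                "junction_distance": distance,
            }
            if is_nmd:
                assert is_target == (plan.ptc_distance >= 50)

        manifest_genes[plan.gene_id] = {
            "chrom": plan.chrom,
            "strand": plan.strand,
            "orf_start": plan.orf_start,
            "ptc_distance": plan.ptc_distance,
            "met_trim": plan.met_trim,
            "exons": {tid: list(map(list, genomic_chains[tid])) for tid in plan.tx_order},
            "matrix_rows": matrix_rows,
            "variants": variants,
            "nmd": nmd_expect,
            "planted_events": plan.planted_events,
        }

    genome = {
        chrom: GenomeSequence(chrom=chrom, sequence="".join(chrom_parts[chrom]))
        for chrom in sorted(chrom_parts)
    }

    # self-check: the canonical cDNA spliced back out of the genome must
    # equal the designed sense sequence
    for plan, gene in zip(plans, genes):
        tid = plan.tx_order[0]
        chain = gene.transcripts[0].exons
        seq = "".join(genome[gene.chrom].fetch(s, e) for s, e in chain)
        if gene.strand == "-":
            seq = reverse_complement(seq)
        if seq != _variant_cdna(plan, tid):
            raise SpliceForgeError(f"internal fixture error: {tid} cDNA mismatch")

    # reference proteome: the canonical protein of every gene (met-trim
    # genes reference the downstream-Met form, exercising the correction)
    reference_records = []
    for i, plan in enumerate(plans):
        canonical = manifest_genes[plan.gene_id]["variants"][0]
        acc = f"P{i + 1:05d}"
        reference_records.append(
            ProteinRecord(
                protein_id=acc,
                sequence=canonical["protein"],
                description=(
                    f"sp|{acc}|{plan.gene_id}_SYN synthetic reference "
                    f"GN={plan.gene_id}"
                ),
            )
        )
        manifest_genes[plan.gene_id]["reference_accession"] = acc

    psm_rng = random.Random(master.randrange(2**31))
    psm_rows_a, psm_rows_b, psm_expect = _plan_psm(
        psm_rng, spec, manifest_genes, [r.sequence for r in reference_records]
    )

    fixture = Fixture(
        spec=spec,
        genome=genome,
        genes=genes,
        reference_records=reference_records,
        psm_rows_a=psm_rows_a,
        psm_rows_b=psm_rows_b,
        manifest={
            "seed": spec.seed,
            "n_genes": spec.n_genes,
            "genes": manifest_genes,
            "psm": psm_expect,
        },
    )

    if spec.n_species >= 2:
        _plan_species(fixture, plans, manifest_genes, master)
    return fixture


def _expected_representative(
    members: list[str], flags: dict[str, dict], chains: dict[str, list[Interval]]
) -> str:
    def appris_rank(tag):
        return 1 if tag else 99

    def key(tid):
        f = flags[tid]
        length = sum(e - s for s, e in chains[tid])
        return (
            not (f["biotype"] == "protein_coding" and f["havana"]),
            f["tsl"] if f["tsl"] is not None else 6,
            appris_rank(f["appris"]),
            -length,
            tid,
        )

    return min(members, key=key)


def _unique_window(
    rng: random.Random,
    protein: str,
    all_db: dict[str, str],
    owner: str,
    references: Sequence[str],
    length: int = 12,
) -> Optional[str]:
    """A peptide occurring in exactly one database protein and no reference."""
    if len(protein) <= length:
        return None
    offsets = list(range(len(protein) - length))
    rng.shuffle(offsets)
    for off in offsets:
        pep = protein[off : off + length]
        if any(pep in ref for ref in references):
            continue
        owners = [pid for pid, seq in all_db.items() if pep in seq]
        if owners == [owner]:
            return pep
    return None


def _plan_psm(
    rng: random.Random,
    spec: FixtureSpec,
    manifest_genes: dict,
    references: Sequence[str],
) -> tuple[list[dict], list[dict], dict]:
    # expected PSM-search database: reference canonical per gene plus the
    # novel (non-NMD, non-reference-matching) variant proteoforms
    db: dict[str, str] = {}
    for gid, g in manifest_genes.items():
        db[g["reference_accession"] + "-1"] = g["variants"][0]["protein"]
        seen: set[str] = set()
        for v in g["variants"][1:]:
            seq = v["protein"]
            if v["nmd_target"] or seq in seen:
                continue
            if any(seq == r or seq in r or r in seq for r in references):
                continue  # the reference purge removes these
            seen.add(seq)
            db[v["protein_id"]] = seq
    novel = [(pid, seq) for pid, seq in db.items() if not pid.endswith("-1")]

    def ms1() -> float:
        return round(rng.uniform(400.0, 1600.0), 4)

    def row(pep, prots, score, dcn, mass=None):
        return {
            "peptide": pep,
            "proteins": prots,
            "primary_score": score,
            "delta_cn": dcn,
            "ms1": mass if mass is not None else ms1(),
        }

    rows_a: list[dict] = []
    rows_b: list[dict] = []
    true_peptides: list[str] = []
    used: set[str] = set()

    pool = list(novel)
    rng.shuffle(pool)
    for pid, seq in pool:
        if len(true_peptides) >= spec.n_true_peptides:
            break
        pep = _unique_window(rng, seq, db, pid, references)
        if pep is None or pep in used:
            continue
        used.add(pep)
        true_peptides.append(pep)
        rows_a.append(row(pep, pid, round(rng.uniform(3.0, 6.0), 2), round(rng.uniform(0.1, 0.4), 3)))

    expected_exclusive = list(true_peptides)
    expected_surviving_a = list(true_peptides)

    if spec.plant_psm_decoys and novel:
        def pick_peptide() -> tuple[str, str]:
            for pid, seq in novel:
                pep = _unique_window(rng, seq, db, pid, references)
                if pep and pep not in used:
                    used.add(pep)
                    return pep, pid
            # synthetic decoy: residues whose codons all contain adenine
            # (K,N,E,D,Q,H,I) never occur in the generated proteins, so
            # the peptide is guaranteed absent from db and reference
            pep = "".join(rng.choice("KNEDQHI") for _ in range(12))
            while pep in used:
                pep = "".join(rng.choice("KNEDQHI") for _ in range(12))
            used.add(pep)
            return pep, novel[rng.randrange(len(novel))][0]

        # boundary rows: scores exactly at the cutoffs
        pep, pid = pick_peptide()
        rows_a.append(row(pep, pid, 2.5, 0.1))  # passes: score >= 2.5
        expected_surviving_a.append(pep)
        expected_exclusive.append(pep)

        pep, pid = pick_peptide()
        rows_a.append(row(pep, pid, 2.4, 0.2))  # fails primary score

        pep, pid = pick_peptide()
        rows_a.append(row(pep, pid, 3.0, 0.05))  # fails: Delta CN not strictly > 0.05

        pep, pid = pick_peptide()
        rows_a.append(row(pep, pid, 3.0, 0.051))  # passes the strict bound
        expected_surviving_a.append(pep)
        expected_exclusive.append(pep)

        # multi-protein peptide: dropped by the uniqueness filter
        pep, pid = pick_peptide()
        other = next((q for q, _ in novel if q != pid), "DECOY_P")
        rows_a.append(row(pep, f"{pid};{other}", 4.0, 0.2))

        # MS1 duplicates: same peptide and mass, highest score survives once
        pep, pid = pick_peptide()
        mass = ms1()
        rows_a.append(row(pep, pid, 3.0, 0.2, mass))
        rows_a.append(row(pep, pid, 4.0, 0.25, mass))
        expected_surviving_a.append(pep)
        expected_exclusive.append(pep)

        # same peptide at two distinct masses attributed to two proteins:
        # both rows survive deduplication, the union exceeds one protein
        pep, pid = pick_peptide()
        other2 = next((q for q, _ in novel if q != pid), "DECOY_P")
        rows_a.append(row(pep, pid, 4.0, 0.2))
        rows_a.append(row(pep, other2, 4.2, 0.2))

        # peptide identified in both databases: never exclusive
        pep, pid = pick_peptide()
        rows_a.append(row(pep, pid, 4.0, 0.2))
        rows_b.append(row(pep, "B_" + pid, 4.0, 0.2))
        expected_surviving_a.append(pep)

        # peptide contained in a reference protein: excluded at the end
        ref = references[0]
        start = rng.randint(0, max(len(ref) - 12, 0))
        refpep = ref[start : start + 12]
        rows_a.append(row(refpep, pid, 4.5, 0.2))
        if refpep not in expected_surviving_a:
            expected_surviving_a.append(refpep)

        # a row unique to the comparison database
        pep, pid = pick_peptide()
        rows_b.append(row(pep, "B_" + pid, 3.5, 0.2))

    expect = {
        "db_records": {pid: seq for pid, seq in sorted(db.items())},
        "true_peptides": true_peptides,
        "expected_surviving_a": sorted(set(expected_surviving_a)),
        "expected_exclusive": sorted(set(expected_exclusive)),
    }
    return rows_a, rows_b, expect


def _plan_species(
    fixture: Fixture,
    plans: Sequence[_GenePlan],
    manifest_genes: dict,
    master: random.Random,
) -> None:
    """Derive mutated ortholog proteomes (species B and C) plus gene pairs."""
    spec = fixture.spec
    proteins_a: list[tuple[str, str]] = []
    nmd_flags_a: dict[str, bool] = {}
    gene_of: dict[str, str] = {}
    for gid, g in manifest_genes.items():
        for v in g["variants"]:
            proteins_a.append((v["protein_id"], v["protein"]))
            nmd_flags_a[v["protein_id"]] = v["nmd_target"]
            gene_of[v["protein_id"]] = gid

    def derive(suffix: str, seed: int) -> tuple[list[ProteinRecord], dict[str, bool]]:
        mutated = mutate_orthologs(proteins_a, spec.mutation_rate, seed)
        records = []
        flags = {}
        for (pid, _), (_, seq) in zip(proteins_a, mutated):
            new_id = f"{pid}_{suffix}"
            records.append(
                ProteinRecord(
                    protein_id=new_id,
                    gene_id=f"{gene_of[pid]}_{suffix}",
                    transcript_id="",
                    canonical=False,
                    nmd_target=nmd_flags_a[pid],
                    sequence=seq,
                )
            )
            flags[new_id] = nmd_flags_a[pid]
        return records, flags

    fixture.proteome_b, nmd_flags_b = derive("B", master.randrange(2**31))
    fixture.gene_pairs_ab = [(gid, f"{gid}_B") for gid in manifest_genes]
    pairs_ab = [(pid, f"{pid}_B") for pid, _ in proteins_a]
    ortho = {
        "planted_pairs_ab": pairs_ab,
        "nmd_flags_a": nmd_flags_a,
        "nmd_flags_b": nmd_flags_b,
        "mutation_rate": spec.mutation_rate,
    }
    if spec.n_species >= 3:
        fixture.proteome_c, nmd_flags_c = derive("C", master.randrange(2**31))
        fixture.gene_pairs_ac = [(gid, f"{gid}_C") for gid in manifest_genes]
        fixture.gene_pairs_cb = [(f"{gid}_C", f"{gid}_B") for gid in manifest_genes]
        ortho["planted_pairs_ac"] = [(pid, f"{pid}_C") for pid, _ in proteins_a]
        ortho["planted_pairs_cb"] = [(f"{pid}_C", f"{pid}_B") for pid, _ in proteins_a]
        ortho["planted_triads"] = [
            (pid, f"{pid}_B", f"{pid}_C") for pid, _ in proteins_a
        ]
        ortho["nmd_flags_c"] = nmd_flags_c
    fixture.manifest["orthology"] = ortho


# ---------------------------------------------------------------------------
# standalone purge fixture (database-invariant testing)
# ---------------------------------------------------------------------------

def generate_purge_fixture(
    seed: int,
    n_genes: int = 10,
    n_reference: int = 15,
) -> tuple[list[Proteoform], list[str], dict[str, str], set[str]]:
    """Random proteoform sets with planted reference-containment relations.

    Returns (proteoforms, reference sequences, expected removals with
    reasons, expected kept record ids).  Plants, across genes: sequences
    identical to a reference, substrings of a reference, superstrings of
    a reference, and sub-10-residue entries.
    """
    rng = random.Random(seed)

    def protein(n: int) -> str:
        return "".join(rng.choice(_AA20) for _ in range(n))

    references = [protein(rng.randint(40, 90)) for _ in range(n_reference)]
    proteoforms: list[Proteoform] = []
    expected_removed: dict[str, str] = {}
    expected_kept: set[str] = set()
    counter = 0

    def add(gene: str, seq: str, expect: Optional[str]) -> None:
        nonlocal counter
        pid = f"Q{counter:04d}"
        counter += 1
        proteoforms.append(
            Proteoform(
                protein_id=pid,
                gene_id=gene,
                transcript_id=f"t{counter}",
                sequence=seq,
                orf_end=3 * len(seq),
                translatable=False,
            )
        )
        if expect is None:
            expected_kept.add(pid)
        else:
            expected_removed[pid] = expect

    for gi in range(n_genes):
        gene = f"PG{gi:03d}"
        ref = references[rng.randrange(len(references))]
        novel = protein(rng.randint(25, 60))
        while any(novel in r or r in novel for r in references):
            novel = protein(rng.randint(25, 60))
        add(gene, novel, None)
        kind = rng.choice(["identical", "substring", "superstring", "short", "none"])
        if kind == "identical":
            add(gene, ref, "identical")
        elif kind == "substring":
            a = rng.randint(0, len(ref) - 15)
            add(gene, ref[a : a + 14], "substring")
        elif kind == "superstring":
            add(gene, protein(8) + ref + protein(8), "superstring")
        elif kind == "short":
            add(gene, protein(rng.randint(1, 9)), "short")
    return proteoforms, references, expected_removed, expected_kept
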