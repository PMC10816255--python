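"""End-to-end orchestration: reconstruction -> translation -> NMD ->
PSM database -> proteotypic filtering -> orthology.

Every stage is a thin composition of the per-module operations so that
library users can run any slice of the pipeline; :func:`run_pipeline`
drives the whole chain from files and writes a JSON run manifest with
per-stage parameters and output checksums.  All stages are
deterministic, so identical inputs and configuration produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from . import io_formats, nmd as nmd_mod, orthology, psmdb, splicegraph, translator
from .models import (
    GeneModel,
    GenomeSequence,
    NMDVerdict,
    Proteoform,
    SpliceForgeError,
    TranscriptModel,
)
from .splicegraph import SpliceVariant, TernaryMatrix, _reliability_key

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run; unknown keys are rejected."""

    genome: Optional[str] = None
    gtf: Optional[str] = None
    reference_proteome: Optional[str] = None
    psm_table_a: Optional[str] = None
    psm_table_b: Optional[str] = None
    proteome_b: Optional[str] = None
    proteome_c: Optional[str] = None
    gene_pairs_ab: Optional[str] = None
    gene_pairs_ac: Optional[str] = None
    gene_pairs_cb: Optional[str] = None
    out_dir: str = "spliceforge_out"
    mode: str = "tsl"
    nmd_threshold_nt: int = nmd_mod.DEFAULT_NMD_THRESHOLD_NT
    min_len: int = psmdb.DEFAULT_MIN_LENGTH
    primary_score_min: float = psmdb.DEFAULT_PRIMARY_SCORE_MIN
    delta_cn_min: float = psmdb.DEFAULT_DELTA_CN_MIN
    min_similarity: float = orthology.DEFAULT_MIN_SIMILARITY
    max_gap: float = orthology.DEFAULT_MAX_GAP
    rbh_tcov: float = orthology.DEFAULT_RBH_TARGET_COV
    rbh_qcov: float = orthology.DEFAULT_RBH_QUERY_COV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("tsl", "appris"):
            raise SpliceForgeError(f"mode must be tsl or appris, got {self.mode!r}")
        checks = [
            (0 <= self.nmd_threshold_nt <= 10_000, "nmd_threshold_nt"),
            (self.min_len >= 0, "min_len"),
            (0 <= self.min_similarity <= 100, "min_similarity"),
            (0 <= self.max_gap <= 1, "max_gap"),
            (0 <= self.rbh_tcov <= 100, "rbh_tcov"),
            (0 <= self.rbh_qcov <= 100, "rbh_qcov"),
        ]
        for ok, name in checks:
            if not ok:
                raise SpliceForgeError(f"config value {name} outside documented range")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise SpliceForgeError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# in-memory stages
# ---------------------------------------------------------------------------

@dataclass
class GeneResult:
    gene: GeneModel
    matrix: TernaryMatrix
    variants: list[SpliceVariant]


def reconstruct_genes(
    genes: Sequence[GeneModel],
    genome: Mapping[str, GenomeSequence],
    mode: str = "tsl",
) -> list[GeneResult]:
    """Ternary matrix, pattern clustering, consensus and cDNA per gene."""
    results = []
    for gene in genes:
        matrix, variants = splicegraph.build_gene_variants(gene, genome, mode=mode)
        results.append(GeneResult(gene=gene, matrix=matrix, variants=variants))
    return results


def proteoform_id(gene_id: str, representative_id: str) -> str:
    return f"SP2_{gene_id}_{representative_id}"


def translate_genes(
    results: Sequence[GeneResult],
    reference_map: Optional[Mapping[str, tuple[str, str]]] = None,
) -> list[Proteoform]:
    """One proteoform per splice variant, with start-Met correction when
    the gene has an annotation-linked reference protein."""
    proteoforms = []
    for res in results:
        designated = (reference_map or {}).get(res.gene.gene_id)
        for variant in res.variants:
            p = translator.translate_variant(
                proteoform_id(res.gene.gene_id, variant.representative_id),
                res.gene.gene_id,
                variant.representative_id,
                variant.cdna,
            )
            if not p.translatable or not p.sequence:
                logger.info("variant %s untranslatable; skipped", p.protein_id)
                continue
            if designated is not None:
                p = translator.correct_start_methionine(p, designated[1])
            proteoforms.append(p)
    return proteoforms


def _variant_exon_lengths_tx_order(variant: SpliceVariant, strand: str) -> list[int]:
    exons = variant.exons if strand == "+" else list(reversed(variant.exons))
    return [e - s for s, e in exons]


def call_nmd(
    results: Sequence[GeneResult],
    proteoforms: Sequence[Proteoform],
    threshold_nt: int = nmd_mod.DEFAULT_NMD_THRESHOLD_NT,
) -> dict[str, NMDVerdict]:
    """NMD verdict per proteoform; flags are written onto the proteoforms
    and the causal splicing event classified against a non-target
    reference transcript of the same gene."""
    by_id = {p.protein_id: p for p in proteoforms}
    verdicts: dict[str, NMDVerdict] = {}
    for res in results:
        gene = res.gene
        gene_verdicts = []
        for variant in res.variants:
            pid = proteoform_id(gene.gene_id, variant.representative_id)
            p = by_id.get(pid)
            if p is None:
                continue
            verdict = nmd_mod.classify_nmd(
                variant.representative_id,
                p,
                _variant_exon_lengths_tx_order(variant, gene.strand),
                threshold_nt=threshold_nt,
            )
            p.nmd_target = verdict.is_target
            gene_verdicts.append((variant, p, verdict))
            verdicts[pid] = verdict

        transcripts = {t.transcript_id: t for t in gene.transcripts}
        non_targets = [v for v, _, verdict in gene_verdicts if not verdict.is_target]
        reference = None
        if non_targets:
            reference = min(
                non_targets,
                key=lambda v: _reliability_key(transcripts[v.representative_id]),
            )
        for variant, p, verdict in gene_verdicts:
            if not verdict.is_target:
                continue
            if reference is None:
                verdict.event = "complex"
                logger.info(
                    "gene %s has no non-target reference transcript", gene.gene_id
                )
                continue
            verdict.event = nmd_mod.classify_as_event(
                variant.exons, reference.exons, strand=gene.strand
            )
    return verdicts


def ortholog_clusters(
    proteins_a: Mapping[str, list[tuple[str, str]]],
    proteins_b: Mapping[str, list[tuple[str, str]]],
    gene_pairs: Sequence[tuple[str, str]],
) -> list[tuple[tuple[str, str], list[tuple[str, str]], list[tuple[str, str]]]]:
    """Group (id, sequence) lists by ortholog gene pair for the aligner."""
    clusters = []
    for ga, gb in gene_pairs:
        pa = proteins_a.get(ga, [])
        pb = proteins_b.get(gb, [])
        if pa and pb:
            clusters.append(((ga, gb), pa, pb))
    return clusters


def proteins_by_gene(records) -> dict[str, list[tuple[str, str]]]:
    """Index proteoforms/protein records as gene -> [(id, sequence)]."""
    out: dict[str, list[tuple[str, str]]] = {}
    for rec in records:
        out.setdefault(rec.gene_id, []).append((rec.protein_id, rec.sequence))
    return out


# ---------------------------------------------------------------------------
# file-level run
# ---------------------------------------------------------------------------

def _transcript_from_exons(transcript_id: str, gene: GeneModel, exons) -> TranscriptModel:
    """A minimal transcript carrying a reconstructed exon chain."""
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene.gene_id,
        gene_symbol=gene.gene_symbol,
        chrom=gene.chrom,
        strand=gene.strand,
        exons=[tuple(e) for e in exons],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_gene_pairs(path: Union[str, Path]) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or (i == 0 and parts[0].lower().startswith("gene")):
                continue
            pairs.append((parts[0], parts[1]))
    return pairs


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the run manifest dict.

    Raises :class:`SpliceForgeError` on missing inputs or invariant
    violations; the CLI maps these to exit codes 2 and 3.
    """
    for name in ("genome", "gtf"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"required input --{name} missing: {path}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": []}

    def stage(name: str, outputs: dict[str, Path], **params) -> None:
        manifest["stages"].append(
            {
                "name": name,
                "params": params,
                "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
            }
        )

    # 1. load
    genome = io_formats.read_genome_fasta(config.genome)
    genes = io_formats.read_gtf(config.gtf)
    reference_records = []
    reference_map: dict[str, tuple[str, str]] = {}
    if config.reference_proteome:
        reference_records = io_formats.read_protein_fasta(config.reference_proteome)
        reference_map = io_formats.reference_canonical_map(reference_records)
    stage("load", {}, n_chromosomes=len(genome), n_genes=len(genes))

    # 2. build: matrices + variants + cDNA
    results = reconstruct_genes(genes, genome, mode=config.mode)
    matrices_path = out_dir / "matrices.txt"
    with open(matrices_path, "w") as fh:
        for res in results:
            fh.write(f"# {res.gene.gene_id}\n{res.matrix.as_text()}\n")
    variants_path = out_dir / "variants.json"
    with open(variants_path, "w") as fh:
        json.dump(
            {
                res.gene.gene_id: [
                    {
                        "pattern": v.pattern,
                        "members": v.member_ids,
                        "representative": v.representative_id,
                        "exons": v.exons,
                        "cdna": v.cdna,
                    }
                    for v in res.variants
                ]
                for res in results
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    stage(
        "build",
        {"matrices": matrices_path, "variants": variants_path},
        mode=config.mode,
    )

    # 3. translate (+ start-Met correction)
    proteoforms = translate_genes(results, reference_map)
    stage("translate", {}, n_proteoforms=len(proteoforms))

    # 4. NMD
    verdicts = call_nmd(results, proteoforms, threshold_nt=config.nmd_threshold_nt)
    nmd_path = out_dir / "nmd.tsv"
    with open(nmd_path, "w") as fh:
        fh.write(
            "protein_id\ttranscript_id\tis_target\tstop_tx_pos\t"
            "last_junction_tx_pos\tjunction_distance\tevent\n"
        )
        for pid in sorted(verdicts):
            v = verdicts[pid]
            fh.write(
                f"{pid}\t{v.transcript_id}\t{int(v.is_target)}\t"
                f"{v.stop_tx_pos if v.stop_tx_pos is not None else 'NA'}\t"
                f"{v.last_junction_tx_pos if v.last_junction_tx_pos is not None else 'NA'}\t"
                f"{v.junction_distance if v.junction_distance is not None else 'NA'}\t"
                f"{v.event}\n"
            )
    # customized GTF of the reconstructed variants, transcript-id prefix
    # stripped to force de-novo annotation by external NMD predictors
    custom_gtf_path = out_dir / "variants.gtf"
    custom_genes = []
    for res in results:
        txs = {t.transcript_id: t for t in res.gene.transcripts}
        stripped, _ = nmd_mod.strip_id_prefix(
            [v.representative_id for v in res.variants]
        )
        custom_genes.append(
            GeneModel(
                gene_id=res.gene.gene_id,
                chrom=res.gene.chrom,
                strand=res.gene.strand,
                gene_symbol=res.gene.gene_symbol,
                transcripts=[
                    _transcript_from_exons(sid, res.gene, v.exons)
                    for sid, v in zip(stripped, res.variants)
                ],
            )
        )
    io_formats.write_gtf(custom_genes, custom_gtf_path)
    proteoforms_path = out_dir / "proteoforms.fa"
    io_formats.write_proteoform_fasta(proteoforms, proteoforms_path)
    stage(
        "nmd",
        {"nmd": nmd_path, "custom_gtf": custom_gtf_path, "proteoforms": proteoforms_path},
        threshold_nt=config.nmd_threshold_nt,
        n_targets=sum(v.is_target for v in verdicts.values()),
    )

    # 5. PSM-search database
    reference_sequences = [r.sequence for r in reference_records]
    database = psmdb.build_psm_database(
        proteoforms,
        reference_sequences,
        reference_map,
        min_len=config.min_len,
        drop_nmd=True,
    )
    psm_fa_path = out_dir / "psm_search.fa"
    io_formats.write_proteoform_fasta(database.records, psm_fa_path)
    stage(
        "psmdb",
        {"psm_search": psm_fa_path},
        min_len=config.min_len,
        n_records=len(database.records),
        n_removed_reference=len(database.removed_reference),
    )

    # 6. proteotypic filtering
    exclusive: Optional[set[str]] = None
    if config.psm_table_a and config.psm_table_b:
        psms_a = io_formats.read_psm_table(config.psm_table_a)
        psms_b = io_formats.read_psm_table(config.psm_table_b)
        result_a = psmdb.filter_proteotypic(
            psms_a, config.primary_score_min, config.delta_cn_min
        )
        result_b = psmdb.filter_proteotypic(
            psms_b, config.primary_score_min, config.delta_cn_min
        )
        exclusive = psmdb.exclusive_peptides(result_a, result_b, reference_sequences)
        peptides_path = out_dir / "proteotypic_peptides.tsv"
        with open(peptides_path, "w") as fh:
            fh.write("peptide\tprotein_id\tprimary_score\tdelta_cn\n")
            for pep in sorted(exclusive):
                rec = result_a.peptides[pep]
                fh.write(
                    f"{pep}\t{rec.protein_ids[0]}\t{rec.primary_score}\t{rec.delta_cn}\n"
                )
        stage(
            "proteotypic",
            {"peptides": peptides_path},
            primary_score_min=config.primary_score_min,
            delta_cn_min=config.delta_cn_min,
            n_exclusive=len(exclusive),
        )
    else:
        stage("proteotypic", {}, skipped=True)

    # 7. orthology
    if config.proteome_b and config.gene_pairs_ab:
        prots_a = proteins_by_gene(proteoforms)
        prots_b = proteins_by_gene(io_formats.read_protein_fasta(config.proteome_b))
        pairs_ab = orthology.find_ortholog_pairs(
            ortholog_clusters(prots_a, prots_b, _read_gene_pairs(config.gene_pairs_ab)),
            min_similarity=config.min_similarity,
            max_gap=config.max_gap,
            rbh_tcov=config.rbh_tcov,
            rbh_qcov=config.rbh_qcov,
        )
        pairs_path = out_dir / "ortholog_pairs.tsv"
        with open(pairs_path, "w") as fh:
            fh.write(
                "protein_a\tprotein_b\tmethod\tidentity_pct\tsimilarity_pct\tgap_fraction\n"
            )
            for p in sorted(pairs_ab, key=lambda p: p.key()):
                fh.write(
                    f"{p.species_a_protein}\t{p.species_b_protein}\t{p.method}\t"
                    f"{p.metrics.identity_pct:.2f}\t{p.metrics.similarity_pct:.2f}\t"
                    f"{p.metrics.gap_fraction:.4f}\n"
                )
        outputs = {"pairs": pairs_path}
        n_triads = None
        if config.proteome_c and config.gene_pairs_ac and config.gene_pairs_cb:
            prots_c = proteins_by_gene(io_formats.read_protein_fasta(config.proteome_c))
            pairs_ac = orthology.find_ortholog_pairs(
                ortholog_clusters(prots_a, prots_c, _read_gene_pairs(config.gene_pairs_ac)),
                min_similarity=config.min_similarity,
                max_gap=config.max_gap,
                rbh_tcov=config.rbh_tcov,
                rbh_qcov=config.rbh_qcov,
            )
            pairs_cb = orthology.find_ortholog_pairs(
                ortholog_clusters(prots_c, prots_b, _read_gene_pairs(config.gene_pairs_cb)),
                min_similarity=config.min_similarity,
                max_gap=config.max_gap,
                rbh_tcov=config.rbh_tcov,
                rbh_qcov=config.rbh_qcov,
            )
            triads = orthology.triad_match(pairs_ab, pairs_ac, pairs_cb)
            triads_path = out_dir / "ortholog_triads.tsv"
            with open(triads_path, "w") as fh:
                fh.write("protein_a\tprotein_b\tprotein_c\n")
                for t in triads:
                    fh.write(f"{t.protein_a}\t{t.protein_b}\t{t.protein_c}\n")
            outputs["triads"] = triads_path
            n_triads = len(triads)
        stage(
            "ortho",
            outputs,
            min_similarity=config.min_similarity,
            max_gap=config.max_gap,
            rbh_tcov=config.rbh_tcov,
            rbh_qcov=config.rbh_qcov,
            n_pairs=len(pairs_ab),
            n_triads=n_triads,
        )
    else:
        stage("ortho", {}, skipped=True)

    manifest_path = out_dir / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
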