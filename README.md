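# spliceforge

Proteogenomics toolkit for building splice-variant-aware protein
sequence databases. From a genome FASTA and an Ensembl-style transcript
annotation it reconstructs alternative-splicing variants via per-gene
**ternary matrices**, translates them in silico, purges predicted
**nonsense-mediated decay (NMD)** targets, emits a **PSM-search-optimized
proteoform FASTA**, filters **proteotypic peptides** from
peptide-spectrum-match tables, and calls **orthologous proteoforms**
across species by global alignment plus reciprocal-best-hit rescue.

It is aimed at proteomics groups who search MS/MS spectra against
customized databases: reference proteomes (e.g. UniProtKB/SwissProt)
miss many splice isoforms, and isoform-specific (proteotypic) peptides
can only be detected if the corresponding proteoform sequence is in the
search database.

## The core representations and rules

**Ternary matrix.** Each gene is a matrix: rows are transcripts, columns
are genomic segments cut at the union of all exon boundaries. A cell is
`1` when the segment lies in an exon of that transcript, `0` when the
segment is exonic in some other transcript of the gene but absent here,
and `|` when it is intronic in every transcript. Decoding the maximal
contiguous runs of `1` reproduces each exon chain exactly, so the matrix
is an invertible summary of the gene's splicing patterns. Transcripts
sharing a row form one splice variant; the most reliable member (HAVANA
manual annotation of a protein-coding biotype, then lowest TSL, then
best APPRIS tag, then longest, then smallest id) represents it.

**Translation.** Each variant cDNA is translated in all three frames of
the known gene orientation; the longest ATG-to-stop (or open-ended) ORF
wins. When a gene has an annotation-linked reference protein, a
mischosen initiator methionine is corrected by trimming to the internal
Met whose suffix matches the reference start.

**NMD rule.** With the stop codon at transcript position *s* and the
last exon–exon junction at *j* (both 0-based, exon lengths in transcript
order), the transcript is a predicted NMD target iff

    j − (s + 3) ≥ 50 nt

Single-exon transcripts and open-ended ORFs are never targets. Flagged
variants are classified against a non-target transcript of the same gene
into the event taxonomy {IntronRetention, NMD_in/NMD_ex,
multi_NMD_in/multi_NMD_ex, A3SS, A5SS, A3SS+A5SS, UTR-related, complex}.

**PSM database.** Proteoforms flagged as NMD targets are dropped,
sequences shorter than 10 residues are removed, and any sequence
identical to, a substring of, or a superstring of a reference sequence
is purged (the reference copy remains). Within each gene exactly one
canonical is labeled: the SwissProt-designated canonical when one exists
(its record id gains the `-1` marker, e.g. `P12345-1`), otherwise the
longest sequence.

**Proteotypic filter.** PSM rows survive iff Primary Score ≥ 2.5 and
Delta CN > 0.05; rows duplicated at the same peptide+MS1 value collapse
to the highest-scoring one; peptides attributed to more than one protein
are discarded. Peptides surviving in one database but not a comparison
database, and absent from the reference proteome, are the exclusively
identified proteotypic peptides.

**Orthology.** Within each ortholog gene pair, all proteoform pairs are
aligned by Needleman–Wunsch with affine gaps in EMBOSS `needle`
semantics (BLOSUM62, gap open 10.0, extend 0.5, end gaps free). Pairs
with similarity ≥ 80% and gap fraction ≤ 0.1 pass directly; leftovers
enter a reciprocal-best-hit pass accepted at target coverage ≥ 60% and
query coverage ≥ 90%. Three-species triads require a perfect match
across the a–b, a–c and c–b pairwise analyses.

## Worked example

```python
from spliceforge.models import GeneModel, TranscriptModel
from spliceforge.splicegraph import build_ternary_matrix, exons_from_row

gene = GeneModel("DEMO", "chr1", "+", [
    TranscriptModel("T1", "DEMO", "chr1", "+", [(0, 100), (200, 300)]),
    TranscriptModel("T2", "DEMO", "chr1", "+", [(0, 100), (150, 300)]),
])
matrix = build_ternary_matrix(gene)
print(matrix.as_text())
```

prints

```
T1	1|01
T2	1|11
```

Column 2 (`[100,150)`) is intronic in both transcripts (`|`); column 3
(`[150,200)`) is spliced in by T2 only, so T1 carries `0` there.
Decoding each row with `exons_from_row` returns the exact input chains.

Running `python examples/02_translate_and_nmd.py` (synthetic genes with
premature stops planted at controlled junction distances) prints lines
such as

```
SP2_G0002_T0002V0   frame=2 len= 198aa junction_distance=50 NMD-target NMD_in
SP2_G0003_T0003V0   frame=0 len= 136aa junction_distance=49 stable
```

— a stop 50 nt upstream of the last junction is flagged (and attributed
to an exon-inclusion event), while 49 nt falls on the stable side of the
rule. The other scripts under `examples/` demonstrate the PSM database
build, the proteotypic filter and two-species orthology, each printing
the numbers it computes.

## Command line

Every stage is also a subcommand of the `spliceforge` CLI:

```bash
spliceforge fixtures --seed 5 --out fx/          # synthetic study + manifest
spliceforge run --genome fx/genome.fa --gtf fx/annotation.gtf \
    --reference-proteome fx/reference_proteome.fa --out-dir out/
spliceforge proteotypic --psm-a a.tsv --psm-b b.tsv --reference ref.fa --out peptides.tsv
spliceforge ortho --fasta-a a.fa --fasta-b b.fa --gene-pairs-ab ab.tsv --out pairs.tsv
```

`run` executes load → build → translate → nmd → psmdb → proteotypic →
ortho (stages without inputs are skipped) and writes a JSON run manifest
with per-stage parameters and output checksums. Missing inputs exit
with code 2, invariant violations with code 3.

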