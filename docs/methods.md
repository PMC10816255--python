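# Methods

This note documents the models and procedures implemented by
`spliceforge`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Coordinates and data model

All genomic intervals are 0-based half-open internally; the GTF dialect
(1-based inclusive) is converted at the parsing boundary and nowhere
else. Transcripts are ordered exon chains on one chromosome and strand;
"genes" mixing strands are rejected at parse time because the matrix
encoding assumes a single orientation. Exon chains are assumed to have
introns of at least 1 nt: a zero-length intron is indistinguishable from
a merged exon in the matrix representation (decoding merges adjacent
exonic segments), so such chains cannot round-trip.

## Ternary matrix semantics

Segment boundaries are the union of all exon starts/ends of the gene, so
every exon edge of every transcript coincides with a segment boundary.
Cell semantics: `|` is reserved for segments exonic in *no* transcript
of the gene; a segment exonic in any transcript is `0` in transcripts
lacking it. This is the only reading under which "exonic elsewhere" is
well defined and the encoding invertible, and it covers intron retention
naturally (the retained intron is `1` in the retaining transcript and
`0` in the others, never `|`). Row order follows annotation input order;
no meaning is attached to it.

Representative selection among transcripts sharing a pattern uses the
lexicographic priority (protein-coding ∧ HAVANA) → lowest TSL (absent
ranks below TSL 5) → APPRIS rank (principal1 < … < principal5 <
alternative1 < alternative2 < absent) → greatest spliced length →
smallest transcript id. The final id tie-break exists purely for
determinism.

Consensus outer coordinates come from the gene's reference transcript —
lowest TSL in `tsl` mode (human/mouse usage), best APPRIS tag in
`appris` mode (rat usage), longest transcript as the fallback when the
flags are absent — and adjustment is extension-only: first/last exons
are extended to the consensus span but never trimmed, and internal
junctions are never touched. Trimming behavior is not specified by the
upstream procedure this mirrors, and extension-only is the conservative
reading of external-coordinate quality control.

## Translation and ORF selection

Translation uses the standard nuclear codon table; codons containing N
translate to `X`; trailing partial codons are dropped. ORF selection
considers every ATG-to-next-in-frame-stop ORF in all three frames of the
known gene orientation and keeps the longest, breaking ties toward the
lower frame and then the smaller start offset. Open-ended ORFs (no stop
before the transcript end) are allowed because splice variants may
truncate 3' exons; such proteoforms carry `has_stop=False` and are
exempt from NMD calling. No minimum ORF length is imposed — short
products are handled later by the database length purge.

Start-methionine correction replaces an alignment-based reconciliation
with a deterministic prefix test of equivalent intent: if the
translation disagrees with the annotation-linked reference protein at
its start, the earliest internal Met whose suffix matches the reference
prefix over a window of k = min(20, available length) residues becomes
the new start. Twenty residues make a chance match on the 20-letter
amino-acid alphabet vanishingly unlikely while tolerating short
references. The correction never lengthens a sequence and is skipped
when no internal Met matches (logged).

## NMD prediction

The operative threshold is 50 nt (the 50–55 nt range quoted in the
literature is exposed as `--threshold`/`nmd_threshold_nt`). The distance
convention — junction position minus the position one past the stop
codon — is ours; the boundary case "distance exactly 50" is a target.
Raising the threshold is monotone: it can only unflag.

Event classification compares the flagged variant's exon chain with a
non-target transcript of the same gene (chosen by the representative
priority above) in a fixed decision order: (a) a target exon fully
covering a reference intron → IntronRetention; (b)/(c) one / several
exons present in only one chain → (multi_)NMD_in / (multi_)NMD_ex, with
simultaneous gains and losses → complex; (d) equal-length chains
differing only at exon boundaries → A3SS / A5SS / A3SS+A5SS, mapped
through strand so the labels refer to acceptor/donor sites; (e)
identical chains with the stop outside the reference coding span →
UTR-related; (f) anything else → complex. The order is a design choice;
the external classifier this taxonomy mirrors does not document its
internal precedence.

## PSM database construction

Pipeline order: drop NMD-flagged proteoforms (the PSM-search variant;
the full proteome export keeps them) → drop sequences < 10 aa → purge
against the reference proteome (identical, substring, or superstring;
the reference sequence always remains; containment is tested by exact
string search, equivalent to a naive all-pairs scan) → per-gene
deduplication → canonical labeling. Identity purge is exact string
equality rather than gapped alignment at 100% identity; with end gaps
free the two notions coincide on containment relations, which the purge
already covers.

## Proteotypic filtering

Filter 1 applies Primary Score ≥ 2.5 (the operative methods value; the
alternative cutoff of 2 that appears in benchmarking contexts is
available via `primary_score_min`) and Delta CN strictly > 0.05. Filter
2 treats MS1 values as equal after rounding to 4 decimal places (no
tolerance is documented upstream; 4 decimals matches the printed
precision of the inputs) and keeps the highest-scoring duplicate.
Filter 3 drops peptides whose surviving rows attribute them to more than
one protein, with protein sets unioned across rows. Exclusivity against
a second search result additionally requires absence from the reference
proteome by substring test.

## Orthology

The aligner is an explicit Gotoh dynamic program with EMBOSS `needle`
cost semantics: BLOSUM62, a gap of length L costs 10.0 + 0.5·L, end gaps
free. It is written in-process rather than delegated so that traceback
tie-breaking is fully specified (match state preferred over a gap in the
target over a gap in the query; trailing end gaps minimized), making
repeated runs byte-identical; its scores are cross-checked against an
independent aligner implementation in the test suite. Similarity counts
positive-scoring substitution pairs over the full alignment length
(EMBOSS convention); coverage is the mutually aligned (non-gap) span
over each sequence's length.

The primary filter accepts similarity ≥ 80% and gap fraction ≤ 0.1 (the
figure-level "gap ratio ≤ 1%" variant that also circulates is available
via `max_gap`). The RBH rescue runs only on proteoforms in no accepted
pair, uses the same global aligner (the original pipeline used a local
aligner here; the contract is the coverage thresholds, not the engine),
ranks hits by score with identity and then partner id as tie-breaks, and
accepts mutual bests at target coverage ≥ 60% and query coverage ≥ 90%.
Triads are the perfect-match intersection of the a–b, a–c and c–b pair
sets; the NMD-restricted variant keeps triads whose three members all
derive from flagged transcripts.

## Synthetic data generator

The generator plants gene structures with exact, constructively known
ground truth. All background sequence (exons, introns, spacers) is drawn
from {C, G, T}; since every start and stop codon contains an adenine,
the only ORFs in any transcript, in any frame, are the explicitly
planted ATG→TAA spans. Splicing events (cassette inclusion/exclusion,
A3SS, A5SS, intron retention) are sized in multiples of three so all
variants share the canonical frame, and premature stops are created by
truncating the last exon just downstream of the shared stop and
appending a 3'-UTR cassette exon — which sets the junction distance to
the requested value exactly without touching the ORF. The manifest
(matrix rows by per-base classification, proteins by direct
slice-and-translate, junction distances from the construction, expected
database membership, planted PSM outcomes and ortholog pairs) is
computed during generation, never by running the pipeline, so it is a
true oracle.

Defaults: 12 genes, 2–5 transcripts each, 4–6 exons of 90–180 nt,
introns 60–150 nt, ~40% minus-strand, premature stops at junction
distances {0, 49, 50, 51, 500} (one gene each, bracketing the rule's
boundary), 5% per-residue ortholog substitution (70% conservative,
i.e. BLOSUM62-positive), six planted proteotypic peptides plus decoy
rows at every filter boundary (scores 2.4/2.5, Delta CN 0.05/0.051,
multi-protein rows, MS1 duplicates, shared and reference-contained
peptides). Because conservative substitutions score positive, a 40%
substitution rate drives identity toward 60% while EMBOSS-style
similarity stays near ~88%; tests therefore assert identity-level
degradation for the high-rate regime.

Not emulated: realistic codon usage, GC content, splice-site motifs,
sequencing noise, search-engine score distributions beyond the planted
cases, paralogy, and gene families. Passing tests demonstrate
correctness of the algorithms and bookkeeping on structurally realistic
inputs, not performance of the rules on real transcriptomes.

Test and acceptance problem sizes — 8-gene/3-species studies for
end-to-end checks, 500 random genes for matrix round trips, 1000 random
cDNAs for ORF enumeration, 200+ short peptide pairs for the alignment
oracle — were chosen as the package's own desk-scale defaults; all are
regenerated from seeds at run time.

## Known limitations

* Overlapping-locus resolution, fusion transcripts and trans-splicing
  are out of scope; each gene is processed independently.
* PSL input supports best-alignment selection only (ranked by
  matches − mismatches with block-count and chromosome tie-breaks, a
  concretization chosen because the upstream ranking script is not
  documented); alignment itself is external.
* The aligner is quadratic pure Python: adequate for proteoform-scale
  inputs (hundreds of residues, thousands of pairs), not for
  genome-scale all-vs-all searches.
* NMD prediction implements the junction-distance rule only — no
  uORF-triggered or long-3'UTR decay rules.
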