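"""Build the PSM-search-optimized proteoform database and filter
proteotypic peptides from a PSM result table.

Shows the redundancy purge (short sequences, reference substrings /
superstrings / identical matches), canonical labeling with the "-1"
marker for SwissProt-designated canonicals, and the three-stage peptide
filter (score cutoffs, MS1-duplicate collapse, single-protein rule).
"""

from spliceforge.fixtures import FixtureSpec, generate_fixture
from spliceforge.io_formats import reference_canonical_map
from spliceforge.models import PSMRecord
from spliceforge import pipeline, psmdb

fx = generate_fixture(FixtureSpec(seed=11, n_genes=6, ptc_distances=(50,)))
results = pipeline.reconstruct_genes(fx.genes, fx.genome)
refmap = reference_canonical_map(fx.reference_records)
proteoforms = pipeline.translate_genes(results, refmap)
pipeline.call_nmd(results, proteoforms)

references = [r.sequence for r in fx.reference_records]
db = psmdb.build_psm_database(proteoforms, references, refmap)
print(f"{len(proteoforms)} proteoforms -> {len(db.records)} database records")
print(f"removed as reference-redundant: {len(db.removed_reference)}")
for rec in db.records[:6]:
    label = "canonical" if rec.canonical else "variant"
    print(f"  {rec.protein_id:24s} {label:9s} {len(rec.sequence)} aa")

rows = [
    PSMRecord(r["peptide"], str(r["proteins"]).split(";"),
              float(r["primary_score"]), float(r["delta_cn"]), float(r["ms1"]))
    for r in fx.psm_rows_a
]
result = psmdb.filter_proteotypic(rows)
print(f"{len(rows)} PSM rows -> {len(result.peptides)} proteotypic peptides")
# Canonical records carry the SwissProt accession + "-1"; each surviving
# peptide maps to exactly one database protein.
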