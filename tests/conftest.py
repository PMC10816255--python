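"""Shared fixtures: one seeded synthetic study generated once per session."""

from __future__ import annotations

import pytest

from spliceforge.fixtures import FixtureSpec, generate_fixture
from spliceforge.io_formats import reference_canonical_map
from spliceforge import pipeline

SEED = 1


@pytest.fixture(scope="session")
def fixture_spec() -> FixtureSpec:
    return FixtureSpec(seed=SEED, n_genes=8, n_species=3)


@pytest.fixture(scope="session")
def fixture_bundle(fixture_spec, tmp_path_factory):
    fx = generate_fixture(fixture_spec)
    paths = fx.write(tmp_path_factory.mktemp("fixture"))
    return fx, paths


@pytest.fixture(scope="session")
def run_config(fixture_bundle, tmp_path_factory):
    _, paths = fixture_bundle
    return pipeline.RunConfig(
        genome=str(paths["genome"]),
        gtf=str(paths["gtf"]),
        reference_proteome=str(paths["reference"]),
        psm_table_a=str(paths["psm_a"]),
        psm_table_b=str(paths["psm_b"]),
        proteome_b=str(paths["proteome_b"]),
        proteome_c=str(paths["proteome_c"]),
        gene_pairs_ab=str(paths["gene_pairs_ab"]),
        gene_pairs_ac=str(paths["gene_pairs_ac"]),
        gene_pairs_cb=str(paths["gene_pairs_cb"]),
        out_dir=str(tmp_path_factory.mktemp("pipeline_out")),
    )


@pytest.fixture(scope="session")
def pipeline_run(fixture_bundle, run_config):
    """Full in-memory pipeline over the session fixture."""
    fx, _ = fixture_bundle
    results = pipeline.reconstruct_genes(fx.genes, fx.genome, mode="tsl")
    refmap = reference_canonical_map(fx.reference_records)
    proteoforms = pipeline.translate_genes(results, refmap)
    verdicts = pipeline.call_nmd(results, proteoforms)
    return {
        "fixture": fx,
        "results": results,
        "refmap": refmap,
        "proteoforms": proteoforms,
        "verdicts": verdicts,
    }
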