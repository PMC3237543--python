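import io
from dataclasses import dataclass

import pytest

from prokino.fixtures import BundleDocuments, FixtureConfig, fig1_bundle, generate_bundle
from prokino.population import KnowledgeGraph, populate
from prokino.schema import SchemaGraph, load_default_schema
from prokino.sources import SourceBundle, read_bundle
from prokino.subdomains import SubDomainInterval, assign_subdomains, locate_anchors


@dataclass
class Pipeline:
    """Everything the population pipeline produced for one bundle."""

    bundle: SourceBundle
    subdomains: dict[str, list[SubDomainInterval]]
    kg: KnowledgeGraph


def run_pipeline(docs: BundleDocuments, schema: SchemaGraph) -> Pipeline:
    bundle = read_bundle(docs.kinome, docs.fasta, docs.annotations,
                         docs.mutations, docs.pathways)
    subdomains = {
        seq.symbol: assign_subdomains(locate_anchors(seq.residues), len(seq.residues))
        for seq in bundle.sequences
    }
    return Pipeline(bundle=bundle, subdomains=subdomains,
                    kg=populate(schema, bundle, subdomains))


@pytest.fixture(scope="session")
def schema() -> SchemaGraph:
    return load_default_schema()


@pytest.fixture(scope="session")
def fig1(schema) -> Pipeline:
    return run_pipeline(fig1_bundle(), schema)


@pytest.fixture(scope="session")
def seeded_pipeline(schema):
    """Generated bundle (seed 3) through the full pipeline, with ground truth."""
    docs, truth = generate_bundle(FixtureConfig(seed=3))
    return run_pipeline(docs, schema), truth


@pytest.fixture()
def empty_stream():
    return io.StringIO("")
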