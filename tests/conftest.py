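import pandas as pd
import pytest

from panfam import duplication as dup
from panfam import pipeline
from panfam import simulate as sim


def classify_bundle_pairs(bundle):
    """Run the duplication stage (candidate pairs -> blocks -> cascade)
    on a synthetic bundle; returns {frozenset(pair): mode}."""
    positions = dup.rank_genes(
        pd.concat([bundle.genes, bundle.outgroup_genes.assign(og="")], ignore_index=True)
    )
    params = dict(pipeline.DEFAULT_PARAMS)
    by_genome = pipeline._candidate_pairs(bundle.self_hits, positions, params)
    out_blocks = dup.chain_collinear(
        list(zip(bundle.outgroup_hits["query"], bundle.outgroup_hits["subject"])),
        positions, 5, 25,
    )
    calls = {}
    for genome in sorted(by_genome):
        pairs = by_genome[genome]
        blocks = dup.chain_collinear(pairs, positions, 5, 25)
        for p in dup.classify_duplications(pairs, blocks, out_blocks, positions):
            calls[p.pair] = p.mode
    return calls


@pytest.fixture(scope="session")
def bundle_mode_calls(bundle):
    return classify_bundle_pairs(bundle)


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic pan-genome (10 genomes, full duplication
    playground), shared read-only across tests."""
    return sim.generate_pangenome(sim.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def sv_bundle(bundle):
    return sim.plant_sv_effects(bundle)


@pytest.fixture(scope="session")
def bundle20():
    """Larger collection (20 genomes) used where association power needs
    a realistic genome count."""
    return sim.generate_pangenome(sim.GeneratorConfig(n_genomes=20, seed=1))
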