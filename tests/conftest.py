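"""Shared fixtures: one default synthetic corpus per session plus the
trained coding model, normalized expression matrix and DE calls derived
from it.  A reduced configuration is provided for tests that only need a
structurally complete (not statistically powered) study."""

from __future__ import annotations

import pytest

from pollen_lncrna.discovery import fit_coding_model
from pollen_lncrna.expression import (
    ExpressionMatrix,
    aggregate_to_locus,
    cpm_filter,
    noiseq_de,
    tmm_factors,
)
from pollen_lncrna.simulate import (
    CULTIVARS,
    STAGES,
    SimulationConfig,
    simulate_corpus,
)

CORPUS_SEED = 1


def small_config(seed: int = 5) -> SimulationConfig:
    """A miniature study: structurally complete, fast to build."""
    return SimulationConfig(
        seed=seed,
        n_coding_genes=60,
        n_lncrna_loci=30,
        n_novel_coding=10,
        n_domain_planted=2,
        n_mirnas=6,
        n_sponge_pairs=3,
        n_precursor_pairs=2,
        n_cis_pairs=3,
        n_trans_pairs=2,
        n_heat_markers=8,
        n_species=4,
        n_diverged=3,
        n_subgenome_pairs=3,
        n_subgenome_triples=1,
        n_training_noncoding=60,
    )


@pytest.fixture(scope="session")
def corpus():
    return simulate_corpus(SimulationConfig(seed=CORPUS_SEED))


@pytest.fixture(scope="session")
def coding_model(corpus):
    reference = set(corpus.truth.reference_coding_ids)
    coding_train = [
        corpus.tx_seqs[t] for t in corpus.tx_seqs
        if corpus.tx_to_gene[t] in reference
    ]
    return fit_coding_model(coding_train, list(corpus.training_noncoding.values()))


@pytest.fixture(scope="session")
def gene_matrix(corpus):
    counts = aggregate_to_locus(corpus.counts, corpus.tx_to_gene)
    matrix = ExpressionMatrix(counts, corpus.design)
    matrix.tmm = tmm_factors(matrix.counts)
    return cpm_filter(matrix)


@pytest.fixture(scope="session")
def de_results(corpus, gene_matrix):
    truth = corpus.truth
    lnc = set(truth.noncoding_ids) | set(truth.domain_ids)
    biotypes = {
        g: ("lncRNA" if g in lnc else "coding") for g in gene_matrix.counts.index
    }
    results = []
    for cultivar in CULTIVARS:
        for stage in STAGES:
            results.extend(
                noiseq_de(gene_matrix, cultivar, stage, biotypes=biotypes)
            )
    return results


@pytest.fixture(scope="session")
def small_corpus():
    return simulate_corpus(small_config())
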