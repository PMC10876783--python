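"""The synthetic study generator: determinism, planted structure, and the
statistical properties the downstream stages rely on."""

import numpy as np
import pytest

from pollen_lncrna.coexpression import critical_r, pearson_test
from pollen_lncrna.discovery import longest_orf
from pollen_lncrna.simulate import (
    SimulationConfig,
    destroy_orfs,
    make_coding_sequence,
    make_noncoding_sequence,
    mutate_sequence,
    simulate_corpus,
    simulate_counts,
    simulate_de_calibration,
    simulate_correlation_panel,
    simulate_genome,
    write_corpus,
)

from conftest import small_config


class TestDeterminism:
    def test_same_seed_reproduces_files_byte_for_byte(self, tmp_path):
        hashes = []
        for run in ("a", "b"):
            corpus = simulate_corpus(small_config(seed=5))
            outdir = tmp_path / run
            paths = write_corpus(corpus, outdir)
            digest = {
                name: path.read_bytes()
                for name, path in paths.items() if path.is_file()
            }
            hashes.append(digest)
        assert hashes[0].keys() == hashes[1].keys()
        for name in hashes[0]:
            assert hashes[0][name] == hashes[1][name], name


class TestGenome:
    def test_all_u_fraction_forces_u_codes(self):
        config = small_config(seed=6)
        config.class_code_fractions = {"u": 1.0, "x": 0.0, "i": 0.0, "o": 0.0}
        corpus = simulate_genome(config)
        lnc = set(corpus.truth.noncoding_ids) | set(corpus.truth.domain_ids)
        codes = {t.class_code for t in corpus.transcripts if t.gene_id in lnc}
        assert codes == {"u"}

    def test_planted_coding_orfs_verified_by_orf_finder(self, small_corpus):
        coding = set(small_corpus.truth.reference_coding_ids
                     + small_corpus.truth.coding_ids)
        for tid, seq in small_corpus.tx_seqs.items():
            if small_corpus.tx_to_gene[tid] in coding:
                assert longest_orf(seq)[0] >= 300

    def test_noncoding_have_no_long_orf(self, small_corpus):
        noncoding = set(small_corpus.truth.noncoding_ids)
        for tid, seq in small_corpus.tx_seqs.items():
            if small_corpus.tx_to_gene[tid] in noncoding:
                assert longest_orf(seq)[0] < 150

    def test_length_means_match_study_profile(self, corpus):
        noncoding = set(corpus.truth.noncoding_ids)
        coding = set(corpus.truth.reference_coding_ids)
        lnc_lens = [len(s) for t, s in corpus.tx_seqs.items()
                    if corpus.tx_to_gene[t] in noncoding]
        cod_lens = [len(s) for t, s in corpus.tx_seqs.items()
                    if corpus.tx_to_gene[t] in coding]
        assert 2000 < np.mean(lnc_lens) < 2800
        assert 3700 < np.mean(cod_lens) < 4700

    def test_precursor_lncrnas_embed_exact_mirna_complement(self, corpus):
        from pollen_lncrna.mirna import plant_target_score
        gene_to_tx = {v: k for k, v in corpus.tx_to_gene.items()}
        for lnc, mir, _, _, _ in corpus.truth.precursor_triples:
            hit = plant_target_score(
                mir, corpus.mirnas[mir], lnc, corpus.tx_seqs[gene_to_tx[lnc]]
            )
            assert hit is not None and hit.perfect

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(de_log2fc_range=(0.3, 2.0)).validate()
        with pytest.raises(ValueError):
            SimulationConfig(
                class_code_fractions={"u": 0.5, "x": 0.2, "i": 0.2, "o": 0.2}
            ).validate()
        with pytest.raises(ValueError):
            SimulationConfig(n_species=99).validate()


class TestSequencePrimitives:
    def test_destroy_orfs_respects_protected_windows(self):
        rng = np.random.default_rng(3)
        seq = make_coding_sequence(rng, 1500)
        protected = [(0, 10)]
        out = destroy_orfs(seq, rng, protected=protected)
        assert longest_orf(out)[0] < 150
        assert out[:10] == seq[:10]

    @pytest.mark.parametrize("rate, lo, hi", [(0.1, 87.0, 93.0), (0.5, 44.0, 56.0)])
    def test_mutation_rate_sets_homolog_identity(self, rate, lo, hi):
        rng = np.random.default_rng(4)
        seq = make_noncoding_sequence(rng, 2000)
        mutated = mutate_sequence(seq, rng, rate)
        identity = 100.0 * sum(a == b for a, b in zip(seq, mutated)) / len(seq)
        assert lo < identity < hi


class TestCounts:
    def test_planted_fold_change_recovered_at_large_n(self):
        counts, design, planted = simulate_de_calibration(
            n_genes=60, n_planted=30, log2fc=2.0, replicates=200, seed=2
        )
        heat = design.index[(design["cultivar"] == "cranbrook")
                            & (design["stage"] == "meiosis")
                            & (design["condition"] == "heat")]
        ctrl = design.index[(design["cultivar"] == "cranbrook")
                            & (design["stage"] == "meiosis")
                            & (design["condition"] == "control")]
        lfc = np.log2(counts.loc[planted, heat].mean(axis=1)
                      / counts.loc[planted, ctrl].mean(axis=1))
        assert np.all(np.abs(lfc - 2.0) < 0.3)

    def test_planted_pairs_exceed_critical_r_usually(self):
        x, y, planted = simulate_correlation_panel(
            n_null=0, n_planted=300, seed=3
        )
        crit = critical_r(x.shape[1])
        hits = sum(
            abs(pearson_test(x[i], y[i])[0]) > crit for i in range(len(x))
        )
        assert hits / len(x) >= 0.9

    def test_lncrnas_less_expressed_than_coding(self, corpus, gene_matrix):
        cpm = gene_matrix.normalized_cpm()
        noncoding = [g for g in cpm.index if g in set(corpus.truth.noncoding_ids)]
        coding = [g for g in cpm.index
                  if g in set(corpus.truth.reference_coding_ids)]
        assert (cpm.loc[noncoding].mean(axis=1).median()
                < cpm.loc[coding].mean(axis=1).median())


class TestTruthConsistency:
    def test_every_planted_id_exists_in_emitted_files(self, small_corpus):
        truth = small_corpus.truth
        loci = {small_corpus.tx_to_gene[t] for t in small_corpus.tx_seqs}
        planted = (
            set(truth.noncoding_ids) | set(truth.coding_ids)
            | set(truth.domain_ids) | set(truth.de_table["gene"])
            | {g for pair in truth.subgenome_pairs for g in pair}
            | {x for p in truth.cis_pairs + truth.trans_pairs for x in p[:2]}
            | {p[0] for p in truth.sponge_triples + truth.precursor_triples}
            | {p[2] for p in truth.sponge_triples + truth.precursor_triples}
        )
        assert planted <= loci

    def test_sponge_and_precursor_triples_disjoint(self, small_corpus):
        truth = small_corpus.truth
        sponge = {(l, m, g) for l, m, g, _, _ in truth.sponge_triples}
        precursor = {(l, m, g) for l, m, g, _, _ in truth.precursor_triples}
        assert not sponge & precursor
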