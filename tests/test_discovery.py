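"""The candidate-filter cascade: class codes, length, ORF features, the
three-scorer consensus and the protein-domain veto."""

import numpy as np
import pytest

from pollen_lncrna._tables import (
    FICKETT_CONTENT_PROBABILITIES,
    FICKETT_CONTENT_THRESHOLDS,
    FICKETT_CONTENT_WEIGHTS,
    FICKETT_POSITION_PROBABILITIES,
    FICKETT_POSITION_THRESHOLDS,
    FICKETT_POSITION_WEIGHTS,
    STOP_CODONS,
)
from pollen_lncrna.discovery import (
    CodingModel,
    consensus_filter,
    domain_veto,
    fickett_score,
    fit_coding_model,
    hexamer_score,
    length_filter,
    longest_orf,
    orf_sequence,
    run_discovery,
    select_candidates,
    train_hexamer_table,
    two_graph_roc_cutoff,
    _translate,
)
from pollen_lncrna.formats import GenomicInterval, TranscriptModel


def make_tx(tid, length, code="u"):
    return TranscriptModel(
        tid, tid, GenomicInterval("1A", 0, length),
        exons=[GenomicInterval("1A", 0, length)], class_code=code,
    )


class TestSelection:
    def test_keeps_exactly_ioux(self):
        txs = [make_tx(f"t{i}", 300, c) for i, c in enumerate("=uxioj c".replace(" ", ""))]
        kept = select_candidates(txs)
        assert {t.class_code for t in kept} == set("uxio")

    def test_empty_and_all_reference(self):
        assert select_candidates([]) == []
        assert select_candidates([make_tx("t", 300, "=")]) == []

    @pytest.mark.parametrize("length, kept", [(199, False), (200, True), (2400, True)])
    def test_length_filter_strict_below_200(self, length, kept):
        out = length_filter([make_tx("t", length)])
        assert bool(out) is kept


class TestLongestOrf:
    def test_minimal_orf_with_stop_included(self):
        assert longest_orf("ATGAAATAG") == (9, 1.0, 0)

    def test_no_orf(self):
        assert longest_orf("CCCCCC") == (0, 0.0, -1)

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        for _ in range(10):
            seq = "".join(rng.choice(bases, size=10_000))
            # oracle: every ATG paired with the first in-frame stop
            best = 0
            for start in range(len(seq) - 2):
                if seq[start:start + 3] != "ATG":
                    continue
                for stop in range(start + 3, len(seq) - 2, 3):
                    if seq[stop:stop + 3] in STOP_CODONS:
                        best = max(best, stop + 3 - start)
                        break
            assert longest_orf(seq)[0] == best

    def test_orf_sequence_consistent_with_length(self):
        seq = "CCATGAAATTTTAGGG"
        length, coverage, _ = longest_orf(seq)
        orf = orf_sequence(seq)
        assert len(orf) == length
        assert orf.startswith("ATG") and orf[-3:] in STOP_CODONS


class TestFickett:
    def test_position_and_content_params_match_hand_enumeration(self):
        seq = "ACGTACGTACGTACGTACGTACGT"  # period-4: every base visits all phases
        # direct counting oracle
        expected = 0.0
        for base in "ACGT":
            phases = [sum(1 for i in range(p, len(seq), 3) if seq[i] == base)
                      for p in range(3)]
            position = max(phases) / (min(phases) + 1)
            content = sum(phases) / len(seq)
            pos_prob = next(
                p for t, p in zip(FICKETT_POSITION_THRESHOLDS,
                                  FICKETT_POSITION_PROBABILITIES[base])
                if position >= t
            )
            cont_prob = next(
                p for t, p in zip(FICKETT_CONTENT_THRESHOLDS,
                                  FICKETT_CONTENT_PROBABILITIES[base])
                if content >= t
            )
            expected += (FICKETT_POSITION_WEIGHTS[base] * pos_prob
                         + FICKETT_CONTENT_WEIGHTS[base] * cont_prob)
        assert fickett_score(seq) == pytest.approx(expected)

    def test_deterministic(self):
        seq = "ATGGCGGCGAAGGTGACCTGA" * 10
        assert fickett_score(seq) == fickett_score(str(seq))

    def test_separates_coding_from_noncoding_corpus(self, corpus):
        coding_ids = set(corpus.truth.reference_coding_ids)
        coding = [s for t, s in corpus.tx_seqs.items()
                  if corpus.tx_to_gene[t] in coding_ids][:100]
        noncoding = list(corpus.training_noncoding.values())[:100]
        assert (np.mean([fickett_score(s) for s in coding])
                > np.mean([fickett_score(s) for s in noncoding]))


class TestHexamer:
    def test_no_orf_scores_zero(self):
        uniform = {k: 1.0 for k in ["A" * 6]}
        assert hexamer_score("CCCCCCCC", uniform, uniform) == 0.0

    def test_uniform_tables_score_zero(self):
        table = train_hexamer_table([], in_frame=False)
        seq = "ATG" + "GCT" * 40 + "TGA"
        assert hexamer_score(seq, table, table) == pytest.approx(0.0)

    def test_trained_tables_separate_classes(self, corpus, coding_model):
        coding_ids = set(corpus.truth.reference_coding_ids)
        coding = [s for t, s in corpus.tx_seqs.items()
                  if corpus.tx_to_gene[t] in coding_ids][:60]
        noncoding = list(corpus.training_noncoding.values())[:60]
        score = lambda s: hexamer_score(
            s, coding_model.coding_table, coding_model.noncoding_table
        )
        assert np.mean([score(s) for s in coding]) > 0
        assert np.mean([score(s) for s in noncoding]) < 0


class TestCodingModel:
    def test_perfect_separation_gives_training_accuracy_one(self, corpus, coding_model):
        coding_ids = set(corpus.truth.reference_coding_ids)
        coding = [s for t, s in corpus.tx_seqs.items()
                  if corpus.tx_to_gene[t] in coding_ids][:50]
        noncoding = list(corpus.training_noncoding.values())[:50]
        probs = [coding_model.coding_probability(s) for s in coding + noncoding]
        labels = [1] * 50 + [0] * 50
        correct = sum(
            (p >= coding_model.cutoff) == bool(y) for p, y in zip(probs, labels)
        )
        assert correct == 100

    def test_two_graph_cutoff_balances_sensitivity_specificity(self):
        rng = np.random.default_rng(0)
        probs = np.concatenate([rng.beta(5, 2, 300), rng.beta(2, 5, 300)])
        labels = np.array([1] * 300 + [0] * 300)
        cut = two_graph_roc_cutoff(probs, labels)
        sens = np.mean(probs[labels == 1] >= cut)
        spec = np.mean(probs[labels == 0] < cut)
        assert abs(sens - spec) < 0.05

    def test_fixed_cutoff_overrides(self, corpus):
        coding_ids = set(corpus.truth.reference_coding_ids)
        coding = [s for t, s in corpus.tx_seqs.items()
                  if corpus.tx_to_gene[t] in coding_ids][:50]
        noncoding = list(corpus.training_noncoding.values())[:50]
        model = fit_coding_model(coding, noncoding, fixed_cutoff=0.365)
        assert model.cutoff == 0.365

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            fit_coding_model(["ATG" * 100] * 60, [])


class TestConsensusAndVeto:
    def test_consensus_is_intersection_of_noncoding_calls(self, corpus, coding_model):
        candidates = [t for t in corpus.transcripts if t.class_code in "ioux"][:40]
        result = consensus_filter(candidates, corpus.tx_seqs, coding_model)
        for report in result.reports.values():
            expected = all(v == "noncoding" for v in report.calls.values())
            assert (report.consensus == "noncoding") is expected
        triple = result.venn_counts.get("loh", 0)
        assert triple >= len(result.retained)

    def test_exact_protein_copy_vetoed_and_orfless_kept(self, corpus, coding_model):
        coding_tx = next(t for t in corpus.transcripts
                         if t.gene_id in set(corpus.truth.reference_coding_ids))
        orfless = make_tx("no_orf", 300)
        seqs = {coding_tx.transcript_id: corpus.tx_seqs[coding_tx.transcript_id],
                "no_orf": "CT" * 150}
        from pollen_lncrna.discovery import DiscoveryResult, orf_sequence
        start = DiscoveryResult(retained=[coding_tx, orfless])
        protein = _translate(orf_sequence(seqs[coding_tx.transcript_id]))
        result = domain_veto(start, seqs, {"prot": protein})
        assert result.vetoed == [coding_tx.transcript_id]
        assert [t.transcript_id for t in result.retained] == ["no_orf"]

    def test_empty_protein_db_rejected(self, corpus):
        from pollen_lncrna.discovery import DiscoveryResult
        with pytest.raises(ValueError):
            domain_veto(DiscoveryResult(retained=[]), {}, {})

    def test_cascade_counts_are_conserved(self, corpus, coding_model):
        result = run_discovery(
            corpus.transcripts, corpus.tx_seqs, coding_model, corpus.protein_db
        )
        total_dropped = sum(result.drop_counts.values())
        assert total_dropped + len(result.retained) == len(corpus.transcripts)
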