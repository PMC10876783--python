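"""Locus aggregation, TMM, CPM filtering, the dominance DE test and the
stage/cultivar summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pollen_lncrna.expression import (
    DEResult,
    ExpressionMatrix,
    _dominance_probability,
    aggregate_to_locus,
    bh_adjust,
    cpm_filter,
    noiseq_de,
    summarize_de,
    tmm_factors,
)

# edgeR::calcNormFactors(method="TMM") on the matrix generated below
# (independent reference implementation, run once and frozen).
EDGER_TMM = [0.9910590078, 1.0058262255, 0.9724875194,
             1.0557370019, 0.9711345948, 1.0061397957]


def edger_fixture_matrix():
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.negative_binomial(5, 5 / 55.0, size=(400, 6))
        * rng.integers(1, 4, size=(400, 1)),
        index=[f"g{i}" for i in range(400)],
        columns=[f"s{j}" for j in range(6)],
    )
    counts["s3"] = (counts["s3"] * 2.5).astype(int)
    return counts


class TestAggregate:
    def test_sums_member_transcripts(self):
        counts = pd.DataFrame({"s1": [10, 5, 7]}, index=["t1", "t2", "t3"])
        out = aggregate_to_locus(counts, {"t1": "g1", "t2": "g1", "t3": "g2"})
        assert out.loc["g1", "s1"] == 15
        assert out.loc["g2", "s1"] == 7

    def test_permutation_invariant_and_identity(self):
        counts = pd.DataFrame({"s1": [3, 9]}, index=["t1", "t2"])
        mapping = {"t1": "g1", "t2": "g2"}
        direct = aggregate_to_locus(counts, mapping)
        flipped = aggregate_to_locus(counts.iloc[::-1], mapping)
        pd.testing.assert_frame_equal(direct, flipped)

    def test_unmapped_transcript_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["t1"])
        with pytest.raises(ValueError, match="without a gene mapping"):
            aggregate_to_locus(counts, {})


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame(
            np.tile(np.arange(1, 101)[:, None], (1, 3)), columns=list("abc")
        )
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_global_scaling_leaves_factors_unchanged(self):
        counts = edger_fixture_matrix()
        assert np.allclose(tmm_factors(counts * 3), tmm_factors(counts), atol=1e-8)

    def test_matches_edger_reference_run(self):
        factors = tmm_factors(edger_fixture_matrix())
        assert np.allclose(factors.to_numpy(), EDGER_TMM, atol=1e-6)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            tmm_factors(pd.DataFrame({"a": [1, 2]}))


def two_condition_design(n_reps=2):
    samples = [f"{cond}_{r}" for cond in ("control", "heat") for r in range(n_reps)]
    return pd.DataFrame(
        {
            "cultivar": "cranbrook", "stage": "meiosis",
            "condition": [s.split("_")[0] for s in samples],
            "replicate": [int(s.split("_")[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )


class TestCpmFilter:
    def test_zero_gene_removed_expressed_gene_kept(self):
        design = two_condition_design()
        counts = pd.DataFrame(
            {s: [0, 10, 999_990] for s in design.index},
            index=["silent", "ok", "filler"],
        )
        filtered = cpm_filter(ExpressionMatrix(counts, design))
        assert "silent" not in filtered.counts.index
        assert "ok" in filtered.counts.index

    def test_boundary_cpm_exactly_one_is_kept(self):
        design = two_condition_design()
        counts = pd.DataFrame(
            {s: [1, 999_999] for s in design.index}, index=["edge", "filler"]
        )
        filtered = cpm_filter(ExpressionMatrix(counts, design))
        assert "edge" in filtered.counts.index  # 'smaller than one' is strict


class TestDominance:
    def test_zero_ratio_gene_never_beats_same_d_gene(self):
        m_noise = np.array([0.5, -0.5, 1.0, -1.5])
        d_noise = np.array([5.0, 10.0, 2.0, 8.0])
        flat = _dominance_probability(np.array([0.0]), np.array([7.0]),
                                      m_noise, d_noise)
        shifted = _dominance_probability(np.array([2.0]), np.array([7.0]),
                                         m_noise, d_noise)
        assert flat[0] <= shifted[0]

    @given(
        st.integers(0, 2 ** 31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_probability_monotone_in_signal(self, seed):
        rng = np.random.default_rng(seed)
        m_noise = rng.normal(0, 1, 200)
        d_noise = np.abs(rng.normal(0, 5, 200))
        m = rng.normal(0, 2)
        d = abs(rng.normal(0, 5))
        base = _dominance_probability(np.array([m]), np.array([d]),
                                      m_noise, d_noise)[0]
        more_m = _dominance_probability(np.array([m * 2 + np.sign(m) + 0.1]),
                                        np.array([d]), m_noise, d_noise)[0]
        more_d = _dominance_probability(np.array([m]), np.array([d + 3]),
                                        m_noise, d_noise)[0]
        assert more_m >= base
        assert more_d >= base

    def test_contrast_needs_replicates(self, gene_matrix):
        with pytest.raises(ValueError):
            noiseq_de(gene_matrix, "cranbrook", "no-such-stage")


class TestBh:
    def test_step_up_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_step_up(self, pvals):
        expected = brute_force_bh(pvals)
        assert np.allclose(bh_adjust(pvals), expected, atol=1e-12)


def brute_force_bh(pvals):
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvals[idx] * m / rank)
        q[idx] = running
    return q


class TestSummaries:
    def test_variance_ranking_matches_hand_computation(self):
        design = two_condition_design()
        counts = pd.DataFrame(
            np.array([[1, 1, 1, 1], [10, 0, 10, 0], [5, 5, 5, 6],
                      [100, 1, 1, 1], [2, 2, 2, 2]]),
            index=[f"g{i}" for i in range(5)], columns=design.index,
        )
        matrix = ExpressionMatrix(counts, design)
        summary = summarize_de([], matrix=matrix, top_k=5)
        cpm = matrix.normalized_cpm()
        expected = list(cpm.var(axis=1).sort_values(ascending=False).index)
        assert summary["top_variance_genes"] == expected

    def test_stage_concordant_counts_shared_direction(self):
        results = [
            DEResult("g1", "young", "meiosis", 2.0, 0.99, 0.01, "up", "lncRNA"),
            DEResult("g1", "young", "tetrad", 1.5, 0.99, 0.01, "up", "lncRNA"),
            DEResult("g2", "young", "meiosis", 2.0, 0.99, 0.01, "up", "lncRNA"),
            DEResult("g2", "young", "tetrad", -1.5, 0.99, 0.01, "down", "lncRNA"),
            DEResult("g3", "young", "meiosis", 2.0, 0.99, 0.01, "up", "lncRNA"),
        ]
        summary = summarize_de(results)
        assert summary["stage_concordant"] == 1

    def test_single_contrast_venn_collapses(self):
        results = [
            DEResult("g1", "young", "meiosis", 2.0, 0.99, 0.01, "up", "lncRNA"),
        ]
        summary = summarize_de(results)
        assert summary["cultivar_overlap"]["meiosis"]["all_cultivars"] == 1
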