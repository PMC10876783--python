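"""Cis windows, correlation testing, BH and the hybridization filter."""

import numpy as np
import pandas as pd
import pytest

from pollen_lncrna.coexpression import (
    STACK_TABLE,
    GeneIndex,
    _IDX,
    build_cis_trans,
    critical_r,
    ndg_score,
    pearson_test,
    summarize_edges,
)
from pollen_lncrna.expression import ExpressionMatrix
from pollen_lncrna.formats import GenomicInterval
from pollen_lncrna.simulate import revcomp

PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


def naive_ndg(sa, sb):
    """Brute-force helix enumeration over every antiparallel register."""
    short, long_ = sorted((sa, sb), key=len)
    s = short[::-1]
    best = 0.0
    for off in range(-(len(s) - 1), len(long_)):
        run = 0.0
        for j in range(len(s) - 1):
            tp = off + j
            if (0 <= tp and tp + 1 < len(long_)
                    and (long_[tp], s[j]) in PAIRS
                    and (long_[tp + 1], s[j + 1]) in PAIRS):
                run += STACK_TABLE[_IDX[long_[tp]], _IDX[s[j]],
                                   _IDX[long_[tp + 1]], _IDX[s[j + 1]]]
                best = min(best, run)
            else:
                run = 0.0
    return best / len(s)


class TestCisWindow:
    def make_index(self, n=25, spacing=1000):
        loci = {
            f"g{i:02d}": GenomicInterval("3B", (i + 1) * spacing,
                                         (i + 1) * spacing + 100)
            for i in range(n)
        }
        return GeneIndex(loci)

    def test_window_spans_ten_each_side(self):
        index = self.make_index()
        lnc = GenomicInterval("3B", 13_500, 13_600)  # between g12 and g13
        names = [g for g, _ in index.cis_window(lnc)]
        assert names == [f"g{i:02d}" for i in range(3, 23)]

    def test_lncrna_before_first_gene_gets_ten_downstream(self):
        index = self.make_index()
        lnc = GenomicInterval("3B", 1, 50)
        names = [g for g, _ in index.cis_window(lnc)]
        assert len(names) == 10 and names[0] == "g00"

    def test_overlapping_gene_distance_zero(self):
        index = self.make_index()
        lnc = GenomicInterval("3B", 2010, 2080)
        distances = dict(index.cis_window(lnc))
        assert distances["g01"] == 0

    def test_absent_chromosome_gives_empty(self):
        index = self.make_index()
        assert index.cis_window(GenomicInterval("7D", 0, 100)) == []


class TestPearson:
    def test_perfect_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = pearson_test(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-6
        r_neg, _ = pearson_test(x, [-v for v in x])
        assert r_neg == pytest.approx(-1.0)

    def test_critical_r_at_n6_is_081(self):
        crit = critical_r(6)
        assert 0.81 < crit < 0.812

    def test_r_0812_significant_but_080_not_at_n6(self):
        x = np.arange(6.0)

        def vector_with_r(r):
            z = np.array([1.0, -1, 1, -1, 1, -1])
            xs = (x - x.mean()) / x.std()
            zs = z - z.mean()
            zs -= zs @ xs / (xs @ xs) * xs
            zs /= np.sqrt(zs @ zs / len(zs))
            return r * xs + np.sqrt(1 - r * r) * zs

        _, p_hi = pearson_test(x, vector_with_r(0.812))
        _, p_lo = pearson_test(x, vector_with_r(0.80))
        assert p_hi < 0.05 < p_lo

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1, 1, 1, 1], [1, 2, 3, 4])


class TestNdg:
    def test_perfect_duplex_is_minimum_for_pair(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(np.array(list("ACGT")), 60))
        value = ndg_score(seq, revcomp(seq))
        assert value == pytest.approx(naive_ndg(seq, revcomp(seq)))
        assert value < -1.0  # a full 60-mer helix

    def test_polya_has_no_pairs(self):
        assert ndg_score("A" * 30, "A" * 40) == 0.0

    def test_matches_brute_force_on_toy_pairs(self):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        for _ in range(10):
            a = "".join(rng.choice(bases, int(rng.integers(20, 61))))
            b = "".join(rng.choice(bases, int(rng.integers(20, 61))))
            assert ndg_score(a, b) == pytest.approx(naive_ndg(a, b))

    def test_short_or_invalid_sequences_rejected(self):
        with pytest.raises(ValueError):
            ndg_score("ACGT", "ACGT" * 10)
        with pytest.raises(ValueError):
            ndg_score("ACGTN" * 5, "ACGT" * 10)


def coexpression_scenario(rng, trans_complementary):
    """Two lncRNAs and six coding genes; lnc1 co-expressed with its neighbor
    g0 (cis) and with the distal g5 (trans)."""
    genes = {f"g{i}": GenomicInterval("1A", 10_000 * (i + 1),
                                      10_000 * (i + 1) + 500) for i in range(5)}
    genes["g5"] = GenomicInterval("5D", 1000, 2000)
    lnc_loci = {"lnc1": GenomicInterval("1A", 15_500, 16_000)}
    samples = [f"cr_meiosis_{c}_{r}" for c in ("control", "heat") for r in (1, 2, 3)]
    design = pd.DataFrame(
        {"cultivar": "cranbrook", "stage": "meiosis",
         "condition": [s.split("_")[2] for s in samples],
         "replicate": [int(s.split("_")[3]) for s in samples]},
        index=pd.Index(samples, name="sample"),
    )
    shared = 2.0 ** rng.normal(0, 2, 6)
    rows = {
        "lnc1": 200 * shared,
        "g0": 180 * shared,
        "g5": 150 * shared,
    }
    for g in ("g1", "g2", "g3", "g4"):
        rows[g] = rng.poisson(150, 6).astype(float)
    counts = pd.DataFrame(rows, index=samples).T
    matrix = ExpressionMatrix(counts, design)

    base = "".join(rng.choice(np.array(list("ACGT")), 400))
    lnc_seq = base
    if trans_complementary:
        g5_seq = "".join(rng.choice(np.array(list("ACGT")), 100)) \
            + revcomp(base[50:250]) + "".join(rng.choice(np.array(list("ACGT")), 100))
    else:
        g5_seq = "".join(rng.choice(np.array(list("ACGT")), 400))
    seqs = {"lnc1": lnc_seq, "g5": g5_seq,
            **{g: "".join(rng.choice(np.array(list("ACGT")), 300))
               for g in ("g0", "g1", "g2", "g3", "g4")}}
    de_lnc = {("cranbrook", "meiosis"): {"lnc1"}}
    de_genes = {("cranbrook", "meiosis"): set(genes)}
    return de_lnc, de_genes, matrix, lnc_loci, genes, seqs


class TestBuildEdges:
    def test_cis_found_and_trans_needs_hybridization(self):
        rng = np.random.default_rng(21)
        de_lnc, de_genes, matrix, lnc_loci, genes, seqs = coexpression_scenario(
            rng, trans_complementary=True
        )
        edges = build_cis_trans(de_lnc, de_genes, matrix, lnc_loci, genes, seqs)
        modes = {(e.gene_id, e.mode) for e in edges}
        assert ("g0", "cis") in modes
        assert ("g5", "trans") in modes
        cis_ids = {e.gene_id for e in edges if e.mode == "cis"}
        trans_ids = {e.gene_id for e in edges if e.mode == "trans"}
        assert not cis_ids & trans_ids  # neighborhood partition

    def test_trans_without_complementarity_excluded(self):
        rng = np.random.default_rng(21)
        de_lnc, de_genes, matrix, lnc_loci, genes, seqs = coexpression_scenario(
            rng, trans_complementary=False
        )
        edges = build_cis_trans(de_lnc, de_genes, matrix, lnc_loci, genes, seqs)
        assert not any(e.gene_id == "g5" for e in edges)

    def test_summary_shapes(self):
        rng = np.random.default_rng(21)
        args = coexpression_scenario(rng, trans_complementary=True)
        edges = build_cis_trans(*args)
        summary = summarize_edges(edges)
        assert "cranbrook" in summary["per_cultivar"]
        assert sum(summary["targets_per_lncrna"].values()) >= 1
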