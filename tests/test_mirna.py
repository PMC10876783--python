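"""Plant penalty scoring of miRNA sites and sponge/precursor assembly."""

import numpy as np
import pytest

from pollen_lncrna.expression import DEResult
from pollen_lncrna.mirna import (
    MirnaInteraction,
    _score_register,
    classify_modules,
    module_summary,
    plant_target_score,
)
from pollen_lncrna.simulate import revcomp

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_best_score(mirna, target):
    """Independent register/bulge enumeration via the scalar scorer."""
    n = len(mirna)
    best = None
    for start in range(len(target) - n + 1):
        s, _, _ = _score_register(mirna, target[start:start + n], None)
        best = s if best is None else min(best, s)
        if start + n + 1 <= len(target):
            for b in range(1, n):
                s, _, _ = _score_register(mirna, target[start:start + n + 1], b)
                best = min(best, s)
    return best


def mirna_of_length(rng, n=21):
    return "".join(rng.choice(np.array(list("ACGT")), n))


class TestScoring:
    def test_exact_reverse_complement_is_perfect(self):
        rng = np.random.default_rng(0)
        mir = mirna_of_length(rng)
        target = "GGGG" + revcomp(mir) + "CCCC"
        hit = plant_target_score("m", mir, "t", target)
        assert hit.score == 0.0 and hit.perfect
        assert hit.site_start == 4

    def test_mismatch_in_core_costs_double(self):
        rng = np.random.default_rng(1)
        mir = mirna_of_length(rng)
        site = list(revcomp(mir))
        pos = 9  # miRNA position 10, inside the 2-13 core
        t_index = len(site) - 1 - pos
        mir_base = mir[pos]
        site[t_index] = next(
            b for b in "ACGT"
            if b != COMP[mir_base] and {mir_base, b} != {"G", "T"}
        )
        hit = plant_target_score("m", mir, "t", "".join(site), allow_bulge=False)
        assert hit.score == 2.0 and not hit.perfect

    def test_wobble_at_position_one_scores_half(self):
        rng = np.random.default_rng(2)
        mir = "G" + mirna_of_length(rng, 20)
        site = list(revcomp(mir))
        site[len(site) - 1] = "T"  # pairs miRNA position 1 (G) with U
        hit = plant_target_score("m", mir, "t", "".join(site), allow_bulge=False)
        assert hit.score == 0.5
        assert not hit.perfect  # wobble-containing full matches are not perfect

    def test_target_shorter_than_mirna_has_no_site(self):
        rng = np.random.default_rng(3)
        mir = mirna_of_length(rng)
        assert plant_target_score("m", mir, "t", "ACGT") is None

    def test_mirna_length_validated(self):
        with pytest.raises(ValueError):
            plant_target_score("m", "ACGT", "t", "ACGT" * 20)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for trial in range(8):
            mir = mirna_of_length(rng)
            target = "".join(rng.choice(bases, 120))
            if trial % 2 == 0:  # plant a degenerate site
                pos = int(rng.integers(0, 90))
                target = target[:pos] + revcomp(mir)[2:] + target[pos + 19:]
            hit = plant_target_score("m", mir, "t", target, max_score=1e9)
            assert hit.score == pytest.approx(naive_best_score(mir, target))

    def test_score_zero_iff_full_watson_crick(self):
        rng = np.random.default_rng(6)
        mir = mirna_of_length(rng)
        perfect_target = revcomp(mir)
        assert plant_target_score("m", mir, "t", perfect_target).score == 0.0
        chars = list(perfect_target)
        chars[10] = next(b for b in "ACGT" if b != chars[10])
        mutated = plant_target_score("m", mir, "t", "".join(chars), max_score=1e9)
        assert mutated.score > 0.0


def interaction(mirna_id, rna_id, rna_class, perfect=False, score=1.0):
    return MirnaInteraction(
        mirna_id=mirna_id, rna_id=rna_id, rna_class=rna_class,
        score=0.0 if perfect else score, site_start=0, pairing="|" * 21,
        perfect=perfect,
    )


def de(gene, direction, cultivar="young", stage="meiosis", biotype="coding"):
    lfc = 2.0 if direction == "up" else -2.0
    return DEResult(gene, cultivar, stage, lfc, 0.99, 0.01, direction, biotype)


class TestClassification:
    def test_concordant_trends_make_a_sponge(self):
        modules = classify_modules(
            [interaction("miR1", "lnc1", "lncRNA", score=3.0)],
            [interaction("miR1", "g1", "mRNA", score=3.0)],
            [de("lnc1", "up", biotype="lncRNA"), de("g1", "up")],
        )
        assert [m.role for m in modules] == ["sponge"]

    def test_opposite_trends_with_perfect_site_make_a_precursor(self):
        modules = classify_modules(
            [interaction("miR1", "lnc1", "lncRNA", perfect=True)],
            [interaction("miR1", "g1", "mRNA", score=2.0)],
            [de("lnc1", "up", biotype="lncRNA"), de("g1", "down")],
        )
        assert [m.role for m in modules] == ["precursor"]

    def test_opposite_trends_without_perfect_site_make_nothing(self):
        modules = classify_modules(
            [interaction("miR1", "lnc1", "lncRNA", score=2.0)],
            [interaction("miR1", "g1", "mRNA", score=2.0)],
            [de("lnc1", "up", biotype="lncRNA"), de("g1", "down")],
        )
        assert modules == []

    def test_contrast_must_match(self):
        modules = classify_modules(
            [interaction("miR1", "lnc1", "lncRNA", score=1.0)],
            [interaction("miR1", "g1", "mRNA", score=1.0)],
            [de("lnc1", "up", cultivar="young"), de("g1", "up", cultivar="halberd")],
        )
        assert modules == []


class TestSummary:
    def test_shared_module_lists_both_cultivars(self):
        lnc_hits = [interaction("miR1", "lnc1", "lncRNA", score=1.0)]
        mrna_hits = [interaction("miR1", "g1", "mRNA", score=1.0)]
        des = [
            de("lnc1", "up", cultivar="young"), de("g1", "up", cultivar="young"),
            de("lnc1", "up", cultivar="halberd"), de("g1", "up", cultivar="halberd"),
        ]
        summary = module_summary(classify_modules(lnc_hits, mrna_hits, des))
        (shared,) = summary["shared_modules"]
        assert shared["cultivars"] == ["halberd", "young"]

    def test_empty_modules_all_zero(self):
        summary = module_summary([])
        assert summary["counts"]["sponge"]["modules"] == 0
        assert summary["counts"]["precursor"]["mrnas"] == 0
        assert summary["shared_modules"] == []
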