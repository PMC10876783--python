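"""Synthetic study generator with planted ground truth.

Emulates the inputs of a four-cultivar (two heat-sensitive, two tolerant),
two-stage (meiosis, tetrad), heat-vs-control anther RNA-seq study on a
hexaploid genome: a GTF of assembled transcripts with gffcompare class
codes, genome/transcript FASTA, a negative-binomial count matrix with a
sample design, miRNA sequences, per-species lncRNA sets for conservation,
GO annotations with a small ontology, and a protein database for the
domain veto.  Every planted signal (non-coding vs coding transcripts,
differential expression, cis/trans co-expression, sponge/precursor triples,
cross-species and cross-sub-genome homologs, an enriched GO term) is
recorded in a :class:`GroundTruth` object so recovery can be measured.

Design choices that matter (see docs/methods.md for rationale): background
DE effects default to |log2FC| in [2, 3] and module/marker/pair genes to
[4.5, 5], the biomarker scale of the emulated study system; module genes
are planted in a well-expressed stratum (with down-regulated members at the
top tier, since an absolute-difference statistic sees a decrease only
against a high baseline); 3 replicates per condition make n = 6 per
cultivar/stage, where two-sided P < 0.05 corresponds to |r| > 0.81.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._tables import CODON_USAGE, STOP_CODONS
from .discovery import longest_orf, orf_sequence, _translate
from .formats import (
    GenomicInterval,
    TranscriptModel,
    write_fasta,
    write_gtf,
    write_tsv,
)

CULTIVARS = ("cranbrook", "wyalkatchem", "halberd", "young")
SENSITIVE = ("cranbrook", "wyalkatchem")
TOLERANT = ("halberd", "young")
STAGES = ("meiosis", "tetrad")
CONDITIONS = ("control", "heat")

SPECIES = (
    "hordeum_vulgare", "oryza_sativa", "brachypodium_distachyon", "zea_mays",
    "sorghum_bicolor", "setaria_italica", "nicotiana_tabacum", "brassica_napus",
    "setaria_viridis", "glycine_max", "gossypium_barbadense",
    "arabidopsis_thaliana", "pisum_sativum",
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes_per_subgenome: int = 2
    n_coding_genes: int = 300
    n_lncrna_loci: int = 120
    class_code_fractions: dict = field(
        default_factory=lambda: {"u": 0.7, "x": 0.1, "i": 0.1, "o": 0.1}
    )
    n_novel_coding: int = 40        # coding transfrags hidden among candidates
    n_domain_planted: int = 4       # consensus survivors caught by the veto
    replicates: int = 3
    de_fraction: float = 0.5
    de_log2fc_range: tuple[float, float] = (2.0, 3.0)
    module_log2fc_range: tuple[float, float] = (4.5, 5.0)
    n_heat_markers: int = 25
    nb_dispersion: float = 0.05
    n_mirnas: int = 20
    n_sponge_pairs: int = 10
    n_precursor_pairs: int = 8
    n_cis_pairs: int = 12
    n_trans_pairs: int = 8
    latent_sd: float = 1.5          # log2 sd of the shared co-expression factor
    n_species: int = 13
    conserved_fraction: float = 0.3
    mutation_rate: float = 0.1
    diverged_mutation_rate: float = 0.5
    n_diverged: int = 10
    n_subgenome_pairs: int = 12     # cross-sub-genome lncRNA duplicates
    n_subgenome_triples: int = 4
    lnc_length_mean: float = 2400.0
    coding_length_mean: float = 4200.0
    n_training_noncoding: int = 100
    fraction_unplaced: float = 0.05  # lncRNAs on the 'U' chromosome

    def validate(self) -> None:
        fracs = self.class_code_fractions
        if set(fracs) - set("ioux") or abs(sum(fracs.values()) - 1.0) > 1e-6:
            raise ValueError("class-code fractions must cover {i,o,u,x} and sum to 1")
        if not all(0.0 <= v <= 1.0 for v in fracs.values()):
            raise ValueError("class-code fractions must lie in [0, 1]")
        for lo, hi in (self.de_log2fc_range, self.module_log2fc_range):
            if not 0.5 < lo <= hi:
                raise ValueError("log2FC ranges must lie entirely above 0.5")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.lnc_length_mean < 400 or self.coding_length_mean < 1200:
            raise ValueError("length means too small to satisfy ORF constraints")
        if self.n_species > len(SPECIES):
            raise ValueError(f"at most {len(SPECIES)} species supported")


@dataclass
class GroundTruth:
    noncoding_ids: list[str] = field(default_factory=list)
    coding_ids: list[str] = field(default_factory=list)       # novel coding transfrags
    reference_coding_ids: list[str] = field(default_factory=list)
    domain_ids: list[str] = field(default_factory=list)
    de_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    cis_pairs: list[tuple] = field(default_factory=list)      # (lnc, gene, cultivar, stage)
    trans_pairs: list[tuple] = field(default_factory=list)
    sponge_triples: list[tuple] = field(default_factory=list)  # (lnc, mirna, mrna, cultivar, stage)
    precursor_triples: list[tuple] = field(default_factory=list)
    homolog_map: dict = field(default_factory=dict)           # lnc -> [species]
    diverged_map: dict = field(default_factory=dict)
    subgenome_pairs: list[tuple] = field(default_factory=list)
    tree_lncrna: str | None = None
    enriched_term: str | None = None


@dataclass
class Corpus:
    config: SimulationConfig
    transcripts: list[TranscriptModel]
    genome: dict[str, str]
    tx_seqs: dict[str, str]
    tx_to_gene: dict[str, str]
    protein_db: dict[str, str]
    training_noncoding: dict[str, str]
    truth: GroundTruth
    mirnas: dict[str, str] = field(default_factory=dict)
    counts: pd.DataFrame | None = None
    design: pd.DataFrame | None = None
    species_sets: dict[str, dict[str, str]] = field(default_factory=dict)
    go_annotations: dict[str, list[str]] = field(default_factory=dict)
    obo_text: str = ""

    @property
    def gene_loci(self) -> dict[str, GenomicInterval]:
        return {t.gene_id: t.interval for t in self.transcripts}


# ---------------------------------------------------------------------------
# Sequence construction primitives
# ---------------------------------------------------------------------------

_NONCODING_P = np.array([0.32, 0.18, 0.18, 0.32])  # AT-rich intergenic
_UTR_P = np.array([0.22, 0.28, 0.28, 0.22])        # GC-rich genic


def random_sequence(rng: np.random.Generator, length: int,
                    probs: np.ndarray = _NONCODING_P) -> str:
    return "".join(rng.choice(_BASES, size=length, p=probs))


_CODONS = list(CODON_USAGE)
_CODON_P = np.array([CODON_USAGE[c] for c in _CODONS])
_CODON_P = _CODON_P / _CODON_P.sum()


def make_coding_sequence(rng: np.random.Generator, length: int,
                         orf_fraction: float = 0.55) -> str:
    """UTR + ATG..stop ORF built from the codon-usage table + UTR."""
    n_codons = max(100, int(length * orf_fraction) // 3)
    orf = "ATG" + "".join(rng.choice(_CODONS, size=n_codons - 2, p=_CODON_P))
    orf += rng.choice(np.array(STOP_CODONS))
    utr_total = max(40, length - len(orf))
    utr5 = utr_total // 2
    seq = (
        random_sequence(rng, utr5, _UTR_P)
        + orf
        + random_sequence(rng, utr_total - utr5, _UTR_P)
    )
    if longest_orf(seq)[0] < 300:
        raise ValueError("length constraints leave no room for a >=300 nt ORF")
    return seq


def make_noncoding_sequence(rng: np.random.Generator, length: int,
                            self_bias: float = 0.12) -> str:
    """Order-1 Markov sequence, AT-rich with slight homotypic runs."""
    seq = np.empty(length, dtype="<U1")
    seq[0] = rng.choice(_BASES, p=_NONCODING_P)
    idx = {b: i for i, b in enumerate(_BASES)}
    transitions = np.tile(_NONCODING_P, (4, 1))
    for i in range(4):
        transitions[i, i] += self_bias
        transitions[i] /= transitions[i].sum()
    prev = idx[seq[0]]
    for i in range(1, length):
        prev = rng.choice(4, p=transitions[prev])
        seq[i] = _BASES[prev]
    return "".join(seq)


def _orf_spans(seq: str, min_len: int) -> list[tuple[int, int]]:
    spans = []
    n = len(seq)
    for frame in range(3):
        start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                if pos + 3 - start >= min_len:
                    spans.append((start, pos + 3))
                start = None
    return spans


def destroy_orfs(seq: str, rng: np.random.Generator, min_len: int = 150,
                 protected: list[tuple[int, int]] | None = None) -> str:
    """Break every ORF >= ``min_len`` by dropping a premature stop codon.

    Codons overlapping ``protected`` windows are never edited; the loop
    retries until no long ORF remains (long ORFs fully inside a protected
    window would be unbreakable, so protection windows must be short).
    """
    protected = protected or []
    chars = list(seq)
    for iteration in range(1000):
        spans = _orf_spans("".join(chars), min_len)
        if not spans:
            return "".join(chars)
        start, end = spans[0]
        codon_starts = [
            p for p in range(start + 3, end - 3, 3)
            if not any(p < pe and p + 3 > ps for ps, pe in protected)
        ]
        if not codon_starts:
            raise ValueError("cannot break ORF without touching a protected window")
        # a fixed (middle) codon can oscillate by erasing stops in the other
        # frames; randomize the break point instead
        pos = codon_starts[int(rng.integers(len(codon_starts)))]
        chars[pos : pos + 3] = "TAA"
    raise ValueError("ORF destruction did not converge")


def mutate_sequence(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Point substitutions at the given per-base rate."""
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    for i in np.where(hit)[0]:
        options = [b for b in "ACGT" if b != chars[i]]
        chars[i] = options[rng.integers(3)]
    return "".join(chars)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# Genome + relations
# ---------------------------------------------------------------------------

def _draw_length(rng: np.random.Generator, mean: float, sigma: float,
                 lo: int, hi: int) -> int:
    mu = math.log(mean) - sigma ** 2 / 2.0
    return int(np.clip(rng.lognormal(mu, sigma), lo, hi))


def simulate_genome(config: SimulationConfig) -> Corpus:
    """Sequences, annotation, planted relations and the protein database.

    Deterministic in ``config.seed``: the same config reproduces the corpus
    byte for byte.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    chroms = [
        f"{i + 1}{sub}"
        for sub in "ABD"
        for i in range(config.n_chromosomes_per_subgenome)
    ]

    # --- base sequences -------------------------------------------------
    coding_ids = [f"GENE.{i + 1:04d}" for i in range(config.n_coding_genes)]
    seqs: dict[str, str] = {}
    for cid in coding_ids:
        length = _draw_length(rng, config.coding_length_mean, 0.35, 1400, 12000)
        seqs[cid] = make_coding_sequence(rng, length)

    novel_ids = [f"MSTRG.C{i + 1:03d}.1" for i in range(config.n_novel_coding)]
    for nid in novel_ids:
        length = _draw_length(rng, config.coding_length_mean * 0.8, 0.35, 1400, 9000)
        seqs[nid] = make_coding_sequence(rng, length, orf_fraction=0.45)

    lnc_ids = [f"MSTRG.{i + 1:05d}.1" for i in range(config.n_lncrna_loci)]
    for lid in lnc_ids:
        length = _draw_length(rng, config.lnc_length_mean, 0.45, 300, 8000)
        seqs[lid] = destroy_orfs(make_noncoding_sequence(rng, length), rng)

    # cross-sub-genome duplicates: rewrite later lncRNAs as mutated copies
    subgenome_pairs: list[tuple] = []
    pair_pool = list(lnc_ids)
    n_dup = config.n_subgenome_pairs + config.n_subgenome_triples
    donors = pair_pool[:n_dup]
    copies = pair_pool[n_dup : 2 * n_dup]
    triple_copies = pair_pool[2 * n_dup : 2 * n_dup + config.n_subgenome_triples]
    for idx, (src, dst) in enumerate(zip(donors, copies)):
        seqs[dst] = destroy_orfs(
            mutate_sequence(seqs[src], rng, config.mutation_rate), rng
        )
        subgenome_pairs.append((src, dst))
    for idx, dst in enumerate(triple_copies):
        src = donors[idx]
        seqs[dst] = destroy_orfs(
            mutate_sequence(seqs[src], rng, config.mutation_rate), rng
        )
        subgenome_pairs.append((src, dst))

    # --- class codes, domain-planted picks ------------------------------
    codes, fracs = zip(*sorted(config.class_code_fractions.items()))
    class_codes = {
        lid: str(rng.choice(np.array(codes), p=np.array(fracs) / sum(fracs)))
        for lid in lnc_ids
    }
    for nid in novel_ids:
        class_codes[nid] = str(rng.choice(np.array(codes), p=np.array(fracs) / sum(fracs)))

    dup_members = {x for pair in subgenome_pairs for x in pair}
    domain_ids = []
    for lid in lnc_ids:
        if len(domain_ids) == config.n_domain_planted:
            break
        if lid in dup_members:
            continue
        if 93 <= longest_orf(seqs[lid])[0] < 150:
            domain_ids.append(lid)
    if len(domain_ids) < config.n_domain_planted:
        raise ValueError("too few candidate ORFs for domain planting; enlarge corpus")

    plain_lnc = [l for l in lnc_ids if l not in domain_ids]

    # --- miRNAs and regulatory relations --------------------------------
    mirnas = {
        f"tae-miR{1000 + i}": random_sequence(rng, 21, np.array([0.25] * 4))
        for i in range(config.n_mirnas)
    }
    mirna_ids = list(mirnas)

    contrasts = [(c, s) for c in CULTIVARS for s in STAGES]
    # strongly co-regulated (latent-factor) pairs violate the within-condition
    # exchangeability the DE noise model assumes, so they are confined to one
    # cultivar and the miRNA modules to the remaining three (see methods note)
    pair_cultivar = CULTIVARS[0]
    module_contrasts = [(c, s) for c, s in contrasts if c != pair_cultivar]
    pair_contrasts = [(c, s) for c, s in contrasts if c == pair_cultivar]

    def pick_contrast(pool=None):
        pool = pool if pool is not None else contrasts
        return pool[rng.integers(len(pool))]

    def draw_lfc(module: bool = False):
        lo, hi = config.module_log2fc_range if module else config.de_log2fc_range
        return float(rng.uniform(lo, hi))

    de_rows: list[dict] = []
    planted_de: set[tuple[str, str, str]] = set()

    def plant_de(gene: str, cultivar: str, stage: str, direction: str,
                 lfc: float | None = None) -> None:
        if (gene, cultivar, stage) in planted_de:
            return
        planted_de.add((gene, cultivar, stage))
        de_rows.append(
            {
                "gene": gene, "cultivar": cultivar, "stage": stage,
                "log2fc": lfc if lfc is not None else draw_lfc(),
                "direction": direction,
            }
        )

    protected: dict[str, list[tuple[int, int]]] = {}

    def plant_site(rna_id: str, site: str, window: tuple[int, int] | None = None) -> None:
        """Overwrite a window of the transcript with a target site."""
        seq = seqs[rna_id]
        lo, hi = window or (50, len(seq) - 50)
        hi = min(hi, len(seq)) - len(site)
        if hi <= lo:
            raise ValueError(f"no room to plant a site in {rna_id}")
        for _ in range(20):
            start = int(rng.integers(lo, hi))
            span = (start, start + len(site))
            if not any(s < span[1] and e > span[0]
                       for s, e in protected.get(rna_id, [])):
                break
        else:
            raise ValueError(f"site placement collision in {rna_id}")
        seqs[rna_id] = seq[: span[0]] + site + seq[span[1]:]
        protected.setdefault(rna_id, []).append(span)

    def near_perfect_site(mirna_seq: str) -> str:
        """Reverse complement with one mismatch outside positions 2-13."""
        site = list(revcomp(mirna_seq))
        pos = 15  # miRNA position 16, weight 1 -> penalty exactly 1
        t_index = len(site) - 1 - pos
        current = site[t_index]
        complement_of_g = {"G": "C"}  # avoid creating a wobble pair
        for alt in "ACGT":
            mir_base = mirna_seq[pos]
            if alt == current:
                continue
            if {mir_base, alt} in ({"G", "T"}, {"T", "G"}):
                continue
            if alt != {"A": "T", "C": "G", "G": "C", "T": "A"}[mir_base]:
                site[t_index] = alt
                break
        return "".join(site)

    # Module genes sit in a well-expressed stratum and carry biomarker-scale
    # effects; down-regulated members get a much higher baseline because the
    # DE test's D-axis (absolute difference of means) scales with expression
    # level, so a decrease is only as detectable as its baseline is high
    # (see docs/methods.md).
    # The D-axis ladder: a down-shift is detectable only against the
    # replicate-pair differences of the *largest* expression states in the
    # data, so down-regulated module members must sit at the very top of the
    # expression range.
    stratum: dict[str, float] = {}
    STRATUM_UP, STRATUM_DOWN, STRATUM_MARKER = 400.0, 11000.0, 400.0

    sponge_triples, precursor_triples = [], []
    module_lncs = plain_lnc[-(config.n_sponge_pairs + config.n_precursor_pairs):]
    mrna_pool = [c for c in coding_ids]
    rng.shuffle(mrna_pool)
    for i in range(config.n_sponge_pairs):
        lnc = module_lncs[i]
        mir = mirna_ids[i]
        mrna = mrna_pool[i]
        cultivar, stage = pick_contrast(module_contrasts)
        direction = "up" if rng.random() < 0.7 else "down"
        plant_site(lnc, near_perfect_site(mirnas[mir]))
        plant_site(mrna, near_perfect_site(mirnas[mir]),
                   window=(len(seqs[mrna]) - 400, len(seqs[mrna])))
        plant_de(lnc, cultivar, stage, direction, draw_lfc(module=True))
        plant_de(mrna, cultivar, stage, direction, draw_lfc(module=True))
        if i < 3:  # a few modules recur in a second cultivar (shared-module table)
            other = next(c for c, s in module_contrasts
                         if c != cultivar and s == stage)
            plant_de(lnc, other, stage, direction, draw_lfc(module=True))
            plant_de(mrna, other, stage, direction, draw_lfc(module=True))
        stratum[lnc] = stratum[mrna] = (
            STRATUM_UP if direction == "up" else STRATUM_DOWN
        )
        sponge_triples.append((lnc, mir, mrna, cultivar, stage))
    for i in range(config.n_precursor_pairs):
        lnc = module_lncs[config.n_sponge_pairs + i]
        mir = mirna_ids[config.n_sponge_pairs + i]
        mrna = mrna_pool[config.n_sponge_pairs + i]
        cultivar, stage = pick_contrast(module_contrasts)
        lnc_dir = "up" if rng.random() < 0.7 else "down"
        mrna_dir = "down" if lnc_dir == "up" else "up"
        plant_site(lnc, revcomp(mirnas[mir]))          # perfect complement
        plant_site(mrna, near_perfect_site(mirnas[mir]),
                   window=(len(seqs[mrna]) - 400, len(seqs[mrna])))
        plant_de(lnc, cultivar, stage, lnc_dir, draw_lfc(module=True))
        plant_de(mrna, cultivar, stage, mrna_dir, draw_lfc(module=True))
        stratum[lnc] = STRATUM_UP if lnc_dir == "up" else STRATUM_DOWN
        stratum[mrna] = STRATUM_UP if mrna_dir == "up" else STRATUM_DOWN
        precursor_triples.append((lnc, mir, mrna, cultivar, stage))

    # re-destroy ORFs possibly created by site planting, away from the sites
    for rna_id in protected:
        if rna_id in lnc_ids:
            seqs[rna_id] = destroy_orfs(
                seqs[rna_id], rng, protected=protected[rna_id]
            )

    # --- placement on chromosomes ---------------------------------------
    order: dict[str, list[str]] = {c: [] for c in chroms + ["U"]}
    for i, cid in enumerate(coding_ids):
        order[chroms[i % len(chroms)]].append(cid)
    sub_of = {}
    n_unplaced = int(config.fraction_unplaced * len(lnc_ids))
    unplaced = [l for l in lnc_ids
                if l not in {x for p in subgenome_pairs for x in p}][:n_unplaced]
    for lid in lnc_ids + novel_ids:
        if lid in unplaced:
            chrom = "U"
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
        sub_of[lid] = chrom
    # force sub-genome pair members onto distinct sub-genomes
    for idx, (src, dst) in enumerate(subgenome_pairs):
        sub_of[src] = chroms[0]                       # an A chromosome
        letter = "B" if idx < config.n_subgenome_pairs else "D"
        sub_of[dst] = next(c for c in chroms if c.endswith(letter))
    for lid, chrom in sub_of.items():
        pos = int(rng.integers(len(order[chrom]) + 1))
        order[chrom].insert(pos, lid)

    # --- cis / trans pairs ----------------------------------------------
    cis_pairs, trans_pairs = [], []
    used = set(module_lncs) | set(domain_ids)
    free_lnc = [l for l in plain_lnc if l not in used and sub_of[l] != "U"]
    chrom_of = {g: c for c, genes in order.items() for g in genes}
    for lnc in free_lnc[: config.n_cis_pairs]:
        chrom = chrom_of[lnc]
        idx = order[chrom].index(lnc)
        partner = next(
            (g for g in order[chrom][idx + 1:] + order[chrom][:idx][::-1]
             if g in set(coding_ids) and g not in stratum
             and not any(g == x for (x, _, _) in planted_de)), None,
        )
        if partner is None:
            continue
        cultivar, stage = pick_contrast(pair_contrasts)
        plant_de(lnc, cultivar, stage, "up", draw_lfc(module=True))
        plant_de(partner, cultivar, stage, "up", draw_lfc(module=True))
        stratum[lnc] = stratum[partner] = 300.0
        cis_pairs.append((lnc, partner, cultivar, stage))
    for lnc in free_lnc[config.n_cis_pairs : config.n_cis_pairs + config.n_trans_pairs]:
        partner = next(
            g for g in mrna_pool[config.n_sponge_pairs + config.n_precursor_pairs:]
            if chrom_of[g] != chrom_of[lnc]
        )
        mrna_pool.remove(partner)
        cultivar, stage = pick_contrast(pair_contrasts)
        direction = "up"
        # hybridization signal: the mRNA carries a reverse complement of a
        # lncRNA segment long enough to push ndG below the -0.15 cutoff
        shorter = min(len(seqs[lnc]), len(seqs[partner]))
        seg_len = max(150, int(0.13 * shorter))
        start = int(rng.integers(100, max(101, len(seqs[lnc]) - seg_len - 100)))
        segment = revcomp(seqs[lnc][start : start + seg_len])
        plant_site(partner, segment, window=(len(seqs[partner]) - seg_len - 300,
                                             len(seqs[partner])))
        plant_de(lnc, cultivar, stage, direction, draw_lfc(module=True))
        plant_de(partner, cultivar, stage, direction, draw_lfc(module=True))
        stratum[lnc] = stratum[partner] = 300.0
        trans_pairs.append((lnc, partner, cultivar, stage))

    # --- heat-shock marker cohort ----------------------------------------
    # A block of strongly induced genes (HSP-like) up-regulated in every
    # contrast.  Besides mirroring the biology of heat-stressed anthers,
    # this cohort anchors the BH rejection cascade of the empirical DE test
    # in every contrast (see methods note).
    used_genes = {g for (g, _, _) in planted_de}
    markers = [c for c in coding_ids if c not in used_genes][: config.n_heat_markers]
    for gene in markers:
        stratum[gene] = STRATUM_MARKER
        for cultivar, stage in contrasts:
            plant_de(gene, cultivar, stage, "up", draw_lfc(module=True))

    # --- background DE ---------------------------------------------------
    n_lnc_de = int(config.de_fraction * len(plain_lnc))
    background_lnc = [l for l in plain_lnc if not any(
        g == l for (g, _, _) in planted_de)]
    for lnc in background_lnc[:max(0, n_lnc_de - len(
            {g for (g, _, _) in planted_de if g in set(plain_lnc)}))]:
        cultivar, stage = pick_contrast()
        plant_de(lnc, cultivar, stage, "up" if rng.random() < 0.6 else "down")
    n_coding_de = int(config.de_fraction * 0.5 * len(coding_ids))
    background_coding = [c for c in coding_ids if not any(
        g == c for (g, _, _) in planted_de)]
    for gene in background_coding[:n_coding_de]:
        cultivar, stage = pick_contrast()
        plant_de(gene, cultivar, stage, "up" if rng.random() < 0.5 else "down")

    # --- assemble chromosomes + transcript models ------------------------
    transcripts: list[TranscriptModel] = []
    genome: dict[str, str] = {}
    tx_seqs: dict[str, str] = {}
    tx_to_gene: dict[str, str] = {}
    for chrom, genes in order.items():
        parts: list[str] = []
        cursor = 0
        for gene in genes:
            gap = int(rng.integers(3000, 15000))
            parts.append(random_sequence(rng, gap))
            cursor += gap
            seq = seqs[gene]
            if gene in class_codes:
                code = class_codes[gene]
                strand = str(rng.choice(np.array(["+", "-", "."]))) if code == "u" \
                    else str(rng.choice(np.array(["+", "-"])))
            else:
                code = "="
                strand = str(rng.choice(np.array(["+", "-"])))
            genomic = seq if strand != "-" else revcomp(seq)
            two_exons = len(seq) > 800 and rng.random() < 0.4
            exons = []
            if two_exons:
                split = len(seq) // 2
                intron = int(rng.integers(100, 500))
                exons = [
                    GenomicInterval(chrom, cursor, cursor + split, strand),
                    GenomicInterval(chrom, cursor + split + intron,
                                    cursor + len(seq) + intron, strand),
                ]
                parts.append(genomic[:split])
                parts.append(random_sequence(rng, intron))
                parts.append(genomic[split:])
                cursor += len(seq) + intron
            else:
                exons = [GenomicInterval(chrom, cursor, cursor + len(seq), strand)]
                parts.append(genomic)
                cursor += len(seq)
            span = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
            gene_id = gene.rsplit(".", 1)[0] if gene.startswith("MSTRG") else gene
            tid = gene if gene.startswith("MSTRG") else f"{gene}.1"
            transcripts.append(
                TranscriptModel(transcript_id=tid, gene_id=gene_id,
                                interval=span, exons=exons, class_code=code)
            )
            tx_seqs[tid] = seq
            tx_to_gene[tid] = gene_id
        parts.append(random_sequence(rng, int(rng.integers(3000, 15000))))
        genome[chrom] = "".join(parts)

    # ids used downstream are gene/locus ids (1:1 with transcripts here)
    def locus(name: str) -> str:
        return name.rsplit(".", 1)[0] if name.startswith("MSTRG") else name

    # --- protein database ------------------------------------------------
    protein_db = {
        f"PROT.{cid}": _translate(orf_sequence(seqs[cid])) for cid in coding_ids
    }
    for lid in domain_ids:
        protein_db[f"PFAM.{locus(lid)}"] = _translate(orf_sequence(seqs[lid]))

    training_noncoding = {
        f"TRAIN.NC.{i + 1:03d}": destroy_orfs(
            make_noncoding_sequence(
                rng, _draw_length(rng, config.lnc_length_mean, 0.45, 300, 8000)
            ),
            rng,
        )
        for i in range(config.n_training_noncoding)
    }

    de_table = pd.DataFrame(de_rows)
    de_table["gene"] = de_table["gene"].map(locus)

    truth = GroundTruth(
        noncoding_ids=[locus(l) for l in plain_lnc],
        coding_ids=[locus(n) for n in novel_ids],
        reference_coding_ids=list(coding_ids),
        domain_ids=[locus(d) for d in domain_ids],
        de_table=de_table,
        cis_pairs=[(locus(a), b, c, s) for a, b, c, s in cis_pairs],
        trans_pairs=[(locus(a), b, c, s) for a, b, c, s in trans_pairs],
        sponge_triples=[(locus(a), m, b, c, s) for a, m, b, c, s in sponge_triples],
        precursor_triples=[(locus(a), m, b, c, s)
                           for a, m, b, c, s in precursor_triples],
        subgenome_pairs=[(locus(a), locus(b)) for a, b in subgenome_pairs],
    )

    corpus = Corpus(
        config=config,
        transcripts=transcripts,
        genome=genome,
        tx_seqs=tx_seqs,
        tx_to_gene=tx_to_gene,
        protein_db=protein_db,
        training_noncoding=training_noncoding,
        truth=truth,
        mirnas=mirnas,
    )
    corpus._stratum = {locus(k): v for k, v in stratum.items()}  # type: ignore[attr-defined]
    return corpus


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def nb_sample(rng: np.random.Generator, mean: np.ndarray,
              dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(config: SimulationConfig, corpus: Corpus) -> None:
    """Realize the planted expression program as NB transcript counts.

    Gene baselines are log-normal (lncRNAs ~3x lower than coding genes, as
    in anther expression profiles); heat samples of a planted contrast get
    the 2^log2fc multiplier; cis/trans pair members share a per-sample
    latent log2-normal factor inducing the planted co-expression.
    """
    rng = np.random.default_rng(config.seed + 1)
    samples = [
        f"{cultivar[:2]}_{stage}_{condition}_{rep + 1}"
        for cultivar in CULTIVARS
        for stage in STAGES
        for condition in CONDITIONS
        for rep in range(config.replicates)
    ]
    design = pd.DataFrame(
        [
            {
                "sample": f"{c[:2]}_{s}_{cond}_{r + 1}",
                "cultivar": c, "stage": s, "condition": cond, "replicate": r + 1,
            }
            for c in CULTIVARS for s in STAGES for cond in CONDITIONS
            for r in range(config.replicates)
        ]
    ).set_index("sample")

    tids = list(corpus.tx_seqs)
    genes = [corpus.tx_to_gene[t] for t in tids]
    stratum = getattr(corpus, "_stratum", {})
    noncoding = set(corpus.truth.noncoding_ids) | set(corpus.truth.domain_ids)
    base = np.empty(len(tids))
    for i, gene in enumerate(genes):
        if gene in stratum:
            base[i] = rng.lognormal(math.log(stratum[gene]), 0.1)
        elif gene in noncoding:
            base[i] = rng.lognormal(math.log(40.0), 0.4)
        else:
            base[i] = rng.lognormal(math.log(100.0), 0.35)

    mean = np.tile(base[:, None], (1, len(samples)))
    sample_meta = design.loc[samples]

    de = corpus.truth.de_table
    gene_row = {g: i for i, g in enumerate(genes)}
    for _, row in de.iterrows():
        i = gene_row.get(row["gene"])
        if i is None:
            continue
        mask = (
            (sample_meta["cultivar"] == row["cultivar"])
            & (sample_meta["stage"] == row["stage"])
            & (sample_meta["condition"] == "heat")
        ).to_numpy()
        factor = 2.0 ** (row["log2fc"] if row["direction"] == "up" else -row["log2fc"])
        mean[i, mask] *= factor

    # The shared factor is drawn per condition group, not per sample: the
    # co-regulated response magnitude varies between states while biological
    # replicates stay exchangeable within a group (so planted pairs do not
    # distort the DE test's within-condition noise cloud).
    for lnc, gene, cultivar, stage in (
        corpus.truth.cis_pairs + corpus.truth.trans_pairs
    ):
        for condition in CONDITIONS:
            mask = (
                (sample_meta["cultivar"] == cultivar)
                & (sample_meta["stage"] == stage)
                & (sample_meta["condition"] == condition)
            ).to_numpy()
            factor = 2.0 ** (config.latent_sd * rng.normal())
            for g in (lnc, gene):
                i = gene_row.get(g)
                if i is not None:
                    mean[i, mask] *= factor

    depth = rng.uniform(0.7, 1.3, size=len(samples))
    mean *= depth[None, :]
    counts = nb_sample(rng, mean, config.nb_dispersion)
    corpus.counts = pd.DataFrame(counts, index=pd.Index(tids, name="transcript_id"),
                                 columns=samples)
    corpus.design = design


# ---------------------------------------------------------------------------
# miRNA FASTA, species sets, GO
# ---------------------------------------------------------------------------

_OBO_TERMS = [
    ("GO:0008150", "biological_process", []),
    ("GO:0006950", "response to stress", ["GO:0008150"]),
    ("GO:0009628", "response to abiotic stimulus", ["GO:0008150"]),
    ("GO:0008152", "metabolic process", ["GO:0008150"]),
    ("GO:0065007", "biological regulation", ["GO:0008150"]),
    ("GO:0032502", "developmental process", ["GO:0008150"]),
    ("GO:0009266", "response to temperature stimulus",
     ["GO:0006950", "GO:0009628"]),
    ("GO:0009408", "response to heat", ["GO:0009266"]),
    ("GO:0019538", "protein metabolic process", ["GO:0008152"]),
    ("GO:0006457", "protein folding", ["GO:0019538"]),
    ("GO:0006412", "translation", ["GO:0019538"]),
    ("GO:0010468", "regulation of gene expression", ["GO:0065007"]),
    ("GO:0009555", "pollen development", ["GO:0032502"]),
]

ENRICHED_TERM = "GO:0009408"
_LEAF_TERMS = ["GO:0006457", "GO:0006412", "GO:0010468", "GO:0009555", "GO:0009266"]


def _obo_text() -> str:
    out = ["format-version: 1.2", "ontology: go", ""]
    for term_id, name, parents in _OBO_TERMS:
        out.append("[Term]")
        out.append(f"id: {term_id}")
        out.append(f"name: {name}")
        out.append("namespace: biological_process")
        for parent in parents:
            out.append(f"is_a: {parent}")
        out.append("")
    return "\n".join(out)


def simulate_mirnas_and_homologs(config: SimulationConfig, corpus: Corpus) -> None:
    """Cross-species homolog sets, GO annotations and the ontology text.

    Conserved lncRNAs get point-mutated full-length copies in one to four
    species (closest species first, echoing the barley-heavy homology of
    grass lncRNAs); a 'diverged' control set mutates at a rate far past the
    60%-identity filter.  One lncRNA is copied into eleven species to serve
    as the phylogeny exemplar.  GO annotations plant one heat-response term
    enriched among differentially expressed coding genes.
    """
    rng = np.random.default_rng(config.seed + 2)
    truth = corpus.truth
    species = list(SPECIES[: config.n_species])
    lnc_by_locus = {
        corpus.tx_to_gene[t]: corpus.tx_seqs[t]
        for t in corpus.tx_seqs
        if corpus.tx_to_gene[t] in set(truth.noncoding_ids)
    }
    pool = sorted(lnc_by_locus)
    rng.shuffle(pool)
    n_conserved = int(config.conserved_fraction * len(pool))
    conserved = pool[:n_conserved]
    diverged = pool[n_conserved : n_conserved + config.n_diverged]

    sets: dict[str, dict[str, str]] = {sp: {} for sp in species}
    homolog_map: dict[str, list[str]] = {}
    weights = np.linspace(2.0, 0.5, num=len(species))
    weights /= weights.sum()
    for lnc in conserved:
        k = int(rng.integers(1, 5))
        chosen = list(rng.choice(species, size=min(k, len(species)),
                                 replace=False, p=weights))
        homolog_map[lnc] = sorted(chosen)
        for sp in chosen:
            sets[sp][f"{sp[:3]}_{lnc}"] = mutate_sequence(
                lnc_by_locus[lnc], rng, config.mutation_rate
            )
    tree_lnc = conserved[0] if conserved else None
    if tree_lnc is not None:
        chosen = species[: min(11, len(species))]
        homolog_map[tree_lnc] = sorted(set(homolog_map.get(tree_lnc, [])) | set(chosen))
        for sp in chosen:
            sets[sp][f"{sp[:3]}_{tree_lnc}"] = mutate_sequence(
                lnc_by_locus[tree_lnc], rng, config.mutation_rate
            )
    diverged_map: dict[str, list[str]] = {}
    for lnc in diverged:
        sp = species[int(rng.integers(len(species)))]
        diverged_map[lnc] = [sp]
        sets[sp][f"{sp[:3]}_div_{lnc}"] = mutate_sequence(
            lnc_by_locus[lnc], rng, config.diverged_mutation_rate
        )
    for sp in species:
        for i in range(8):  # unrelated decoys
            sets[sp][f"{sp[:3]}_decoy_{i}"] = make_noncoding_sequence(
                rng, int(rng.integers(600, 2000))
            )

    truth.homolog_map = homolog_map
    truth.diverged_map = diverged_map
    truth.tree_lncrna = tree_lnc
    truth.enriched_term = ENRICHED_TERM
    corpus.species_sets = sets

    de_genes = set(truth.de_table["gene"]) & set(truth.reference_coding_ids)
    annotations: dict[str, list[str]] = {}
    for gene in truth.reference_coding_ids:
        terms = set(rng.choice(_LEAF_TERMS, size=int(rng.integers(1, 3)),
                               replace=False))
        p_heat = 0.6 if gene in de_genes else 0.05
        if rng.random() < p_heat:
            terms.add(ENRICHED_TERM)
        annotations[gene] = sorted(terms)
    corpus.go_annotations = annotations
    corpus.obo_text = _obo_text()


def simulate_corpus(config: SimulationConfig | None = None) -> Corpus:
    """The full synthetic study: genome, counts and trans-world in one call."""
    config = config or SimulationConfig()
    corpus = simulate_genome(config)
    simulate_counts(config, corpus)
    simulate_mirnas_and_homologs(config, corpus)
    return corpus


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_corpus(corpus: Corpus, outdir: str | Path) -> dict[str, Path]:
    """Write every emitted file of the synthetic study; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": outdir / "annotation.gtf",
        "genome": outdir / "genome.fa",
        "transcripts": outdir / "transcripts.fa",
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "mirnas": outdir / "mirnas.fa",
        "proteins": outdir / "proteins.fa",
        "training_noncoding": outdir / "training_noncoding.fa",
        "go_annotations": outdir / "go_annotations.tsv",
        "obo": outdir / "ontology.obo",
        "truth": outdir / "ground_truth.json",
    }
    write_gtf(corpus.transcripts, paths["gtf"])
    write_fasta(corpus.genome, paths["genome"])
    write_fasta(corpus.tx_seqs, paths["transcripts"])
    if corpus.counts is not None:
        write_tsv(corpus.counts, paths["counts"])
        write_tsv(corpus.design, paths["design"])
    write_fasta(corpus.mirnas, paths["mirnas"])
    write_fasta(corpus.protein_db, paths["proteins"])
    write_fasta(corpus.training_noncoding, paths["training_noncoding"])
    pd.DataFrame(
        [(g, t) for g, terms in corpus.go_annotations.items() for t in terms],
        columns=["gene_id", "term_id"],
    ).to_csv(paths["go_annotations"], sep="\t", index=False)
    paths["obo"].write_text(corpus.obo_text)
    species_dir = outdir / "species"
    species_dir.mkdir(exist_ok=True)
    for sp, seqs in corpus.species_sets.items():
        write_fasta(seqs, species_dir / f"{sp}.fa")
        paths[f"species:{sp}"] = species_dir / f"{sp}.fa"
    truth = corpus.truth
    payload = {
        "noncoding_ids": truth.noncoding_ids,
        "coding_ids": truth.coding_ids,
        "reference_coding_ids": truth.reference_coding_ids,
        "domain_ids": truth.domain_ids,
        "de_table": truth.de_table.to_dict(orient="records"),
        "cis_pairs": truth.cis_pairs,
        "trans_pairs": truth.trans_pairs,
        "sponge_triples": truth.sponge_triples,
        "precursor_triples": truth.precursor_triples,
        "homolog_map": truth.homolog_map,
        "diverged_map": truth.diverged_map,
        "subgenome_pairs": truth.subgenome_pairs,
        "tree_lncrna": truth.tree_lncrna,
        "enriched_term": truth.enriched_term,
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths


# ---------------------------------------------------------------------------
# Focused calibration harnesses (DE power/type-I, correlation recovery)
# ---------------------------------------------------------------------------

def simulate_de_calibration(
    n_genes: int = 1000,
    n_planted: int = 0,
    log2fc: float = 2.0,
    dispersion: float = 0.1,
    replicates: int = 3,
    mean_log: float = math.log(100.0),
    mean_sd: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """A DE calibration panel: one perturbed contrast in a multi-group design.

    Two cultivars x two stages x two conditions x ``replicates`` are
    simulated (as in the emulated study, where many groups are quantified
    together); the first ``n_planted`` genes are up-regulated by ``log2fc``
    in the heat samples of the cranbrook/meiosis contrast only, every other
    group is null.  Returns (counts, design, planted gene ids).
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    rows = [
        (f"{c[:2]}_{s}_{cond}_{r + 1}", c, s, cond, r + 1)
        for c in CULTIVARS[:2] for s in STAGES for cond in CONDITIONS
        for r in range(replicates)
    ]
    design = pd.DataFrame(
        [dict(cultivar=c, stage=s, condition=cond, replicate=r)
         for _, c, s, cond, r in rows],
        index=pd.Index([name for name, *_ in rows], name="sample"),
    )
    base = rng.lognormal(mean_log, mean_sd, size=n_genes)
    mean = np.tile(base[:, None], (1, len(rows)))
    target = (
        (design["cultivar"] == "cranbrook")
        & (design["stage"] == "meiosis")
        & (design["condition"] == "heat")
    ).to_numpy()
    mean[:n_planted][:, target] *= 2.0 ** log2fc
    counts = pd.DataFrame(
        nb_sample(rng, mean, dispersion),
        index=pd.Index(genes, name="gene_id"), columns=design.index,
    )
    return counts, design, genes[:n_planted]


def simulate_correlation_panel(
    n_null: int = 2000,
    n_planted: int = 0,
    latent_sd: float = 2.0,
    n_samples: int = 6,
    dispersion: float = 0.05,
    base_mean: float = 300.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairs of expression vectors for correlation calibration.

    Returns (x, y, planted_mask) with shape (n_pairs, n_samples); planted
    pairs share a per-sample log2-normal latent factor, null pairs are
    independent NB draws.
    """
    rng = np.random.default_rng(seed)
    n_pairs = n_null + n_planted
    planted = np.zeros(n_pairs, dtype=bool)
    planted[:n_planted] = True
    z = rng.normal(0.0, 1.0, size=(n_pairs, n_samples))
    factor = 2.0 ** (latent_sd * z)
    mean_x = np.where(planted[:, None], base_mean * factor, base_mean)
    mean_y = np.where(planted[:, None], base_mean * factor, base_mean)
    x = nb_sample(rng, mean_x, dispersion).astype(float)
    y = nb_sample(rng, mean_y, dispersion).astype(float)
    return x, y, planted
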