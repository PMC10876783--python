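"""Homology-based conservation of lncRNAs across species and sub-genomes.

The default search engine is an internal seed-and-extend nucleotide aligner
(exact 11-mer seeds, ungapped extension at +1/-2 with an X-drop of 20,
Karlin-Altschul E-values), so conservation runs with no external binary; an
external ``blastn`` producing outfmt-6 can stand in when fidelity matters.

A lncRNA counts as conserved in a species when some hit satisfies all of:
E-value < 1e-5 (strict), identity >= 60% and alignment covering >= 30% of
the shorter sequence (both inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .formats import BlastHit, GenomicInterval

WORD_SIZE = 11
MATCH, MISMATCH = 1, -2
XDROP = 20
# Karlin-Altschul parameters for ungapped +1/-2 nucleotide scoring
KA_LAMBDA = 1.28
KA_K = 0.46

EVALUE_MAX = 1e-5
MIN_IDENTITY = 60.0
MIN_COVERAGE = 0.30


@dataclass
class ConservationCall:
    lncrna_id: str
    species: str
    best_hit: BlastHit
    identity: float
    coverage_of_shorter: float
    conserved: bool


def is_conserved(evalue: float, identity: float, coverage: float) -> bool:
    """E < 1e-5 strict; identity >= 60% and coverage >= 30% inclusive."""
    return evalue < EVALUE_MAX and identity >= MIN_IDENTITY and coverage >= MIN_COVERAGE


# ---------------------------------------------------------------------------
# Seed-and-extend aligner
# ---------------------------------------------------------------------------

def _extend(q: str, s: str, qi: int, si: int, word: int) -> tuple[int, int, int, int]:
    """Ungapped X-drop extension of an exact seed in both directions.

    Returns (q_start, q_end, matches, score) for the best-scoring segment.
    """
    score = word * MATCH
    best = score
    # right
    i, j = qi + word, si + word
    right_end = i
    while i < len(q) and j < len(s):
        score += MATCH if q[i] == s[j] else MISMATCH
        i += 1
        j += 1
        if score > best:
            best, right_end = score, i
        elif best - score > XDROP:
            break
    # left
    score = best
    i, j = qi - 1, si - 1
    left_start = qi
    while i >= 0 and j >= 0:
        score += MATCH if q[i] == s[j] else MISMATCH
        if score > best:
            best, left_start = score, i
        elif best - score > XDROP:
            break
        i -= 1
        j -= 1
    length = right_end - left_start
    # matches from the score identity: score = m*1 - (len-m)*2 -> m = (score+2len)/3
    matches = (best + 2 * length) // 3
    return left_start, right_end, int(matches), int(best)


def _evalue(score: int, query_len: int, db_len: int) -> float:
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * score)


def homology_search(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    word_size: int = WORD_SIZE,
    max_evalue: float = 10.0,
) -> list[BlastHit]:
    """Best hit per (query, subject) pair from the internal aligner.

    Seeds are exact ``word_size``-mers; each seeded diagonal is extended
    once.  E-values use the ungapped Karlin-Altschul formula with the total
    subject length as the database size.
    """
    if not subjects:
        return []
    db_len = sum(len(s) for s in subjects.values())
    index: dict[str, dict[str, list[int]]] = {}
    for sid, seq in subjects.items():
        words: dict[str, list[int]] = {}
        for j in range(len(seq) - word_size + 1):
            words.setdefault(seq[j : j + word_size], []).append(j)
        index[sid] = words
    hits: list[BlastHit] = []
    for qid, qseq in queries.items():
        for sid, words in index.items():
            sseq = subjects[sid]
            best: tuple[int, int, int, int] | None = None  # score, len, matches
            seen: set[int] = set()
            for i in range(len(qseq) - word_size + 1):
                for j in words.get(qseq[i : i + word_size], ()):
                    diag = i - j
                    if diag in seen:
                        continue
                    seen.add(diag)
                    qs, qe, matches, score = _extend(qseq, sseq, i, j, word_size)
                    if best is None or score > best[0]:
                        best = (score, qe - qs, matches, qs)
            if best is None:
                continue
            score, length, matches, _ = best
            evalue = _evalue(score, len(qseq), db_len)
            if evalue > max_evalue:
                continue
            hits.append(
                BlastHit(
                    query_id=qid,
                    subject_id=sid,
                    percent_identity=100.0 * matches / length,
                    alignment_length=length,
                    evalue=evalue,
                    query_len=len(qseq),
                    subject_len=len(sseq),
                    bitscore=float(score),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Conservation calls
# ---------------------------------------------------------------------------

def call_conservation(
    hits_by_species: Mapping[str, Sequence[BlastHit]],
    query_lens: Mapping[str, int],
    subject_lens: Mapping[str, Mapping[str, int]] | None = None,
) -> tuple[list[ConservationCall], dict]:
    """Apply the conservation thresholds per (lncRNA, species).

    ``hits_by_species`` maps species name to the BLAST hits of all wheat
    queries against that species' lncRNA set.  Returns the per-pair calls
    and a summary with per-species conserved counts plus the counts of loci
    conserved in >= 1, >= 2 and > 9 species.
    """
    calls: list[ConservationCall] = []
    conserved_species: dict[str, set[str]] = {}
    for species, hits in hits_by_species.items():
        best_per_query: dict[str, BlastHit] = {}
        for hit in hits:
            if hit.query_id not in query_lens:
                raise ValueError(f"hit references unknown query {hit.query_id}")
            prev = best_per_query.get(hit.query_id)
            if prev is None or hit.evalue < prev.evalue:
                best_per_query[hit.query_id] = hit
        for qid, hit in sorted(best_per_query.items()):
            qlen = query_lens[qid]
            slen = hit.subject_len
            if slen is None and subject_lens is not None:
                slen = subject_lens[species][hit.subject_id]
            shorter = min(qlen, slen) if slen else qlen
            coverage = hit.alignment_length / shorter
            conserved = is_conserved(hit.evalue, hit.percent_identity, coverage)
            calls.append(
                ConservationCall(
                    lncrna_id=qid, species=species, best_hit=hit,
                    identity=hit.percent_identity,
                    coverage_of_shorter=coverage, conserved=conserved,
                )
            )
            if conserved:
                conserved_species.setdefault(qid, set()).add(species)
    per_species = {
        sp: sum(1 for c in calls if c.species == sp and c.conserved)
        for sp in hits_by_species
    }
    n_species_per_locus = {q: len(sps) for q, sps in conserved_species.items()}
    summary = {
        "per_species": per_species,
        "conserved_any": len(conserved_species),
        "conserved_ge2": sum(1 for n in n_species_per_locus.values() if n >= 2),
        "conserved_gt9": sum(1 for n in n_species_per_locus.values() if n > 9),
    }
    return calls, summary


# ---------------------------------------------------------------------------
# Sub-genome conservation
# ---------------------------------------------------------------------------

SUBGENOMES = ("A", "B", "D")


def subgenome_of(chrom: str) -> str | None:
    """Sub-genome letter from a wheat chromosome name; None for 'U'/unknown."""
    if chrom and chrom[-1] in SUBGENOMES:
        return chrom[-1]
    return None


def subgenome_conservation(
    loci: Mapping[str, GenomicInterval],
    sequences: Mapping[str, str],
    word_size: int = WORD_SIZE,
) -> dict:
    """Within-wheat homology between A/B/D sub-genome lncRNA sets.

    Each lncRNA is assigned to the sub-genome of its chromosome (U loci are
    excluded); homology between the three sets uses the internal aligner
    and the standard conservation thresholds.  Returns the 3-set overlap
    table (counts of loci conserved in >= 2 sub-genomes and in all three).
    """
    groups: dict[str, dict[str, str]] = {g: {} for g in SUBGENOMES}
    excluded = []
    for lnc_id, locus in loci.items():
        sub = subgenome_of(locus.chrom)
        if sub is None:
            excluded.append(lnc_id)
            continue
        if lnc_id in sequences:
            groups[sub][lnc_id] = sequences[lnc_id]

    conserved_in: dict[str, set[str]] = {}
    for target in SUBGENOMES:
        for source in SUBGENOMES:
            if source == target:
                continue
            hits = homology_search(groups[source], groups[target], word_size)
            lens_q = {k: len(v) for k, v in groups[source].items()}
            calls, _ = call_conservation({target: hits}, lens_q)
            for call in calls:
                if call.conserved:
                    conserved_in.setdefault(call.lncrna_id, {subgenome_of(
                        loci[call.lncrna_id].chrom)}).add(target)

    sizes = {g: len(groups[g]) for g in SUBGENOMES}
    shared_ge2 = sum(1 for s in conserved_in.values() if len(s) >= 2)
    shared_all = sum(1 for s in conserved_in.values() if len(s) == 3)
    return {
        "subgenome_sizes": sizes,
        "excluded": excluded,
        "loci_shared_ge2": shared_ge2,
        "loci_shared_all3": shared_all,
        "per_locus": {k: sorted(v) for k, v in conserved_in.items()},
    }


def make_benchmark_panel(n_pairs: int = 20, seed: int = 77
                         ) -> list[tuple[str, str, str, str]]:
    """Deterministic (query, subject) pairs for aligner benchmarking.

    Subjects are point-mutated copies of the queries at divergences from 2%
    to 30%, the range where identity estimates between engines can differ.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    panel = []
    for i in range(n_pairs):
        length = int(rng.integers(800, 2000))
        query = "".join(rng.choice(bases, size=length))
        rate = 0.02 + 0.28 * i / max(1, n_pairs - 1)
        chars = np.array(list(query))
        hit = rng.random(length) < rate
        for j in np.where(hit)[0]:
            options = [b for b in "ACGT" if b != chars[j]]
            chars[j] = options[rng.integers(3)]
        panel.append((f"q{i:02d}", query, f"s{i:02d}", "".join(chars)))
    return panel
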