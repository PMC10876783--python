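"""The lncRNA candidate-filter cascade.

Assembled transcripts annotated with gffcompare class codes are narrowed to
long non-coding candidates in four stages:

1. class-code selection — keep intronic/overlapping/intergenic/antisense
   transfrags (codes ``i``, ``o``, ``u``, ``x``);
2. length filter — drop spliced lengths shorter than 200 nt (strict);
3. a three-scorer coding-potential consensus (a CPAT-like logistic model on
   ORF/Fickett/hexamer features with a trained or fixed probability cutoff,
   an ORF-size rule, and a hexamer-bias sign rule) — a candidate survives
   only when *all three* call it non-coding;
4. a protein-domain veto: candidates whose translated longest ORF matches a
   protein database are removed.

Scorers 2 and 3 deliberately reduce CPC/CNCI to their load-bearing features
(ORF geometry, hexamer usage) so the three-way intersection logic can be
tested exactly; they are not ports of those tools.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from sklearn.linear_model import LogisticRegression

from ._tables import (
    FICKETT_CONTENT_PROBABILITIES,
    FICKETT_CONTENT_THRESHOLDS,
    FICKETT_CONTENT_WEIGHTS,
    FICKETT_POSITION_PROBABILITIES,
    FICKETT_POSITION_THRESHOLDS,
    FICKETT_POSITION_WEIGHTS,
    STOP_CODONS,
)
from .formats import TranscriptModel

LNCRNA_CLASS_CODES = frozenset("ioux")
MIN_LNCRNA_LENGTH = 200

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Stage 1 + 2: class codes and length
# ---------------------------------------------------------------------------

def select_candidates(transcripts: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """Keep transcripts whose class code is one of ``i``, ``o``, ``u``, ``x``."""
    return [t for t in transcripts if t.class_code in LNCRNA_CLASS_CODES]


def length_filter(
    candidates: Iterable[TranscriptModel], min_len: int = MIN_LNCRNA_LENGTH
) -> list[TranscriptModel]:
    """Drop candidates with spliced length shorter than ``min_len`` (strict)."""
    return [t for t in candidates if t.spliced_length >= min_len]


# ---------------------------------------------------------------------------
# ORF scan
# ---------------------------------------------------------------------------

def longest_orf(sequence: str) -> tuple[int, float, int]:
    """Longest ATG..stop ORF over the three forward frames.

    Returns ``(orf_length, orf_coverage, frame)`` with the stop codon counted
    in the length; ties are broken by the leftmost start.  ``(0, 0.0, -1)``
    when no complete ORF exists.
    """
    n = len(sequence)
    best_len, best_start, best_frame = 0, n, -1
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = sequence[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - start
                if length > best_len or (length == best_len and start < best_start):
                    best_len, best_start, best_frame = length, start, frame
                start = None
    if best_len == 0:
        return 0, 0.0, -1
    return best_len, best_len / n, best_frame


def orf_sequence(sequence: str) -> str:
    """The nucleotide sequence of the longest ORF (empty if none)."""
    length, _, frame = longest_orf(sequence)
    if length == 0:
        return ""
    # re-scan the winning frame for the leftmost start achieving the length
    n = len(sequence)
    start = None
    for pos in range(frame, n - 2, 3):
        codon = sequence[pos : pos + 3]
        if start is None:
            if codon == "ATG":
                start = pos
        elif codon in STOP_CODONS:
            if pos + 3 - start == length:
                return sequence[start : pos + 3]
            start = None
    return ""


# ---------------------------------------------------------------------------
# Fickett TESTCODE
# ---------------------------------------------------------------------------

def _lookup(value: float, thresholds: Sequence[float], probs: Sequence[float]) -> float:
    for threshold, prob in zip(thresholds, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_score(sequence: str) -> float:
    """Fickett (1982) TESTCODE score from base periodicity and composition.

    For each base the position parameter is ``max(phase counts) /
    (min(phase counts) + 1)`` over the three codon phases, and the content
    parameter is the base's overall frequency; both are mapped through the
    published lookup tables and combined as a weighted sum of the eight
    probabilities.
    """
    seq = sequence.upper()
    score = 0.0
    phase_counts = {b: [0, 0, 0] for b in _BASES}
    for i, base in enumerate(seq):
        if base in phase_counts:
            phase_counts[base][i % 3] += 1
    total = sum(sum(v) for v in phase_counts.values())
    if total == 0:
        return 0.0
    for base in _BASES:
        counts = phase_counts[base]
        position = max(counts) / (min(counts) + 1)
        content = sum(counts) / total
        score += FICKETT_POSITION_WEIGHTS[base] * _lookup(
            position, FICKETT_POSITION_THRESHOLDS, FICKETT_POSITION_PROBABILITIES[base]
        )
        score += FICKETT_CONTENT_WEIGHTS[base] * _lookup(
            content, FICKETT_CONTENT_THRESHOLDS, FICKETT_CONTENT_PROBABILITIES[base]
        )
    return score


# ---------------------------------------------------------------------------
# Hexamer usage bias
# ---------------------------------------------------------------------------

def train_hexamer_table(
    sequences: Iterable[str], in_frame: bool, pseudocount: float = 0.5
) -> dict[str, float]:
    """Hexamer frequency table from a training corpus.

    ``in_frame=True`` counts codon-phased hexamers of each sequence's longest
    ORF (a coding corpus); ``in_frame=False`` counts all overlapping hexamers
    (a non-coding corpus).  Frequencies carry a pseudocount floor so log
    ratios stay finite.
    """
    counts: Counter[str] = Counter()
    for seq in sequences:
        if in_frame:
            orf = orf_sequence(seq)
            counts.update(orf[i : i + 6] for i in range(0, len(orf) - 5, 3))
        else:
            counts.update(seq[i : i + 6] for i in range(len(seq) - 5))
    kmers = ["".join(p) for p in itertools.product(_BASES, repeat=6)]
    total = sum(counts[k] for k in kmers) + pseudocount * len(kmers)
    return {k: (counts[k] + pseudocount) / total for k in kmers}


def hexamer_score(
    sequence: str,
    coding_table: Mapping[str, float],
    noncoding_table: Mapping[str, float],
) -> float:
    """Mean log-ratio of coding vs non-coding hexamer usage over the longest ORF.

    Returns 0.0 when the longest ORF is shorter than 6 nt.
    """
    orf = orf_sequence(sequence)
    if len(orf) < 6:
        return 0.0
    ratios = []
    for i in range(0, len(orf) - 5, 3):
        hexamer = orf[i : i + 6]
        fc = coding_table.get(hexamer)
        fn = noncoding_table.get(hexamer)
        if fc and fn:
            ratios.append(math.log(fc / fn))
    return float(np.mean(ratios)) if ratios else 0.0


# ---------------------------------------------------------------------------
# Logistic coding model (CPAT-like)
# ---------------------------------------------------------------------------

@dataclass
class CodingModel:
    """A logistic regression on (log ORF length, ORF coverage, Fickett, hexamer)."""

    model: LogisticRegression
    cutoff: float
    coding_table: Mapping[str, float]
    noncoding_table: Mapping[str, float]

    def features(self, sequence: str) -> np.ndarray:
        length, coverage, _ = longest_orf(sequence)
        return np.array(
            [
                math.log1p(length),
                coverage,
                fickett_score(sequence),
                hexamer_score(sequence, self.coding_table, self.noncoding_table),
            ]
        )

    def coding_probability(self, sequence: str) -> float:
        return float(self.model.predict_proba(self.features(sequence)[None, :])[0, 1])


def two_graph_roc_cutoff(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Probability at the sensitivity/specificity crossing of the training ROC.

    ``labels`` are 1 for coding.  The returned cutoff minimizes
    ``|sensitivity - specificity|`` over the observed probabilities.
    """
    candidates = np.unique(probabilities)
    pos = labels == 1
    best_cut, best_gap = 0.5, float("inf")
    for cut in candidates:
        sens = float(np.mean(probabilities[pos] >= cut)) if pos.any() else 0.0
        spec = float(np.mean(probabilities[~pos] < cut)) if (~pos).any() else 0.0
        gap = abs(sens - spec)
        if gap < best_gap:
            best_gap, best_cut = gap, float(cut)
    return best_cut


def fit_coding_model(
    coding_seqs: Sequence[str],
    noncoding_seqs: Sequence[str],
    fixed_cutoff: float | None = None,
) -> CodingModel:
    """Fit the logistic coding-potential model on a labeled training corpus.

    The probability cutoff is located at the two-graph ROC crossing on the
    training data unless a fixed cutoff (e.g. the conventional 0.365) is
    supplied.
    """
    if len(coding_seqs) < 50 or len(noncoding_seqs) < 50:
        raise ValueError("need at least 50 training examples per class")
    coding_table = train_hexamer_table(coding_seqs, in_frame=True)
    noncoding_table = train_hexamer_table(noncoding_seqs, in_frame=False)
    stub = CodingModel(
        model=LogisticRegression(C=np.inf, max_iter=2000),
        cutoff=0.5,
        coding_table=coding_table,
        noncoding_table=noncoding_table,
    )
    X = np.array([stub.features(s) for s in list(coding_seqs) + list(noncoding_seqs)])
    y = np.array([1] * len(coding_seqs) + [0] * len(noncoding_seqs))
    stub.model.fit(X, y)
    probs = stub.model.predict_proba(X)[:, 1]
    stub.cutoff = (
        float(fixed_cutoff) if fixed_cutoff is not None
        else two_graph_roc_cutoff(probs, y)
    )
    return stub


# ---------------------------------------------------------------------------
# Consensus filter + domain veto
# ---------------------------------------------------------------------------

@dataclass
class CodingPotentialReport:
    transcript_id: str
    orf_length: int
    orf_coverage: float
    fickett_score: float
    hexamer_score: float
    logistic_probability: float
    calls: dict[str, str]
    consensus: str

    @property
    def noncoding(self) -> bool:
        return self.consensus == "noncoding"


@dataclass
class DiscoveryResult:
    retained: list[TranscriptModel]
    reports: dict[str, CodingPotentialReport] = field(default_factory=dict)
    drop_counts: dict[str, int] = field(default_factory=dict)
    venn_counts: dict[str, int] = field(default_factory=dict)
    vetoed: list[str] = field(default_factory=list)


# Rule thresholds for the two orthogonal non-logistic scorers.
ORF_RULE_MAX_LENGTH = 300   # nt: short ORF
ORF_RULE_MAX_COVERAGE = 0.5


def consensus_filter(
    candidates: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
    model: CodingModel,
) -> DiscoveryResult:
    """Retain candidates that all three scorers call non-coding.

    * logistic scorer: non-coding iff coding probability < cutoff;
    * ORF-size rule: non-coding iff longest ORF < 300 nt *and* covers < 50%;
    * hexamer-sign rule: non-coding iff the ORF hexamer log-ratio is < 0.

    The seven-region Venn of the three scorers' non-coding calls is recorded
    so intersection reporting can be checked against the retained set.
    """
    retained, reports = [], {}
    venn = Counter()
    dropped = 0
    for tx in candidates:
        seq = sequences[tx.transcript_id]
        length, coverage, _ = longest_orf(seq)
        fick = fickett_score(seq)
        hexv = hexamer_score(seq, model.coding_table, model.noncoding_table)
        prob = model.coding_probability(seq)
        calls = {
            "logistic": "noncoding" if prob < model.cutoff else "coding",
            "orf_rule": (
                "noncoding"
                if length < ORF_RULE_MAX_LENGTH and coverage < ORF_RULE_MAX_COVERAGE
                else "coding"
            ),
            "hexamer_rule": "noncoding" if hexv < 0 else "coding",
        }
        key = "".join(
            scorer[0] for scorer in ("logistic", "orf_rule", "hexamer_rule")
            if calls[scorer] == "noncoding"
        ) or "none"
        venn[key] += 1
        consensus = (
            "noncoding" if all(v == "noncoding" for v in calls.values()) else "coding"
        )
        report = CodingPotentialReport(
            transcript_id=tx.transcript_id,
            orf_length=length,
            orf_coverage=coverage,
            fickett_score=fick,
            hexamer_score=hexv,
            logistic_probability=prob,
            calls=calls,
            consensus=consensus,
        )
        reports[tx.transcript_id] = report
        if consensus == "noncoding":
            retained.append(tx)
        else:
            dropped += 1
    return DiscoveryResult(
        retained=retained,
        reports=reports,
        drop_counts={"consensus": dropped},
        venn_counts=dict(venn),
    )


# Domain-veto alignment thresholds (translated longest ORF vs protein db).
VETO_SEED_LENGTH = 8     # exact amino-acid seed
VETO_MIN_IDENTITY = 0.40
VETO_MIN_LENGTH = 30     # aa


def _translate(orf_nt: str) -> str:
    orf_nt = orf_nt[: len(orf_nt) // 3 * 3]
    aa = str(Seq(orf_nt).translate())
    return aa.rstrip("*")


def _seed_extend_protein(query: str, subject: str) -> bool:
    """True if an exact 8-aa seed extends to >=40% identity over >=30 aa."""
    if len(query) < VETO_SEED_LENGTH or len(subject) < VETO_SEED_LENGTH:
        return False
    index: dict[str, list[int]] = {}
    for j in range(len(subject) - VETO_SEED_LENGTH + 1):
        index.setdefault(subject[j : j + VETO_SEED_LENGTH], []).append(j)
    seen_diagonals: set[int] = set()
    for i in range(len(query) - VETO_SEED_LENGTH + 1):
        for j in index.get(query[i : i + VETO_SEED_LENGTH], ()):
            diag = i - j
            if diag in seen_diagonals:
                continue
            seen_diagonals.add(diag)
            # ungapped comparison over the full diagonal; accept if any
            # window of >= 30 aa reaches 40% identity
            lo = max(0, diag)
            hi = min(len(query), len(subject) + diag)
            pairs = [(query[k], subject[k - diag]) for k in range(lo, hi)]
            m = np.array([a == b for a, b in pairs], dtype=np.int32)
            if len(m) < VETO_MIN_LENGTH:
                continue
            csum = np.concatenate([[0], np.cumsum(m)])
            length = len(m)
            # check all windows of length >= VETO_MIN_LENGTH for identity
            for w in range(VETO_MIN_LENGTH, length + 1):
                window = csum[w:] - csum[:-w]
                if window.size and window.max() >= VETO_MIN_IDENTITY * w:
                    return True
    return False


def domain_veto(
    result: DiscoveryResult,
    sequences: Mapping[str, str],
    protein_db: Mapping[str, str],
) -> DiscoveryResult:
    """Remove retained transcripts whose translated longest ORF hits the protein db.

    Transcripts without an ORF have nothing to match and are kept.
    """
    if not protein_db:
        raise ValueError("empty protein database")
    kept, vetoed = [], []
    for tx in result.retained:
        orf_nt = orf_sequence(sequences[tx.transcript_id])
        aa = _translate(orf_nt) if orf_nt else ""
        hit = any(_seed_extend_protein(aa, prot) for prot in protein_db.values()) if aa else False
        (vetoed if hit else kept).append(tx)
    drops = dict(result.drop_counts)
    drops["domain_veto"] = len(vetoed)
    return DiscoveryResult(
        retained=kept,
        reports=result.reports,
        drop_counts=drops,
        venn_counts=result.venn_counts,
        vetoed=[t.transcript_id for t in vetoed],
    )


def run_discovery(
    transcripts: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
    model: CodingModel,
    protein_db: Mapping[str, str] | None = None,
    min_len: int = MIN_LNCRNA_LENGTH,
) -> DiscoveryResult:
    """The full cascade: class codes -> length -> consensus -> domain veto."""
    candidates = select_candidates(transcripts)
    n_class_dropped = len(list(transcripts)) - len(candidates)
    long_enough = length_filter(candidates, min_len)
    n_short = len(candidates) - len(long_enough)
    result = consensus_filter(long_enough, sequences, model)
    result.drop_counts = {
        "class_code": n_class_dropped,
        "length": n_short,
        **result.drop_counts,
    }
    if protein_db:
        result = domain_veto(result, sequences, protein_db)
    return result
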