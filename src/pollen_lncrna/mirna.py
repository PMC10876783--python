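"""Plant-rule miRNA target scoring and sponge/precursor module assembly.

Targets are scored with the canonical plant penalty scheme used by
TargetFinder-style predictors: every register of the miRNA's reverse
complement along the target is evaluated, penalties are 1 per mismatch, 0.5
per G:U wobble and 1 per single-nucleotide target bulge, doubled at miRNA
positions 2-13 (5'->3'), and a site is a hit when the total is at most 4
(the tool's default cutoff).  At most one bulge per site keeps the scoring
exact and enumerable.

Modules combine those hits with differential-expression directions: a lncRNA
and mRNA targeted by the same miRNA in the same cultivar/stage contrast form
a *sponge* module when their trends agree, and a *precursor* module when the
trends are opposite and the lncRNA carries a perfect (full-length,
Watson-Crick only) copy of the miRNA's complement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import DEResult

MAX_SCORE = 4.0
CORE_START, CORE_END = 2, 13  # miRNA positions (1-based) with doubled penalties

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE = {("G", "T"), ("T", "G")}  # miRNA base, target base (DNA letters)


@dataclass
class MirnaInteraction:
    mirna_id: str
    rna_id: str
    rna_class: str          # lncRNA / mRNA
    score: float
    site_start: int         # 0-based on the target
    pairing: str            # one char per miRNA position: |, o, x, -
    perfect: bool


@dataclass(frozen=True)
class RegulatoryModule:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    role: str               # sponge / precursor
    cultivar: str
    stage: str
    lnc_direction: str
    mrna_direction: str


def _position_weight(mirna_pos: int) -> float:
    """Penalty multiplier for a 1-based miRNA position (doubled in 2-13)."""
    return 2.0 if CORE_START <= mirna_pos <= CORE_END else 1.0


def _score_register(mirna: str, site: str, bulge_at: int | None) -> tuple[float, str, bool]:
    """Penalty of one ungapped register (or one with a single target bulge).

    ``site`` is the target subsequence read 5'->3'; miRNA position ``i``
    (0-based) pairs with ``site[len(site) - 1 - i - shift]`` where ``shift``
    accounts for a bulged (unpaired) target nucleotide, if any.  Returns
    (score, pairing string 5'->3' on the miRNA, perfect flag).
    """
    n = len(mirna)
    score = 0.0
    pairing = []
    perfect = True
    t_idx = len(site) - 1
    for i, base in enumerate(mirna):
        pos = i + 1
        if bulge_at is not None and i == bulge_at:
            score += 1.0 * _position_weight(pos)
            t_idx -= 1  # skip the bulged target base
            pairing.append("-")
            perfect = False
        target_base = site[t_idx]
        t_idx -= 1
        if _COMPLEMENT[base] == target_base:
            pairing.append("|")
        elif (base, target_base) in _WOBBLE:
            score += 0.5 * _position_weight(pos)
            pairing.append("o")
            perfect = False
        else:
            score += 1.0 * _position_weight(pos)
            pairing.append("x")
            perfect = False
    return score, "".join(pairing), perfect


_B2I = {b: i for i, b in enumerate("ACGT")}


def _penalty_tables() -> tuple[np.ndarray, np.ndarray]:
    """4x4 penalty lookup (miRNA base x target base) and its wobble mask."""
    pen = np.ones((4, 4))
    for a, b in _COMPLEMENT.items():
        pen[_B2I[a], _B2I[b]] = 0.0
    for a, b in _WOBBLE:
        pen[_B2I[a], _B2I[b]] = 0.5
    return pen, pen == 0.5


_PENALTY, _ = _penalty_tables()


def _best_site(mirna: str, target: str, allow_bulge: bool
               ) -> tuple[float, int, int | None] | None:
    """Exact minimum-penalty site over all registers (and single bulges).

    A register with a target bulge after miRNA position ``b`` pairs
    positions < b as in the next register and positions >= b as in the
    current one, so all bulged scores derive from two cumulative-sum
    matrices of the ungapped per-position penalties.
    """
    n = len(mirna)
    t = np.array([_B2I[c] for c in target], dtype=np.int64)
    mir = np.array([_B2I[c] for c in mirna], dtype=np.int64)
    n_reg = len(t) - n + 1
    if n_reg <= 0:
        return None
    # windows[o, i] = target base paired with miRNA position i at register o
    windows = np.lib.stride_tricks.sliding_window_view(t, n)[:, ::-1]
    weights = np.array([2.0 if CORE_START <= i + 1 <= CORE_END else 1.0
                        for i in range(n)])
    pen = _PENALTY[mir[None, :], windows] * weights[None, :]
    totals = pen.sum(axis=1)
    best_score = float(totals.min())
    best = (best_score, int(totals.argmin()), None)
    if allow_bulge and n_reg >= 2:
        prefix = np.concatenate(
            [np.zeros((n_reg, 1)), np.cumsum(pen, axis=1)], axis=1
        )
        bulge_pen = weights  # bulge after position b costs 1 * weight(b+1)
        # score(start, b) = prefix[start+1, b] + w(b+1) + totals[start] - prefix[start, b]
        b_range = np.arange(1, n)
        scores = (
            prefix[1:, b_range]
            + bulge_pen[None, b_range]
            + totals[:-1, None]
            - prefix[:-1, b_range]
        )
        idx = np.unravel_index(scores.argmin(), scores.shape)
        if scores[idx] < best[0]:
            best = (float(scores[idx]), int(idx[0]), int(b_range[idx[1]]))
    return best


def plant_target_score(
    mirna_id: str,
    mirna_seq: str,
    rna_id: str,
    rna_seq: str,
    rna_class: str = "mRNA",
    max_score: float = MAX_SCORE,
    allow_bulge: bool = True,
) -> MirnaInteraction | None:
    """Best-scoring target site of a miRNA on an RNA, or None if above cutoff.

    miRNAs are expected to be 18-26 nt; targets shorter than the miRNA have
    no site.
    """
    mirna = mirna_seq.upper().replace("U", "T")
    target = rna_seq.upper().replace("U", "T")
    if not 18 <= len(mirna) <= 26:
        raise ValueError(f"miRNA {mirna_id} length {len(mirna)} outside 18-26 nt")
    n = len(mirna)
    if len(target) < n:
        return None
    best = _best_site(mirna, target, allow_bulge)
    if best is None or best[0] > max_score:
        return None
    score, start, bulge_at = best
    if bulge_at is None:
        score, pairing, perfect = _score_register(mirna, target[start : start + n], None)
    else:
        score, pairing, perfect = _score_register(
            mirna, target[start : start + n + 1], bulge_at
        )
    return MirnaInteraction(
        mirna_id=mirna_id, rna_id=rna_id, rna_class=rna_class,
        score=score, site_start=start, pairing=pairing,
        perfect=perfect and score == 0.0,
    )


def scan_targets(
    mirnas: Mapping[str, str],
    rnas: Mapping[str, str],
    rna_class: str,
    max_score: float = MAX_SCORE,
) -> list[MirnaInteraction]:
    hits = []
    for mirna_id, mirna_seq in mirnas.items():
        for rna_id, rna_seq in rnas.items():
            hit = plant_target_score(
                mirna_id, mirna_seq, rna_id, rna_seq, rna_class, max_score
            )
            if hit is not None:
                hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Module classification
# ---------------------------------------------------------------------------

def classify_modules(
    lnc_hits: Iterable[MirnaInteraction],
    mrna_hits: Iterable[MirnaInteraction],
    de_results: Iterable[DEResult],
) -> list[RegulatoryModule]:
    """Assemble sponge/precursor modules from miRNA hits and DE directions.

    Both the lncRNA and the mRNA must be differentially expressed in the
    same cultivar/stage contrast and targeted by the same miRNA.  Concordant
    trends give a sponge; opposite trends give a precursor only when the
    lncRNA-miRNA interaction is perfect.
    """
    directions: dict[tuple[str, str, str], str] = {}
    for r in de_results:
        if r.direction != "ns":
            directions[(r.gene_id, r.cultivar, r.stage)] = r.direction

    by_mirna_lnc: dict[str, list[MirnaInteraction]] = {}
    for hit in lnc_hits:
        by_mirna_lnc.setdefault(hit.mirna_id, []).append(hit)
    modules: list[RegulatoryModule] = []
    for mrna_hit in mrna_hits:
        for lnc_hit in by_mirna_lnc.get(mrna_hit.mirna_id, ()):
            for (gene, cultivar, stage), mrna_dir in directions.items():
                if gene != mrna_hit.rna_id:
                    continue
                lnc_dir = directions.get((lnc_hit.rna_id, cultivar, stage))
                if lnc_dir is None:
                    continue
                if lnc_dir == mrna_dir:
                    role = "sponge"
                elif lnc_hit.perfect:
                    role = "precursor"
                else:
                    continue
                modules.append(
                    RegulatoryModule(
                        lncrna_id=lnc_hit.rna_id,
                        mirna_id=mrna_hit.mirna_id,
                        mrna_id=mrna_hit.rna_id,
                        role=role,
                        cultivar=cultivar,
                        stage=stage,
                        lnc_direction=lnc_dir,
                        mrna_direction=mrna_dir,
                    )
                )
    return modules


def module_table(modules: Sequence[RegulatoryModule]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": m.lncrna_id, "mirna_id": m.mirna_id,
                "mrna_id": m.mrna_id, "role": m.role, "cultivar": m.cultivar,
                "stage": m.stage, "lnc_direction": m.lnc_direction,
                "mrna_direction": m.mrna_direction,
            }
            for m in modules
        ]
    )


def module_summary(modules: Sequence[RegulatoryModule]) -> dict:
    """Counts per role plus the cross-cultivar sharing table.

    A module identity is the (lncRNA, miRNA, mRNA, role) quadruple; the
    shared table lists identities present in two or more cultivars.
    """
    counts = {
        role: {
            "modules": 0, "lncrnas": 0, "mirnas": 0, "mrnas": 0,
        }
        for role in ("sponge", "precursor")
    }
    by_identity: dict[tuple[str, str, str, str], set[str]] = {}
    for role in counts:
        sub = [m for m in modules if m.role == role]
        counts[role]["modules"] = len({(m.lncrna_id, m.mirna_id, m.mrna_id) for m in sub})
        counts[role]["lncrnas"] = len({m.lncrna_id for m in sub})
        counts[role]["mirnas"] = len({m.mirna_id for m in sub})
        counts[role]["mrnas"] = len({m.mrna_id for m in sub})
    for m in modules:
        by_identity.setdefault(
            (m.lncrna_id, m.mirna_id, m.mrna_id, m.role), set()
        ).add(m.cultivar)
    shared = [
        {
            "lncrna_id": lnc, "mirna_id": mir, "mrna_id": mrna, "role": role,
            "cultivars": sorted(cultivars),
        }
        for (lnc, mir, mrna, role), cultivars in sorted(by_identity.items())
        if len(cultivars) >= 2
    ]
    role_venn = Counter(
        (role, len(cvs)) for (_, _, _, role), cvs in by_identity.items()
    )
    return {
        "counts": counts,
        "shared_modules": shared,
        "cultivar_multiplicity": {
            f"{role}_{n}": int(v) for (role, n), v in sorted(role_venn.items())
        },
    }
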