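"""Cis/trans target inference for differentially expressed lncRNAs.

A lncRNA's *cis* candidates are the 10 protein-coding genes on either side of
its locus; every other gene is a *trans* candidate.  Candidate pairs are
scored by Pearson correlation of normalized expression across a cultivar's
samples; cis pairs are kept at P < 0.05 (at n = 6 this is |r| > 0.81), trans
pairs additionally pass Benjamini-Hochberg correction and an RNA-RNA
hybridization filter: the normalized binding free energy (ndG, minimum
nearest-neighbor duplex energy divided by the shorter sequence length) must
be at most -0.15 kcal/mol/nt.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._tables import WC_STACKS_RNA, WOBBLE_SCALE
from .expression import ExpressionMatrix, bh_adjust
from .formats import GenomicInterval

ALPHA = 0.05
NDG_CUTOFF = -0.15
CIS_WINDOW_GENES = 10


@dataclass
class CorrelationEdge:
    lncrna_id: str
    gene_id: str
    mode: str                 # cis / trans
    r: float
    p: float
    cultivar: str
    stage: str
    q: float | None = None    # BH-adjusted (trans only)
    distance_bp: int | None = None  # signed (cis only)
    ndg: float | None = None  # kcal/mol/nt (trans only)


# ---------------------------------------------------------------------------
# Cis neighborhoods
# ---------------------------------------------------------------------------

class GeneIndex:
    """Protein-coding gene loci indexed by chromosome and genomic order."""

    def __init__(self, gene_loci: Mapping[str, GenomicInterval]):
        self._by_chrom: dict[str, list[tuple[int, str, GenomicInterval]]] = {}
        for gene_id, iv in gene_loci.items():
            self._by_chrom.setdefault(iv.chrom, []).append((iv.start, gene_id, iv))
        for entries in self._by_chrom.values():
            entries.sort()

    def cis_window(
        self, locus: GenomicInterval, k: int = CIS_WINDOW_GENES
    ) -> list[tuple[str, int]]:
        """Up to ``k`` genes on each side of ``locus``, with signed distances.

        Genes are taken in genomic order on the locus's chromosome, ignoring
        strand; distance is the signed gap between closest edges (0 when the
        gene overlaps the locus, positive downstream).
        """
        entries = self._by_chrom.get(locus.chrom)
        if not entries:
            return []
        starts = [s for s, _, _ in entries]
        split = bisect.bisect_left(starts, locus.start)
        upstream = entries[max(0, split - k):split]
        downstream = entries[split:split + k]
        out = []
        for _, gene_id, iv in upstream + downstream:
            out.append((gene_id, locus.distance_to(iv)))
        return out


# ---------------------------------------------------------------------------
# Correlation machinery
# ---------------------------------------------------------------------------

def pearson_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with a two-sided t-test p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def critical_r(n: int, alpha: float = ALPHA) -> float:
    """The minimal |r| that reaches two-sided significance ``alpha`` at size n.

    Inverts ``t = r sqrt(n-2) / sqrt(1-r^2)`` at the alpha/2 tail of the
    t-distribution with n-2 degrees of freedom.
    """
    t = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t / np.sqrt(n - 2 + t ** 2))


# ---------------------------------------------------------------------------
# RNA-RNA hybridization (ndG)
# ---------------------------------------------------------------------------

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}
_IDX = {b: i for i, b in enumerate("ACGT")}


def _build_stack_table() -> np.ndarray:
    """(pair1, pair2) -> stacking energy, indexed by 4x4 base codes.

    Entry ``[x1, y1, x2, y2]`` is the energy of the duplex step
    5'-x1 x2-3' / 3'-y1 y2-5' (DNA letters stand in for RNA; T == U).
    Non-paired steps are 0.
    """
    table = np.zeros((4, 4, 4, 4))
    as_rna = str.maketrans("T", "U")

    def wc_energy(x1, y1, x2, y2) -> float | None:
        key = f"{x1}{x2}/{y1}{y2}".translate(as_rna)
        if key in WC_STACKS_RNA:
            return WC_STACKS_RNA[key]
        # 180-degree rotational symmetry of a duplex step
        alt = f"{y2}{y1}/{x2}{x1}".translate(as_rna)
        return WC_STACKS_RNA.get(alt)

    def substitutions(x, y):
        if (x, y) in _PAIRS:
            return [(x, y)]
        # G:U -> keep G (pair with C) or keep U (pair with A)
        return [("G", "C"), ("A", "T")] if (x, y) == ("G", "T") else [("C", "G"), ("T", "A")]

    all_pairs = list(_PAIRS | _WOBBLE)
    for x1, y1 in all_pairs:
        for x2, y2 in all_pairs:
            n_wobble = ((x1, y1) in _WOBBLE) + ((x2, y2) in _WOBBLE)
            if n_wobble == 0:
                e = wc_energy(x1, y1, x2, y2)
            else:
                vals = [
                    wc_energy(a1, b1, a2, b2)
                    for a1, b1 in substitutions(x1, y1)
                    for a2, b2 in substitutions(x2, y2)
                ]
                vals = [v for v in vals if v is not None]
                e = float(np.mean(vals)) * (WOBBLE_SCALE ** n_wobble) if vals else 0.0
            if e is not None:
                table[_IDX[x1], _IDX[y1], _IDX[x2], _IDX[y2]] = e
    return table


STACK_TABLE = _build_stack_table()


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_IDX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base {exc} after normalization") from exc


def ndg_score(lncrna_seq: str, target_seq: str) -> float:
    """Normalized binding free energy of the best local duplex.

    The shorter sequence is slid antiparallel along the longer at every
    offset (overhangs allowed).  Within a register, consecutive paired
    positions (Watson-Crick or G:U) form helices scored by nearest-neighbor
    stacking; a mismatch breaks the helix.  dG is the minimum helix energy
    over all registers and ndG = dG / len(shorter), in kcal/mol per nt.
    """
    if len(lncrna_seq) < 20 or len(target_seq) < 20:
        raise ValueError("sequences must be >= 20 nt")
    short, long_ = sorted((lncrna_seq, target_seq), key=len)
    s = _encode(short)[::-1]  # antiparallel: reverse the shorter strand
    t = _encode(long_)
    ls, lt = s.size, t.size
    # pad the longer sequence with a non-pairing sentinel so overhanging
    # registers become ordinary rows of a sliding-window matrix
    pad = np.full(ls - 1, 4, dtype=np.int8)
    tp = np.concatenate([pad, t.astype(np.int8), pad])
    windows = np.lib.stride_tricks.sliding_window_view(tp, ls)  # registers x ls
    paired = _PAIRED5[windows, s[None, :]]
    both = paired[:, :-1] & paired[:, 1:]
    rows, cols = np.nonzero(both)
    if rows.size == 0:
        return 0.0
    # stack energies only at paired dinucleotide steps (~15% of positions);
    # steps are row-major sorted, so each helix is a consecutive slice
    energies = _STACK5[
        windows[rows, cols], s[cols], windows[rows, cols + 1], s[cols + 1]
    ]
    new_run = np.empty(rows.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = (np.diff(rows) != 0) | (np.diff(cols) != 1)
    run_sums = np.add.reduceat(energies, np.flatnonzero(new_run))
    return float(run_sums.min()) / ls


def _extend_tables() -> tuple[np.ndarray, np.ndarray]:
    """Pairing/stack lookups extended with a 5th non-pairing sentinel code."""
    paired5 = np.zeros((5, 5), dtype=bool)
    for a, b in _PAIRS | _WOBBLE:
        paired5[_IDX[a], _IDX[b]] = True
    stack5 = np.zeros((5, 5, 5, 5))
    stack5[:4, :4, :4, :4] = STACK_TABLE
    return paired5, stack5


_PAIRED5, _STACK5 = _extend_tables()


# ---------------------------------------------------------------------------
# Edge construction
# ---------------------------------------------------------------------------

def build_cis_trans(
    de_lncrnas: Mapping[tuple[str, str], set[str]],
    de_genes: Mapping[tuple[str, str], set[str]],
    matrix: ExpressionMatrix,
    lnc_loci: Mapping[str, GenomicInterval],
    gene_loci: Mapping[str, GenomicInterval],
    sequences: Mapping[str, str] | None = None,
    k: int = CIS_WINDOW_GENES,
    alpha: float = ALPHA,
    ndg_cutoff: float = NDG_CUTOFF,
    log_expression: bool = True,
) -> list[CorrelationEdge]:
    """Correlation edges between DE lncRNAs and DE protein-coding genes.

    ``de_lncrnas``/``de_genes`` map (cultivar, stage) contrasts to the DE
    gene ids.  Correlations use the cultivar/stage's samples (conditions x
    replicates, n = 6 at the default design) on log2 CPM.  Cis edges need
    p < alpha; trans edges need BH q < alpha *and* ndG <= ``ndg_cutoff``
    (skipped when no sequences are supplied).
    """
    index = GeneIndex(gene_loci)
    cpm = matrix.normalized_cpm()
    expr = np.log2(cpm + PSEUDO) if log_expression else cpm
    edges: list[CorrelationEdge] = []
    ndg_cache: dict[tuple[str, str], float] = {}

    for (cultivar, stage), lnc_ids in de_lncrnas.items():
        genes = de_genes.get((cultivar, stage), set())
        if not genes:
            continue
        samples = matrix.samples_for(cultivar, stage)
        sub = expr[samples]
        cis_edges: list[CorrelationEdge] = []
        trans_candidates: list[CorrelationEdge] = []
        for lnc in sorted(lnc_ids):
            locus = lnc_loci.get(lnc)
            if locus is None or lnc not in sub.index:
                continue
            neighbors = dict(index.cis_window(locus, k)) if locus else {}
            x = sub.loc[lnc].to_numpy()
            for gene in sorted(genes):
                if gene == lnc or gene not in sub.index:
                    continue
                y = sub.loc[gene].to_numpy()
                try:
                    r, p = pearson_test(x, y)
                except ValueError:
                    continue  # zero-variance profile: no testable signal
                if gene in neighbors:
                    if p < alpha:
                        cis_edges.append(
                            CorrelationEdge(
                                lncrna_id=lnc, gene_id=gene, mode="cis",
                                r=r, p=p, cultivar=cultivar, stage=stage,
                                distance_bp=neighbors[gene],
                            )
                        )
                else:
                    trans_candidates.append(
                        CorrelationEdge(
                            lncrna_id=lnc, gene_id=gene, mode="trans",
                            r=r, p=p, cultivar=cultivar, stage=stage,
                        )
                    )
        if trans_candidates:
            qvals = bh_adjust([e.p for e in trans_candidates])
            for edge, q in zip(trans_candidates, qvals):
                edge.q = float(q)
                if edge.q >= alpha:
                    continue
                if sequences is not None:
                    key = (edge.lncrna_id, edge.gene_id)
                    try:
                        if key not in ndg_cache:
                            ndg_cache[key] = ndg_score(
                                sequences[edge.lncrna_id], sequences[edge.gene_id]
                            )
                        edge.ndg = ndg_cache[key]
                    except KeyError:
                        continue
                    if edge.ndg > ndg_cutoff:
                        continue
                edges.append(edge)
        edges.extend(cis_edges)
    return edges


PSEUDO = 0.5


def edge_table(edges: Sequence[CorrelationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": e.lncrna_id, "gene_id": e.gene_id, "mode": e.mode,
                "cultivar": e.cultivar, "stage": e.stage, "r": e.r, "p": e.p,
                "q": e.q, "distance_bp": e.distance_bp, "ndg": e.ndg,
            }
            for e in edges
        ]
    )


def summarize_edges(edges: Sequence[CorrelationEdge]) -> dict:
    """Per-cultivar lncRNA/target counts, targets-per-lncRNA histogram and
    the cis distance density mode (in kb bins)."""
    table = edge_table(edges)
    if table.empty:
        return {"per_cultivar": {}, "targets_per_lncrna": {}, "cis_distance_mode_kb": None}
    per_cultivar = {}
    for (cultivar, mode), sub in table.groupby(["cultivar", "mode"]):
        per_cultivar.setdefault(cultivar, {})[mode] = {
            "lncrnas": int(sub["lncrna_id"].nunique()),
            "targets": int(sub["gene_id"].nunique()),
            "edges": int(len(sub)),
        }
    targets_per = (
        table.groupby("lncrna_id")["gene_id"].nunique().value_counts().sort_index()
    )
    cis = table[table["mode"] == "cis"].dropna(subset=["distance_bp"])
    mode_kb = None
    if len(cis):
        kb = (cis["distance_bp"].abs() // 10_000) * 10  # 10-kb bins
        mode_kb = int(kb.mode().iloc[0])
    return {
        "per_cultivar": per_cultivar,
        "targets_per_lncrna": {int(k): int(v) for k, v in targets_per.items()},
        "cis_distance_mode_kb": mode_kb,
    }
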