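"""Quantification-to-DE stage: locus aggregation, TMM, CPM filtering and a
nonparametric noise-distribution differential-expression test.

The DE test follows the NOISeq idea: a gene's signal is the pair
``(M, D)`` — log2 ratio and absolute difference of its normalized condition
means — and is compared against an empirical noise cloud built from all
within-condition replicate pairs, pooled across genes and across every
replicate group in the design.  The probability of differential expression
is the fraction of noise points the gene dominates on both axes, and
``1 - probability`` is the test's FDR-like quantity: a call at probability
>= 0.95 corresponds to an empirical FDR of 0.05.  (A BH correction of these
empirical p-values is provided for downstream uses with continuous
p-values, but is not the DE call criterion; the granularity and the NB
noise tail make it uninformative here — see docs/methods.md.)
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PSEUDOCOUNT = 0.5
LNC_LFC_THRESHOLD = 0.5   # |log2FC| rule for lncRNAs (their expression is low)
CODING_LFC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.05


@dataclass
class ExpressionMatrix:
    """Genes x samples counts plus the sample design and TMM factors."""

    counts: pd.DataFrame            # genes x samples, non-negative
    design: pd.DataFrame            # sample -> cultivar/stage/condition/replicate
    tmm: pd.Series | None = None    # per-sample normalization factor

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples absent from design: {sorted(missing)}")
        self.design = self.design.loc[self.counts.columns]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def normalized_cpm(self) -> pd.DataFrame:
        """Counts per million on TMM-scaled library sizes."""
        factors = self.tmm if self.tmm is not None else pd.Series(
            1.0, index=self.counts.columns
        )
        eff = self.library_sizes * factors
        return self.counts.div(eff, axis=1) * 1e6

    def samples_for(self, cultivar: str, stage: str | None = None,
                    condition: str | None = None) -> list[str]:
        mask = self.design["cultivar"] == cultivar
        if stage is not None:
            mask &= self.design["stage"] == stage
        if condition is not None:
            mask &= self.design["condition"] == condition
        return list(self.design.index[mask])


@dataclass
class DEResult:
    gene_id: str
    cultivar: str
    stage: str
    log2fc: float
    de_probability: float
    fdr: float
    direction: str        # up / down / ns
    biotype: str = "coding"


# ---------------------------------------------------------------------------
# Locus aggregation
# ---------------------------------------------------------------------------

def aggregate_to_locus(
    transcript_counts: pd.DataFrame, transcript_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Sum transcript-level counts to the gene (locus) level."""
    unmapped = [t for t in transcript_counts.index if t not in transcript_to_gene]
    if unmapped:
        raise ValueError(f"transcripts without a gene mapping: {unmapped[:5]}")
    genes = pd.Index([transcript_to_gene[t] for t in transcript_counts.index],
                     name=transcript_counts.index.name or "gene_id")
    return transcript_counts.groupby(genes).sum().sort_index()


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values)
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray,
              log_ratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    n_obs, n_ref = obs.sum(), ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if log_r.size == 0:
        raise ValueError("no genes expressed in both sample and reference")
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, ref_sample: str | None = None) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference defaults to the sample whose library-size-scaled upper
    quartile is closest to the mean upper quartile, and per-sample factors
    come from a doubly trimmed (30% on M, 5% on A), precision-weighted mean
    of the M-values of genes expressed in both libraries.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if ref_sample is None:
        f75 = np.array(
            [np.quantile(counts.iloc[:, j].to_numpy(dtype=float), 0.75)
             for j in range(counts.shape[1])]
        ) / lib
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_sample)
    ref = counts.iloc[:, ref_idx].to_numpy(dtype=float)
    factors = np.array(
        [_tmm_pair(counts.iloc[:, j].to_numpy(dtype=float), ref)
         for j in range(counts.shape[1])]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm")


# ---------------------------------------------------------------------------
# CPM filter
# ---------------------------------------------------------------------------

def cpm_filter(matrix: ExpressionMatrix, min_cpm: float = 1.0) -> ExpressionMatrix:
    """Drop genes below ``min_cpm`` (strict) in every condition group.

    A gene is kept when its CPM is >= ``min_cpm`` in *all* samples of at
    least one cultivar/stage/condition group.
    """
    cpm = matrix.normalized_cpm()
    keep = pd.Series(False, index=cpm.index)
    groups = matrix.design.groupby(["cultivar", "stage", "condition"]).groups
    for samples in groups.values():
        keep |= (cpm[list(samples)] >= min_cpm).all(axis=1)
    return ExpressionMatrix(
        counts=matrix.counts.loc[keep],
        design=matrix.design,
        tmm=matrix.tmm,
    )


# ---------------------------------------------------------------------------
# NOISeq-style DE
# ---------------------------------------------------------------------------

def _signal_md(values: np.ndarray, cond_a: np.ndarray, cond_b: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    mean_a = values[:, cond_a].mean(axis=1) + PSEUDOCOUNT
    mean_b = values[:, cond_b].mean(axis=1) + PSEUDOCOUNT
    return np.log2(mean_a / mean_b), np.abs(mean_a - mean_b)


def noise_distribution(values: np.ndarray, groups: Sequence[np.ndarray]
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-condition (M, D) from every replicate pair of every gene."""
    ms, ds = [], []
    for group in groups:
        for i, j in combinations(range(len(group)), 2):
            a = values[:, group[i]] + PSEUDOCOUNT
            b = values[:, group[j]] + PSEUDOCOUNT
            ms.append(np.log2(a / b))
            ds.append(np.abs(a - b))
    if not ms:
        raise ValueError("no within-condition replicate pairs available")
    return np.concatenate(ms), np.concatenate(ds)


def _dominance_probability(m_sig: np.ndarray, d_sig: np.ndarray,
                           m_noise: np.ndarray, d_noise: np.ndarray) -> np.ndarray:
    """Fraction of noise points strictly dominated on both |M| and D axes."""
    abs_m_noise = np.abs(m_noise)
    n = abs_m_noise.size
    probs = np.empty(m_sig.size)
    chunk = 256
    for start in range(0, m_sig.size, chunk):
        stop = min(start + chunk, m_sig.size)
        dominated = (
            (abs_m_noise[None, :] < np.abs(m_sig[start:stop, None]))
            & (d_noise[None, :] < d_sig[start:stop, None])
        )
        probs[start:stop] = dominated.sum(axis=1) / n
    return probs


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")


def noiseq_de(
    matrix: ExpressionMatrix,
    cultivar: str,
    stage: str,
    biotypes: Mapping[str, str] | None = None,
    stress: str = "heat",
    control: str = "control",
    lnc_lfc: float = LNC_LFC_THRESHOLD,
    coding_lfc: float = CODING_LFC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> list[DEResult]:
    """NOISeq-style DE for one heat-vs-control contrast.

    ``biotypes`` maps gene ids to ``lncRNA``/``coding`` and selects the
    |log2FC| threshold used for the up/down call (0.5 for lncRNAs, 1 for
    coding genes); unlisted genes are treated as coding.
    """
    stress_samples = matrix.samples_for(cultivar, stage, stress)
    control_samples = matrix.samples_for(cultivar, stage, control)
    if len(stress_samples) < 2 or len(control_samples) < 2:
        raise ValueError(
            f"contrast {cultivar}/{stage} needs >= 2 replicates per condition"
        )
    cpm = matrix.normalized_cpm()
    samples = stress_samples + control_samples
    values = cpm[samples].to_numpy(dtype=float)
    idx_stress = np.arange(len(stress_samples))
    idx_control = np.arange(len(stress_samples), len(samples))
    m_sig, d_sig = _signal_md(values, idx_stress, idx_control)
    # replicate noise is homogeneous across groups, so the noise cloud pools
    # every within-condition replicate pair of the whole design; this also
    # gives the empirical p a finer resolution than the contrast's own
    # samples could
    all_values = cpm.to_numpy(dtype=float)
    col_of = {s: i for i, s in enumerate(cpm.columns)}
    groups = [
        np.array([col_of[s] for s in idx_samples])
        for _, idx_samples in matrix.design.groupby(
            ["cultivar", "stage", "condition"]
        ).groups.items()
    ]
    m_noise, d_noise = noise_distribution(all_values, groups)
    prob = _dominance_probability(m_sig, d_sig, m_noise, d_noise)
    # NOISeq threshold semantics: 1 - probability is the FDR-like quantity,
    # so probability >= 0.95 corresponds to FDR <= 0.05 (see docs/methods.md
    # for why a BH correction of these granular empirical p-values is not
    # usable as the call criterion)
    fdr = 1.0 - prob

    results = []
    biotypes = biotypes or {}
    for gene, lfc, p, q in zip(cpm.index, m_sig, prob, fdr):
        biotype = biotypes.get(gene, "coding")
        threshold = lnc_lfc if biotype == "lncRNA" else coding_lfc
        if q <= fdr_threshold and lfc > threshold:
            direction = "up"
        elif q <= fdr_threshold and lfc < -threshold:
            direction = "down"
        else:
            direction = "ns"
        results.append(
            DEResult(
                gene_id=gene, cultivar=cultivar, stage=stage,
                log2fc=float(lfc), de_probability=float(p), fdr=float(q),
                direction=direction, biotype=biotype,
            )
        )
    return results


DE_COLUMNS = ["gene_id", "cultivar", "stage", "log2fc", "de_probability",
              "fdr", "direction", "biotype"]


def de_table(results: Iterable[DEResult]) -> pd.DataFrame:
    results = list(results)
    if not results:
        return pd.DataFrame(columns=DE_COLUMNS)
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id, "cultivar": r.cultivar, "stage": r.stage,
                "log2fc": r.log2fc, "de_probability": r.de_probability,
                "fdr": r.fdr, "direction": r.direction, "biotype": r.biotype,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Summaries (up/down counts, cultivar Venns, stage overlap, top-variance genes)
# ---------------------------------------------------------------------------

def summarize_de(
    results: Sequence[DEResult],
    matrix: ExpressionMatrix | None = None,
    sensitive: Sequence[str] = ("cranbrook", "wyalkatchem"),
    tolerant: Sequence[str] = ("halberd", "young"),
    top_k: int = 1000,
) -> dict:
    """Stage/cultivar tabulations of the DE calls.

    Emits per-contrast up/down counts, per-stage cultivar overlap counts
    (sensitive pair, tolerant pair, all cultivars), the number of genes DE in
    both stages of a cultivar with concordant direction, and the ``top_k``
    genes by variance of normalized expression (for heatmapping).
    """
    table = de_table(results)
    de = table[table["direction"] != "ns"]

    updown = (
        de.groupby(["cultivar", "stage", "direction"]).size().unstack(fill_value=0)
        if len(de) else pd.DataFrame()
    )

    stage_overlap: dict[str, dict[str, int]] = {}
    cultivars = sorted(table["cultivar"].unique())
    stages = sorted(table["stage"].unique())
    for stage in stages:
        sets = {
            c: set(de[(de["cultivar"] == c) & (de["stage"] == stage)]["gene_id"])
            for c in cultivars
        }
        entry = {}
        sens = [sets[c] for c in sensitive if c in sets]
        tol = [sets[c] for c in tolerant if c in sets]
        if len(sens) == 2:
            entry["sensitive_pair"] = len(sens[0] & sens[1])
        if len(tol) == 2:
            entry["tolerant_pair"] = len(tol[0] & tol[1])
        if sets:
            entry["all_cultivars"] = len(set.intersection(*sets.values()))
        stage_overlap[stage] = entry

    concordant = 0
    if len(stages) >= 2:
        directed = {
            (r.gene_id, r.cultivar, r.stage): r.direction
            for r in results if r.direction != "ns"
        }
        seen = set()
        for (gene, cultivar, _), direction in directed.items():
            if (gene, cultivar) in seen:
                continue
            dirs = {
                directed.get((gene, cultivar, s)) for s in stages
            }
            if None not in dirs and len(dirs) == 1:
                concordant += 1
                seen.add((gene, cultivar))

    top_variance: list[str] = []
    if matrix is not None:
        cpm = matrix.normalized_cpm()
        variances = cpm.var(axis=1, ddof=1)
        top_variance = list(variances.sort_values(ascending=False).index[:top_k])

    return {
        "updown_counts": updown,
        "cultivar_overlap": stage_overlap,
        "stage_concordant": concordant,
        "top_variance_genes": top_variance,
    }
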