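#!/usr/bin/env python
"""Cis and trans target inference for the heat-responsive lncRNAs.

Cis: the 10 protein-coding genes either side of the lncRNA locus at
Pearson P < 0.05 (|r| > 0.81 at n = 6).  Trans: all other coding genes at
BH q < 0.05 plus hybridization ndG <= -0.15.  Writes results/targets.tsv
and results/targets_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

from pollen_lncrna.coexpression import build_cis_trans, edge_table, summarize_edges
from pollen_lncrna.expression import (
    ExpressionMatrix, aggregate_to_locus, cpm_filter, tmm_factors,
)
from pollen_lncrna.formats import read_counts, read_design, read_fasta, read_gtf

RESULTS = Path(__file__).resolve().parent.parent / "results"
CORPUS = RESULTS / "corpus"


def main() -> None:
    transcripts = read_gtf(CORPUS / "annotation.gtf")
    lnc_tx = read_gtf(RESULTS / "lncrnas.gtf")
    tx_seqs = read_fasta(CORPUS / "transcripts.fa")
    de = pd.read_csv(RESULTS / "de_results.tsv", sep="\t")
    de = de[de["direction"] != "ns"]
    matrix = ExpressionMatrix(
        aggregate_to_locus(read_counts(CORPUS / "counts.tsv"),
                           {t.transcript_id: t.gene_id for t in transcripts}),
        read_design(CORPUS / "design.tsv"),
    )
    matrix.tmm = tmm_factors(matrix.counts)
    matrix = cpm_filter(matrix)

    de_lnc = {(c, s): set(sub[sub["biotype"] == "lncRNA"]["gene_id"])
              for (c, s), sub in de.groupby(["cultivar", "stage"])}
    de_cod = {(c, s): set(sub[sub["biotype"] == "coding"]["gene_id"])
              for (c, s), sub in de.groupby(["cultivar", "stage"])}
    edges = build_cis_trans(
        de_lnc, de_cod, matrix,
        {t.gene_id: t.interval for t in lnc_tx},
        {t.gene_id: t.interval for t in transcripts if t.class_code == "="},
        sequences={t.gene_id: tx_seqs[t.transcript_id] for t in transcripts},
    )
    edge_table(edges).to_csv(RESULTS / "targets.tsv", sep="\t", index=False)
    summary = summarize_edges(edges)
    (RESULTS / "targets_summary.json").write_text(json.dumps(summary, indent=1))
    n_cis = sum(e.mode == "cis" for e in edges)
    n_trans = len(edges) - n_cis
    print(f"edges: {n_cis} cis, {n_trans} trans "
          f"({len({e.lncrna_id for e in edges})} lncRNAs, "
          f"{len({e.gene_id for e in edges})} coding targets)")
    print(f"cis distance density mode: {summary['cis_distance_mode_kb']} kb bin")


if __name__ == "__main__":
    main()
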