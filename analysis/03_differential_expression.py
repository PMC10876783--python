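#!/usr/bin/env python
"""Heat-vs-control differential expression for every cultivar and stage.

TMM normalization, CPM >= 1 filtering and the NOISeq-style dominance test
(|log2FC| > 0.5 for lncRNAs, > 1 for coding genes, empirical FDR <= 0.05);
writes results/de_results.tsv and results/de_summary.json and prints the
up/down table.
"""

import json
from pathlib import Path

from pollen_lncrna.expression import (
    ExpressionMatrix,
    aggregate_to_locus,
    cpm_filter,
    de_table,
    noiseq_de,
    summarize_de,
    tmm_factors,
)
from pollen_lncrna.formats import read_counts, read_design, read_gtf

RESULTS = Path(__file__).resolve().parent.parent / "results"
CORPUS = RESULTS / "corpus"


def main() -> None:
    transcripts = read_gtf(CORPUS / "annotation.gtf")
    lnc_ids = {t.gene_id for t in read_gtf(RESULTS / "lncrnas.gtf")}
    matrix = ExpressionMatrix(
        aggregate_to_locus(
            read_counts(CORPUS / "counts.tsv"),
            {t.transcript_id: t.gene_id for t in transcripts},
        ),
        read_design(CORPUS / "design.tsv"),
    )
    matrix.tmm = tmm_factors(matrix.counts)
    matrix = cpm_filter(matrix)
    biotypes = {g: ("lncRNA" if g in lnc_ids else "coding")
                for g in matrix.counts.index}
    results = []
    for cultivar, stage in sorted(
        set(zip(matrix.design["cultivar"], matrix.design["stage"]))
    ):
        results.extend(noiseq_de(matrix, cultivar, stage, biotypes=biotypes))
    de_table(results).to_csv(RESULTS / "de_results.tsv", sep="\t", index=False)
    summary = summarize_de(results, matrix)
    (RESULTS / "de_summary.json").write_text(json.dumps(
        {
            "updown": {f"{c}/{s}": row.to_dict()
                       for (c, s), row in summary["updown_counts"].iterrows()},
            "cultivar_overlap": summary["cultivar_overlap"],
            "stage_concordant": summary["stage_concordant"],
            "top_variance_genes": summary["top_variance_genes"][:50],
        }, indent=1))
    n_de = sum(r.direction != "ns" for r in results)
    n_lnc = sum(r.direction != "ns" and r.biotype == "lncRNA" for r in results)
    print(f"genes tested: {matrix.counts.shape[0]}; DE calls: {n_de} "
          f"({n_lnc} lncRNA)")
    print(summary["updown_counts"].to_string())
    print(f"genes concordant across stages: {summary['stage_concordant']}")


if __name__ == "__main__":
    main()
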