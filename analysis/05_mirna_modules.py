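#!/usr/bin/env python
"""Assemble lncRNA-miRNA-mRNA regulatory modules.

Plant-rule target scoring (penalty <= 4, doubled in miRNA positions 2-13)
of wheat miRNAs against the DE lncRNAs and DE mRNAs, then sponge vs
precursor classification from the expression trends.  Writes
results/modules.tsv and results/modules_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

from pollen_lncrna.expression import DEResult
from pollen_lncrna.formats import read_fasta, read_gtf
from pollen_lncrna.mirna import (
    classify_modules, module_summary, module_table, scan_targets,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
CORPUS = RESULTS / "corpus"


def main() -> None:
    transcripts = read_gtf(CORPUS / "annotation.gtf")
    tx_of = {t.gene_id: t.transcript_id for t in transcripts}
    tx_seqs = read_fasta(CORPUS / "transcripts.fa")
    mirnas = read_fasta(CORPUS / "mirnas.fa")
    lnc_ids = {t.gene_id for t in read_gtf(RESULTS / "lncrnas.gtf")}

    de = pd.read_csv(RESULTS / "de_results.tsv", sep="\t")
    de_results = [
        DEResult(r.gene_id, r.cultivar, r.stage, r.log2fc, r.de_probability,
                 r.fdr, r.direction, r.biotype)
        for r in de.itertuples()
    ]
    de_genes = set(de[de["direction"] != "ns"]["gene_id"])
    lnc_hits = scan_targets(
        mirnas, {g: tx_seqs[tx_of[g]] for g in de_genes & lnc_ids}, "lncRNA"
    )
    mrna_hits = scan_targets(
        mirnas, {g: tx_seqs[tx_of[g]] for g in de_genes - lnc_ids
                 if not g.startswith("MSTRG")}, "mRNA"
    )
    modules = classify_modules(lnc_hits, mrna_hits, de_results)
    module_table(modules).to_csv(RESULTS / "modules.tsv", sep="\t", index=False)
    summary = module_summary(modules)
    (RESULTS / "modules_summary.json").write_text(json.dumps(summary, indent=1))
    for role in ("sponge", "precursor"):
        c = summary["counts"][role]
        print(f"{role}: {c['modules']} modules "
              f"({c['lncrnas']} lncRNAs, {c['mirnas']} miRNAs, {c['mrnas']} mRNAs)")
    print(f"modules shared by >= 2 cultivars: {len(summary['shared_modules'])}")


if __name__ == "__main__":
    main()
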