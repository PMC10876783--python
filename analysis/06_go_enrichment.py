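#!/usr/bin/env python
"""GO enrichment of the lncRNA target genes.

Classic one-sided Fisher tests over the expressed-gene population with
true-path annotation propagation, and a depth-2 parent-term rollup of the
significant terms.  Writes results/enrichment.tsv.
"""

from pathlib import Path

import pandas as pd

from pollen_lncrna.enrichment import (
    enrichment_table, fisher_enrich, propagate_annotations, rollup_terms,
)
from pollen_lncrna.formats import read_gtf, read_obo

RESULTS = Path(__file__).resolve().parent.parent / "results"
CORPUS = RESULTS / "corpus"


def main() -> None:
    annotations_df = pd.read_csv(CORPUS / "go_annotations.tsv", sep="\t")
    annotations = {g: list(sub["term_id"])
                   for g, sub in annotations_df.groupby("gene_id")}
    dag = read_obo(CORPUS / "ontology.obo")
    closure = propagate_annotations(annotations, dag)
    population = {t.gene_id for t in read_gtf(CORPUS / "annotation.gtf")
                  if t.class_code == "="}

    targets = pd.read_csv(RESULTS / "targets.tsv", sep="\t")
    modules = pd.read_csv(RESULTS / "modules.tsv", sep="\t")
    study = (set(targets["gene_id"]) | set(modules.get("mrna_id", []))) & population

    rows = rollup_terms(fisher_enrich(study, population, closure, dag), dag,
                        max_depth=2)
    enrichment_table(rows).to_csv(RESULTS / "enrichment.tsv", sep="\t",
                                  index=False)
    significant = [r for r in rows if r.significant]
    print(f"study genes: {len(study)}; terms tested: {len(rows)}; "
          f"significant: {len(significant)}")
    for r in sorted(significant, key=lambda r: r.p_fisher)[:5]:
        print(f"  {r.term_id}  {r.name:35s} p={r.p_fisher:.2e} "
              f"({r.study_count}/{r.population_count}) -> {r.parent_term}")


if __name__ == "__main__":
    main()
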