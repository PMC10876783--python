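#!/usr/bin/env python
"""Conservation of the discovered lncRNAs and a homolog phylogeny.

Seed-and-extend homology of every retained lncRNA against 13 plant species
(E < 1e-5, identity >= 60%, coverage >= 30% of the shorter sequence),
A/B/D sub-genome overlap, and a 1000-replicate bootstrap neighbor-joining
tree for the most broadly conserved lncRNA.  Writes results/conservation.tsv,
results/conservation_summary.json and results/tree.nwk.
"""

import json
from pathlib import Path

import pandas as pd

from pollen_lncrna.conservation import (
    call_conservation, homology_search, subgenome_conservation,
)
from pollen_lncrna.formats import read_fasta, read_gtf, write_newick
from pollen_lncrna.phylo import nj_tree

RESULTS = Path(__file__).resolve().parent.parent / "results"
CORPUS = RESULTS / "corpus"


def main(seed: int = 1, bootstrap: int = 1000) -> None:
    lnc_tx = read_gtf(RESULTS / "lncrnas.gtf")
    lnc_seqs = {
        t.gene_id: seq for t, seq in (
            (t, read_fasta(RESULTS / "lncrnas.fa").get(t.transcript_id))
            for t in lnc_tx
        ) if seq
    }
    species_seqs = {
        fa.stem: read_fasta(fa) for fa in sorted((CORPUS / "species").glob("*.fa"))
    }
    hits_by_species = {sp: homology_search(lnc_seqs, subjects)
                       for sp, subjects in species_seqs.items()}
    calls, summary = call_conservation(
        hits_by_species, {k: len(v) for k, v in lnc_seqs.items()},
        {sp: {k: len(v) for k, v in seqs.items()}
         for sp, seqs in species_seqs.items()},
    )
    pd.DataFrame(
        [{"lncrna_id": c.lncrna_id, "species": c.species,
          "identity": round(c.identity, 2),
          "coverage": round(c.coverage_of_shorter, 3),
          "evalue": c.best_hit.evalue, "conserved": c.conserved}
         for c in calls]
    ).to_csv(RESULTS / "conservation.tsv", sep="\t", index=False)

    sub = subgenome_conservation({t.gene_id: t.interval for t in lnc_tx},
                                 lnc_seqs)
    (RESULTS / "conservation_summary.json").write_text(json.dumps(
        {"species": summary,
         "subgenomes": {k: v for k, v in sub.items() if k != "per_locus"}},
        indent=1))
    print(f"loci conserved in >= 1 species: {summary['conserved_any']} "
          f"(>= 2: {summary['conserved_ge2']}, > 9: {summary['conserved_gt9']})")
    print("per species:", dict(sorted(summary["per_species"].items(),
                                      key=lambda kv: -kv[1])[:5]), "...")
    print(f"sub-genome overlap: >= 2 sub-genomes {sub['loci_shared_ge2']}, "
          f"all three {sub['loci_shared_all3']}")

    per_lnc: dict[str, list] = {}
    for c in calls:
        if c.conserved:
            per_lnc.setdefault(c.lncrna_id, []).append(
                (c.species, c.best_hit.subject_id))
    if per_lnc:
        top = max(per_lnc, key=lambda k: len(per_lnc[k]))
        homologs = {top: lnc_seqs[top]}
        homologs.update({sid: species_seqs[sp][sid] for sp, sid in per_lnc[top]})
        tree = nj_tree(top, homologs, bootstrap=bootstrap, seed=seed)
        write_newick(tree, RESULTS / "tree.nwk")
        supports = sorted(tree.supports.values(), reverse=True)
        print(f"phylogeny exemplar {top}: {len(homologs)} leaves, "
              f"top bootstrap supports {supports[:3]}")


if __name__ == "__main__":
    main()
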