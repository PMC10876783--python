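"""End-to-end orchestration of the analysis stages.

Stages run in a fixed order — discover, de, targets, mirna, enrich,
conserve — each reading and writing plain files in the run directory so any
stage can be re-run on its own; a manifest records the seed, every
threshold, and per-stage record counts.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .conservation import (
    call_conservation,
    homology_search,
    subgenome_conservation,
)
from .coexpression import build_cis_trans, edge_table, summarize_edges
from .discovery import fit_coding_model, run_discovery
from .enrichment import (
    enrichment_table,
    fisher_enrich,
    propagate_annotations,
    rollup_terms,
)
from .expression import (
    ExpressionMatrix,
    aggregate_to_locus,
    cpm_filter,
    de_table,
    noiseq_de,
    summarize_de,
    tmm_factors,
)
from .formats import (
    read_counts,
    read_design,
    read_fasta,
    read_gtf,
    read_obo,
    write_fasta,
    write_gtf,
    write_newick,
    write_tsv,
)
from .mirna import classify_modules, module_summary, module_table, scan_targets
from .phylo import nj_tree


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a pipeline run (defaults = study values)."""

    gtf: str = "annotation.gtf"
    transcripts_fasta: str = "transcripts.fa"
    counts: str = "counts.tsv"
    design: str = "design.tsv"
    mirna_fasta: str = "mirnas.fa"
    protein_db: str = "proteins.fa"
    training_noncoding: str = "training_noncoding.fa"
    go_annotations: str = "go_annotations.tsv"
    obo: str = "ontology.obo"
    species_dir: str = "species"

    min_len: int = 200
    cutoff: float | str = 0.365     # CPAT-style probability cutoff, or "auto"
    min_cpm: float = 1.0
    lnc_lfc: float = 0.5
    coding_lfc: float = 1.0
    fdr: float = 0.05
    k: int = 10
    alpha: float = 0.05
    ndg: float = -0.15
    mirna_max_score: float = 4.0
    evalue: float = 1e-5
    min_ident: float = 60.0
    min_cov: float = 0.30
    bootstrap: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_all(config: PipelineConfig, indir: str | Path, outdir: str | Path) -> Path:
    """Run every stage on the inputs under ``indir``; returns the run directory."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: v for k, v in asdict(config).items()
            if isinstance(v, (int, float)) or k == "cutoff"
        },
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    required = [config.gtf, config.transcripts_fasta, config.counts, config.design]
    missing = [p for p in required if not (indir / p).exists()]
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")

    # ---- discover ------------------------------------------------------
    try:
        transcripts = read_gtf(indir / config.gtf)
        tx_seqs = read_fasta(indir / config.transcripts_fasta)
        coding_train = [
            tx_seqs[t.transcript_id] for t in transcripts
            if t.class_code == "=" and t.transcript_id in tx_seqs
        ]
        noncoding_train = list(
            read_fasta(indir / config.training_noncoding).values()
        )
        model = fit_coding_model(
            coding_train, noncoding_train,
            fixed_cutoff=None if config.cutoff == "auto" else float(config.cutoff),
        )
        protein_db = (
            read_fasta(indir / config.protein_db)
            if (indir / config.protein_db).exists() else None
        )
        discovery = run_discovery(
            transcripts, tx_seqs, model, protein_db, min_len=config.min_len
        )
        lnc_ids = {t.gene_id for t in discovery.retained}
        write_gtf(discovery.retained, outdir / "lncrnas.gtf")
        write_fasta(
            {t.transcript_id: tx_seqs[t.transcript_id] for t in discovery.retained},
            outdir / "lncrnas.fa",
        )
        report = pd.DataFrame(
            [
                {
                    "transcript_id": r.transcript_id, "orf_length": r.orf_length,
                    "orf_coverage": r.orf_coverage, "fickett": r.fickett_score,
                    "hexamer": r.hexamer_score,
                    "coding_probability": r.logistic_probability,
                    "consensus": r.consensus,
                }
                for r in discovery.reports.values()
            ]
        )
        write_tsv(report, outdir / "discovery_report.tsv", index=False)
        (outdir / "discovery_venn.json").write_text(json.dumps(
            {"venn": discovery.venn_counts, "drops": discovery.drop_counts,
             "cutoff": model.cutoff}, indent=1))
        manifest["stages"]["discover"] = {
            "input_transcripts": len(transcripts),
            "retained_lncrnas": len(discovery.retained),
            "vetoed": len(discovery.vetoed),
        }
    except Exception as exc:
        raise StageError("discover", exc) from exc

    # ---- de ------------------------------------------------------------
    try:
        counts = read_counts(indir / config.counts)
        design = read_design(indir / config.design)
        tx_to_gene = {t.transcript_id: t.gene_id for t in transcripts}
        gene_counts = aggregate_to_locus(counts, tx_to_gene)
        matrix = ExpressionMatrix(gene_counts, design)
        matrix.tmm = tmm_factors(matrix.counts)
        matrix = cpm_filter(matrix, min_cpm=config.min_cpm)
        biotypes = {
            g: ("lncRNA" if g in lnc_ids else "coding") for g in matrix.counts.index
        }
        contrasts = sorted(
            set(zip(design["cultivar"], design["stage"]))
        )
        results = []
        for cultivar, stage in contrasts:
            results.extend(
                noiseq_de(
                    matrix, cultivar, stage, biotypes=biotypes,
                    lnc_lfc=config.lnc_lfc, coding_lfc=config.coding_lfc,
                    fdr_threshold=config.fdr,
                )
            )
        de_df = de_table(results)
        write_tsv(de_df, outdir / "de_results.tsv", index=False)
        summary = summarize_de(results, matrix)
        (outdir / "de_summary.json").write_text(json.dumps(
            {
                "updown": {
                    f"{c}/{s}": row.to_dict()
                    for (c, s), row in summary["updown_counts"].iterrows()
                } if len(summary["updown_counts"]) else {},
                "cultivar_overlap": summary["cultivar_overlap"],
                "stage_concordant": summary["stage_concordant"],
                "top_variance_genes": summary["top_variance_genes"][:50],
            }, indent=1))
        manifest["stages"]["de"] = {
            "genes_tested": int(matrix.counts.shape[0]),
            "contrasts": len(contrasts),
            "de_calls": int((de_df["direction"] != "ns").sum()),
        }
    except Exception as exc:
        raise StageError("de", exc) from exc

    # ---- targets (cis/trans) -------------------------------------------
    try:
        de_calls = de_df[de_df["direction"] != "ns"]
        de_lnc = {
            (c, s): set(sub[sub["biotype"] == "lncRNA"]["gene_id"])
            for (c, s), sub in de_calls.groupby(["cultivar", "stage"])
        }
        de_cod = {
            (c, s): set(sub[sub["biotype"] == "coding"]["gene_id"])
            for (c, s), sub in de_calls.groupby(["cultivar", "stage"])
        }
        lnc_loci = {t.gene_id: t.interval for t in discovery.retained}
        gene_loci = {
            t.gene_id: t.interval for t in transcripts if t.class_code == "="
        }
        gene_seqs = {t.gene_id: tx_seqs[t.transcript_id] for t in transcripts
                     if t.transcript_id in tx_seqs}
        edges = build_cis_trans(
            de_lnc, de_cod, matrix, lnc_loci, gene_loci, sequences=gene_seqs,
            k=config.k, alpha=config.alpha, ndg_cutoff=config.ndg,
        )
        write_tsv(edge_table(edges), outdir / "targets.tsv", index=False)
        (outdir / "targets_summary.json").write_text(
            json.dumps(summarize_edges(edges), indent=1))
        manifest["stages"]["targets"] = {
            "edges": len(edges),
            "cis": sum(1 for e in edges if e.mode == "cis"),
            "trans": sum(1 for e in edges if e.mode == "trans"),
        }
    except Exception as exc:
        raise StageError("targets", exc) from exc

    # ---- mirna ---------------------------------------------------------
    try:
        mirnas = read_fasta(indir / config.mirna_fasta)
        de_genes_all = set(de_calls["gene_id"])
        lnc_seq_by_gene = {
            t.gene_id: tx_seqs[t.transcript_id] for t in discovery.retained
            if t.gene_id in de_genes_all
        }
        mrna_seq_by_gene = {
            g: s for g, s in gene_seqs.items()
            if g in de_genes_all and g not in lnc_ids
        }
        lnc_hits = scan_targets(mirnas, lnc_seq_by_gene, "lncRNA",
                                max_score=config.mirna_max_score)
        mrna_hits = scan_targets(mirnas, mrna_seq_by_gene, "mRNA",
                                 max_score=config.mirna_max_score)
        modules = classify_modules(lnc_hits, mrna_hits, results)
        write_tsv(module_table(modules), outdir / "modules.tsv", index=False)
        (outdir / "modules_summary.json").write_text(
            json.dumps(module_summary(modules), indent=1))
        manifest["stages"]["mirna"] = {
            "lnc_hits": len(lnc_hits), "mrna_hits": len(mrna_hits),
            "modules": len(modules),
        }
    except Exception as exc:
        raise StageError("mirna", exc) from exc

    # ---- enrich --------------------------------------------------------
    try:
        annotations_df = pd.read_csv(indir / config.go_annotations, sep="\t")
        annotations = {
            g: list(sub["term_id"]) for g, sub in annotations_df.groupby("gene_id")
        }
        dag = read_obo(indir / config.obo)
        closure = propagate_annotations(annotations, dag)
        population = {g for g in matrix.counts.index if g not in lnc_ids}
        target_genes = {e.gene_id for e in edges} | {m.mrna_id for m in modules}
        study = target_genes & population
        rows = rollup_terms(
            fisher_enrich(study, population, closure, dag, alpha=config.alpha),
            dag,
        )
        write_tsv(enrichment_table(rows), outdir / "enrichment.tsv", index=False)
        manifest["stages"]["enrich"] = {
            "study_genes": len(study),
            "terms_tested": len(rows),
            "significant": sum(1 for r in rows if r.significant),
        }
    except Exception as exc:
        raise StageError("enrich", exc) from exc

    # ---- conserve ------------------------------------------------------
    try:
        lnc_seqs_all = {t.gene_id: tx_seqs[t.transcript_id]
                        for t in discovery.retained}
        species_dir = indir / config.species_dir
        hits_by_species = {}
        subject_lens: dict[str, dict[str, int]] = {}
        species_seqs: dict[str, dict[str, str]] = {}
        if species_dir.is_dir():
            for fa in sorted(species_dir.glob("*.fa")):
                sp = fa.stem
                subjects = read_fasta(fa)
                species_seqs[sp] = subjects
                subject_lens[sp] = {k: len(v) for k, v in subjects.items()}
                hits_by_species[sp] = homology_search(lnc_seqs_all, subjects)
        calls, cons_summary = call_conservation(
            hits_by_species, {k: len(v) for k, v in lnc_seqs_all.items()},
            subject_lens,
        )
        calls_df = pd.DataFrame(
            [
                {
                    "lncrna_id": c.lncrna_id, "species": c.species,
                    "identity": c.identity, "coverage": c.coverage_of_shorter,
                    "evalue": c.best_hit.evalue, "conserved": c.conserved,
                }
                for c in calls
            ]
        )
        write_tsv(calls_df, outdir / "conservation.tsv", index=False)
        sub = subgenome_conservation(lnc_loci, lnc_seqs_all)
        (outdir / "conservation_summary.json").write_text(json.dumps(
            {"species": cons_summary,
             "subgenomes": {k: v for k, v in sub.items() if k != "per_locus"}},
            indent=1))
        # phylogeny of the most broadly conserved lncRNA
        conserved_per_lnc: dict[str, list[tuple[str, str]]] = {}
        for c in calls:
            if c.conserved:
                conserved_per_lnc.setdefault(c.lncrna_id, []).append(
                    (c.species, c.best_hit.subject_id)
                )
        if conserved_per_lnc:
            top_lnc = max(conserved_per_lnc, key=lambda k: len(conserved_per_lnc[k]))
            homolog_seqs = {top_lnc: lnc_seqs_all[top_lnc]}
            for sp, sid in conserved_per_lnc[top_lnc]:
                homolog_seqs[sid] = species_seqs[sp][sid]
            if len(homolog_seqs) >= 3:
                tree = nj_tree(top_lnc, homolog_seqs,
                               bootstrap=config.bootstrap, seed=config.seed)
                write_newick(tree, outdir / "tree.nwk")
                manifest["stages"]["tree"] = {
                    "lncrna": top_lnc, "leaves": len(homolog_seqs),
                    "bootstrap": config.bootstrap,
                }
        manifest["stages"]["conserve"] = {
            "species": len(hits_by_species),
            "conserved_loci": cons_summary["conserved_any"],
            "subgenome_shared_ge2": sub["loci_shared_ge2"],
        }
    except Exception as exc:
        raise StageError("conserve", exc) from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
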