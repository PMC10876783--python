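"""Classic Fisher GO enrichment with true-path propagation and parent rollup.

Annotations are propagated to every ``is_a`` ancestor (the true-path rule),
each term with at least one study gene gets a one-sided Fisher exact test
(hypergeometric upper tail) against the expressed-gene population, and
significant terms are summarized to an ancestor at a bounded depth from the
namespace root — a lightweight stand-in for semantic-similarity reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class EnrichmentRow:
    term_id: str
    name: str
    study_count: int
    study_size: int
    population_count: int
    population_size: int
    p_fisher: float
    significant: bool
    parent_term: str | None = None


def propagate_annotations(
    annotations: Mapping[str, Iterable[str]], dag: nx.DiGraph
) -> dict[str, set[str]]:
    """Annotate each gene to every ancestor of its direct terms.

    ``dag`` carries ``is_a`` edges child -> parent; propagation is the
    transitive closure upward and is idempotent.
    """
    unknown = sorted(
        {t for terms in annotations.values() for t in terms} - set(dag.nodes)
    )
    if unknown:
        raise ValueError(f"terms absent from ontology: {unknown}")
    cache: dict[str, set[str]] = {}

    def ancestors(term: str) -> set[str]:
        if term not in cache:
            cache[term] = nx.descendants(dag, term)  # edges point rootward
        return cache[term]

    return {
        gene: set(terms) | set().union(*(ancestors(t) for t in terms))
        if terms else set()
        for gene, terms in ((g, set(ts)) for g, ts in annotations.items())
    }


def fisher_enrich(
    study: Iterable[str],
    population: Iterable[str],
    closure: Mapping[str, set[str]],
    dag: nx.DiGraph | None = None,
    alpha: float = ALPHA,
) -> list[EnrichmentRow]:
    """One-sided Fisher exact enrichment per term with >= 1 study gene."""
    study = set(study)
    population = set(population)
    if not study <= population:
        raise ValueError("study genes must be a subset of the population")
    if not study:
        return []
    pop_terms: dict[str, int] = {}
    study_terms: dict[str, int] = {}
    for gene in population:
        for term in closure.get(gene, ()):
            pop_terms[term] = pop_terms.get(term, 0) + 1
            if gene in study:
                study_terms[term] = study_terms.get(term, 0) + 1
    n_pop, n_study = len(population), len(study)
    rows = []
    for term, k in sorted(study_terms.items()):
        big_k = pop_terms[term]
        # upper tail: P(X >= k), X ~ Hypergeom(N=n_pop, K=big_k, n=n_study)
        p = float(stats.hypergeom.sf(k - 1, n_pop, big_k, n_study))
        name = dag.nodes[term].get("name", term) if dag is not None else term
        rows.append(
            EnrichmentRow(
                term_id=term, name=name, study_count=k, study_size=n_study,
                population_count=big_k, population_size=n_pop,
                p_fisher=p, significant=p < alpha,
            )
        )
    return rows


def term_depths(dag: nx.DiGraph) -> dict[str, int]:
    """Shortest-path depth of each term from its namespace root (depth 0)."""
    roots = [n for n in dag.nodes if dag.out_degree(n) == 0]
    depths: dict[str, int] = {}
    reversed_dag = dag.reverse(copy=False)
    for root in roots:
        for node, depth in nx.single_source_shortest_path_length(
            reversed_dag, root
        ).items():
            if node not in depths or depth < depths[node]:
                depths[node] = depth
    return depths


def rollup_terms(
    rows: list[EnrichmentRow], dag: nx.DiGraph, max_depth: int = 2
) -> list[EnrichmentRow]:
    """Map each significant term to its ancestor at depth <= ``max_depth``.

    Terms already at or above the bound map to themselves; otherwise the
    ancestor at depth exactly ``max_depth`` on a shortest root path is used
    (ties broken by smallest term id).
    """
    depths = term_depths(dag)
    for row in rows:
        if not row.significant:
            continue
        depth = depths.get(row.term_id, 0)
        if depth <= max_depth:
            row.parent_term = row.term_id
            continue
        candidates = [
            anc for anc in nx.descendants(dag, row.term_id)
            if depths.get(anc) == max_depth
        ]
        row.parent_term = min(candidates) if candidates else row.term_id
    return rows


def enrichment_table(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id, "name": r.name,
                "study_count": r.study_count, "study_size": r.study_size,
                "population_count": r.population_count,
                "population_size": r.population_size,
                "p_fisher": r.p_fisher, "significant": r.significant,
                "parent_term": r.parent_term,
            }
            for r in rows
        ]
    )
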