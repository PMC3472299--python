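"""GO-term over-representation with true-path annotation propagation.

Gene Ontology annotations obey the true-path rule: a gene annotated to
a term is implicitly annotated to every ancestor of that term.  The
enrichment procedure propagates direct annotations up the DAG, tests
each term carrying at least one study gene with a one-sided Fisher's
exact test against the annotated population, and controls the FDR at
q < 0.05 by Benjamini-Hochberg.  Related enriched terms are summarized
as a network: the transitive reduction of the ancestor relation
restricted to the enriched terms.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .de import bh_adjust
from .motif import ContingencyTable, fisher_exact_one_sided

__all__ = [
    "validate_go_graph",
    "go_root",
    "term_ancestors",
    "propagate_annotations",
    "term_enrichment",
    "enrichment_network",
]


def validate_go_graph(g: nx.DiGraph) -> str:
    """Check acyclicity and single-rootedness; return the root term.

    Edges point child -> parent (is_a and part_of merged), so the root
    is the unique node with no outgoing edge.
    """
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("GO graph contains a cycle")
    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    if len(roots) != 1:
        raise ValueError(f"GO graph must have exactly one root, found {roots}")
    return roots[0]


def term_ancestors(g: nx.DiGraph, term: str) -> set[str]:
    """All ancestors of a term (excluding itself), following child->parent edges."""
    return set(nx.descendants(g, term))


def propagate_annotations(
    g: nx.DiGraph, direct: dict[str, set[str]]
) -> dict[str, set[str]]:
    """Close gene annotations under the parent relation (true-path rule).

    propagated(gene) = direct(gene) plus every ancestor of each directly
    annotated term; the operation is idempotent.
    """
    unknown = sorted({t for ts in direct.values() for t in ts if t not in g})
    if unknown:
        raise ValueError(f"annotations to unknown terms: {unknown[:5]}")
    closure: dict[str, set[str]] = {}  # per-term closure, shared across genes
    propagated: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        out: set[str] = set()
        for t in terms:
            if t not in closure:
                closure[t] = {t} | term_ancestors(g, t)
            out |= closure[t]
        propagated[gene] = out
    return propagated


def term_enrichment(
    study: set[str],
    population: set[str],
    propagated: dict[str, set[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-term one-sided Fisher over-representation with BH FDR.

    The population is the annotated gene universe and must contain the
    study set.  Only terms with at least one study gene are tested (the
    multiple-testing universe excludes untestable terms).  Returns a
    DataFrame indexed by term with study/population counts, p, q and an
    ``enriched`` flag (q < fdr), sorted by p.
    """
    study = set(study)
    population = set(population)
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in population:
        for t in propagated.get(gene, ()):
            term_pop[t] = term_pop.get(t, 0) + 1
            if gene in study:
                term_study[t] = term_study.get(t, 0) + 1
    rows = []
    for t, k in sorted(term_study.items()):
        table = ContingencyTable(
            a=k,
            b=len(study) - k,
            c=term_pop[t] - k,
            d=len(population) - len(study) - (term_pop[t] - k),
        )
        p, odds = fisher_exact_one_sided(table)
        rows.append((t, k, term_pop[t], p, odds))
    out = pd.DataFrame(
        rows, columns=["term", "study_count", "pop_count", "p_value", "odds_ratio"]
    ).set_index("term")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    out["enriched"] = out["q_value"] < fdr
    return out.sort_values("p_value")


def enrichment_network(enriched: set[str], g: nx.DiGraph) -> list[tuple[str, str]]:
    """Edges among enriched terms: nearest enriched ancestors only.

    An edge (u, v) is drawn iff v is an ancestor of u and no other
    enriched term lies between them (i.e. is simultaneously an ancestor
    of u and a descendant of v) — the transitive reduction of the
    ancestor relation restricted to the enriched set.
    """
    enriched = set(enriched)
    missing = enriched - set(g.nodes)
    if missing:
        raise ValueError(f"enriched terms not in graph: {sorted(missing)[:5]}")
    anc = {t: term_ancestors(g, t) & enriched for t in enriched}
    edges = []
    for u in sorted(enriched):
        for v in sorted(anc[u]):
            if not any(v in anc[w] for w in anc[u] if w != v):
                edges.append((u, v))
    return edges
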