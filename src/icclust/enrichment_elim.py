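"""Ontology enrichment with the elim procedure.

Tests each ontology term for over-representation of a study gene set with
a one-sided Fisher's exact (hypergeometric) test, walking the DAG from the
deepest terms up to the root.  When a term comes out significant, its
study genes are eliminated from all of its ancestors before those are
tested, so enrichment signal is attributed to the most specific term that
carries it rather than echoed up the hierarchy.  Bonferroni adjustment
multiplies the raw p by the number of terms mapping at least one
annotated gene (after the minimum-node-size filter).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
from scipy import stats

from ._errors import ValidationError
from .expression_io import logger


@dataclass
class OntologyDAG:
    """An is_a hierarchy of terms: acyclic, possibly multi-parent."""

    terms: dict[str, str]            # id -> name
    parents: dict[str, set[str]]     # child -> direct parents

    def __post_init__(self) -> None:
        g = self._digraph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(f"ontology contains a cycle: {cycle}")

    def _digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        return g

    @property
    def roots(self) -> set[str]:
        return {t for t in self.terms if not self.parents.get(t)}

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` via is_a edges (term excluded)."""
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents.get(p, ()))
        return out

    def depths(self) -> dict[str, int]:
        """Depth of each term = longest is_a path from a root down to it."""
        g = self._digraph().reverse()  # root -> leaf direction
        depth = {t: 0 for t in self.terms}
        for t in nx.topological_sort(g):
            for child in g.successors(t):
                depth[child] = max(depth[child], depth[t] + 1)
        return depth


@dataclass
class AnnotationMap:
    """Gene-term annotations, direct and propagated to all ancestors."""

    direct: dict[str, set[str]]      # gene -> terms
    propagated: dict[str, set[str]]  # term -> genes (true-path closure)
    skipped: int = 0                 # annotations to unknown terms


@dataclass
class EnrichmentResult:
    term: str
    name: str
    annotated_universe: int
    annotated_study: int
    expected_study: float
    p_raw: float
    p_adjusted: float
    significant: bool
    eliminated_genes: int


def read_obo(path) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 file into an is_a DAG; obsolete terms are skipped."""
    graph = obonet.read_obo(path, ignore_obsolete=True)
    terms = {t: d.get("name", t) for t, d in graph.nodes(data=True)}
    parents: dict[str, set[str]] = {t: set() for t in terms}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    return OntologyDAG(terms, parents)


def propagate_annotations(
    dag: OntologyDAG, direct: Mapping[str, Iterable[str]]
) -> AnnotationMap:
    """Apply the true-path rule: a gene at a term counts at every ancestor.

    Annotations to terms absent from the DAG are skipped with a warning
    and counted in ``skipped``; a gene reachable by several paths is still
    counted once per term (set semantics).
    """
    clean: dict[str, set[str]] = {}
    skipped = 0
    for gene, ts in direct.items():
        kept = set()
        for t in ts:
            if t in dag.terms:
                kept.add(t)
            else:
                skipped += 1
        if kept:
            clean[gene] = kept
    if skipped:
        logger.warning("skipped %d annotation(s) to unknown terms", skipped)
    propagated: dict[str, set[str]] = {t: set() for t in dag.terms}
    anc_cache: dict[str, set[str]] = {}
    for gene, ts in clean.items():
        reach: set[str] = set()
        for t in ts:
            if t not in anc_cache:
                anc_cache[t] = dag.ancestors(t)
            reach.add(t)
            reach |= anc_cache[t]
        for t in reach:
            propagated[t].add(gene)
    return AnnotationMap(clean, propagated, skipped)


def fisher_exact_enrichment(
    study_hits: int, study_size: int, term_hits_universe: int, universe_size: int
) -> float:
    """One-sided over-representation p-value, P(X >= study_hits), hypergeometric.

    Drawing ``study_size`` genes from a universe of ``universe_size`` of
    which ``term_hits_universe`` carry the term.
    """
    if not (
        0 <= study_hits <= study_size <= universe_size
        and study_hits <= term_hits_universe <= universe_size
    ):
        raise ValidationError(
            f"inconsistent counts: {study_hits}/{study_size} study, "
            f"{term_hits_universe}/{universe_size} universe"
        )
    return float(
        stats.hypergeom.sf(study_hits - 1, universe_size, term_hits_universe, study_size)
    )


def elim_enrichment(
    dag: OntologyDAG,
    ann: AnnotationMap,
    study: Iterable[str],
    universe: Iterable[str],
    min_node_size: int = 20,
    node_cutoff: float = 0.01,
    report_alpha: float = 0.05,
    eliminate_on: str = "adjusted",
) -> list[EnrichmentResult]:
    """Leaf-to-root enrichment with elimination of already-explained genes.

    Terms annotating fewer than ``min_node_size`` universe genes are
    dropped before testing; the Bonferroni factor m is the number of terms
    that survive.  Terms are processed in decreasing depth (longest path
    from a root), lexicographic within a level.  A term whose p-value —
    adjusted, or raw when ``eliminate_on='raw'`` as in the original elim
    formulation — falls below ``node_cutoff`` has its propagated study
    genes removed from all ancestors before they are tested.  Universe
    genes without any annotation are excluded from the universe total.
    Results come back sorted by adjusted p.
    """
    study_set = set(study)
    universe_set = set(universe)
    if not study_set:
        raise ValidationError("empty study set")
    if not universe_set:
        raise ValidationError("empty universe")
    if not study_set <= universe_set:
        raise ValidationError("study set must be a subset of the universe")
    if eliminate_on not in ("adjusted", "raw"):
        raise ValidationError("eliminate_on must be 'adjusted' or 'raw'")

    annotated = {g for genes in ann.propagated.values() for g in genes}
    universe_ann = universe_set & annotated
    study_ann = study_set & universe_ann
    if not universe_ann:
        raise ValidationError("no universe gene carries any annotation")

    term_universe = {
        t: genes & universe_ann for t, genes in ann.propagated.items()
    }
    kept = [t for t, genes in term_universe.items() if len(genes) >= min_node_size]
    m = len(kept)
    if m == 0:
        return []

    depth = dag.depths()
    kept.sort(key=lambda t: (-depth[t], t))

    eliminated: dict[str, set[str]] = {t: set() for t in dag.terms}
    results: list[EnrichmentResult] = []
    n_univ = len(universe_ann)
    n_study = len(study_ann)
    for t in kept:
        pool = term_universe[t] - eliminated[t]
        hits = len(pool & study_ann)
        p_raw = fisher_exact_enrichment(hits, n_study, len(pool), n_univ)
        p_adj = min(1.0, p_raw * m)
        expected = n_study * len(pool) / n_univ
        results.append(
            EnrichmentResult(
                term=t,
                name=dag.terms[t],
                annotated_universe=len(pool),
                annotated_study=hits,
                expected_study=expected,
                p_raw=p_raw,
                p_adjusted=p_adj,
                significant=p_adj < report_alpha,
                eliminated_genes=len(eliminated[t]),
            )
        )
        p_check = p_adj if eliminate_on == "adjusted" else p_raw
        if p_check < node_cutoff:
            to_remove = ann.propagated[t] & study_ann
            for anc in dag.ancestors(t):
                eliminated[anc] |= to_remove
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term))
    return results


def category_mean_p(
    category_genes: Iterable[str],
    results: list[EnrichmentResult],
    ann: AnnotationMap,
) -> float:
    """Average enrichment signal over a gene category.

    Each gene is represented by its single best (minimum p) tested term;
    the category score is the arithmetic mean of those per-gene minima.
    Genes with no tested term are excluded with a warning.
    """
    p_by_term = {r.term: r.p_raw for r in results}
    minima = []
    dropped = []
    for gene in category_genes:
        # true-path semantics: a gene counts at its direct terms and all
        # their ancestors, so the minimum ranges over every tested term
        # that contains it
        ps = [
            p_by_term[t]
            for t, genes in ann.propagated.items()
            if gene in genes and t in p_by_term
        ]
        if ps:
            minima.append(min(ps))
        else:
            dropped.append(gene)
    if dropped:
        logger.warning("category genes with no tested term: %s", ", ".join(dropped[:10]))
    if not minima:
        raise ValidationError("no category gene has a tested term")
    return float(sum(minima) / len(minima))


def read_annotations(path) -> dict[str, set[str]]:
    """Read gene-term annotations: 2-column TSV (gene, term) or minimal GAF.

    GAF lines (detected by the ``!`` comment header or >= 15 columns) use
    column 2 for the gene and column 5 for the term.
    """
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 15:       # GAF
                gene, term = parts[1], parts[4]
            elif len(parts) >= 2:      # plain 2-column
                gene, term = parts[0], parts[1]
            else:
                raise ValidationError(f"unparseable annotation line: {line!r}")
            direct.setdefault(gene, set()).add(term)
    return direct
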