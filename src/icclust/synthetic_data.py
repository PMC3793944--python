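"""Synthetic expression matrices with a planted co-expression cluster.

Emulates the shape of the microarray datasets this method targets — a few
thousand genes over roughly 6-21 arrays — with a known ground truth: a
target gene, a planted block of genes strongly correlated (positively or
negatively) with it, and independent-noise background genes.  Each
planted gene mixes the target profile with a noise term that is itself
partly shared across the block, gene = s*(rho*target +
sqrt(1-rho^2)*(sqrt(w)*shared + sqrt(1-w)*own)) with w = rho/(1+rho), so
that the population correlation of every planted gene with the target
*and* of every planted pair equals rho in magnitude: the block is a bona
fide planted clique at any threshold below rho.  With fully independent
per-gene noise the pairwise level would only be rho^2 and the block
would fray at tight thresholds.  The construction stays exact and costs
O(genes x samples).  All randomness flows from numpy's PCG64
generator seeded explicitly, so identical seeds reproduce identical
matrices on any platform.

An ontology-fixture generator with a planted enriched term serves the
enrichment module the same way.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._errors import ValidationError
from .enrichment_elim import AnnotationMap, OntologyDAG, propagate_annotations
from .expression_io import ExpressionMatrix

TARGET_ID = "TARGET"


@dataclass
class SyntheticSpec:
    """Parameters of the planted-cluster generator.

    Defaults mirror the study conditions the method was designed around:
    ~2000 background genes measured over 12 arrays, a planted block of 10
    genes at |r| ~ 0.99 of which 30% are anticorrelated with the target.
    """

    n_genes: int = 2000
    n_samples: int = 12
    planted_size: int = 10
    planted_rho: float = 0.99
    frac_negative: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_size < 2:
            raise ValidationError("planted_size must be >= 2")
        if self.n_samples < 4:
            raise ValidationError("n_samples must be >= 4")
        if not 0 < self.planted_rho < 1:
            raise ValidationError("planted_rho must lie in (0, 1)")
        if not 0 <= self.frac_negative <= 1:
            raise ValidationError("frac_negative must lie in [0, 1]")
        if self.planted_size > self.n_genes:
            raise ValidationError("planted_size cannot exceed n_genes")


def generate_planted_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, dict[str, int], str]:
    """Generate a matrix with a planted target-conditioned cluster.

    Returns (matrix, truth, target_id) where truth maps each planted gene
    to its sign (+1 correlated, -1 anticorrelated with the target).  The
    target profile is i.i.d. standard normal; each planted gene mixes the
    target with block-shared and private noise so that both its
    correlation with the target and with every other planted gene equal
    rho in magnitude; background genes are pure noise.  Gene rows are
    shuffled deterministically by the seed so planted genes are not
    positionally identifiable.
    """
    rng = np.random.default_rng(spec.seed)
    t = rng.standard_normal(spec.n_samples)
    rho = spec.planted_rho
    k = spec.planted_size
    n_neg = int(round(spec.frac_negative * k))
    signs = np.array([-1] * n_neg + [1] * (k - n_neg))

    # w solves rho^2 + (1-rho^2)*w = rho: pairwise correlation equals rho
    w = rho / (1 + rho)
    shared = rng.standard_normal(spec.n_samples)
    noise = rng.standard_normal((k, spec.n_samples))
    planted = signs[:, None] * (
        rho * t
        + math.sqrt(1 - rho**2)
        * (math.sqrt(w) * shared + math.sqrt(1 - w) * noise)
    )
    background = spec.noise_sd * rng.standard_normal(
        (spec.n_genes, spec.n_samples)
    )

    values = np.vstack([t, planted, background])
    width = len(str(spec.n_genes + k))
    gene_ids = (
        [TARGET_ID]
        + [f"PLANT{i:0{width}d}" for i in range(1, k + 1)]
        + [f"BG{i:0{width}d}" for i in range(1, spec.n_genes + 1)]
    )
    truth = {f"PLANT{i:0{width}d}": int(signs[i - 1]) for i in range(1, k + 1)}

    perm = rng.permutation(len(gene_ids))
    gene_ids = [gene_ids[i] for i in perm]
    values = values[perm]
    sample_ids = [f"S{j:02d}" for j in range(1, spec.n_samples + 1)]
    return ExpressionMatrix(gene_ids, sample_ids, values), truth, TARGET_ID


@dataclass
class OntologyFixture:
    dag: OntologyDAG
    annotations: AnnotationMap
    study: set[str]
    universe: set[str]
    enriched_term: str


def generate_ontology_fixture(
    n_terms: int = 30,
    depth: int = 4,
    genes: int = 300,
    enriched_term_fraction: float = 0.8,
    seed: int = 0,
    study_size: int = 30,
    mean_terms_per_gene: float = 2.0,
) -> OntologyFixture:
    """Random single-root is_a DAG with one term over-represented in the study.

    Terms are arranged in ``depth`` levels below a root; each non-root term
    gets one or two parents from the level above.  Genes receive direct
    annotations to random terms.  The designated enriched term is a deep
    term with a healthy annotation count; ``enriched_term_fraction`` of the
    study set is drawn from its annotated genes, the rest uniformly — set
    the fraction to the background rate to simulate the null.
    """
    if depth < 2:
        raise ValidationError("depth must be >= 2")
    if n_terms < depth:
        raise ValidationError("need at least one term per level")
    if study_size > genes:
        raise ValidationError("study_size cannot exceed the universe")
    rng = np.random.default_rng(seed)

    root = "T:ROOT"
    levels: list[list[str]] = [[root]]
    remaining = n_terms - 1
    per_level = max(1, remaining // depth)
    terms = {root: "root"}
    parents: dict[str, set[str]] = {root: set()}
    count = 0
    for lvl in range(1, depth + 1):
        size = remaining - count if lvl == depth else min(per_level, remaining - count)
        if size <= 0:
            break
        level_terms = []
        for _ in range(size):
            count += 1
            tid = f"T:{count:04d}"
            terms[tid] = f"term {count}"
            n_par = 1 + int(rng.random() < 0.3 and len(levels[-1]) > 1)
            parents[tid] = set(
                rng.choice(levels[-1], size=min(n_par, len(levels[-1])), replace=False)
            )
            level_terms.append(tid)
        levels.append(level_terms)

    gene_ids = [f"G{i:04d}" for i in range(1, genes + 1)]
    non_root = [t for t in terms if t != root]
    direct: dict[str, set[str]] = {}
    for g in gene_ids:
        k = max(1, rng.poisson(mean_terms_per_gene))
        direct[g] = set(rng.choice(non_root, size=min(k, len(non_root)), replace=False))

    # pick the deepest term with the most direct annotations as ground truth
    deep_terms = levels[-1]
    counts = {t: sum(t in ts for ts in direct.values()) for t in deep_terms}
    enriched = max(counts, key=lambda t: (counts[t], t))
    carriers = [g for g, ts in direct.items() if enriched in ts]
    if not carriers:
        raise ValidationError("no gene annotated to the designated term")

    n_from_term = min(len(carriers), int(round(enriched_term_fraction * study_size)))
    study = set(rng.choice(carriers, size=n_from_term, replace=False))
    others = [g for g in gene_ids if g not in study]
    fill = study_size - len(study)
    if fill > 0:
        study |= set(rng.choice(others, size=fill, replace=False))

    dag = OntologyDAG(terms, parents)
    ann = propagate_annotations(dag, direct)
    return OntologyFixture(dag, ann, study, set(gene_ids), enriched)
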