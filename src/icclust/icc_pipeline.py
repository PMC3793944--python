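"""End-to-end interconnected correlation clustering.

Orchestrates the four steps — target-conditioned correlation, threshold
selection, graph construction, largest-clique search — plus the
threshold-robustness overlap check and per-gene regulation-direction
annotation.  The pipeline itself is deterministic: all randomness lives in
the synthetic-data generator.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import pandas as pd

from . import __version__
from ._errors import PipelineError, ValidationError
from .clique_graph import ICGC, CoexpressionGraph, build_graph, largest_icgc
from .correlation_stats import (
    CorrelationProfile,
    ZDiagnostics,
    pearson_profile,
    select_genes,
    z_diagnostics,
)
from .expression_io import ExpressionMatrix

OverlapMethod = Literal["jaccard", "min_set", "reference_a"]


@dataclass
class ICCResult:
    """Everything produced by one pipeline run.

    ``run_config`` records every parameter used, which together with the
    input matrix suffices to reproduce the result bit-for-bit.
    """

    icgc: ICGC
    profile: CorrelationProfile
    diagnostics: ZDiagnostics
    graph: CoexpressionGraph
    selected: dict[str, int]
    threshold: float
    run_config: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _matrix_digest(m: ExpressionMatrix) -> str:
    h = hashlib.sha256()
    h.update("\t".join(m.gene_ids).encode())
    h.update("\t".join(m.sample_ids).encode())
    h.update(m.values.tobytes())
    return h.hexdigest()


def run_icc(
    m: ExpressionMatrix,
    target: str,
    threshold: float = 0.95,
    alpha: float = 0.10,
    max_cliques: int = 10**6,
) -> ICCResult:
    """Run the full pipeline and return all intermediate artifacts.

    ``threshold`` is the |r| cut for both the target-selection and the
    pairwise edge rule; ``alpha`` is the two-tailed level at which the
    empirical critical z-scores are reported.  Errors from component
    stages are wrapped with the stage name.
    """
    try:
        profile = pearson_profile(m, target)
    except ValidationError as e:
        raise PipelineError("pearson_profile", e) from e
    try:
        diagnostics = z_diagnostics(profile.z, alpha=alpha)
    except ValidationError as e:
        raise PipelineError("z_diagnostics", e) from e
    try:
        selected = select_genes(profile, threshold)
    except ValidationError as e:
        raise PipelineError("select_genes", e) from e
    try:
        if selected:
            graph = build_graph(m, selected, threshold)
            graph.target_gene = target
        else:
            import networkx as nx

            graph = CoexpressionGraph(nx.Graph(), threshold, target)
        icgc = largest_icgc(graph, profile, max_cliques=max_cliques)
    except ValidationError as e:
        raise PipelineError("clique_search", e) from e
    return ICCResult(
        icgc=icgc,
        profile=profile,
        diagnostics=diagnostics,
        graph=graph,
        selected=selected,
        threshold=threshold,
        run_config={
            "target": target,
            "threshold": threshold,
            "alpha": alpha,
            "max_cliques": max_cliques,
        },
        provenance={"matrix_sha256": _matrix_digest(m), "version": __version__},
    )


def icgc_overlap(a, b, method: OverlapMethod = "jaccard") -> float:
    """Percent overlap between two gene sets.

    jaccard = 100*|a&b|/|a|b|; min_set = 100*|a&b|/min(|a|,|b|);
    reference_a = 100*|a&b|/|a|.  The first two are symmetric.
    """
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValidationError("overlap requires two nonempty sets")
    inter = len(sa & sb)
    if method == "jaccard":
        return 100.0 * inter / len(sa | sb)
    if method == "min_set":
        return 100.0 * inter / min(len(sa), len(sb))
    if method == "reference_a":
        return 100.0 * inter / len(sa)
    raise ValidationError(f"unknown overlap method {method!r}")


def threshold_sweep(
    m: ExpressionMatrix,
    target: str,
    thresholds: Sequence[float],
    overlap_method: OverlapMethod = "jaccard",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[float, ICCResult]]:
    """Run the pipeline at each threshold and cross-tabulate ICGC overlaps.

    Returns (per-threshold summary, pairwise overlap table, results by
    threshold).  Judging how much the cluster composition moves between
    thresholds is the recommended robustness check before settling on one.
    """
    results: dict[float, ICCResult] = {}
    rows = []
    for t in thresholds:
        res = run_icc(m, target, threshold=t)
        results[t] = res
        rows.append(
            {
                "threshold": t,
                "n_selected": len(res.selected),
                "icgc_size": res.icgc.size,
                "mean_abs_r": res.icgc.mean_abs_r,
            }
        )
    overlaps = []
    for t1, t2 in combinations(sorted(results), 2):
        a = set(results[t1].icgc.members)
        b = set(results[t2].icgc.members)
        overlaps.append(
            {
                "threshold_a": t1,
                "threshold_b": t2,
                "method": overlap_method,
                "overlap_pct": icgc_overlap(a, b, overlap_method),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(overlaps), results


def annotate_direction(
    res: ICCResult, mode: Literal["correlation_sign", "time_contrast"] = "correlation_sign"
) -> pd.DataFrame:
    """Tag each cluster member as up- or down-regulated relative to the target.

    The default uses the sign of the gene's correlation with the target
    (positive r = co-regulated upward at the end of the course, since the
    target itself rises late).  ``time_contrast`` instead compares mean
    expression at the last versus first time label in sample_meta.
    """
    if not res.icgc.members:
        raise ValidationError("empty cluster")
    rows = []
    for gene in res.icgc.members:
        if gene == res.icgc.target_gene:
            rows.append({"gene_id": gene, "r": 1.0, "direction": "up"})
            continue
        r = res.profile.r_of(gene)
        rows.append({"gene_id": gene, "r": r, "direction": "up" if r > 0 else "down"})
    if mode == "correlation_sign":
        return pd.DataFrame(rows)
    raise ValidationError(
        "time_contrast mode requires calling annotate_direction_time with the matrix"
    )


def annotate_direction_time(
    res: ICCResult, m: ExpressionMatrix, time_key: str = "time"
) -> pd.DataFrame:
    """Direction from the last-versus-first time-point contrast.

    Requires sample_meta with a sortable time label on every sample.
    """
    if not m.sample_meta:
        raise ValidationError("time-contrast direction requires sample_meta")
    times = {}
    for s in m.sample_ids:
        meta = m.sample_meta.get(s, {})
        if time_key not in meta:
            raise ValidationError(f"sample {s!r} lacks a {time_key!r} label")
        times.setdefault(str(meta[time_key]), []).append(m.sample_ids.index(s))
    ordered = sorted(times)
    first, last = times[ordered[0]], times[ordered[-1]]
    rows = []
    for gene in res.icgc.members:
        row = m.row(gene)
        delta = row[last].mean() - row[first].mean()
        rows.append(
            {"gene_id": gene, "delta": float(delta), "direction": "up" if delta > 0 else "down"}
        )
    return pd.DataFrame(rows)
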