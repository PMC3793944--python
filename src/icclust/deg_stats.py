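"""Differential expression between two sample groups by Welch's t-test.

One two-sided unequal-variance t-test per gene, thresholded on the raw
p-value.  No multiple-testing correction is applied to the reported DEG
counts — the procedure deliberately thresholds raw p at alpha — but a
Benjamini-Hochberg column is emitted alongside for modern use.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .expression_io import ExpressionMatrix


@dataclass
class DEGRecord:
    gene_id: str
    mean_a: float
    mean_b: float
    t_stat: float
    df: float
    p_two_sided: float
    direction: str  # up_in_b | down_in_b

    def __post_init__(self) -> None:
        if not 0 <= self.p_two_sided <= 1:
            raise ValidationError("p-value outside [0, 1]")


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic, Satterthwaite df, two-sided p.

    t = (mean_b - mean_a) / sqrt(s_a^2/n_a + s_b^2/n_b), so a positive t
    means the second group is higher.  Both groups constant and equal is
    the defined limit t = 0, p = 1; constant groups with unequal means
    leave the statistic undefined and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    ma, mb = a.mean(), b.mean()
    if va == 0 and vb == 0:
        if ma == mb:
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValidationError("zero variance in both groups with unequal means")
    se2 = va / a.size + vb / b.size
    t = (mb - ma) / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _welch_matrix(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch test, one row per gene."""
    na, nb = xa.shape[1], xb.shape[1]
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    ma = xa.mean(axis=1)
    mb = xb.mean(axis=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    both_const = se2 == 0
    equal = both_const & (ma == mb)
    t[equal] = 0.0
    df[equal] = na + nb - 2
    bad = both_const & (ma != mb)
    if bad.any():
        raise ValidationError(
            f"{bad.sum()} gene(s) constant in both groups with unequal means"
        )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p


def identify_degs(
    m: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
) -> tuple[list[DEGRecord], dict[str, int], pd.DataFrame]:
    """Per-gene Welch tests between two disjoint sample groups.

    Returns the records passing p < alpha, summary counts
    (total = up + down, directions relative to group_b), and the full
    per-gene table including a BH-adjusted column (informational only —
    the counts follow the raw-p threshold).
    """
    ga, gb = list(group_a), list(group_b)
    if set(ga) & set(gb):
        raise ValidationError("sample groups overlap")
    if len(ga) < 2 or len(gb) < 2:
        raise ValidationError("each group needs at least 2 samples")
    for s in ga + gb:
        if s not in m.sample_ids:
            raise ValidationError(f"sample {s!r} not in matrix")
    ia = [m.sample_ids.index(s) for s in ga]
    ib = [m.sample_ids.index(s) for s in gb]
    t, df, p = _welch_matrix(m.values[:, ia], m.values[:, ib])
    ma = m.values[:, ia].mean(axis=1)
    mb = m.values[:, ib].mean(axis=1)

    order = np.argsort(p, kind="stable")
    ranked = np.empty_like(order)
    ranked[order] = np.arange(1, p.size + 1)
    bh = np.minimum.accumulate((p[order] * p.size / np.arange(1, p.size + 1))[::-1])[::-1]
    p_bh = np.empty_like(p)
    p_bh[order] = np.minimum(bh, 1.0)

    table = pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "mean_a": ma,
            "mean_b": mb,
            "t_stat": t,
            "df": df,
            "p_two_sided": p,
            "p_bh": p_bh,
            "direction": np.where(mb >= ma, "up_in_b", "down_in_b"),
        }
    )
    hits = table[table["p_two_sided"] < alpha]
    records = [
        DEGRecord(
            gene_id=row.gene_id,
            mean_a=float(row.mean_a),
            mean_b=float(row.mean_b),
            t_stat=float(row.t_stat),
            df=float(row.df),
            p_two_sided=float(row.p_two_sided),
            direction=row.direction,
        )
        for row in hits.itertuples(index=False)
    ]
    up = int((hits["direction"] == "up_in_b").sum())
    down = len(records) - up
    summary = {"total": len(records), "up": up, "down": down}
    return records, summary, table
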