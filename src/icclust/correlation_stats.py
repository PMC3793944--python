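"""Target-conditioned correlation, Fisher transformation and threshold calibration.

The first two steps of interconnected correlation clustering: compute the
Pearson correlation r of every gene's expression profile against the target
gene, map the r values to Fisher z-scores (z = 0.5*ln((1+r)/(1-r))) whose
distribution is approximately normal, inspect that distribution to calibrate
a correlation threshold, and select the genes with |r| above it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._errors import ValidationError
from .expression_io import ExpressionMatrix, logger


@dataclass
class CorrelationProfile:
    """Per-gene Pearson r against the target gene, with Fisher z-scores.

    ``gene_ids`` excludes the target; ``excluded`` lists zero-variance genes
    for which r is undefined.
    """

    target_gene: str
    gene_ids: list[str]
    r: np.ndarray
    z: np.ndarray
    n_samples: int
    excluded: list[str]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.gene_ids) == self.r.size == self.z.size):
            raise ValidationError("profile fields have inconsistent lengths")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValidationError("correlation outside [-1, 1]")

    def r_of(self, gene_id: str) -> float:
        try:
            return float(self.r[self.gene_ids.index(gene_id)])
        except ValueError:
            raise ValidationError(f"gene {gene_id!r} not in profile") from None


@dataclass
class ZDiagnostics:
    """Normality diagnostics of the Fisher z-score population.

    ``variance`` is sigma_z^2 with the n-1 denominator, ``skewness`` the
    adjusted Fisher-Pearson standardized third moment, ``ses`` the exact
    finite-sample standard error of skewness, ``kurtosis_excess`` the
    bias-adjusted excess kurtosis.  ``critical_z`` holds the empirical
    alpha/2 and 1-alpha/2 quantiles used as two-tailed critical values.
    """

    variance: float
    skewness: float
    ses: float
    kurtosis_excess: float
    sw_W: float
    sw_p: float
    ks_D: float
    ks_p: float
    critical_z: tuple[float, float]
    alpha: float
    n: int

    def as_dict(self) -> dict[str, float]:
        d = {
            "n": self.n,
            "variance": self.variance,
            "skewness": self.skewness,
            "ses": self.ses,
            "kurtosis_excess": self.kurtosis_excess,
            "shapiro_wilk_W": self.sw_W,
            "shapiro_wilk_p": self.sw_p,
            "ks_D": self.ks_D,
            "ks_p": self.ks_p,
            "alpha": self.alpha,
            "critical_z_lower": self.critical_z[0],
            "critical_z_upper": self.critical_z[1],
        }
        return d


def pearson_profile(m: ExpressionMatrix, target: str) -> CorrelationProfile:
    """Pearson correlation of every gene against the target gene's profile.

    Zero-variance genes are excluded (correlation undefined) and reported in
    the returned profile.  Requires at least 3 samples and a non-constant
    target row.
    """
    if m.n_samples < 3:
        raise ValidationError("need at least 3 samples for correlation")
    if target not in m.gene_ids:
        raise ValidationError(f"target gene {target!r} not in matrix")
    t_idx = m.gene_ids.index(target)
    x = m.values
    sd = x.std(axis=1, ddof=1)
    if sd[t_idx] == 0:
        raise ValidationError(f"target gene {target!r} has zero variance")

    keep = np.ones(m.n_genes, dtype=bool)
    keep[t_idx] = False
    zero_var = (sd == 0) & keep
    excluded = [m.gene_ids[i] for i in np.where(zero_var)[0]]
    if excluded:
        logger.info("excluded %d zero-variance gene(s) from correlation", len(excluded))
    keep &= ~zero_var

    n = m.n_samples
    centered = x - x.mean(axis=1, keepdims=True)
    t_std = centered[t_idx] / sd[t_idx]
    r = (centered[keep] / sd[keep, None]) @ t_std / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    gene_ids = [m.gene_ids[i] for i in np.where(keep)[0]]
    with np.errstate(divide="ignore"):
        z = np.arctanh(r)
    return CorrelationProfile(target, gene_ids, r, z, n, excluded)


def fisher_z(r):
    """Fisher r-to-z transformation, z = 0.5*ln((1+r)/(1-r)); requires |r| < 1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1):
        raise ValidationError("fisher_z requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def inverse_fisher(z):
    """Inverse Fisher transformation, r = tanh(z); strictly inside (-1, 1)."""
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("inverse_fisher requires finite z")
    out = np.tanh(arr)
    return float(out) if np.isscalar(z) or arr.ndim == 0 else out


def skewness_standard_error(n: int) -> float:
    """Exact finite-sample standard error of skewness.

    sqrt(6n(n-1) / ((n-2)(n+1)(n+3))); differs from the large-sample
    sqrt(6/n) approximation in the fifth decimal at n in the thousands.
    """
    if n < 3:
        raise ValidationError("SES undefined for n < 3")
    return math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))


def z_diagnostics(z: np.ndarray, alpha: float = 0.10) -> ZDiagnostics:
    """Summarize the Fisher z-score population and derive empirical critical values.

    Skewness and excess kurtosis use bias-adjusted estimators.  Normality is
    checked with Shapiro-Wilk and a two-sided one-sample Kolmogorov-Smirnov
    test against a normal with the sample's own mean and SD; because the
    reference is estimated from the same data the KS p-value is approximate.
    Critical values are the empirical alpha/2 and 1-alpha/2 quantiles under
    the linear-interpolation (type 7) convention.
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 8:
        raise ValidationError("need at least 8 finite z-scores for diagnostics")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    n = z.size
    variance = float(z.var(ddof=1))
    skew = float(stats.skew(z, bias=False))
    kurt = float(stats.kurtosis(z, bias=False))
    sw_W, sw_p = (float(v) for v in stats.shapiro(z))
    mu, sd = z.mean(), z.std(ddof=1)
    ks = stats.kstest(z, "norm", args=(mu, sd))
    lo, hi = np.quantile(z, [alpha / 2, 1 - alpha / 2])
    return ZDiagnostics(
        variance=variance,
        skewness=skew,
        ses=skewness_standard_error(n),
        kurtosis_excess=kurt,
        sw_W=sw_W,
        sw_p=sw_p,
        ks_D=float(ks.statistic),
        ks_p=float(ks.pvalue),
        critical_z=(float(lo), float(hi)),
        alpha=float(alpha),
        n=n,
    )


def select_genes(p: CorrelationProfile, threshold: float) -> dict[str, int]:
    """Genes with |r| strictly above the threshold, mapped to sign(r).

    Strict inequality: a gene at exactly the threshold is excluded.
    Selection at a higher threshold is always a subset of selection at a
    lower one.
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie in (0, 1)")
    sel = np.abs(p.r) > threshold
    return {
        p.gene_ids[i]: (1 if p.r[i] > 0 else -1) for i in np.where(sel)[0]
    }
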