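"""Reading, validating, normalizing and writing gene-expression tables.

The on-disk dialect is a plain tab-separated matrix: first row sample
identifiers, first column gene identifiers, remaining cells real-valued
expression (log2-scale assumed but not enforced).  Matrices are held
genes x samples throughout the package.
"""
from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ValidationError

logger = logging.getLogger("icclust")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers; unique, order preserved.
    sample_ids : list of str
        Column identifiers; unique, order preserved.
    values : ndarray of shape (n_genes, n_samples)
        Expression values; no missing entries after validation.
    sample_meta : dict, optional
        Maps sample_id -> metadata mapping (e.g. group / time / replicate
        labels) used by the DEG and direction-annotation utilities.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_meta: dict[str, Mapping[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValidationError(f"duplicate {label} id: {i!r}")
                seen.add(i)
        if not np.isfinite(self.values).all():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self.gene_ids.index(gene_id)]
        except ValueError:
            raise ValidationError(f"gene {gene_id!r} not in matrix") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given samples, preserving the requested order."""
        idx = []
        for s in sample_ids:
            if s not in self.sample_ids:
                raise ValidationError(f"sample {s!r} not in matrix")
            idx.append(self.sample_ids.index(s))
        meta = {s: self.sample_meta[s] for s in sample_ids if s in self.sample_meta}
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, idx], meta
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def read_expression_matrix(
    path,
    missing_policy: Literal["error", "drop_gene"] = "error",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First row holds sample ids, first column gene ids.  ``missing_policy``
    controls what happens to rows with empty or unparseable cells:
    ``"error"`` aborts with coordinates, ``"drop_gene"`` removes the gene
    and logs the count.  ``transpose`` accepts samples-in-rows input.
    No imputation is ever performed: correlations computed on imputed
    profiles would silently distort downstream cluster membership.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        df = df.T
    gene_ids = [str(g) for g in df.index]
    dupes = df.index[df.index.duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"duplicate gene id: {dupes[0]!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample id: {dup!r}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.values.any():
        if missing_policy == "error":
            r, c = np.argwhere(bad.values)[0]
            raise ValidationError(
                f"non-numeric or empty cell at gene {gene_ids[r]!r}, "
                f"sample {df.columns[c]!r}"
            )
        elif missing_policy == "drop_gene":
            drop_mask = bad.any(axis=1)
            dropped = [str(g) for g in df.index[drop_mask]]
            logger.info(
                "dropped %d gene(s) with missing/unparseable cells: %s",
                len(dropped),
                ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
            )
            numeric = numeric.loc[~drop_mask]
        else:
            raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    return ExpressionMatrix(
        [str(g) for g in numeric.index],
        [str(s) for s in numeric.columns],
        numeric.to_numpy(dtype=float),
    )


def zscore_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, SD 1 across samples.

    Uses the n-1 (sample) SD denominator, consistent with the t-test
    module.  Rows with zero variance cannot be standardized and raise.
    """
    sd = m.values.std(axis=1, ddof=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        names = ", ".join(m.gene_ids[i] for i in zero[:10])
        raise ValidationError(f"zero-variance gene row(s): {names}")
    vals = (m.values - m.values.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), vals, dict(m.sample_meta))


def average_replicates(m: ExpressionMatrix, replicate_key: str = "replicate") -> ExpressionMatrix:
    """Average columns sharing all sample_meta labels except ``replicate_key``.

    Off the default analysis path: replicate columns are normally treated
    as independent samples for correlation.
    """
    if not m.sample_meta:
        raise ValidationError("replicate averaging requires sample_meta")
    groups: dict[tuple, list[int]] = {}
    for j, s in enumerate(m.sample_ids):
        meta = dict(m.sample_meta.get(s, {}))
        meta.pop(replicate_key, None)
        groups.setdefault(tuple(sorted(meta.items())), []).append(j)
    new_ids = []
    cols = []
    for key, idx in groups.items():
        new_ids.append("|".join(f"{k}={v}" for k, v in key) or m.sample_ids[idx[0]])
        cols.append(m.values[:, idx].mean(axis=1))
    return ExpressionMatrix(list(m.gene_ids), new_ids, np.column_stack(cols))


def write_gene_table(rows: pd.DataFrame | Sequence[Mapping], path) -> None:
    """Write records as a tab-separated table, header first, order as given."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    # %.17g guarantees binary round-trip for doubles
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def read_sample_groups(path) -> dict[str, str]:
    """Read a 2-column TSV (sample_id, group) into a mapping."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError("sample-group table needs 2 columns: sample_id, group")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
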