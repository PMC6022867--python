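"""Expression-correlated gene (ECG) ranking and condition fold-change tables.

Genes are ranked by plain Pearson correlation of their expression profile
with a query gene across all samples; the top-k list mirrors the usual
"ECG200" style analysis.  A separate helper computes log2 fold changes of
group means between two labelled conditions, producing a heatmap-ready
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "CorrelationResult", "CorrelationTable",
           "ZeroVarianceError", "pearson_r", "top_correlated",
           "log2_fold_change"]


class ZeroVarianceError(ValueError):
    """A correlation was requested for a constant vector."""


@dataclass(frozen=True)
class CorrelationResult:
    gene_id: str
    r: float
    rank: int


@dataclass(frozen=True)
class CorrelationTable:
    """Ranked ECG list for one query gene."""

    query_gene: str
    results: tuple

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    @property
    def min_r(self) -> float:
        """Smallest correlation in the list (the '>0.7'-style statistic)."""
        if not self.results:
            return float("nan")
        return self.results[-1].r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gene": c.gene_id, "r": c.r, "rank": c.rank} for c in self.results]
        )


class ExpressionMatrix:
    """Genes x samples expression values with optional condition labels."""

    def __init__(self, values: pd.DataFrame, group_labels: dict | None = None):
        if values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        self.values = values.astype(float)
        if group_labels is not None:
            unknown = set(group_labels) - set(values.columns)
            if unknown:
                raise ValueError(f"group labels for unknown samples: {unknown}")
        self.group_labels = dict(group_labels) if group_labels else None

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def expression_of(self, gene: str) -> np.ndarray:
        if gene not in self.values.index:
            raise KeyError(f"gene {gene!r} not in matrix")
        return self.values.loc[gene].to_numpy()

    # -- I/O: TSV with gene ids in the first column, sample ids as header --

    @classmethod
    def from_tsv(cls, path, groups_path=None) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        groups = None
        if groups_path is not None:
            gdf = pd.read_csv(groups_path, sep="\t")
            groups = dict(zip(gdf.iloc[:, 0].astype(str),
                              gdf.iloc[:, 1].astype(str)))
        return cls(df, groups)

    def to_tsv(self, path, groups_path=None) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")
        if groups_path is not None and self.group_labels is not None:
            pd.DataFrame(
                {"sample": list(self.group_labels),
                 "condition": list(self.group_labels.values())}
            ).to_csv(groups_path, sep="\t", index=False)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be one-dimensional and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def top_correlated(mat: ExpressionMatrix, query_gene: str,
                   k: int = 200) -> CorrelationTable:
    """Rank genes by Pearson correlation to *query_gene*, take the top k.

    The query gene itself is excluded; genes with undefined correlation
    (zero variance) are dropped with a logged warning.  Ties are broken by
    gene id so the ranking is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ref = mat.expression_of(query_gene)  # raises KeyError if absent
    scored = []
    for gene in mat.gene_ids:
        if gene == query_gene:
            continue
        try:
            r = pearson_r(ref, mat.expression_of(gene))
        except ZeroVarianceError:
            logger.warning("gene %s has zero variance; excluded from ranking",
                           gene)
            continue
        scored.append((gene, r))
    scored.sort(key=lambda t: (-t[1], t[0]))
    results = tuple(
        CorrelationResult(gene_id=g, r=r, rank=i + 1)
        for i, (g, r) in enumerate(scored[:k]))
    return CorrelationTable(query_gene=query_gene, results=results)


def log2_fold_change(mat: ExpressionMatrix, treatment: str, control: str,
                     genes=None) -> pd.DataFrame:
    """log2(mean treatment / mean control) per gene.

    Both condition labels must be present in the matrix's group labels with
    at least one sample each.  A non-positive group mean is an error naming
    the gene — values are assumed to be microarray-style intensities, so no
    silent pseudocounts are applied.
    """
    if mat.group_labels is None:
        raise ValueError("matrix has no condition labels")
    cols = {cond: [s for s, c in mat.group_labels.items() if c == cond]
            for cond in (treatment, control)}
    for cond, samples in cols.items():
        if not samples:
            raise ValueError(f"condition {cond!r} has no samples")
    if genes is None:
        genes = mat.gene_ids
    rows = []
    for gene in genes:
        expr = mat.values.loc[gene]
        mt = float(expr[cols[treatment]].mean())
        mc = float(expr[cols[control]].mean())
        if mt <= 0 or mc <= 0:
            raise ValueError(
                f"non-positive mean expression for gene {gene!r} "
                f"(treatment={mt}, control={mc})")
        rows.append({"gene": gene, "log2fc": float(np.log2(mt / mc))})
    return pd.DataFrame(rows)
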