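"""Per-gene translation efficiency from paired RNA and ribosome occupancy.

Ribosome profiling and RNA-seq are treated as two experimental
manipulations of the same RNA pool: per gene, a weighted least-squares
model of log2-cpm on individual indicators plus per-individual
ribosome-profiling contrasts makes each individual's TE directly
readable as the coefficient of that individual's ribo indicator (a log2
ribo-minus-RNA ratio).  The global TE is the precision-weighted mean of
the per-individual TEs.

A simpler common-assay-effect parameterization (individual main effects
plus one assay contrast) is provided for analyses that need a single TE
per gene, such as the Kozak per-position tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .normalization import ExpressionSet

logger = logging.getLogger(__name__)


@dataclass
class TEResult:
    gene_id: str
    te_global: float
    te_by_individual: Dict[str, float]
    se_by_individual: Dict[str, float]
    residual_df: int


def _design_per_individual(samples: pd.DataFrame):
    individuals = sorted(samples["individual"].unique())
    has_both = [
        i for i in individuals
        if (samples["individual"].eq(i) & samples["assay"].eq("rna")).any()
        and (samples["individual"].eq(i) & samples["assay"].eq("ribo")).any()
    ]
    skipped = set(individuals) - set(has_both)
    if skipped:
        logger.warning("individuals missing an assay, TE absent: %s", sorted(skipped))
    n = len(samples)
    X = np.zeros((n, len(individuals) + len(has_both)))
    for j, ind in enumerate(individuals):
        X[(samples["individual"] == ind).to_numpy(), j] = 1.0
    for k, ind in enumerate(has_both):
        mask = (samples["individual"] == ind) & (samples["assay"] == "ribo")
        X[mask.to_numpy(), len(individuals) + k] = 1.0
    return X, individuals, has_both


def estimate_te(expr: ExpressionSet) -> List[TEResult]:
    """Weighted least squares per gene; TE_i = ribo-indicator coefficient."""
    if expr.logcpm is None or expr.weights is None:
        raise ValueError("run voom_transform first")
    X, individuals, has_both = _design_per_individual(expr.samples)
    n, p = X.shape
    df_resid = n - p
    Y = expr.logcpm.to_numpy(dtype=float)
    W = expr.weights.to_numpy(dtype=float)
    te_cols = slice(len(individuals), p)

    results: List[TEResult] = []
    for g, gene in enumerate(expr.logcpm.index):
        w = W[g]
        y = Y[g]
        XtW = X.T * w
        XtWX = XtW @ X
        beta = np.linalg.solve(XtWX, XtW @ y)
        resid = y - X @ beta
        s2 = float((w * resid ** 2).sum() / max(df_resid, 1))
        cov = np.linalg.inv(XtWX) * s2
        te = beta[te_cols]
        se = np.sqrt(np.diag(cov)[te_cols])
        prec = 1.0 / np.maximum(se, 1e-12) ** 2
        te_global = float(np.sum(prec * te) / np.sum(prec))
        results.append(TEResult(
            gene_id=gene,
            te_global=te_global,
            te_by_individual=dict(zip(has_both, te.tolist())),
            se_by_individual=dict(zip(has_both, se.tolist())),
            residual_df=df_resid,
        ))
    return results


def estimate_te_common(expr: ExpressionSet) -> pd.Series:
    """Common-assay-effect model: one TE per gene (the ribo coefficient)."""
    if expr.logcpm is None or expr.weights is None:
        raise ValueError("run voom_transform first")
    samples = expr.samples
    individuals = sorted(samples["individual"].unique())
    n = len(samples)
    X = np.zeros((n, len(individuals) + 1))
    for j, ind in enumerate(individuals):
        X[(samples["individual"] == ind).to_numpy(), j] = 1.0
    X[(samples["assay"] == "ribo").to_numpy(), -1] = 1.0
    Y = expr.logcpm.to_numpy(dtype=float)
    W = expr.weights.to_numpy(dtype=float)
    te = np.empty(Y.shape[0])
    for g in range(Y.shape[0]):
        XtW = X.T * W[g]
        beta = np.linalg.solve(XtW @ X, XtW @ Y[g])
        te[g] = beta[-1]
    return pd.Series(te, index=expr.logcpm.index, name="te_global")


def te_matrix(results: Sequence[TEResult]) -> pd.DataFrame:
    """Genes x individuals matrix of per-individual TE estimates."""
    individuals = sorted({i for r in results for i in r.te_by_individual})
    data = {
        r.gene_id: [r.te_by_individual.get(i, np.nan) for i in individuals]
        for r in results
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=individuals)


def te_global_series(results: Sequence[TEResult]) -> pd.Series:
    return pd.Series({r.gene_id: r.te_global for r in results}, name="te_global")
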