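"""Shared per-gene dosage regression used by the uORF and Kozak tests.

Approach 1 is a precision-weighted linear regression of per-library
log2-cpm on the per-individual predictor (event copy number or
PWM-score-coded dosage).  Approach 2, the conservative variant, is a
linear mixed model with an individual random intercept, treating
replicate libraries of one individual as technical replicates.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


def _wls_slope(y: np.ndarray, x: np.ndarray, w: np.ndarray):
    X = np.column_stack([np.ones_like(x), x])
    model = sm.WLS(y, X, weights=w)
    fit = model.fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def _lmm_slope(y: np.ndarray, x: np.ndarray, groups: np.ndarray) -> float:
    """Wald p-value for the predictor in a random-intercept model (ML)."""
    X = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        # boundary fits (zero random-effect variance) can break a single
        # optimizer; try a second one before giving up
        for method in (None, "powell"):
            try:
                kwargs = {} if method is None else {"method": method}
                fit = model.fit(reml=False, **kwargs)
                return float(fit.pvalues[1])
            except Exception as exc:
                last = exc
        logger.warning("LMM failed (%s); reporting NaN", last)
        return float("nan")


def dosage_association(
    expr,
    gene_id: str,
    predictor_by_individual: Mapping[str, float],
    use_lmm: bool = True,
) -> Optional[dict]:
    """Regress one gene's RO and RNA log2-cpm on a per-individual predictor.

    ``expr`` is a voom-transformed ExpressionSet (logcpm + weights).
    Returns a dict with beta/p for both phenotypes and the LMM p for the
    ribosome-occupancy phenotype, or None if the gene is absent.
    """
    if gene_id not in expr.logcpm.index:
        logger.warning("gene %s not in expression matrix", gene_id)
        return None
    out = {}
    for assay, key in (("ribo", "ribo"), ("rna", "rna")):
        mask = expr.samples["assay"].values == key
        libs = expr.samples.index[mask]
        inds = expr.samples.loc[libs, "individual"].values
        keep = np.array([i in predictor_by_individual for i in inds])
        libs, inds = libs[keep], inds[keep]
        x = np.array([predictor_by_individual[i] for i in inds], dtype=float)
        y = expr.logcpm.loc[gene_id, libs].to_numpy(dtype=float)
        w = expr.weights.loc[gene_id, libs].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            return None
        beta, p = _wls_slope(y, x, w)
        out[f"beta_{assay}"] = beta
        out[f"p_{assay}"] = p
        if assay == "ribo":
            out["p_lmm_ribo"] = _lmm_slope(y, x, inds) if use_lmm else float("nan")
    return out
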