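"""Count filtering, TMM library normalization, and the voom transform.

TMM (trimmed mean of M-values) and the voom log2-cpm transform with
observation-level inverse-variance precision weights are implemented
directly from their published recipes.  The mean-variance trend is fit
with a lowess of sqrt(residual sd) on average log2 count, using a design
that encodes which libraries are replicates of the same individual, and
weights are the fitted fourth inverse power evaluated at the fitted
log2-count of each observation.

RNA-seq and ribosome-profiling libraries are normalized jointly (one TMM
reference pool) by default because translation-efficiency estimation
contrasts the two assays; ``per_assay=True`` switches to separate pools.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

SQRT_SD_FLOOR = 1e-2  # caps weights when the fitted trend reaches zero noise
WEIGHT_FLOOR = 1e-4


@dataclass
class ExpressionSet:
    """Genes x libraries counts with sample metadata and derived matrices.

    ``samples`` is indexed by library id with columns ``individual``,
    ``assay`` ("rna" or "ribo") and ``replicate``; its rows correspond
    1:1 to the columns of ``counts``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    norm_factors: Optional[pd.Series] = None
    logcpm: Optional[pd.DataFrame] = None
    weights: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("sample sheet rows must match count columns 1:1")

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def libraries(self, assay: Optional[str] = None) -> pd.Index:
        if assay is None:
            return self.samples.index
        return self.samples.index[self.samples["assay"] == assay]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionSet":
        return ExpressionSet(
            counts=self.counts.loc[genes].copy(),
            samples=self.samples.copy(),
            norm_factors=None if self.norm_factors is None else self.norm_factors.copy(),
            logcpm=None if self.logcpm is None else self.logcpm.loc[genes].copy(),
            weights=None if self.weights is None else self.weights.loc[genes].copy(),
        )


def load_expression(counts_path: str, samples_path: str) -> ExpressionSet:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return ExpressionSet(counts=counts, samples=samples.loc[counts.columns])


def cpm(counts: pd.DataFrame, lib_sizes: Optional[pd.Series] = None) -> pd.DataFrame:
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    return counts.div(lib_sizes, axis=1) * 1e6


def cpm_filter(
    expr: ExpressionSet,
    min_cpm: float = 1.0,
    min_libraries_rna: Optional[int] = None,
    min_libraries_ribo: Optional[int] = None,
) -> ExpressionSet:
    """Keep genes with cpm > ``min_cpm`` in enough libraries of BOTH assays.

    Default library thresholds are ceil(0.9 x n_libraries) per assay,
    the proportional analogue of requiring expression in ~90% of
    libraries.
    """
    c = cpm(expr.counts)
    kept_masks = []
    for assay, threshold in (("rna", min_libraries_rna), ("ribo", min_libraries_ribo)):
        libs = expr.libraries(assay)
        if len(libs) == 0:
            raise ValueError(f"no libraries for assay {assay}")
        k = math.ceil(0.9 * len(libs)) if threshold is None else threshold
        if k > len(libs):
            raise ValueError(
                f"threshold {k} exceeds {len(libs)} {assay} libraries"
            )
        kept_masks.append((c[libs] > min_cpm).sum(axis=1) >= k)
    keep = kept_masks[0] & kept_masks[1]
    logger.info("cpm_filter: kept %d / %d genes", int(keep.sum()), len(keep))
    return ExpressionSet(expr.counts.loc[keep].copy(), expr.samples.copy())


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """TMM factor of one library against the reference (log2 scale -> 2^f)."""
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * (np.log2(o / n_obs) + np.log2(r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not kept.any():
        return 1.0
    f = np.sum(m[kept] / v[kept]) / np.sum(1.0 / v[kept])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    expr: ExpressionSet, trim_m: float = 0.30, trim_a: float = 0.05,
    per_assay: bool = False,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference library is the one whose 75th-percentile count
    fraction is closest to the mean of those; per-gene M-values against
    the reference are doubly trimmed (30% on M, 5% on A) and averaged
    with inverse asymptotic binomial variance weights.
    """
    counts = expr.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("all-zero library")
    if per_assay:
        factors = pd.Series(1.0, index=expr.counts.columns)
        for assay in ("rna", "ribo"):
            libs = expr.libraries(assay)
            sub = ExpressionSet(expr.counts[libs], expr.samples.loc[libs])
            factors[libs] = tmm_factors(sub, trim_m, trim_a)
        return factors

    f75 = np.quantile(counts, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = counts[:, ref_idx]
    raw = np.array([
        _tmm_pair(counts[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(counts.shape[1])
    ])
    raw /= np.exp(np.mean(np.log(raw)))
    return pd.Series(raw, index=expr.counts.columns, name="norm_factor")


def _individual_design(samples: pd.DataFrame) -> np.ndarray:
    """Cell-means design on individual x assay (replicate structure)."""
    groups = samples["individual"].astype(str) + ":" + samples["assay"].astype(str)
    levels = pd.unique(groups)
    X = np.zeros((len(samples), len(levels)))
    for j, level in enumerate(levels):
        X[(groups == level).to_numpy(), j] = 1.0
    return X


def voom_transform(
    expr: ExpressionSet,
    span: float = 0.5,
    weight_floor: float = WEIGHT_FLOOR,
) -> ExpressionSet:
    """log2-cpm with inverse-variance precision weights from a lowess trend.

    logcpm = log2((count + 0.5) / (lib_size x factor + 1) x 1e6).  The
    per-gene residual sd comes from a linear fit on indicators of
    (individual, assay) replicate groups; a lowess of sqrt(sd) against
    average log2 count gives the trend, and each observation's weight is
    the trend value at its fitted log2 count raised to the -4th power.
    Weights are clipped to a positive floor (and implicitly capped by a
    small sqrt-sd floor so zero-noise genes get large equal weights).
    """
    if expr.norm_factors is None:
        expr.norm_factors = tmm_factors(expr)
    counts = expr.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0) * expr.norm_factors.to_numpy()
    y = np.log2((counts + 0.5) / (lib + 1.0) * 1e6)

    X = _individual_design(expr.samples)
    # one least-squares solve for all genes (common design)
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    fitted = (X @ beta).T
    resid = y - fitted
    n, p = X.shape[0], np.linalg.matrix_rank(X)
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom in the replicate design")
    sigma = np.sqrt((resid ** 2).sum(axis=1) / df_resid)

    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    if np.ptp(sy) == 0 or np.ptp(sx) == 0:  # degenerate: flat trend
        tx = np.array([sx.min() - 1.0, sx.max() + 1.0])
        ty = np.array([sy[0], sy[0]])
    else:
        trend = lowess(sy, sx, frac=span, it=3, return_sorted=True)
        tx, ty = trend[:, 0], trend[:, 1]

    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, tx, ty)  # constant extrapolation
    pred = np.clip(pred, SQRT_SD_FLOOR, None)
    w = pred ** -4.0
    w = np.clip(w, weight_floor, None)

    expr.logcpm = pd.DataFrame(y, index=expr.counts.index, columns=expr.counts.columns)
    expr.weights = pd.DataFrame(w, index=expr.counts.index, columns=expr.counts.columns)
    return expr
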