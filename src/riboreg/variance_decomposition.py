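"""Inter-individual variance components and the simulation-based exact LRT.

Per gene and assay, log2-cpm values are modelled as

    y_ij = mu + b_i + e_ij,    b_i ~ N(0, sigma2_individual),
                               e_ij ~ N(0, sigma2_residual / w_ij),

with the voom precision weights w treated as fixed known precisions and
both fits by maximum likelihood (not REML).  The null hypothesis is
sigma2_individual = 0.  Because the null parameter sits on the boundary,
the chi-square approximation fails (the LRT statistic has an atom of
roughly 1/2 at zero), so p-values come from a parametric bootstrap: the
null model is fitted, responses are re-simulated from it with the same
design and weights, both models are refitted per replicate, and

    p = (1 + #{sim_stat >= observed_stat}) / (1 + n_sim).

The bootstrap refits are vectorized through a profile likelihood in the
variance ratio lambda = sigma2_individual / sigma2_residual, which after
profiling out mu and sigma2_residual depends on the data only through
per-group weighted sums.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-4, 3, 80)])
_STAT_ATOL = 1e-8

CLASS_NONE = "none"
CLASS_RNA_ONLY = "rna_only"
CLASS_RIBO_ONLY = "ribo_only"
CLASS_BOTH = "both"


def _group_codes(individuals: Sequence[str]) -> Tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(individuals))
    return codes.astype(np.intp), len(uniques)


def _profile_parts(y, w, codes, m):
    s = np.bincount(codes, weights=w, minlength=m)
    t = np.bincount(codes, weights=w * y, minlength=m)
    q = float(np.sum(w * y * y))
    return s, t, q


def _profile_loglik(lam: float, s, t, q, n: int, sum_log_w: float) -> float:
    """Log-likelihood at variance ratio lam, with mu and sigma2 profiled out."""
    d = 1.0 + lam * s
    u0 = np.sum(s / d)
    u1 = np.sum(t / d)
    big_q = q - lam * np.sum(t * t / d)
    r = big_q - u1 * u1 / u0
    r = max(r, 1e-300)
    return (
        -0.5 * n * (np.log(2.0 * np.pi * r / n) + 1.0)
        - 0.5 * np.sum(np.log(d))
        + 0.5 * sum_log_w
    )


def fit_varcomp(
    y: np.ndarray,
    weights: Optional[np.ndarray],
    individuals: Sequence[str],
) -> Tuple[float, float, float]:
    """ML estimates (sigma2_individual, sigma2_residual, loglik).

    sigma2_individual is constrained to be non-negative; the boundary
    estimate 0 is allowed.  Requires at least two individuals with at
    least two libraries each for the variance component to be
    identifiable.
    """
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    codes, m = _group_codes(individuals)
    n = y.size
    s, t, q = _profile_parts(y, w, codes, m)
    sum_log_w = float(np.sum(np.log(w)))

    def neg_ll(log_lam: float) -> float:
        return -_profile_loglik(np.exp(log_lam), s, t, q, n, sum_log_w)

    ll0 = _profile_loglik(0.0, s, t, q, n, sum_log_w)
    opt = minimize_scalar(neg_ll, bounds=(-30.0, 35.0), method="bounded",
                          options={"xatol": 1e-10})
    lam_hat, ll_hat = (np.exp(opt.x), -opt.fun)
    if ll0 >= ll_hat:
        lam_hat, ll_hat = 0.0, ll0
    # residual variance at the optimum
    d = 1.0 + lam_hat * s
    u0, u1 = np.sum(s / d), np.sum(t / d)
    r = (q - lam_hat * np.sum(t * t / d)) - u1 * u1 / u0
    sigma2_res = max(r / n, 1e-300)
    return lam_hat * sigma2_res, sigma2_res, ll_hat


def _lrt_stats_matrix(Y: np.ndarray, w: np.ndarray, codes: np.ndarray, m: int,
                      lam_grid: np.ndarray = _LAMBDA_GRID) -> np.ndarray:
    """LRT statistics for each column of Y (n_obs x B), grid-profiled.

    The same grid is used for observed and bootstrap statistics so the
    bootstrap p-value compares like with like.
    """
    n, B = Y.shape
    A = np.zeros((m, n))
    A[codes, np.arange(n)] = w
    T = A @ Y                              # (m, B) per-group weighted sums
    q = w @ (Y * Y)                        # (B,)
    s = np.bincount(codes, weights=w, minlength=m)

    t_tot = T.sum(axis=0)
    r0 = q - t_tot ** 2 / s.sum()
    r0 = np.maximum(r0, 1e-300)
    ll0 = -0.5 * n * (np.log(2.0 * np.pi * r0 / n) + 1.0)
    best = ll0.copy()
    for lam in lam_grid[1:]:
        d = 1.0 + lam * s
        u0 = np.sum(s / d)
        u1 = (T / d[:, None]).sum(axis=0)
        r = (q - lam * ((T * T) / d[:, None]).sum(axis=0)) - u1 * u1 / u0
        r = np.maximum(r, 1e-300)
        ll = (-0.5 * n * (np.log(2.0 * np.pi * r / n) + 1.0)
              - 0.5 * np.sum(np.log(d)))
        np.maximum(best, ll, out=best)
    stats = 2.0 * (best - ll0)
    stats[stats < _STAT_ATOL] = 0.0
    return stats


def exact_lrt(
    y: np.ndarray,
    weights: Optional[np.ndarray],
    individuals: Sequence[str],
    n_sim: int = 10_000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Parametric-bootstrap exact LRT for sigma2_individual = 0.

    Deterministic given ``seed``.  The add-one estimator keeps p in
    (0, 1]; a zero statistic yields p = 1 (the boundary point mass).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    codes, m = _group_codes(individuals)
    n = y.size

    obs = float(_lrt_stats_matrix(y[:, None], w, codes, m)[0])
    if obs == 0.0:
        return 0.0, 1.0

    mu0 = float(np.sum(w * y) / np.sum(w))
    sigma2_0 = float(np.sum(w * (y - mu0) ** 2) / n)
    rng = np.random.default_rng(seed)
    sd = np.sqrt(sigma2_0 / w)
    Y = mu0 + rng.standard_normal((n, n_sim)) * sd[:, None]
    sim = _lrt_stats_matrix(Y, w, codes, m)
    p = (1.0 + float(np.sum(sim >= obs - _STAT_ATOL))) / (1.0 + n_sim)
    return obs, p


def varcomp_scan(
    expr,
    assay: str,
    n_sim: int = 10_000,
    seed: int = 0,
    genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Run fit + exact LRT for every gene on one assay's libraries."""
    libs = expr.libraries(assay)
    individuals = expr.samples.loc[libs, "individual"].tolist()
    if genes is None:
        genes = list(expr.logcpm.index)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(genes)) % (2 ** 31)
    rows = []
    for gene, sub_seed in zip(genes, child_seeds):
        y = expr.logcpm.loc[gene, libs].to_numpy(dtype=float)
        w = expr.weights.loc[gene, libs].to_numpy(dtype=float)
        try:
            s2_ind, s2_res, _ = fit_varcomp(y, w, individuals)
            stat, p = exact_lrt(y, w, individuals, n_sim=n_sim, seed=int(sub_seed))
        except Exception as exc:
            logger.warning("gene %s (%s): varcomp failed (%s)", gene, assay, exc)
            rows.append({"gene_id": gene, "assay": assay,
                         "sigma2_individual": np.nan, "sigma2_residual": np.nan,
                         "lrt_stat": np.nan, "p_value": np.nan})
            continue
        rows.append({"gene_id": gene, "assay": assay,
                     "sigma2_individual": s2_ind, "sigma2_residual": s2_res,
                     "lrt_stat": stat, "p_value": p})
    return pd.DataFrame(rows).set_index("gene_id")


def holm_adjust(p: pd.Series) -> pd.Series:
    """Holm step-down adjustment over the converged (non-NaN) family."""
    out = pd.Series(np.nan, index=p.index)
    ok = p.notna()
    if ok.any():
        out[ok] = multipletests(p[ok], method="holm")[1]
    return out


def classify_variability(
    results_rna: pd.DataFrame,
    results_ribo: pd.DataFrame,
    alpha: float = 0.05,
    dominance_ratio: float = 2.0,
) -> pd.DataFrame:
    """Per-gene variability class from the two assays' Holm-adjusted tests.

    Classes: none / rna_only / ribo_only / both; genes in class "both"
    get a dominance subset (comparable / rna_dominant / ribo_dominant)
    from the ratio of the two sigma2_individual estimates.
    """
    genes = results_rna.index
    if not genes.equals(results_ribo.index):
        raise ValueError("result sets must cover the same genes")
    p_holm_rna = holm_adjust(results_rna["p_value"])
    p_holm_ribo = holm_adjust(results_ribo["p_value"])
    sig_rna = p_holm_rna < alpha
    sig_ribo = p_holm_ribo < alpha

    classes, subsets = [], []
    for g in genes:
        r, b = bool(sig_rna[g]), bool(sig_ribo[g])
        if r and b:
            cls = CLASS_BOTH
            ratio = results_rna.loc[g, "sigma2_individual"] / max(
                results_ribo.loc[g, "sigma2_individual"], 1e-300)
            if ratio >= dominance_ratio:
                subset = "rna_dominant"
            elif ratio <= 1.0 / dominance_ratio:
                subset = "ribo_dominant"
            else:
                subset = "comparable"
        else:
            cls = CLASS_RNA_ONLY if r else (CLASS_RIBO_ONLY if b else CLASS_NONE)
            subset = ""
        classes.append(cls)
        subsets.append(subset)
    return pd.DataFrame({
        "class": classes, "subset": subsets,
        "p_holm_rna": p_holm_rna, "p_holm_ribo": p_holm_ribo,
    }, index=genes)
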