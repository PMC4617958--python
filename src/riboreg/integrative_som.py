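"""Rank-percentile integration, SOM training, AP clustering, correlations.

Ribosome occupancy, RNA expression, translation efficiency and protein
level are each converted to empirical-CDF percentiles across genes so the
four measures enter the self-organizing map on equal footing.  The SOM
is a classic online Kohonen map on a hexagonal grid (140 units by
default); its codebook vectors are then clustered with affinity
propagation on negative squared Euclidean similarities, and each cluster
is summarized by the rank profile of its exemplar unit together with the
number of member genes.

The per-gene expression-protein Spearman analysis (with BH FDR and
stratification by variability class) lives here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.cluster import AffinityPropagation
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MEASURES = ("ribosome_occupancy", "rna_expression", "translation_efficiency",
            "protein_level")


def rank_transform(values_by_measure: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Empirical-CDF percentile of each gene, per measure independently.

    Only genes present in every measure are kept (dropped genes are
    logged).  Ties share a percentile; each column lies in (0, 1].
    """
    keys = list(values_by_measure)
    common = None
    for k in keys:
        idx = values_by_measure[k].dropna().index
        common = idx if common is None else common.intersection(idx)
    total = len(set().union(*(values_by_measure[k].index for k in keys)))
    if len(common) < total:
        logger.info("rank_transform: %d of %d genes in all measures",
                    len(common), total)
    out = {}
    for k in keys:
        v = values_by_measure[k].loc[common].to_numpy(dtype=float)
        out[k] = rankdata(v, method="max") / len(v)
    return pd.DataFrame(out, index=common)


def hex_grid(rows: int, cols: int) -> np.ndarray:
    """Planar coordinates of a hexagonal grid, row-major unit order."""
    coords = np.empty((rows * cols, 2))
    for r in range(rows):
        for c in range(cols):
            coords[r * cols + c] = (c + 0.5 * (r % 2), r * np.sqrt(3.0) / 2.0)
    return coords


@dataclass
class SomModel:
    grid_shape: Tuple[int, int]
    grid_coords: np.ndarray
    codebook: np.ndarray            # units x features
    unit_of_gene: pd.Series         # gene -> unit index
    feature_names: Tuple[str, ...]
    cluster_of_unit: Optional[np.ndarray] = None
    exemplar_of_cluster: Optional[np.ndarray] = None
    qe_initial: float = float("nan")
    qe_final: float = float("nan")

    @property
    def n_units(self) -> int:
        return self.codebook.shape[0]


def _bmu(codebook: np.ndarray, x: np.ndarray) -> int:
    d = codebook - x
    return int(np.argmin(np.einsum("ij,ij->i", d, d)))


def quantization_error(codebook: np.ndarray, X: np.ndarray) -> float:
    d = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d.min(axis=1)).mean())


def train_som(
    profiles: pd.DataFrame,
    grid_shape: Tuple[int, int] = (14, 10),
    epochs: int = 20,
    lr_schedule: Tuple[float, float] = (0.3, 0.01),
    radius_schedule: Optional[Tuple[float, float]] = None,
    seed: int = 0,
) -> SomModel:
    """Online SOM: sample-initialized codebook, Gaussian hex neighborhood,
    linearly decaying radius and learning rate.  Deterministic given
    ``seed``."""
    X = profiles.to_numpy(dtype=float)
    n, d = X.shape
    n_units = grid_shape[0] * grid_shape[1]
    if n < n_units:
        logger.warning("fewer genes (%d) than SOM units (%d)", n, n_units)
    rng = np.random.default_rng(seed)
    coords = hex_grid(*grid_shape)
    init_idx = rng.choice(n, size=n_units, replace=n < n_units)
    codebook = X[init_idx].copy()
    qe_initial = quantization_error(codebook, X)

    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    if radius_schedule is None:
        # anneal from broad ordering to near-BMU-only fine tuning
        radius_schedule = (np.sqrt(grid_d2.max()) / 2.0, 0.05)
    r0, r1 = radius_schedule
    lr0, lr1 = lr_schedule
    total_steps = epochs * n
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in order:
            frac = step / max(total_steps - 1, 1)
            radius = r0 + (r1 - r0) * frac
            lr = lr0 + (lr1 - lr0) * frac
            b = _bmu(codebook, X[i])
            h = np.exp(-grid_d2[b] / (2.0 * radius ** 2))
            codebook += (lr * h)[:, None] * (X[i] - codebook)
            step += 1

    units = np.array([_bmu(codebook, X[i]) for i in range(n)])
    return SomModel(
        grid_shape=grid_shape,
        grid_coords=coords,
        codebook=codebook,
        unit_of_gene=pd.Series(units, index=profiles.index, name="unit"),
        feature_names=tuple(profiles.columns),
        qe_initial=qe_initial,
        qe_final=quantization_error(codebook, X),
    )


def cluster_codebook(
    som: SomModel,
    damping: float = 0.9,
    preference: Optional[float] = None,
    max_iter: int = 1000,
    convergence_iter: int = 50,
) -> pd.DataFrame:
    """Affinity propagation on the codebook; returns the cluster summary.

    Similarity is the negative squared Euclidean distance between
    codebook vectors; the preference defaults to the median similarity.
    The summary table has, per cluster, the exemplar unit's rank profile
    and the number of genes mapped to the cluster's units.
    """
    cb = som.codebook
    S = -((cb[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
    if preference is None:
        preference = float(np.median(S[np.triu_indices_from(S, k=1)]))
    ap = AffinityPropagation(
        affinity="precomputed", damping=damping, preference=preference,
        max_iter=max_iter, convergence_iter=convergence_iter, random_state=0,
    ).fit(S)
    labels = ap.labels_
    if ap.cluster_centers_indices_ is None or len(ap.cluster_centers_indices_) == 0:
        logger.warning("affinity propagation did not converge to exemplars")
        som.cluster_of_unit = np.zeros(som.n_units, dtype=int)
        som.exemplar_of_cluster = np.array([0])
    else:
        som.cluster_of_unit = labels
        som.exemplar_of_cluster = ap.cluster_centers_indices_

    genes_per_unit = som.unit_of_gene.value_counts()
    rows = []
    for k, exemplar in enumerate(som.exemplar_of_cluster):
        member_units = np.flatnonzero(som.cluster_of_unit == k)
        n_genes = int(sum(genes_per_unit.get(u, 0) for u in member_units))
        row = {"cluster": k, "exemplar_unit": int(exemplar),
               "n_units": len(member_units), "n_genes": n_genes}
        for f, name in enumerate(som.feature_names):
            row[f"exemplar_{name}"] = float(som.codebook[exemplar, f])
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


def plot_som(som: SomModel, path: str) -> None:
    """Minimal SOM map: one panel per measure, units colored by their
    codebook value, placed at the hexagonal grid coordinates."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_feat = len(som.feature_names)
    fig, axes = plt.subplots(1, n_feat, figsize=(3.2 * n_feat, 3.2))
    for f, (ax, name) in enumerate(zip(np.atleast_1d(axes),
                                       som.feature_names)):
        sc = ax.scatter(som.grid_coords[:, 0], som.grid_coords[:, 1],
                        c=som.codebook[:, f], s=180, marker="h",
                        cmap="viridis", vmin=0, vmax=1)
        ax.set_title(str(name), fontsize=9)
        ax.set_aspect("equal")
        ax.axis("off")
        fig.colorbar(sc, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def gene_protein_correlation(
    expr_by_individual: pd.DataFrame,
    protein_by_individual: pd.DataFrame,
    min_individuals: int = 8,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Spearman correlation across individuals, with BH FDR.

    ``expr_by_individual`` and ``protein_by_individual`` are genes x
    individuals; genes with fewer than ``min_individuals`` paired
    observations are skipped.
    """
    common_inds = expr_by_individual.columns.intersection(
        protein_by_individual.columns)
    rows = []
    for gene in expr_by_individual.index.intersection(protein_by_individual.index):
        x = expr_by_individual.loc[gene, common_inds].to_numpy(dtype=float)
        y = protein_by_individual.loc[gene, common_inds].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_individuals:
            continue
        if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            rho, p = 0.0, 1.0
        else:
            rho, p = spearmanr(x[ok], y[ok])
        rows.append({"gene_id": gene, "rho": float(rho), "p_value": float(p),
                     "n": int(ok.sum())})
    if not rows:
        return pd.DataFrame(
            columns=["rho", "p_value", "n", "fdr", "significant"],
            index=pd.Index([], name="gene_id"))
    out = pd.DataFrame(rows).set_index("gene_id")
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_level
    return out


def summarize_by_stratum(
    corr: pd.DataFrame, classes: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Median rho and fraction significant, overall and per variability class."""
    rows = [{
        "stratum": "all", "n_genes": len(corr),
        "median_rho": float(corr["rho"].median()),
        "frac_significant": float(corr["significant"].mean()),
    }]
    if classes is not None:
        for cls in sorted(classes.unique()):
            genes = classes.index[classes == cls].intersection(corr.index)
            if len(genes) == 0:
                continue
            sub = corr.loc[genes]
            rows.append({
                "stratum": cls, "n_genes": len(sub),
                "median_rho": float(sub["rho"].median()),
                "frac_significant": float(sub["significant"].mean()),
            })
    return pd.DataFrame(rows).set_index("stratum")
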