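"""cis-QTL mapping and FuncAssociate-style gene-set enrichment.

cis-QTLs: per gene, replicate-averaged expression is regressed on the
0/1/2 alternate-allele dosage of each variant on that gene's transcript
(additive model), restricted to variants with minor allele frequency
above 10% in the tested panel; BH FDR per phenotype.

Enrichment: one-sided Fisher exact tests of a query set against an
explicit background, with a min-p permutation adjustment (random
same-size queries drawn from the background) that accounts for term
overlap, and a kappa-similarity term graph over the significant terms.
"""

from __future__ import annotations

import logging
from typing import Dict, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def cis_qtl(
    expr_avg: pd.DataFrame,
    genotypes: pd.DataFrame,
    gene_of_variant: Mapping[str, str],
    maf_min: float = 0.10,
    phenotype: str = "ribo",
    fdr_level: float = 0.30,
) -> pd.DataFrame:
    """Additive cis association of averaged expression with variant dosage.

    ``expr_avg`` is genes x individuals (replicates already averaged);
    ``genotypes`` is variants x individuals with dosage 0/1/2.  Only the
    individuals present in both matrices are tested.
    """
    inds = expr_avg.columns.intersection(genotypes.columns)
    rows = []
    for vid in genotypes.index:
        gene = gene_of_variant.get(vid)
        if gene is None or gene not in expr_avg.index:
            continue
        g = genotypes.loc[vid, inds].to_numpy(dtype=float)
        af = g.mean() / 2.0
        maf = min(af, 1.0 - af)
        if maf <= maf_min:
            continue
        y = expr_avg.loc[gene, inds].to_numpy(dtype=float)
        x = g - g.mean()
        sxx = float(np.sum(x * x))
        if sxx == 0:
            continue
        beta = float(np.sum(x * (y - y.mean())) / sxx)
        n = len(y)
        resid = (y - y.mean()) - beta * x
        df = n - 2
        s2 = float(np.sum(resid ** 2) / df)
        se = np.sqrt(s2 / sxx)
        from scipy.stats import t as t_dist
        tval = beta / se if se > 0 else np.inf
        p = float(2.0 * t_dist.sf(abs(tval), df))
        rows.append({"gene_id": gene, "variant_id": vid, "phenotype": phenotype,
                     "maf": maf, "beta": beta, "p_value": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_level
    return out


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """2x2 odds ratio with Haldane 0.5 correction when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


def _term_pvalues(
    query_mask: np.ndarray, membership: np.ndarray, n_background: int
) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided (enrichment) Fisher p per term, vectorized hypergeometric."""
    q = int(query_mask.sum())
    k = membership @ query_mask            # query genes in each term
    K = membership.sum(axis=1)             # term sizes in background
    p = hypergeom.sf(k - 1, n_background, K, q)
    return p, k


def cohen_kappa(u: np.ndarray, v: np.ndarray) -> float:
    """Cohen's kappa between two binary membership vectors."""
    n = u.size
    po = float(np.mean(u == v))
    pu, pv = float(u.mean()), float(v.mean())
    pe = pu * pv + (1 - pu) * (1 - pv)
    if pe >= 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def go_enrichment(
    query_genes: Sequence[str],
    background_genes: Sequence[str],
    term_to_genes: Mapping[str, Set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    or_threshold: float = 2.0,
    alpha: float = 0.05,
    min_term_size: int = 3,
    kappa_threshold: float = 0.1,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Term enrichment of a query set with min-p permutation adjustment.

    The adjusted p of term t is the fraction of ``n_perm`` random
    same-size queries (drawn from the background) whose minimum raw p
    across all terms is <= the raw p of t (add-one estimator).
    Significant terms require odds ratio > ``or_threshold`` and adjusted
    p < ``alpha``; kappa edges above ``kappa_threshold`` between
    significant terms are returned as the term graph.
    """
    background = list(dict.fromkeys(background_genes))
    query = set(query_genes)
    if not query <= set(background):
        raise ValueError("query must be a subset of the background")
    gene_pos = {g: i for i, g in enumerate(background)}
    n_bg = len(background)

    terms = [t for t, genes in term_to_genes.items()
             if len(set(genes) & set(background)) >= min_term_size]
    n_small = len(term_to_genes) - len(terms)
    if n_small:
        logger.info("excluding %d terms with < %d background genes",
                    n_small, min_term_size)
    if not terms:
        return pd.DataFrame(), pd.DataFrame()
    membership = np.zeros((len(terms), n_bg), dtype=np.int8)
    for ti, t in enumerate(terms):
        for g in term_to_genes[t]:
            if g in gene_pos:
                membership[ti, gene_pos[g]] = 1

    query_mask = np.zeros(n_bg, dtype=np.int8)
    for g in query:
        query_mask[gene_pos[g]] = 1
    p_raw, k = _term_pvalues(query_mask, membership, n_bg)

    rng = np.random.default_rng(seed)
    q = int(query_mask.sum())
    min_ps = np.empty(n_perm)
    for b in range(n_perm):
        perm_mask = np.zeros(n_bg, dtype=np.int8)
        perm_mask[rng.choice(n_bg, size=q, replace=False)] = 1
        pp, _ = _term_pvalues(perm_mask, membership, n_bg)
        min_ps[b] = pp.min()
    p_adj = (1.0 + np.array([(min_ps <= p).sum() for p in p_raw])) / (1.0 + n_perm)

    K = membership.sum(axis=1)
    rows = []
    for ti, t in enumerate(terms):
        a = int(k[ti])                      # query & term
        b_ = int(K[ti]) - a                 # term only
        c = q - a                           # query only
        d = n_bg - q - b_                   # neither
        orr = _odds_ratio(a, b_, c, d)
        rows.append({"term_id": t, "n_query": a, "term_size": int(K[ti]),
                     "odds_ratio": orr, "p_raw": float(p_raw[ti]),
                     "p_adjusted": float(p_adj[ti]),
                     "significant": orr > or_threshold and p_adj[ti] < alpha})
    results = pd.DataFrame(rows).set_index("term_id")

    sig = results.index[results["significant"]].tolist()
    edges = []
    for i in range(len(sig)):
        for j in range(i + 1, len(sig)):
            ui = membership[terms.index(sig[i])]
            vj = membership[terms.index(sig[j])]
            kap = cohen_kappa(ui, vj)
            if kap > kappa_threshold:
                edges.append({"term_a": sig[i], "term_b": sig[j], "kappa": kap})
    return results, pd.DataFrame(edges)
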