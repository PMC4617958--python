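import math

import numpy as np
import pandas as pd
import pytest

from riboreg.normalization import (
    ExpressionSet,
    cpm,
    cpm_filter,
    tmm_factors,
    voom_transform,
)


def _expr(counts: np.ndarray, n_ind=None, reps=2) -> ExpressionSet:
    genes = [f"g{i}" for i in range(counts.shape[0])]
    n_lib = counts.shape[1]
    half = n_lib // 2
    rows = []
    for j in range(n_lib):
        assay = "rna" if j < half else "ribo"
        ind = f"i{j % max(n_ind or half, 1)}"
        rows.append((f"lib{j}", ind, assay, 1))
    samples = pd.DataFrame(rows, columns=["library_id", "individual", "assay",
                                          "replicate"]).set_index("library_id")
    return ExpressionSet(pd.DataFrame(counts, index=genes,
                                      columns=samples.index), samples)


def _nb_counts(rng, n_genes=400, n_lib=12, phi=0.05):
    mu_g = 2.0 ** rng.normal(7, 1.5, n_genes)
    lib_scale = rng.uniform(0.5, 1.5, n_lib)
    mean = mu_g[:, None] * lib_scale[None, :]
    size = 1.0 / phi
    return rng.negative_binomial(size, size / (size + mean))


class TestCpmFilter:
    def test_zero_count_gene_dropped_and_expressed_gene_kept(self, rng):
        counts = _nb_counts(rng, n_genes=50)
        counts[0] = 0
        expr = _expr(counts)
        out = cpm_filter(expr)
        assert "g0" not in out.counts.index
        high = (cpm(expr.counts) > 1).all(axis=1)
        assert set(expr.counts.index[high]) <= set(out.counts.index)

    def test_matches_brute_force_rule(self, rng):
        counts = _nb_counts(rng, n_genes=1000)
        counts[rng.random(counts.shape) < 0.3] = 0
        expr = _expr(counts)
        out = cpm_filter(expr)
        # independent recomputation, straight from the rule's definition
        c = counts / counts.sum(axis=0, keepdims=True) * 1e6
        rna_cols = np.array([a == "rna" for a in expr.samples["assay"]])
        k_rna = math.ceil(0.9 * rna_cols.sum())
        k_ribo = math.ceil(0.9 * (~rna_cols).sum())
        keep = (((c[:, rna_cols] > 1).sum(axis=1) >= k_rna)
                & ((c[:, ~rna_cols] > 1).sum(axis=1) >= k_ribo))
        assert list(out.counts.index) == [f"g{i}" for i in np.flatnonzero(keep)]

    def test_threshold_above_library_count_errors(self, rng):
        expr = _expr(_nb_counts(rng, n_genes=20, n_lib=6))
        with pytest.raises(ValueError):
            cpm_filter(expr, min_libraries_rna=10)


def _tmm_oracle(counts: np.ndarray, trim_m=0.30, trim_a=0.05) -> np.ndarray:
    """Literal transcription of the TMM definition, written independently
    (sorting-based trims instead of ranks)."""
    lib = counts.sum(axis=0).astype(float)
    f75 = np.quantile(counts.astype(float), 0.75, axis=0) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = []
    for j in range(counts.shape[1]):
        o = counts[:, j].astype(float)
        r = counts[:, ref].astype(float)
        keep = (o > 0) & (r > 0)
        o, r = o[keep], r[keep]
        m = np.log2((o / lib[j]) / (r / lib[ref]))
        a = 0.5 * (np.log2(o / lib[j]) + np.log2(r / lib[ref]))
        v = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
        if m.size == 0 or np.max(np.abs(m)) < 1e-6:
            factors.append(1.0)
            continue
        n = m.size
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        from scipy.stats import rankdata
        rm, ra = rankdata(m), rankdata(a)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        factors.append(2.0 ** (np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])))
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        counts = np.tile(np.arange(1, 101)[:, None], (1, 6))
        f = tmm_factors(_expr(counts))
        assert np.allclose(f, 1.0)

    def test_scaled_copy_of_reference_normalizes_out(self, rng):
        base = rng.integers(1, 2000, size=300)
        counts = np.column_stack([base] * 5 + [2 * base])
        f = tmm_factors(_expr(counts))
        # doubling a library's depth changes no M value, so factors stay 1
        assert np.allclose(f, 1.0, atol=1e-8)

    def test_matches_independent_transcription(self, rng):
        counts = _nb_counts(rng, n_genes=800, n_lib=10)
        f = tmm_factors(_expr(counts)).to_numpy()
        assert np.allclose(f, _tmm_oracle(counts), atol=1e-10)

    def test_invariant_to_global_rescaling(self, rng):
        counts = _nb_counts(rng, n_genes=300, n_lib=8)
        f1 = tmm_factors(_expr(counts)).to_numpy()
        f2 = tmm_factors(_expr(counts * 3)).to_numpy()
        assert np.allclose(f1, f2, atol=1e-9)

    def test_geometric_mean_is_one(self, rng):
        counts = _nb_counts(rng, n_genes=300, n_lib=9)
        f = tmm_factors(_expr(counts)).to_numpy()
        assert abs(np.exp(np.mean(np.log(f))) - 1.0) < 1e-8

    def test_all_zero_library_errors(self):
        counts = np.ones((10, 4), dtype=int)
        counts[:, 2] = 0
        with pytest.raises(ValueError):
            tmm_factors(_expr(counts))


class TestVoom:
    def test_constant_counts_give_equal_capped_weights(self):
        counts = np.full((30, 8), 500)
        expr = voom_transform(_expr(counts, n_ind=2))
        w = expr.weights.to_numpy()
        assert np.allclose(w, w[0, 0])
        assert w[0, 0] > 1e4  # at the zero-noise cap

    def test_weights_positive_and_finite(self, rng):
        expr = voom_transform(_expr(_nb_counts(rng), n_ind=3))
        w = expr.weights.to_numpy()
        assert np.all(np.isfinite(w)) and np.all(w > 0)

    def test_logcpm_monotone_in_counts_within_library(self, rng):
        expr = voom_transform(_expr(_nb_counts(rng, n_genes=200), n_ind=3))
        counts0 = expr.counts.iloc[:, 0].to_numpy()
        log0 = expr.logcpm.iloc[:, 0].to_numpy()
        order = np.argsort(counts0)
        assert np.all(np.diff(log0[order]) >= 0)

    def test_mean_variance_trend_decreasing_on_nb_data(self, rng):
        counts = _nb_counts(rng, n_genes=2000, n_lib=12)
        expr = voom_transform(_expr(counts, n_ind=3))
        # reconstruct the fitted trend: weight^(-1/4) vs fitted log-count
        lib = expr.counts.sum(axis=0).to_numpy() * expr.norm_factors.to_numpy()
        logcount = expr.logcpm.to_numpy() + np.log2(lib + 1)[None, :] - np.log2(1e6)
        pred_sqrt_sd = expr.weights.to_numpy() ** -0.25
        x, y = logcount.ravel(), pred_sqrt_sd.ravel()
        qs = np.quantile(x, [0.1, 0.9])
        lo = y[x < qs[0]].mean()
        hi = y[x > qs[1]].mean()
        assert hi < lo  # noise falls with abundance

    def test_weights_stable_under_depth_doubling(self, rng):
        counts = _nb_counts(rng, n_genes=800, n_lib=12)
        w1 = voom_transform(_expr(counts, n_ind=3)).weights.to_numpy()
        w2 = voom_transform(_expr(counts * 2, n_ind=3)).weights.to_numpy()
        ratio = np.log(w2 / w1)
        assert np.median(np.abs(ratio)) < 0.2
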