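import numpy as np
import pytest

from riboreg import normalization, variance_decomposition
from riboreg.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Default-condition study at a small transcript count."""
    cfg = SimulationConfig(seed=7, n_transcripts=60, n_individuals=20)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def voomed(small_study):
    expr = normalization.cpm_filter(small_study["expression"])
    return normalization.voom_transform(expr)


@pytest.fixture(scope="session")
def recovery_study():
    """Study with planted variability classes (individual sd about twice
    the replicate noise), no planted variant effects; shared by the
    variance-recovery and correlation-stratification tests."""
    cfg = SimulationConfig(
        seed=11, n_transcripts=300, n_individuals=28,
        frac_genes_rna_variable=0.10, frac_genes_ro_variable=0.10,
        frac_genes_both_variable=0.10,
        planted_uorf_event_types=(), n_kozak_variants=0, n_eqtl=0,
    )
    study = simulate_study(cfg)
    study["expr"] = normalization.voom_transform(
        normalization.cpm_filter(study["expression"]))
    return study


@pytest.fixture(scope="session")
def recovery_classes(recovery_study):
    expr = recovery_study["expr"]
    res_rna = variance_decomposition.varcomp_scan(expr, "rna", n_sim=8000,
                                                  seed=101)
    res_ribo = variance_decomposition.varcomp_scan(expr, "ribo", n_sim=8000,
                                                   seed=102)
    classes = variance_decomposition.classify_variability(res_rna, res_ribo)
    return res_rna, res_ribo, classes


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
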