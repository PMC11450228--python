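import numpy as np
import pytest

from fibreggp import (
    simulate_annotation,
    simulate_coexpression,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def annotation():
    return simulate_annotation(n_genes=120, n_chrom=2, seed=5)


@pytest.fixture(scope="session")
def panel(annotation):
    return simulate_genotypes(annotation, n_lines=300, snps_per_gene_mean=2.0,
                              intergenic_snp_rate=2.0, seed=6)


@pytest.fixture(scope="session")
def expr_truth(annotation):
    return simulate_coexpression(annotation, n_modules=4, module_size=15,
                                 de_fraction=0.4, lfc_magnitude=3.0,
                                 dispersion=0.05, seed=7)


@pytest.fixture(scope="session")
def pheno(panel, expr_truth):
    _, truth = expr_truth
    rng = np.random.default_rng(8)
    causal = sorted(rng.choice(panel.snp_ids, size=25, replace=False))
    return simulate_phenotypes(panel, truth, causal, h2=0.5, seed=9)
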