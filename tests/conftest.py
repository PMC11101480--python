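"""Shared fixtures: the default seeded bundle and derived pipeline objects.

Everything is generated programmatically at test time; session scope keeps
the expensive default-size bundle and the six trained models to one build.
"""

from __future__ import annotations

import numpy as np
import pytest

from emtridge.model_concordance import concordance_matrix, select_models
from emtridge.plasticity_ridge import train_phenotype_model
from emtridge.preprocess import expression_filter, variance_filter
from emtridge.synthetic_data import GeneratorConfig, generate_bundle

CONCORDANT = ("morphology", "CDH2", "ZEB1")
DISCORDANT = ("CD24", "CXCR4", "VIM")


@pytest.fixture(scope="session")
def default_bundle():
    """The default study-sized cohort (seed 0)."""
    return generate_bundle(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def small_config():
    """A fast, small cohort for structural tests."""
    return GeneratorConfig(
        n_genes=2000,
        n_informative=300,
        n_patients=40,
        tf_regulon_size=80,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def selected_genes(default_bundle):
    expressed = expression_filter(
        default_bundle.cellline_expression, default_bundle.patient_expression
    )
    return variance_filter(default_bundle.cellline_expression, expressed)


@pytest.fixture(scope="session")
def trained_models(default_bundle, selected_genes):
    return [
        train_phenotype_model(
            default_bundle.cellline_expression,
            default_bundle.phenotypes,
            name,
            selected_genes,
        )
        for name in default_bundle.phenotypes.phenotype_names
    ]


@pytest.fixture(scope="session")
def default_selection(trained_models, default_bundle):
    matrix = concordance_matrix(trained_models, default_bundle.phenotypes)
    return select_models(matrix)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240517)
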