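"""Shared fixtures: one canonical synthetic study plus cheap small variants.

The canonical bundle uses the generator defaults (n=2000 healthy, 200
patients, seed 0) and is computed once per session together with the fitted
normative model, deviation scores, cell-type map, and coupling matrix, so
the expensive stages are shared across test modules.
"""

from __future__ import annotations

import warnings

import pytest

from corticell import (
    build_cell_map,
    compute_coupling,
    deviation_scores,
    fit_normative_model,
)
from corticell.simulate import SimConfig, gen_fixture_bundle

CANONICAL_SEED = 0

#: cell types carrying planted coupling in the default subtype configuration
PLANTED_CELL_TYPES = ["astrocyte", "endothelial", "OPC", "excitatory", "inhibitory"]


@pytest.fixture(scope="session")
def default_bundle():
    return gen_fixture_bundle(SimConfig(seed=CANONICAL_SEED))


@pytest.fixture(scope="session")
def default_model(default_bundle):
    return fit_normative_model(default_bundle.healthy)


@pytest.fixture(scope="session")
def default_deviations(default_model, default_bundle):
    return deviation_scores(default_model, default_bundle.patients)


@pytest.fixture(scope="session")
def default_map(default_bundle):
    return build_cell_map(default_bundle.expression, default_bundle.gene_sets)


@pytest.fixture(scope="session")
def default_coupling(default_deviations, default_map):
    return compute_coupling(default_deviations.delta_z, default_map)


@pytest.fixture()
def small_config():
    """Cheap configuration for structural (non-statistical) checks."""
    return SimConfig(
        n_healthy=120,
        n_patient=60,
        n_genes=220,
        markers_per_celltype=10,
        n_snps=300,
        n_family_pairs=6,
        seed=11,
    )


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        yield
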