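"""Shared fixtures.

The expensive ensembles (the self-renewing ESC culture at the shipped
slow-Nanog parameter point, and its two-allele variant) are session-scoped
and shared between the behavioural tests and the acceptance suite.  Sizes
are desk-scale: a few hundred cells for a few simulated days after burn-in,
which is enough for modality and fraction checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from escdyn import DAY, build_default_network, load_config, run_ensemble


@pytest.fixture(scope="session")
def default_network():
    return build_default_network()


@pytest.fixture(scope="session")
def default_params():
    """The shipped parameter set, loaded through the config layer."""
    return load_config().params


@pytest.fixture(scope="session")
def esc_ensemble(default_network, default_params):
    """Slow-Nanog ESC culture: 200 cells, 3 recorded days after burn-in."""
    return run_ensemble(
        default_network, default_params, n_cells=200, duration=3 * DAY,
        base_seed=101, burn_in=8 * DAY,
    )


@pytest.fixture(scope="session")
def esc_ensemble_small(default_network, default_params):
    """A cheaper 30-cell ESC ensemble for mean-level checks."""
    return run_ensemble(
        default_network, default_params, n_cells=30, duration=3 * DAY,
        base_seed=202, burn_in=8 * DAY,
    )


@pytest.fixture(scope="session")
def two_allele_ensemble(default_params):
    """Both Nanog alleles dynamic (allelic regulation invalidated)."""
    net = build_default_network(nanog_alleles=2)
    return run_ensemble(
        net, default_params, n_cells=100, duration=3 * DAY,
        base_seed=303, burn_in=8 * DAY,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
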