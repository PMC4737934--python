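"""Shared fixtures: small communities and cached simulation runs.

Heavy simulations are session-scoped so that module tests and the
acceptance suite reuse the same runs instead of regenerating them.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from epicpcr.construct import DEFAULT_CONSTRUCT
from epicpcr.pipeline import run_spikein_experiment
from epicpcr.simulate import (
    SimConfig,
    make_default_community,
    make_default_controls,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def construct():
    return DEFAULT_CONSTRUCT


@pytest.fixture(scope="session")
def community():
    return make_default_community(n_taxa=12, frac_with_target=0.25, seed=7)


@pytest.fixture(scope="session")
def controls():
    return make_default_controls()


@pytest.fixture(scope="session")
def clean_sim(community):
    """Error-free target-assay run: no sequencing error, no artifacts."""
    cfg = SimConfig(
        seed=11,
        n_droplets=3000,
        assay="target16s",
        subst_error_rate=0.0,
        degraded_frac=0.0,
        chimera_rate=0.0,
        partial_fusion_rate=0.1,
    )
    return simulate_experiment(community, cfg)


@pytest.fixture(scope="session")
def barcode_sim(community):
    """Barcode-assay run with defaults (errors, partials, skew, chimeras)."""
    cfg = SimConfig(seed=13, n_droplets=3000, assay="barcode16s")
    return simulate_experiment(community, cfg)


@pytest.fixture(scope="session")
def spikein_10k():
    """The full two-assay spike-in experiment at 10^4 droplets."""
    return run_spikein_experiment(seed=5, n_droplets=10_000)
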