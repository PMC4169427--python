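"""Shared fixtures: small ensembles and the surrogate study potential.

Heavier simulation products used by several tests are session-scoped so the
Brownian runs are paid for once.
"""

from __future__ import annotations

import pytest

from aspull import surrogate
from aspull.potentials import PotentialSpec
from aspull.protocols import ProtocolSpec
from aspull.simulator import SimulationConfig, run_ensemble


@pytest.fixture(scope="session")
def double_well() -> PotentialSpec:
    return surrogate.default_potential()


@pytest.fixture(scope="session")
def flat_potential() -> PotentialSpec:
    return PotentialSpec(form="flat", domain=(-50.0, 150.0))


@pytest.fixture(scope="session")
def small_fast_ensemble(double_well):
    """50-trajectory fast normal-pulling ensemble on the study fixture."""
    return surrogate.run_normal(surrogate.fast_config(50), seed=421)


@pytest.fixture(scope="session")
def tiny_flat_config() -> SimulationConfig:
    """Cheap schedule on a flat potential (21 samples, 50 sub-steps each)."""
    return SimulationConfig(
        dt_fs=2.0, D_m2s=3.5e-9, k_pN_A=500.0, v_ms=100.0, L_A=2.0,
        n_samples=21, T_K=300.0, n_traj=64, x0_A=10.0, equil_steps=200,
    )


@pytest.fixture(scope="session")
def flat_fast_ensemble(flat_potential, tiny_flat_config):
    return run_ensemble(flat_potential, tiny_flat_config, ProtocolSpec(kind="normal"), seed=7)


@pytest.fixture(scope="session")
def slow_reference_estimate():
    """Referent run: 100x slower pulling, weighted-histogram estimate."""
    return surrogate.slow_reference(seed=1234)


@pytest.fixture(scope="session")
def protocol_study():
    """FM vs normal pulling at equal cost, 5 independent pipeline seeds."""
    comps = [surrogate.protocol_comparison(3000 + 211 * s, kinds=("normal", "fm"))
             for s in range(5)]
    return comps
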