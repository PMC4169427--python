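"""Unit conversions for the reduced simulation unit system.

Internally everything runs in Angstrom (length), femtosecond (time) and
k_BT at the configured temperature (energy).  Published pulling parameters
are usually quoted in a mixture of SI and molecular-dynamics units
(velocities in m/s, spring constants in pN/A, diffusion coefficients in
m^2/s), so all user-facing entry points accept those and convert here.
"""

from __future__ import annotations

KB_J_PER_K = 1.380649e-23
"""Boltzmann constant in J/K."""

DEFAULT_TEMPERATURE_K = 300.0
"""Room temperature default used throughout the package."""


def kbt_joules(T_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """k_BT in joules at temperature ``T_K``."""
    if T_K <= 0:
        raise ValueError(f"temperature must be positive, got {T_K}")
    return KB_J_PER_K * T_K


def diffusion_m2s_to_A2fs(D_m2s: float) -> float:
    """Convert a diffusion coefficient from m^2/s to A^2/fs."""
    # 1 m^2 = 1e20 A^2, 1 s = 1e15 fs
    return D_m2s * 1e5


def velocity_ms_to_Afs(v_ms: float) -> float:
    """Convert a pulling velocity from m/s to A/fs."""
    return v_ms * 1e-5


def spring_pNA_to_kbtA2(k_pN_per_A: float, T_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Convert a spring constant from pN/A to k_BT/A^2.

    1 pN*A = 1e-22 J, so k[pN/A] * 1e-22 / (k_B T) gives k_BT/A^2.
    """
    return k_pN_per_A * 1e-22 / kbt_joules(T_K)


def energy_kbt_to_pNA(E_kbt: float, T_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Convert an energy from k_BT to pN*A."""
    return E_kbt * kbt_joules(T_K) / 1e-22
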