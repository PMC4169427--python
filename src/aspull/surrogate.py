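"""Desk-scale surrogate study: a rugged double well pulled fast and slow.

This module freezes the package's reference study conditions: a quartic
double well with a 20 k_BT central barrier, decorated with a 2 k_BT cosine
corrugation of 2 A wavelength that mimics the small-scale ruggedness (and
hence the pathway heterogeneity and fat-tailed work statistics) of real
molecular free-energy profiles.  The particle is pulled over 16 A between
the two minima with the published spring stiffness (500 pN/A), diffusion
coefficient (3.5e-9 m^2/s) and time step (2 fs).

Fast pulling at 25 m/s dissipates ~20 k_BT and leaves a multi-k_BT
Jarzynski bias at 200 trajectories -- the regime the adaptive protocols are
designed for.  The referent profile comes from 100x slower pulling
(0.25 m/s, 120 trajectories) reconstructed with the weighted-histogram
formula; it is deliberately far more expensive than any production run
(the equivalent of ~12,000 fast trajectories) because everything else is
judged against it.

The full adaptive pipeline (pilot runs -> bias prediction -> guiding curve
-> amplitude calibration -> modulated production runs -> quality metrics)
is wired together here so tests, scripts and the command line can run the
whole study from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Sequence

import numpy as np

from . import bias_analysis, calibration, estimators, metrics
from .bias_analysis import VNoiseCurve
from .potentials import PotentialSpec, reference_pmf
from .protocols import ProtocolSpec
from .simulator import SimulationConfig, WorkEnsemble, run_ensemble

FAST_VELOCITY_MS = 25.0
SLOW_VELOCITY_MS = 0.25
N_SAMPLES = 81
N_TRAJ_PRODUCTION = 200
N_TRAJ_PILOT_BIAS = 100
N_PILOT_RECONSTRUCTIONS = 5
N_TRAJ_PER_PILOT = 10
N_TRAJ_REFERENCE = 120


def default_potential() -> PotentialSpec:
    """The rugged double-well fixture (barrier ~20 k_BT over 16 A)."""
    return PotentialSpec(
        form="double_well",
        parameters={
            "r_left": 2.0,
            "r_right": 18.0,
            "height": 20.0,
            "corrugation_height": 2.0,
            "corrugation_wavelength": 2.0,
        },
        domain=(-10.0, 30.0),
    )


def fast_config(n_traj: int = N_TRAJ_PRODUCTION) -> SimulationConfig:
    return SimulationConfig(
        dt_fs=2.0, D_m2s=3.5e-9, k_pN_A=500.0, v_ms=FAST_VELOCITY_MS,
        L_A=16.0, n_samples=N_SAMPLES, T_K=300.0, n_traj=n_traj, x0_A=2.0,
        equil_steps=2000,
    )


def slow_config(n_traj: int = N_TRAJ_REFERENCE, v_ms: float = SLOW_VELOCITY_MS) -> SimulationConfig:
    return replace(fast_config(n_traj), v_ms=v_ms)


def reference_profile(grid=None) -> np.ndarray:
    cfg = fast_config()
    g = cfg.grid if grid is None else grid
    return reference_pmf(default_potential(), g)


def run_normal(config: SimulationConfig, seed: int) -> WorkEnsemble:
    return run_ensemble(default_potential(), config, ProtocolSpec(kind="normal"), seed)


def slow_reference(seed: int, n_traj: int = N_TRAJ_REFERENCE) -> estimators.PMFEstimate:
    """Referent PMF estimate: slow pulling + weighted-histogram reconstruction."""
    ens = run_normal(slow_config(n_traj), seed)
    return estimators.jarzynski_pmf(ens, mode="wham")


@dataclass(frozen=True)
class PilotAnalysis:
    """Outputs of the cheap pilot stage of the adaptive pipeline."""

    mean_work_bias: float
    jarzynski_bias: float
    v_noise: VNoiseCurve
    amplitude: float
    n_substeps: int


def pilot_analysis(seed: int, mode: str = "jarzynski") -> PilotAnalysis:
    """Pilot stage: predict the mean-work bias, build V_noise, calibrate m.

    Runs one 100-trajectory fast ensemble for the bias prediction (the
    multi-cutoff fluctuation predictor applied to the weighted-histogram
    reconstruction, plus the mean-work / Jarzynski gap) and five
    10-trajectory ensembles for the guiding curve.  The noise amplitude is
    obtained by inverting the effective-work relation with the measured
    run average of the guiding curve as modulation factor.
    """
    cfg = fast_config(N_TRAJ_PILOT_BIAS)
    ens = run_normal(cfg, seed)
    est_wham = estimators.jarzynski_pmf(ens, mode="wham")
    est_stiff = estimators.jarzynski_pmf(ens, mode="stiff_spring")
    mean_prof = estimators.mean_work_profile(ens)
    b_j = bias_analysis.max_bias_predictor(est_wham, cfg.n_traj)
    b_mw = bias_analysis.mean_work_bias(
        b_j, mean_prof.values[-1], est_stiff.values[-1]
    )
    pilots = [
        estimators.jarzynski_pmf(
            run_normal(fast_config(N_TRAJ_PER_PILOT), seed + 1 + i), mode="wham"
        )
        for i in range(N_PILOT_RECONSTRUCTIONS)
    ]
    # the guiding-curve smoothing cutoff is quoted for 500-point
    # reconstructions; rescale it so the same physical wavelengths pass on
    # this grid resolution
    smooth_cutoff = 0.004 * 500.0 / cfg.n_samples
    v_noise = bias_analysis.build_v_noise(pilots, smooth_cutoff=smooth_cutoff)
    n = cfg.n_substeps
    m = calibration.amplitude_for_bias(
        b_mw,
        mode,
        k_pN_A=cfg.k_pN_A,
        D_m2s=cfg.D_m2s,
        dt_fs=cfg.dt_fs,
        n=n,
        T_K=cfg.T_K,
        modulation_factor=v_noise.average() ** 2,
    )
    return PilotAnalysis(
        mean_work_bias=b_mw, jarzynski_bias=b_j, v_noise=v_noise,
        amplitude=m, n_substeps=n,
    )


def run_protocol(
    kind: str,
    seed: int,
    pilot: PilotAnalysis,
    n_traj: int = N_TRAJ_PRODUCTION,
    noise_distribution: str = "gaussian",
) -> WorkEnsemble:
    """Production run under one of the four pulling protocols."""
    protocol = ProtocolSpec(
        kind=kind,
        noise_distribution=noise_distribution,
        m=0.0 if kind == "normal" else pilot.amplitude,
        v_noise=pilot.v_noise if kind in ("am", "fm") else None,
    )
    return run_ensemble(default_potential(), fast_config(n_traj), protocol, seed)


def protocol_comparison(
    seed: int,
    kinds: Sequence[str] = ("normal", "fm"),
    n_traj: int = N_TRAJ_PRODUCTION,
    estimator_mode: str = "stiff_spring",
) -> Dict[str, float]:
    """Relative RMSD (percent of barrier height) per protocol at equal cost.

    One pilot stage is shared by all protocols (its cost -- 150
    trajectories -- is the pipeline's fixed overhead, small next to the
    production ensembles it steers).
    """
    pilot = pilot_analysis(seed)
    ref = reference_profile()
    out: Dict[str, float] = {}
    for kind in kinds:
        ens = run_protocol(kind, seed + 1000, pilot, n_traj=n_traj)
        est = estimators.jarzynski_pmf(ens, mode=estimator_mode)
        out[kind] = metrics.relative_rmsd(est, ref)
    return out
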