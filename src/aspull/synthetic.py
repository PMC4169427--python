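"""Synthetic work-ensemble generator.

Produces work matrices with prescribed slice-wise statistics, without
running any dynamics.  Used by estimator and bias-analysis tests where the
exact per-slice work law must be known in closed form, and as a stand-in
for measured steered-pulling work data.  Real pulling work distributions
are rarely ideal Gaussians -- they develop fat tails under fast
perturbation -- hence the skewed (offset-gamma) law option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .simulator import WorkEnsemble

_LAWS = ("gaussian", "skewed")


@dataclass(frozen=True)
class SyntheticWorkSpec:
    """Slice-wise law for a synthetic work ensemble.

    ``mean_drift`` and ``sd_profile`` give the per-slice mean and standard
    deviation of the accumulated work (k_BT); slice 0 is always exactly 0
    regardless of the profiles.  The ``skewed`` law adds positive skewness
    via a standardised offset-gamma deviate (``skewness = 2/sqrt(shape)``).
    """

    law: str
    mean_drift: np.ndarray
    sd_profile: np.ndarray
    n_traj: int
    seed: int
    gamma_shape: float = 4.0
    grid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.law not in _LAWS:
            raise ValueError(f"law must be one of {_LAWS}")
        mean = np.asarray(self.mean_drift, dtype=float)
        sd = np.asarray(self.sd_profile, dtype=float)
        if mean.shape != sd.shape or mean.ndim != 1:
            raise ValueError("mean_drift and sd_profile must be 1-D of equal length")
        if np.any(sd < 0):
            raise ValueError("sd_profile must be non-negative")
        if self.n_traj < 1:
            raise ValueError("n_traj must be positive")
        if self.law == "skewed" and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        object.__setattr__(self, "mean_drift", mean)
        object.__setattr__(self, "sd_profile", sd)


def synth_work_ensemble(spec: SyntheticWorkSpec) -> WorkEnsemble:
    """Draw an independent per-trajectory, per-slice synthetic work ensemble."""
    rng = np.random.default_rng(spec.seed)
    n_s = len(spec.mean_drift)
    if spec.law == "gaussian":
        eps = rng.standard_normal((spec.n_traj, n_s))
    else:
        a = spec.gamma_shape
        eps = (rng.gamma(a, 1.0, size=(spec.n_traj, n_s)) - a) / np.sqrt(a)
    works = spec.mean_drift + spec.sd_profile * eps
    works[:, 0] = 0.0
    grid = np.asarray(spec.grid, dtype=float) if spec.grid is not None else np.arange(n_s, dtype=float)
    positions = np.broadcast_to(grid, works.shape).copy()
    return WorkEnsemble(works=works, positions=positions, grid=grid)
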