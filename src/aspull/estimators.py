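"""PMF reconstruction from nonequilibrium work ensembles.

Three averaging schemes are provided, all anchored to 0 at the first grid
point:

* the exponential (Jarzynski) work average, either in the stiff-spring
  shortcut form

      G0(x_j) = -(1/beta) * ln < exp(-beta W(t_j)) > ,

  valid when the hard pulling spring keeps the particle on the schedule, or
  in the full weighted-histogram form of Hummer and Szabo which combines
  exp(-beta W)-weighted position histograms across time slices and removes
  the instantaneous deflection potential V(x, t) = (1/2) k (x_t - x)**2:

      exp(-beta G0(x)) =
          sum_t < delta(x - r_t) e^{-beta W_t} > / < e^{-beta W_t} >
          -----------------------------------------------------------
          sum_t  e^{-beta V(x, t)} / < e^{-beta W_t} > ;

* the second-order cumulant expansion
  G0 = <W> - (beta/2) (<W**2> - <W>**2), exact for Gaussian work;

* the plain mean-work profile (an upper bound by Jensen's inequality).

All exponential averages are evaluated in log space (log-sum-exp); naive
exponentiation of tens of k_BT would overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .simulator import WorkEnsemble

ESTIMATORS = ("jarzynski_wham", "jarzynski_stiff", "cumulant2", "mean_work")


@dataclass(frozen=True)
class PMFEstimate:
    """A reconstructed free-energy profile on the sampling grid."""

    grid: np.ndarray
    values: np.ndarray
    estimator: str
    n_traj: int
    beta: float = 1.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if g.shape != v.shape or g.ndim != 1:
            raise ValueError("grid and values must be 1-D arrays of equal length")
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")
        if abs(v[0]) > 1e-9:
            raise ValueError("PMF estimates are anchored: values[0] must be 0")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "values", v)


def _check(ensemble: WorkEnsemble, min_traj: int = 1) -> None:
    if ensemble.n_traj < min_traj:
        raise ValueError(f"need at least {min_traj} trajectories, got {ensemble.n_traj}")
    if not np.all(np.isfinite(ensemble.works)):
        raise ValueError("work matrix contains non-finite entries")


def mean_work_profile(ensemble: WorkEnsemble, beta: float = 1.0) -> PMFEstimate:
    """Arithmetic mean of the accumulated work per grid point."""
    _check(ensemble)
    prof = ensemble.works.mean(axis=0)
    return PMFEstimate(ensemble.grid, prof - prof[0], "mean_work", ensemble.n_traj, beta)


def jarzynski_pmf(ensemble: WorkEnsemble, mode: str = "stiff_spring", beta: float = 1.0) -> PMFEstimate:
    """Exponential-average PMF reconstruction.

    ``mode='stiff_spring'`` applies the work-only shortcut per grid point;
    ``mode='wham'`` evaluates the weighted-histogram formula on the
    sampling grid (bin centres = grid points, bin width = grid spacing;
    empty bins are excluded from the log and filled by linear
    interpolation).
    """
    _check(ensemble)
    if mode == "stiff_spring":
        W = ensemble.works
        n = W.shape[0]
        g = -(logsumexp(-beta * W, axis=0) - np.log(n)) / beta
        return PMFEstimate(ensemble.grid, g - g[0], "jarzynski_stiff", n, beta)
    if mode != "wham":
        raise ValueError("mode must be 'stiff_spring' or 'wham'")
    return _wham(ensemble, beta)


def _wham(ensemble: WorkEnsemble, beta: float) -> PMFEstimate:
    if ensemble.config is None:
        raise ValueError("wham mode needs the simulation config (spring constant)")
    k = ensemble.config.k
    grid = ensemble.grid
    W = ensemble.works
    pos = ensemble.positions
    n_traj, n_s = W.shape
    dx = grid[1] - grid[0]
    edges = np.concatenate([grid - dx / 2.0, [grid[-1] + dx / 2.0]])
    # a global work shift cancels after anchoring but keeps exponentials tame
    Wsh = beta * (W - np.median(W))
    ew = np.exp(-Wsh)
    mean_ew = ew.mean(axis=0)
    num = np.zeros(n_s)
    den = np.zeros(n_s)
    for t in range(n_s):
        hist, _ = np.histogram(pos[:, t], bins=edges, weights=ew[:, t])
        num += hist / (n_traj * mean_ew[t])
        den += np.exp(-beta * 0.5 * k * (grid[t] - grid) ** 2) / mean_ew[t]
    with np.errstate(divide="ignore", invalid="ignore"):
        g = -np.log(num / den) / beta
    finite = np.isfinite(g)
    if not finite.any():
        raise ValueError("wham reconstruction empty: no visited bins")
    if not finite.all():
        g[~finite] = np.interp(grid[~finite], grid[finite], g[finite])
    g = g - g[0]
    return PMFEstimate(grid, g, "jarzynski_wham", n_traj, beta)


def cumulant_pmf(ensemble: WorkEnsemble, beta: float = 1.0) -> PMFEstimate:
    """Second-order cumulant expansion G0 = <W> - (beta/2) Var(W).

    Smooth by construction (no filtering needed): only the slowly varying
    mean and variance of the work enter, the distribution tails do not.
    """
    _check(ensemble, min_traj=2)
    W = ensemble.works
    mean = W.mean(axis=0)
    var = W.var(axis=0)
    g = mean - 0.5 * beta * var
    return PMFEstimate(ensemble.grid, g - g[0], "cumulant2", W.shape[0], beta)


def reconstruct(ensemble: WorkEnsemble, estimator: str, beta: float = 1.0,
                mode: Optional[str] = None) -> PMFEstimate:
    """Dispatch by estimator name: jarzynski / cumulant / mean."""
    if estimator == "jarzynski":
        return jarzynski_pmf(ensemble, mode=mode or "stiff_spring", beta=beta)
    if estimator == "cumulant":
        return cumulant_pmf(ensemble, beta=beta)
    if estimator == "mean":
        return mean_work_profile(ensemble, beta=beta)
    raise ValueError("estimator must be 'jarzynski', 'cumulant' or 'mean'")
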