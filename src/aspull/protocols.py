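"""Pulling-point laws and noise distributions.

Four pulling protocols are implemented:

``normal``
    Plain constant-velocity pulling; the pulling point moves
    deterministically, x(t) = x0 + v*t.
``constant_noise``
    Constant-velocity pulling plus zero-mean jitter of the pulling point at
    every integration sub-step, with constant standard deviation
    sigma_x = m * sigma_r.
``am`` (amplitude modulation)
    The jitter SD is modulated along the path by the guiding curve:
    sigma_x(t) = m * sigma_r * V_noise(t).  Injected noise energy scales
    with V_noise**2.
``fm`` (frequency modulation)
    Full-amplitude jitter is gated stochastically: at each sub-step a
    uniform deviate R is drawn and the noise applied only if R <= V_noise.
    Injected noise energy scales linearly with V_noise.

In every stochastic protocol the jitter is omitted at the very sampling
moments, so the recorded work always refers to the deterministic
pulling-point position and the reconstruction grid stays exact.

Two jitter distributions are available: Gaussian, and a "chi-inducing"
density chosen such that the quadratic spring work of the offset follows a
(non-negative-support) normal-form density -- the distribution needed for
the second-order cumulant expansion to stay unbiased at high noise
amplitude.  The chi-inducing draws are produced by rejection sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .bias_analysis import VNoiseCurve

_KINDS = ("normal", "constant_noise", "am", "fm")
_DISTRIBUTIONS = ("gaussian", "chi_inducing")


@dataclass(frozen=True)
class ProtocolSpec:
    """Pulling-schedule noise law.

    Parameters
    ----------
    kind:
        One of ``normal``, ``constant_noise``, ``am``, ``fm``.
    noise_distribution:
        ``gaussian`` or ``chi_inducing``.
    m:
        Noise multiplication factor (jitter SD in units of sigma_r).
        Ignored for ``normal``.
    v_noise:
        Guiding curve; required for ``am`` and ``fm``.
    """

    kind: str = "normal"
    noise_distribution: str = "gaussian"
    m: float = 0.0
    v_noise: Optional[VNoiseCurve] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}; choose from {_KINDS}")
        if self.noise_distribution not in _DISTRIBUTIONS:
            raise ValueError(f"noise_distribution must be one of {_DISTRIBUTIONS}")
        if self.m < 0:
            raise ValueError("noise amplitude m must be non-negative")
        if self.kind in ("am", "fm") and self.v_noise is None:
            raise ValueError(f"protocol kind {self.kind!r} requires a v_noise curve")


def deterministic_position(x0_A: float, v_Afs: float, dt_fs: float, j_substep: int) -> float:
    """Deterministic pulling-point position x0 + v * j * dt (A)."""
    if j_substep < 0:
        raise ValueError("j_substep must be non-negative")
    return x0_A + v_Afs * dt_fs * j_substep


def sample_pulling_noise_gaussian(sigma_x_A: float, rng: np.random.Generator, size=None):
    """Zero-mean Gaussian pulling-point offset(s) with SD ``sigma_x_A``."""
    if sigma_x_A < 0:
        raise ValueError("sigma_x must be non-negative")
    if sigma_x_A == 0.0:
        return 0.0 if size is None else np.zeros(size)
    return rng.normal(0.0, sigma_x_A, size=size)


class ChiInducingSampler:
    """Rejection sampler for the work-Gaussianising pulling-point density.

    For spring work W = (1/2) k X**2 to follow the half-normal density

        f_W(w) = sqrt(2 / (pi * sigma_w**2)) * exp(-w**2 / (2 sigma_w**2)),  w >= 0,

    the offset X must be distributed as

        f_X(x) = k |x| / (sigma_w * sqrt(2 pi)) * exp(-k**2 x**4 / (8 sigma_w**2)).

    Draws use rejection from a double-exponential (Laplace) proposal whose
    scale is matched to the target's mode; the envelope constant is
    computed numerically at construction.  The running acceptance rate is
    tracked and a numerical warning is emitted if it falls below a floor.
    """

    #: acceptance-rate floor below which a warning is raised
    MIN_ACCEPTANCE = 0.1

    def __init__(self, sigma_w_target: float, k_kbtA2: float):
        if sigma_w_target <= 0 or k_kbtA2 <= 0:
            raise ValueError("sigma_w_target and k must be strictly positive")
        self.sigma_w = float(sigma_w_target)
        self.k = float(k_kbtA2)
        self._a = self.k**2 / (8.0 * self.sigma_w**2)
        # mode of |x| f-part: x* = (1/(4a))**(1/4); Laplace scale ~ x*
        self._xstar = (1.0 / (4.0 * self._a)) ** 0.25
        self._b = self._xstar
        xs = np.linspace(1e-9, 8.0 * self._xstar, 4001)
        ratio = self.density(xs) * 2.0 * self._b * np.exp(xs / self._b)
        self._envelope = 1.05 * float(ratio.max())
        self.n_proposed = 0
        self.n_accepted = 0

    def density(self, x) -> np.ndarray:
        """Target offset density f_X(x)."""
        x = np.asarray(x, dtype=float)
        return (
            self.k
            * np.abs(x)
            / (self.sigma_w * np.sqrt(2.0 * np.pi))
            * np.exp(-self._a * x**4)
        )

    def work_density(self, w) -> np.ndarray:
        """Induced work density f_W(w) (half-normal with scale sigma_w)."""
        w = np.asarray(w, dtype=float)
        out = np.sqrt(2.0 / (np.pi * self.sigma_w**2)) * np.exp(-(w**2) / (2.0 * self.sigma_w**2))
        return np.where(w >= 0, out, 0.0)

    def work_of(self, x) -> np.ndarray:
        """Spring work (1/2) k x**2 of offset(s) ``x``."""
        return 0.5 * self.k * np.asarray(x, dtype=float) ** 2

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else float("nan")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` offsets by rejection."""
        out = np.empty(size, dtype=float)
        filled = 0
        while filled < size:
            batch = max(64, int(1.6 * (size - filled)))
            prop = rng.laplace(0.0, self._b, size=batch)
            g = np.exp(-np.abs(prop) / self._b) / (2.0 * self._b)
            accept = rng.random(batch) * self._envelope * g <= self.density(prop)
            self.n_proposed += batch
            acc = prop[accept]
            take = min(len(acc), size - filled)
            out[filled : filled + take] = acc[:take]
            filled += take
            self.n_accepted += take
        if self.n_proposed > 1000 and self.acceptance_rate < self.MIN_ACCEPTANCE:
            warnings.warn(
                f"chi-inducing rejection acceptance rate low: {self.acceptance_rate:.3f}",
                RuntimeWarning,
            )
        return out


def sigma_w_for_sigma_x(sigma_x_A: float, k_kbtA2: float) -> float:
    """Work-density scale giving chi-inducing offsets the same variance as
    Gaussian jitter of SD ``sigma_x_A``.

    E[X**2] = (2 sigma_w / k) * sqrt(2/pi) for the chi-inducing density, so
    matching E[X**2] = sigma_x**2 gives sigma_w = (k sigma_x**2 / 2) sqrt(pi/2).
    """
    return 0.5 * k_kbtA2 * sigma_x_A**2 * np.sqrt(np.pi / 2.0)


def sample_pulling_noise_chi_inducing(
    sigma_w_target: float,
    k_kbtA2: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Offsets whose quadratic spring work follows the target half-normal density."""
    sampler = ChiInducingSampler(sigma_w_target, k_kbtA2)
    return sampler.sample(rng, size)


def amplitude_schedule(v_noise: VNoiseCurve, m: float, sigma_r_A: float) -> np.ndarray:
    """Per-interval jitter SD series sigma_x(t_j) = m * sigma_r * V_noise(t_j).

    The guiding curve is constant between consecutive sampling moments, so
    the schedule has one value per sampling interval.
    """
    if m < 0 or sigma_r_A < 0:
        raise ValueError("m and sigma_r must be non-negative")
    vals = v_noise.interval_values()
    return m * sigma_r_A * vals


def fm_gate(p: float, R: float):
    """Frequency-modulation gate: apply noise iff the uniform deviate R <= p."""
    p_arr = np.asarray(p, dtype=float)
    r_arr = np.asarray(R, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("gate probability p must lie in [0, 1]")
    if np.any(r_arr < 0) or np.any(r_arr > 1):
        raise ValueError("uniform deviate R must lie in [0, 1]")
    out = r_arr <= p_arr
    if np.isscalar(p) and np.isscalar(R):
        return bool(out)
    return out


def _noise_draw(protocol: ProtocolSpec, sigma_x: float, k_kbtA2: Optional[float],
                rng: np.random.Generator, size):
    if protocol.noise_distribution == "gaussian":
        return sample_pulling_noise_gaussian(sigma_x, rng, size=size)
    if k_kbtA2 is None:
        raise ValueError("chi_inducing noise needs the spring constant k")
    if sigma_x == 0.0:
        return 0.0 if size is None else np.zeros(size)
    sampler = ChiInducingSampler(sigma_w_for_sigma_x(sigma_x, k_kbtA2), k_kbtA2)
    n = 1 if size is None else int(np.prod(size))
    draws = sampler.sample(rng, n)
    return float(draws[0]) if size is None else draws.reshape(size)


def stochastic_offset(
    protocol: ProtocolSpec,
    interval_index: int,
    is_sampling_moment: bool,
    sigma_r_A: float,
    rng: np.random.Generator,
    k_kbtA2: Optional[float] = None,
    size=None,
):
    """Pulling-point offset for the current sub-step under ``protocol``.

    ``interval_index`` selects the (constant) guiding-curve value for the
    current sampling interval.  Whenever ``is_sampling_moment`` is set the
    offset is exactly 0, so the recorded work refers to the deterministic
    schedule.
    """
    zero = 0.0 if size is None else np.zeros(size)
    if is_sampling_moment or protocol.kind == "normal":
        return zero
    sigma_x = protocol.m * sigma_r_A
    if protocol.kind == "constant_noise":
        return _noise_draw(protocol, sigma_x, k_kbtA2, rng, size)
    vals = protocol.v_noise.interval_values()
    if not 0 <= interval_index < len(vals):
        raise ValueError(f"interval_index {interval_index} outside the guiding curve")
    v = float(vals[interval_index])
    if protocol.kind == "am":
        return _noise_draw(protocol, sigma_x * v, k_kbtA2, rng, size)
    # fm: gated constant-amplitude noise
    gate = fm_gate(v, rng.random() if size is None else rng.random(size))
    draw = _noise_draw(protocol, sigma_x, k_kbtA2, rng, size)
    if size is None:
        return draw if gate else 0.0
    return np.where(gate, draw, 0.0)


def injected_noise_energy(offsets, k_kbtA2: float) -> float:
    """Total spring energy (1/2) k eta**2 carried by a set of offsets (k_BT)."""
    eta = np.asarray(offsets, dtype=float)
    return float(0.5 * k_kbtA2 * np.sum(eta**2))
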