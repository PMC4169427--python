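"""Noise-amplitude calibration for stochastic pulling protocols.

The central quantity is the noise multiplication factor ``m``: the standard
deviation of the pulling-point jitter expressed as a multiple of the thermal
displacement scale sigma_r = sqrt(2*D*dt) of the pulled particle.  Given a
target bias (the mean-work bias of a pilot reconstruction) the calibration
inverts the effective-work-fluctuation relation to find the amplitude that
makes the injected work fluctuation match the bias.

Two inversion modes exist:

``jarzynski``
    The effective standard deviation of the injected random work is set
    equal to the mean-work bias B.  Since that deviation is quadratic in
    ``m``, the amplitude scales as ``m ~ B**(1/2) * n**(1/4)``.
``cumulant``
    The second cumulant term (beta/2) * Var(W_eff) of the second-order
    cumulant expansion is set equal to B.  The bias then has a
    fourth-degree dependence on the amplitude: ``m ~ B**(1/4)``.

Conventions.  The instantaneous work injected by a pulling-point offset X
against a Hookean spring is taken as the spring energy W = (1/2) k X**2;
with Gaussian X of SD sigma_x this work is chi-square distributed with
standard deviation sqrt(2) * (k/2) * sigma_x**2.  Omitting the noise at
sampling moments reduces the effective per-interval deviation by a factor
sqrt(n), with n sub-steps per sampling interval.  An optional modulation
factor accounts for amplitude modulation by a guiding curve: modulating
the noise SD by V(t) scales injected energy by V**2, so the run-averaged
reduction is (mean V)**2.  The published instance of that average is 0.74.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .units import (
    DEFAULT_TEMPERATURE_K,
    diffusion_m2s_to_A2fs,
    spring_pNA_to_kbtA2,
    velocity_ms_to_Afs,
)

#: Run-average of the published noise guiding curve; its square is the
#: default amplitude-modulation factor for Jarzynski-mode calibration.
DEFAULT_VNOISE_AVERAGE = 0.74

_MODES = ("jarzynski", "cumulant")


class ScheduleError(ValueError):
    """Raised when a pulling schedule is internally inconsistent."""


@dataclass(frozen=True)
class NoiseCalibration:
    """Result bundle of a noise-amplitude calibration."""

    m: float
    sigma_r: float
    sigma_x: float
    sigma_w_eff: float
    target_bias: float
    mode: str
    n: int
    modulation_factor: float

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        for name in ("m", "sigma_r", "sigma_x", "sigma_w_eff", "target_bias"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def steps_between_samples(L_A: float, n_samples: int, v_ms: float, dt_fs: float) -> int:
    """Number of integration sub-steps between two successive sampling points.

    ``n_samples`` counts the grid points of the reconstruction (the work is
    recorded at ``n_samples`` positions including the path start), so the
    sampling interval is ``L / (n_samples - 1)``.  The result must be an
    exact integer; a schedule whose time step does not divide the
    inter-sample time is rejected.
    """
    if L_A <= 0 or v_ms <= 0 or dt_fs <= 0:
        raise ValueError("L, v and dt must be strictly positive")
    if n_samples < 2:
        raise ValueError("need at least two sampling points")
    interval_A = L_A / (n_samples - 1)
    n = interval_A / (velocity_ms_to_Afs(v_ms) * dt_fs)
    n_int = round(n)
    if n_int < 1 or abs(n - n_int) > 1e-9 * max(1.0, n):
        raise ScheduleError(
            f"dt does not divide the inter-sample time: got n = {n:.6g} sub-steps"
        )
    return int(n_int)


def sigma_r(D_m2s: float, dt_fs: float) -> float:
    """Thermal displacement scale sqrt(2*D*dt) of the pulled particle, in A."""
    if D_m2s < 0 or dt_fs < 0:
        raise ValueError("D and dt must be non-negative")
    return math.sqrt(2.0 * diffusion_m2s_to_A2fs(D_m2s) * dt_fs)


def instantaneous_work_std(m: float, k_kbtA2: float, sigma_r_A: float) -> float:
    """SD of the chi-square instantaneous noise work, sqrt(2)*(k/2)*(m*sigma_r)**2."""
    return math.sqrt(2.0) * 0.5 * k_kbtA2 * (m * sigma_r_A) ** 2


def effective_work_std(
    m: float,
    k_kbtA2: float,
    sigma_r_A: float,
    n: int,
    modulation_factor: float = 1.0,
) -> float:
    """Effective per-interval SD of the injected work (k_BT).

    The instantaneous SD, reduced by the modulation factor and averaged over
    the ``n`` sub-steps between sampling moments (root-mean-square over the
    interval, i.e. a 1/sqrt(n) reduction).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if m < 0 or k_kbtA2 < 0 or sigma_r_A < 0 or modulation_factor < 0:
        raise ValueError("arguments must be non-negative")
    return instantaneous_work_std(m, k_kbtA2, sigma_r_A) * modulation_factor / math.sqrt(n)


def round_to_decade(m: float) -> float:
    """Round half-up to the nearest multiple of 10."""
    return math.floor(m / 10.0 + 0.5) * 10.0


def amplitude_for_bias(
    target_bias: float,
    mode: str,
    k_pN_A: float = 500.0,
    D_m2s: float = 3.5e-9,
    dt_fs: float = 2.0,
    n: int = 200,
    T_K: float = DEFAULT_TEMPERATURE_K,
    modulation_factor: float | None = None,
    rounding: str = "none",
    anchor: tuple[float, float] | None = None,
) -> float:
    """Noise amplitude ``m`` whose injected work fluctuation matches a bias.

    Parameters
    ----------
    target_bias:
        Mean-work bias to cancel, in k_BT.  Must be positive.
    mode:
        ``jarzynski`` (effective work SD = bias, m ~ B**(1/2)) or
        ``cumulant`` (second cumulant = bias, m ~ B**(1/4)).
    modulation_factor:
        Run-average reduction of amplitude-modulated noise.  Defaults to
        0.74**2 in jarzynski mode and 1 in cumulant mode.
    rounding:
        ``none`` or ``decade`` (round half-up to the nearest multiple of 10).
    anchor:
        Optional ``(m_ref, bias_ref)`` pair.  When given, the amplitude is
        obtained by pure power-law scaling from the anchor instead of the
        absolute inversion: ``m = m_ref * (B/B_ref)**p`` with p = 1/2
        (jarzynski) or 1/4 (cumulant).  Useful when an empirically trusted
        amplitude/bias pair is available.
    """
    if target_bias <= 0:
        raise ValueError("target_bias must be positive")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    if rounding not in ("none", "decade"):
        raise ValueError("rounding must be 'none' or 'decade'")
    power = 0.5 if mode == "jarzynski" else 0.25
    if anchor is not None:
        m_ref, bias_ref = anchor
        if m_ref <= 0 or bias_ref <= 0:
            raise ValueError("anchor values must be positive")
        m = m_ref * (target_bias / bias_ref) ** power
    else:
        if modulation_factor is None:
            modulation_factor = DEFAULT_VNOISE_AVERAGE**2 if mode == "jarzynski" else 1.0
        k = spring_pNA_to_kbtA2(k_pN_A, T_K)
        sr = sigma_r(D_m2s, dt_fs)
        # invert effective_work_std (jarzynski) or (1/2)*sigma_eff**2 (cumulant)
        if mode == "jarzynski":
            m2 = target_bias * math.sqrt(2.0 * n) / (k * sr**2 * modulation_factor)
            m = math.sqrt(m2)
        else:
            m4 = 4.0 * n * target_bias / (k**2 * sr**4 * modulation_factor**2)
            m = m4**0.25
    if rounding == "decade":
        m = round_to_decade(m)
    return float(m)


def bias_from_amplitude(
    m: float,
    mode: str,
    k_pN_A: float = 500.0,
    D_m2s: float = 3.5e-9,
    dt_fs: float = 2.0,
    n: int = 200,
    T_K: float = DEFAULT_TEMPERATURE_K,
    modulation_factor: float | None = None,
    anchor: tuple[float, float] | None = None,
) -> float:
    """Inverse of :func:`amplitude_for_bias` (bias in k_BT for amplitude ``m``)."""
    if m <= 0:
        raise ValueError("m must be positive")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    power = 2.0 if mode == "jarzynski" else 4.0
    if anchor is not None:
        m_ref, bias_ref = anchor
        return float(bias_ref * (m / m_ref) ** power)
    if modulation_factor is None:
        modulation_factor = DEFAULT_VNOISE_AVERAGE**2 if mode == "jarzynski" else 1.0
    k = spring_pNA_to_kbtA2(k_pN_A, T_K)
    sr = sigma_r(D_m2s, dt_fs)
    sigma_eff = effective_work_std(m, k, sr, n, modulation_factor)
    if mode == "jarzynski":
        return float(sigma_eff)
    return float(0.5 * sigma_eff**2)


def scale_amplitude_with_n(m: float, n_old: int, n_new: int) -> float:
    """Rescale an amplitude when the sub-step count per interval changes.

    At fixed target bias the amplitude scales as n**(1/4) (from the
    1/sqrt(n) term inside the inversion), so doubling the pulling velocity
    (halving n) reduces the amplitude by 2**(1/4).
    """
    if m <= 0 or n_old <= 0 or n_new <= 0:
        raise ValueError("all arguments must be positive")
    return float(m * (n_new / n_old) ** 0.25)


def equivalent_trajectory_cost(n_traj: int, v_ref_ms: float, v_fast_ms: float) -> float:
    """Cost of ``n_traj`` trajectories at ``v_ref`` in fast-velocity trajectory units.

    At fixed path length the wall-clock cost of a trajectory scales as
    1/velocity, so the equivalent count is n_traj * v_fast / v_ref.
    """
    if v_ref_ms <= 0 or v_fast_ms <= 0:
        raise ValueError("velocities must be positive")
    return float(n_traj * v_fast_ms / v_ref_ms)


def calibrate(
    target_bias: float,
    mode: str,
    k_pN_A: float = 500.0,
    D_m2s: float = 3.5e-9,
    dt_fs: float = 2.0,
    n: int = 200,
    T_K: float = DEFAULT_TEMPERATURE_K,
    modulation_factor: float | None = None,
    rounding: str = "none",
) -> NoiseCalibration:
    """Full calibration bundle for a target bias (see :func:`amplitude_for_bias`)."""
    if modulation_factor is None:
        modulation_factor = DEFAULT_VNOISE_AVERAGE**2 if mode == "jarzynski" else 1.0
    m = amplitude_for_bias(
        target_bias,
        mode,
        k_pN_A=k_pN_A,
        D_m2s=D_m2s,
        dt_fs=dt_fs,
        n=n,
        T_K=T_K,
        modulation_factor=modulation_factor,
        rounding=rounding,
    )
    sr = sigma_r(D_m2s, dt_fs)
    k = spring_pNA_to_kbtA2(k_pN_A, T_K)
    return NoiseCalibration(
        m=m,
        sigma_r=sr,
        sigma_x=m * sr,
        sigma_w_eff=effective_work_std(m, k, sr, n, modulation_factor),
        target_bias=target_bias,
        mode=mode,
        n=n,
        modulation_factor=modulation_factor,
    )
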