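"""One-dimensional model free-energy surfaces.

These potentials stand in for the molecular PMF that a steered-pulling
experiment probes.  Each form provides an analytic energy and gradient so
the Brownian simulator can integrate forces exactly, and a reference
profile (the ground-truth PMF) for quality metrics.

Available forms
---------------
``flat``
    U(r) = c.  Useful for testing dissipation-only behaviour.
``harmonic``
    U(r) = 0.5 * kappa * (r - r0)**2 + c.
``double_well``
    A quartic double well with minima at ``r_left``/``r_right`` and a
    barrier of ``height`` (k_BT) halfway between them, optionally
    decorated with a cosine corrugation.  The corrugation mimics the
    small-scale ruggedness of real molecular free-energy profiles, which
    is what makes reconstruction fluctuations look like real pulling
    data rather than a textbook-smooth curve.
``spline_knots``
    A C^2 cubic spline through user-supplied knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

_FORMS = ("flat", "harmonic", "double_well", "spline_knots")


class DomainError(ValueError):
    """Raised when a position lies outside a potential's domain."""


@dataclass(frozen=True)
class PotentialSpec:
    """Declarative description of a 1-D model potential.

    Parameters
    ----------
    form:
        One of ``flat``, ``harmonic``, ``double_well``, ``spline_knots``.
    parameters:
        Named real parameters of the form (energies in k_BT, lengths in A).
    domain:
        Closed interval ``(r_min, r_max)`` in A on which the potential is
        defined.
    """

    form: str
    parameters: Mapping[str, object] = field(default_factory=dict)
    domain: Tuple[float, float] = (-10.0, 30.0)

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown potential form {self.form!r}; choose from {_FORMS}")
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError(f"domain must satisfy r_min < r_max, got {self.domain}")
        if self.form == "spline_knots":
            r = np.asarray(self.parameters["knots_r"], dtype=float)
            if r.ndim != 1 or len(r) < 3:
                raise ValueError("spline_knots needs at least 3 knot abscissae")
            if not np.all(np.diff(r) > 0):
                raise ValueError("spline knot abscissae must be strictly increasing")
            if r[0] < lo or r[-1] > hi:
                raise ValueError("spline knots must lie inside the domain")
            u = np.asarray(self.parameters["knots_u"], dtype=float)
            if u.shape != r.shape:
                raise ValueError("knots_r and knots_u must have equal length")

    def _spline(self) -> CubicSpline:
        r = np.asarray(self.parameters["knots_r"], dtype=float)
        u = np.asarray(self.parameters["knots_u"], dtype=float)
        return CubicSpline(r, u, bc_type="natural")


def _check_domain(spec: PotentialSpec, r: np.ndarray) -> None:
    lo, hi = spec.domain
    if np.any(r < lo) or np.any(r > hi):
        bad = np.asarray(r)[(np.asarray(r) < lo) | (np.asarray(r) > hi)]
        raise DomainError(
            f"position(s) {np.atleast_1d(bad)[:3]} outside potential domain [{lo}, {hi}]"
        )


def evaluate(spec: PotentialSpec, r, check_domain: bool = True):
    """Energy U(r) (k_BT) and gradient dU/dr (k_BT/A) at position(s) ``r``.

    ``r`` may be a scalar or an array; the return matches its shape.
    """
    r_arr = np.asarray(r, dtype=float)
    if check_domain:
        _check_domain(spec, r_arr)
    p = spec.parameters
    if spec.form == "flat":
        c = float(p.get("offset", 0.0))
        u = np.full_like(r_arr, c, dtype=float)
        g = np.zeros_like(r_arr, dtype=float)
    elif spec.form == "harmonic":
        kappa = float(p["kappa"])
        r0 = float(p.get("r0", 0.0))
        c = float(p.get("offset", 0.0))
        u = 0.5 * kappa * (r_arr - r0) ** 2 + c
        g = kappa * (r_arr - r0)
    elif spec.form == "double_well":
        u, g = _double_well(p, r_arr)
    else:  # spline_knots
        cs = spec._spline()
        u = cs(r_arr)
        g = cs(r_arr, 1)
    if np.isscalar(r):
        return float(u), float(g)
    return u, g


def _double_well(p: Mapping[str, object], r: np.ndarray):
    a = float(p["r_left"])
    b = float(p["r_right"])
    H = float(p["height"])
    if not a < b:
        raise ValueError("double_well requires r_left < r_right")
    c = 0.5 * (a + b)
    w = 0.5 * (b - a)
    z = r - c
    u = H * (z * z - w * w) ** 2 / w**4
    g = H * 4.0 * z * (z * z - w * w) / w**4
    amp = float(p.get("corrugation_height", 0.0))
    if amp:
        lam = float(p.get("corrugation_wavelength", 2.0))
        ph = float(p.get("corrugation_phase", 0.0))
        u = u + amp * np.cos(2.0 * np.pi * r / lam + ph)
        g = g - amp * 2.0 * np.pi / lam * np.sin(2.0 * np.pi * r / lam + ph)
    return u, g


def reference_pmf(spec: PotentialSpec, grid) -> np.ndarray:
    """Ground-truth free-energy profile on ``grid``, anchored to 0 at grid[0].

    The anchoring matches the convention of every reconstruction in this
    package: PMF estimates start at zero at the beginning of the pulling
    path, so reference and estimate are directly comparable.
    """
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        raise ValueError("reference_pmf needs a non-empty grid")
    u, _ = evaluate(spec, g)
    return u - u[0]


def barrier_height(spec: PotentialSpec, grid) -> float:
    """max(reference) - reference[0] on ``grid`` (k_BT)."""
    prof = reference_pmf(spec, grid)
    return float(prof.max() - prof[0])
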