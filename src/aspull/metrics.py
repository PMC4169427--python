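"""Quality metrics comparing PMF reconstructions to a reference profile."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class QualityReport:
    """Per-estimate comparison against a reference profile."""

    relative_rmsd_percent: float
    max_abs_error: float
    end_bias: float

    def __post_init__(self) -> None:
        if self.relative_rmsd_percent < 0:
            raise ValueError("relative RMSD cannot be negative")


def _align(estimate, reference):
    est_vals = np.asarray(getattr(estimate, "values", estimate), dtype=float)
    ref_vals = np.asarray(getattr(reference, "values", reference), dtype=float)
    est_grid = getattr(estimate, "grid", None)
    ref_grid = getattr(reference, "grid", None)
    if est_grid is not None and ref_grid is not None:
        if not np.allclose(np.asarray(est_grid), np.asarray(ref_grid)):
            raise ValueError("estimate and reference are on different grids")
    if est_vals.shape != ref_vals.shape:
        raise ValueError("estimate and reference must have equal length")
    return est_vals, ref_vals


def relative_rmsd(estimate, reference) -> float:
    """RMS deviation from the reference, as a percent of its barrier height.

    For N reconstruction points,

        rRMSD = 100 * sqrt( (1/N) * sum_j (G_est(x_j) - G_ref(x_j))**2 ) / H ,

    where H = max(G_ref) - G_ref[0] is the reference barrier height.  The
    reference curve supplies the normalisation because it is the only
    bias-free profile available.
    """
    est, ref = _align(estimate, reference)
    barrier = ref.max() - ref[0]
    if barrier <= 0:
        raise ValueError("reference has no barrier; relative RMSD undefined")
    return float(100.0 * np.sqrt(np.mean((est - ref) ** 2)) / barrier)


def compare(estimate, reference) -> QualityReport:
    """Full quality report of an estimate against a reference profile."""
    est, ref = _align(estimate, reference)
    return QualityReport(
        relative_rmsd_percent=relative_rmsd(estimate, reference),
        max_abs_error=float(np.max(np.abs(est - ref))),
        end_bias=float(est[-1] - ref[-1]),
    )
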