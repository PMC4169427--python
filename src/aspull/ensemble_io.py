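"""Delimited-text serialisation of work ensembles, PMF estimates and curves.

Work-ensemble files are comma-separated with '#'-prefixed header lines.
The header carries a JSON metadata block (simulation config and protocol),
then one row per trajectory per sampling point:

    trajectory_index, sample_index, x_grid_A, position_A, work_kbt

Floats are written at full precision so a write/read round trip is
lossless to representation accuracy.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np

from .bias_analysis import VNoiseCurve
from .estimators import PMFEstimate
from .protocols import ProtocolSpec
from .simulator import SimulationConfig, WorkEnsemble

FORMAT_VERSION = 1


class ParseError(ValueError):
    """Malformed file content; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _config_meta(config: Optional[SimulationConfig]) -> Optional[dict]:
    if config is None:
        return None
    return {
        "dt_fs": config.dt_fs, "D_m2s": config.D_m2s, "k_pN_A": config.k_pN_A,
        "v_ms": config.v_ms, "L_A": config.L_A, "n_samples": config.n_samples,
        "T_K": config.T_K, "n_traj": config.n_traj, "x0_A": config.x0_A,
        "equil_steps": config.equil_steps,
    }


def _protocol_meta(protocol: Optional[ProtocolSpec]) -> Optional[dict]:
    if protocol is None:
        return None
    meta = {"kind": protocol.kind, "noise_distribution": protocol.noise_distribution,
            "m": protocol.m}
    if protocol.v_noise is not None:
        meta["v_noise_values"] = [float(v) for v in protocol.v_noise.values]
    return meta


def write_work_ensemble(ensemble: WorkEnsemble, path) -> None:
    meta = {
        "format": "aspull-work-ensemble",
        "version": FORMAT_VERSION,
        "n_traj": ensemble.n_traj,
        "n_samples": ensemble.n_samples,
        "config": _config_meta(ensemble.config),
        "protocol": _protocol_meta(ensemble.protocol),
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("# trajectory,sample,x_A,position_A,work_kbt\n")
        for i in range(ensemble.n_traj):
            for j in range(ensemble.n_samples):
                fh.write(
                    f"{i},{j},{ensemble.grid[j]:.17g},{ensemble.positions[i, j]:.17g},"
                    f"{ensemble.works[i, j]:.17g}\n"
                )


def read_work_ensemble(path) -> WorkEnsemble:
    meta = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if meta is None and body.startswith("{"):
                    try:
                        meta = json.loads(body)
                    except json.JSONDecodeError as exc:
                        raise ParseError(f"bad metadata header: {exc}", lineno) from exc
                continue
            parts = line.split(",")
            if len(parts) != 5:
                raise ParseError(f"expected 5 comma-separated fields, got {len(parts)}", lineno)
            try:
                rows.append((int(parts[0]), int(parts[1]), float(parts[2]),
                             float(parts[3]), float(parts[4])))
            except ValueError as exc:
                raise ParseError(f"unparsable field: {exc}", lineno) from exc
    if meta is None:
        raise ParseError("missing metadata header", 1)
    n_traj, n_samples = meta["n_traj"], meta["n_samples"]
    if len(rows) != n_traj * n_samples:
        raise ParseError(
            f"expected {n_traj * n_samples} data rows, found {len(rows)}",
            len(rows) + 2,
        )
    works = np.full((n_traj, n_samples), np.nan)
    positions = np.full((n_traj, n_samples), np.nan)
    grid = np.full(n_samples, np.nan)
    for i, j, x, p, w in rows:
        if not (0 <= i < n_traj and 0 <= j < n_samples):
            raise ParseError(f"trajectory/sample index ({i}, {j}) out of range", 3)
        works[i, j] = w
        positions[i, j] = p
        grid[j] = x
    if np.any(np.isnan(works)):
        raise ParseError("incomplete ensemble: some trajectory/sample cells missing", 3)
    config = None
    if meta.get("config"):
        config = SimulationConfig(**meta["config"])
    protocol = None
    if meta.get("protocol"):
        pm = dict(meta["protocol"])
        vn_vals = pm.pop("v_noise_values", None)
        if vn_vals is not None:
            pm["v_noise"] = VNoiseCurve(grid=grid, values=np.asarray(vn_vals))
        protocol = ProtocolSpec(**pm)
    return WorkEnsemble(works=works, positions=positions, grid=grid,
                        config=config, protocol=protocol)


def write_pmf(estimate: PMFEstimate, path) -> None:
    """Two-column (position A, G0 k_BT) text file with a metadata header."""
    meta = {"format": "aspull-pmf", "version": FORMAT_VERSION,
            "estimator": estimate.estimator, "n_traj": estimate.n_traj,
            "beta": estimate.beta}
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("# position_A,G0_kbt\n")
        for x, g in zip(estimate.grid, estimate.values):
            fh.write(f"{x:.17g},{g:.17g}\n")


def read_pmf(path) -> PMFEstimate:
    meta = None
    xs, gs = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if meta is None and body.startswith("{"):
                    meta = json.loads(body)
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"expected 2 fields, got {len(parts)}", lineno)
            try:
                xs.append(float(parts[0]))
                gs.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"unparsable field: {exc}", lineno) from exc
    if meta is None:
        raise ParseError("missing metadata header", 1)
    return PMFEstimate(grid=np.asarray(xs), values=np.asarray(gs),
                       estimator=meta["estimator"], n_traj=meta["n_traj"],
                       beta=meta.get("beta", 1.0))


def write_v_noise(curve: VNoiseCurve, path) -> None:
    """Two-column (grid position, value) text file."""
    with open(path, "w") as fh:
        fh.write("# aspull-vnoise\n")
        for x, v in zip(curve.grid, curve.values):
            fh.write(f"{x:.17g} {v:.17g}\n")


def read_v_noise(path) -> VNoiseCurve:
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("v_noise file must have two columns: grid, value")
    return VNoiseCurve(grid=data[:, 0], values=data[:, 1])
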