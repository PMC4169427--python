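"""Run-configuration files (YAML key-value schema, versioned).

A run config bundles a potential, the simulation parameters and the pulling
protocol, plus a mandatory random seed -- there is no silent
nondeterminism.  Schema::

    schema_version: 1
    seed: 1234
    potential:
      form: double_well
      parameters: {r_left: 2.0, r_right: 18.0, height: 20.0}
      domain: [-10.0, 30.0]
    simulation:
      dt_fs: 2.0
      D_m2s: 3.5e-9
      k_pN_A: 500.0
      v_ms: 25.0
      L_A: 16.0
      n_samples: 81
      T_K: 300.0
      n_traj: 200
      x0_A: 2.0
    protocol:
      kind: fm               # normal | constant_noise | am | fm
      noise_distribution: gaussian   # gaussian | chi_inducing
      amplitude: 200.0
      v_noise_file: vnoise.tsv       # required for am/fm
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import yaml

from . import ensemble_io
from .potentials import PotentialSpec
from .protocols import ProtocolSpec
from .simulator import SimulationConfig

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass(frozen=True)
class RunConfig:
    potential: PotentialSpec
    simulation: SimulationConfig
    protocol: ProtocolSpec
    seed: int

    def validate(self) -> "RunConfig":
        lo, hi = self.potential.domain
        if self.simulation.x0_A < lo or self.simulation.x0_A + self.simulation.L_A > hi:
            raise ConfigError("potential domain does not cover the pulling path")
        self.simulation.n_substeps  # raises ScheduleError if dt does not divide
        if self.protocol.kind in ("am", "fm"):
            if self.protocol.v_noise is None:
                raise ConfigError(f"protocol {self.protocol.kind!r} needs a v_noise curve")
            if len(self.protocol.v_noise.values) != self.simulation.n_samples:
                raise ConfigError("v_noise length must match the sampling grid")
        return self


def load_run_config(path) -> RunConfig:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")
    if "seed" not in raw:
        raise ConfigError("run configs must declare an explicit 'seed'")
    try:
        pot_raw = raw["potential"]
        potential = PotentialSpec(
            form=pot_raw["form"],
            parameters=pot_raw.get("parameters", {}),
            domain=tuple(pot_raw.get("domain", (-10.0, 30.0))),
        )
        simulation = SimulationConfig(**raw["simulation"])
        prot_raw = dict(raw.get("protocol", {"kind": "normal"}))
        vn_file = prot_raw.pop("v_noise_file", None)
        v_noise = None
        if vn_file is not None:
            vn_path = Path(vn_file)
            if not vn_path.is_absolute():
                vn_path = path.parent / vn_path
            v_noise = ensemble_io.read_v_noise(vn_path)
        protocol = ProtocolSpec(
            kind=prot_raw.get("kind", "normal"),
            noise_distribution=prot_raw.get("noise_distribution", "gaussian"),
            m=float(prot_raw.get("amplitude", 0.0)),
            v_noise=v_noise,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid run config {path}: {exc}") from exc
    return RunConfig(potential=potential, simulation=simulation,
                     protocol=protocol, seed=int(raw["seed"])).validate()
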