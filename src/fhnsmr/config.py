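"""Flat JSON run configuration shared by all command-line tools.

Defaults reproduce the reference operating point of the study: eps=0.01,
a=1.1, A=0.14, Te=14, g=0.01 on a Watts-Strogatz network with N=100, k=30,
p=0.15, integrated with dt=0.001 from zero initial conditions; ordinal
analysis with embedding dimension d=3.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

from fhnsmr.model import ModelParams, SimControl
from fhnsmr.network import NetworkParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    # network
    N: int = 100
    k: int = 30
    p: float = 0.15
    # model
    eps: float = 0.01
    a: float = 1.1
    A: float = 0.14
    Te: float = 14.0
    g: float = 0.01
    D: float = 0.0
    tau: float = 0.0
    noise_convention: str = "amplitude"
    # integration
    dt: float = 0.001
    t_total: float = 500.0
    t_transient: float = 100.0
    seed: int = 0
    record_stride: int = 10
    record_raster: bool = False
    # analysis
    d: int = 3
    threshold: float = 0.0
    refractory: float = 1.0
    prominence: float = 0.05
    L_target: int = 2000
    max_realizations: int = 200
    reps_snr: int = 0
    # sweep grid (used by the sweep subcommands)
    control: str = "D"
    values: tuple[float, ...] = ()
    # output
    outdir: str = "."

    def __post_init__(self) -> None:
        # delegate invariant checks to the domain types
        self.network_params()
        self.model_params()
        self.sim_control()
        if not 2 <= self.d <= 7:
            raise ValueError(f"embedding dimension d must be in 2..7, got {self.d}")

    def network_params(self) -> NetworkParams:
        return NetworkParams(N=self.N, k=self.k, p=self.p, seed=self.seed)

    def model_params(self) -> ModelParams:
        return ModelParams(
            eps=self.eps,
            a=self.a,
            A=self.A,
            Te=self.Te,
            g=self.g,
            D=self.D,
            tau=self.tau,
            noise_convention=self.noise_convention,
        )

    def sim_control(self) -> SimControl:
        return SimControl(
            t_total=self.t_total,
            t_transient=self.t_transient,
            dt=self.dt,
            seed=self.seed,
            record_stride=self.record_stride,
            record_raster=self.record_raster,
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["values"] = list(self.values)
        return out


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load and validate a flat JSON config; unknown keys are rejected."""
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a JSON object")
    unknown = set(raw) - set(_FIELD_TYPES)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "values" in raw:
        raw["values"] = tuple(raw["values"])
    for key, val in raw.items():
        if key in ("values",):
            continue
        if isinstance(val, bool):
            if key != "record_raster":
                raise ValueError(f"config key {key!r}: unexpected boolean")
        elif isinstance(val, (int, float)):
            pass
        elif isinstance(val, str):
            if key not in ("noise_convention", "outdir", "control"):
                raise ValueError(f"config key {key!r}: expected a number, got string")
        else:
            raise ValueError(f"config key {key!r}: unsupported value type")
    return RunConfig(**raw)


def save_config(path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
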