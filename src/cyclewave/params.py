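"""Kinetic parameters of the nine-species embryonic Cdk1 oscillator.

The constants live in a human-readable YAML file (one scalar per named
constant, with units and a comment per line); :func:`load_params` reads it
and :class:`KineticParams` carries the values.  The packaged file
``data/xenopus_calibrated.yaml`` is the single source of truth for the
wild-type set.
"""
from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["KineticParams", "load_params", "default_params", "save_params"]

_RATE_FIELDS = (
    "ks", "k_bind", "k_unbind", "k_cak", "k_pp",
    "k_wee1_basal", "k_wee1_act", "k_cdc25_basal", "k_cdc25_act", "kdest",
    "kc25_on", "kc25_off", "K_cdc25", "n_cdc25",
    "kwee_off", "kwee_on", "K_wee1", "n_wee1",
    "kplx_on", "kplx_off", "K_plx", "n_plx",
    "kapc_on", "kapc_off", "K_apc", "n_apc",
    "cdc25_total", "wee1_total", "plx1_total", "apc_total",
)


@dataclasses.dataclass(frozen=True)
class KineticParams:
    """Rate constants, Hill parameters, regulator totals and the diffusion
    constant of the cell-cycle network.

    Concentrations are in nM, times in minutes; ``D`` is in um^2/s (the
    conventional unit for protein diffusion) and is converted by the
    spatial solvers.  All rates and totals must be strictly positive;
    ``D`` may be zero (well-mixed limit).
    """

    ks: float
    k_bind: float
    k_unbind: float
    k_cak: float
    k_pp: float
    k_wee1_basal: float
    k_wee1_act: float
    k_cdc25_basal: float
    k_cdc25_act: float
    kdest: float
    kc25_on: float
    kc25_off: float
    K_cdc25: float
    n_cdc25: float
    kwee_off: float
    kwee_on: float
    K_wee1: float
    n_wee1: float
    kplx_on: float
    kplx_off: float
    K_plx: float
    n_plx: float
    kapc_on: float
    kapc_off: float
    K_apc: float
    n_apc: float
    cdc25_total: float = 1.0
    wee1_total: float = 1.0
    plx1_total: float = 1.0
    apc_total: float = 1.0
    D: float = 10.0

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not (value > 0.0):
                raise ValueError(f"kinetic constant {name!r} must be strictly "
                                 f"positive, got {value!r}")
        if self.D < 0.0:
            raise ValueError(f"diffusion constant D must be >= 0, got {self.D!r}")

    def replace(self, **changes: float) -> "KineticParams":
        """Return a copy with the given constants replaced."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def load_params(path: str | Path) -> KineticParams:
    """Read a parameter file (YAML, one scalar per constant)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} does not contain a mapping")
    known = {f.name for f in dataclasses.fields(KineticParams)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown constants in {path}: {sorted(unknown)}")
    return KineticParams(**{k: float(v) for k, v in raw.items()})


def save_params(params: KineticParams, path: str | Path) -> None:
    """Write a parameter set as YAML (units documented in the default file)."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.as_dict(), fh, sort_keys=False)


def default_params() -> KineticParams:
    """The calibrated wild-type Xenopus set shipped with the package."""
    ref = resources.files("cyclewave").joinpath("data/xenopus_calibrated.yaml")
    with resources.as_file(ref) as path:
        return load_params(path)
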