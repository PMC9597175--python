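"""YAML configuration mapping for the command-line workflows.

The library itself takes explicit arguments; this module only binds a
YAML document to those arguments for the ``actd`` command.  Every block
is optional and falls back to the library defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .inner_solvers import DEFAULT_EPSILON, SolverSettings
from .nhde import NHDEParams

__all__ = ["ACTDConfig", "load_config"]


@dataclass
class ACTDConfig:
    ca_model: str | None = None
    ht_model: str | None = None
    biomass_rxn_id: str | None = None
    atp_rxn_id: str | None = None
    epsilon: float = DEFAULT_EPSILON
    alpha: float = 1.0
    w_min_factor: float = 0.1
    quantiles: tuple[float, float, float] = (0.25, 0.5, 0.75)
    exhaustive_cap: int = 2000
    solver: SolverSettings = field(default_factory=SolverSettings)
    nhde: NHDEParams = field(default_factory=NHDEParams)


def load_config(path: str | Path | None) -> ACTDConfig:
    if path is None:
        return ACTDConfig()
    doc = yaml.safe_load(Path(path).read_text()) or {}
    solver = SolverSettings(**doc.pop("solver", {}))
    nhde = NHDEParams(**doc.pop("nhde", {}))
    membership = doc.pop("membership", {})
    cfg = ACTDConfig(
        solver=solver,
        nhde=nhde,
        alpha=membership.get("alpha", 1.0),
        w_min_factor=membership.get("w_min_factor", 0.1),
        **doc,
    )
    if "quantiles" in membership:
        cfg.quantiles = tuple(membership["quantiles"])
    return cfg
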