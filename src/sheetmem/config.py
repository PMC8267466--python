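"""Run configuration: a validated, losslessly serialisable key tree.

Every default equals the study's stated value where one exists: side
length 2.89 nm, T = 300 K, restraint k = 2000 kJ/mol/nm^2, window
spacing 0.1 nm (50 windows over 0-4.9 nm), non-bonded cutoff 1.2 nm,
contact cutoff 0.5 nm, bound-water cutoff 0.35 nm, locality radius
1.0 nm, 316 lipids per leaflet.  Unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Configuration schema violation (maps to CLI exit code 2)."""


@dataclass
class LatticeConfig:
    a: float = 0.316  # nm, in-plane lattice constant
    mo_s_offset: float = 0.156  # nm


@dataclass
class SheetConfig:
    side_length: float = 2.89  # nm
    aging: str = "fresh"
    wca: float | None = None  # optional: derive eps_S from a contact angle


@dataclass
class MembraneConfig:
    n_lipids_per_leaflet: int = 316
    spacing: float = 0.8  # nm grid spacing
    beads_per_chain: int = 3


@dataclass
class SimulatorConfig:
    dt: float = 0.02  # ps
    temperature: float = 300.0  # K
    gamma_sheet: float = 50.0
    gamma_bead: float = 20.0
    cutoff: float = 1.2  # nm
    n_steps: int = 20000
    report_interval: int = 100
    start_distance: float = 4.2  # nm
    depth_per_eps: float = 10.0
    n_lipids_per_leaflet: int = 36  # coarse dynamic runs use a small patch


@dataclass
class UmbrellaConfig:
    d_min: float = 0.0  # nm
    d_max: float = 4.9  # nm
    spacing: float = 0.1  # nm
    k: float = 2000.0  # kJ/mol/nm^2
    n_samples: int = 2000
    equil_steps: int = 2000
    thin: int = 60


@dataclass
class WhamConfig:
    n_bins: int = 200
    tol: float = 1e-7
    max_iter: int = 100000
    bootstrap: int = 50


@dataclass
class AnalysisConfig:
    contact_cutoff: float = 0.5  # nm
    water_cutoff: float = 0.35  # nm
    local_radius: float = 1.0  # nm


@dataclass
class RunConfig:
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    sheet: SheetConfig = field(default_factory=SheetConfig)
    membrane: MembraneConfig = field(default_factory=MembraneConfig)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    umbrella: UmbrellaConfig = field(default_factory=UmbrellaConfig)
    wham: WhamConfig = field(default_factory=WhamConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    out_dir: str = "sheetmem_out"

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> "RunConfig":
        checks = [
            (self.lattice.a > 0, "lattice.a must be positive"),
            (self.sheet.side_length >= self.lattice.a,
             "sheet.side_length must be at least one lattice spacing"),
            (self.sheet.aging in ("fresh", "aged"),
             "sheet.aging must be 'fresh' or 'aged'"),
            (self.umbrella.k > 0, "umbrella.k must be positive"),
            (self.umbrella.spacing > 0, "umbrella.spacing must be positive"),
            (self.simulator.dt > 0, "simulator.dt must be positive"),
            (self.simulator.temperature > 0, "simulator.temperature must be positive"),
            (self.wham.n_bins >= 2, "wham.n_bins must be >= 2"),
            (self.analysis.contact_cutoff > 0, "analysis.contact_cutoff must be positive"),
            (self.membrane.beads_per_chain >= 2,
             "membrane.beads_per_chain must be >= 2"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        return self


def _build(cls, data, path=""):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(f'{path}{k}' for k in unknown))}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        sub = f.type if isinstance(f.type, type) else None
        target = {
            "lattice": LatticeConfig, "sheet": SheetConfig, "membrane": MembraneConfig,
            "simulator": SimulatorConfig, "umbrella": UmbrellaConfig,
            "wham": WhamConfig, "analysis": AnalysisConfig,
        }.get(name, sub)
        if target is not None and name in (
            "lattice", "sheet", "membrane", "simulator", "umbrella", "wham", "analysis"
        ):
            kwargs[name] = _build(target, data[name], path=f"{name}.")
        else:
            kwargs[name] = data[name]
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; omissions take study defaults."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    cfg = _build(RunConfig, data or {})
    return cfg.validate()


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
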