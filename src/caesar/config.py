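"""TOML run configuration with validated defaults.

Every default matches the model's standard settings: Matérn order 3/2 with
magnitude 0.1 and length-scale 3.6 s, Student-t noise dof 4 with
tau ~ Gamma(1, 0.01), self-link weight 1, size prior (d=200, w=5, off by
default), single-chain protocol 50/100/50 with consensus threshold 0.9,
population protocol 50 chains / 11 link sweeps / first-sweep temperature
1000.  Unknown keys are a hard error so typos cannot silently revert a
setting to its default.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .likelihood import GPSpec, NoiseState
from .popmc import PopulationConfig
from .sampler import SamplerConfig
from .spatial import SizePrior

__all__ = ["RunConfig", "parse_config"]


class ConfigError(ValueError):
    pass


_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "model": {
        "kind": str, "magnitude": float, "length_scale": float, "order": float,
    },
    "noise": {"tau": float, "a0": float, "b0": float, "dof": float},
    "spatial": {
        "self_weight": float, "rows": int, "cols": int, "cutoff": float,
        "edge_list": str, "triangles": str,
    },
    "size_prior": {"enabled": bool, "d": int, "w": float},
    "sampler": {
        "n_burnin": int, "n_samples": int, "n_timecourse_samples": int,
        "coassign_threshold": float, "temperature": float,
        "scan_order": str, "init_n_clusters": int,
    },
    "population": {
        "n_chains": int, "link_sweeps_per_round": int,
        "first_sweep_temperature": float, "n_rounds": int,
    },
    "run": {"seed": int, "standardize": bool},
}


@dataclass
class RunConfig:
    gp: GPSpec = field(default_factory=GPSpec)
    noise: NoiseState = field(default_factory=NoiseState)
    self_weight: float = 1.0
    rows: int | None = None
    cols: int | None = None
    cutoff: float = 1.0
    edge_list: str | None = None
    triangles: str | None = None
    size_prior: SizePrior = field(
        default_factory=lambda: SizePrior(enabled=False)
    )
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    seed: int = 0
    standardize: bool = True


def _check_keys(raw: dict) -> None:
    for section, content in raw.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section [{section}]")
        if not isinstance(content, dict):
            raise ConfigError(f"[{section}] must be a table")
        for key in content:
            if key not in _SCHEMA[section]:
                raise ConfigError(f"unknown key '{key}' in [{section}]")


def parse_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration.

    Omitted keys take the standard defaults; unknown keys or out-of-range
    values raise :class:`ConfigError` naming the offending key.
    """
    raw = tomllib.loads(Path(path).read_text())
    _check_keys(raw)
    cfg = RunConfig()

    m = raw.get("model", {})
    try:
        cfg.gp = GPSpec(
            kind=m.get("kind", "matern"),
            magnitude=m.get("magnitude", 0.1),
            length_scale=m.get("length_scale", 3.6),
            order=m.get("order", 1.5),
        )
    except ValueError as err:
        raise ConfigError(f"invalid [model] settings: {err}") from err

    nz = raw.get("noise", {})
    cfg.noise = NoiseState(
        tau=nz.get("tau", 1.0),
        prior_a0=nz.get("a0", 1.0),
        prior_b0=nz.get("b0", 0.01),
        dof=nz.get("dof", 4.0),
    )
    if cfg.noise.tau <= 0 or cfg.noise.prior_b0 <= 0 or cfg.noise.dof <= 0:
        raise ConfigError("noise parameters tau, b0 and dof must be positive")

    sp = raw.get("spatial", {})
    cfg.self_weight = sp.get("self_weight", 1.0)
    if cfg.self_weight < 0:
        raise ConfigError("spatial.self_weight must be nonnegative")
    cfg.rows, cfg.cols = sp.get("rows"), sp.get("cols")
    cfg.cutoff = sp.get("cutoff", 1.0)
    cfg.edge_list = sp.get("edge_list")
    cfg.triangles = sp.get("triangles")

    z = raw.get("size_prior", {})
    try:
        cfg.size_prior = SizePrior(
            d=z.get("d", 200), w=z.get("w", 5.0),
            enabled=z.get("enabled", "d" in z or "w" in z),
        )
    except ValueError as err:
        raise ConfigError(f"invalid [size_prior]: {err}") from err

    s = raw.get("sampler", {})
    try:
        cfg.sampler = SamplerConfig(
            n_burnin=s.get("n_burnin", 50),
            n_samples=s.get("n_samples", 100),
            n_timecourse_samples=s.get("n_timecourse_samples", 50),
            coassign_threshold=s.get("coassign_threshold", 0.9),
            temperature=s.get("temperature", 1.0),
            scan_order=s.get("scan_order", "shuffled"),
            init_n_clusters=s.get("init_n_clusters", 20),
        )
    except ValueError as err:
        raise ConfigError(f"invalid [sampler]: {err}") from err

    p = raw.get("population", {})
    try:
        cfg.population = PopulationConfig(
            n_chains=p.get("n_chains", 50),
            link_sweeps_per_round=p.get("link_sweeps_per_round", 11),
            first_sweep_temperature=p.get("first_sweep_temperature", 1000.0),
            n_rounds=p.get("n_rounds", 100),
        )
    except ValueError as err:
        raise ConfigError(f"invalid [population]: {err}") from err

    r = raw.get("run", {})
    cfg.seed = r.get("seed", 0)
    cfg.standardize = r.get("standardize", True)
    cfg.sampler.seed = cfg.seed
    cfg.population.seed = cfg.seed
    return cfg
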