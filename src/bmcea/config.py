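"""Configuration schema, validation and run manifests.

Configs are YAML/JSON mappings with a fixed, documented key set; any
unknown key is a hard error so typos never silently fall back to
defaults.  Every result file a run emits can reference a ``RunManifest``
recording the config hash, seed, package version, timestamps, input-file
checksums and the assumption flags (PSA distribution defaults,
half-cycle setting) in force.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field

import yaml

from .cohort import CostParams, ModelConfig
from .utilities import UtilityParams

__all__ = ["load_config", "build_components", "RunManifest", "get_logger"]

__version__ = "0.1.0"

log = logging.getLogger("bmcea")


def get_logger() -> logging.Logger:
    if not log.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(h)
        log.setLevel(logging.INFO)
    return log


class ConfigError(ValueError):
    pass


_SCHEMA: dict[str, set[str]] = {
    "model": {
        "cycle_len_days",
        "horizon_years",
        "discount_rate_annual",
        "wtp_per_qaly",
        "half_cycle_correction",
    },
    "costs": {f.name for f in dataclasses.fields(CostParams)},
    "utilities": {
        "u_pf_pre",
        "u_pf_post",
        "u_pd_nobm",
        "u_pd_bm",
        "d_leukocyte",
        "d_anemia",
        "d_platelet",
    },
    "psa": {"n_draws", "seed"},
    "dsa": {"conversion_factor_bounds", "rel_range"},
    "scenarios": {"horizons"},
}


def _validate(cfg: dict):
    unknown_sections = set(cfg) - set(_SCHEMA)
    if unknown_sections:
        raise ConfigError(f"unknown config section(s): {sorted(unknown_sections)}")
    for section, keys in cfg.items():
        if not isinstance(keys, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        bad = set(keys) - _SCHEMA[section]
        if bad:
            raise ConfigError(f"unknown key(s) in [{section}]: {sorted(bad)}")


def load_config(path) -> dict:
    """Read and validate a YAML/JSON config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    _validate(cfg)
    return cfg


def build_components(cfg: dict) -> tuple[ModelConfig, CostParams, UtilityParams]:
    """Materialise config sections, logging which values were overridden."""
    logger = get_logger()
    m = dict(cfg.get("model", {}))
    if "cycle_len_days" in m:
        m["cycle_len"] = float(m.pop("cycle_len_days")) / 365.25
    model_cfg = ModelConfig(**m)
    for k in m:
        logger.info("model.%s set from config", k)

    costs = CostParams(**cfg.get("costs", {}))
    for k in cfg.get("costs", {}):
        logger.info("costs.%s set from config", k)

    u = dict(cfg.get("utilities", {}))
    disutility = {
        cat: u.pop(f"d_{cat}")
        for cat in ("leukocyte", "anemia", "platelet")
        if f"d_{cat}" in u
    }
    if disutility:
        base = UtilityParams().disutility
        base.update(disutility)
        u["disutility"] = base
    utilities = UtilityParams(**u)
    for k in cfg.get("utilities", {}):
        logger.info("utilities.%s set from config", k)
    return model_cfg, costs, utilities


@dataclass
class RunManifest:
    """Provenance record attached to every emitted result file."""

    seed: int
    config_hash: str
    package_version: str = __version__
    created_utc: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )
    input_checksums: dict[str, str] = field(default_factory=dict)
    assumptions: dict[str, object] = field(
        default_factory=lambda: {
            "psa_distributions": "beta(utilities/proportions, SE=10% of base), "
            "gamma(costs, SE=25% of base), negated gamma(disutilities), "
            "MVN(survival coefficients, fit covariance)",
            "half_cycle_correction": True,
        }
    )

    @classmethod
    def create(cls, cfg: dict, seed: int, input_paths=()) -> "RunManifest":
        blob = json.dumps(cfg, sort_keys=True).encode()
        checksums = {}
        for p in input_paths:
            with open(p, "rb") as fh:
                checksums[str(p)] = hashlib.sha256(fh.read()).hexdigest()[:16]
        return cls(
            seed=seed,
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            input_checksums=checksums,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)
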