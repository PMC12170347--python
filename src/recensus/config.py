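"""One-file YAML configuration for the whole pipeline.

A config file holds up to four blocks — ``sim``, ``perturb``, ``priors``,
``mcmc`` — each mapping directly onto the corresponding dataclass; absent
blocks fall back to defaults.  Two-element lists become the tuples the
dataclasses expect.
"""

from __future__ import annotations

import yaml

from .mcmc import MCMCConfig
from .model import PriorSpec
from .perturbation import PerturbConfig
from .synthetic import RegisterConfig, SimConfig

__all__ = ["load_config"]

_TUPLE_FIELDS = {
    "pop_range",
    "response_rate_range",
    "remoteness_effects",
    "noise_pmf",
    "beta0_young",
    "beta0_old",
    "beta_ses",
    "gamma",
    "log_sigma_u",
    "log_rho",
}


def _coerce(block: dict) -> dict:
    out = {}
    for k, v in (block or {}).items():
        out[k] = tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
    return out


def load_config(path) -> dict:
    """Load a pipeline config; returns dataclasses keyed by block name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {
        "sim": SimConfig(**_coerce(raw.get("sim", {}))),
        "perturb": PerturbConfig(**_coerce(raw.get("perturb", {}))),
        "priors": PriorSpec(**_coerce(raw.get("priors", {}))),
        "mcmc": MCMCConfig(**_coerce(raw.get("mcmc", {}))),
        "registers": RegisterConfig(**_coerce(raw.get("registers", {}))),
    }
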