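"""YAML/JSON configuration helpers for model parameters."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .core import HierarchicalParams
from .stochastic import StochasticParams

__all__ = ["load_config", "params_from_config", "stochastic_params_from_config"]

_HIER_KEYS = {"delta", "n_senescence", "death_prob", "division_rate", "csc_fraction_0"}
_STOCH_KEYS = {"p_dup", "p_die", "p_sen", "death_prob"}


def load_config(path) -> dict:
    """Load a YAML or JSON mapping."""
    text = Path(path).read_text()
    data = (
        json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    )
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def params_from_config(config: dict) -> HierarchicalParams:
    """Build :class:`HierarchicalParams` from a config block, accepting
    either ``delta`` or explicit division probabilities ``p2``/``p0``."""
    cfg = dict(config)
    if "p2" in cfg or "p0" in cfg:
        return HierarchicalParams.from_division_probs(
            p_sym_csc=cfg.pop("p2", 0.0),
            p_sym_cc=cfg.pop("p0", 0.0),
            **{k: v for k, v in cfg.items() if k in _HIER_KEYS - {"delta"}},
        )
    unknown = set(cfg) - _HIER_KEYS
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return HierarchicalParams(**cfg)


def stochastic_params_from_config(config: dict) -> StochasticParams:
    unknown = set(config) - _STOCH_KEYS
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return StochasticParams(**config)
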