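"""Named parameter schemes and config-file loading.

Schemes A-D are the exploratory settings (increasing tumble/population/
iteration load, shared attraction/repulsion parameters, w_repel = 0.001);
scheme K is the 30-run comparison setting (w_repel = 0.002, swim = 50);
``dtp`` is the elitist variant's setting (population 8, 200 iterations,
tumble 100, swim 1, w_repel = 1, normalized scoring, per-matrix NFE);
``ga`` is the matching Genetic Algorithm baseline.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .ga import GAConfig
from .optimizers import SchemeConfig
from .scoring import ScoringConfig
from .swarm import SwarmParams

__all__ = ["SCHEME_NAMES", "scheme", "load_scheme_file"]

SCHEME_NAMES = ("A", "B", "C", "D", "K", "dtp", "ga")

_BFOA_PRESETS: dict[str, dict] = {
    "A": dict(tumble=100, population=22, iterations=100, swim=0, w_repel=0.001),
    "B": dict(tumble=160, population=44, iterations=200, swim=0, w_repel=0.001),
    "C": dict(tumble=180, population=88, iterations=400, swim=0, w_repel=0.001),
    "D": dict(tumble=330, population=120, iterations=800, swim=0, w_repel=0.001),
    "K": dict(tumble=200, population=120, iterations=33, swim=50, w_repel=0.002),
}


def scheme(name: str, seed: int = 0, **overrides) -> SchemeConfig | GAConfig:
    """Build a preset configuration, optionally overriding top-level fields.

    ``w_repel`` and other swarm/scoring fields may be overridden directly;
    they are routed into the nested configs.
    """
    if name in _BFOA_PRESETS:
        p = dict(_BFOA_PRESETS[name])
        p.update(overrides)
        swarm_kw = {
            k: p.pop(k) for k in ("d_attr", "w_attr", "h_repel", "w_repel") if k in p
        }
        scoring_kw = {
            k: p.pop(k)
            for k in ("indel_penalty", "gap_gap_score", "normalize", "alphabet")
            if k in p
        }
        return SchemeConfig(
            swarm=SwarmParams(**swarm_kw),
            scoring=ScoringConfig(**scoring_kw),
            seed=seed,
            **p,
        )
    if name == "dtp":
        p = dict(tumble=100, population=8, iterations=200, swim=1, w_repel=1.0)
        p.update(overrides)
        swarm_kw = {
            k: p.pop(k) for k in ("d_attr", "w_attr", "h_repel", "w_repel") if k in p
        }
        scoring_kw = {
            k: p.pop(k)
            for k in ("indel_penalty", "gap_gap_score", "alphabet")
            if k in p
        }
        return SchemeConfig(
            swarm=SwarmParams(**swarm_kw),
            scoring=ScoringConfig(normalize=True, **scoring_kw),
            nfe_mode="per_matrix",
            elitism=int(p.pop("elitism", 1)),
            seed=seed,
            **p,
        )
    if name == "ga":
        return GAConfig(seed=seed, **overrides)
    raise ValueError(f"unknown scheme {name!r}; options: {SCHEME_NAMES}")


def load_scheme_file(path) -> SchemeConfig | GAConfig:
    """Load a configuration from YAML or JSON.

    The file either names a preset (``scheme: K``) with optional overrides,
    or spells out the fields of a scheme/GA config directly (``algorithm:
    ga`` selects the GA form).
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    data = dict(data)
    seed = int(data.pop("seed", 0))
    name = data.pop("scheme", None)
    algo = data.pop("algorithm", None)
    if name:
        return scheme(str(name), seed=seed, **data)
    if algo == "ga":
        return GAConfig(seed=seed, **data)
    swarm_kw = {k: data.pop(k) for k in ("d_attr", "w_attr", "h_repel", "w_repel") if k in data}
    scoring_kw = {
        k: data.pop(k)
        for k in ("indel_penalty", "gap_gap_score", "normalize", "alphabet")
        if k in data
    }
    return SchemeConfig(
        swarm=SwarmParams(**swarm_kw),
        scoring=ScoringConfig(**scoring_kw),
        seed=seed,
        **data,
    )


def scheme_to_dict(cfg: SchemeConfig | GAConfig) -> dict:
    """Flatten a config to a plain dict (for summary JSON files)."""
    if isinstance(cfg, GAConfig):
        return dataclasses.asdict(cfg)
    d = dataclasses.asdict(cfg)
    d["swarm"] = dataclasses.asdict(cfg.swarm)
    d["scoring"] = dataclasses.asdict(cfg.scoring)
    return d
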