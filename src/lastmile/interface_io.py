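"""Run configuration, YAML round-trip, log export, and test fixtures.

A :class:`RunConfig` bundles everything a single simulation needs: island
dimensions and founders, life-history rates, the toxicant window, the
release plan, and the horizon.  Configs round-trip losslessly through YAML;
unknown or out-of-range keys are rejected with an error naming the key.
``config_id`` hashes the canonical form so logs can record exact
provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .genetics import Strategy
from .interventions import ReleasePlan, ToxicantPlan
from .population_core import CycleLog, LifeHistoryParams

__all__ = [
    "IslandConfig",
    "RunConfig",
    "default_config",
    "parse_config",
    "config_to_dict",
    "write_config",
    "make_fixture_island",
    "cycle_log_frame",
]

# Per-patch carrying capacities calibrated (experiments.calibrate_K) so the
# 8-year burn-in equilibrates at ~11,000 on the 16x16 island and ~700 on
# the 8x8 mini fixture, under the default life-history rates.
PAPER_K = 49.7
MINI_K = 13.7


@dataclass(frozen=True)
class IslandConfig:
    rows: int = 16
    cols: int = 16
    founders: int = 2000

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("island dims must be positive")
        if self.founders < 0:
            raise ValueError("founders must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    """Full specification of one simulation run."""

    seed: int = 1
    island: IslandConfig = field(default_factory=IslandConfig)
    life_history: LifeHistoryParams = field(default_factory=LifeHistoryParams)
    toxicant: Optional[ToxicantPlan] = field(default_factory=ToxicantPlan)
    release: Optional[ReleasePlan] = field(default_factory=ReleasePlan)
    cycles: int = 200
    burn_in_years: int = 8

    def __post_init__(self) -> None:
        if self.cycles <= 0:
            raise ValueError("cycles must be > 0")
        if self.burn_in_years < 0:
            raise ValueError("burn_in_years must be >= 0")

    @property
    def config_id(self) -> str:
        payload = json.dumps(config_to_dict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def default_config(seed: int = 1) -> RunConfig:
    """The headline scenario: 16 x 16 island, 8-year burn-in, one year of
    toxicant at c_s = 0.2, then broad Gravid Lethal releases."""
    return RunConfig(seed=seed, life_history=LifeHistoryParams(K=PAPER_K))


def _build(cls, data: dict, path: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under '{path}'")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid value under '{path}': {exc}") from exc


def parse_config(source) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``source`` is a path or an already-loaded mapping.  Missing sections
    take the documented defaults; unknown keys anywhere are an error.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source or {})
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")

    top_valid = {
        "seed",
        "island",
        "life_history",
        "toxicant",
        "release",
        "cycles",
        "burn_in_years",
    }
    unknown = set(data) - top_valid
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)}")

    island = _build(IslandConfig, data.get("island", {}) or {}, "island")
    lh_data = dict(data.get("life_history", {}) or {})
    lh_data.setdefault("K", PAPER_K)
    life_history = _build(LifeHistoryParams, lh_data, "life_history")

    toxicant = None
    if data.get("toxicant", "default") is not None:
        toxicant = _build(ToxicantPlan, data.get("toxicant", {}) or {}, "toxicant")

    release = None
    if data.get("release", "default") is not None:
        rel = dict(data.get("release", {}) or {})
        if "genetic_strategy" in rel:
            try:
                rel["genetic_strategy"] = Strategy(rel["genetic_strategy"])
            except ValueError as exc:
                raise ValueError(
                    f"invalid value under 'release.genetic_strategy': {exc}"
                ) from exc
        release = _build(ReleasePlan, rel, "release")

    kwargs = {k: data[k] for k in ("seed", "cycles", "burn_in_years") if k in data}
    return RunConfig(
        island=island,
        life_history=life_history,
        toxicant=toxicant,
        release=release,
        **kwargs,
    )


def config_to_dict(cfg: RunConfig) -> dict:
    """Canonical plain-dict form of a config (YAML/JSON serializable)."""
    out = {
        "seed": cfg.seed,
        "cycles": cfg.cycles,
        "burn_in_years": cfg.burn_in_years,
        "island": dataclasses.asdict(cfg.island),
        "life_history": dataclasses.asdict(cfg.life_history),
        "toxicant": dataclasses.asdict(cfg.toxicant) if cfg.toxicant else None,
        "release": None,
    }
    if cfg.release:
        rel = dataclasses.asdict(cfg.release)
        rel["genetic_strategy"] = cfg.release.genetic_strategy.value
        out["release"] = rel
    return out


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def make_fixture_island(scale: str, seed: int = 1) -> RunConfig:
    """Canned configurations.

    ``paper``: the full 16 x 16 / ~11,000-mouse scenario.
    ``mini``: an 8 x 8 island whose burn-in equilibrates near 700 mice, so
    a complete scenario (burn-in, toxicant, releases, horizon) runs in
    well under a second for tests.
    """
    if scale == "paper":
        return default_config(seed=seed)
    if scale == "mini":
        return RunConfig(
            seed=seed,
            island=IslandConfig(rows=8, cols=8, founders=250),
            life_history=LifeHistoryParams(K=MINI_K),
            # culling scaled up so the small population reliably leaves a
            # post-toxicant remnant to hand over to biocontrol
            toxicant=ToxicantPlan(c_s=0.35, start_cycle=48, duration_cycles=6),
            release=ReleasePlan(
                strategy="broad",
                n_p=16,
                n_i=12,
                N_i=10,
                start_cycle=54,
                genetic_strategy=Strategy.GRAVID_LETHAL,
            ),
            cycles=200,
            burn_in_years=8,
        )
    raise ValueError(f"unknown fixture scale {scale!r}; use 'mini' or 'paper'")


def cycle_log_frame(logs: list[CycleLog]):
    """Flatten per-cycle logs into a pandas DataFrame with the documented
    CSV columns."""
    import pandas as pd

    return pd.DataFrame([log.as_row() for log in logs], columns=CycleLog.CSV_COLUMNS)
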