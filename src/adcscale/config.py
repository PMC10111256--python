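"""YAML run-configuration schema and validation.

A run configuration has four blocks — ``kinetics``, ``vessel``, ``feed`` and
``simulation`` — plus an optional ``physical`` block with impeller/fluid data
for the scale-up metrics.  All units follow the package conventions: mM,
seconds, m^3, rpm.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .compartment import (
    CompartmentNetwork,
    VesselTemplate,
    build_template,
    load_flow_map,
    vessel_template,
)
from .kinetics import (
    ActivationDistribution,
    FeedSchedule,
    KineticParameters,
    molar_from_mass,
)

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


def _require(block: dict, key: str, context: str):
    if key not in block:
        raise ConfigError(f"missing required key {key!r} in {context} block")
    return block[key]


def _number(block: dict, key: str, context: str, default=None, positive=False):
    v = block.get(key, default)
    if v is None:
        raise ConfigError(f"missing required key {key!r} in {context} block")
    if not isinstance(v, (int, float)) or isinstance(v, bool):
        raise ConfigError(f"{context}.{key} must be a number, got {v!r}")
    if positive and v <= 0:
        raise ConfigError(f"{context}.{key} must be positive, got {v}")
    return float(v)


@dataclass
class RunConfig:
    """Validated, fully resolved run configuration."""

    params: KineticParameters
    distribution: ActivationDistribution
    c_mab0: float  # mM
    excess: float
    molar_mass: float
    feed: FeedSchedule
    vessel: VesselTemplate | None
    network: CompartmentNetwork | None
    t_end: float
    output_grid: float
    seed: int
    physical: dict = field(default_factory=dict)
    config_hash: str = ""

    @property
    def total_payload(self) -> float:
        return self.feed.total_payload


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        loc = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"malformed YAML{loc}: {exc}") from None
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a YAML mapping")

    kin = doc.get("kinetics", {})
    if not isinstance(kin, dict):
        raise ConfigError("kinetics block must be a mapping")
    params = KineticParameters(
        k1=_number(kin, "k1", "kinetics", 0.797),
        k2=_number(kin, "k2", "kinetics", 1.476),
        k3=_number(kin, "k3", "kinetics", 0.00155),
    )
    dist_block = kin.get("distribution")
    if dist_block is None:
        distribution = ActivationDistribution()
    elif isinstance(dist_block, dict):
        try:
            distribution = ActivationDistribution(
                p2=float(dist_block.get("p2", 0.0)),
                p1=float(dist_block.get("p1", 0.0)),
                p0=float(dist_block.get("p0", 0.0)),
            )
        except ValueError as exc:
            raise ConfigError(f"invalid activation distribution: {exc}") from None
    else:
        raise ConfigError("kinetics.distribution must be a mapping with p2/p1/p0")
    molar_mass = _number(kin, "molar_mass", "kinetics", 150000.0, positive=True)
    mab_mg_per_ml = _number(kin, "mab_mg_per_ml", "kinetics", 5.0, positive=True)
    excess = _number(kin, "excess", "kinetics", 5.0, positive=True)
    c_mab0 = molar_from_mass(mab_mg_per_ml, molar_mass)

    feed_block = doc.get("feed", {})
    if not isinstance(feed_block, dict):
        raise ConfigError("feed block must be a mapping")
    mode = feed_block.get("mode", "constant-rate")
    duration = _number(feed_block, "duration_s", "feed", 60.0)
    stock = _number(feed_block, "stock_mM", "feed", 10.0, positive=True)
    total_payload = excess * c_mab0
    try:
        if mode == "batch-instant" or duration == 0:
            feed = FeedSchedule.batch(total_payload, stock)
        else:
            feed = FeedSchedule(mode, duration, total_payload, stock)
    except ValueError as exc:
        raise ConfigError(f"invalid feed block: {exc}") from None

    vessel_block = doc.get("vessel")
    vessel = None
    network = None
    if vessel_block is not None:
        if not isinstance(vessel_block, dict):
            raise ConfigError("vessel block must be a mapping")
        if "flow_map" in vessel_block:
            fm = Path(vessel_block["flow_map"])
            if not fm.exists():
                raise ConfigError(f"flow map file not found: {fm}")
            try:
                network = load_flow_map(fm)
            except (ValueError, KeyError) as exc:
                raise ConfigError(f"invalid flow map: {exc}") from None
        elif "template" in vessel_block:
            overrides = {}
            if "target_mixing_time_s" in vessel_block:
                overrides["target_global_mixing_time"] = _number(
                    vessel_block, "target_mixing_time_s", "vessel", positive=True
                )
            for k_yaml, k_field in (("levels", "levels"), ("rings", "rings")):
                if k_yaml in vessel_block:
                    overrides[k_field] = int(vessel_block[k_yaml])
            try:
                vessel = vessel_template(vessel_block["template"], **overrides)
                network = build_template(vessel)
            except ValueError as exc:
                raise ConfigError(str(exc)) from None
            for k_yaml, attr in (("feed_index", "feed_index"), ("probe_index", "probe_index")):
                if vessel_block.get(k_yaml) is not None:
                    idx = int(vessel_block[k_yaml])
                    if not 0 <= idx < network.n:
                        raise ConfigError(f"vessel.{k_yaml}={idx} out of range")
                    from dataclasses import replace

                    network = replace(network, **{attr: idx})
        else:
            raise ConfigError("vessel block needs either 'template' or 'flow_map'")

    sim = doc.get("simulation", {})
    if not isinstance(sim, dict):
        raise ConfigError("simulation block must be a mapping")
    t_end = _number(sim, "t_end_s", "simulation", 300.0, positive=True)
    output_grid = _number(sim, "output_grid_s", "simulation", 0.1, positive=True)
    seed = sim.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError("simulation.seed must be an integer")

    physical = doc.get("physical", {}) or {}
    if not isinstance(physical, dict):
        raise ConfigError("physical block must be a mapping")

    return RunConfig(
        params=params,
        distribution=distribution,
        c_mab0=c_mab0,
        excess=excess,
        molar_mass=molar_mass,
        feed=feed,
        vessel=vessel,
        network=network,
        t_end=t_end,
        output_grid=output_grid,
        seed=seed,
        physical=physical,
        config_hash=hashlib.sha256(text.encode()).hexdigest()[:16],
    )
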