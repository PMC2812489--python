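"""Species life-history archetypes and the cyclic weather-year sequence."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from ._rng import child_rng

__all__ = ["SpeciesParams", "make_archetype", "ARCHETYPE_NAMES", "WeatherSequence"]

ARCHETYPE_NAMES = ("beetle", "vole", "skylark", "spider")


@dataclass(frozen=True)
class SpeciesParams:
    """Parameters of a life-history archetype.

    ``r_max`` is the maximum per-capita yearly offspring rate; per-type
    multipliers scale it by habitat quality.  ``capacity_density`` is the
    carrying density (individuals per cell) entering the emergent logistic
    density dependence.  Short dispersers are stopped by barrier cells
    (``barriers_block``); fliers/ballooners cross them at no extra cost.
    ``complementation_*`` encodes landscape complementation (overwinter
    survival requires habitat of the given types within the radius);
    ``avoidance_*`` suppresses breeding near the given types.  Semelparous
    archetypes die after breeding; iteroparous adults face the same
    overwinter survival as juveniles.
    """

    name: str
    r_max: float
    fecundity_multiplier: Mapping[str, float]
    overwinter_survival: Mapping[str, float]
    capacity_density: Mapping[str, float]
    d_max: int
    dispersal_mortality: float
    barriers_block: bool
    semelparous: bool
    complementation_radius: int = 0
    complementation_types: frozenset = frozenset()
    avoidance_radius: int = 0
    avoidance_types: frozenset = frozenset()

    def __post_init__(self):
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.d_max < 0:
            raise ValueError("d_max must be non-negative")
        for m in (self.fecundity_multiplier, self.overwinter_survival):
            for t, v in m.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{self.name}: probability for {t} outside [0,1]: {v}")
        if not 0.0 <= self.dispersal_mortality <= 1.0:
            raise ValueError("dispersal_mortality outside [0,1]")

    def with_overrides(self, **kwargs) -> "SpeciesParams":
        return replace(self, **kwargs)


def _load_config() -> dict:
    text = resources.files("mosaicpop.data").joinpath("archetypes.yaml").read_text()
    return yaml.safe_load(text)


def make_archetype(name: str) -> SpeciesParams:
    """Packaged default parameterization of one of the four archetypes.

    ``beetle``: fast-reproducing short disperser blocked by barriers,
    overwinter survival requires field-boundary/hedgerow habitat within a
    small complementation radius.  ``vole``: slower-reproducing short
    disperser tied to grassland, with elevated mortality in the arable
    matrix.  ``skylark``: slow-reproducing long disperser breeding in open
    fields, not breeding within the avoidance radius of trees (forest,
    hedgerow).  ``spider``: fast-reproducing ballooner crossing barriers
    freely but paying high dispersal mortality.
    """
    cfg = _load_config()["archetypes"]
    if name not in cfg:
        raise KeyError(f"unknown archetype {name!r}; valid archetypes: {sorted(cfg)}")
    c = cfg[name]
    return SpeciesParams(
        name=name,
        r_max=float(c["r_max"]),
        fecundity_multiplier=dict(c["fecundity_multiplier"]),
        overwinter_survival=dict(c["overwinter_survival"]),
        capacity_density=dict(c["capacity_density"]),
        d_max=int(c["d_max"]),
        dispersal_mortality=float(c["dispersal_mortality"]),
        barriers_block=bool(c["barriers_block"]),
        semelparous=bool(c["semelparous"]),
        complementation_radius=int(c["complementation_radius"]),
        complementation_types=frozenset(c["complementation_types"]),
        avoidance_radius=int(c["avoidance_radius"]),
        avoidance_types=frozenset(c["avoidance_types"]),
    )


@dataclass(frozen=True)
class WeatherSequence:
    """A cycle of 10 labelled yearly fecundity multipliers.

    The multiplier of calendar year ``y`` is the one labelled
    ``(y - 1) mod 10``, so "weather years" form stable, reproducible
    groups across runs and design cells — the random grouping factor of
    the recovery fits.
    """

    multipliers: tuple

    def __post_init__(self):
        if len(self.multipliers) != 10:
            raise ValueError("weather cycle length must be exactly 10")
        if any(w <= 0 for w in self.multipliers):
            raise ValueError("weather multipliers must be positive")

    @classmethod
    def constant(cls, value: float = 1.0) -> "WeatherSequence":
        return cls(tuple([float(value)] * 10))

    @classmethod
    def lognormal(cls, sigma: float = 0.15, seed: int = 0) -> "WeatherSequence":
        """Multipliers drawn log-normal(0, sigma^2), fixed per label."""
        rng = child_rng(seed, "weather")
        return cls(tuple(np.exp(rng.normal(0.0, sigma, size=10)).tolist()))

    @property
    def labels(self) -> tuple:
        return tuple(f"w{i}" for i in range(10))

    def label_for_year(self, year: int) -> str:
        return f"w{(year - 1) % 10}"

    def multiplier_for_year(self, year: int) -> float:
        return float(self.multipliers[(year - 1) % 10])
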