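"""Scenario configuration for synthetic structured cohorts.

A :class:`ScenarioConfig` fully specifies a synthetic cohort: the deme
layout, the coancestry model (spatial decay + within-deme boost + Dirichlet
noise), the IBD segment model (Poisson event counts, gamma coalescence
times, Erlang segment lengths), ancestry gradients and a stratified binary
phenotype.  Identical ``(config, seed)`` always yields a bit-identical
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a scenario configuration field is invalid."""


@dataclass(frozen=True)
class GradientSpec:
    """A linear spatial gradient for one ancestry source.

    The true share of ``source`` in an individual at coordinates (lon, lat)
    is ``intercept + slope * p`` where ``p = lon*sin(bearing) +
    lat*cos(bearing)`` is the projection of the coordinates on the compass
    bearing (degrees clockwise from north).  ``noise_sd`` is the standard
    deviation of zero-mean Gaussian noise added to the corresponding
    component of the *target* copying vector (not to the truth).
    """

    source: str
    bearing_deg: float
    intercept: float
    slope_per_deg: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bearing_deg < 360.0:
            raise ConfigError(f"gradient_specs[{self.source!r}].bearing_deg "
                              f"must be in [0, 360), got {self.bearing_deg}")
        if self.noise_sd < 0:
            raise ConfigError(f"gradient_specs[{self.source!r}].noise_sd must be >= 0")


# Default deme centres: three Dutch towns spanning the country's
# north/south axis (Amsterdam, Leeuwarden, Maastricht), in (lon, lat).
_DEFAULT_CENTERS = ((4.90, 52.37), (5.80, 53.20), (5.69, 50.85))

_DEFAULT_GRADIENTS = (
    GradientSpec("source_east", 90.0, 0.30, 0.06, 0.0),
    GradientSpec("source_south", 180.0, 0.40, 0.08, 0.0),
    GradientSpec("source_north", 0.0, 0.30, 0.04, 0.0),
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic structured cohort.

    Parameters
    ----------
    n_demes, deme_centers, n_per_deme
        Discrete subpopulations with planar (longitude, latitude) centres
        in degrees; individuals scatter around their centre with
        ``coord_jitter_sd``.
    genome_length_cM
        Total map length each recipient receives from donors (row sum of
        the coancestry matrix).
    within_deme_boost
        kappa >= 0; multiplies expected donation within a deme by
        ``1 + kappa``.
    spatial_decay
        rho > 0 in degrees; expected donation decays as exp(-d/rho).
    dirichlet_concentration
        alpha > 0; realized coancestry rows are genome_length * Dirichlet
        with concentration vector ``alpha * expectation``.  Large alpha
        gives near-deterministic rows.
    ibd_rate_within, ibd_rate_between
        Poisson mean number of IBD segment events per pair, by pair class.
    tmrca_within, tmrca_between
        (shape, scale) of the gamma law of coalescence time in generations
        for each pair class.
    min_length_cM
        Detection floor; shorter segments are discarded.
    gradient_specs
        One :class:`GradientSpec` per ancestry source.
    phenotype_base, phenotype_intercepts
        Case probability in deme d is ``logistic(phenotype_base +
        phenotype_intercepts[d])``.
    seed
        Master seed; expanded into independent substreams for coancestry,
        IBD, ancestry, and phenotype so toggling one component does not
        shift another's draws.
    """

    n_demes: int = 3
    deme_centers: Sequence[tuple[float, float]] | None = None
    n_per_deme: int = 20
    genome_length_cM: float = 3500.0
    within_deme_boost: float = 5.0
    spatial_decay: float = 1.0
    dirichlet_concentration: float = 1000.0
    ibd_rate_within: float = 20.0
    ibd_rate_between: float = 20.0
    tmrca_within: tuple[float, float] = (4.0, 10.0)
    tmrca_between: tuple[float, float] = (4.0, 30.0)
    min_length_cM: float = 1.0
    coord_jitter_sd: float = 0.15
    gradient_specs: Sequence[GradientSpec] = _DEFAULT_GRADIENTS
    phenotype_base: float = 0.0
    phenotype_intercepts: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_demes < 1:
            raise ConfigError("n_demes must be >= 1")
        if self.deme_centers is None:
            # default layout: the three reference towns, or a ring of demes
            # around the Dutch centroid for larger counts
            if self.n_demes <= len(_DEFAULT_CENTERS):
                centers = [tuple(map(float, c))
                           for c in _DEFAULT_CENTERS[:self.n_demes]]
            else:
                import math
                centers = [
                    (5.5 + 1.2 * math.sin(2 * math.pi * d / self.n_demes),
                     52.0 + 1.2 * math.cos(2 * math.pi * d / self.n_demes))
                    for d in range(self.n_demes)]
            object.__setattr__(self, "deme_centers", tuple(centers))
        if len(self.deme_centers) != self.n_demes:
            raise ConfigError(
                f"deme_centers must have n_demes={self.n_demes} entries, "
                f"got {len(self.deme_centers)}")
        centers = tuple(tuple(map(float, c)) for c in self.deme_centers)
        object.__setattr__(self, "deme_centers", centers)
        object.__setattr__(self, "tmrca_within", tuple(map(float, self.tmrca_within)))
        object.__setattr__(self, "tmrca_between", tuple(map(float, self.tmrca_between)))
        object.__setattr__(self, "gradient_specs", tuple(self.gradient_specs))
        if self.phenotype_intercepts is not None:
            object.__setattr__(self, "phenotype_intercepts",
                               tuple(map(float, self.phenotype_intercepts)))
        if len(set(centers)) != len(centers):
            raise ConfigError("deme_centers must be distinct")
        if self.n_per_deme < 2:
            raise ConfigError("n_per_deme must be >= 2")
        for name in ("genome_length_cM", "spatial_decay",
                     "dirichlet_concentration", "min_length_cM"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.within_deme_boost < 0:
            raise ConfigError("within_deme_boost must be >= 0")
        for name in ("ibd_rate_within", "ibd_rate_between"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("tmrca_within", "tmrca_between"):
            shape, scale = getattr(self, name)
            if shape <= 0 or scale <= 0:
                raise ConfigError(f"{name} (shape, scale) must be strictly positive")
        if self.coord_jitter_sd < 0:
            raise ConfigError("coord_jitter_sd must be >= 0")
        if self.phenotype_intercepts is not None and \
                len(self.phenotype_intercepts) != self.n_demes:
            raise ConfigError(
                f"phenotype_intercepts must have n_demes={self.n_demes} entries")
        names = [g.source for g in self.gradient_specs]
        if len(set(names)) != len(names):
            raise ConfigError("gradient_specs source names must be unique")

    # -- derived quantities -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.n_demes * self.n_per_deme

    @property
    def source_names(self) -> list[str]:
        return [g.source for g in self.gradient_specs]

    def intercepts(self) -> list[float]:
        if self.phenotype_intercepts is None:
            return [0.0] * self.n_demes
        return list(self.phenotype_intercepts)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["deme_centers"] = [list(c) for c in self.deme_centers]
        d["tmrca_within"] = list(self.tmrca_within)
        d["tmrca_between"] = list(self.tmrca_between)
        d["gradient_specs"] = [asdict(g) for g in self.gradient_specs]
        if self.phenotype_intercepts is not None:
            d["phenotype_intercepts"] = list(self.phenotype_intercepts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        if "deme_centers" in d:
            d["deme_centers"] = tuple(tuple(map(float, c)) for c in d["deme_centers"])
        for key in ("tmrca_within", "tmrca_between"):
            if key in d:
                d[key] = tuple(map(float, d[key]))
        if "gradient_specs" in d:
            d["gradient_specs"] = tuple(
                g if isinstance(g, GradientSpec) else GradientSpec(**g)
                for g in d["gradient_specs"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
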