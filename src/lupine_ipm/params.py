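"""Vital-rate parameter containers and (de)serialization.

A :class:`VitalRateParams` bundles everything one origin x treatment cell of
the demographic model needs: the size-dependent vital-rate functions
(survival, growth, flowering probability, flowering-shoot number, recruit-size
distribution) and the size-independent life-cycle constants (establishment
probabilities, seed-bank survival, seeds per flowering shoot). The continuous
size variable throughout is log-transformed plant height.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping

import yaml

ORIGINS = ("invasive_FI", "native_US")
TREATMENTS = ("intact", "autoclaved")
CELLS = tuple((o, t) for o in ORIGINS for t in TREATMENTS)


@dataclass(frozen=True)
class LogisticRate:
    """Linear predictor on the logit scale: logit(rate) = intercept + slope * x."""

    intercept: float
    slope: float

    def linear_predictor(self, x):
        return self.intercept + self.slope * x


@dataclass(frozen=True)
class GaussianRate:
    """Gaussian response with linear mean: y ~ N(intercept + slope * x, variance)."""

    intercept: float
    slope: float
    variance: float

    def mean(self, x):
        return self.intercept + self.slope * x


@dataclass(frozen=True)
class LinearRate:
    """Plain linear mean function (flowering-shoot counts)."""

    intercept: float
    slope: float

    def mean(self, x):
        return self.intercept + self.slope * x


@dataclass(frozen=True)
class RecruitSize:
    """Gaussian distribution of log plant size early in life (f_d)."""

    mean: float
    variance: float


@dataclass(frozen=True)
class VitalRateParams:
    """All vital rates and constants for one origin x treatment cell.

    Attributes
    ----------
    survival : LogisticRate
        s(x), probability of surviving the projection interval.
    growth : GaussianRate
        g(y, x), Gaussian density of size y at t+1 given size x at t.
    flowering : LogisticRate
        p(x), probability of flowering at t+1.
    shoots : LinearRate
        f1(x), expected number of flowering shoots (clamped at 0 in the kernel).
    recruit_size : RecruitSize
        f_d(y), distribution of recruit log size.
    e, e_sb : float
        Establishment probability of a fresh seed / of a seed-bank seed.
    s_sb : float
        Annual survival of seeds in the seed bank.
    seeds_per_shoot : float
        Average seed output per flowering shoot (regional constant).
    """

    survival: LogisticRate
    growth: GaussianRate
    flowering: LogisticRate
    shoots: LinearRate
    recruit_size: RecruitSize
    e: float
    e_sb: float
    s_sb: float
    seeds_per_shoot: float

    def validate(self) -> None:
        """Raise ValueError naming the first invalid or non-finite component."""
        for name, value in self.flat_items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite vital-rate parameter: {name} = {value}")
        if self.growth.variance <= 0:
            raise ValueError(f"growth variance must be > 0, got {self.growth.variance}")
        if self.recruit_size.variance <= 0:
            raise ValueError(
                f"recruit-size variance must be > 0, got {self.recruit_size.variance}"
            )
        for name in ("e", "e_sb", "s_sb"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.seeds_per_shoot < 0:
            raise ValueError(f"seeds_per_shoot must be >= 0, got {self.seeds_per_shoot}")

    def flat_items(self):
        """Yield (dotted name, value) for every scalar component."""
        for rate in ("survival", "growth", "flowering", "shoots", "recruit_size"):
            obj = getattr(self, rate)
            for f in dataclasses.fields(obj):
                yield f"{rate}.{f.name}", float(getattr(obj, f.name))
        for name in ("e", "e_sb", "s_sb", "seeds_per_shoot"):
            yield name, float(getattr(self, name))

    def replace_component(self, name: str, value: float) -> "VitalRateParams":
        """Return a copy with one dotted-name scalar component replaced."""
        if "." in name:
            rate, field = name.split(".", 1)
            obj = getattr(self, rate)
            new_obj = dataclasses.replace(obj, **{field: value})
            return dataclasses.replace(self, **{rate: new_obj})
        return dataclasses.replace(self, **{name: value})

    def to_dict(self) -> dict:
        return {
            "survival": dataclasses.asdict(self.survival),
            "growth": dataclasses.asdict(self.growth),
            "flowering": dataclasses.asdict(self.flowering),
            "shoots": dataclasses.asdict(self.shoots),
            "recruit_size": dataclasses.asdict(self.recruit_size),
            "e": self.e,
            "e_sb": self.e_sb,
            "s_sb": self.s_sb,
            "seeds_per_shoot": self.seeds_per_shoot,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VitalRateParams":
        return cls(
            survival=LogisticRate(**d["survival"]),
            growth=GaussianRate(**d["growth"]),
            flowering=LogisticRate(**d["flowering"]),
            shoots=LinearRate(**d["shoots"]),
            recruit_size=RecruitSize(**d["recruit_size"]),
            e=float(d["e"]),
            e_sb=float(d["e_sb"]),
            s_sb=float(d["s_sb"]),
            seeds_per_shoot=float(d["seeds_per_shoot"]),
        )


def params_to_yaml(params_by_cell: Mapping[tuple, VitalRateParams], path) -> None:
    """Serialize a {(origin, treatment): VitalRateParams} mapping to YAML."""
    doc = {}
    for (origin, treatment), p in params_by_cell.items():
        doc.setdefault(origin, {})[treatment] = p.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def params_from_yaml(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for origin, by_treatment in doc.items():
        for treatment, d in by_treatment.items():
            out[(origin, treatment)] = VitalRateParams.from_dict(d)
    return out
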