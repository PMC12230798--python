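"""Synthetic greenhouse and field-fecundity data.

The generator inverts the fitted-model family of the demographic analysis so
that parameter recovery is a well-posed test: initial log size is Gaussian,
survival and flowering are Bernoulli with logit-linear probabilities, size at
t+1 is Gaussian with a linear mean, and flowering-shoot counts are Gaussian
truncated at zero. The design labels mirror the greenhouse layout (2 origins x
2 inoculum treatments x 3 inoculum source sites x 5 populations per origin x
5 blocks), assigned round-robin.

Conditional structure: ``size_t1`` and ``flowered`` exist only for survivors,
``n_shoots`` only for flowerers; missing values are empty cells in CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .params import VitalRateParams

RECORD_COLUMNS = [
    "origin",
    "treatment",
    "inoculum_source",
    "population",
    "block",
    "size_t",
    "survived",
    "size_t1",
    "flowered",
    "n_shoots",
]

FIELD_COLUMNS = [
    "population",
    "plant_id",
    "pods_per_inflorescence",
    "seeds_pod_1",
    "seeds_pod_2",
    "seeds_pod_3",
]

#: Field-fecundity generator defaults per origin: (pods per inflorescence,
#: seeds per pod) Poisson means whose product matches the regional
#: seeds-per-flowering-shoot constants (79 invasive, 42 native).
FIELD_DEFAULTS = {"invasive_FI": (18.0, 4.4), "native_US": (12.0, 3.5)}

INOCULUM_SOURCES = ("site1", "site2", "site3")
N_POPULATIONS = 5
N_BLOCKS = 5


@dataclass
class GeneratorSpec:
    """Generating truth and design for one synthetic greenhouse dataset.

    ``params`` maps (origin, treatment) to the generating VitalRateParams;
    ``n_per_cell`` is the number of retained individuals per cell (55 matches
    the published per-cell sample sizes). ``shoot_variance`` is the residual
    variance of the flowering-shoot model (not published; defaults to 1.0).
    ``random_intercept_sd`` adds optional population- and block-level Gaussian
    intercepts to every linear predictor for stress-testing the fitting stage
    (default 0, matching the fixed-effect-only published estimates).
    """

    params: Mapping[tuple, VitalRateParams]
    seed: int
    n_per_cell: int = 55
    shoot_variance: float = 1.0
    random_intercept_sd: float = 0.0

    def validate(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError(f"n_per_cell must be >= 1, got {self.n_per_cell}")
        if self.shoot_variance <= 0:
            raise ValueError(f"shoot_variance must be > 0, got {self.shoot_variance}")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")
        if self.seed is None:
            raise ValueError("an RNG seed is mandatory")
        for cell, p in self.params.items():
            try:
                p.validate()
            except ValueError as err:
                raise ValueError(f"cell {cell}: {err}") from err

    def to_yaml(self, path) -> None:
        doc = {
            "seed": int(self.seed),
            "n_per_cell": int(self.n_per_cell),
            "shoot_variance": float(self.shoot_variance),
            "random_intercept_sd": float(self.random_intercept_sd),
            "params": {},
        }
        for (origin, treatment), p in self.params.items():
            doc["params"].setdefault(origin, {})[treatment] = p.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "seed" not in doc:
            raise ValueError("generator spec file must state an RNG seed")
        params = {
            (origin, treatment): VitalRateParams.from_dict(d)
            for origin, by_t in doc["params"].items()
            for treatment, d in by_t.items()
        }
        return cls(
            params=params,
            seed=int(doc["seed"]),
            n_per_cell=int(doc.get("n_per_cell", 55)),
            shoot_variance=float(doc.get("shoot_variance", 1.0)),
            random_intercept_sd=float(doc.get("random_intercept_sd", 0.0)),
        )


def _expit(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def simulate_greenhouse(spec: GeneratorSpec) -> pd.DataFrame:
    """Simulate individual demographic records for every cell of the design.

    Returns a DataFrame with :data:`RECORD_COLUMNS`; identical specs
    (including the seed) produce byte-identical tables.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    cells = sorted(spec.params.keys())
    # Population/block random intercepts (shared across cells of an origin).
    pop_effects = {}
    block_effects = {}
    if spec.random_intercept_sd > 0:
        for origin in sorted({c[0] for c in cells}):
            for i in range(N_POPULATIONS):
                pop_effects[f"{origin}_pop{i + 1}"] = rng.normal(0, spec.random_intercept_sd)
        for i in range(N_BLOCKS):
            block_effects[f"block{i + 1}"] = rng.normal(0, spec.random_intercept_sd)

    for origin, treatment in cells:
        p = spec.params[(origin, treatment)]
        n = spec.n_per_cell
        populations = [f"{origin}_pop{(i % N_POPULATIONS) + 1}" for i in range(n)]
        blocks = [f"block{(i // N_POPULATIONS) % N_BLOCKS + 1}" for i in range(n)]
        sources = [INOCULUM_SOURCES[i % len(INOCULUM_SOURCES)] for i in range(n)]
        ranef = np.array(
            [pop_effects.get(pop, 0.0) + block_effects.get(blk, 0.0)
             for pop, blk in zip(populations, blocks)]
        )

        size_t = rng.normal(p.recruit_size.mean, math.sqrt(p.recruit_size.variance), n)
        survived = rng.random(n) < _expit(p.survival.linear_predictor(size_t) + ranef)
        size_t1 = np.full(n, np.nan)
        flowered = np.full(n, np.nan)
        n_shoots = np.full(n, np.nan)

        idx = np.flatnonzero(survived)
        if idx.size:
            size_t1[idx] = rng.normal(
                p.growth.mean(size_t[idx]) + ranef[idx], math.sqrt(p.growth.variance)
            )
            flowered[idx] = (
                rng.random(idx.size) < _expit(p.flowering.linear_predictor(size_t[idx]) + ranef[idx])
            ).astype(float)
        fidx = np.flatnonzero(flowered == 1.0)
        if fidx.size:
            mu = p.shoots.mean(size_t[fidx]) + ranef[fidx]
            sd = math.sqrt(spec.shoot_variance)
            n_shoots[fidx] = truncnorm.rvs(
                (0.0 - mu) / sd, np.inf, loc=mu, scale=sd, random_state=rng
            )

        rows.append(
            pd.DataFrame(
                {
                    "origin": origin,
                    "treatment": treatment,
                    "inoculum_source": sources,
                    "population": populations,
                    "block": blocks,
                    "size_t": size_t,
                    "survived": survived.astype(int),
                    "size_t1": size_t1,
                    "flowered": flowered,
                    "n_shoots": n_shoots,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[RECORD_COLUMNS]


def simulate_field_fecundity(
    pod_mean: float,
    seed_mean: float,
    n_populations: int = 5,
    n_plants: int = 15,
    rng_seed: Optional[int] = None,
    population_prefix: str = "pop",
) -> pd.DataFrame:
    """Simulate pods-per-inflorescence and seeds-per-pod field counts.

    Each of ``n_plants`` plants per population gets a Poisson pod count and
    three Poisson seeds-per-pod observations (one per sampled pod).
    """
    if pod_mean <= 0 or seed_mean <= 0:
        raise ValueError(
            f"Poisson means must be > 0 (pod_mean={pod_mean}, seed_mean={seed_mean})"
        )
    if n_populations < 0 or n_plants < 0:
        raise ValueError("n_populations and n_plants must be >= 0")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for ip in range(n_populations):
        for jp in range(n_plants):
            seeds = rng.poisson(seed_mean, 3)
            rows.append(
                {
                    "population": f"{population_prefix}{ip + 1}",
                    "plant_id": f"{population_prefix}{ip + 1}_plant{jp + 1}",
                    "pods_per_inflorescence": int(rng.poisson(pod_mean)),
                    "seeds_pod_1": int(seeds[0]),
                    "seeds_pod_2": int(seeds[1]),
                    "seeds_pod_3": int(seeds[2]),
                }
            )
    return pd.DataFrame(rows, columns=FIELD_COLUMNS)


def write_records(df: pd.DataFrame, path) -> None:
    """Write individual records as CSV; conditional fields become empty cells."""
    df.to_csv(path, index=False, na_rep="")


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records file {path} lacks columns: {missing}")
    return df[RECORD_COLUMNS]


def write_field(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_field(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FIELD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"field-fecundity file {path} lacks columns: {missing}")
    return df[FIELD_COLUMNS]
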