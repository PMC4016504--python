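"""Replicate case-count datasets under homogeneous and single-cluster risk.

Under the null hypothesis of risk homogeneity the observed count in SU *i*
is Poisson with mean the expected count eps_i = incidence x population_i.
Under a single-cluster alternative the mean is multiplied by the relative
risk theta inside the cluster:

    H0: N_i ~ Pois(eps_i)
    H1: N_i ~ Pois(pi_i),  pi_i = theta * eps_i  inside the cluster,
                           pi_i = eps_i          outside.

Monte Carlo replicates for scan inference are, by default, drawn
conditionally on the observed total: the total case count is redistributed
multinomially with cell probabilities eps_i / sum(eps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .region import Cluster, Region

__all__ = [
    "RiskScenario",
    "CaseDataset",
    "expected_counts",
    "simulate_dataset",
    "simulate_null_conditional",
    "simulate_batch",
    "child_seed",
]

#: column order of the on-disk dataset format: coordinates, observed cases,
#: at-risk population, expected cases.
DATASET_COLUMNS = ("x", "y", "observed", "population", "expected")


@dataclass(frozen=True)
class RiskScenario:
    """Baseline incidence, relative risk and (optionally) a true cluster.

    ``cluster=None`` means pure homogeneous risk (the null).  ``years``
    scales expected counts for multi-year study windows; populations are
    per-year means, so the default of 1 simulates annual counts.
    """

    incidence: float
    relative_risk: float = 1.0
    cluster: Cluster | None = None
    years: float = 1.0
    name: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.incidence < 1.0:
            raise ValueError(f"incidence must be in (0, 1), got {self.incidence}")
        if self.relative_risk < 1.0:
            raise ValueError(f"relative_risk must be >= 1, got {self.relative_risk}")
        if self.years <= 0:
            raise ValueError("years must be > 0")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        return f"I={self.incidence:g},RR={self.relative_risk:g}"


@dataclass
class CaseDataset:
    """One simulated realization: per-SU counts with populations/expectations."""

    x: np.ndarray
    y: np.ndarray
    observed: np.ndarray
    population: np.ndarray
    expected: np.ndarray
    su_ids: tuple[str, ...] | None = None  # row order; not part of the 5-column file
    scenario: RiskScenario | None = None
    replicate: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("y", "observed", "population", "expected"):
            if len(getattr(self, name)) != n:
                raise ValueError("all dataset columns must have equal length")
        if np.any(self.observed < 0):
            raise ValueError("observed counts must be >= 0")

    @property
    def n_units(self) -> int:
        return len(self.x)

    @property
    def n_total(self) -> int:
        return int(self.observed.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(zip(DATASET_COLUMNS, (self.x, self.y, self.observed, self.population, self.expected))))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CaseDataset":
        df = pd.read_csv(path)
        missing = set(DATASET_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset CSV missing columns {sorted(missing)}")
        return cls(
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            observed=df["observed"].to_numpy(np.int64),
            population=df["population"].to_numpy(float),
            expected=df["expected"].to_numpy(float),
        )


def expected_counts(region: Region, incidence: float, years: float = 1.0) -> np.ndarray:
    """Per-SU expected counts eps_i = incidence * population_i (* years)."""
    if not 0.0 < incidence < 1.0:
        raise ValueError(f"incidence must be in (0, 1), got {incidence}")
    return incidence * years * region.populations


def _cluster_mask(region: Region, cluster: Cluster | None) -> np.ndarray:
    mask = np.zeros(region.n_units, dtype=bool)
    if cluster is not None:
        for m in cluster.members:
            mask[region.index(m)] = True
    return mask


def child_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed for a (cluster, scenario, replicate) key.

    Uses numpy's SeedSequence spawn-key mechanism so any single replicate is
    regenerable in isolation; the returned integer is < 2**31.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=key)
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def simulate_dataset(
    region: Region,
    scenario: RiskScenario,
    rng: np.random.Generator | int | None = None,
    replicate: int | None = None,
) -> CaseDataset:
    """Draw one dataset of independent Poisson counts under the scenario."""
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = rng
        rng = np.random.default_rng(rng)
    eps = expected_counts(region, scenario.incidence, scenario.years)
    mask = _cluster_mask(region, scenario.cluster)
    mean = np.where(mask, scenario.relative_risk * eps, eps)
    obs = rng.poisson(mean)
    return CaseDataset(
        x=region.centroids[:, 0].copy(),
        y=region.centroids[:, 1].copy(),
        observed=obs.astype(np.int64),
        population=region.populations.copy(),
        expected=eps,
        su_ids=region.su_ids,
        scenario=scenario,
        replicate=replicate,
        seed=seed,
    )


def simulate_null_conditional(
    dataset: CaseDataset, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """One conditional null replicate: the total redistributed multinomially.

    Cell probabilities are eps_i / sum(eps); the replicate total equals the
    dataset total exactly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = dataset.n_total
    total_eps = dataset.expected.sum()
    if total_eps <= 0:
        if n > 0:
            raise ValueError("cannot redistribute cases: all expected counts are zero")
        return np.zeros(dataset.n_units, dtype=np.int64)
    p = dataset.expected / total_eps
    return rng.multinomial(n, p).astype(np.int64)


def simulate_batch(
    region: Region,
    scenario: RiskScenario,
    n_replicates: int,
    master_seed: int,
    batch_key: tuple[int, ...] = (),
) -> Iterator[CaseDataset]:
    """Lazily yield ``n_replicates`` reproducible datasets.

    Per-replicate seeds derive from ``master_seed`` through
    :func:`child_seed` with key ``(*batch_key, replicate)``, so the same
    master seed always reproduces the identical batch, and distinct batch
    keys (e.g. one per cluster x scenario) give independent streams.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for r in range(n_replicates):
        seed = child_seed(master_seed, *batch_key, r)
        yield simulate_dataset(region, scenario, rng=seed, replicate=r)
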