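"""Rarefaction by repeated subsampling without replacement.

To compare polymorphism across populations of unequal size, each population
is repeatedly subsampled to a common size g; per replicate the number of
segregating sites S and the number of sequence classes h are recorded, and
the proportion of replicates retaining polymorphism (S > 0) summarises
sensitivity to sample-size disparity.

Closed-form hypergeometric expectations for the same quantities are provided
as oracles for the Monte-Carlo procedure: a site with minor-state carrier
count m segregates in a subsample of g from N with probability
``1 - [C(N-m, g) + C(m, g)] / C(N, g)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment import Alignment
from .variants import assign_haplotypes, detect_variable_sites


@dataclass(frozen=True)
class RarefactionConfig:
    population: str
    subsample_size: int = 16  # g
    replicates: int = 1000  # B
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subsample_size < 2:
            raise ValueError(f"subsample size must be >= 2, got {self.subsample_size}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass(frozen=True)
class RarefactionSummary:
    """Per-replicate arrays and their summaries for one population."""

    config: RarefactionConfig
    n: int
    S_r: np.ndarray
    h_r: np.ndarray

    @property
    def retention(self) -> float:
        """Proportion of replicates retaining polymorphism (S > 0)."""
        return float(np.mean(self.S_r > 0))

    @property
    def mean_S(self) -> float:
        return float(np.mean(self.S_r))

    @property
    def sd_S(self) -> float:
        return float(np.std(self.S_r, ddof=1)) if len(self.S_r) > 1 else 0.0

    @property
    def mean_h(self) -> float:
        return float(np.mean(self.h_r))

    @property
    def sd_h(self) -> float:
        return float(np.std(self.h_r, ddof=1)) if len(self.h_r) > 1 else 0.0

    @property
    def interval95_S(self) -> tuple[int, int]:
        return _order_statistic_interval(self.S_r)

    @property
    def interval95_h(self) -> tuple[int, int]:
        return _order_statistic_interval(self.h_r)

    def as_dict(self) -> dict:
        """JSON-ready summary (per-replicate arrays omitted)."""
        return {
            "population": self.config.population,
            "n": self.n,
            "subsample_size": self.config.subsample_size,
            "replicates": self.config.replicates,
            "seed": self.config.seed,
            "retention": self.retention,
            "retention_pct_1dp": round(100 * self.retention, 1),
            "retention_pct_int": round(100 * self.retention),
            "mean_S": self.mean_S,
            "sd_S": self.sd_S,
            "interval95_S": list(self.interval95_S),
            "mean_h": self.mean_h,
            "sd_h": self.sd_h,
            "interval95_h": list(self.interval95_h),
        }


def _order_statistic_interval(values: np.ndarray) -> tuple[int, int]:
    """95% resampling interval as order statistics at 1-based ranks
    ceil(0.025 B) and floor(0.975 B); no interpolation."""
    b = len(values)
    ordered = np.sort(values)
    lo = ordered[max(math.ceil(0.025 * b), 1) - 1]
    hi = ordered[math.floor(0.975 * b) - 1]
    return int(lo), int(hi)


def _population_rng(seed: int, population: str) -> np.random.Generator:
    # substream per population: adding a population never perturbs another's
    entropy = [seed] + list(population.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def rarefy_population(aln: Alignment, cfg: RarefactionConfig) -> RarefactionSummary:
    """B uniform subsamples of g records without replacement.

    Per replicate, S counts the columns still variable within the subsample
    and h the distinct state-tuples over those columns; both are computed on
    the population's variable columns only (constant columns cannot become
    variable in a subsample). Fully reproducible from the seed.
    """
    sub = aln.subset(cfg.population)
    n = len(sub)
    g, b = cfg.subsample_size, cfg.replicates
    if g > n:
        raise ValueError(
            f"subsample size g={g} exceeds population {cfg.population!r} size n={n}"
        )
    sites = detect_variable_sites(sub)
    # (n, S_pop) matrix of states at the population's variable columns
    states = np.array(
        [[rec.residues[s.column] for s in sites] for rec in sub.records]
    ).reshape(n, len(sites))

    rng = _population_rng(cfg.seed, cfg.population)
    s_r = np.empty(b, dtype=int)
    h_r = np.empty(b, dtype=int)
    for rep in range(b):
        idx = rng.choice(n, size=g, replace=False)
        chosen = states[idx]
        if chosen.size == 0:
            s_r[rep], h_r[rep] = 0, 1
            continue
        s_r[rep] = int(np.sum(np.any(chosen != chosen[0], axis=0)))
        h_r[rep] = len({tuple(row) for row in chosen})
    return RarefactionSummary(config=cfg, n=n, S_r=s_r, h_r=h_r)


def expected_site_retention(N: int, m: int, g: int) -> float:
    """P(a site with minor-state carrier count m segregates in a subsample
    of size g drawn without replacement from N sequences)."""
    if not (0 <= m <= N):
        raise ValueError(f"carrier count m={m} outside [0, N={N}]")
    if not (2 <= g <= N):
        raise ValueError(f"subsample size g={g} outside [2, N={N}]")
    total = math.comb(N, g)
    return 1 - (math.comb(N - m, g) + math.comb(m, g)) / total


def expected_counts(
    class_counts: Mapping[str, int] | Sequence[int],
    site_carriers: Sequence[int],
    g: int,
) -> tuple[float, float]:
    """Closed-form (E[S], E[h]) for a subsample of size g.

    ``class_counts`` are copy counts per sequence class (summing to N);
    ``site_carriers`` the minor-state carrier count of each variable site.
    E[S] sums per-site segregation probabilities; E[h] sums per-class
    presence probabilities ``1 - C(N-c, g)/C(N, g)``.
    """
    counts = (
        list(class_counts.values())
        if isinstance(class_counts, Mapping)
        else list(class_counts)
    )
    if any(c < 0 for c in counts) or sum(counts) <= 0:
        raise ValueError("class counts must be non-negative and sum to N > 0")
    N = sum(counts)
    if not (2 <= g <= N):
        raise ValueError(f"subsample size g={g} outside [2, N={N}]")
    e_s = sum(expected_site_retention(N, m, g) for m in site_carriers)
    total = math.comb(N, g)
    e_h = sum(1 - math.comb(N - c, g) / total for c in counts)
    return e_s, e_h
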