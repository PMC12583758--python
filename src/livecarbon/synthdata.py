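"""Synthetic panel generator.

Emulates the structure of a provincial livestock statistics panel: 18
cities grouped into 5 regions observed over 2001–2021, with per-species
head counts that decline slowly over time, one dominant livestock region,
multiplicative lognormal noise, and an output-value (GDP proxy) series that
grows geometrically with occasional recession years.

None of the levels are calibrated to any real province; the generator's job
is to reproduce the *statistical shape* the downstream analyses assume
(positivity, right-skew, regional heterogeneity, smooth trends) so that
every stage of the pipeline is testable without external data.

Also provides a typed-sequence generator (independent realisations of a
known Markov chain) used as a recovery oracle for the transition-matrix
estimators, and ring/lattice adjacency builders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .panel import (AdjacencyList, Panel, PanelRecord, RegionScheme,
                    default_region_scheme)

# species -> (product, t product per head per year)
_PRODUCT_YIELDS = {
    "cattle": [("beef", 0.06), ("milk", 0.40)],
    "pig": [("pork", 0.08)],
    "sheep": [("mutton", 0.015)],
    "poultry": [("poultry_meat", 0.0015), ("eggs", 0.010)],
}

_FEED_FACTORS = {
    # t concentrate feed per t product
    "pork": 3.5, "beef": 7.0, "mutton": 6.0, "poultry_meat": 2.0,
    "milk": 0.9, "eggs": 2.5,
}

_GRAIN_SHARES = {"corn": 0.60, "wheat": 0.20, "soybean": 0.15}

_BASE_INVENTORY = {
    # lognormal median head per city
    "cattle": 4.0e5, "pig": 2.0e6, "sheep": 5.0e5, "poultry": 2.0e7,
}

_ENERGY_COSTS = {
    # species -> (electricity CNY/head/a, coal CNY/head/a)
    "cattle": (30.0, 40.0), "pig": (20.0, 25.0),
    "sheep": (5.0, 6.0), "poultry": (0.5, 0.4),
}

# One region roughly twice the others: the dominant livestock belt.
_REGION_MULTIPLIERS = {
    "Southern": 2.0, "Eastern": 1.2, "North": 1.0, "Central": 0.9, "West": 0.6,
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic panel.

    The defaults describe the emulated study conditions: an 18-city,
    5-region, 21-year panel whose provincial emissions decline about 1.2%
    per year, with a dominant southern livestock region (~2× scale), mild
    lognormal noise, and ~9%/a nominal output-value growth interrupted by a
    few recession years.
    """

    n_cities: int = 18
    n_regions: int = 5
    years: Tuple[int, int] = (2001, 2021)
    species: Tuple[str, ...] = ("cattle", "pig", "sheep", "poultry")
    base_inventory: Mapping[str, float] = field(
        default_factory=lambda: dict(_BASE_INVENTORY))
    # fraction per year; scalar applies to every species
    trend: Union[float, Mapping[str, float]] = -0.0118
    noise_cv: float = 0.08
    city_sigma: float = 0.35  # lognormal sigma of city base levels
    region_multipliers: Optional[Mapping[str, float]] = None
    gdp_base: float = 2.0e9  # CNY, median city output value in the first year
    gdp_growth_mean: float = 0.09
    gdp_growth_sd: float = 0.04
    recession_years: frozenset = frozenset({2006, 2009, 2014, 2020})
    recession_growth_mean: float = -0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions > self.n_cities:
            raise ConfigError("n_regions cannot exceed n_cities")
        trends = (self.trend.values() if isinstance(self.trend, Mapping)
                  else [self.trend])
        for t in trends:
            if not -1.0 < t < 1.0:
                raise ConfigError(f"trend {t} outside (-1, 1)")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")

    def trend_for(self, species: str) -> float:
        if isinstance(self.trend, Mapping):
            return float(self.trend.get(species, 0.0))
        return float(self.trend)


def _city_names(config: SynthConfig) -> Tuple[List[str], RegionScheme]:
    """18 cities / 5 regions use the default scheme; otherwise synthetic names."""
    if config.n_cities == 18 and config.n_regions == 5:
        scheme = default_region_scheme()
        return sorted(scheme), scheme
    cities = [f"City{i + 1:02d}" for i in range(config.n_cities)]
    regions = [f"Region{chr(ord('A') + i)}" for i in range(config.n_regions)]
    scheme = {c: regions[i % config.n_regions] for i, c in enumerate(cities)}
    return cities, scheme


def generate_panel(config: SynthConfig) -> Tuple[Panel, RegionScheme, AdjacencyList]:
    """Generate a complete synthetic panel, region scheme and ring adjacency.

    Inventories follow city-specific lognormal base levels × region
    multiplier × (1 + trend)^(year − start) × multiplicative lognormal noise;
    product outputs are proportional to inventories through per-head yields;
    output value follows geometric growth with recession-year draws.
    Deterministic under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cities, scheme = _city_names(config)
    y0, y1 = config.years
    years = list(range(y0, y1 + 1))

    multipliers = dict(config.region_multipliers or {})
    if not multipliers:
        region_labels = sorted(set(scheme.values()))
        if set(region_labels) == set(_REGION_MULTIPLIERS):
            multipliers = dict(_REGION_MULTIPLIERS)
        else:
            # spread multipliers over [0.6, 2.0] with one dominant region
            vals = np.linspace(0.6, 2.0, len(region_labels))
            multipliers = dict(zip(region_labels, vals))

    # city base levels (lognormal around the species median)
    base = {
        (c, sp): config.base_inventory.get(sp, 1e5)
        * multipliers[scheme[c]]
        * np.exp(rng.normal(0.0, config.city_sigma))
        for c in cities for sp in config.species
    }

    sigma = (np.sqrt(np.log1p(config.noise_cv ** 2)) if config.noise_cv > 0 else 0.0)

    records: List[PanelRecord] = []
    gdp_level = {c: config.gdp_base * np.exp(rng.normal(0.0, config.city_sigma))
                 for c in cities}
    for year in years:
        if year != y0:
            for c in cities:
                mean = (config.recession_growth_mean
                        if year in config.recession_years else config.gdp_growth_mean)
                sd = config.gdp_growth_sd if config.noise_cv > 0 else 0.0
                gdp_level[c] *= 1.0 + mean + rng.normal(0.0, sd)
        for c in cities:
            inventories = {}
            for sp in config.species:
                # geometric trend: the annualized rate of a noise-free series
                # equals the configured trend exactly
                level = base[(c, sp)] * (1.0 + config.trend_for(sp)) ** (year - y0)
                if sigma > 0:
                    # mean-one lognormal noise
                    level *= np.exp(rng.normal(-0.5 * sigma ** 2, sigma))
                inventories[sp] = level
            outputs = {}
            for sp, yields in _PRODUCT_YIELDS.items():
                if sp not in inventories:
                    continue
                for product, per_head in yields:
                    outputs[product] = outputs.get(product, 0.0) + \
                        inventories[sp] * per_head
            elec = {sp: _ENERGY_COSTS.get(sp, (10.0, 10.0))[0] for sp in config.species}
            coal = {sp: _ENERGY_COSTS.get(sp, (10.0, 10.0))[1] for sp in config.species}
            rec = PanelRecord(
                city=c, year=year,
                inventories=inventories, outputs=outputs,
                feed_factor={p: _FEED_FACTORS.get(p, 3.0) for p in outputs},
                grain_shares=dict(_GRAIN_SHARES),
                elec_cost=elec, coal_cost=coal,
                output_value=max(gdp_level[c], 1.0),
            )
            rec.validate()
            records.append(rec)

    panel = Panel(records=records, cities=cities, years=years)
    adjacency = generate_adjacency(cities, "ring")
    return panel, scheme, adjacency


def generate_adjacency(cities: Sequence[str], layout: str = "ring") -> AdjacencyList:
    """Build a symmetric, connected adjacency structure over the cities.

    ``ring`` gives every city exactly two neighbours; ``lattice`` arranges
    the cities on an r×c grid (r the largest divisor of n not exceeding
    √n) with rook contiguity.
    """
    n = len(cities)
    if n < 3:
        raise ConfigError("need at least 3 cities for an adjacency structure")
    if layout == "ring":
        graph = nx.cycle_graph(n)
    elif layout == "lattice":
        rows = max(d for d in range(1, int(np.sqrt(n)) + 1) if n % d == 0)
        graph = nx.convert_node_labels_to_integers(nx.grid_2d_graph(rows, n // rows))
    else:
        raise ConfigError(f"unknown adjacency layout {layout!r}")
    adj: AdjacencyList = {c: set() for c in cities}
    for a, b in graph.edges():
        adj[cities[a]].add(cities[b])
        adj[cities[b]].add(cities[a])
    return adj


def generate_typed_sequences(P_true: np.ndarray, n_units: int, n_years: int,
                             seed: int) -> pd.DataFrame:
    """Simulate independent realisations of a known Markov chain.

    Each of ``n_units`` units starts in a uniformly drawn state and evolves
    for ``n_years`` steps under the row-stochastic matrix ``P_true``.
    Returns a long DataFrame (city, year, type) with 1-based type labels,
    shaped like the output of the level classifier so the transition-matrix
    estimators can be exercised against known dynamics.
    """
    P = np.asarray(P_true, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValidationError("P_true must be square")
    if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
        raise ValidationError("P_true rows must be nonnegative and sum to 1")
    k = P.shape[0]
    rng = np.random.default_rng(seed)
    states = np.empty((n_units, n_years), dtype=int)
    states[:, 0] = rng.integers(0, k, size=n_units)
    cum = np.cumsum(P, axis=1)
    for t in range(1, n_years):
        u = rng.random(n_units)
        states[:, t] = (cum[states[:, t - 1]] < u[:, None]).sum(axis=1)
    rows = [(f"U{i + 1:03d}", t, states[i, t] + 1)
            for i in range(n_units) for t in range(n_years)]
    return pd.DataFrame(rows, columns=["city", "year", "type"])
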