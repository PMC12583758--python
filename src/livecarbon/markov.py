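"""Conventional and spatially conditioned Markov chains of emission types.

City-level emission values are pooled over all city-years and cut at the
empirical quantiles j/K into K ordered types (K = 4 by default: low,
medium-low, medium-high, high).  Annual transitions between types are
counted over all cities and year pairs and row-normalised by maximum
likelihood, p̂_ij = n_ij / n_i.

The spatial variant stratifies each transition by the *spatial lag class*
of the city in the origin year: the unweighted mean of its neighbours'
emission values (row-standardised binary contiguity weights), binned with
the same pooled thresholds.  Summing the stratified counts over strata
reproduces the conventional counts exactly.  Rows never observed are kept
as all-zero rows and flagged rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .panel import AdjacencyList


@dataclass
class TypedPanel:
    """Type labels (1..K) per city-year plus the thresholds that made them."""

    data: pd.DataFrame  # columns: city, year, type
    k: int
    thresholds: np.ndarray  # K-1 interior quantile cuts


@dataclass
class TransitionMatrix:
    """Counts and MLE probabilities of a K-state annual transition matrix."""

    k: int
    counts: np.ndarray  # K×K integer counts n_ij
    probs: np.ndarray  # K×K probabilities, all-zero rows where n_i = 0
    row_totals: np.ndarray  # n_i
    zero_row_flags: np.ndarray  # boolean, True where n_i = 0


@dataclass
class SpatialTransitionMatrix:
    """One TransitionMatrix per neighbour-lag class g in 1..K."""

    k: int
    strata: Dict[int, TransitionMatrix]


def classify_levels(values: pd.DataFrame, k: int = 4,
                    value_col: str = "value") -> TypedPanel:
    """Cut pooled city-year values into K quantile types.

    Thresholds are the empirical quantiles at j/K (j = 1..K−1) over all
    city-years; bins are lower-closed / upper-open except the top bin.
    Being rank-based, the typing is invariant under any strictly increasing
    transformation of the values.
    """
    if k < 2:
        raise ValidationError("need K >= 2 types")
    arr = values[value_col].to_numpy(dtype=float)
    if np.unique(arr).size < k:
        raise ValidationError(
            f"need at least {k} distinct values for {k} quantile bins")
    thresholds = np.quantile(arr, [j / k for j in range(1, k)])
    types = assign_types(arr, thresholds)
    out = values[["city", "year"]].copy()
    out["type"] = types
    return TypedPanel(data=out, k=k, thresholds=thresholds)


def assign_types(arr: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """1-based bin index under lower-closed thresholds (value ≥ cut ⇒ next bin)."""
    return np.searchsorted(thresholds, np.asarray(arr, dtype=float),
                           side="right") + 1


def transition_matrix(typed: TypedPanel, lag: int = 1) -> TransitionMatrix:
    """MLE transition matrix pooled over all cities and (t, t+lag) pairs."""
    df = typed.data
    years = sorted(df["year"].unique())
    if len(years) < lag + 1:
        raise DomainError("need at least lag+1 years of typed data")
    wide = df.pivot(index="city", columns="year", values="type")
    counts = np.zeros((typed.k, typed.k), dtype=int)
    for t in years[:-lag]:
        if t + lag not in wide.columns:
            continue
        origin = wide[t].to_numpy(dtype=int)
        dest = wide[t + lag].to_numpy(dtype=int)
        np.add.at(counts, (origin - 1, dest - 1), 1)
    return _from_counts(counts)


def _from_counts(counts: np.ndarray) -> TransitionMatrix:
    k = counts.shape[0]
    row_totals = counts.sum(axis=1)
    probs = np.zeros_like(counts, dtype=float)
    occupied = row_totals > 0
    probs[occupied] = counts[occupied] / row_totals[occupied, None]
    return TransitionMatrix(k=k, counts=counts, probs=probs,
                            row_totals=row_totals, zero_row_flags=~occupied)


def spatial_lag_class(values: pd.DataFrame, adjacency: AdjacencyList,
                      thresholds: np.ndarray,
                      value_col: str = "value") -> pd.DataFrame:
    """Neighbour-mean lag value per city-year, binned with the given cuts.

    Every city must have at least one neighbour; the lag value is the
    unweighted mean of the neighbours' values in the same year (binary
    contiguity weights, row-standardised).
    """
    cities = values["city"].unique()
    for c in cities:
        if not adjacency.get(c):
            raise ValidationError(f"city {c!r} has no neighbours")
    wide = values.pivot(index="city", columns="year", values=value_col)
    rows = []
    for c in cities:
        nbrs = sorted(adjacency[c] & set(wide.index))
        if not nbrs:
            raise ValidationError(f"city {c!r} has no neighbours inside the panel")
        lag_vals = wide.loc[nbrs].mean(axis=0)
        for year, v in lag_vals.items():
            rows.append((c, int(year), float(v)))
    out = pd.DataFrame(rows, columns=["city", "year", "lag_value"])
    out["lag_class"] = assign_types(out["lag_value"].to_numpy(), thresholds)
    return out


def spatial_transition_matrices(typed: TypedPanel,
                                lag_classes: pd.DataFrame) -> SpatialTransitionMatrix:
    """Transition matrices stratified by origin-year neighbour-lag class.

    Each transition (t → t+1) of a city is assigned to the stratum given by
    the city's lag class at time t.  Counts summed over strata equal the
    conventional counts.
    """
    merged = typed.data.merge(lag_classes[["city", "year", "lag_class"]],
                              on=["city", "year"], how="left")
    if merged["lag_class"].isna().any():
        bad = merged[merged["lag_class"].isna()][["city", "year"]].iloc[0]
        raise ValidationError(
            f"missing lag class for {bad['city']}/{bad['year']}")
    years = sorted(merged["year"].unique())
    wide_t = merged.pivot(index="city", columns="year", values="type")
    wide_g = merged.pivot(index="city", columns="year", values="lag_class")
    strata_counts = {g: np.zeros((typed.k, typed.k), dtype=int)
                     for g in range(1, typed.k + 1)}
    for t in years[:-1]:
        origin = wide_t[t].to_numpy(dtype=int)
        dest = wide_t[t + 1].to_numpy(dtype=int)
        strat = wide_g[t].to_numpy(dtype=int)
        for g in strata_counts:
            sel = strat == g
            np.add.at(strata_counts[g], (origin[sel] - 1, dest[sel] - 1), 1)
    return SpatialTransitionMatrix(
        k=typed.k, strata={g: _from_counts(c) for g, c in strata_counts.items()})


def diagonal_summary(matrix: TransitionMatrix) -> Tuple[float, float]:
    """(min, max) self-locking probability over occupied rows."""
    occupied = ~matrix.zero_row_flags
    if not occupied.any():
        raise DomainError("all rows of the transition matrix are empty")
    diag = np.diag(matrix.probs)[occupied]
    return float(diag.min()), float(diag.max())


def matrix_frame(matrix: TransitionMatrix,
                 lag_class: Optional[int] = None) -> pd.DataFrame:
    """Long-format rows (from_type, to_type, count, prob) of one matrix."""
    rows = []
    for i in range(matrix.k):
        for j in range(matrix.k):
            row = {"from_type": i + 1, "to_type": j + 1,
                   "count": int(matrix.counts[i, j]),
                   "prob": float(matrix.probs[i, j])}
            if lag_class is not None:
                row = {"lag_class": lag_class, **row}
            rows.append(row)
    return pd.DataFrame(rows)
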