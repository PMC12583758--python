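"""Theil index of regional inequality and its within/between decomposition.

The Theil-T index (generalized entropy with α = 1) over city values E_i
with mean μ is

    T = (1/n) Σ_i (E_i/μ) · ln(E_i/μ),

zero under perfect equality and bounded above by ln n.  Grouping the cities
into regions g with group means μ_g and emission shares
s_g = n_g μ_g / (n μ) gives the exact additive decomposition

    T = Σ_g s_g T_g            (within-region)
      + Σ_g s_g ln(μ_g/μ)      (between-region),

the unique decomposition additive under this entropy form.  Contribution
percentages are component/total × 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .panel import RegionScheme


@dataclass
class TheilResult:
    """Total Theil index with its within/between-region split for one year."""

    year: Optional[int]
    total_T: float
    within_T: float
    between_T: float
    group_T: Dict[str, float]
    within_contrib_pct: Optional[float]
    between_contrib_pct: Optional[float]


def theil(values: Mapping[str, float]) -> float:
    """Theil-T index of a mapping of positive city values."""
    arr = np.asarray(list(values.values()), dtype=float)
    if arr.size == 0:
        raise DomainError("theil of an empty collection is undefined")
    if (arr <= 0).any():
        raise DomainError("theil requires strictly positive values")
    ratio = arr / arr.mean()
    return float(np.mean(ratio * np.log(ratio)))


def theil_decompose(values: Mapping[str, float], scheme: RegionScheme,
                    year: Optional[int] = None) -> TheilResult:
    """Decompose the Theil index into within- and between-region parts.

    ``within + between`` equals the total exactly (up to float round-off).
    When the total is zero (perfect equality) the contribution percentages
    are reported as ``None``.
    """
    missing = set(values) - set(scheme)
    if missing:
        raise ValidationError(f"cities not in region scheme: {sorted(missing)}")
    groups: Dict[str, List[float]] = {}
    for city, v in values.items():
        groups.setdefault(scheme[city], []).append(v)
    if any(len(members) == 0 for members in groups.values()):
        raise ValidationError("empty region group")

    n = len(values)
    mu = float(np.mean(list(values.values())))
    total = theil(values)

    within = 0.0
    between = 0.0
    group_T: Dict[str, float] = {}
    for region, members in groups.items():
        arr = np.asarray(members, dtype=float)
        mu_g = float(arr.mean())
        share = len(arr) * mu_g / (n * mu)
        t_g = theil(dict(enumerate(arr)))
        group_T[region] = t_g
        within += share * t_g
        between += share * np.log(mu_g / mu)

    if total > 0:
        w_pct = within / total * 100.0
        b_pct = between / total * 100.0
    else:
        w_pct = b_pct = None
    return TheilResult(year=year, total_T=total, within_T=within, between_T=between,
                       group_T=group_T, within_contrib_pct=w_pct,
                       between_contrib_pct=b_pct)


def theil_series(table: pd.DataFrame, scheme: RegionScheme, value_col: str,
                 years: Optional[Iterable[int]] = None) -> List[TheilResult]:
    """One Theil decomposition per year of a (city, year, value) table."""
    years = sorted(years) if years is not None else sorted(table["year"].unique())
    results = []
    for year in years:
        sub = table[table["year"] == year]
        values = dict(zip(sub["city"], sub[value_col].astype(float)))
        results.append(theil_decompose(values, scheme, year=year))
    return results


def theil_frame(results: Iterable[TheilResult], variable: str) -> pd.DataFrame:
    """Flatten TheilResults to the theil.csv layout."""
    rows = []
    for res in results:
        row = {"year": res.year, "variable": variable, "total": res.total_T,
               "within": res.within_T, "between": res.between_T,
               "within_pct": res.within_contrib_pct,
               "between_pct": res.between_contrib_pct}
        for region, t in sorted(res.group_T.items()):
            row[f"T_{region}"] = t
        rows.append(row)
    return pd.DataFrame(rows)
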