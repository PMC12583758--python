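"""City×year livestock panel: data model, CSV I/O, validation, imputation.

A :class:`Panel` holds one :class:`PanelRecord` per (city, year) over a
contiguous year range.  Each record carries the per-species head counts,
per-product output tonnages, energy expenditure per head, the feed
consumption factor per product and the grain shares of the concentrate
formulation, and the livestock output value used as the economic series.

CSV schemas (UTF-8, header row, "." decimal):

========================  =====================================================
inventory.csv             city,year,species,head
output.csv                city,year,product,tonnes
feed.csv                  product,feed_factor_t_per_t
shares.csv                grain,share
energycost.csv            city,year,species,elec_cny_per_head,coal_cny_per_head
gdp.csv                   city,year,output_value_cny
regions.csv               city,region
adjacency.csv             city_a,city_b
========================  =====================================================

Missing cells in the city×year tables are filled by a distance-weighted
average of the nearest preceding and following observations in the same city
series (linear interpolation in the year index); boundary gaps take the
nearest observed value.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

PANEL_FILES = ("inventory", "output", "feed", "shares", "energycost", "gdp")

# Table-driven default regionalisation: 18 prefecture-level cities in five
# geographic divisions of Henan.
_DEFAULT_REGIONS = {
    "Kaifeng": "Eastern", "Shangqiu": "Eastern", "Zhoukou": "Eastern",
    "Zhengzhou": "Central", "Pingdingshan": "Central", "Xuchang": "Central",
    "Luohe": "Central",
    "Nanyang": "Southern", "Xinyang": "Southern", "Zhumadian": "Southern",
    "Luoyang": "West", "Jiaozuo": "West", "Sanmenxia": "West", "Jiyuan": "West",
    "Anyang": "North", "Hebi": "North", "Xinxiang": "North", "Puyang": "North",
}


@dataclass
class PanelRecord:
    """One city×year observation."""

    city: str
    year: int
    inventories: Dict[str, float] = field(default_factory=dict)  # species -> head
    outputs: Dict[str, float] = field(default_factory=dict)  # product -> t/a
    feed_factor: Dict[str, float] = field(default_factory=dict)  # product -> t feed/t
    grain_shares: Dict[str, float] = field(default_factory=dict)  # grain -> fraction
    elec_cost: Dict[str, float] = field(default_factory=dict)  # species -> CNY/head/a
    coal_cost: Dict[str, float] = field(default_factory=dict)  # species -> CNY/head/a
    output_value: float = 0.0  # CNY/a

    def validate(self) -> None:
        for label, mapping in (("inventories", self.inventories),
                               ("outputs", self.outputs),
                               ("feed_factor", self.feed_factor),
                               ("elec_cost", self.elec_cost),
                               ("coal_cost", self.coal_cost)):
            for key, value in mapping.items():
                if value < 0 or not np.isfinite(value):
                    raise ValidationError(
                        f"{self.city}/{self.year}: {label}[{key}]={value} must be >= 0"
                    )
        total_share = 0.0
        for grain, share in self.grain_shares.items():
            if not 0.0 <= share <= 1.0:
                raise ValidationError(
                    f"{self.city}/{self.year}: grain share {grain}={share} not in [0,1]"
                )
            total_share += share
        if total_share > 1.0 + 1e-9:
            raise ValidationError(
                f"{self.city}/{self.year}: grain shares sum to {total_share} > 1"
            )
        if not self.output_value > 0:
            raise ValidationError(
                f"{self.city}/{self.year}: output_value must be > 0"
            )


RegionScheme = Dict[str, str]
AdjacencyList = Dict[str, Set[str]]


@dataclass
class Panel:
    """All records of a city×year panel with contiguous years."""

    records: List[PanelRecord]
    cities: List[str]
    years: List[int]

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            key = (rec.city, rec.year)
            if key in seen:
                raise FormatError(f"duplicate record for {key}")
            seen.add(key)
        expected = {(c, y) for c in self.cities for y in self.years}
        if seen != expected:
            missing = sorted(expected - seen)[:5]
            extra = sorted(seen - expected)[:5]
            raise ValidationError(
                f"panel is not complete: missing={missing} extra={extra}"
            )
        if self.years != list(range(min(self.years), max(self.years) + 1)):
            raise ValidationError("panel years must be contiguous")

    def record(self, city: str, year: int) -> PanelRecord:
        return self._index[(city, year)]

    @property
    def _index(self) -> Dict[Tuple[str, int], PanelRecord]:
        idx = getattr(self, "_index_cache", None)
        if idx is None or len(idx) != len(self.records):
            idx = {(r.city, r.year): r for r in self.records}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    def validate(self) -> None:
        for rec in self.records:
            rec.validate()


def default_region_scheme() -> RegionScheme:
    """The 18-city, five-region scheme used for regional decomposition."""
    return dict(_DEFAULT_REGIONS)


# ---------------------------------------------------------------------------
# Imputation


def impute_series(years: Iterable[int], values: Iterable[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Fill NaN cells of one annual series by inverse-distance weighting.

    An interior gap is the weighted average of the nearest preceding and
    following observed values, weighted inversely by distance in years —
    i.e. linear interpolation in the year index.  Gaps at either boundary
    take the nearest observed value.  Returns (filled values, imputed mask).
    """
    idx = pd.Index(list(years), name="year")
    s = pd.Series(list(values), index=idx, dtype=float)
    mask = s.isna().to_numpy()
    if mask.all():
        raise ValidationError("cannot impute an all-missing series")
    filled = s.interpolate(method="index", limit_direction="both")
    return filled.to_numpy(), mask


def impute_missing(frame: pd.DataFrame, value_cols: Iterable[str],
                   by: Iterable[str] = ("city",), year_col: str = "year"
                   ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing cells of a long-format city×year table.

    Each group defined by ``by`` (e.g. city, or city+species) is treated as
    one annual series per value column and filled with
    :func:`impute_series`.  Returns the filled frame and a boolean frame of
    the same shape flagging imputed cells.  Idempotent: running it on an
    already-complete table returns it unchanged.
    """
    frame = frame.sort_values([*by, year_col]).reset_index(drop=True)
    flags = pd.DataFrame(False, index=frame.index, columns=list(value_cols))
    out = frame.copy()
    for _, group in frame.groupby(list(by), sort=False):
        for col in value_cols:
            filled, mask = impute_series(group[year_col], group[col])
            # touch only the cells that were missing: observed values stay
            # bit-identical through a read/write round trip
            out.loc[group.index[mask], col] = filled[mask]
            flags.loc[group.index, col] = mask
    return out, flags


# ---------------------------------------------------------------------------
# CSV I/O


def _read_csv(path: str, columns: List[str]) -> pd.DataFrame:
    # round_trip parsing keeps write->read->write bit-stable
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(columns) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def _check_no_duplicates(df: pd.DataFrame, keys: List[str], path: str) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        first = df.loc[dup, keys].iloc[0].to_dict()
        raise FormatError(f"{path}: duplicated row for {first}")


def read_panel(directory: str, impute: bool = True) -> Panel:
    """Read and validate a panel from its CSV file set.

    Parameters
    ----------
    directory
        Directory holding ``inventory.csv``, ``output.csv``, ``feed.csv``,
        ``shares.csv``, ``energycost.csv`` and ``gdp.csv``.
    impute
        Fill missing numeric cells with the weighted-average rule before
        assembling records.
    """
    paths = {name: os.path.join(directory, f"{name}.csv") for name in PANEL_FILES}
    for name, p in paths.items():
        if not os.path.exists(p):
            raise FormatError(f"missing panel file {p}")

    inv = _read_csv(paths["inventory"], ["city", "year", "species", "head"])
    outp = _read_csv(paths["output"], ["city", "year", "product", "tonnes"])
    feed = _read_csv(paths["feed"], ["product", "feed_factor_t_per_t"])
    shares = _read_csv(paths["shares"], ["grain", "share"])
    cost = _read_csv(paths["energycost"],
                     ["city", "year", "species", "elec_cny_per_head", "coal_cny_per_head"])
    gdp = _read_csv(paths["gdp"], ["city", "year", "output_value_cny"])

    _check_no_duplicates(inv, ["city", "year", "species"], paths["inventory"])
    _check_no_duplicates(outp, ["city", "year", "product"], paths["output"])
    _check_no_duplicates(cost, ["city", "year", "species"], paths["energycost"])
    _check_no_duplicates(gdp, ["city", "year"], paths["gdp"])
    _check_no_duplicates(feed, ["product"], paths["feed"])
    _check_no_duplicates(shares, ["grain"], paths["shares"])

    if impute:
        inv, _ = impute_missing(inv, ["head"], by=("city", "species"))
        outp, _ = impute_missing(outp, ["tonnes"], by=("city", "product"))
        cost, _ = impute_missing(cost, ["elec_cny_per_head", "coal_cny_per_head"],
                                 by=("city", "species"))
        gdp, _ = impute_missing(gdp, ["output_value_cny"], by=("city",))

    cities = sorted(set(inv["city"]) | set(gdp["city"]))
    years = sorted(set(inv["year"].astype(int)) | set(gdp["year"].astype(int)))
    if years != list(range(years[0], years[-1] + 1)):
        raise ValidationError(f"panel years {years[0]}..{years[-1]} contain gaps")

    feed_map = dict(zip(feed["product"], feed["feed_factor_t_per_t"].astype(float)))
    share_map = dict(zip(shares["grain"], shares["share"].astype(float)))

    def nest(df: pd.DataFrame, key: str, val: str) -> Dict[Tuple[str, int], Dict[str, float]]:
        table: Dict[Tuple[str, int], Dict[str, float]] = {}
        for row in df.itertuples(index=False):
            table.setdefault((row.city, int(row.year)), {})[getattr(row, key)] = float(
                getattr(row, val))
        return table

    inv_map = nest(inv, "species", "head")
    out_map = nest(outp, "product", "tonnes")
    elec_map = nest(cost, "species", "elec_cny_per_head")
    coal_map = nest(cost, "species", "coal_cny_per_head")
    gdp_map = {(row.city, int(row.year)): float(row.output_value_cny)
               for row in gdp.itertuples(index=False)}

    records = []
    for city in cities:
        for year in years:
            key = (city, year)
            rec = PanelRecord(
                city=city, year=year,
                inventories=inv_map.get(key, {}),
                outputs=out_map.get(key, {}),
                feed_factor=dict(feed_map),
                grain_shares=dict(share_map),
                elec_cost=elec_map.get(key, {}),
                coal_cost=coal_map.get(key, {}),
                output_value=gdp_map.get(key, float("nan")),
            )
            rec.validate()
            records.append(rec)
    return Panel(records=records, cities=cities, years=years)


def write_panel(panel: Panel, directory: str) -> None:
    """Write a panel back to the CSV schema set (inverse of read_panel)."""
    os.makedirs(directory, exist_ok=True)
    inv_rows, out_rows, cost_rows, gdp_rows = [], [], [], []
    for rec in sorted(panel.records, key=lambda r: (r.city, r.year)):
        for sp, head in sorted(rec.inventories.items()):
            inv_rows.append((rec.city, rec.year, sp, head))
        for prod, t in sorted(rec.outputs.items()):
            out_rows.append((rec.city, rec.year, prod, t))
        species = sorted(set(rec.elec_cost) | set(rec.coal_cost))
        for sp in species:
            cost_rows.append((rec.city, rec.year, sp,
                              rec.elec_cost.get(sp, 0.0), rec.coal_cost.get(sp, 0.0)))
        gdp_rows.append((rec.city, rec.year, rec.output_value))

    first = panel.records[0]
    pd.DataFrame(inv_rows, columns=["city", "year", "species", "head"]).to_csv(
        os.path.join(directory, "inventory.csv"), index=False)
    pd.DataFrame(out_rows, columns=["city", "year", "product", "tonnes"]).to_csv(
        os.path.join(directory, "output.csv"), index=False)
    pd.DataFrame(sorted(first.feed_factor.items()),
                 columns=["product", "feed_factor_t_per_t"]).to_csv(
        os.path.join(directory, "feed.csv"), index=False)
    pd.DataFrame(sorted(first.grain_shares.items()), columns=["grain", "share"]).to_csv(
        os.path.join(directory, "shares.csv"), index=False)
    pd.DataFrame(cost_rows, columns=["city", "year", "species",
                                     "elec_cny_per_head", "coal_cny_per_head"]).to_csv(
        os.path.join(directory, "energycost.csv"), index=False)
    pd.DataFrame(gdp_rows, columns=["city", "year", "output_value_cny"]).to_csv(
        os.path.join(directory, "gdp.csv"), index=False)


def read_region_scheme(path: str) -> RegionScheme:
    df = _read_csv(path, ["city", "region"])
    _check_no_duplicates(df, ["city"], path)
    return dict(zip(df["city"], df["region"]))


def write_region_scheme(scheme: RegionScheme, path: str) -> None:
    pd.DataFrame(sorted(scheme.items()), columns=["city", "region"]).to_csv(
        path, index=False)


def read_adjacency(path: str) -> AdjacencyList:
    df = _read_csv(path, ["city_a", "city_b"])
    adj: AdjacencyList = {}
    for row in df.itertuples(index=False):
        if row.city_a == row.city_b:
            raise ValidationError(f"{path}: self-loop on {row.city_a}")
        adj.setdefault(row.city_a, set()).add(row.city_b)
        adj.setdefault(row.city_b, set()).add(row.city_a)
    return adj


def write_adjacency(adj: AdjacencyList, path: str) -> None:
    edges = sorted({tuple(sorted((a, b))) for a, nbrs in adj.items() for b in nbrs})
    pd.DataFrame(edges, columns=["city_a", "city_b"]).to_csv(path, index=False)


def validate_adjacency(adj: AdjacencyList, cities: Iterable[str]) -> None:
    """Check symmetry, no self-loops, and coverage of all panel cities."""
    for a, nbrs in adj.items():
        if a in nbrs:
            raise ValidationError(f"adjacency self-loop on {a}")
        for b in nbrs:
            if a not in adj.get(b, set()):
                raise ValidationError(f"adjacency not symmetric: {a}->{b}")
    missing = set(cities) - set(adj)
    if missing:
        raise ValidationError(f"cities without adjacency entry: {sorted(missing)}")
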