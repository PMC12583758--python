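"""Life-cycle GHG accounting for livestock panels.

Seven emission stages per city×year, in source units:

===========  ============================================  ========
stage        meaning                                       unit
===========  ============================================  ========
efc          feed-grain cultivation                        t CO2-eq
eft          feed-grain transport & processing             t CO2-eq
efg_ch4      enteric (gastrointestinal) fermentation       kg CH4
efm_ch4      manure management CH4                         kg CH4
efs_n2o      manure management N2O                         kg N2O
efe          feeding energy (electricity + coal)           t CO2
efp          slaughter & product processing                t CO2
===========  ============================================  ========

The CO2-equivalent total weights the gas stages by the GWP of the active
set after converting kg gas to tonnes:

    etotal = efc + eft + (efg + efm)·GWP_CH4/1000 + efs·GWP_N2O/1000
             + efe + efp                            [t CO2-eq]

Unit bridges are fixed here, forced by the source units of the factors:
electricity expenditure (CNY/head) ÷ price (CNY/kWh) gives kWh, while the
grid emission factor is t CO2 per MWh, hence a ÷1000; likewise processing
energy MJ ÷ (MJ/kWh) gives kWh.  Gas masses are kept in kg through the
stage tables and divided by 1000 only in the GWP aggregation.

Annualized rates of change are geometric: (v1/v0)^(1/(y1−y0)) − 1.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ValidationError
from .factors import EmissionFactorSet, GwpSet
from .panel import Panel, PanelRecord

logger = logging.getLogger(__name__)

STAGE_COLUMNS = ["efc", "eft", "efg_ch4", "efm_ch4", "efs_n2o", "efe", "efp"]

_warned_grains: set = set()


def _feed_tonnage(record: PanelRecord) -> Dict[str, float]:
    """Concentrate feed consumed per product: Q_T · t  [t feed]."""
    feed = {}
    for product, q in record.outputs.items():
        if product not in record.feed_factor:
            raise ValidationError(
                f"{record.city}/{record.year}: product {product!r} has no feed factor"
            )
        feed[product] = q * record.feed_factor[product]
    return feed


def efc(record: PanelRecord, factors: EmissionFactorSet) -> float:
    """Feed-grain cultivation emissions, t CO2-eq.

    Σ_products Q_T·t · Σ_grains q_i·ef_cultivation.  Grains without a
    cultivation factor (e.g. soybean in the default registry) are skipped
    with a warning.
    """
    grain_term = 0.0
    for grain, share in record.grain_shares.items():
        gf = factors.grain_factors.get(grain)
        if gf is None:
            raise ValidationError(f"unknown feed grain {grain!r}")
        if gf.cultivation_co2 is None:
            if grain not in _warned_grains:
                logger.warning(
                    "grain %r has no cultivation factor; skipped in efc", grain)
                _warned_grains.add(grain)
            continue
        grain_term += share * gf.cultivation_co2
    return sum(_feed_tonnage(record).values()) * grain_term


def eft(record: PanelRecord, factors: EmissionFactorSet) -> float:
    """Feed-grain transport & processing emissions, t CO2-eq."""
    grain_term = 0.0
    for grain, share in record.grain_shares.items():
        gf = factors.grain_factors.get(grain)
        if gf is None:
            raise ValidationError(f"unknown feed grain {grain!r}")
        grain_term += share * gf.transport_processing_co2
    return sum(_feed_tonnage(record).values()) * grain_term


def _per_head(record: PanelRecord, factors: EmissionFactorSet, attr: str) -> float:
    total = 0.0
    for species, head in record.inventories.items():
        sf = factors.species_factors.get(species)
        if sf is None:
            raise ValidationError(f"unknown species {species!r}")
        total += head * getattr(sf, attr)
    return total


def efg(record: PanelRecord, factors: EmissionFactorSet) -> float:
    """Enteric fermentation CH4, kg."""
    return _per_head(record, factors, "enteric_ch4")


def efm(record: PanelRecord, factors: EmissionFactorSet) -> float:
    """Manure management CH4, kg."""
    return _per_head(record, factors, "manure_ch4")


def efs(record: PanelRecord, factors: EmissionFactorSet) -> float:
    """Manure management N2O, kg."""
    return _per_head(record, factors, "manure_n2o")


def efe(record: PanelRecord, factors: EmissionFactorSet) -> float:
    """Feeding-stage energy CO2, t.

    Electricity: head · (CNY/head ÷ CNY/kWh) kWh → ÷1000 MWh · t CO2/MWh.
    Coal: head · (CNY/head ÷ CNY/t) t coal · t CO2/t coal.
    """
    en = factors.energy
    total = 0.0
    for species, head in record.inventories.items():
        kwh = record.elec_cost.get(species, 0.0) / en.price_e
        t_coal = record.coal_cost.get(species, 0.0) / en.price_c
        total += head * (kwh / 1000.0 * en.ef_e + t_coal * en.ef_c)
    return total


def efp(record: PanelRecord, factors: EmissionFactorSet) -> float:
    """Slaughter & processing CO2, t: Q(kg) · MJ/kg ÷ (MJ/kWh) ÷1000 · t/MWh."""
    en = factors.energy
    total = 0.0
    for product, tonnes in record.outputs.items():
        pf = factors.processing.get(product)
        if pf is None:
            raise ValidationError(f"unknown product {product!r} in processing factors")
        kwh = tonnes * 1000.0 * pf.mj_per_kg / en.e_n
        total += kwh / 1000.0 * en.ef_e
    return total


def etotal(stages: Mapping[str, float], gwp: GwpSet) -> float:
    """CO2-equivalent total of one stage row, t CO2-eq."""
    return (stages["efc"] + stages["eft"]
            + (stages["efg_ch4"] + stages["efm_ch4"]) * gwp.gwp_ch4 / 1000.0
            + stages["efs_n2o"] * gwp.gwp_n2o / 1000.0
            + stages["efe"] + stages["efp"])


def account_record(record: PanelRecord, factors: EmissionFactorSet) -> Dict[str, float]:
    """All stage emissions plus the CO2-eq total for one record."""
    row = {
        "efc": efc(record, factors),
        "eft": eft(record, factors),
        "efg_ch4": efg(record, factors),
        "efm_ch4": efm(record, factors),
        "efs_n2o": efs(record, factors),
        "efe": efe(record, factors),
        "efp": efp(record, factors),
    }
    row["etotal"] = etotal(row, factors.gwp)
    return row


def account_panel(panel: Panel, factors: EmissionFactorSet) -> pd.DataFrame:
    """Stage emissions for every (city, year) of a panel.

    Returns a DataFrame with columns city, year, the seven stages, and
    ``etotal`` (t CO2-eq under the factor set's GWP).  Provincial totals
    are plain column sums; record order never affects the result.
    """
    rows = []
    for rec in sorted(panel.records, key=lambda r: (r.city, r.year)):
        row = {"city": rec.city, "year": rec.year}
        row.update(account_record(rec, factors))
        rows.append(row)
    return pd.DataFrame(rows)


def provincial_series(stage_table: pd.DataFrame, column: str = "etotal") -> pd.Series:
    """Year-indexed provincial (all-city) sum of one stage column."""
    return stage_table.groupby("year")[column].sum()


def manure_co2eq(stage_table: pd.DataFrame, gwp: GwpSet) -> pd.Series:
    """Combined manure-management emissions (CH4 + N2O) in t CO2-eq per row."""
    return (stage_table["efm_ch4"] * gwp.gwp_ch4
            + stage_table["efs_n2o"] * gwp.gwp_n2o) / 1000.0


def annualized_rate(series: Mapping[int, float], y0: int, y1: int) -> float:
    """Geometric mean annual rate of change between two years.

    ``(series[y1] / series[y0]) ** (1/(y1−y0)) − 1``; requires strictly
    positive endpoint values and ``y1 > y0``.
    """
    if y1 <= y0:
        raise DomainError(f"need y1 > y0, got {y0}..{y1}")
    v0, v1 = series[y0], series[y1]
    if not (v0 > 0 and v1 > 0):
        raise DomainError(f"endpoints must be > 0, got {v0}, {v1}")
    return (v1 / v0) ** (1.0 / (y1 - y0)) - 1.0


def stage_correlations(stage_table: pd.DataFrame, period: Tuple[int, int],
                       gwp: GwpSet) -> pd.DataFrame:
    """Pearson correlation of each stage's provincial series with the total.

    Stages are expressed in CO2-eq (manure CH4 and N2O are combined into one
    manure series, matching how the stages are usually reported).  Returns a
    DataFrame indexed by stage with columns ``r`` and ``p`` (two-sided, from
    the t distribution with n−2 df).  A zero-variance stage yields NaN in
    both columns rather than raising.
    """
    y0, y1 = period
    sub = stage_table[(stage_table["year"] >= y0) & (stage_table["year"] <= y1)].copy()
    if sub["year"].nunique() < 3:
        raise DomainError("need at least 3 years for a correlation")
    sub["ems"] = manure_co2eq(sub, gwp)
    sub["efg_co2eq"] = sub["efg_ch4"] * gwp.gwp_ch4 / 1000.0
    yearly = sub.groupby("year")[["efc", "eft", "efg_co2eq", "ems", "efe", "efp",
                                  "etotal"]].sum()
    total = yearly["etotal"].to_numpy()
    out = {}
    for stage in ["efc", "eft", "efg_co2eq", "ems", "efe", "efp"]:
        x = yearly[stage].to_numpy()
        if np.std(x) == 0 or np.std(total) == 0:
            out[stage] = (np.nan, np.nan)
        else:
            r, p = stats.pearsonr(x, total)
            out[stage] = (r, p)
    return pd.DataFrame(out, index=["r", "p"]).T
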