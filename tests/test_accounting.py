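"""Stage-by-stage arithmetic checks of the LCA engine against a hand oracle."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from livecarbon import accounting as acc
from livecarbon.errors import DomainError, ValidationError
from livecarbon.factors import GwpSet, default_factors
from livecarbon.panel import Panel, PanelRecord
from livecarbon.synthdata import SynthConfig, generate_panel


def hand_oracle(record, gwp_ch4, gwp_n2o):
    """Fully scripted arithmetic for the one-pig-city fixture.

    Written out long-hand and independently of the engine: every factor is a
    literal, every unit conversion explicit.
    """
    feed_t = 2.0 * 3.5  # t product × t feed / t product
    efc = feed_t * (0.6 * 1.50 + 0.2 * 1.22)  # soybean has no cultivation factor
    eft = feed_t * (0.6 * 0.0102 + 0.2 * 0.0319 + 0.15 * 0.1013)
    efg = 100.0 * 1.00  # kg CH4
    efm = 100.0 * 3.50  # kg CH4
    efs = 100.0 * 0.53  # kg N2O
    kwh_per_head = 21.375 / 0.4275
    t_coal_per_head = 80.0 / 800.0
    efe = 100.0 * (kwh_per_head / 1000.0 * 0.9734 + t_coal_per_head * 1.98)
    efp = 2.0 * 1000.0 * 3.76 / 3.60 / 1000.0 * 0.9734
    etotal = (efc + eft + (efg + efm) * gwp_ch4 / 1000.0
              + efs * gwp_n2o / 1000.0 + efe + efp)
    return dict(efc=efc, eft=eft, efg_ch4=efg, efm_ch4=efm, efs_n2o=efs,
                efe=efe, efp=efp, etotal=etotal)


def test_feed_cultivation_hand_value(factors100):
    record = PanelRecord(city="c", year=2001, outputs={"pork": 2.0},
                         feed_factor={"pork": 3.5},
                         grain_shares={"corn": 0.6, "wheat": 0.2},
                         output_value=1.0)
    assert acc.efc(record, factors100) == pytest.approx(8.008)
    record.outputs["pork"] = 0.0
    assert acc.efc(record, factors100) == 0.0


def test_feed_transport_hand_value(factors100):
    record = PanelRecord(city="c", year=2001, outputs={"pork": 2.0},
                         feed_factor={"pork": 3.5},
                         grain_shares={"corn": 0.6, "soybean": 0.2},
                         output_value=1.0)
    assert acc.eft(record, factors100) == pytest.approx(7 * (0.00612 + 0.02026))
    record.grain_shares = {"corn": 0.0, "soybean": 0.0}
    assert acc.eft(record, factors100) == 0.0


def test_enteric_fermentation(factors100):
    cattle = PanelRecord(city="c", year=2001, inventories={"cattle": 100.0},
                         output_value=1.0)
    assert acc.efg(cattle, factors100) == pytest.approx(5290.0)
    birds = PanelRecord(city="c", year=2001, inventories={"poultry": 1000.0},
                        output_value=1.0)
    assert acc.efg(birds, factors100) == 0.0
    empty = PanelRecord(city="c", year=2001, output_value=1.0)
    assert acc.efg(empty, factors100) == 0.0


def test_manure_stages(factors100):
    pigs = PanelRecord(city="c", year=2001, inventories={"pig": 1000.0},
                       output_value=1.0)
    assert acc.efm(pigs, factors100) == pytest.approx(3500.0)
    assert acc.efs(pigs, factors100) == pytest.approx(530.0)
    pigs.inventories["pig"] = 0.0
    assert acc.efm(pigs, factors100) == 0.0


def test_unknown_species_raises(factors100):
    rec = PanelRecord(city="c", year=2001, inventories={"yak": 10.0},
                      output_value=1.0)
    with pytest.raises(ValidationError):
        acc.efg(rec, factors100)


def test_feeding_energy_hand_value(factors100):
    rec = PanelRecord(city="c", year=2001, inventories={"pig": 10.0},
                      elec_cost={"pig": 21.375}, coal_cost={"pig": 80.0},
                      output_value=1.0)
    assert acc.efe(rec, factors100) == pytest.approx(2.46670, abs=1e-5)
    rec.elec_cost["pig"] = rec.coal_cost["pig"] = 0.0
    assert acc.efe(rec, factors100) == 0.0
    rec.elec_cost["pig"], rec.coal_cost["pig"] = 21.375, 80.0
    rec2 = dataclasses.replace(rec, inventories={"pig": 20.0})
    assert acc.efe(rec2, factors100) == pytest.approx(2 * 2.46670, abs=1e-5)


def test_processing_hand_values(factors100):
    pork = PanelRecord(city="c", year=2001, outputs={"pork": 1.0},
                       feed_factor={"pork": 3.5}, output_value=1.0)
    assert acc.efp(pork, factors100) == pytest.approx(1000 * (3.76 / 3.60) / 1000 * 0.9734)
    milk = PanelRecord(city="c", year=2001, outputs={"milk": 1.0},
                       feed_factor={"milk": 0.9}, output_value=1.0)
    assert acc.efp(milk, factors100) == pytest.approx(0.30283, abs=1e-5)
    pork.outputs["pork"] = 0.0
    assert acc.efp(pork, factors100) == 0.0


def test_etotal_gwp_weighting():
    gwp100 = GwpSet("GWP100", 27.0, 273.0)
    zeros = dict(efc=0, eft=0, efg_ch4=0, efm_ch4=0, efs_n2o=0, efe=0, efp=0)
    assert acc.etotal(zeros, gwp100) == 0.0
    assert acc.etotal({**zeros, "efg_ch4": 1000.0}, gwp100) == pytest.approx(27.0)
    assert acc.etotal({**zeros, "efs_n2o": 1000.0}, gwp100) == pytest.approx(273.0)


@pytest.mark.parametrize("gwp_name", ["GWP100", "GWP20"])
def test_account_record_equals_hand_oracle(pig_record, gwp_name):
    factors = default_factors(gwp_name)
    row = acc.account_record(pig_record, factors)
    expected = hand_oracle(pig_record, factors.gwp.gwp_ch4, factors.gwp.gwp_n2o)
    for key, value in expected.items():
        assert row[key] == pytest.approx(value, rel=1e-9), key


def test_account_panel_composition_and_additivity(pig_record, factors100):
    single = Panel(records=[pig_record], cities=["Testville"], years=[2001])
    table = acc.account_panel(single, factors100)
    assert len(table) == 1
    row = acc.account_record(pig_record, factors100)
    for key, value in row.items():
        assert table.iloc[0][key] == pytest.approx(value)
    # two identical cities double the provincial total
    twin = dataclasses.replace(pig_record, city="Twinville")
    double = Panel(records=[pig_record, twin], cities=["Testville", "Twinville"],
                   years=[2001])
    t2 = acc.account_panel(double, factors100)
    assert t2["etotal"].sum() == pytest.approx(2 * table["etotal"].sum())
    # record order never matters
    rev = Panel(records=[twin, pig_record], cities=["Testville", "Twinville"],
                years=[2001])
    pd.testing.assert_frame_equal(acc.account_panel(rev, factors100), t2)


@settings(deadline=None, derandomize=True)
@given(scale=st.floats(min_value=0.0, max_value=1e4))
def test_stage_ops_are_homogeneous_of_degree_one(scale):
    factors = default_factors()
    base = PanelRecord(city="c", year=2001,
                       inventories={"pig": 10.0, "cattle": 3.0},
                       outputs={"pork": 1.0, "beef": 0.4},
                       feed_factor={"pork": 3.5, "beef": 7.0},
                       grain_shares={"corn": 0.6, "wheat": 0.2},
                       elec_cost={"pig": 20.0, "cattle": 30.0},
                       coal_cost={"pig": 25.0, "cattle": 40.0},
                       output_value=1.0)
    scaled = dataclasses.replace(
        base,
        inventories={k: v * scale for k, v in base.inventories.items()},
        outputs={k: v * scale for k, v in base.outputs.items()})
    for op in (acc.efc, acc.eft, acc.efg, acc.efm, acc.efs, acc.efe, acc.efp):
        assert op(scaled, factors) == pytest.approx(scale * op(base, factors),
                                                    rel=1e-9, abs=1e-12)


def test_gwp20_total_dominates_gwp100_on_random_panels():
    """With any CH4 emitted, the 20-year horizon total is the larger one."""
    for seed in (1, 2, 3):
        panel, _, _ = generate_panel(SynthConfig(seed=seed))
        t100 = acc.account_panel(panel, default_factors("GWP100"))
        t20 = acc.account_panel(panel, default_factors("GWP20"))
        assert (t20["etotal"] >= t100["etotal"]).all()
        assert (t20["etotal"] > t100["etotal"]).any()


# --- annualized rates -------------------------------------------------------

def test_annualized_rate_reproduces_published_provincial_decline():
    series = {2001: 4829.90, 2021: 3805.48}
    assert acc.annualized_rate(series, 2001, 2021) * 100 == pytest.approx(-1.18, abs=0.005)


def test_annualized_rate_first_phase():
    series = {2001: 4829.90, 2007: 4533.08}
    assert acc.annualized_rate(series, 2001, 2007) * 100 == pytest.approx(-1.05, abs=0.005)


def test_annualized_rate_second_phase():
    series = {2015: 5069.75, 2021: 3805.48}
    assert acc.annualized_rate(series, 2015, 2021) * 100 == pytest.approx(-4.67, abs=0.005)


def test_annualized_rate_constant_series_and_scale_invariance():
    assert acc.annualized_rate({2001: 5.0, 2011: 5.0}, 2001, 2011) == 0.0
    a = acc.annualized_rate({2001: 4.0, 2011: 9.0}, 2001, 2011)
    b = acc.annualized_rate({2001: 40.0, 2011: 90.0}, 2001, 2011)
    assert a == pytest.approx(b, rel=1e-12)


def test_annualized_rate_domain_errors():
    with pytest.raises(DomainError):
        acc.annualized_rate({2001: 0.0, 2002: 1.0}, 2001, 2002)
    with pytest.raises(DomainError):
        acc.annualized_rate({2001: 1.0, 2002: 1.0}, 2002, 2001)


# --- correlations -----------------------------------------------------------

def test_stage_correlations_hand_values(synth_panel, factors100):
    panel, _, _ = synth_panel
    table = acc.account_panel(panel, factors100)
    corr = acc.stage_correlations(table, (panel.years[0], panel.years[-1]),
                                  factors100.gwp)
    assert set(corr.index) == {"efc", "eft", "efg_co2eq", "ems", "efe", "efp"}
    assert ((corr["r"] >= -1) & (corr["r"] <= 1)).all()
    # a stage identical to the total correlates perfectly
    clone = table.copy()
    for col in ["eft", "efg_ch4", "efm_ch4", "efs_n2o", "efe", "efp"]:
        clone[col] = 0.0
    clone["efc"] = clone["etotal"]
    corr2 = acc.stage_correlations(clone, (panel.years[0], panel.years[-1]),
                                   factors100.gwp)
    assert corr2.loc["efc", "r"] == pytest.approx(1.0)


def test_pearson_hand_series():
    from scipy import stats
    assert stats.pearsonr([1, 2, 3], [2, 4, 6])[0] == pytest.approx(1.0)
    r, _ = stats.pearsonr([1, 2, 3], [6, 4, 5])
    assert r == pytest.approx(-0.5)


def test_zero_variance_stage_is_flagged_not_raised(synth_panel, factors100):
    panel, _, _ = synth_panel
    table = acc.account_panel(panel, factors100)
    table["efc"] = 1.0
    corr = acc.stage_correlations(table, (panel.years[0], panel.years[-1]),
                                  factors100.gwp)
    assert np.isnan(corr.loc["efc", "r"]) and np.isnan(corr.loc["efc", "p"])
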