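"""Tapio decoupling elasticity between emissions and economic output.

The elasticity over a year pair is

    E = (ΔC/C) / (ΔG/G),

the ratio of the relative change in emissions C to the relative change in
output value G.  Together with the signs of the two changes, E places the
period in one of eight states:

================  ====  ====  ================
state             ΔC    ΔG    elasticity band
================  ====  ====  ================
strong decoupling  <0    >0   E < 0
weak decoupling    >0    >0   0 ≤ E < 0.8
recessive decpl.   <0    <0   E > 1.2
weak neg. decpl.   <0    <0   0 ≤ E < 0.8
strong neg. decpl. >0    <0   E < 0
expansive neg. d.  >0    >0   E > 1.2
expansive cpl.     >0    >0   0.8 ≤ E ≤ 1.2
recessive cpl.     <0    <0   0.8 ≤ E ≤ 1.2
================  ====  ====  ================

For consistent inputs the state is determined entirely by sign(ΔG) and the
band of E (the sign of ΔC is implied by E's sign), which also makes the
classifier total over boundary inputs such as ΔC = 0: an unchanged emission
level during economic growth has E = 0 and counts as weak decoupling.
ΔG = 0 leaves E undefined and yields the sentinel ``undefined`` state.

The classifier takes the elasticity at face value rather than recomputing
it from the two relative changes, so that triples quoted at limited
precision (where the rounded ratio can drift across a band edge) classify
by their reported elasticity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import List, Mapping, Optional, Tuple

import pandas as pd

from .errors import DomainError


class DecouplingState(enum.Enum):
    strong_decoupling = "G"
    weak_decoupling = "D"
    recessive_decoupling = "N"
    weak_negative_decoupling = "DI"
    strong_negative_decoupling = "GI"
    expansive_negative_decoupling = "Q"
    expansive_coupling = "QI"
    recessive_coupling = "NI"
    undefined = "?"

    @property
    def letter(self) -> str:
        """Compact letter code used in tabular output."""
        return self.value


@dataclass
class DecouplingRecord:
    """Relative changes, elasticity and state for one year pair."""

    period: Tuple[int, int]
    dC_rel: float
    dG_rel: float
    elasticity: Optional[float]
    state: DecouplingState


def elasticity(C0: float, C1: float, G0: float, G1: float
               ) -> Tuple[float, float, Optional[float]]:
    """Relative changes and Tapio elasticity between two years.

    Returns ``(dC_rel, dG_rel, E)`` with ``E`` ``None`` when the output
    value did not change.  Base-year values must be positive.
    """
    if not (C0 > 0 and G0 > 0):
        raise DomainError(f"base-year values must be > 0, got C0={C0}, G0={G0}")
    dC = (C1 - C0) / C0
    dG = (G1 - G0) / G0
    return dC, dG, (dC / dG if dG != 0 else None)


def classify(dC_rel: float, dG_rel: float,
             E: Optional[float]) -> DecouplingState:
    """Assign the eight-state Tapio class from signs and elasticity band."""
    if dG_rel == 0 or E is None:
        return DecouplingState.undefined
    if dG_rel > 0:
        if E < 0:
            return DecouplingState.strong_decoupling
        if E < 0.8:
            return DecouplingState.weak_decoupling
        if E <= 1.2:
            return DecouplingState.expansive_coupling
        return DecouplingState.expansive_negative_decoupling
    # economic contraction
    if E < 0:
        return DecouplingState.strong_negative_decoupling
    if E < 0.8:
        return DecouplingState.weak_negative_decoupling
    if E <= 1.2:
        return DecouplingState.recessive_coupling
    return DecouplingState.recessive_decoupling


def decoupling_series(emissions: Mapping[int, float], values: Mapping[int, float]
                      ) -> List[DecouplingRecord]:
    """Decoupling record for every consecutive year pair of two series."""
    years_e = sorted(emissions)
    years_g = sorted(values)
    if years_e != years_g:
        raise DomainError("emission and value series must cover the same years")
    if years_e != list(range(years_e[0], years_e[-1] + 1)):
        raise DomainError("series years must be contiguous")
    records = []
    for y0, y1 in zip(years_e[:-1], years_e[1:]):
        dC, dG, E = elasticity(emissions[y0], emissions[y1], values[y0], values[y1])
        records.append(DecouplingRecord(period=(y0, y1), dC_rel=dC, dG_rel=dG,
                                        elasticity=E, state=classify(dC, dG, E)))
    return records


def decoupling_frame(records: List[DecouplingRecord]) -> pd.DataFrame:
    """Flatten decoupling records to the decoupling.csv layout."""
    return pd.DataFrame([
        {"period": f"{r.period[0]}-{r.period[1]}", "dc_rel": r.dC_rel,
         "dg_rel": r.dG_rel, "elasticity": r.elasticity,
         "state": r.state.name, "code": r.state.letter}
        for r in records
    ])
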