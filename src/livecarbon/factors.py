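"""Registry of emission coefficients, energy prices and GWP sets.

All coefficients are stored in their source units (per-head kg of gas,
t CO2-eq per t grain, t CO2 per MWh, MJ per kg product); every unit
conversion happens downstream in :mod:`livecarbon.accounting`, never here.

Species factors cover enteric (gastrointestinal) fermentation CH4 and manure
management CH4/N2O per head and year.  Poultry emit no enteric CH4 (their
digestive tract lacks rumen fermentation); the registry encodes this as an
exact 0 and logs the convention once at load.

Soybean appears as a feed grain with a transport/processing coefficient but
no cultivation coefficient; its cultivation term is therefore *absent*
(``None``), which is distinct from zero and makes the feed-cultivation stage
skip it with a warning unless an override supplies a value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import yaml

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

GWP_SETS = {
    # 100-year horizon: CH4 27, N2O 273 (AR6); 20-year horizon: CH4 81.2.
    "GWP100": (27.0, 273.0),
    "GWP20": (81.2, 273.0),
}


@dataclass(frozen=True)
class SpeciesFactors:
    """Per-head annual gas emission factors for one species.

    enteric_ch4 and manure_ch4 are kg CH4 / (head·a); manure_n2o is
    kg N2O / (head·a).  A species with no enteric fermentation stores 0.
    """

    species: str
    enteric_ch4: float
    manure_ch4: float
    manure_n2o: float

    def __post_init__(self) -> None:
        for name in ("enteric_ch4", "manure_ch4", "manure_n2o"):
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"{self.species}.{name} must be >= 0, got {getattr(self, name)}"
                )


@dataclass(frozen=True)
class FeedGrainFactors:
    """CO2-eq factors for one feed grain, in t CO2-eq per t grain.

    ``cultivation_co2`` may be ``None`` when no cultivation factor is known
    for the grain; such grains are excluded from the cultivation stage.
    """

    grain: str
    transport_processing_co2: float
    cultivation_co2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.transport_processing_co2 < 0:
            raise ValidationError(f"{self.grain}: transport factor must be >= 0")
        if self.cultivation_co2 is not None and self.cultivation_co2 < 0:
            raise ValidationError(f"{self.grain}: cultivation factor must be >= 0")


@dataclass(frozen=True)
class EnergyFactors:
    """Energy-related coefficients for the feeding stage.

    ef_e: t CO2 per MWh electricity; price_e: CNY per kWh;
    ef_c: t CO2 per t coal; price_c: CNY per t coal;
    e_n: MJ per kWh (electric heating value).
    """

    ef_e: float
    price_e: float
    ef_c: float
    price_c: float
    e_n: float

    def __post_init__(self) -> None:
        for name in ("ef_e", "price_e", "ef_c", "price_c", "e_n"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"energy.{name} must be > 0")


@dataclass(frozen=True)
class ProcessingFactors:
    """Slaughter/processing energy intensity for one product, MJ per kg."""

    product: str
    mj_per_kg: float

    def __post_init__(self) -> None:
        if self.mj_per_kg < 0:
            raise ValidationError(f"{self.product}: mj_per_kg must be >= 0")


@dataclass(frozen=True)
class GwpSet:
    """Global warming potentials (mass basis, dimensionless vs CO2)."""

    name: str
    gwp_ch4: float
    gwp_n2o: float

    def __post_init__(self) -> None:
        if self.gwp_ch4 <= 1 or self.gwp_n2o <= 1:
            raise ValidationError("GWP values must exceed 1")


@dataclass(frozen=True)
class EmissionFactorSet:
    """The complete coefficient registry used by the accounting engine."""

    species_factors: Mapping[str, SpeciesFactors]
    grain_factors: Mapping[str, FeedGrainFactors]
    energy: EnergyFactors
    processing: Mapping[str, ProcessingFactors]
    gwp: GwpSet

    def with_gwp(self, gwp_name: str) -> "EmissionFactorSet":
        """Return a copy using a different named GWP set."""
        return replace(self, gwp=_gwp_set(gwp_name))


def _gwp_set(name: str) -> GwpSet:
    try:
        ch4, n2o = GWP_SETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown GWP set {name!r}; expected one of {sorted(GWP_SETS)}"
        ) from None
    return GwpSet(name=name, gwp_ch4=ch4, gwp_n2o=n2o)


_DEFAULT_SPECIES = {
    # species: (enteric CH4, manure CH4, manure N2O)  [kg/(head·a)]
    "cattle": (52.90, 3.31, 0.85),
    "pig": (1.00, 3.50, 0.53),
    "sheep": (5.00, 0.16, 0.33),
    "mule": (10.00, 0.90, 1.39),
    "donkey": (10.00, 0.90, 1.39),
    "horse": (18.00, 1.64, 1.39),
    "rabbit": (0.254, 0.08, 0.02),
    "poultry": (0.0, 0.02, 0.02),  # no rumen fermentation: enteric CH4 is 0
}

_DEFAULT_GRAINS = {
    # grain: (cultivation t CO2-eq/t or None, transport+processing t CO2-eq/t)
    "corn": (1.50, 0.0102),
    "wheat": (1.22, 0.0319),
    "soybean": (None, 0.1013),  # no cultivation factor available
}

_DEFAULT_ENERGY = dict(ef_e=0.9734, price_e=0.4275, ef_c=1.98, price_c=800.0, e_n=3.60)

_DEFAULT_PROCESSING = {
    # product: MJ per kg processed
    "pork": 3.76,
    "beef": 4.37,
    "mutton": 10.4,
    "poultry_meat": 2.59,
    "milk": 1.12,
    "eggs": 8.16,
}

_poultry_logged = False


def default_factors(gwp_name: str = "GWP100") -> EmissionFactorSet:
    """Build the default coefficient registry under a named GWP set.

    Parameters
    ----------
    gwp_name
        ``"GWP100"`` (CH4 27, N2O 273) or ``"GWP20"`` (CH4 81.2, N2O 273).
    """
    global _poultry_logged
    if not _poultry_logged:
        logger.info("poultry enteric CH4 factor encoded as 0 (no rumen fermentation)")
        logger.info("soybean has no cultivation CO2 factor; excluded from cultivation stage")
        _poultry_logged = True
    species = {
        name: SpeciesFactors(name, *vals) for name, vals in _DEFAULT_SPECIES.items()
    }
    grains = {
        name: FeedGrainFactors(name, transport_processing_co2=tp, cultivation_co2=cult)
        for name, (cult, tp) in _DEFAULT_GRAINS.items()
    }
    processing = {
        name: ProcessingFactors(name, mj) for name, mj in _DEFAULT_PROCESSING.items()
    }
    return EmissionFactorSet(
        species_factors=species,
        grain_factors=grains,
        energy=EnergyFactors(**_DEFAULT_ENERGY),
        processing=processing,
        gwp=_gwp_set(gwp_name),
    )


def load_factors(config_path) -> EmissionFactorSet:
    """Load a factor set from a YAML file of overrides on a named default.

    The file may contain ``base: GWP100|GWP20`` (default GWP100) plus any of
    the sections ``species``, ``grains``, ``energy``, ``processing``,
    ``gwp``.  Overrides are applied field-wise on top of the defaults and the
    result is re-validated, so e.g. a negative price raises
    :class:`~livecarbon.errors.ValidationError`.
    """
    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{config_path}: factor config must be a mapping")

    base = default_factors(raw.get("base", "GWP100"))
    species = dict(base.species_factors)
    grains = dict(base.grain_factors)
    processing = dict(base.processing)
    energy = base.energy
    gwp = base.gwp

    for name, fields in (raw.get("species") or {}).items():
        current = species.get(name)
        defaults = (
            {"enteric_ch4": current.enteric_ch4, "manure_ch4": current.manure_ch4,
             "manure_n2o": current.manure_n2o}
            if current
            else {"enteric_ch4": 0.0, "manure_ch4": 0.0, "manure_n2o": 0.0}
        )
        unknown = set(fields) - set(defaults)
        if unknown:
            raise ValidationError(f"species {name!r}: unknown keys {sorted(unknown)}")
        defaults.update(fields)
        species[name] = SpeciesFactors(name, **defaults)

    for name, fields in (raw.get("grains") or {}).items():
        current = grains.get(name)
        defaults = (
            {"cultivation_co2": current.cultivation_co2,
             "transport_processing_co2": current.transport_processing_co2}
            if current
            else {"cultivation_co2": None, "transport_processing_co2": 0.0}
        )
        unknown = set(fields) - set(defaults)
        if unknown:
            raise ValidationError(f"grain {name!r}: unknown keys {sorted(unknown)}")
        defaults.update(fields)
        grains[name] = FeedGrainFactors(name, defaults["transport_processing_co2"],
                                        defaults["cultivation_co2"])

    if "energy" in raw and raw["energy"]:
        fields = dict(_DEFAULT_ENERGY)
        current = {k: getattr(energy, k) for k in fields}
        unknown = set(raw["energy"]) - set(fields)
        if unknown:
            raise ValidationError(f"energy: unknown keys {sorted(unknown)}")
        current.update(raw["energy"])
        energy = EnergyFactors(**current)

    for name, mj in (raw.get("processing") or {}).items():
        processing[name] = ProcessingFactors(name, float(mj))

    if "gwp" in raw and raw["gwp"]:
        g = raw["gwp"]
        gwp = GwpSet(name=g.get("name", "custom"),
                     gwp_ch4=float(g.get("gwp_ch4", gwp.gwp_ch4)),
                     gwp_n2o=float(g.get("gwp_n2o", gwp.gwp_n2o)))

    return EmissionFactorSet(species_factors=species, grain_factors=grains,
                             energy=energy, processing=processing, gwp=gwp)
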