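"""Deterministic conversions between brain mass, brain volume, endocranial
volume, adnexa and body mass — the arithmetic backbone of the cavity
accounting and the fossil estimates.

Unit conventions are fixed at this module's boundary and enforced through
the coefficient registry: occipital condyle width (OCW) in mm, body mass in
kg, brain and adnexa mass in g, volumes in cm^3.  Brain tissue density is
selected by group label: 1.04 g/cm^3 for cetaceans, 1.036 g/cm^3 (the human
value) for terrestrial artiodactyls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from .errors import RegistryError
from .pgls import AllometricFit

logger = logging.getLogger(__name__)

__all__ = [
    "PowerLaw",
    "CoefficientRegistry",
    "default_registry",
    "brain_volume_from_mass",
    "percent_not_occupied",
    "reconstructed_endocranial_volume",
    "predict_brain_mass",
    "predict_body_mass_from_ocw",
    "back_calculate_ocw",
    "body_mass_from_length",
    "cavity_accounting",
]


@dataclass(frozen=True)
class PowerLaw:
    """y = base^(slope * log_base(x) + intercept), with declared units."""

    slope: float
    intercept: float
    base: float = 10.0
    x_unit: str = ""
    y_unit: str = ""
    note: str = ""

    def predict(self, x) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError(f"power law requires positive input ({self.x_unit})")
        lb = np.log(x) / np.log(self.base)
        out = self.base ** (self.slope * lb + self.intercept)
        return float(out) if out.ndim == 0 else out

    def invert(self, y) -> float | np.ndarray:
        if self.slope == 0:
            raise ValueError("cannot invert a zero-slope power law")
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise ValueError(f"inversion requires positive input ({self.y_unit})")
        lb = np.log(y) / np.log(self.base)
        out = self.base ** ((lb - self.intercept) / self.slope)
        return float(out) if out.ndim == 0 else out

    @classmethod
    def from_fit(cls, fit: AllometricFit, **units) -> "PowerLaw":
        return cls(slope=fit.slope, intercept=fit.intercept, base=10.0,
                   x_unit=units.get("x_unit", fit.x_unit),
                   y_unit=units.get("y_unit", fit.y_unit),
                   note=f"fitted by {fit.method}, n={fit.n}")


def _as_law(fit) -> PowerLaw:
    if isinstance(fit, PowerLaw):
        return fit
    if isinstance(fit, AllometricFit):
        return PowerLaw.from_fit(fit)
    raise TypeError(f"expected PowerLaw or AllometricFit, got {type(fit)!r}")


@dataclass
class CoefficientRegistry:
    """Named power laws, densities and EQ scaling constants.

    Loaded from YAML; the packaged default carries the published printed
    calibrations so fossil estimates are reproducible without any
    supplementary files.
    """

    power_laws: dict[str, PowerLaw] = field(default_factory=dict)
    densities: dict[str, float] = field(default_factory=dict)
    eq_scalings: dict[str, dict] = field(default_factory=dict)
    rete_correction_fraction: float = 0.20

    @classmethod
    def from_yaml(cls, source: str | Path) -> "CoefficientRegistry":
        text = Path(source).read_text()
        return cls.from_mapping(yaml.safe_load(text))

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "CoefficientRegistry":
        laws = {
            name: PowerLaw(
                slope=float(entry["slope"]),
                intercept=float(entry["intercept"]),
                base=float(entry.get("base", 10)),
                x_unit=str(entry.get("x_unit", "")),
                y_unit=str(entry.get("y_unit", "")),
                note=str(entry.get("note", "")).strip(),
            )
            for name, entry in (cfg.get("power_laws") or {}).items()
        }
        dens = {k: float(v) for k, v in (cfg.get("densities") or {}).items()}
        for k, v in dens.items():
            if v <= 0:
                raise ValueError(f"density for {k!r} must be positive")
        return cls(
            power_laws=laws,
            densities=dens,
            eq_scalings=dict(cfg.get("eq_scalings") or {}),
            rete_correction_fraction=float(cfg.get("rete_correction_fraction", 0.20)),
        )

    def law(self, name: str) -> PowerLaw:
        try:
            return self.power_laws[name]
        except KeyError:
            raise RegistryError(
                f"no power law named {name!r} in registry "
                f"(have: {sorted(self.power_laws)})"
            ) from None

    def density(self, group: str) -> float:
        key = "cetacean" if str(group).lower().startswith("cet") else "terrestrial"
        try:
            return self.densities[key]
        except KeyError:
            raise RegistryError(f"no density for group {key!r}") from None


def default_registry() -> CoefficientRegistry:
    """The packaged registry with the published printed calibrations."""
    text = resources.files("whalebrain.data").joinpath("registry.yaml").read_text()
    return CoefficientRegistry.from_mapping(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# scalar conversions
# ---------------------------------------------------------------------------


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value}")
    return value


def brain_volume_from_mass(mass_g: float, density: float) -> float:
    """Brain volume (cm^3) = brain mass (g) / tissue density (g/cm^3)."""
    return _require_positive("brain mass", mass_g) / _require_positive("density", density)


def percent_not_occupied(endocranial_cm3: float, brain_volume_cm3: float) -> float:
    """Percent of the cranial cavity not occupied by the brain.

    May be negative if the reported brain volume exceeds the cavity; that
    signals inconsistent inputs and is flagged in the log rather than raised.
    """
    v = _require_positive("endocranial volume", endocranial_cm3)
    b = _require_positive("brain volume", brain_volume_cm3)
    pct = 100.0 * (v - b) / v
    if pct < 0:
        logger.warning(
            "brain volume %.1f exceeds endocranial volume %.1f "
            "(percent not occupied = %.1f)", b, v, pct,
        )
    return pct


def reconstructed_endocranial_volume(brain_g: float, adnexa_g: float,
                                     density: float) -> float:
    """Cavity volume as reconstructed from brain + adnexa mass alone.

    Because cerebrospinal fluid contributes no mass to either term, this
    reconstruction systematically underestimates the measured endocranial
    volume whenever CSF volume is positive — the central cavity-accounting
    point of the analysis.
    """
    brain = _require_positive("brain mass", brain_g)
    adnexa = float(adnexa_g)
    if adnexa < 0:
        raise ValueError(f"adnexa mass must be non-negative, got {adnexa}")
    return (brain + adnexa) / _require_positive("density", density)


def predict_brain_mass(endocranial_cm3, fit) -> float | np.ndarray:
    """Brain mass (g) from endocranial volume (cm^3) via a log10 power law."""
    return _as_law(fit).predict(endocranial_cm3)


def predict_body_mass_from_ocw(ocw_mm, fit) -> float | np.ndarray:
    """Body mass (kg) from occipital condyle width (mm); strictly increasing."""
    return _as_law(fit).predict(ocw_mm)


def back_calculate_ocw(body_mass_kg, fit) -> float | np.ndarray:
    """Exact inverse of the OCW power law: recover OCW (mm) from mass (kg)."""
    return _as_law(fit).invert(body_mass_kg)


def body_mass_from_length(length, taxon: str, registry: CoefficientRegistry) -> float:
    """Evaluate the taxon-specific length-to-mass law from the registry.

    There is deliberately no generic fallback: a missing entry is an error
    naming the taxon, because genus-level laws do not transfer across groups.
    """
    name = f"length_to_mass:{taxon}"
    try:
        law = registry.law(name)
    except RegistryError:
        raise RegistryError(
            f"no length-to-mass law registered for taxon {taxon!r} "
            f"(expected registry entry {name!r})"
        ) from None
    return law.predict(length)


def cavity_accounting(
    brain_mass_g: float,
    endocranial_volume_cm3: Optional[float],
    adnexa_mass_g: Optional[float],
    density: float,
) -> dict:
    """Derived cavity columns for one specimen.

    Returns brain volume, percent of the cavity not occupied by the brain
    (when a measured cavity volume exists), and the brain+adnexa
    reconstruction of the cavity (when adnexa mass exists) together with the
    percent fill it would imply.
    """
    out: dict[str, float] = {}
    bv = brain_volume_from_mass(brain_mass_g, density)
    out["brain_volume_cm3"] = bv
    if endocranial_volume_cm3 is not None and np.isfinite(endocranial_volume_cm3):
        out["percent_not_occupied"] = percent_not_occupied(endocranial_volume_cm3, bv)
        out["percent_filled_measured"] = 100.0 - out["percent_not_occupied"]
    if adnexa_mass_g is not None and np.isfinite(adnexa_mass_g):
        rec = reconstructed_endocranial_volume(brain_mass_g, adnexa_mass_g, density)
        out["reconstructed_endocranial_volume_cm3"] = rec
        out["percent_filled_reconstructed"] = 100.0 * bv / rec
        out["adnexa_volume_cm3"] = adnexa_mass_g / density
        out["percent_adnexa_reconstructed"] = 100.0 * out["adnexa_volume_cm3"] / rec
    return out
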