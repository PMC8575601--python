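"""Elemental attenuation data, material composition and Hounsfield scaling.

The package ships per-element tables of the photon mass attenuation
coefficient mu/rho (cm^2/g) over roughly 4-300 keV, split into
photoelectric, incoherent (Compton) and coherent (Rayleigh) components.
Absorption edges are represented by duplicated grid points at
E_edge*(1 -/+ 1e-6); queries exactly at an edge resolve to the above-edge
branch.  Interpolation between grid points is linear in log-log space, the
standard convention for attenuation compilations.

Materials are mass-fraction mixtures of elements; their coefficients follow
Bragg additivity (the mass-fraction-weighted sum of elemental values).
Aqueous contrast solutions are modeled as water plus the radiopaque element
alone: the light atoms of the parent compound (ammonium in ammonium
perrhenate, the organic backbone of iohexol) shift the coefficient by well
under a percent relative to water, and concentrations are stated as
molarity of the element, not of the compound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "ElementRecord", "Material", "ContrastSolution",
    "element", "mass_attenuation", "k_edge", "solution_material",
    "hounsfield_unit", "theoretical_ratio_curve", "linear_attenuation",
    "water", "air", "pmma", "elemental_material",
    "air_mass_energy_absorption",
]

EDGE_EPS = 1e-6

PROCESS_COLUMNS = {
    "total": "mu_over_rho_cm2_g",
    "photoelectric": "photoelectric_cm2_g",
    "incoherent": "incoherent_cm2_g",
    "coherent": "coherent_cm2_g",
}


@dataclass(frozen=True)
class ElementRecord:
    """Tabulated attenuation data for one element."""

    symbol: str
    Z: int
    atomic_mass: float  # g/mol
    energies: np.ndarray  # keV, strictly increasing up to duplicated edge pairs
    tables: dict[str, np.ndarray]  # process name -> mu/rho, cm^2/g
    edges: dict[str, float]  # shell label -> edge energy, keV
    density: float | None = None  # g/cm^3 for the elemental solid, if meaningful

    @property
    def table(self) -> np.ndarray:
        return self.tables["total"]


@dataclass(frozen=True)
class Material:
    """A homogeneous material: density plus elemental mass fractions."""

    name: str
    density: float  # g/cm^3
    composition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions of {self.name} sum to {total}")
        if any(f < 0 for f in self.composition.values()):
            raise ValueError("mass fractions must be non-negative")


@dataclass(frozen=True)
class ContrastSolution:
    """Aqueous contrast agent: a radiopaque element dissolved in water."""

    element: str   # "I" or "Re"
    molarity: float  # mM of the radiopaque element
    base: Material
    derived_material: Material


def _data_root():
    return resources.files("kedgesim") / "data"


@lru_cache(maxsize=1)
def _manifest() -> dict:
    with (_data_root() / "elements" / "manifest.json").open() as fh:
        return json.load(fh)


@lru_cache(maxsize=None)
def element(symbol: str) -> ElementRecord:
    """Load the packaged :class:`ElementRecord` for an element symbol."""
    meta = _manifest()["elements"].get(symbol)
    if meta is None:
        raise KeyError(f"no packaged attenuation table for element {symbol!r}")
    raw = np.genfromtxt(
        (_data_root() / "elements" / f"{symbol}.csv").open("rb"),
        delimiter=",", names=True)
    tables = {name: np.ascontiguousarray(raw[col])
              for name, col in PROCESS_COLUMNS.items()}
    return ElementRecord(
        symbol=symbol,
        Z=meta["Z"],
        atomic_mass=meta["atomic_mass"],
        energies=np.ascontiguousarray(raw["energy_keV"]),
        tables=tables,
        edges=dict(meta["edges"]),
        density=meta.get("density"),
    )


def available_elements() -> list[str]:
    return sorted(_manifest()["elements"])


# --- reference materials ---------------------------------------------------

WATER_COMPOSITION = {"H": 0.1119, "O": 0.8881}
AIR_COMPOSITION = {"N": 0.755, "O": 0.232, "Ar": 0.013}
# poly(methyl methacrylate), C5 H8 O2
PMMA_COMPOSITION = {"H": 0.080538, "C": 0.599848, "O": 0.319614}

AIR_DENSITY = 1.205e-3  # g/cm^3 at room temperature


def water() -> Material:
    return Material("water", 1.000, dict(WATER_COMPOSITION))


def air() -> Material:
    return Material("air", AIR_DENSITY, dict(AIR_COMPOSITION))


def pmma() -> Material:
    return Material("PMMA", 1.19, dict(PMMA_COMPOSITION))


def elemental_material(symbol: str, density: float | None = None) -> Material:
    rec = element(symbol)
    rho = density if density is not None else rec.density
    if rho is None:
        raise ValueError(f"no default solid density for {symbol}")
    return Material(symbol, rho, {symbol: 1.0})


# --- interpolation ---------------------------------------------------------

def _interp_element(rec: ElementRecord, energy, kind: str) -> np.ndarray:
    e = np.asarray(energy, dtype=float)
    grid = rec.energies
    if np.any(e < grid[0]) or np.any(e > grid[-1]):
        raise ValueError(
            f"energy outside tabulated range [{grid[0]:.3g}, {grid[-1]:.3g}] "
            f"keV for {rec.symbol}")
    # snap queries that fall inside an edge bracket onto the above-edge branch
    e = e.copy() if e.ndim else np.atleast_1d(e.copy())
    for edge in rec.edges.values():
        inside = np.abs(e - edge) <= edge * (EDGE_EPS * 1.001)
        if np.any(inside):
            e[inside] = edge * (1 + EDGE_EPS)
    # channels can be numerically zero (e.g. hydrogen photoelectric at high
    # energy); floor them so the log-log interpolation stays defined
    vals = np.maximum(rec.tables[kind], 1e-30)
    out = np.exp(np.interp(np.log(e), np.log(grid), np.log(vals)))
    out[out < 1e-25] = 0.0
    return out if np.asarray(energy).ndim else float(out[0])


def mass_attenuation(target, energy, kind: str = "total"):
    """Mass attenuation coefficient mu/rho in cm^2/g.

    ``target`` may be an :class:`ElementRecord`, an element symbol, or a
    :class:`Material` (evaluated by Bragg additivity over mass fractions).
    ``energy`` is in keV, scalar or array.  ``kind`` selects the interaction
    channel: ``total`` (default), ``photoelectric``, ``incoherent`` or
    ``coherent``.
    """
    if kind not in PROCESS_COLUMNS:
        raise ValueError(f"unknown interaction kind {kind!r}")
    if isinstance(target, str):
        target = element(target)
    if isinstance(target, ElementRecord):
        return _interp_element(target, energy, kind)
    if isinstance(target, Material):
        parts = [frac * _interp_element(element(sym), energy, kind)
                 for sym, frac in target.composition.items()]
        return sum(parts)
    raise TypeError(f"cannot compute attenuation for {type(target)!r}")


def linear_attenuation(material: Material, energy, kind: str = "total"):
    """Linear attenuation coefficient mu in 1/cm."""
    return material.density * mass_attenuation(material, energy, kind)


def k_edge(target) -> float:
    """K absorption-edge energy (keV) recorded in the packaged tables."""
    rec = element(target) if isinstance(target, str) else target
    if "K" not in rec.edges:
        raise LookupError(
            f"{rec.symbol} has no K edge inside the tabulated energy range")
    return rec.edges["K"]


# --- contrast solutions ----------------------------------------------------

def solution_material(symbol: str, molarity_mM: float) -> ContrastSolution:
    """Aqueous solution of a radiopaque element at a given molarity.

    The derived material is water plus ``molarity * atomic_mass`` grams of
    the element per litre, with ideal-mixing density (1.000 g/cm^3 plus the
    solute mass per cm^3).
    """
    if molarity_mM < 0:
        raise ValueError("molarity must be non-negative")
    base = water()
    if molarity_mM == 0:
        return ContrastSolution(symbol, 0.0, base, base)
    rec = element(symbol)
    grams_per_litre = molarity_mM * 1e-3 * rec.atomic_mass
    density = 1.000 + grams_per_litre / 1000.0
    total_mass = 1000.0 + grams_per_litre  # per litre
    f_solute = grams_per_litre / total_mass
    comp = {sym: frac * (1 - f_solute) for sym, frac in base.composition.items()}
    comp[symbol] = comp.get(symbol, 0.0) + f_solute
    name = f"{symbol} {molarity_mM:g} mM in water"
    return ContrastSolution(symbol, molarity_mM, base,
                            Material(name, density, comp))


def hounsfield_unit(mu_sample: float, mu_water: float, mu_air: float) -> float:
    """Hounsfield scale: linear rescaling of mu with water=0, air=-1000."""
    if not mu_water > mu_air:
        raise ValueError("mu_water must exceed mu_air")
    return 1000.0 * (mu_sample - mu_water) / (mu_water - mu_air)


def theoretical_ratio_curve(energy_grid) -> np.ndarray:
    """Pointwise ratio mu/rho(Re) / mu/rho(I) over an energy grid (keV).

    Returns an array of shape (n, 2) with columns (energy, ratio).  The
    curve lies below 1 between the iodine and rhenium K edges and crosses
    above 1 at the rhenium K edge.
    """
    e = np.atleast_1d(np.asarray(energy_grid, dtype=float))
    ratio = (mass_attenuation(element("Re"), e)
             / mass_attenuation(element("I"), e))
    return np.column_stack([e, ratio])


# --- air kerma fixture ------------------------------------------------------

@lru_cache(maxsize=1)
def air_mass_energy_absorption() -> tuple[np.ndarray, np.ndarray]:
    """Tabulated (energy keV, mu_en/rho cm^2/g) for dry air."""
    with (_data_root() / "air_mass_energy_absorption.csv").open() as fh:
        rows = [line.split(",") for line in fh
                if line.strip() and not line.startswith("#")
                and not line.startswith("energy_keV")]
    raw = np.asarray(rows, dtype=float)
    return (np.ascontiguousarray(raw[:, 0]), np.ascontiguousarray(raw[:, 1]))


def air_mu_en(energy) -> np.ndarray:
    """Log-log interpolated mu_en/rho of air (cm^2/g)."""
    grid, vals = air_mass_energy_absorption()
    e = np.asarray(energy, dtype=float)
    if np.any(e < grid[0]) or np.any(e > grid[-1]):
        raise ValueError("energy outside the air mu_en table range")
    return np.exp(np.interp(np.log(e), np.log(grid), np.log(vals)))
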