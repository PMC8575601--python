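"""Tungsten-anode kVp spectra, Beer-Lambert filtration and beam summaries.

The spectrum model is semi-empirical: a Kramers-type bremsstrahlung
continuum, N(E) proportional to (E0 - E)/E, hardened by an effective
tungsten self-filtration path that represents photon escape from the anode,
plus the four tungsten K fluorescence lines when the tube potential exceeds
the tungsten K edge (69.5 keV).  The two shape parameters (effective
self-filtration at the reference potential and the K-line yield
coefficient) were calibrated once so that the mean energies of a 120 kVp
beam under 1 mm Al + 0.15 mm Be inherent filtration and 0/0.6/1.2/1.6 mm of
added copper reproduce the reference spectral-modeling values; see
docs/methods.md.

All fluence values are relative (normalized to unit total fluence at
generation); filtration and kerma weighting are linear, so relative fluence
is sufficient for every statistic in this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import materials as mat

__all__ = [
    "Spectrum", "FilterStack", "ScanConfig",
    "generate_spectrum", "apply_filtration", "mean_energy",
    "air_kerma_weight", "standard_stack", "spectrum_for_config",
    "match_mean_energy", "write_spectrum_csv", "read_spectrum_csv",
]

W_K_EDGE_KEV = 69.525
# tungsten K fluorescence lines: (energy keV, relative intensity)
W_K_LINES = ((57.98, 0.576), (59.32, 1.0), (67.24, 0.326), (69.10, 0.089))

# calibrated shape parameters (see module docstring / docs/methods.md)
SELF_FILTRATION_MM_W = 0.01522  # effective W path at 120 kVp, 20 deg anode
SELF_FILTRATION_EXPONENT = 3.0  # scaling of the effective W path with kVp
CONTINUUM_EXPONENT = 3.2967     # continuum per bin ~ (E0 - E) / E**p
K_LINE_YIELD = 0.0834           # line fluence fraction coefficient
OVERVOLTAGE_EXPONENT = 1.63     # (E0/E_K - 1) exponent for line output

KVP_MIN, KVP_MAX = 40.0, 240.0
E_FLOOR_KEV = 5.0
DEFAULT_STEP_KEV = 0.5
DEFAULT_ANODE_ANGLE_DEG = 20.0


@dataclass(frozen=True)
class Spectrum:
    """Binned photon fluence versus energy for one beam."""

    kvp: float
    bin_centers: np.ndarray  # keV, uniform step, strictly increasing
    fluence: np.ndarray      # photons per bin, relative units
    label: str = ""

    def __post_init__(self) -> None:
        if np.any(self.fluence < 0):
            raise ValueError("fluence must be non-negative")
        if np.any((self.fluence > 0) & (self.bin_centers > self.kvp)):
            raise ValueError("populated bins above the tube potential")
        if not np.any(self.fluence > 0):
            raise ValueError("spectrum has no populated bins")

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())


@dataclass(frozen=True)
class FilterStack:
    """Ordered stack of (material, thickness in mm) attenuators."""

    layers: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for material, mm in self.layers:
            if mm < 0:
                raise ValueError(f"negative filter thickness: {mm} mm")
            if not isinstance(material, mat.Material):
                raise TypeError("filter layers must be (Material, mm) pairs")

    def __iter__(self):
        return iter(self.layers)

    def plus(self, material: mat.Material, mm: float) -> "FilterStack":
        return FilterStack(self.layers + ((material, mm),))


@dataclass(frozen=True)
class ScanConfig:
    """One exposure: tube potential, filtration and tube-output metadata."""

    scan_id: str
    kvp: float
    filter_stack: FilterStack
    mAs: float | None = None
    geometry: str = "radiography"
    excluded: bool = False
    incident_mean_energy_keV: float | None = None

    def __post_init__(self) -> None:
        if not (KVP_MIN <= self.kvp <= KVP_MAX):
            raise ValueError(f"kVp {self.kvp} outside [{KVP_MIN}, {KVP_MAX}]")


def generate_spectrum(kvp: float,
                      anode_angle_deg: float = DEFAULT_ANODE_ANGLE_DEG,
                      energy_step: float = DEFAULT_STEP_KEV,
                      self_filtration_mm_w: float | None = None,
                      k_line_yield: float = K_LINE_YIELD) -> Spectrum:
    """Unfiltered (bare-anode plus anode self-filtration) tungsten spectrum.

    Returns a spectrum normalized to unit total fluence on a uniform grid
    from 5 keV to the tube potential.
    """
    if not (KVP_MIN <= kvp <= KVP_MAX):
        raise ValueError(f"kVp must lie in [{KVP_MIN}, {KVP_MAX}], got {kvp}")
    if energy_step <= 0:
        raise ValueError("energy_step must be positive")
    edges = np.arange(E_FLOOR_KEV, kvp + 0.5 * energy_step, energy_step)
    if edges[-1] < kvp:
        edges = np.append(edges, kvp)
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)

    # Kramers-type continuum per unit energy, integrated over each bin;
    # the energy exponent is a calibrated softness parameter
    cont = (kvp - centers) / centers**CONTINUUM_EXPONENT * widths
    cont = np.clip(cont, 0.0, None)

    # anode self-filtration: effective tungsten escape path
    if self_filtration_mm_w is None:
        self_filtration_mm_w = SELF_FILTRATION_MM_W
    d_mm = (self_filtration_mm_w
            * (kvp / 120.0) ** SELF_FILTRATION_EXPONENT
            * math.tan(math.radians(DEFAULT_ANODE_ANGLE_DEG))
            / math.tan(math.radians(anode_angle_deg)))
    tungsten = mat.elemental_material("W")
    mu_w = mat.linear_attenuation(tungsten, centers)  # 1/cm
    fluence = cont * np.exp(-mu_w * d_mm / 10.0)

    # tungsten K characteristic lines
    if kvp > W_K_EDGE_KEV and k_line_yield > 0:
        overvoltage = kvp / W_K_EDGE_KEV - 1.0
        line_total = (k_line_yield * overvoltage ** OVERVOLTAGE_EXPONENT
                      * fluence.sum())
        weights = np.array([w for _, w in W_K_LINES])
        weights = weights / weights.sum()
        for (e_line, _), w in zip(W_K_LINES, weights):
            idx = int(np.clip(np.searchsorted(edges, e_line) - 1,
                              0, len(centers) - 1))
            fluence[idx] += line_total * w

    fluence = fluence / fluence.sum()
    return Spectrum(kvp=kvp, bin_centers=centers, fluence=fluence,
                    label=f"{kvp:g} kVp unfiltered")


def apply_filtration(spectrum: Spectrum, stack: FilterStack) -> Spectrum:
    """Beer-Lambert attenuation of each bin through the filter stack."""
    factor = np.ones_like(spectrum.fluence)
    names = []
    for material, mm in stack:
        mu = mat.linear_attenuation(material, spectrum.bin_centers)  # 1/cm
        factor = factor * np.exp(-mu * mm / 10.0)
        names.append(f"{mm:g}mm {material.name}")
    label = spectrum.label
    if names:
        base = label.replace(" unfiltered", "")
        label = base + " + " + " + ".join(names)
    return replace(spectrum, fluence=spectrum.fluence * factor, label=label)


def mean_energy(spectrum: Spectrum) -> float:
    """Fluence-weighted mean energy in keV."""
    total = spectrum.fluence.sum()
    if total <= 0:
        raise ValueError("spectrum has zero total fluence")
    return float((spectrum.bin_centers * spectrum.fluence).sum() / total)


def air_kerma_weight(spectrum: Spectrum) -> float:
    """Relative air kerma per unit source output.

    Sum of E * fluence * (mu_en/rho)_air over populated bins, arbitrary
    units; linear in fluence.  Used to normalize exposure-dependent
    statistics.
    """
    populated = spectrum.fluence > 0
    if not np.any(populated):
        return 0.0
    e = spectrum.bin_centers[populated]
    mu_en = mat.air_mu_en(e)
    return float((e * spectrum.fluence[populated] * mu_en).sum())


def standard_stack(inherent: list[tuple[str, float]],
                   cu_mm: float = 0.0) -> FilterStack:
    """Build a stack from (element symbol, mm) inherent layers plus added Cu."""
    layers = [(mat.elemental_material(sym), mm) for sym, mm in inherent]
    if cu_mm > 0:
        layers.append((mat.elemental_material("Cu"), cu_mm))
    return FilterStack(tuple(layers))


def spectrum_for_config(config: ScanConfig,
                        energy_step: float = DEFAULT_STEP_KEV) -> Spectrum:
    """Generate and filter the spectrum for one scan configuration."""
    raw = generate_spectrum(config.kvp, energy_step=energy_step)
    return apply_filtration(raw, config.filter_stack)


def match_mean_energy(config: ScanConfig,
                      target_mean_kev: float,
                      energy_step: float = DEFAULT_STEP_KEV,
                      max_extra_cu_mm: float = 20.0) -> Spectrum:
    """Condition a config's spectrum on a stated incident mean energy.

    Adds an equivalent copper thickness (found by bisection) on top of the
    configured filtration until the fluence-weighted mean energy equals
    ``target_mean_kev``.  Raises if the configured beam is already harder
    than the target.
    """
    base = spectrum_for_config(config, energy_step=energy_step)
    if mean_energy(base) >= target_mean_kev:
        raise ValueError(
            f"configured beam mean {mean_energy(base):.2f} keV already "
            f"exceeds target {target_mean_kev:.2f} keV")
    copper = mat.elemental_material("Cu")

    def mean_at(extra_mm: float) -> float:
        return mean_energy(apply_filtration(
            base, FilterStack(((copper, extra_mm),))))

    lo, hi = 0.0, 0.25
    while mean_at(hi) < target_mean_kev:
        hi *= 2.0
        if hi > max_extra_cu_mm:
            raise ValueError("cannot reach target mean energy with copper")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_at(mid) < target_mean_kev:
            lo = mid
        else:
            hi = mid
    extra = 0.5 * (lo + hi)
    out = apply_filtration(base, FilterStack(((copper, extra),)))
    return replace(out, label=base.label + f" (matched to {target_mean_kev:g} keV)")


# --- CSV round trip ---------------------------------------------------------

def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kVp: {spectrum.kvp}\n# label: {spectrum.label}\n")
        fh.write("energy_keV,fluence\n")
        for e, f in zip(spectrum.bin_centers, spectrum.fluence):
            fh.write(f"{e:.6g},{f:.8g}\n")


def read_spectrum_csv(path) -> Spectrum:
    kvp, label = None, ""
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("# kVp:"):
            kvp = float(line.split(":", 1)[1])
        elif line.startswith("# label:"):
            label = line.split(":", 1)[1].strip()
    data = np.array([[float(v) for v in line.split(",")]
                     for line in lines if line[:1].isdigit()])
    if kvp is None:
        raise ValueError("spectrum CSV missing kVp metadata")
    return Spectrum(kvp=kvp, bin_centers=data[:, 0], fluence=data[:, 1],
                    label=label)
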