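"""Regenerate the packaged elemental attenuation tables.

Photoelectric cross sections are computed from Cromer-Liberman anomalous
scattering factors (via gemmi), incoherent scattering from the free-electron
Klein-Nishina cross section, and coherent (Rayleigh) scattering from a
screened exponential form factor whose single screening constant was fitted
once against published mass attenuation compilations (see docs/methods.md).
Absorption-edge energies are located by bisection on the f'' discontinuity.

Run from the repository root:

    python tools/make_attenuation_tables.py

Requires gemmi (build-time only; the package itself reads the CSV output).
"""

from __future__ import annotations

import json
import math
import pathlib

import gemmi
import numpy as np

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "kedgesim" / "data" / "elements"

N_A = 6.02214076e23          # 1/mol
R_E = 2.8179403262e-13       # classical electron radius, cm
HC_KEV_A = 12.398419843320026  # keV * Angstrom
ELECTRON_MASS_KEV = 510.99895

# Rayleigh screening constant fitted against published mu/rho compilations
# (H, O, Al, Cu, I, W, Pb anchors over 20-200 keV; rms deviation ~1%).
RAYLEIGH_SCREENING = 0.2976

E_MIN, E_MAX, N_GRID = 4.0, 300.0, 170
EDGE_EPS = 1e-6  # relative offset of the duplicated points bracketing an edge

# symbol -> (Z, atomic mass g/mol, density g/cm3 of the elemental solid if
# used as a pure material, nominal edge energies keV inside [E_MIN, E_MAX])
ELEMENTS = {
    "H":  (1, 1.008, None, {}),
    "Be": (4, 9.0122, 1.848, {}),
    "C":  (6, 12.011, None, {}),
    "N":  (7, 14.007, None, {}),
    "O":  (8, 15.999, None, {}),
    "Al": (13, 26.982, 2.699, {}),
    "Ar": (18, 39.948, None, {}),
    "Cu": (29, 63.546, 8.96, {"K": 8.98}),
    "I":  (53, 126.904, 4.93, {"L3": 4.557, "L2": 4.852, "L1": 5.188, "K": 33.17}),
    "W":  (74, 183.84, 19.30, {"L3": 10.207, "L2": 11.544, "L1": 12.100, "K": 69.525}),
    "Re": (75, 186.207, 21.02, {"L3": 10.535, "L2": 11.959, "L1": 12.527, "K": 71.676}),
}


def f2(z: int, energy_kev: float) -> float:
    return gemmi.cromer_liberman(z, energy_kev * 1000.0)[1]


def photoelectric(z: int, a: float, e_kev: np.ndarray) -> np.ndarray:
    lam_cm = HC_KEV_A / np.asarray(e_kev) * 1e-8
    f = np.array([f2(z, e) for e in np.atleast_1d(e_kev)])
    return 2.0 * R_E * lam_cm * f * N_A / a


def klein_nishina_sigma(e_kev: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross section per electron, cm^2."""
    k = np.asarray(e_kev) / ELECTRON_MASS_KEV
    t = ((1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log1p(2 * k) / k)
         + np.log1p(2 * k) / (2 * k) - (1 + 3 * k) / (1 + 2 * k) ** 2)
    return 2 * math.pi * R_E**2 * t


def incoherent(z: int, a: float, e_kev: np.ndarray) -> np.ndarray:
    return klein_nishina_sigma(e_kev) * N_A * z / a


_MU = np.linspace(-1.0, 1.0, 2001)


def coherent(z: int, a: float, e_kev: np.ndarray) -> np.ndarray:
    out = []
    for e in np.atleast_1d(e_kev):
        lam = HC_KEV_A / e
        x = np.sqrt((1 - _MU) / 2) / lam  # sin(theta/2)/lambda, 1/A
        ff = z / (1 + (x / (RAYLEIGH_SCREENING * z ** (1 / 3))) ** 2) ** 2
        dsig = 0.5 * R_E**2 * (1 + _MU**2) * ff**2
        out.append(2 * math.pi * np.trapezoid(dsig, _MU) * N_A / a)
    return np.array(out)


def locate_edge(z: int, nominal_kev: float) -> float:
    """Bisect the f'' discontinuity near a nominal edge energy."""
    lo, hi = nominal_kev - 0.05, nominal_kev + 0.05
    jump = f2(z, hi) - f2(z, lo)
    if jump <= 0:
        raise RuntimeError(f"no edge near {nominal_kev} keV for Z={z}")
    f_lo = f2(z, lo)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f2(z, mid) - f_lo < 0.5 * jump:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_grid(edges: list[float]) -> np.ndarray:
    grid = np.geomspace(E_MIN, E_MAX, N_GRID)
    pts = [grid[(np.abs(np.log(grid[:, None] / np.array(edges or [1e9]))) >
                 5e-3).all(axis=1)]] if edges else [grid]
    for e in edges:
        pts.append(np.array([e * (1 - EDGE_EPS), e * (1 + EDGE_EPS)]))
    return np.unique(np.concatenate(pts))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for sym, (z, a, density, nominal_edges) in ELEMENTS.items():
        edges = {shell: locate_edge(z, e0) for shell, e0 in nominal_edges.items()}
        grid = build_grid(sorted(edges.values()))
        pe = photoelectric(z, a, grid)
        inc = incoherent(z, a, grid)
        coh = coherent(z, a, grid)
        tot = pe + inc + coh
        with open(OUT / f"{sym}.csv", "w") as fh:
            fh.write("energy_keV,photoelectric_cm2_g,incoherent_cm2_g,"
                     "coherent_cm2_g,mu_over_rho_cm2_g\n")
            for row in zip(grid, pe, inc, coh, tot):
                fh.write("{:.9g},{:.6g},{:.6g},{:.6g},{:.6g}\n".format(*row))
        manifest[sym] = {
            "Z": z,
            "atomic_mass": a,
            "density": density,
            "edges": {shell: round(e, 5) for shell, e in sorted(
                edges.items(), key=lambda kv: kv[1])},
        }
        print(f"{sym}: {len(grid)} points, edges {manifest[sym]['edges']}")
    with open(OUT / "manifest.json", "w") as fh:
        json.dump({"energy_range_keV": [E_MIN, E_MAX], "elements": manifest},
                  fh, indent=1)


if __name__ == "__main__":
    main()
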