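"""Monte Carlo photon transport in a water-equivalent cuboid phantom.

Photons are sampled from a binned spectrum, emitted from a point source
through a circular field on the phantom entry face (static divergent beam),
and tracked through homogeneous water.  Interactions are photoelectric
absorption (local deposit), Compton scattering (free-electron Klein-Nishina
sampling via Kahn's method, energy difference deposited locally) and
optional Rayleigh scattering (Thomson angular distribution, no energy
transfer).  Secondary electrons are not transported: their energy is scored
where they are created (kerma approximation; CSDA ranges below 250 keV in
water are well under a millimetre, far smaller than the 1 cm tally slabs).

Deposited energy is tallied in 1 cm depth slabs; photons crossing the
distal face count as transmitted (any lateral position -- the detector is
assumed large with unit efficiency), photons leaving any other face as
escaped.  Energy bookkeeping (deposited + escaped = emitted) closes to
floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from . import materials as mat
from . import spectra as sp

__all__ = [
    "PhantomModel", "DoseResult", "run_mc",
    "equalize_transmission", "relative_dose_table", "depth_dose_profile",
]

ENERGY_CUTOFF_KEV = 5.0  # below this a photon deposits locally and stops
ELECTRON_MASS_KEV = 510.99895


@dataclass(frozen=True)
class PhantomModel:
    """Water-equivalent cuboid with depth-slab dose tallies."""

    length_cm: float = 30.0   # x extent
    width_cm: float = 30.0    # y extent
    depth_cm: float = 20.0    # z extent, along the beam axis
    slab_cm: float = 1.0
    source_distance_cm: float = 100.0
    fov_diameter_cm: float = 20.0
    density: float = 1.0      # g/cm^3, water-equivalent

    def __post_init__(self) -> None:
        n = self.depth_cm / self.slab_cm
        if self.depth_cm > 0 and abs(n - round(n)) > 1e-9:
            raise ValueError("depth must be divisible by the slab thickness")
        if self.fov_diameter_cm > min(self.length_cm, self.width_cm):
            raise ValueError("field of view does not fit the entry face")

    @property
    def n_slabs(self) -> int:
        return int(round(self.depth_cm / self.slab_cm)) if self.depth_cm else 0

    @property
    def slab_mass_g(self) -> float:
        return self.length_cm * self.width_cm * self.slab_cm * self.density

    @property
    def mass_g(self) -> float:
        return self.length_cm * self.width_cm * self.depth_cm * self.density


@dataclass(frozen=True)
class DoseResult:
    """Tallies of one Monte Carlo run."""

    slab_energy: np.ndarray      # keV deposited per depth slab
    slab_sd: np.ndarray          # batch SD of slab_energy
    transmitted: int             # photons out through the distal face
    primary_transmitted: int     # transmitted without any interaction
    histories: int
    emitted_energy: float        # keV
    deposited_energy: float      # keV
    escaped_energy: float        # keV leaving through any face
    seed: int | None = None

    @property
    def transmission_probability(self) -> float:
        return self.transmitted / self.histories

    @property
    def deposited_sd(self) -> float:
        return float(np.sqrt((self.slab_sd ** 2).sum()))


@lru_cache(maxsize=4)
def _water_cross_sections(n: int = 600):
    """Dense log-grid linear attenuation table for water, split by process."""
    w = mat.water()
    grid = np.geomspace(4.0, 300.0, n)
    tables = {}
    for kind in ("photoelectric", "incoherent", "coherent", "total"):
        tables[kind] = mat.linear_attenuation(w, grid, kind)  # 1/cm
    return np.log(grid), {k: np.log(v) for k, v in tables.items()}


def _mu(e_kev: np.ndarray, kind: str) -> np.ndarray:
    loggrid, tables = _water_cross_sections()
    return np.exp(np.interp(np.log(e_kev), loggrid, tables[kind]))


def _sample_compton(k: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Kahn's rejection sampling of the Klein-Nishina distribution.

    ``k`` is photon energy in electron-mass units.  Returns (eta, cos_theta)
    where eta = E/E'.
    """
    n = len(k)
    eta = np.empty(n)
    ct = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        kk = k[todo]
        r1, r2, r3 = rng.random((3, todo.size))
        branch1 = r1 <= (1 + 2 * kk) / (9 + 2 * kk)
        eta_c = np.where(branch1, 1 + 2 * kk * r2,
                         (1 + 2 * kk) / (1 + 2 * kk * r2))
        ct_c = 1 - (eta_c - 1) / kk
        acc1 = r3 <= 4 * (1 / eta_c - 1 / eta_c ** 2)
        acc2 = r3 <= 0.5 * (ct_c ** 2 + 1 / eta_c)
        accepted = np.where(branch1, acc1, acc2)
        idx = todo[accepted]
        eta[idx] = eta_c[accepted]
        ct[idx] = ct_c[accepted]
        todo = todo[~accepted]
    return eta, ct


def _sample_thomson(n: int, rng) -> np.ndarray:
    """cos(theta) from the Thomson distribution p(mu) ~ 1 + mu^2."""
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        mu = rng.uniform(-1, 1, todo.size)
        keep = rng.random(todo.size) <= 0.5 * (1 + mu ** 2)
        out[todo[keep]] = mu[keep]
        todo = todo[~keep]
    return out


def _rotate(direction: np.ndarray, cos_t: np.ndarray, rng) -> np.ndarray:
    """Rotate unit vectors by polar angle arccos(cos_t), uniform azimuth."""
    sin_t = np.sqrt(np.clip(1 - cos_t ** 2, 0, None))
    phi = rng.uniform(0, 2 * np.pi, len(cos_t))
    u, v, w = direction.T
    denom = np.sqrt(np.clip(1 - w ** 2, 1e-24, None))
    cu = sin_t * (u * w * np.cos(phi) - v * np.sin(phi)) / denom + u * cos_t
    cv = sin_t * (v * w * np.cos(phi) + u * np.sin(phi)) / denom + v * cos_t
    cw = -sin_t * np.cos(phi) * denom + w * cos_t
    out = np.column_stack([cu, cv, cw])
    pole = np.abs(w) > 1 - 1e-10
    if np.any(pole):
        sgn = np.sign(w[pole])
        out[pole, 0] = sin_t[pole] * np.cos(phi[pole])
        out[pole, 1] = sin_t[pole] * np.sin(phi[pole])
        out[pole, 2] = sgn * cos_t[pole]
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def run_mc(spectrum: sp.Spectrum,
           phantom: PhantomModel,
           histories: int,
           seed,
           batches: int = 10,
           rayleigh: bool = True) -> DoseResult:
    """Transport ``histories`` photons through the phantom.

    Deterministic for fixed (spectrum, phantom, histories, seed, batches).
    """
    if histories < 1:
        raise ValueError("histories must be at least 1")
    populated = spectrum.fluence > 0
    if not populated.any():
        raise ValueError("spectrum has no populated bins")
    energies = spectrum.bin_centers[populated]
    probs = spectrum.fluence[populated] / spectrum.fluence[populated].sum()
    rng = np.random.default_rng(seed)

    if phantom.depth_cm == 0:
        return DoseResult(slab_energy=np.zeros(0), slab_sd=np.zeros(0),
                          transmitted=histories, primary_transmitted=histories,
                          histories=histories, emitted_energy=0.0,
                          deposited_energy=0.0, escaped_energy=0.0,
                          seed=_as_seed(seed))

    nsl = phantom.n_slabs
    hx, hy = phantom.length_cm / 2, phantom.width_cm / 2
    depth = phantom.depth_cm
    r_fov = phantom.fov_diameter_cm / 2
    sdd = phantom.source_distance_cm

    slab_batches = np.zeros((batches, nsl))
    transmitted = 0
    primary_transmitted = 0
    emitted = deposited = escaped = 0.0

    counts = np.full(batches, histories // batches)
    counts[:histories - counts.sum()] += 1
    cum = np.cumsum(probs)

    for b, n in enumerate(counts):
        n = int(n)
        if n == 0:
            continue
        e = energies[np.searchsorted(cum, rng.random(n),
                                     side="right").clip(0, len(probs) - 1)]
        emitted += e.sum()
        if r_fov > 0:
            r = r_fov * np.sqrt(rng.random(n))
            phi = rng.uniform(0, 2 * np.pi, n)
            x0, y0 = r * np.cos(phi), r * np.sin(phi)
        else:
            x0 = np.zeros(n)
            y0 = np.zeros(n)
        pos = np.column_stack([x0, y0, np.zeros(n)])
        d = np.column_stack([x0, y0, np.full(n, sdd)])
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        pristine = np.ones(n, dtype=bool)

        while len(e):
            step = rng.exponential(1.0 / _mu(e, "total"))
            with np.errstate(divide="ignore"):
                tx = np.where(d[:, 0] > 0, (hx - pos[:, 0]) / d[:, 0],
                              np.where(d[:, 0] < 0,
                                       (-hx - pos[:, 0]) / d[:, 0], np.inf))
                ty = np.where(d[:, 1] > 0, (hy - pos[:, 1]) / d[:, 1],
                              np.where(d[:, 1] < 0,
                                       (-hy - pos[:, 1]) / d[:, 1], np.inf))
                tz = np.where(d[:, 2] > 0, (depth - pos[:, 2]) / d[:, 2],
                              np.where(d[:, 2] < 0,
                                       (0.0 - pos[:, 2]) / d[:, 2], np.inf))
            t_exit = np.minimum(np.minimum(tx, ty), tz)
            out = step >= t_exit
            if np.any(out):
                thru = out & (tz <= np.minimum(tx, ty)) & (d[:, 2] > 0)
                transmitted += int(thru.sum())
                primary_transmitted += int((thru & pristine).sum())
                escaped += e[out].sum()
            stay = ~out
            e, pos, d, step = e[stay], pos[stay], d[stay], step[stay]
            pristine = pristine[stay]
            if not len(e):
                break
            pos = pos + step[:, None] * d
            slab = np.clip((pos[:, 2] // phantom.slab_cm).astype(int),
                           0, nsl - 1)

            u = rng.random(len(e)) * _mu(e, "total")
            mu_pe = _mu(e, "photoelectric")
            mu_inc = _mu(e, "incoherent")
            is_pe = u < mu_pe
            is_inc = ~is_pe & (u < mu_pe + mu_inc)
            is_coh = ~is_pe & ~is_inc

            if np.any(is_pe):
                np.add.at(slab_batches[b], slab[is_pe], e[is_pe])
                deposited += e[is_pe].sum()
            if np.any(is_inc):
                idx = np.where(is_inc)[0]
                eta, ct = _sample_compton(e[idx] / ELECTRON_MASS_KEV, rng)
                e_new = e[idx] / eta
                de = e[idx] - e_new
                np.add.at(slab_batches[b], slab[idx], de)
                deposited += de.sum()
                e[idx] = e_new
                d[idx] = _rotate(d[idx], ct, rng)
                pristine[idx] = False
            if rayleigh and np.any(is_coh):
                idx = np.where(is_coh)[0]
                ct = _sample_thomson(len(idx), rng)
                d[idx] = _rotate(d[idx], ct, rng)
                pristine[idx] = False
            # with Rayleigh disabled, coherent events continue undeflected

            keep = ~is_pe
            low = keep & (e < ENERGY_CUTOFF_KEV)
            if np.any(low):
                np.add.at(slab_batches[b], slab[low], e[low])
                deposited += e[low].sum()
                keep = keep & ~low
            e, pos, d, pristine = e[keep], pos[keep], d[keep], pristine[keep]

    slab_energy = slab_batches.sum(axis=0)
    slab_sd = slab_batches.std(axis=0, ddof=1) * np.sqrt(batches)
    return DoseResult(slab_energy=slab_energy, slab_sd=slab_sd,
                      transmitted=transmitted,
                      primary_transmitted=primary_transmitted,
                      histories=histories,
                      emitted_energy=float(emitted),
                      deposited_energy=float(deposited),
                      escaped_energy=float(escaped),
                      seed=_as_seed(seed))


def _as_seed(seed):
    try:
        return int(seed)
    except (TypeError, ValueError):
        return None


def equalize_transmission(results: dict[str, DoseResult],
                          reference: str,
                          target_transmitted: float = 8.5e5) -> dict[str, float]:
    """Relative tube currents that equalize the transmitted photon count.

    Each configuration's source strength is scaled so it delivers
    ``target_transmitted`` photons out of the phantom; the returned factors
    are normalized to 1.0 at the reference configuration.
    """
    if reference not in results:
        raise ValueError(f"reference {reference!r} not among results")
    p_ref = results[reference].transmission_probability
    out = {}
    for key, res in results.items():
        p = res.transmission_probability
        if p <= 0:
            raise ValueError(f"configuration {key!r} transmits no photons")
        out[key] = p_ref / p
    return out


def relative_dose_table(configs: list[sp.ScanConfig],
                        results: dict[str, DoseResult],
                        spectra: dict[str, sp.Spectrum],
                        reference: str,
                        target_transmitted: float = 8.5e5) -> pd.DataFrame:
    """Per-configuration dose summary at equalized transmitted photon count.

    Columns: kVp, added Cu (mm), beam mean energy (keV), relative current,
    relative average absorbed dose (reference row = 1) and its batch-based
    statistical SD.
    """
    if reference not in results:
        raise ValueError(f"reference {reference!r} missing from results")
    currents = equalize_transmission(results, reference, target_transmitted)
    ref = results[reference]
    ref_dose_per_trans = ref.deposited_energy / ref.transmitted
    rows = []
    for cfg in configs:
        res = results[cfg.scan_id]
        rel_dose = (res.deposited_energy / res.transmitted) / ref_dose_per_trans
        rel_sd = rel_dose * float(np.sqrt(
            (res.deposited_sd / res.deposited_energy) ** 2
            + 1.0 / max(res.transmitted, 1)
            + (ref.deposited_sd / ref.deposited_energy) ** 2
            + 1.0 / max(ref.transmitted, 1)))
        rows.append({
            "scan_id": cfg.scan_id,
            "kvp": cfg.kvp,
            "cu_mm": _cu_mm(cfg),
            "mean_energy_keV": sp.mean_energy(spectra[cfg.scan_id]),
            "relative_current": currents[cfg.scan_id],
            "relative_dose": rel_dose,
            "relative_dose_sd": rel_sd,
        })
    return pd.DataFrame(rows)


def _cu_mm(cfg: sp.ScanConfig) -> float:
    return sum(mm for material, mm in cfg.filter_stack
               if material.name == "Cu")


def depth_dose_profile(result: DoseResult,
                       phantom: PhantomModel) -> pd.DataFrame:
    """Average dose per depth slab versus slab mid-depth.

    Dose is slab energy divided by slab mass (relative units since source
    strength is relative); the SD column carries the batch statistical
    uncertainty.
    """
    if phantom.n_slabs != len(result.slab_energy):
        raise ValueError("result and phantom slab counts differ")
    mid = (np.arange(phantom.n_slabs) + 0.5) * phantom.slab_cm
    mass = phantom.slab_mass_g
    return pd.DataFrame({
        "depth_cm": mid,
        "dose_per_slab": result.slab_energy / mass,
        "dose_sd": result.slab_sd / mass,
    })
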