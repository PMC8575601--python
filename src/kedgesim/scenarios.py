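"""Scenario presets and ground-truth image generation.

Every exposure configuration used anywhere in the package originates here,
from YAML presets shipped in the package data directory: micro-CT scans
(``uct``), planar imaging on the small-animal platform (``sarrp``), clinical
digital radiography (``radiography``) and the Monte Carlo dose study
(``dose``).  The sample set always includes water and air controls next to
the rhenium and iodine solutions at 50, 100 and 200 mM.

Tube-output (mAs/mA) values are carried as metadata only; simulated
intensities are relative.  Two radiography exposures (121 kVp with little
filtration) are flagged ``excluded``: such lightly filtered high-potential
beams saturate real flat-panel detectors, so they carry no usable contrast
statistics and are dropped from analyses by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from . import imaging
from . import materials as mat
from . import spectra as sp

__all__ = [
    "ScenarioSet", "GroundTruthImageSpec", "RoiTruth",
    "make_scenarios", "default_samples", "make_ground_truth_images",
]

PRESETS = ("uct", "sarrp", "radiography", "dose")
CONCENTRATIONS_MM = (50.0, 100.0, 200.0)


@dataclass(frozen=True)
class ScenarioSet:
    """A named collection of scan configurations plus shared geometry."""

    name: str
    geometry: str
    scans: tuple[sp.ScanConfig, ...]
    samples: dict[str, mat.Material]
    inherent_filtration: tuple[tuple[str, float], ...]
    source_distance_cm: float | None = None
    pmma_path_cm: float = 0.0
    sample_path_cm: float = 1.0
    target_transmitted: float | None = None
    reference_scan_id: str | None = None

    def __post_init__(self) -> None:
        if "water" not in self.samples or "air" not in self.samples:
            raise ValueError("sample set must include water and air controls")
        ids = [c.scan_id for c in self.scans]
        if len(set(ids)) != len(ids):
            raise ValueError("scan ids must be unique")

    def scan(self, scan_id: str) -> sp.ScanConfig:
        for cfg in self.scans:
            if cfg.scan_id == scan_id:
                return cfg
        raise KeyError(scan_id)


def default_samples() -> dict[str, mat.Material]:
    """Contrast solutions at 50/100/200 mM plus water and air controls."""
    samples: dict[str, mat.Material] = {}
    for sym in ("Re", "I"):
        for c in CONCENTRATIONS_MM:
            samples[f"{sym}_{c:g}mM"] = mat.solution_material(sym, c).derived_material
    samples["water"] = mat.water()
    samples["air"] = mat.air()
    return samples


def make_scenarios(name: str) -> ScenarioSet:
    """Load one of the packaged scenario presets by name."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    path = resources.files("kedgesim") / "data" / "scenarios" / f"{name}.yaml"
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    inherent = tuple((layer["material"], float(layer["mm"]))
                     for layer in raw["inherent_filtration"])
    scans = []
    for row in raw["scans"]:
        stack = sp.standard_stack(list(inherent), float(row.get("cu_mm", 0.0)))
        mas = row.get("mAs", row.get("mA"))
        scans.append(sp.ScanConfig(
            scan_id=row["scan_id"],
            kvp=float(row["kvp"]),
            filter_stack=stack,
            mAs=None if mas is None else float(mas),
            geometry=raw["geometry"],
            excluded=bool(row.get("excluded", False)),
            incident_mean_energy_keV=row.get("incident_mean_energy_keV"),
        ))
    return ScenarioSet(
        name=raw["name"],
        geometry=raw["geometry"],
        scans=tuple(scans),
        samples=default_samples(),
        inherent_filtration=inherent,
        source_distance_cm=raw.get("source_distance_cm"),
        pmma_path_cm=float(raw.get("pmma_path_cm", 0.0)),
        sample_path_cm=float(raw.get("sample_path_cm", 1.0)),
        target_transmitted=(None if raw.get("target_transmitted") is None
                            else float(raw["target_transmitted"])),
        reference_scan_id=raw.get("reference_scan_id"),
    )


# --- ground-truth noisy images ----------------------------------------------

@dataclass(frozen=True)
class RoiTruth:
    """True mean/SD (detector units) of one rectangular ROI."""

    name: str
    mean: float
    sd: float
    top: int
    left: int
    height: int
    width: int

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.top, self.top + self.height),
                slice(self.left, self.left + self.width))


@dataclass(frozen=True)
class GroundTruthImageSpec:
    """Layout of disjoint ROIs with known first and second moments."""

    shape: tuple[int, int]
    rois: tuple[RoiTruth, ...]
    seed: int = 0
    background_mean: float = 0.0

    def __post_init__(self) -> None:
        taken = np.zeros(self.shape, dtype=bool)
        for roi in self.rois:
            if roi.sd < 0:
                raise ValueError("ROI SD must be non-negative")
            sl = roi.slices()
            if (roi.top < 0 or roi.left < 0
                    or roi.top + roi.height > self.shape[0]
                    or roi.left + roi.width > self.shape[1]):
                raise ValueError(f"ROI {roi.name} exceeds the image bounds")
            if taken[sl].any():
                raise ValueError(f"ROI {roi.name} overlaps another ROI")
            taken[sl] = True


def make_ground_truth_images(spec: GroundTruthImageSpec
                             ) -> tuple[imaging.ProjectionImage, dict]:
    """Reproducible noisy image whose per-ROI truth is known analytically.

    Pixels are scaled Poisson draws: for a requested (mean, sd) the gain is
    sd^2/mean and the Poisson rate mean^2/sd^2, so the generated ROI has
    exactly the requested first two moments.  Returns the image and a truth
    record mapping ROI name to its generating parameters.
    """
    rng = np.random.default_rng(spec.seed)
    img = np.full(spec.shape, float(spec.background_mean))
    truth = {}
    for roi in spec.rois:
        sl = roi.slices()
        npix = roi.height * roi.width
        if roi.sd == 0 or roi.mean == 0:
            img[sl] = roi.mean
        else:
            lam = roi.mean ** 2 / roi.sd ** 2
            gain = roi.sd ** 2 / roi.mean
            img[sl] = gain * rng.poisson(lam, size=(roi.height, roi.width))
        truth[roi.name] = {"mean": roi.mean, "sd": roi.sd, "n": npix}
    return (imaging.ProjectionImage(pixels=img, seed=spec.seed,
                                    mode="counting"),
            truth)
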