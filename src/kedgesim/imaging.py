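"""Ideal-detector projection modeling, ROI statistics, CNR and HU.

The detector is ideal (unit efficiency, no electronic noise, no scatter).
Two response modes are supported: photon ``counting`` (signal is the
transmitted fluence) and energy ``integrating`` (signal is the transmitted
energy fluence, the behavior of scintillator flat panels and micro-CT
detectors).  Pixel noise is pure Poisson.

Contrast statistics follow the usual region-of-interest protocol of
phantom-well imaging: the contrast-to-noise ratio of a sample is its
mean intensity minus the water mean, divided by the water standard
deviation.  Intensities entering CNR and the rhenium-to-iodine ratio are
log-attenuation values, -ln(signal/open-field), so that brighter means more
attenuating, as in reconstructed CT and processed radiographs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import materials as mat
from . import spectra as sp

__all__ = [
    "ProjectionImage", "RoiStats",
    "simulate_transmission", "simulate_roi_image", "roi_stats", "cnr",
    "heel_average", "effective_mu", "predicted_hu", "attenuation_ratio",
]


@dataclass(frozen=True)
class ProjectionImage:
    """Pixel intensities (arbitrary detector units) plus provenance."""

    pixels: np.ndarray
    seed: int | None = None
    mode: str = "integrating"
    config: sp.ScanConfig | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("image must be a non-empty 2-D array")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")


@dataclass(frozen=True)
class RoiStats:
    """Mean, standard deviation and pixel count of one region of interest."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("an ROI needs at least 2 pixels")


def simulate_transmission(spectrum: sp.Spectrum,
                          path: list[tuple[mat.Material, float]],
                          mode: str = "counting") -> float:
    """Expected detector signal behind a stack of material slabs.

    ``path`` lists (material, thickness in cm) along the beam.  In
    ``counting`` mode the signal is the transmitted fluence
    sum_E phi(E) exp(-sum_j mu_j(E) t_j); in ``integrating`` mode each
    photon is weighted by its energy.
    """
    if mode not in ("counting", "integrating"):
        raise ValueError(f"unknown detector mode {mode!r}")
    e = spectrum.bin_centers
    atten = np.zeros_like(e)
    for material, t_cm in path:
        if t_cm < 0:
            raise ValueError("path thicknesses must be non-negative")
        atten = atten + mat.linear_attenuation(material, e) * t_cm
    weight = spectrum.fluence * np.exp(-atten)
    if mode == "integrating":
        weight = weight * e
    return float(weight.sum())


def simulate_roi_image(expected_signal: float,
                       shape: tuple[int, int],
                       seed,
                       gain: float = 1.0,
                       mode: str = "counting") -> ProjectionImage:
    """Poisson noise realization of a uniform expected signal.

    ``expected_signal`` is the mean photon count per pixel before the
    detector gain; pixel values are ``gain * Poisson(expected_signal)``.
    Reproducible for a fixed seed.
    """
    if expected_signal < 0:
        raise ValueError("expected signal must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected_signal, size=shape).astype(float)
    return ProjectionImage(pixels=gain * counts, seed=None if seed is None
                           else int(np.asarray(seed).ravel()[0]), mode=mode)


def roi_stats(image: ProjectionImage | np.ndarray) -> RoiStats:
    """Mean/SD statistics of every pixel in an image or ROI crop."""
    px = image.pixels if isinstance(image, ProjectionImage) else np.asarray(image)
    return RoiStats(mean=float(px.mean()), sd=float(px.std(ddof=1)),
                    n=int(px.size))


def cnr(sample: RoiStats, water: RoiStats) -> float:
    """Contrast-to-noise ratio relative to water.

    (sample mean - water mean) / water SD; may be negative when the sample
    is less intense than water.
    """
    if water.sd <= 0:
        raise ValueError("water SD must be positive")
    return (sample.mean - water.mean) / water.sd


def heel_average(img_a: ProjectionImage, img_b: ProjectionImage) -> ProjectionImage:
    """Pixel-by-pixel mean of the original and mirrored-arrangement images.

    Averaging an acquisition with its left-right-swapped repeat cancels a
    linear anode heel-effect gain ramp and halves the pixel variance.
    """
    if img_a.pixels.shape != img_b.pixels.shape:
        raise ValueError("images must have identical dimensions")
    return ProjectionImage(pixels=0.5 * (img_a.pixels + img_b.pixels),
                           seed=img_a.seed, mode=img_a.mode,
                           config=img_a.config)


def effective_mu(spectrum: sp.Spectrum, material: mat.Material) -> float:
    """Fluence-weighted effective linear attenuation coefficient, 1/cm."""
    mu = mat.linear_attenuation(material, spectrum.bin_centers)
    return float((spectrum.fluence * mu).sum() / spectrum.fluence.sum())


def predicted_hu(spectrum: sp.Spectrum,
                 solution: mat.ContrastSolution | mat.Material) -> float:
    """Predicted Hounsfield units of a solution under a polychromatic beam.

    Uses fluence-weighted effective linear attenuation coefficients of the
    solution, water and air in the Hounsfield transformation.  Tomographic
    reconstruction is not simulated.
    """
    material = (solution.derived_material
                if isinstance(solution, mat.ContrastSolution) else solution)
    mu_s = effective_mu(spectrum, material)
    mu_w = effective_mu(spectrum, mat.water())
    mu_a = effective_mu(spectrum, mat.air())
    return mat.hounsfield_unit(mu_s, mu_w, mu_a)


def attenuation_ratio(mean_re: float, mean_i: float, kerma: float = 1.0) -> float:
    """Rhenium-to-iodine attenuation ratio normalized by incident air kerma.

    ``mean_re`` and ``mean_i`` are mean ROI intensities on the same
    normalization.  In this package the experimental-style curve feeds
    per-unit-mass water-subtracted log-attenuation contrast (see
    :func:`kedgesim.reports.run_ratio_curve`), which makes a ratio above 1
    equivalent to rhenium attenuating more per gram than iodine.
    """
    if mean_i <= 0:
        raise ValueError("iodine mean intensity must be positive")
    if kerma <= 0:
        raise ValueError("air kerma must be positive")
    return (mean_re / mean_i) / kerma
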