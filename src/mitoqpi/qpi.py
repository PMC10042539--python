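"""Phase-shift images to dry-mass maps: background correction, conversion, segmentation.

Quantitative phase imaging measures the optical phase shift through a cell,
which is proportional to its dry (non-water) mass.  With the phase shift
``phi`` expressed as a fraction of a wavelength, the dry mass in a region is

    m = sum_pixels phi * lambda * A / alpha

where ``lambda`` is the illumination wavelength (um), ``A`` the pixel area
(um^2) and ``alpha`` the specific refractive increment (~0.185 um^3/pg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import filters, morphology, segmentation

from .errors import DegenerateFitError, InvalidParameterError

__all__ = [
    "OpticalConstants",
    "PhaseImage",
    "MassMap",
    "LabelMap",
    "correct_background",
    "phase_to_mass",
    "segment_cells",
]


@dataclass(frozen=True)
class OpticalConstants:
    """Optical parameters of the QPI setup.

    wavelength: illumination wavelength, um (default 0.623).
    alpha: specific refractive increment, um^3/pg (default 0.185).
    pixel_area: area of one image pixel, um^2 (default 0.36).
    """

    wavelength: float = 0.623
    alpha: float = 0.185
    pixel_area: float = 0.36

    def __post_init__(self) -> None:
        if not (self.wavelength > 0 and self.alpha > 0 and self.pixel_area > 0):
            raise InvalidParameterError("optical constants must be strictly positive")

    @property
    def pixel_size(self) -> float:
        """Linear pixel size, um/pixel."""
        return float(np.sqrt(self.pixel_area))

    @property
    def mass_per_phase(self) -> float:
        """Dry mass (pg) of one pixel at phi = 1 wavelength: lambda*A/alpha."""
        return self.wavelength * self.pixel_area / self.alpha


@dataclass
class PhaseImage:
    """2-D phase-shift field in fractions of a wavelength, with its frame time (h)."""

    values: np.ndarray
    frame_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("PhaseImage requires a 2-D array")


@dataclass
class MassMap:
    """Per-pixel dry mass (pg), same grid as the source phase image."""

    values: np.ndarray
    frame_time: float = 0.0


@dataclass
class LabelMap:
    """Integer region labels (0 = background) plus a per-region summary table.

    ``regions`` has one row per label with columns ``label``, ``area`` (px),
    ``row``/``col`` (centroid, px) and ``mass_pg`` (summed dry mass).
    """

    values: np.ndarray
    regions: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_regions(self) -> int:
        return len(self.regions)


@lru_cache(maxsize=8)
def _poly_design(shape: tuple[int, int], degree: int) -> np.ndarray:
    """Vandermonde matrix of 2-D terms x^i y^j with i+j <= degree, coords in [-1, 1]."""
    h, w = shape
    y = np.linspace(-1.0, 1.0, h)
    x = np.linspace(-1.0, 1.0, w)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    cols = [
        (xx**i * yy**j).ravel()
        for i in range(degree + 1)
        for j in range(degree + 1 - i)
    ]
    return np.stack(cols, axis=1)


def fit_polynomial_background(
    values: np.ndarray,
    degree: int = 6,
    n_iter: int = 3,
    sigma_factor: float = 2.0,
    max_fit_pixels: int = 50_000,
) -> np.ndarray:
    """Robustly fit a low-order polynomial surface to the image background.

    Iterative reweighting: fit to all pixels, drop pixels more than
    ``sigma_factor`` residual standard deviations *above* the surface
    (cells add positive phase), refit.  Fitting uses at most
    ``max_fit_pixels`` pixels on a regular subgrid; the returned surface is
    evaluated on the full grid.
    """
    values = np.asarray(values, dtype=float)
    V = _poly_design(values.shape, degree)
    n_terms = V.shape[1]

    stride = max(1, int(np.sqrt(values.size / max_fit_pixels)))
    sub = np.zeros(values.shape, dtype=bool)
    sub[::stride, ::stride] = True
    sub = sub.ravel()
    y = values.ravel()

    mask = sub.copy()
    coef = None
    for _ in range(n_iter):
        if mask.sum() < n_terms:
            raise DegenerateFitError(
                f"only {int(mask.sum())} background pixels for {n_terms} "
                "polynomial terms"
            )
        coef, *_ = np.linalg.lstsq(V[mask], y[mask], rcond=None)
        resid = y - V @ coef
        sigma = resid[mask].std()
        if sigma == 0:
            break
        mask = sub & (resid < sigma_factor * sigma)
    assert coef is not None
    return (V @ coef).reshape(values.shape)


def correct_background(
    phase: PhaseImage,
    degree: int = 6,
    n_iter: int = 3,
    sigma_factor: float = 2.0,
) -> PhaseImage:
    """Subtract a robustly fitted degree-6 polynomial surface from the phase image.

    After correction the background (cell-free) phase has median ~0, so
    region mass integrals are not biased by slowly varying optical
    aberrations.
    """
    surface = fit_polynomial_background(
        phase.values, degree=degree, n_iter=n_iter, sigma_factor=sigma_factor
    )
    return PhaseImage(phase.values - surface, frame_time=phase.frame_time)


def phase_to_mass(phase: PhaseImage, constants: OpticalConstants) -> MassMap:
    """Convert phase shift to a per-pixel dry-mass map: m = phi * lambda * A / alpha."""
    return MassMap(
        phase.values * constants.mass_per_phase, frame_time=phase.frame_time
    )


def segment_cells(
    mass: MassMap,
    min_area: int = 200,
    closing_radius: int = 3,
    expand_px: int = 3,
) -> LabelMap:
    """Segment cells from a dry-mass map via Sobel edge detection.

    Pipeline: Sobel gradient magnitude -> Otsu threshold on the gradient ->
    morphological closing (disk of ``closing_radius``) -> hole filling ->
    removal of regions below ``min_area`` -> 8-connected labeling.  Labels
    are then expanded by ``expand_px`` (respecting region boundaries) so the
    faint skirt of each cell contributes to its mass integral.
    """
    values = np.asarray(mass.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise InvalidParameterError("mass map contains non-finite values")

    edges = filters.sobel(values)
    if edges.max() == edges.min():
        return LabelMap(np.zeros(values.shape, dtype=int), _region_table(None, values))

    thresh = filters.threshold_otsu(edges)
    binary = edges > thresh
    if closing_radius > 0:
        binary = morphology.closing(binary, morphology.disk(closing_radius))
    filled = ndi.binary_fill_holes(binary)
    if min_area > 0:
        lab, _ = ndi.label(filled, structure=np.ones((3, 3), dtype=int))
        sizes = np.bincount(lab.ravel())
        filled = sizes[lab] >= min_area
        filled &= lab > 0
    labels, _ = ndi.label(filled, structure=np.ones((3, 3), dtype=int))
    if expand_px > 0:
        labels = segmentation.expand_labels(labels, distance=expand_px)
    return LabelMap(labels, _region_table(labels, values))


def _region_table(labels: np.ndarray | None, mass_values: np.ndarray) -> pd.DataFrame:
    cols = ["label", "area", "row", "col", "mass_pg"]
    if labels is None or labels.max() == 0:
        return pd.DataFrame(columns=cols).astype(
            {"label": int, "area": int, "row": float, "col": float, "mass_pg": float}
        )
    idx = np.arange(1, labels.max() + 1)
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=idx)
    centroids = ndi.center_of_mass(np.ones_like(labels, dtype=float), labels, index=idx)
    masses = ndi.sum_labels(mass_values, labels, index=idx)
    rows = np.array([c[0] for c in centroids])
    cols_ = np.array([c[1] for c in centroids])
    return pd.DataFrame(
        {
            "label": idx,
            "area": areas.astype(int),
            "row": rows,
            "col": cols_,
            "mass_pg": masses,
        }
    )
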