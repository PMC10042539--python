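"""Fluorescence overlay, rolling-ball punctae separation and cell classification.

Donor (macrophage) mitochondria appear in recipient cancer cells as small
bright punctae on the donor-fluorescence channel, whereas macrophages
themselves carry a bright, spatially extended mitochondrial network.  A
rolling-ball filter — grayscale opening with a ball-shaped structuring
element just larger than the punctae — estimates the smooth low-frequency
component; subtracting it isolates the punctae.  Whole-cell intensity gates
(recipient marker at 1.5x background, donor marker at 2x background)
classify tracked cells as cancer cells, macrophages, or recipient cancer
cells (cancer cells carrying donor punctae).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import transform

from .errors import InputError, InvalidParameterError
from .qpi import LabelMap, OpticalConstants

__all__ = [
    "FluorImage",
    "GateParams",
    "CellClassRecord",
    "resize_to_match",
    "per_cell_intensity",
    "background_level",
    "extract_punctae",
    "punctae_mask",
    "punctae_flags",
    "classify_population",
]

CHANNELS = ("recipient_marker", "donor_mito")

CLASS_CANCER = "cancer"
CLASS_MACROPHAGE = "macrophage"
CLASS_RECIPIENT = "recipient_cancer"
CLASS_OTHER = "other"


@dataclass
class FluorImage:
    """2-D fluorescence intensity field (arbitrary units >= 0) for one channel."""

    values: np.ndarray
    channel: str = "donor_mito"
    frame_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("FluorImage requires a 2-D array")
        if self.channel not in CHANNELS:
            raise InputError(f"unknown channel {self.channel!r}; expected {CHANNELS}")


@dataclass(frozen=True)
class GateParams:
    """Intensity gates and rolling-ball geometry.

    rfp_factor: recipient-marker gate, multiple of channel background (1.5).
    donor_factor: donor-marker whole-cell gate, multiple of background (2.0).
    ball_diameter: rolling-ball diameter, um; must lie in ``ball_range``,
        chosen just above the punctae size.
    punctae_min_intensity: punctae detection threshold, in multiples of the
        residual (post-subtraction) robust sigma.
    min_punctae_pixels: minimum connected above-threshold pixels inside a
        cell for the cell to count as punctae-positive in that frame.
    """

    rfp_factor: float = 1.5
    donor_factor: float = 2.0
    ball_diameter: float = 6.0
    ball_range: tuple[float, float] = (4.8, 9.0)
    punctae_min_intensity: float = 5.0
    min_punctae_pixels: int = 2

    def __post_init__(self) -> None:
        if self.rfp_factor <= 1 or self.donor_factor <= 1:
            raise InvalidParameterError("gate factors must exceed 1")
        lo, hi = self.ball_range
        if not lo <= self.ball_diameter <= hi:
            raise InvalidParameterError(
                f"ball_diameter {self.ball_diameter} um outside allowed "
                f"range {self.ball_range}"
            )
        if self.punctae_min_intensity <= 0:
            raise InvalidParameterError("punctae_min_intensity must be positive")


@dataclass
class CellClassRecord:
    """Classification of one tracked cell."""

    track_id: int
    cell_class: str
    recipient_marker_intensity: float
    donor_mito_intensity: float
    punctae_present: bool


def resize_to_match(fluor: FluorImage, target_shape: tuple[int, int]) -> FluorImage:
    """Bilinearly resample a fluorescence image onto the QPI grid shape."""
    if len(target_shape) != 2 or min(target_shape) < 1:
        raise InputError(f"invalid target shape {target_shape}")
    if fluor.values.shape == tuple(target_shape):
        return FluorImage(fluor.values.copy(), fluor.channel, fluor.frame_time)
    resized = transform.resize(
        fluor.values,
        target_shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return FluorImage(resized, fluor.channel, fluor.frame_time)


def per_cell_intensity(fluor: FluorImage, labels: LabelMap) -> pd.Series:
    """Integrated fluorescence per region divided by region area (mean intensity)."""
    if fluor.values.shape != labels.values.shape:
        raise InputError(
            f"fluorescence shape {fluor.values.shape} != label shape "
            f"{labels.values.shape}"
        )
    if labels.n_regions == 0:
        return pd.Series(dtype=float, name=fluor.channel)
    idx = labels.regions["label"].to_numpy()
    means = ndi.mean(fluor.values, labels.values, index=idx)
    return pd.Series(means, index=idx, name=fluor.channel)


def background_level(fluor: FluorImage, labels: LabelMap) -> float:
    """Channel background: median intensity over non-cell (label 0) pixels."""
    bg = fluor.values[labels.values == 0]
    if bg.size == 0:
        raise InputError("label map has no background pixels")
    return float(np.median(bg))


def _ball_structure(radius_px: float) -> np.ndarray:
    """Non-flat structuring element: upper hemisphere of a ball, apex at 0."""
    r = int(np.ceil(radius_px))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = x**2 + y**2
    with np.errstate(invalid="ignore"):
        cap = np.sqrt(np.maximum(radius_px**2 - d2, 0.0)) - radius_px
    cap[d2 > radius_px**2] = -np.inf  # outside the ball footprint
    return cap


def extract_punctae(
    fluor: FluorImage,
    gates: GateParams = GateParams(),
    optical: OpticalConstants = OpticalConstants(),
) -> tuple[FluorImage, FluorImage]:
    """Rolling-ball separation of punctae from the smooth background/network.

    The background is the grayscale opening of the image with a ball-shaped
    (non-flat) structuring element of the configured diameter — the
    rolling-ball filter.  Features narrower than the ball (punctae) are
    removed from the background and appear in the returned punctae image
    (input minus background, clipped at zero).  The background never
    exceeds the input pointwise.
    """
    radius_px = gates.ball_diameter / 2.0 / optical.pixel_size
    if radius_px < 1.0:
        raise InvalidParameterError(
            f"rolling ball radius {radius_px:.2f} px is below 1 px"
        )
    structure = _ball_structure(radius_px)
    footprint = np.isfinite(structure)
    heights = np.where(footprint, structure, 0.0)
    background = ndi.grey_opening(
        fluor.values, structure=heights, footprint=footprint, mode="nearest"
    )
    background = np.minimum(background, fluor.values)
    punctae = np.clip(fluor.values - background, 0.0, None)
    return (
        FluorImage(punctae, fluor.channel, fluor.frame_time),
        FluorImage(background, fluor.channel, fluor.frame_time),
    )


def punctae_mask(punctae: FluorImage, gates: GateParams = GateParams()) -> np.ndarray:
    """Boolean detection mask: punctae image above k-sigma of its residual noise.

    Sigma is the scaled median absolute deviation of the punctae image; a
    tiny floor keeps noise-free synthetic images from thresholding at zero.
    """
    v = punctae.values
    mad = np.median(np.abs(v - np.median(v)))
    sigma = 1.4826 * mad
    floor = 1e-12 + 1e-6 * (v.max() if v.size else 0.0)
    return v > max(gates.punctae_min_intensity * sigma, floor)


def punctae_flags(
    punctae: FluorImage,
    labels: LabelMap,
    gates: GateParams = GateParams(),
) -> pd.Series:
    """Per-region punctae presence: >= ``min_punctae_pixels`` detected pixels."""
    if punctae.values.shape != labels.values.shape:
        raise InputError("punctae image and label map shapes differ")
    if labels.n_regions == 0:
        return pd.Series(dtype=bool)
    mask = punctae_mask(punctae, gates)
    idx = labels.regions["label"].to_numpy()
    counts = ndi.sum_labels(mask.astype(float), labels.values, index=idx)
    return pd.Series(counts >= gates.min_punctae_pixels, index=idx)


def classify_population(
    intensities: pd.DataFrame,
    punctae: pd.Series,
    backgrounds: dict[str, float],
    gates: GateParams = GateParams(),
) -> list[CellClassRecord]:
    """Apply the whole-cell intensity gates and punctae flags.

    Parameters
    ----------
    intensities : one row per cell (index = track or label id), columns
        ``recipient_marker`` and ``donor_mito`` holding area-normalized
        intensities.
    punctae : boolean punctae-presence per cell, same index.
    backgrounds : per-channel background levels (> 0).

    A cell is *cancer* if its recipient-marker intensity is at least
    ``rfp_factor`` times background, *macrophage* if its whole-cell donor
    intensity is at least ``donor_factor`` times background.  A cancer cell
    with donor punctae (and below the macrophage gate) is a
    *recipient_cancer*.  Cells passing both whole-cell gates are treated as
    cancer/macrophage fusions and excluded (class *other*).
    """
    for ch in CHANNELS:
        if ch not in intensities.columns:
            raise InputError(f"intensities table lacks channel column {ch!r}")
        if ch not in backgrounds or backgrounds[ch] <= 0:
            raise InputError(f"background level for {ch!r} missing or non-positive")

    records = []
    for cell_id, row in intensities.iterrows():
        is_cancer = row["recipient_marker"] >= gates.rfp_factor * backgrounds["recipient_marker"]
        is_mac = row["donor_mito"] >= gates.donor_factor * backgrounds["donor_mito"]
        has_punctae = bool(punctae.get(cell_id, False))
        if is_cancer and is_mac:
            cls = CLASS_OTHER  # likely fusion: excluded
        elif is_mac:
            cls = CLASS_MACROPHAGE
        elif is_cancer and has_punctae:
            cls = CLASS_RECIPIENT
        elif is_cancer:
            cls = CLASS_CANCER
        else:
            cls = CLASS_OTHER
        records.append(
            CellClassRecord(
                track_id=int(cell_id),
                cell_class=cls,
                recipient_marker_intensity=float(row["recipient_marker"]),
                donor_mito_intensity=float(row["donor_mito"]),
                punctae_present=has_punctae,
            )
        )
    return records


def persistent_punctae(flags: list[bool], min_consecutive: int = 2) -> bool:
    """Track-level punctae call: detections in >= ``min_consecutive`` consecutive frames."""
    run = 0
    for f in flags:
        run = run + 1 if f else 0
        if run >= min_consecutive:
            return True
    return False
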