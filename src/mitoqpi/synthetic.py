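"""Ground-truthed synthetic QPI movies with fluorescence channels.

Emulates the statistical structure of a mitochondrial-transfer co-culture
time-lapse: exponentially growing cells (default 40 h doubling time, one
frame every 15 min), a small recipient subpopulation (default 5%) growing
15% faster and carrying donor-mitochondria punctae, a smooth low-order
polynomial phase background, additive Gaussian phase noise, random-walk
motility, and division at mass doubling with exactly one daughter
inheriting the punctae.  Every rendered quantity is recorded in a truth
table so pipeline stages can be scored against known ground truth.

Cells are rendered as truncated-Gaussian phase profiles whose integrated
dry mass (via the phase-to-mass formula) equals the prescribed mass
exactly; cell shape does not affect mass integrals, so circular profiles
suffice for testing the mass pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, InvalidParameterError, PlacementError
from .qpi import OpticalConstants, PhaseImage, _poly_design

__all__ = ["SynthParams", "GroundTruth", "render_cell_phase", "generate_timelapse"]


@dataclass(frozen=True)
class SynthParams:
    """Synthetic-movie parameters (defaults reproduce the imaging regime).

    n_cells : founder cells at t=0.
    k0 : baseline specific growth rate, 1/h (default ln2/40 h).
    r : growth multiplier of recipient cells (default 1.15).
    recipient_fraction : probability a founder is a recipient (default 0.05).
    frame_interval : h between frames (default 0.25 = 15 min).
    duration : movie length, h (default 48).
    image_shape : canvas in pixels.
    optical : QPI optical constants (set the pixel size).
    background_poly_coeffs : degree <= 6 polynomial surface coefficients on
        the [-1,1]^2 normalized grid, ordered as in the background fitter;
        ``None`` uses a gentle default aberration.
    noise_sigma : phase-noise s.d. (fraction of a wavelength); ``None``
        means 2% of the typical peak cell phase.
    fluor_noise_frac : fluorescence noise s.d. as a fraction of channel
        background.
    punctae_per_recipient : donor-mitochondria discs per recipient cell.
    punctae_diameter : um (default 1.5; must stay below the 4.8 um lower
        edge of the rolling-ball window).
    punctae_amplitude_factor : punctae amplitude as a multiple of the donor
        channel background.
    motility_sigma : random-walk step s.d., um per frame.
    cell_radius : (lo, hi) um; founder radii drawn uniformly.
    birth_mass : (lo, hi) pg; founder baseline (birth) masses.
    rfp_cell_factor : recipient-marker cell brightness over background.
    """

    n_cells: int = 30
    k0: float = math.log(2.0) / 40.0
    r: float = 1.15
    recipient_fraction: float = 0.05
    frame_interval: float = 0.25
    duration: float = 48.0
    image_shape: tuple[int, int] = (512, 512)
    optical: OpticalConstants = field(default_factory=OpticalConstants)
    background_poly_coeffs: tuple[float, ...] | None = None
    noise_sigma: float | None = None
    fluor_noise_frac: float = 0.05
    punctae_per_recipient: int = 3
    punctae_diameter: float = 1.5
    punctae_amplitude_factor: float = 10.0
    donor_background: float = 10.0
    rfp_background: float = 10.0
    rfp_cell_factor: float = 3.0
    motility_sigma: float = 0.3
    cell_radius: tuple[float, float] = (10.0, 15.0)
    birth_mass: tuple[float, float] = (150.0, 300.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.recipient_fraction <= 1.0:
            raise InvalidParameterError("recipient_fraction must be in [0, 1]")
        if self.frame_interval <= 0 or self.duration <= 0:
            raise InvalidParameterError("frame_interval and duration must be positive")
        if self.punctae_diameter >= 4.8:
            raise InvalidParameterError(
                "punctae_diameter must stay below the rolling-ball window (4.8 um)"
            )
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1


@dataclass
class GroundTruth:
    """Truth tables for a generated movie.

    ``cells``: one row per cell (founders and daughters) with id, recipient
    flag, growth constant (1/h), birth time (h), birth mass (pg), radius
    (um), parent id (-1 for founders) and punctae inheritance flag.
    ``frames``: one row per cell per frame with true mass (pg) and centroid
    (px).
    """

    cells: pd.DataFrame
    frames: pd.DataFrame

    @property
    def n_founders(self) -> int:
        return int((self.cells["parent_id"] < 0).sum())


def render_cell_phase(
    mass: float,
    centroid: tuple[float, float],
    radius_um: float,
    optical: OpticalConstants,
    canvas: PhaseImage,
) -> PhaseImage:
    """Add one cell's truncated-Gaussian phase profile to the canvas, in place.

    The profile is exp(-d^2 / (2 sigma^2)) truncated at ``radius_um`` (with
    sigma = radius/2) and scaled so the phase integral converts to exactly
    the requested dry mass.
    """
    if mass < 0:
        raise InvalidParameterError("mass must be non-negative")
    if mass == 0:
        return canvas
    h, w = canvas.values.shape
    px = optical.pixel_size
    r_px = radius_um / px
    r0, c0 = centroid
    if not (r_px <= r0 <= h - 1 - r_px and r_px <= c0 <= w - 1 - r_px):
        raise PlacementError(
            f"cell footprint (radius {r_px:.1f} px) at {centroid} exceeds canvas"
        )
    lo_r, hi_r = int(np.floor(r0 - r_px)), int(np.ceil(r0 + r_px)) + 1
    lo_c, hi_c = int(np.floor(c0 - r_px)), int(np.ceil(c0 + r_px)) + 1
    yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    d2 = (yy - r0) ** 2 + (xx - c0) ** 2
    sigma = r_px / 2.0
    profile = np.exp(-d2 / (2.0 * sigma**2))
    profile[d2 > r_px**2] = 0.0
    total = profile.sum()
    if total == 0:
        raise PlacementError("cell footprint contains no pixels")
    # scale so that sum(phi) * lambda * A / alpha == mass exactly
    profile *= mass / (total * optical.mass_per_phase)
    canvas.values[lo_r:hi_r, lo_c:hi_c] += profile
    return canvas


def _default_background(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """A gentle degree-6 aberration surface, ~0.05 wavelength peak-to-peak."""
    V = _poly_design(shape, 6)
    coeffs = rng.normal(0.0, 0.008, size=V.shape[1])
    coeffs[0] = 0.02  # constant offset
    return (V @ coeffs).reshape(shape)


def _place_founders(
    n: int,
    radii_px: np.ndarray,
    shape: tuple[int, int],
    rng: np.random.Generator,
    max_tries: int = 20_000,
) -> np.ndarray:
    """Rejection-sample founder centroids with room for two daughters each."""
    h, w = shape
    positions: list[tuple[float, float]] = []
    placed_r: list[float] = []
    tries = 0
    for i in range(n):
        margin = radii_px[i] + 2
        while True:
            tries += 1
            if tries > max_tries:
                raise GenerationError(
                    f"could not place {n} cells of this size on a {shape} canvas"
                )
            r0 = rng.uniform(margin, h - 1 - margin)
            c0 = rng.uniform(margin, w - 1 - margin)
            # reserve room for daughter placement and drift
            ok = all(
                np.hypot(r0 - pr, c0 - pc) >= radii_px[i] + rr + 18
                for (pr, pc), rr in zip(positions, placed_r)
            )
            if ok:
                positions.append((r0, c0))
                placed_r.append(radii_px[i])
                break
    return np.asarray(positions)


class _Cell:
    __slots__ = (
        "cid", "recipient", "k", "birth_time", "birth_mass", "radius_um",
        "pos", "parent_id", "inherited", "punctae_offsets",
    )

    def __init__(self, cid, recipient, k, birth_time, birth_mass, radius_um,
                 pos, parent_id, inherited, punctae_offsets):
        self.cid = cid
        self.recipient = recipient
        self.k = k
        self.birth_time = birth_time
        self.birth_mass = birth_mass
        self.radius_um = radius_um
        self.pos = pos
        self.parent_id = parent_id
        self.inherited = inherited
        self.punctae_offsets = punctae_offsets

    def mass_at(self, t: float) -> float:
        return self.birth_mass * math.exp(self.k * (t - self.birth_time))


def generate_timelapse(
    params: SynthParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Render a full synthetic movie plus its ground truth.

    Returns ``(phase_stack, recipient_marker_stack, donor_mito_stack,
    truth)`` where the stacks are float arrays of shape (T, H, W).  The
    phase stack is in fractions of a wavelength; fluorescence stacks are in
    arbitrary intensity units.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    opt = params.optical
    px = opt.pixel_size

    n = params.n_cells
    radii_um = rng.uniform(*params.cell_radius, size=n)
    radii_px = radii_um / px
    positions = _place_founders(n, radii_px, (h, w), rng)
    recipients = rng.random(n) < params.recipient_fraction
    birth_masses = rng.uniform(*params.birth_mass, size=n)
    # stagger division times: founders start partway through their cycle
    phases = rng.uniform(0.0, 0.7, size=n)

    cells: list[_Cell] = []
    for i in range(n):
        k = params.k0 * (params.r if recipients[i] else 1.0)
        # founder "birth" predates the movie so mass(0) = birth_mass * 2**phase
        birth_time = -phases[i] * math.log(2.0) / k
        offs = _punctae_offsets(params, radii_px[i], rng) if recipients[i] else None
        cells.append(
            _Cell(i, bool(recipients[i]), k, birth_time, birth_masses[i],
                  radii_um[i], positions[i].copy(), -1, bool(recipients[i]), offs)
        )
    next_id = n

    bg = (
        _default_background((h, w), rng)
        if params.background_poly_coeffs is None
        else (_poly_design((h, w), 6) @ np.asarray(params.background_poly_coeffs)).reshape(h, w)
    )
    if params.noise_sigma is None:
        # typical peak phase of a mid-range cell, for the 2% noise default
        m_typ = float(np.mean(params.birth_mass)) * 1.4
        r_typ = float(np.mean(params.cell_radius)) / px
        peak = m_typ / (2 * math.pi * (r_typ / 2.0) ** 2 * opt.mass_per_phase)
        noise_sigma = 0.02 * peak
    else:
        noise_sigma = params.noise_sigma

    times = np.arange(params.n_frames) * params.frame_interval
    phase_stack = np.zeros((params.n_frames, h, w), dtype=float)
    rfp_stack = np.zeros_like(phase_stack)
    donor_stack = np.zeros_like(phase_stack)

    cell_rows: dict[int, dict] = {
        c.cid: _cell_row(c) for c in cells
    }
    frame_rows: list[dict] = []
    step_px = params.motility_sigma / px

    for fi, t in enumerate(times):
        if fi > 0:
            for c in cells:
                c.pos += rng.normal(0.0, step_px, size=2)
                _reflect(c.pos, c.radius_um / px + 2, (h, w))
            # divisions at mass doubling
            newborns: list[_Cell] = []
            survivors: list[_Cell] = []
            for c in cells:
                if c.mass_at(t) >= 2.0 * c.birth_mass:
                    d1, d2, next_id = _divide(c, t, next_id, params, (h, w), rng)
                    newborns.extend((d1, d2))
                    cell_rows[c.cid]["division_time"] = t
                    cell_rows[c.cid]["daughter_ids"] = f"{d1.cid};{d2.cid}"
                else:
                    survivors.append(c)
            cells = survivors + newborns
            for c in newborns:
                cell_rows[c.cid] = _cell_row(c)

        phase = PhaseImage(np.zeros((h, w)), frame_time=t)
        rfp = np.full((h, w), params.rfp_background)
        donor = np.full((h, w), params.donor_background)
        for c in cells:
            m = c.mass_at(t)
            render_cell_phase(m, tuple(c.pos), c.radius_um, opt, phase)
            _render_disc(rfp, c.pos, c.radius_um / px,
                         (params.rfp_cell_factor - 1.0) * params.rfp_background)
            if c.recipient and c.punctae_offsets is not None:
                amp = params.punctae_amplitude_factor * params.donor_background
                for off in c.punctae_offsets:
                    _render_disc(donor, c.pos + off,
                                 params.punctae_diameter / 2.0 / px, amp)
            frame_rows.append(
                {
                    "cell_id": c.cid, "frame": fi, "time_h": t, "true_mass_pg": m,
                    "row": c.pos[0], "col": c.pos[1],
                }
            )
        phase_stack[fi] = phase.values + bg + rng.normal(0.0, noise_sigma, (h, w))
        rfp_stack[fi] = rfp + rng.normal(
            0.0, params.fluor_noise_frac * params.rfp_background, (h, w)
        )
        donor_stack[fi] = donor + rng.normal(
            0.0, params.fluor_noise_frac * params.donor_background, (h, w)
        )

    truth = GroundTruth(
        cells=pd.DataFrame(cell_rows.values()),
        frames=pd.DataFrame(frame_rows),
    )
    np.clip(rfp_stack, 0.0, None, out=rfp_stack)
    np.clip(donor_stack, 0.0, None, out=donor_stack)
    return phase_stack, rfp_stack, donor_stack, truth


def _cell_row(c: _Cell) -> dict:
    return {
        "cell_id": c.cid,
        "recipient": c.recipient,
        "growth_constant": c.k,
        "birth_time_h": c.birth_time,
        "birth_mass_pg": c.birth_mass,
        "radius_um": c.radius_um,
        "parent_id": c.parent_id,
        "punctae_inherited": c.inherited,
        "division_time": np.nan,
        "daughter_ids": "",
    }


def _punctae_offsets(
    params: SynthParams, radius_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Fixed punctae positions relative to the cell centroid (px)."""
    k = params.punctae_per_recipient
    ang = rng.uniform(0, 2 * math.pi, size=k)
    rad = rng.uniform(0.1, 0.5, size=k) * radius_px
    return np.stack([rad * np.sin(ang), rad * np.cos(ang)], axis=1)


def _reflect(pos: np.ndarray, margin: float, shape: tuple[int, int]) -> None:
    for ax, extent in enumerate(shape):
        lo, hi = margin, extent - 1 - margin
        if pos[ax] < lo:
            pos[ax] = lo + (lo - pos[ax])
        if pos[ax] > hi:
            pos[ax] = hi - (pos[ax] - hi)
        pos[ax] = min(max(pos[ax], lo), hi)


def _divide(
    c: _Cell,
    t: float,
    next_id: int,
    params: SynthParams,
    shape: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[_Cell, _Cell, int]:
    """Split a cell into two half-mass daughters placed on opposite sides."""
    px = params.optical.pixel_size
    m_div = c.mass_at(t)
    half = m_div / 2.0
    r_d_um = c.radius_um / math.sqrt(2.0)  # area halves
    r_d_px = r_d_um / px
    ang = rng.uniform(0, 2 * math.pi)
    sep = r_d_px + 8.0  # center offset per daughter; gap ~16 px between discs
    off = np.array([math.sin(ang), math.cos(ang)]) * sep
    p1, p2 = c.pos + off, c.pos - off
    _reflect(p1, r_d_px + 2, shape)
    _reflect(p2, r_d_px + 2, shape)
    inherit_first = bool(rng.random() < 0.5)

    daughters = []
    for j, pos in enumerate((p1, p2)):
        inherits = c.recipient and (inherit_first == (j == 0))
        offs = (
            _punctae_offsets(params, r_d_px, rng) if inherits else None
        )
        daughters.append(
            _Cell(
                next_id + j,
                inherits,  # only the inheriting daughter keeps the boost
                params.k0 * (params.r if inherits else 1.0),
                t,
                half,
                r_d_um,
                pos,
                c.cid,
                inherits,
                offs,
            )
        )
    return daughters[0], daughters[1], next_id + 2


def _render_disc(img: np.ndarray, center: np.ndarray, radius_px: float, amplitude: float) -> None:
    h, w = img.shape
    r0, c0 = center
    lo_r = max(int(np.floor(r0 - radius_px)), 0)
    hi_r = min(int(np.ceil(r0 + radius_px)) + 1, h)
    lo_c = max(int(np.floor(c0 - radius_px)), 0)
    hi_c = min(int(np.ceil(c0 + radius_px)) + 1, w)
    if lo_r >= hi_r or lo_c >= hi_c:
        return
    yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    mask = (yy - r0) ** 2 + (xx - c0) ** 2 <= radius_px**2
    img[lo_r:hi_r, lo_c:hi_c][mask] += amplitude
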