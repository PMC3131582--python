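"""Ground-truthed synthetic frame sequences of particles in the sorting channel.

Emulates what the high-speed bright-field camera sees: dark polystyrene
particles on a bright background, confined to the hydrodynamically focused
sample stream, advancing downstream by ``speed / frame_rate`` per frame.
Arrivals follow a Poisson process so coincidences (two particles in the
sensing volume at once) arise naturally at the rate the occupancy model
predicts.

The camera frame is taller than the 100 μm sensing segment: a vertical margin
(12.5 μm on each side with the default 500×220 frame at 0.25 μm/px) keeps
particles whose centers lie inside the sensing segment away from the frame
border, so the recognizer's edge policy does not clip in-segment particles.

Every random draw comes from one `numpy.random.Generator` seeded explicitly;
a fixed seed reproduces the frame stack bit for bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .chip_model import ChipGeometry, FlowConfig, InvalidConfigError

__all__ = [
    "OpticsModel",
    "ParticlePopulation",
    "TruthRecord",
    "FrameSequence",
    "make_background",
    "render_particle",
    "simulate_stream",
    "iter_stream_frames",
    "per_frame_counts",
]

CHARGE_CLASSES = ("negative", "positive", "neutral")

#: default electrophoretic mobility magnitude, μm·s⁻¹ per V·μm⁻¹ (= μm²/(V·s)).
#: ≈1.1e-4 cm²/(V·s), typical for carboxylated polystyrene; calibrated so the
#: default chip reaches ~90% two-way sorting efficiency at 45 V and 200 mm/s.
DEFAULT_MOBILITY = 1.11e4


@dataclass(frozen=True)
class OpticsModel:
    """Imaging model of the camera + objective.

    The source system gives no numeric optics values, so these are package
    defaults: 0.25 μm/px is plausible for a 40× objective on a small-sensor
    high-speed camera, the PSF is an isotropic Gaussian of σ 0.4 μm, frames
    are 8-bit with dark particles (negative contrast) on a bright background.
    """

    pixel_pitch: float = 0.25  # μm per pixel
    psf_sigma: float = 0.4  # μm
    background_level: float = 180.0  # ADU
    particle_contrast: float = -60.0  # ADU, signed (dark particles)
    noise_sigma: float = 5.0  # ADU
    bit_depth: int = 8
    frame_shape: tuple[int, int] = (500, 220)  # (rows, cols)

    def __post_init__(self) -> None:
        if not self.pixel_pitch > 0:
            raise InvalidConfigError("pixel_pitch must be > 0")
        if self.noise_sigma < 0:
            raise InvalidConfigError("noise_sigma must be >= 0")
        if self.bit_depth not in (8, 16):
            raise InvalidConfigError("bit_depth must be 8 or 16")

    @property
    def max_adu(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)

    def snr(self) -> float:
        """Particle contrast over per-frame noise (∞ for noiseless optics)."""
        if self.noise_sigma == 0:
            return math.inf
        return abs(self.particle_contrast) / self.noise_sigma


@dataclass(frozen=True)
class ParticlePopulation:
    """One particle species: size distribution, charge, optical contrast."""

    label: str
    diameter_mean: float  # μm
    diameter_cv: float = 0.02  # monodisperse polystyrene
    charge_class: str = "neutral"
    electrophoretic_mobility: float = DEFAULT_MOBILITY  # magnitude, μm²/(V·s)
    contrast_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.diameter_mean > 0:
            raise InvalidConfigError("diameter_mean must be > 0")
        if not 0 <= self.diameter_cv < 0.5:
            raise InvalidConfigError("diameter_cv must be in [0, 0.5)")
        if self.charge_class not in CHARGE_CLASSES:
            raise InvalidConfigError(
                f"charge_class must be one of {CHARGE_CLASSES}, got {self.charge_class!r}"
            )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one particle in one frame (pixel coordinates)."""

    frame: int
    particle_id: int
    label: str
    x_px: float
    y_px: float
    diameter_um: float
    charge: str
    partially_visible: bool = False


@dataclass
class FrameSequence:
    """A rendered (or truth-only) stack of frames plus its ground truth."""

    frames: list[np.ndarray] | None
    background: np.ndarray
    truth: list[TruthRecord]
    n_frames: int
    optics: OpticsModel
    geometry: ChipGeometry
    flow: FlowConfig

    def truth_by_frame(self) -> dict[int, list[TruthRecord]]:
        out: dict[int, list[TruthRecord]] = {}
        for rec in self.truth:
            out.setdefault(rec.frame, []).append(rec)
        return out


def make_background(optics: OpticsModel, seed: int) -> np.ndarray:
    """One acquired background image: flat field plus Gaussian read noise."""
    rng = np.random.default_rng(seed)
    img = np.full(optics.frame_shape, optics.background_level, dtype=np.float64)
    if optics.noise_sigma > 0:
        img += rng.normal(0.0, optics.noise_sigma, size=optics.frame_shape)
    return _quantize(img, optics)


def _quantize(img: np.ndarray, optics: OpticsModel) -> np.ndarray:
    return np.clip(np.rint(img), 0, optics.max_adu).astype(optics.dtype)


def render_particle(
    center: tuple[float, float],
    diameter: float,
    optics: OpticsModel,
    *,
    contrast: float | None = None,
    supersample: int = 8,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Render one particle as a signed-contrast patch.

    ``center`` is ``(x, y)`` in μm in frame coordinates (x along columns,
    y along rows; μm = pixel index × pixel_pitch at pixel centers).  The
    projected disc is anti-aliased by ``supersample``× supersampling, blurred
    by the Gaussian PSF, and scaled by the (signed) contrast.

    Returns ``(patch, (row0, col0))``: add ``patch`` into the frame with its
    top-left pixel at ``(row0, col0)`` (indices may be negative or exceed the
    frame; callers clip the overlap).
    """
    if not diameter > 0:
        raise InvalidConfigError("diameter must be > 0")
    if diameter < optics.pixel_pitch:
        warnings.warn(
            f"particle diameter {diameter} μm is below one pixel "
            f"({optics.pixel_pitch} μm); rendering anyway",
            stacklevel=2,
        )
    if contrast is None:
        contrast = optics.particle_contrast

    pitch = optics.pixel_pitch
    cx_px = center[0] / pitch
    cy_px = center[1] / pitch
    r_px = 0.5 * diameter / pitch
    sigma_px = optics.psf_sigma / pitch

    pad = int(math.ceil(r_px + 4.0 * sigma_px + 2.0))
    row0 = int(math.floor(cy_px)) - pad
    col0 = int(math.floor(cx_px)) - pad
    n = 2 * pad + 1

    # supersampled coverage of the disc, then block-mean back to pixel grid
    ss = supersample
    sub = (np.arange(n * ss) + 0.5) / ss - 0.5  # px coords of subsamples
    yy = (row0 + sub)[:, None] - cy_px
    xx = (col0 + sub)[None, :] - cx_px
    mask = (yy * yy + xx * xx) <= r_px * r_px
    coverage = mask.reshape(n, ss, n, ss).mean(axis=(1, 3))

    if sigma_px > 0:
        coverage = ndimage.gaussian_filter(coverage, sigma_px, mode="constant")
    return contrast * coverage, (row0, col0)


def _add_patch(frame: np.ndarray, patch: np.ndarray, top_left: tuple[int, int]) -> None:
    """Accumulate a patch into a frame, clipping the overlap in place."""
    r0, c0 = top_left
    pr, pc = patch.shape
    fr, fc = frame.shape
    rs, re = max(r0, 0), min(r0 + pr, fr)
    cs, ce = max(c0, 0), min(c0 + pc, fc)
    if rs >= re or cs >= ce:
        return
    frame[rs:re, cs:ce] += patch[rs - r0 : re - r0, cs - c0 : ce - c0]


def _arrival_rate_per_frame(
    density_per_ml: float, geometry: ChipGeometry, flow: FlowConfig
) -> float:
    """Expected particle arrivals per frame.

    The occupancy bookkeeping follows the chip's performance model: the
    particle number density applies to the full sensing cross-section, so the
    mean snapshot count in the sensing segment equals density × sensing
    volume (λ = 0.125 at 10⁶/mL for the default 125 pL segment).
    """
    density_per_um3 = density_per_ml / 1e12  # 1 mL = 1e12 μm³
    advance = flow.advance_per_frame
    return density_per_um3 * geometry.sorting_width * geometry.sorting_height * advance


def iter_stream_frames(
    populations: list[ParticlePopulation],
    fractions: list[float],
    flow: FlowConfig,
    geometry: ChipGeometry,
    optics: OpticsModel,
    density: float,
    n_frames: int,
    seed: int,
    render: bool = True,
):
    """Yield ``(frame_index, frame_or_None, truth_records)`` one frame at a time.

    Streaming form of :func:`simulate_stream` for long runs that must not hold
    the whole stack in memory.  Draw order is fixed, so the truth sequence is
    identical whether or not frames are rendered.
    """
    if len(populations) != len(fractions) or not populations:
        raise InvalidConfigError("populations and fractions must be non-empty and match")
    if not math.isclose(sum(fractions), 1.0, rel_tol=1e-9):
        raise InvalidConfigError(f"fractions must sum to 1, got {sum(fractions)!r}")
    if density < 0:
        raise InvalidConfigError("density must be >= 0")

    # independent child streams: arrivals/particles vs camera noise, so a
    # truth-only run draws the same particles as a rendered one
    arrival_ss, noise_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(arrival_ss)
    noise_rng = np.random.default_rng(noise_ss)
    mu = _arrival_rate_per_frame(density, geometry, flow)
    advance = flow.advance_per_frame
    fw = flow.focused_width
    length = geometry.sorting_length
    pitch = optics.pixel_pitch
    rows, cols = optics.frame_shape
    margin = 0.5 * (rows * pitch - length)  # μm of view above/below the segment
    if margin < 0:
        raise InvalidConfigError(
            "frame_shape is shorter than the sorting segment; enlarge frame rows"
        )
    fracs = np.asarray(fractions, dtype=float)

    active: list[dict] = []
    next_id = 0
    for t in range(n_frames):
        # advance, retire, then spawn arrivals of the last inter-frame interval
        for p in active:
            p["y"] += advance
        active = [p for p in active if p["y"] <= length]
        k = rng.poisson(mu)
        for _ in range(k):
            pop_idx = int(rng.choice(len(populations), p=fracs))
            pop = populations[pop_idx]
            d = -1.0
            while d <= 0:
                d = rng.normal(pop.diameter_mean, pop.diameter_cv * pop.diameter_mean)
            particle = {
                "id": next_id,
                "pop": pop,
                "x": rng.uniform(-fw / 2, fw / 2),
                "y": rng.uniform(0.0, advance) if advance > 0 else rng.uniform(0.0, length),
                "d": d,
            }
            # fast flow: a particle may cross the whole segment between frames
            if particle["y"] <= length:
                active.append(particle)
            next_id += 1

        records = []
        for p in active:
            x_um = p["x"] + 0.5 * cols * pitch  # frame coords: 0 at left edge
            y_um = p["y"] + margin
            x_px = x_um / pitch - 0.5
            y_px = y_um / pitch - 0.5
            r_px = 0.5 * p["d"] / pitch
            partial = (
                x_px - r_px < -0.5
                or x_px + r_px > cols - 0.5
                or y_px - r_px < -0.5
                or y_px + r_px > rows - 0.5
            )
            records.append(
                TruthRecord(
                    frame=t,
                    particle_id=p["id"],
                    label=p["pop"].label,
                    x_px=x_px,
                    y_px=y_px,
                    diameter_um=p["d"],
                    charge=p["pop"].charge_class,
                    partially_visible=partial,
                )
            )

        frame = None
        if render:
            img = np.full(optics.frame_shape, optics.background_level, dtype=np.float64)
            for p, rec in zip(active, records):
                patch, top_left = render_particle(
                    ((rec.x_px + 0.5) * pitch, (rec.y_px + 0.5) * pitch),
                    p["d"],
                    optics,
                    contrast=optics.particle_contrast * p["pop"].contrast_scale,
                )
                _add_patch(img, patch, top_left)
            if optics.noise_sigma > 0:
                img += noise_rng.normal(0.0, optics.noise_sigma, size=optics.frame_shape)
            frame = _quantize(img, optics)
        yield t, frame, records


def simulate_stream(
    populations: list[ParticlePopulation],
    fractions: list[float],
    flow: FlowConfig,
    geometry: ChipGeometry,
    optics: OpticsModel,
    density: float,
    duration: float,
    seed: int,
    *,
    render: bool = True,
    background_seed: int | None = None,
) -> FrameSequence:
    """Simulate ``duration`` seconds of the particle stream.

    Arrivals are Poisson at rate density × cross-section × speed; each
    particle advances ``speed / frame_rate`` μm of flow per frame and its
    lateral position is drawn uniformly within the focused stream.  With
    ``render=False`` only truth records are produced (same RNG draws, so the
    truth matches a rendered run with the same seed).
    """
    if not duration > 0:
        raise InvalidConfigError("duration must be > 0")
    n_frames = int(round(duration * flow.frame_rate))
    frames: list[np.ndarray] | None = [] if render else None
    truth: list[TruthRecord] = []
    for _, frame, records in iter_stream_frames(
        populations, fractions, flow, geometry, optics, density, n_frames, seed,
        render=render,
    ):
        if render:
            frames.append(frame)
        truth.extend(records)
    background = make_background(
        optics, seed if background_seed is None else background_seed
    )
    return FrameSequence(
        frames=frames,
        background=background,
        truth=truth,
        n_frames=n_frames,
        optics=optics,
        geometry=geometry,
        flow=flow,
    )


def per_frame_counts(seq: FrameSequence) -> np.ndarray:
    """Number of in-segment particles per frame (the Poisson occupancy)."""
    counts = np.zeros(seq.n_frames, dtype=np.int64)
    for rec in seq.truth:
        counts[rec.frame] += 1
    return counts
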