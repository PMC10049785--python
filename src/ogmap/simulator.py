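"""Generative model for synthetic images of fluorescently labeled DNA molecules.

A stretched DNA molecule is modeled as a straight horizontal segment imaged
onto a 5-row pixel strip.  Labeled motif sites occur along the molecule by
independent per-basepair Bernoulli trials; each site contributes an isotropic
2D Gaussian point-spread function centered on the middle row, and additive
white Gaussian noise is applied at a configurable signal-to-noise ratio
(peak amplitude of a single emitter divided by the noise standard deviation).

The generator serves both as the infinite training stream for the localizer
network and as the fixture generator for tests and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml

__all__ = [
    "SimulationConfig",
    "GroundTruthLabels",
    "MoleculeImage",
    "sample_emitter_positions",
    "render_image",
    "make_training_example",
    "simulate_reference_and_molecule",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the molecule-image generative model.

    Defaults reproduce the study conditions: 335 bp/pixel optical scale,
    one emitter per 4096 bp on average, a Gaussian PSF of 1.5 px standard
    deviation, SNR 2.33, on a 5-row strip 100-1000 px long.
    """

    pixel_size_bp: float = 335.0
    emitter_density: float = 1.0 / 4096.0
    psf_sigma_px: float = 1.5
    snr: float = 2.33
    amplitude: float = 1.0
    image_rows: int = 5
    length_range_px: tuple[int, int] = (100, 1000)
    #: per-image uniform multiplier ranges for (amplitude, snr, density);
    #: ``None`` disables the corresponding jitter.
    jitter_amplitude: tuple[float, float] | None = None
    jitter_snr: tuple[float, float] | None = None
    jitter_density: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.emitter_density < 1.0):
            raise ValueError("emitter_density must lie in (0, 1)")
        for name in ("pixel_size_bp", "psf_sigma_px", "snr", "amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.image_rows < 1:
            raise ValueError("image_rows must be >= 1")
        lo, hi = self.length_range_px
        if lo < 1 or lo > hi:
            raise ValueError("length_range_px must satisfy 1 <= lo <= hi")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "length_range_px" in data:
            data["length_range_px"] = tuple(data["length_range_px"])
        for key in ("jitter_amplitude", "jitter_snr", "jitter_density"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruthLabels:
    """Known emitter positions of a simulated molecule.

    ``emitter_positions_px`` are continuous coordinates in [0, L).  The
    per-pixel encoding is occupancy ``occupancy[i] = 1`` iff an emitter falls
    in pixel ``i`` (at most one per pixel by construction) and
    ``rel_position[i]`` is its fractional offset within the pixel.
    """

    emitter_positions_px: np.ndarray
    occupancy: np.ndarray
    rel_position: np.ndarray

    @property
    def n_emitters(self) -> int:
        return len(self.emitter_positions_px)

    @classmethod
    def from_positions(cls, positions_px: np.ndarray, length_px: int) -> "GroundTruthLabels":
        positions_px = np.sort(np.asarray(positions_px, dtype=np.float64))
        if positions_px.size and (positions_px[0] < 0 or positions_px[-1] >= length_px):
            raise ValueError("emitter positions must lie within [0, length_px)")
        occ = np.zeros(length_px, dtype=np.float64)
        rel = np.zeros(length_px, dtype=np.float64)
        idx = np.floor(positions_px).astype(np.intp)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("at most one emitter per pixel")
        occ[idx] = 1.0
        rel[idx] = positions_px - idx
        return cls(positions_px, occ, rel)


@dataclass(frozen=True)
class MoleculeImage:
    """A 5-row x L-column intensity strip of one stretched molecule."""

    intensities: np.ndarray
    config: SimulationConfig
    labels: GroundTruthLabels | None = None

    @property
    def length_px(self) -> int:
        return self.intensities.shape[1]


def _positions_bp_to_px(positions_bp: np.ndarray, config: SimulationConfig) -> np.ndarray:
    return np.sort(positions_bp / config.pixel_size_bp)


def _resolve_pixel_collisions(
    positions_bp: np.ndarray, n_bp: int, pixel_size_bp: float, rng: np.random.Generator
) -> np.ndarray:
    """Resample any emitter landing in an already occupied pixel.

    Keeps the emitter count fixed while enforcing the at-most-one-emitter-
    per-pixel approximation of the per-pixel label encoding.
    """
    positions_bp = np.sort(positions_bp)
    for _ in range(1000):
        px = np.floor(positions_bp / pixel_size_bp).astype(np.intp)
        # mark later duplicates (first occupant of a pixel keeps its place)
        dup = np.zeros(len(px), dtype=bool)
        dup[1:] = px[1:] == px[:-1]
        if not dup.any():
            return positions_bp
        positions_bp[dup] = rng.integers(0, n_bp, size=int(dup.sum()))
        positions_bp = np.sort(positions_bp)
    raise RuntimeError("failed to resolve pixel collisions")  # pragma: no cover


def sample_emitter_positions(
    length_px: int, config: SimulationConfig, rng: np.random.Generator
) -> GroundTruthLabels:
    """Draw emitter positions by per-basepair Bernoulli trials.

    Each of the ``length_px * pixel_size_bp`` basepairs independently carries
    an emitter with probability ``emitter_density``; equivalently a binomial
    count of emitters is placed uniformly without replacement on the basepair
    grid, then converted to pixel units.  Emitters colliding in one pixel are
    resampled so the per-pixel encoding stays exact.
    """
    if length_px < 1:
        raise ValueError("length_px must be >= 1")
    n_bp = int(round(length_px * config.pixel_size_bp))
    if config.emitter_density == 0.0:  # degenerate escape hatch used in tests
        return GroundTruthLabels.from_positions(np.empty(0), length_px)
    k = rng.binomial(n_bp, config.emitter_density)
    # uniform without replacement == Bernoulli process conditioned on its count
    positions_bp = rng.integers(0, n_bp, size=k).astype(np.float64)
    positions_bp = _dedupe_bp(positions_bp, n_bp, rng)
    positions_bp = _resolve_pixel_collisions(positions_bp, n_bp, config.pixel_size_bp, rng)
    return GroundTruthLabels.from_positions(
        _positions_bp_to_px(positions_bp, config), length_px
    )


def _dedupe_bp(positions_bp: np.ndarray, n_bp: int, rng: np.random.Generator) -> np.ndarray:
    for _ in range(1000):
        positions_bp = np.sort(positions_bp)
        dup = np.zeros(len(positions_bp), dtype=bool)
        dup[1:] = positions_bp[1:] == positions_bp[:-1]
        if not dup.any():
            return positions_bp
        positions_bp[dup] = rng.integers(0, n_bp, size=int(dup.sum()))
    raise RuntimeError("failed to draw distinct basepair positions")  # pragma: no cover


def render_image(
    labels: GroundTruthLabels,
    length_px: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    *,
    noise: bool = True,
    amplitude: float | None = None,
    snr: float | None = None,
) -> MoleculeImage:
    """Render emitters through the Gaussian-PSF forward model.

    Each emitter adds ``A * exp(-((x-x0)^2 + (y-y0)^2) / (2 sigma^2))`` with
    the emitter centered on the middle row; contributions sum, then white
    Gaussian noise of standard deviation ``A / snr`` is added.
    """
    pos = labels.emitter_positions_px
    if pos.size and (pos.min() < 0 or pos.max() >= length_px):
        raise ValueError("emitter coordinate outside [0, length_px)")
    amplitude = config.amplitude if amplitude is None else amplitude
    snr = config.snr if snr is None else snr
    rows, sigma = config.image_rows, config.psf_sigma_px
    img = np.zeros((rows, length_px), dtype=np.float64)
    if pos.size:
        center_row = (rows - 1) / 2.0
        half = int(np.ceil(4 * sigma))
        offs = np.arange(-half, half + 1)
        px0 = np.floor(pos).astype(np.intp)
        cols = px0[:, None] + offs[None, :]  # (E, W)
        dx = cols - pos[:, None]
        gx = np.exp(-(dx**2) / (2 * sigma**2))
        gy = np.exp(-((np.arange(rows) - center_row) ** 2) / (2 * sigma**2))
        contrib = amplitude * gy[None, :, None] * gx[:, None, :]  # (E, rows, W)
        valid = (cols >= 0) & (cols < length_px)
        flat_cols = np.broadcast_to(cols[:, None, :], contrib.shape)
        flat_rows = np.broadcast_to(np.arange(rows)[None, :, None], contrib.shape)
        m = np.broadcast_to(valid[:, None, :], contrib.shape)
        np.add.at(img, (flat_rows[m], flat_cols[m]), contrib[m])
    if noise:
        if rng is None:
            raise ValueError("rng is required when noise is enabled")
        img = img + rng.normal(0.0, amplitude / snr, size=img.shape)
    return MoleculeImage(img, config, labels)


def _sample_jitter(rng: np.random.Generator, rng_range: tuple[float, float] | None) -> float:
    if rng_range is None:
        return 1.0
    return float(rng.uniform(*rng_range))


def make_training_example(
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    length_px: int | None = None,
) -> tuple[MoleculeImage, GroundTruthLabels]:
    """Generate one fresh (image, labels) pair of the training stream.

    A molecule length is drawn uniformly from ``length_range_px`` (unless
    pinned), per-image jitter multipliers are applied to amplitude, SNR and
    density, and the image is rendered with noise.  Each call consumes fresh
    randomness; no example is ever reused.
    """
    lo, hi = config.length_range_px
    if length_px is None:
        length_px = int(rng.integers(lo, hi + 1))
    density = config.emitter_density * _sample_jitter(rng, config.jitter_density)
    labels = sample_emitter_positions(
        length_px, config.with_overrides(emitter_density=min(density, 0.999)), rng
    )
    image = render_image(
        labels,
        length_px,
        config,
        rng,
        amplitude=config.amplitude * _sample_jitter(rng, config.jitter_amplitude),
        snr=config.snr * _sample_jitter(rng, config.jitter_snr),
    )
    return image, labels


def simulate_reference_and_molecule(
    genome_length_bp: int,
    fragment_length_bp: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, MoleculeImage, tuple[int, int]]:
    """Simulate a genome-wide motif map plus the image of one fragment of it.

    Returns ``(reference_positions_bp, molecule_image, (start_bp, end_bp))``
    where the image renders exactly the reference sites inside the half-open
    true interval, re-based to the fragment origin.
    """
    if fragment_length_bp > genome_length_bp:
        raise ValueError("fragment cannot be longer than the genome")
    k = rng.binomial(genome_length_bp, config.emitter_density)
    sites_bp = np.sort(_dedupe_bp(
        rng.integers(0, genome_length_bp, size=k).astype(np.float64), genome_length_bp, rng
    ))
    start = int(rng.integers(0, genome_length_bp - fragment_length_bp + 1))
    end = start + fragment_length_bp
    inside = sites_bp[(sites_bp >= start) & (sites_bp < end)] - start
    length_px = int(np.ceil(fragment_length_bp / config.pixel_size_bp))
    local_bp = _resolve_pixel_collisions(
        inside.copy(), fragment_length_bp, config.pixel_size_bp, rng
    )
    labels = GroundTruthLabels.from_positions(
        _positions_bp_to_px(local_bp, config), length_px
    )
    image = render_image(labels, length_px, config, rng)
    return sites_bp, image, (start, end)
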