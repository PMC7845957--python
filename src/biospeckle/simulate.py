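"""Phase-screen simulation of laser speckle from rough surfaces.

The simulator emulates the objective-speckle recording geometry: a coherent
beam of wavelength ``lambda`` illuminates a spot of diameter ``D`` on a rough
surface, and the backscattered field is observed in the far field at distance
``L``.  A surface of average roughness Ra (arithmetic mean absolute height
deviation, in nanometres) is modelled as a Gaussian-correlated random height
field ``h``.  The reflected field on the surface plane is

    E(x, y) = A(x, y) * exp(-Ra / R0) * exp(i * [4*pi/lambda * h * cos(theta) + phi_m])

where ``A`` is the illuminated-spot aperture, ``theta`` the incidence angle,
and ``phi_m`` a correlated microstructure phase screen that accounts for the
sub-resolution scattering of biological tissue (it makes the speckle fully
developed at every Ra, as observed for real tissue).  The recorded intensity
is the centred squared magnitude of the 2-D discrete Fourier transform of
``E``, quantised to 8 bits.

Two empirical knobs couple the image statistics to Ra:

* ``attenuation_scale`` (R0): backscattered amplitude falls as exp(-Ra/R0),
  so the mean gray level decays with roughness.
* ``patch_growth_scale`` (R1): the effective coherent spot shrinks as
  D / (1 + Ra/R1), so the far-field speckle grain (whose size is set by the
  autocorrelation of the illuminated spot) grows with roughness and bright
  patches become larger.

Both are phenomenological scales, not tissue physics; they reproduce the
qualitative behaviour of cartilage biospeckle (darker images with larger
bright patches as the surface degrades).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "SurfaceSpec",
    "HeightMap",
    "OpticsConfig",
    "SpeckleImage",
    "DEFAULT_RA_GRID_NM",
    "generate_surface",
    "surface_ra",
    "objective_speckle_size",
    "subjective_speckle_size",
    "render_intensity",
    "render_speckle",
    "generate_dataset",
]

#: Twelve roughness targets (nm) spanning the nanoscale degeneration range
#: from near-intact (10 nm) up to 2500 nm, spaced roughly geometrically.
DEFAULT_RA_GRID_NM: tuple[float, ...] = (
    10.0, 40.0, 90.0, 170.0, 300.0, 480.0,
    700.0, 980.0, 1280.0, 1600.0, 2000.0, 2500.0,
)


@dataclass(frozen=True)
class SurfaceSpec:
    """Prescription for a random rough surface.

    Parameters
    ----------
    ra_target
        Desired average roughness Ra in nanometres (> 0).
    correlation_length
        Lateral correlation length of the height field in micrometres.
    grid_size
        (rows, cols) of the simulation grid; each dimension must be >= 16.
    pixel_pitch
        Physical size of one grid cell in micrometres.
    """

    ra_target: float
    correlation_length: float = 150.0
    grid_size: tuple[int, int] = (400, 400)
    pixel_pitch: float = 32.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.ra_target) or self.ra_target <= 0:
            raise ValueError(f"ra_target must be > 0, got {self.ra_target!r}")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        rows, cols = self.grid_size
        if rows < 16 or cols < 16:
            raise ValueError("grid_size components must be >= 16")


@dataclass(frozen=True)
class HeightMap:
    """A realised surface topography: heights in nm on a regular grid."""

    heights: np.ndarray
    pixel_pitch: float  # um per grid cell

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2 or h.size < 2:
            raise ValueError("heights must be a 2-D array with >= 2 samples")
        if not np.all(np.isfinite(h)):
            raise ValueError("heights must be finite")
        object.__setattr__(self, "heights", h)


@dataclass(frozen=True)
class OpticsConfig:
    """Optical-bench and rendering parameters.

    Defaults follow a He-Ne bench: 632 nm laser, 4 mm illuminated spot,
    camera 50 cm from the specimen, ~15 degree incidence.
    """

    wavelength: float = 632.0            # nm
    propagation_distance: float = 50.0   # cm, surface -> observation plane
    spot_diameter: float = 4.0           # mm, illuminated spot
    incidence_angle: float = 15.0        # degrees from surface normal
    focal_length: float = 50.0           # mm (subjective-speckle formula only)
    magnification: float = 1.0           # dimensionless
    lens_diameter: float = 10.0          # mm (subjective-speckle formula only)
    attenuation_scale: float = 2000.0    # nm; R0 in exp(-Ra/R0)
    patch_growth_scale: float = 1500.0   # nm; R1 in D/(1 + Ra/R1)
    quantization_percentile: float = 99.0
    quantization_gray: int = 250
    micro_phase_std: float = 20.0        # rad; tissue microstructure screen
    micro_corr_length: float = 150.0     # um; its lateral correlation length
    apply_aperture: bool = True

    def __post_init__(self) -> None:
        for name in ("wavelength", "propagation_distance", "spot_diameter",
                     "focal_length", "lens_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.incidence_angle < 90.0):
            raise ValueError("incidence_angle must be in [0, 90) degrees")
        if self.magnification < 0:
            raise ValueError("magnification must be >= 0")
        if self.attenuation_scale <= 0 or self.patch_growth_scale <= 0:
            raise ValueError("attenuation and patch-growth scales must be > 0")
        if not (0.0 < self.quantization_percentile <= 100.0):
            raise ValueError("quantization_percentile must be in (0, 100]")
        if not (0 < self.quantization_gray <= 255):
            raise ValueError("quantization_gray must be in (0, 255]")
        if self.micro_phase_std < 0:
            raise ValueError("micro_phase_std must be >= 0")


@dataclass(frozen=True)
class SpeckleImage:
    """An 8-bit speckle image plus the provenance needed to reproduce it."""

    pixels: np.ndarray
    surface: SurfaceSpec | None = None
    optics: OpticsConfig | None = None
    seed: int | None = None
    ra_nm: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if p.size == 0:
            raise ValueError("pixels must be non-empty")
        if p.min() < 0 or p.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", p.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def surface_ra(h: HeightMap | np.ndarray) -> float:
    """Average roughness Ra = mean |h - mean(h)| in the units of ``h`` (nm).

    This is the arithmetic-mean-deviation roughness a stylus profilometer
    reports, evaluated over the whole map rather than a single trace.
    """
    heights = h.heights if isinstance(h, HeightMap) else np.asarray(h, dtype=float)
    if heights.size < 2:
        raise ValueError("need at least 2 height samples")
    return float(np.mean(np.abs(heights - heights.mean())))


def generate_surface(spec: SurfaceSpec, seed: int) -> HeightMap:
    """Draw a Gaussian-correlated height field with exactly the requested Ra.

    White Gaussian noise is smoothed with a Gaussian kernel of standard
    deviation ``correlation_length / pixel_pitch`` grid cells, centred, and
    rescaled so that the achieved Ra equals ``spec.ra_target``.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rows, cols = spec.grid_size
    noise = rng.standard_normal((rows, cols))
    sigma_px = spec.correlation_length / spec.pixel_pitch
    h = gaussian_filter(noise, sigma=sigma_px, mode="wrap")
    h -= h.mean()
    ra = np.mean(np.abs(h))
    if ra == 0:  # pragma: no cover - smoothed white noise is never flat
        raise RuntimeError("degenerate height field")
    h *= spec.ra_target / ra
    return HeightMap(heights=h, pixel_pitch=spec.pixel_pitch)


def objective_speckle_size(cfg: OpticsConfig) -> float:
    """Mean grain size (um) of free-space speckle: 1.22 * lambda * L / D."""
    lam_um = cfg.wavelength * 1e-3
    dist_um = cfg.propagation_distance * 1e4
    spot_um = cfg.spot_diameter * 1e3
    return 1.22 * lam_um * dist_um / spot_um


def subjective_speckle_size(cfg: OpticsConfig) -> float:
    """Mean grain size (um) of imaged speckle: 1.22 * lambda * (1+M) * f / d."""
    lam_um = cfg.wavelength * 1e-3
    f_um = cfg.focal_length * 1e3
    d_um = cfg.lens_diameter * 1e3
    return 1.22 * lam_um * (1.0 + cfg.magnification) * f_um / d_um


def _aperture_mask(shape: tuple[int, int], radius_px: float) -> np.ndarray:
    rows, cols = shape
    r = np.arange(rows) - (rows - 1) / 2.0
    c = np.arange(cols) - (cols - 1) / 2.0
    rr, cc = np.meshgrid(r, c, indexing="ij")
    return (rr * rr + cc * cc <= radius_px * radius_px).astype(float)


def render_intensity(h: HeightMap, cfg: OpticsConfig, seed: int) -> np.ndarray:
    """Far-field intensity (float, unquantised) for a surface realisation.

    The microstructure phase screen is drawn from ``seed``; the surface phase
    comes deterministically from ``h``.
    """
    heights = h.heights
    ra = surface_ra(h)
    cos_inc = np.cos(np.deg2rad(cfg.incidence_angle))
    phase = (4.0 * np.pi / cfg.wavelength) * heights * cos_inc

    if cfg.micro_phase_std > 0:
        rng = np.random.default_rng(seed)
        micro = gaussian_filter(rng.standard_normal(heights.shape),
                                sigma=cfg.micro_corr_length / h.pixel_pitch,
                                mode="wrap")
        std = micro.std()
        if std > 0:
            phase = phase + micro * (cfg.micro_phase_std / std)

    amplitude = np.exp(-ra / cfg.attenuation_scale)
    field = amplitude * np.exp(1j * phase)
    if cfg.apply_aperture:
        growth = 1.0 + ra / cfg.patch_growth_scale
        spot_um = cfg.spot_diameter * 1e3 / growth
        radius_px = 0.5 * spot_um / h.pixel_pitch
        # compensate the aperture-area loss so the patch-growth knob changes
        # only the grain size, not the image energy (R0 alone sets darkening)
        field = field * _aperture_mask(heights.shape, radius_px) * growth

    far = np.fft.fftshift(np.fft.fft2(field))
    return np.abs(far) ** 2 / field.size


def quantize(intensity: np.ndarray, scale: float) -> np.ndarray:
    """Map float intensity to 8-bit gray levels: clip(round(I * scale))."""
    levels = np.floor(intensity * scale + 0.5)  # round half-up
    return np.clip(levels, 0, 255).astype(np.uint8)


def quantization_scale(intensity: np.ndarray, cfg: OpticsConfig) -> float:
    """Scale mapping the configured percentile of ``intensity`` to the
    configured gray level (the batch-reference rule)."""
    ref = np.percentile(intensity, cfg.quantization_percentile)
    if ref <= 0:
        ref = intensity.max()
    if ref <= 0:
        return 1.0
    return cfg.quantization_gray / ref


def render_speckle(h: HeightMap, cfg: OpticsConfig, seed: int, *,
                   scale: float | None = None,
                   surface: SurfaceSpec | None = None,
                   label: str | None = None) -> SpeckleImage:
    """Render an 8-bit speckle image of a surface realisation.

    If ``scale`` is None the image is self-referenced: its own
    ``quantization_percentile`` maps to ``quantization_gray``.  Within a
    batch, pass the scale of the batch reference image instead so that
    absolute gray levels remain comparable across images.
    """
    intensity = render_intensity(h, cfg, seed)
    if scale is None:
        scale = quantization_scale(intensity, cfg)
    pixels = quantize(intensity, scale)
    return SpeckleImage(pixels=pixels, surface=surface, optics=cfg, seed=seed,
                        ra_nm=surface_ra(h), label=label)


def generate_dataset(ra_list: Sequence[float],
                     cfg: OpticsConfig | None = None,
                     seed: int = 0,
                     surface: SurfaceSpec | None = None) -> list[SpeckleImage]:
    """Render one labelled speckle image per requested Ra value.

    Per-image seeds are spawned reproducibly from the master seed.  All
    images share one quantisation scale, fixed by the lowest-Ra (brightest)
    image of the batch, so cross-image gray-level ordering is preserved.
    """
    ra_values = [float(r) for r in ra_list]
    if not ra_values:
        raise ValueError("ra_list must be non-empty")
    if any(r <= 0 for r in ra_values):
        raise ValueError("all Ra values must be > 0")
    cfg = cfg or OpticsConfig()
    template = surface or SurfaceSpec(ra_target=ra_values[0])

    seeds = np.random.SeedSequence(seed).generate_state(2 * len(ra_values))
    seeds = [int(s % (2 ** 31)) for s in seeds]

    realisations = []
    for idx, ra in enumerate(ra_values):
        spec = dataclasses.replace(template, ra_target=ra)
        hmap = generate_surface(spec, seeds[2 * idx])
        intensity = render_intensity(hmap, cfg, seeds[2 * idx + 1])
        realisations.append((spec, hmap, intensity, seeds[2 * idx + 1]))

    ref_idx = int(np.argmin(ra_values))
    scale = quantization_scale(realisations[ref_idx][2], cfg)

    images = []
    for idx, (spec, hmap, intensity, render_seed) in enumerate(realisations):
        images.append(SpeckleImage(
            pixels=quantize(intensity, scale),
            surface=spec, optics=cfg, seed=render_seed,
            ra_nm=surface_ra(hmap), label=f"img_{idx:03d}",
        ))
    return images
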