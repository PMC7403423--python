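"""Synthetic-data generator: digital breast phantoms and simulated exams.

This module stands in for the clinical scanner.  It builds slab phantoms
with spherical absorbers, runs the FEM forward model on a fine simulation
mesh (default 1 mm - half the default reconstruction fine spacing, so
reconstructions of simulated data never commit the inverse crime), and
corrupts the clean channel data the way the hardware does: fixed
per-channel gains and phase offsets (laser power / APD sensitivity / RF
path-length variation), severe attenuation on air-gap-contaminated
peripheral channels, and random amplitude/phase measurement noise.

Background optical properties default to literature-typical healthy breast
values (mu_a = 0.005 mm^-1, mu_s' = 1.0 mm^-1); they are configuration, not
constants.  All randomness flows from the seeds recorded on the
:class:`NoiseModel`, so exams are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem_forward import SlabChannelModel, build_slab_mesh
from .measurement import ProbeGeometry, RawFrame, default_probe_geometry
from .optics import OpticalProperties

__all__ = [
    "Inclusion",
    "DigitalPhantom",
    "NoiseModel",
    "SimulatedExam",
    "make_phantom",
    "simulate_exam",
    "make_calibration_exam",
    "peripheral_airgap_channels",
    "make_synthetic_dbt",
    "DEFAULT_BACKGROUND",
]

DEFAULT_BACKGROUND = OpticalProperties(0.005, 1.0)
#: Default simulation mesh spacing, mm (half the 2 mm reconstruction
#: fine spacing - the inverse-crime guard).
DEFAULT_SIM_SPACING = 1.0


@dataclass(frozen=True)
class Inclusion:
    """Spherical lesion: centre (mm), radius (mm) and contrast factors
    applied multiplicatively to the background properties."""

    center: tuple
    radius: float
    mu_a_contrast: float = 2.0
    mu_s_contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("inclusion radius must be positive")
        if self.mu_a_contrast <= 0 or self.mu_s_contrast <= 0:
            raise ValueError("contrast factors must be positive")


@dataclass
class DigitalPhantom:
    """Compressed-breast slab with optional spherical inclusions.

    ``background`` holds one :class:`OpticalProperties` per wavelength (a
    single instance is broadcast).  The slab occupies
    [-Lx/2, Lx/2] x [-Ly/2, Ly/2] x [0, thickness].
    """

    lateral_extent: tuple = (80.0, 80.0)
    thickness: float = 50.0
    background: tuple = (DEFAULT_BACKGROUND,)
    inclusions: tuple = ()

    def __post_init__(self) -> None:
        if isinstance(self.background, OpticalProperties):
            self.background = (self.background,)
        self.background = tuple(self.background)
        self.inclusions = tuple(self.inclusions)
        if not 20.0 <= self.thickness <= 74.0:
            raise ValueError(
                "thickness outside the clinical compression range 20-74 mm"
            )
        lx, ly = self.lateral_extent
        for inc in self.inclusions:
            c = np.asarray(inc.center, dtype=float)
            if (
                abs(c[0]) + inc.radius > lx / 2.0
                or abs(c[1]) + inc.radius > ly / 2.0
                or c[2] - inc.radius < 0.0
                or c[2] + inc.radius > self.thickness
            ):
                raise ValueError(f"inclusion at {tuple(c)} extends outside the slab")

    def props(self, wavelength_index: int) -> OpticalProperties:
        if len(self.background) == 1:
            return self.background[0]
        return self.background[wavelength_index]

    def mu_a_field(self, points, wavelength_index: int = 0) -> np.ndarray:
        """Nodal absorption map, mm^-1 (point-in-sphere for each inclusion)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        bg = self.props(wavelength_index)
        out = np.full(len(pts), bg.mu_a)
        for inc in self.inclusions:
            inside = (
                np.sum((pts - np.asarray(inc.center)) ** 2, axis=1)
                <= inc.radius**2
            )
            out[inside] = bg.mu_a * inc.mu_a_contrast
        return out

    def mu_s_field(self, points, wavelength_index: int = 0) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        bg = self.props(wavelength_index)
        out = np.full(len(pts), bg.mu_s_prime)
        for inc in self.inclusions:
            inside = (
                np.sum((pts - np.asarray(inc.center)) ** 2, axis=1)
                <= inc.radius**2
            )
            out[inside] = bg.mu_s_prime * inc.mu_s_contrast
        return out

    def kappa_field(self, points, wavelength_index: int = 0) -> np.ndarray:
        mu_a = self.mu_a_field(points, wavelength_index)
        mu_s = self.mu_s_field(points, wavelength_index)
        return 1.0 / (3.0 * (mu_a + mu_s))

    @property
    def homogeneous(self) -> bool:
        return len(self.inclusions) == 0


def make_phantom(
    lateral_extent=(80.0, 80.0),
    thickness: float = 50.0,
    mu_a: float = DEFAULT_BACKGROUND.mu_a,
    mu_s_prime: float = DEFAULT_BACKGROUND.mu_s_prime,
    refractive_index: float = 1.4,
    n_wavelengths: int = 3,
    inclusions=(),
) -> DigitalPhantom:
    """Convenience constructor with literature-typical breast defaults."""
    bg = OpticalProperties(mu_a, mu_s_prime, refractive_index)
    return DigitalPhantom(
        lateral_extent=tuple(lateral_extent),
        thickness=thickness,
        background=(bg,) * n_wavelengths,
        inclusions=tuple(inclusions),
    )


@dataclass(frozen=True)
class NoiseModel:
    """Instrument imperfections applied to clean channel data.

    Fixed per-channel effects are drawn from ``gain_seed`` (shared between a
    calibration exam and a patient exam acquired back-to-back on the same
    hardware); per-measurement noise is drawn from ``seed``.  Gains are
    log-normal (exp of a zero-mean normal with SD ``channel_gain_spread``)
    so they are strictly positive.
    """

    amplitude_noise: float = 0.01
    phase_noise: float = float(np.deg2rad(0.5))
    channel_gain_spread: float = 0.2
    channel_phase_offset_spread: float = 0.1
    airgap_channels: tuple = ()
    airgap_attenuation: float = 0.01
    seed: int = 0
    gain_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("amplitude_noise", "phase_noise", "channel_gain_spread",
                     "channel_phase_offset_spread"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        object.__setattr__(self, "airgap_channels",
                           tuple(tuple(c) for c in self.airgap_channels))

    @property
    def effective_gain_seed(self) -> int:
        return self.seed if self.gain_seed is None else self.gain_seed


@dataclass
class SimulatedExam:
    """Raw frame plus its ground truth and provenance."""

    raw: RawFrame
    phantom: DigitalPhantom
    clean_amplitude: np.ndarray
    clean_phase: np.ndarray
    noise: NoiseModel
    mesh_spacing: float

    @property
    def geometry(self) -> ProbeGeometry:
        return self.raw.geometry


def _channel_effects(noise: NoiseModel, shape) -> tuple:
    rng = np.random.default_rng(noise.effective_gain_seed)
    gains = np.exp(noise.channel_gain_spread * rng.standard_normal(shape))
    offsets = noise.channel_phase_offset_spread * rng.standard_normal(shape)
    return gains, offsets


def simulate_exam(
    phantom: DigitalPhantom,
    geometry: ProbeGeometry,
    noise: NoiseModel,
    mesh_spacing: float = DEFAULT_SIM_SPACING,
    rtol: float = 1e-8,
) -> SimulatedExam:
    """Forward-model a phantom exam and apply the instrument noise chain.

    The FEM solve runs on a mesh at ``mesh_spacing`` (default 1 mm); the
    provenance spacing is recorded so that :func:`fdot.recon.reconstruct`
    can refuse inverse-crime data.  Clean per-channel amplitude / phase-lag
    arrays are stored alongside the noisy IQ frame.
    """
    if abs(geometry.slab_thickness - phantom.thickness) > 1e-9:
        raise ValueError(
            "geometry slab_thickness must equal the phantom thickness"
        )
    mesh = build_slab_mesh(phantom.lateral_extent, phantom.thickness, mesh_spacing)
    shape = geometry.channel_shape
    clean_amp = np.empty(shape)
    clean_lag = np.empty(shape)
    for w in range(geometry.n_wavelengths):
        model = SlabChannelModel(mesh, geometry, phantom.props(w))
        mu_a = phantom.mu_a_field(mesh.nodes, w)
        kappa = (
            None
            if phantom.homogeneous
            else phantom.kappa_field(mesh.nodes, w)
        )
        ch = model.channels(mu_a, rtol=rtol, kappa_field=kappa)
        amp, lag = SlabChannelModel.amplitude_lag(ch, geometry)
        clean_amp[:, :, w] = amp
        clean_lag[:, :, w] = lag

    gains, offsets = _channel_effects(noise, shape)
    rng = np.random.default_rng(noise.seed)
    amp = clean_amp * gains
    lag = clean_lag + offsets
    for s, d in noise.airgap_channels:
        amp[s, d, :] *= noise.airgap_attenuation
    amp = amp * (1.0 + noise.amplitude_noise * rng.standard_normal(shape))
    lag = lag + noise.phase_noise * rng.standard_normal(shape)
    raw = RawFrame(iq=amp * np.exp(1j * lag), geometry=geometry)
    return SimulatedExam(
        raw=raw,
        phantom=phantom,
        clean_amplitude=clean_amp,
        clean_phase=clean_lag,
        noise=noise,
        mesh_spacing=float(mesh_spacing),
    )


def make_calibration_exam(
    props,
    geometry: ProbeGeometry,
    noise: NoiseModel,
    mesh_spacing: float = DEFAULT_SIM_SPACING,
    rtol: float = 1e-8,
    lateral_extent=None,
) -> SimulatedExam:
    """Homogeneous calibration-phantom exam.

    Shares the fixed channel gains/offsets with any exam generated from a
    NoiseModel carrying the same ``gain_seed``, which is what makes the
    calibration transferable.  ``props`` may be a single
    :class:`OpticalProperties` or one per wavelength; inclusions are not
    allowed by construction.  ``lateral_extent`` should match the footprint
    of the paired patient slab (default: optode span plus a 10 mm margin per
    side); a mismatched footprint leaves channel-dependent boundary effects
    in the calibration factors.
    """
    if isinstance(props, OpticalProperties):
        props = (props,) * geometry.n_wavelengths
    if lateral_extent is None:
        lateral_extent = (
            2.0 * np.abs(geometry.source_positions[:, 0]).max() + 20.0,
            2.0 * np.abs(geometry.source_positions[:, 1]).max() + 20.0,
        )
    phantom = DigitalPhantom(
        lateral_extent=tuple(lateral_extent),
        thickness=geometry.slab_thickness,
        background=tuple(props),
        inclusions=(),
    )
    return simulate_exam(phantom, geometry, noise, mesh_spacing, rtol)


def peripheral_airgap_channels(geometry: ProbeGeometry, count: int = 5) -> tuple:
    """The ``count`` most peripheral (source, detector) pairs - the channels
    the air gap between paddle and breast edge corrupts first."""
    s_r = np.linalg.norm(geometry.source_positions[:, :2], axis=1)
    d_r = np.linalg.norm(geometry.detector_positions[:, :2], axis=1)
    score = s_r[:, None] + d_r[None, :]
    flat = np.argsort(-score.ravel(), kind="stable")[:count]
    return tuple(
        (int(i // geometry.n_detectors), int(i % geometry.n_detectors))
        for i in flat
    )


def make_synthetic_dbt(
    shape=(220, 180),
    pixel_spacing: float = 0.5,
    seed: int = 0,
):
    """Synthetic craniocaudal DBT-like background slice.

    A half-elliptical breast outline with smooth fibroglandular texture;
    purely a stand-in for a reconstructed DBT slice when rendering fusion
    overlays of simulated exams.  Returns (image in [0, 1], pixel spacing
    mm).
    """
    ny, nx = shape
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:ny, 0:nx].astype(float)
    cy, rx, ry = ny / 2.0, nx * 0.92, ny * 0.42
    ellipse = (x / rx) ** 2 + ((y - cy) / ry) ** 2
    breast = ellipse < 1.0
    base = np.where(breast, 0.35 + 0.45 * (1.0 - ellipse), 0.02)
    # low-frequency texture: sum of a few random smooth cosines
    tex = np.zeros_like(base)
    for _ in range(6):
        fx, fy = rng.uniform(1.0, 4.0, 2)
        ph = rng.uniform(0, 2 * np.pi, 2)
        tex += np.cos(2 * np.pi * fx * x / nx + ph[0]) * np.cos(
            2 * np.pi * fy * y / ny + ph[1]
        )
    img = np.clip(base + 0.05 * tex * breast, 0.0, 1.0)
    return img, float(pixel_spacing)
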