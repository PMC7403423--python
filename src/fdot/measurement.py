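"""Acquisition geometry, raw frequency-domain data, calibration and channel masking.

The instrument delivers one in-phase/quadrature (IQ) pair per
source-detector-wavelength channel.  This module turns those into
amplitude / phase-lag arrays, builds and applies per-channel calibration
factors measured on a homogeneous phantom of known optical properties, and
rejects channels corrupted by peripheral air gaps between the breast and the
compression paddles.

Phase is stored as the demodulated *lag* (radians), unwrapped along
increasing source-detector distance within each source group, so that the
lag slope d(theta)/d(rho) is positive (see :mod:`fdot.optics`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd

from .optics import OpticalProperties, robin_coefficient, slab_fluence

__all__ = [
    "ProbeGeometry",
    "fem_channel_model",
    "RawFrame",
    "ChannelMask",
    "CalibrationTable",
    "MeasurementSet",
    "default_probe_geometry",
    "iq_to_amplitude_phase",
    "compute_calibration",
    "apply_calibration",
    "select_channels",
    "homogeneous_channel_model",
    "unwrap_lag",
    "save_raw_frame",
    "load_raw_frame",
    "read_raw_csv",
    "save_measurement_set",
    "load_measurement_set",
]

DEFAULT_WAVELENGTHS_NM = (785.0, 808.0, 850.0)
DEFAULT_MODULATION_HZ = 7.0e7


@dataclass(frozen=True)
class ProbeGeometry:
    """Parallel-plate probe: sources on z=0, detectors on z=slab_thickness.

    All positions are mm in a frame whose z axis is the compression axis.
    The clinical system uses 64 source positions and 40 detector fibres; the
    counts are not enforced so that reduced geometries can be used in tests.
    """

    source_positions: np.ndarray
    detector_positions: np.ndarray
    slab_thickness: float
    wavelengths: tuple = DEFAULT_WAVELENGTHS_NM
    modulation_frequency: float = DEFAULT_MODULATION_HZ

    def __post_init__(self) -> None:
        src = np.atleast_2d(np.asarray(self.source_positions, dtype=float))
        det = np.atleast_2d(np.asarray(self.detector_positions, dtype=float))
        object.__setattr__(self, "source_positions", src)
        object.__setattr__(self, "detector_positions", det)
        object.__setattr__(self, "wavelengths", tuple(float(w) for w in self.wavelengths))
        if src.shape[1] != 3 or det.shape[1] != 3:
            raise ValueError("positions must be (n, 3) arrays in mm")
        if not self.slab_thickness > 0:
            raise ValueError("slab_thickness must be positive")
        if np.ptp(src[:, 2]) > 1e-9 or np.ptp(det[:, 2]) > 1e-9:
            raise ValueError("sources and detectors must each be coplanar")
        sep = abs(det[0, 2] - src[0, 2])
        if abs(sep - self.slab_thickness) > 1e-9:
            raise ValueError(
                "source and detector planes must be separated by slab_thickness"
            )

    @property
    def n_sources(self) -> int:
        return len(self.source_positions)

    @property
    def n_detectors(self) -> int:
        return len(self.detector_positions)

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths)

    @property
    def omega(self) -> float:
        """Angular modulation frequency, rad/s."""
        return 2.0 * np.pi * self.modulation_frequency

    def rho(self) -> np.ndarray:
        """(n_sources, n_detectors) source-detector distances, mm."""
        diff = self.source_positions[:, None, :] - self.detector_positions[None, :, :]
        return np.linalg.norm(diff, axis=2)

    @property
    def channel_shape(self) -> tuple:
        return (self.n_sources, self.n_detectors, self.n_wavelengths)


def _centered_grid(nx: int, ny: int, pitch: float, z: float) -> np.ndarray:
    xs = (np.arange(nx) - (nx - 1) / 2.0) * pitch
    ys = (np.arange(ny) - (ny - 1) / 2.0) * pitch
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(nx * ny, float(z))])
    return pts


def default_probe_geometry(
    slab_thickness: float = 50.0,
    wavelengths: tuple = DEFAULT_WAVELENGTHS_NM,
    source_grid: tuple = (8, 8),
    detector_grid: tuple = (8, 5),
    pitch: float = 10.0,
    modulation_frequency: float = DEFAULT_MODULATION_HZ,
) -> ProbeGeometry:
    """Clinical-style layout: 8x8 = 64 sources and 8x5 = 40 detectors,
    both centred on the compression axis at 10 mm pitch."""
    return ProbeGeometry(
        source_positions=_centered_grid(*source_grid, pitch=pitch, z=0.0),
        detector_positions=_centered_grid(
            *detector_grid, pitch=pitch, z=slab_thickness
        ),
        slab_thickness=slab_thickness,
        wavelengths=wavelengths,
        modulation_frequency=modulation_frequency,
    )


@dataclass
class RawFrame:
    """Raw complex IQ data, shape (n_sources, n_detectors, n_wavelengths)."""

    iq: np.ndarray
    geometry: ProbeGeometry

    def __post_init__(self) -> None:
        self.iq = np.asarray(self.iq, dtype=complex)
        if self.iq.shape != self.geometry.channel_shape:
            raise ValueError(
                f"iq shape {self.iq.shape} does not match geometry "
                f"{self.geometry.channel_shape}"
            )
        if not np.all(np.isfinite(self.iq)):
            raise ValueError("raw IQ data contain non-finite values")


@dataclass
class ChannelMask:
    """Boolean keep-flag per (source, detector, wavelength) channel."""

    keep: np.ndarray

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_retained(self) -> int:
        return int(self.keep.sum())

    def __and__(self, other: "ChannelMask") -> "ChannelMask":
        return ChannelMask(self.keep & other.keep)


@dataclass
class CalibrationTable:
    """Per-channel correction factors from a homogeneous-phantom exam.

    ``cf_amplitude``/``cf_phase`` are the printed ratio-to-mean forms
    (mean = 1 over each wavelength by construction).  Phase correction is
    *applied* as subtraction of the model-referenced ``phase_offset``
    (radians), because the channel phase errors are additive RF path-length
    offsets; ``cf_phase`` is stored for completeness only.
    ``amplitude_scale`` (one value per wavelength) is the mean
    measured-to-model amplitude ratio of the phantom exam; dividing by
    ``cf_amplitude * amplitude_scale`` expresses amplitudes in the absolute
    units of the homogeneous model (unit source strength).
    """

    cf_amplitude: np.ndarray
    cf_phase: np.ndarray
    phase_offset: np.ndarray
    amplitude_scale: np.ndarray
    phantom_props: tuple

    def __post_init__(self) -> None:
        self.cf_amplitude = np.asarray(self.cf_amplitude, dtype=float)
        self.cf_phase = np.asarray(self.cf_phase, dtype=float)
        self.phase_offset = np.asarray(self.phase_offset, dtype=float)
        self.amplitude_scale = np.asarray(self.amplitude_scale, dtype=float)
        if np.any(self.cf_amplitude <= 0):
            raise ValueError("cf_amplitude must be positive everywhere")

    def to_json(self, path) -> None:
        payload = {
            "cf_amplitude": self.cf_amplitude.tolist(),
            "cf_phase": self.cf_phase.tolist(),
            "phase_offset": self.phase_offset.tolist(),
            "amplitude_scale": self.amplitude_scale.tolist(),
            "phantom_props": [
                {
                    "mu_a": p.mu_a,
                    "mu_s_prime": p.mu_s_prime,
                    "refractive_index": p.refractive_index,
                }
                for p in self.phantom_props
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CalibrationTable":
        with open(path) as fh:
            payload = json.load(fh)
        props = tuple(
            OpticalProperties(p["mu_a"], p["mu_s_prime"], p["refractive_index"])
            for p in payload["phantom_props"]
        )
        return cls(
            cf_amplitude=np.array(payload["cf_amplitude"]),
            cf_phase=np.array(payload["cf_phase"]),
            phase_offset=np.array(payload["phase_offset"]),
            amplitude_scale=np.array(payload["amplitude_scale"]),
            phantom_props=props,
        )


@dataclass
class MeasurementSet:
    """Amplitude / phase-lag arrays with geometry, distances and mask."""

    amplitude: np.ndarray
    phase: np.ndarray
    rho: np.ndarray
    geometry: ProbeGeometry
    mask: ChannelMask = None

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        shape = self.geometry.channel_shape
        if self.amplitude.shape != shape or self.phase.shape != shape:
            raise ValueError("amplitude/phase shape does not match geometry")
        if self.mask is None:
            self.mask = ChannelMask(np.ones(shape, dtype=bool))
        if self.mask.keep.shape != shape:
            raise ValueError("mask shape does not match geometry")
        if np.any(self.amplitude[self.mask.keep] <= 0):
            raise ValueError("retained channels must have positive amplitude")

    def retained(self, wavelength_index: int):
        """(rho, amplitude, phase) 1-D arrays of the retained channels at one
        wavelength, in (source, detector) C order."""
        keep = self.mask.keep[:, :, wavelength_index]
        return (
            self.rho[keep],
            self.amplitude[:, :, wavelength_index][keep],
            self.phase[:, :, wavelength_index][keep],
        )

    def with_mask(self, mask: ChannelMask) -> "MeasurementSet":
        return replace(self, mask=mask)


def unwrap_lag(phase: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Unwrap per-source phase lags cumulatively along increasing rho.

    ``phase`` is (n_sources, n_detectors) wrapped lags; returns the unwrapped
    array (same shape).  Within each source group the channels are sorted by
    distance, unwrapped with numpy, and scattered back.
    """
    out = np.empty_like(phase)
    for s in range(phase.shape[0]):
        order = np.argsort(rho[s], kind="stable")
        out[s, order] = np.unwrap(phase[s, order])
    return out


def iq_to_amplitude_phase(raw: RawFrame) -> MeasurementSet:
    """Convert raw IQ to amplitude and unwrapped phase lag.

    Zero-modulus channels are pre-masked (their amplitude would be invalid
    downstream); this is flagged through the mask, not an exception.
    """
    amplitude = np.abs(raw.iq)
    keep = amplitude > 0.0
    rho = raw.geometry.rho()
    phase = np.zeros_like(amplitude)
    wrapped = np.angle(raw.iq)
    for w in range(raw.geometry.n_wavelengths):
        phase[:, :, w] = unwrap_lag(wrapped[:, :, w], rho)
    phase[~keep] = 0.0
    safe_amp = np.where(keep, amplitude, 1.0)  # placeholder for masked channels
    safe_amp[keep] = amplitude[keep]
    return MeasurementSet(
        amplitude=safe_amp,
        phase=phase,
        rho=rho,
        geometry=raw.geometry,
        mask=ChannelMask(keep),
    )


def _props_per_wavelength(props, n_wavelengths: int) -> tuple:
    if isinstance(props, OpticalProperties):
        return (props,) * n_wavelengths
    props = tuple(props)
    if len(props) != n_wavelengths:
        raise ValueError("need one OpticalProperties per wavelength")
    return props


def homogeneous_channel_model(
    geometry: ProbeGeometry,
    props,
    strength: complex = 1.0,
    n_images: int = 7,
):
    """Analytic homogeneous-slab prediction for every channel.

    Returns (amplitude, lag) arrays of shape (n_sources, n_detectors,
    n_wavelengths).  The isotropic source is embedded one reduced scattering
    length below the source paddle and the extrapolated-boundary image series
    is used (see :func:`fdot.optics.slab_fluence`).
    """
    props = _props_per_wavelength(props, geometry.n_wavelengths)
    rho = geometry.rho()
    amp = np.empty(geometry.channel_shape)
    lag = np.empty(geometry.channel_shape)
    for w, p in enumerate(props):
        robin_a = robin_coefficient(p.refractive_index)
        z0 = 1.0 / p.mu_s_prime
        wrapped = np.empty((geometry.n_sources, geometry.n_detectors))
        for s, spos in enumerate(geometry.source_positions):
            src = np.array([spos[0], spos[1], spos[2] + z0])
            phi = slab_fluence(
                p,
                geometry.omega,
                src,
                geometry.detector_positions,
                geometry.slab_thickness,
                robin_a=robin_a,
                strength=strength,
                n_images=n_images,
            )
            amp[s, :, w] = np.abs(phi)
            wrapped[s] = -np.angle(phi)
        lag[:, :, w] = unwrap_lag(wrapped, rho)
    return amp, lag


def fem_channel_model(
    geometry: ProbeGeometry,
    props,
    lateral_extent=None,
    spacing: float = 2.0,
    rtol: float = 1e-8,
):
    """FEM homogeneous-slab prediction for every channel.

    Same contract as :func:`homogeneous_channel_model` but computed with the
    finite-element solver on a finite slab (optode span plus a 10 mm margin
    per side by default).  Using this as the calibration reference keeps the
    calibrated data in the same geometry family as the reconstruction's
    forward model, so the lateral-boundary factors of peripheral channels
    cancel instead of contaminating the perturbation data.
    """
    from .fem_forward import SlabChannelModel, build_slab_mesh

    props = _props_per_wavelength(props, geometry.n_wavelengths)
    if lateral_extent is None:
        span_x = 2.0 * np.abs(
            np.concatenate([geometry.source_positions[:, 0],
                            geometry.detector_positions[:, 0]])
        ).max()
        span_y = 2.0 * np.abs(
            np.concatenate([geometry.source_positions[:, 1],
                            geometry.detector_positions[:, 1]])
        ).max()
        lateral_extent = (span_x + 20.0, span_y + 20.0)
    mesh = build_slab_mesh(lateral_extent, geometry.slab_thickness, spacing)
    amp = np.empty(geometry.channel_shape)
    lag = np.empty(geometry.channel_shape)
    for w, p in enumerate(props):
        model = SlabChannelModel(mesh, geometry, p)
        ch = model.channels(np.full(mesh.n_nodes, p.mu_a), rtol=rtol)
        amp[:, :, w], lag[:, :, w] = SlabChannelModel.amplitude_lag(ch, geometry)
    return amp, lag


def compute_calibration(
    phantom_frame: RawFrame,
    phantom_props,
    reference: str = "analytic",
    lateral_extent=None,
) -> CalibrationTable:
    """Build per-channel correction factors from a homogeneous-phantom exam.

    Each channel's measured amplitude is divided by the homogeneous-model
    prediction at its own distance first (making channels at different rho
    commensurable), then normalized by the mean over all channels of the same
    wavelength, so mean(cf_amplitude) = 1 per wavelength by construction.

    ``reference`` selects the homogeneous model: "analytic" (image-series
    slab, instantaneous) or "fem" (finite-element slab over ``lateral_extent``
    - the reference to use when the data feed a FEM reconstruction, see
    :func:`fem_channel_model`).
    """
    geometry = phantom_frame.geometry
    props = _props_per_wavelength(phantom_props, geometry.n_wavelengths)
    meas = iq_to_amplitude_phase(phantom_frame)
    if not np.all(meas.mask.keep):
        raise ValueError("calibration phantom data must be clean (no dead channels)")
    if reference == "analytic":
        model_amp, model_lag = homogeneous_channel_model(geometry, props)
    elif reference == "fem":
        model_amp, model_lag = fem_channel_model(
            geometry, props, lateral_extent=lateral_extent
        )
    else:
        raise ValueError("reference must be 'analytic' or 'fem'")
    ratio = meas.amplitude / model_amp
    scale = ratio.mean(axis=(0, 1))
    cf_amplitude = ratio / scale
    offset = meas.phase - model_lag
    mean_phase = meas.phase.mean(axis=(0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        cf_phase = np.where(mean_phase != 0.0, meas.phase / mean_phase, 1.0)
    return CalibrationTable(
        cf_amplitude=cf_amplitude,
        cf_phase=cf_phase,
        phase_offset=offset,
        amplitude_scale=scale,
        phantom_props=props,
    )


def apply_calibration(meas: MeasurementSet, cal: CalibrationTable) -> MeasurementSet:
    """Divide amplitudes by the channel factors and subtract the phase offsets.

    Output amplitudes are in the absolute units of the homogeneous model
    (unit source strength); phases are referenced to the model's lag.
    Idempotent only when the table is all-ones/zero-offset.
    """
    if cal.cf_amplitude.shape != meas.amplitude.shape:
        raise ValueError(
            f"calibration shape {cal.cf_amplitude.shape} does not match "
            f"measurement shape {meas.amplitude.shape}"
        )
    amplitude = meas.amplitude / (cal.cf_amplitude * cal.amplitude_scale)
    phase = meas.phase - cal.phase_offset
    return MeasurementSet(
        amplitude=amplitude,
        phase=phase,
        rho=meas.rho,
        geometry=meas.geometry,
        mask=ChannelMask(meas.mask.keep.copy()),
    )


def select_channels(
    meas: MeasurementSet,
    bulk_guess,
    rel_tolerance: float = 1.0,
    floor: float | None = None,
    center: bool = True,
    reference: str = "analytic",
) -> ChannelMask:
    """Keep channels whose amplitude is plausible under a homogeneous model.

    A channel survives iff ``amplitude >= floor`` and
    ``|ln(amplitude / model_amplitude)| <= rel_tolerance`` with the model
    evaluated at ``bulk_guess``; air-gap-contaminated peripheral channels are
    attenuated by orders of magnitude and fall outside the band.  The default
    floor is 1e-6 times the maximum retained amplitude per wavelength.

    With ``center`` (default) the per-wavelength median of the log-ratio is
    subtracted before thresholding, making the rule invariant to a global
    amplitude scale and robust to a biased ``bulk_guess``; the handful of
    corrupted channels cannot move the median of thousands.

    ``reference`` chooses the homogeneous model ("analytic" or "fem"); use
    the same reference the calibration used, so peripheral-channel boundary
    factors do not masquerade as outliers.
    """
    if rel_tolerance <= 0:
        raise ValueError("rel_tolerance must be positive")
    props = _props_per_wavelength(bulk_guess, meas.geometry.n_wavelengths)
    if reference == "analytic":
        model_amp, _ = homogeneous_channel_model(meas.geometry, props)
    elif reference == "fem":
        model_amp, _ = fem_channel_model(meas.geometry, props)
    else:
        raise ValueError("reference must be 'analytic' or 'fem'")
    keep = meas.mask.keep.copy()
    for w in range(meas.geometry.n_wavelengths):
        amp = meas.amplitude[:, :, w]
        base = keep[:, :, w]
        flo = floor
        if flo is None:
            flo = 1e-6 * amp[base].max() if base.any() else 0.0
        with np.errstate(divide="ignore"):
            logratio = np.log(np.where(amp > 0, amp, np.nan) / model_amp[:, :, w])
        if center and base.any():
            logratio = logratio - np.nanmedian(logratio[base])
        ok = base & (amp >= flo) & (np.abs(logratio) <= rel_tolerance)
        keep[:, :, w] = ok
    if not keep.any():
        raise ValueError(
            "all channels rejected; loosen rel_tolerance or lower the floor"
        )
    return ChannelMask(keep)


# ---------------------------------------------------------------------------
# IO: HDF5 container, CSV import
# ---------------------------------------------------------------------------


def _write_geometry(group: h5py.Group, geometry: ProbeGeometry) -> None:
    group.create_dataset("source_positions", data=geometry.source_positions)
    group.create_dataset("detector_positions", data=geometry.detector_positions)
    group.attrs["slab_thickness"] = geometry.slab_thickness
    group.create_dataset("wavelengths", data=np.asarray(geometry.wavelengths))
    group.attrs["modulation_frequency"] = geometry.modulation_frequency


def _read_geometry(group: h5py.Group) -> ProbeGeometry:
    return ProbeGeometry(
        source_positions=group["source_positions"][()],
        detector_positions=group["detector_positions"][()],
        slab_thickness=float(group.attrs["slab_thickness"]),
        wavelengths=tuple(group["wavelengths"][()]),
        modulation_frequency=float(group.attrs["modulation_frequency"]),
    )


def save_raw_frame(path, frame: RawFrame, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        _write_geometry(fh.create_group("geometry"), frame.geometry)
        fh.create_dataset("raw_iq", data=frame.iq)
        mg = fh.create_group("meta")
        for key, val in (meta or {}).items():
            mg.attrs[key] = val


def load_raw_frame(path) -> RawFrame:
    with h5py.File(path, "r") as fh:
        geometry = _read_geometry(fh["geometry"])
        iq = fh["raw_iq"][()]
    return RawFrame(iq=iq, geometry=geometry)


def read_raw_csv(path, geometry: ProbeGeometry) -> RawFrame:
    """CSV import: columns source, detector, wavelength_nm, I, Q (one row per
    channel).  Source/detector are 0-based indices into the geometry."""
    df = pd.read_csv(path)
    iq = np.zeros(geometry.channel_shape, dtype=complex)
    wl_index = {w: i for i, w in enumerate(geometry.wavelengths)}
    for row in df.itertuples(index=False):
        w = wl_index[float(row.wavelength_nm)]
        iq[int(row.source), int(row.detector), w] = row.I + 1j * row.Q
    return RawFrame(iq=iq, geometry=geometry)


def save_measurement_set(path, meas: MeasurementSet) -> None:
    with h5py.File(path, "w") as fh:
        _write_geometry(fh.create_group("geometry"), meas.geometry)
        fh.create_dataset("amplitude", data=meas.amplitude)
        fh.create_dataset("phase", data=meas.phase)
        fh.create_dataset("rho", data=meas.rho)
        fh.create_dataset("mask", data=meas.mask.keep)


def load_measurement_set(path) -> MeasurementSet:
    with h5py.File(path, "r") as fh:
        geometry = _read_geometry(fh["geometry"])
        amplitude = fh["amplitude"][()]
        phase = fh["phase"][()]
        rho = fh["rho"][()]
        mask = ChannelMask(fh["mask"][()])
    return MeasurementSet(
        amplitude=amplitude, phase=phase, rho=rho, geometry=geometry, mask=mask
    )
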