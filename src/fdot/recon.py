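"""Dual-mesh Levenberg-Marquardt reconstruction of absorption maps.

The inverse problem is posed in the Rytov form: with ``Phi = Phi0 exp(Phi_sca^R)``,
the data vector per retained channel is ``[ln(amp_meas/amp_model);
lag_meas - lag_model]`` - the real and negated-imaginary parts of
``ln(Phi/Phi0)`` under this package's lag convention.  Absorption is
represented on a coarse mesh (default 5 mm) and interpolated onto the fine
forward mesh (default 2 mm) for every solve; each accepted LM step divides
the damping parameter, each rejected step multiplies it, and the iteration
stops when the relative image update is marginal.

The Jacobian is the exact derivative of the discrete Galerkin system:
``d(ln Phi_ch)/d(mu_j) = -(Phi_d^T dK/dmu_j Phi_s) / Phi_ch`` with the
consistent third-order barycentric integrals of ``dK/dmu_j``, restricted to
the coarse basis.  That is why it matches finite differences to
finite-difference truncation error rather than to a quadrature error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import bulk_fit
from .fem_forward import (
    Mesh,
    SlabChannelModel,
    build_slab_mesh,
    interpolation_matrix,
)
from .measurement import MeasurementSet
from .optics import OpticalProperties

__all__ = [
    "RytovData",
    "ReconSettings",
    "Jacobian",
    "ReconResult",
    "compute_rytov_data",
    "compute_jacobian",
    "lm_step",
    "reconstruct",
    "absorption_peak_centroid",
]

MU_A_IMAGE_BOUNDS = (1e-4, 0.1)


@dataclass
class RytovData:
    """Stacked data vector: first the log-amplitude ratios, then the phase
    differences, over the retained channels (length 2 * n_channels)."""

    vector: np.ndarray
    n_channels: int

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if len(self.vector) != 2 * self.n_channels:
            raise ValueError("Rytov vector length must be 2 * n_channels")
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("Rytov data contain non-finite values")

    @property
    def log_amplitude(self) -> np.ndarray:
        return self.vector[: self.n_channels]

    @property
    def phase(self) -> np.ndarray:
        return self.vector[self.n_channels:]


@dataclass(frozen=True)
class ReconSettings:
    """Levenberg-Marquardt and dual-mesh configuration.

    lambda_init scales the regularized normal matrix diagonal; classic LM
    schedule (divide by ``lambda_decrease`` on accept, multiply by
    ``lambda_increase`` on reject).  ``stop_tolerance`` is the relative
    image-update norm considered marginal.  ``solver_rtol`` is the inner
    linear-solve tolerance used during the iteration.
    """

    lambda_init: float = 10.0
    lambda_decrease: float = 10.0
    lambda_increase: float = 10.0
    max_iterations: int = 20
    stop_tolerance: float = 0.02
    #: Second reading of "updates considered marginal": stop after an
    #: accepted step whose relative projection-error improvement falls below
    #: this fraction.
    stop_improvement: float = 0.01
    fine_spacing: float = 2.0
    coarse_spacing: float = 5.0
    reconstruct_scattering: bool = False
    #: Reference-fitting of the Rytov data at initialization: None,
    #: "constant" (remove the mean log-amplitude / phase residual - the
    #: unknown global source scale) or "linear" (additionally remove a
    #: linear-in-rho trend; aggressive - distance trends also carry
    #: perturbation signal).  Fitted once at the bulk initialization and
    #: then held fixed.
    detrend: str | None = "constant"
    solver_rtol: float = 1e-7
    mu_a_bounds: tuple = MU_A_IMAGE_BOUNDS
    #: Physical lateral extent (mm) of the reconstruction slab; defaults to
    #: the optode span plus a 10 mm margin per side when None.  Set it to the
    #: compressed-breast footprint when known.
    lateral_extent: tuple | None = None
    #: Floor for the sensitivity normalization, as a fraction of the largest
    #: column norm (columns weaker than this are not amplified further).
    sensitivity_floor: float = 0.1
    #: Reconstruct only coarse nodes inside the sensing aperture - the
    #: intersection of the source and detector lateral footprints dilated by
    #: one coarse spacing - freezing the rest at the bulk initialization.
    #: Off by default: freezing merely moves the weakly-determined boundary
    #: (and its residual artifacts) inward; prefer reading the image inside
    #: the aperture instead (see fdot.fusion.hotspot_centroid).
    restrict_support: bool = False
    #: Recompute the Jacobian every this many accepted steps (1 = classic
    #: LM).  The adjoint Jacobian is the dominant cost per iteration and
    #: varies slowly between iterates; a delayed refresh trades a few extra
    #: cheap iterations for skipping most of the expensive ones.
    jacobian_refresh: int = 3

    def __post_init__(self) -> None:
        if self.lambda_init <= 0 or self.stop_tolerance <= 0:
            raise ValueError("lambda_init and stop_tolerance must be positive")
        if self.coarse_spacing < self.fine_spacing:
            raise ValueError("coarse_spacing must be >= fine_spacing")
        if self.detrend not in (None, "constant", "linear"):
            raise ValueError("detrend must be None, 'constant' or 'linear'")
        if self.reconstruct_scattering:
            raise NotImplementedError(
                "scattering reconstruction is not implemented; this geometry "
                "determines it too weakly (absorption-only is the default)"
            )


@dataclass
class Jacobian:
    """Real-stacked sensitivity matrix (2 * n_channels, n_coarse_nodes):
    log-amplitude rows first, then phase rows, in mm per unit mu_a."""

    matrix: np.ndarray
    n_channels: int

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != 2 * self.n_channels:
            raise ValueError("Jacobian row count must be 2 * n_channels")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("Jacobian contains non-finite values")


@dataclass
class ReconResult:
    """Per-wavelength coarse-mesh absorption images with iteration logs."""

    mu_a_images: np.ndarray  # (n_wavelengths, n_coarse_nodes)
    coarse_mesh: Mesh
    fine_mesh: Mesh
    bulk: list
    logs: list  # one DataFrame per wavelength
    settings: ReconSettings

    def log(self, wavelength_index: int = 0) -> pd.DataFrame:
        return self.logs[wavelength_index]


def compute_rytov_data(
    meas: MeasurementSet,
    model_amplitude: np.ndarray,
    model_phase: np.ndarray,
    wavelength_index: int = 0,
) -> RytovData:
    """Log-amplitude ratio and phase difference over retained channels.

    ``model_amplitude``/``model_phase`` are (n_sources, n_detectors) channel
    predictions of the current (initially homogeneous-bulk) model.
    """
    keep = meas.mask.keep[:, :, wavelength_index]
    amp = meas.amplitude[:, :, wavelength_index][keep]
    lag = meas.phase[:, :, wavelength_index][keep]
    m_amp = np.asarray(model_amplitude)[keep]
    m_lag = np.asarray(model_phase)[keep]
    if np.any(amp <= 0):
        raise ValueError("retained channels contain non-positive amplitudes")
    if np.any(m_amp <= 0):
        raise ValueError("model amplitudes must be positive")
    return RytovData(
        vector=np.concatenate([np.log(amp / m_amp), lag - m_lag]),
        n_channels=int(keep.sum()),
    )


class _JacobianWorkspace:
    """Mesh-dependent constants reused across Jacobian evaluations."""

    def __init__(self, fine_mesh: Mesh, prolong: sp.csr_matrix):
        vol, _ = fine_mesh.element_geometry()
        elems = fine_mesh.elements
        m = len(elems)
        n = fine_mesh.n_nodes
        rows = elems.reshape(-1)
        cols = np.repeat(np.arange(m), 4)
        w = np.repeat(vol / 120.0, 4)
        # node <- element scatter weighted by V/120
        self.scatter = sp.csr_matrix((w, (rows, cols)), shape=(n, m)).astype(
            np.float32
        )
        self.elements = elems
        self.w2 = np.asarray(self.scatter @ np.ones(m, dtype=np.float32))
        self.restrict32 = prolong.T.tocsr().astype(np.float32)


def _complex_log_jacobian(
    ws: _JacobianWorkspace,
    phi_s: np.ndarray,
    phi_d: np.ndarray,
    channels: np.ndarray,
) -> np.ndarray:
    """(n_sources, n_detectors, n_coarse) complex d(ln Phi_ch)/d(mu_coarse).

    Element-exact accumulation of -(Phi_d^T dK/dmu_j Phi_s) restricted to
    the coarse basis; single-precision intermediates (the 2% validation
    tolerance is far above float32 resolution).
    """
    elems = ws.elements
    ns = phi_s.shape[1]
    nd = phi_d.shape[1]
    nc = ws.restrict32.shape[0]
    ps32 = phi_s.astype(np.complex64)
    pd32 = phi_d.astype(np.complex64)
    vd = [pd32[elems[:, a], :] for a in range(4)]  # 4 x (m, nd)
    sv = vd[0] + vd[1] + vd[2] + vd[3]
    wsv = np.asarray(ws.scatter @ sv)  # (n, nd)
    out = np.empty((ns, nd, nc), dtype=np.complex64)
    for s in range(ns):
        u = ps32[:, s]
        ue = [u[elems[:, a]] for a in range(4)]
        su = ue[0] + ue[1] + ue[2] + ue[3]
        duv = ue[0][:, None] * vd[0]
        for a in range(1, 4):
            duv += ue[a][:, None] * vd[a]
        shared = su[:, None] * sv + duv
        jf = np.asarray(ws.scatter @ shared)  # terms 1 + 4
        jf += pd32 * np.asarray(ws.scatter @ su)[:, None]  # term 2
        jf += u[:, None] * wsv  # term 3
        jf += 2.0 * ws.w2[:, None] * u[:, None] * pd32  # term 5
        out[s] = (ws.restrict32 @ jf).T
    out /= -channels.astype(np.complex64)[:, :, None]
    return out


def compute_jacobian(
    fine_mesh: Mesh,
    phi_sources: np.ndarray,
    phi_detectors: np.ndarray,
    channels: np.ndarray,
    keep: np.ndarray,
    prolong: sp.csr_matrix,
    workspace: _JacobianWorkspace | None = None,
) -> Jacobian:
    """Rytov-scaled adjoint sensitivity of the retained channels to the
    coarse-mesh absorption image.

    phi_sources / phi_detectors are (n_nodes, n_sources/n_detectors) fields
    of the same forward solve; ``channels`` the complex channel matrix;
    ``keep`` the (n_sources, n_detectors) retained-channel mask; ``prolong``
    the coarse-to-fine interpolation matrix.  Row order matches
    :class:`RytovData`: log-amplitude block then phase block.
    """
    if prolong.shape[0] != fine_mesh.n_nodes:
        raise ValueError("prolongation matrix does not match the fine mesh")
    ws = workspace or _JacobianWorkspace(fine_mesh, prolong)
    jc = _complex_log_jacobian(ws, phi_sources, phi_detectors, channels)
    jck = jc[keep]  # (n_channels, n_coarse)
    # lag = -Im ln(Phi): phase rows get the negated imaginary part
    mat = np.concatenate([jck.real, -jck.imag]).astype(float)
    return Jacobian(matrix=mat, n_channels=int(keep.sum()))


class _NormalEquations:
    """Cached J^T J / J^T r for repeated lm_step calls at varying lambda."""

    def __init__(self, jac: Jacobian, residual: np.ndarray):
        j = jac.matrix
        self.jtj = j.T @ j
        self.jtr = j.T @ residual
        self.diag_max = float(self.jtj.diagonal().max())


def lm_step(
    jac: Jacobian,
    residual,
    lam: float,
    normal: _NormalEquations | None = None,
) -> np.ndarray:
    """Solve (J^T J + lambda * max(diag(J^T J)) I) delta = J^T r."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    r = residual.vector if isinstance(residual, RytovData) else np.asarray(residual)
    ne = normal or _NormalEquations(jac, r)
    n = ne.jtj.shape[0]
    a = ne.jtj + lam * max(ne.diag_max, np.finfo(float).tiny) * np.eye(n)
    try:
        return np.linalg.solve(a, ne.jtr)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("normal matrix singular even with damping") from exc


class ReconstructionError(RuntimeError):
    """Forward failure mid-iteration; carries the log so far."""

    def __init__(self, message: str, log=None):
        super().__init__(message)
        self.log = log


def _reconstruct_wavelength(
    meas: MeasurementSet,
    w: int,
    bulk: OpticalProperties,
    settings: ReconSettings,
    fine_mesh: Mesh,
    coarse_mesh: Mesh,
    prolong: sp.csr_matrix,
    workspace: _JacobianWorkspace,
):
    geometry = meas.geometry
    keep = meas.mask.keep[:, :, w]
    amp = meas.amplitude[:, :, w][keep]
    lag = meas.phase[:, :, w][keep]
    if np.any(amp <= 0):
        raise ValueError("retained channels contain non-positive amplitudes")
    model = SlabChannelModel(fine_mesh, geometry, bulk)
    lo, hi = settings.mu_a_bounds
    mu_c = np.full(coarse_mesh.n_nodes, np.clip(bulk.mu_a, lo, hi))
    rtol = settings.solver_rtol
    rho = geometry.rho()

    def model_channels(mu_c_vec, with_fields=False):
        mu_f = np.asarray(prolong @ mu_c_vec)
        try:
            if with_fields:
                phi_s, phi_d, ch = model.fields_and_channels(mu_f, rtol=rtol)
            else:
                ch = model.channels(mu_f, rtol=rtol)
                phi_s = phi_d = None
        except Exception as exc:  # pragma: no cover - solver failure path
            raise ReconstructionError(f"forward solve failed: {exc}", log) from exc
        m_amp, m_lag = SlabChannelModel.amplitude_lag(ch, geometry)
        return phi_s, phi_d, ch, m_amp[keep], m_lag[keep]

    log = []

    def residual_from(m_amp_k, m_lag_k, off):
        return np.concatenate(
            [np.log(amp / m_amp_k) - off[0], lag - m_lag_k - off[1]]
        )

    if settings.restrict_support:
        margin = settings.coarse_spacing
        src_xy = geometry.source_positions[:, :2]
        det_xy = geometry.detector_positions[:, :2]
        lim = [
            (max(src_xy[:, d].min(), det_xy[:, d].min()) - margin,
             min(src_xy[:, d].max(), det_xy[:, d].max()) + margin)
            for d in (0, 1)
        ]
        free = np.where(
            (coarse_mesh.nodes[:, 0] >= lim[0][0])
            & (coarse_mesh.nodes[:, 0] <= lim[0][1])
            & (coarse_mesh.nodes[:, 1] >= lim[1][0])
            & (coarse_mesh.nodes[:, 1] <= lim[1][1])
        )[0]
    else:
        free = np.arange(coarse_mesh.n_nodes)

    def scaled_jacobian(jac):
        # sensitivity normalization: weak (deep) columns are rescaled so the
        # uniform LM damping does not push all of the update into the
        # high-sensitivity nodes under the optodes; only aperture columns
        # are solved for
        sub = jac.matrix[:, free]
        norms = np.linalg.norm(sub, axis=0)
        scale = 1.0 / np.maximum(norms, settings.sensitivity_floor * norms.max())
        return Jacobian(sub * scale[None, :], jac.n_channels), scale

    phi_s, phi_d, ch, m_amp_k, m_lag_k = model_channels(mu_c, with_fields=True)
    offsets = (0.0, 0.0)
    if settings.detrend is not None:
        rho_k = rho[keep]
        basis = np.ones((len(rho_k), 1))
        if settings.detrend == "linear":
            basis = np.column_stack([basis[:, 0], rho_k - rho_k.mean()])
        raw_a = np.log(amp / m_amp_k)
        raw_p = lag - m_lag_k
        coef_a, *_ = np.linalg.lstsq(basis, raw_a, rcond=None)
        coef_p, *_ = np.linalg.lstsq(basis, raw_p, rcond=None)
        offsets = (basis @ coef_a, basis @ coef_p)
    r = residual_from(m_amp_k, m_lag_k, offsets)
    err = float(np.linalg.norm(r))
    lam = settings.lambda_init
    n_accepted = 0
    jac = compute_jacobian(fine_mesh, phi_s, phi_d, ch, keep, prolong, workspace)
    jac_s, scale = scaled_jacobian(jac)
    normal = _NormalEquations(jac_s, r)
    log.append(
        dict(iteration=0, projection_error=err, lam=lam, update_norm=0.0,
             accepted=True)
    )
    for it in range(1, settings.max_iterations + 1):
        delta = np.zeros_like(mu_c)
        delta[free] = scale * lm_step(jac_s, r, lam, normal=normal)
        cand = np.clip(mu_c + delta, lo, hi)
        upd = float(np.linalg.norm(cand - mu_c) / np.linalg.norm(mu_c))
        _, _, ch_c, m_amp_c, m_lag_c = model_channels(cand)
        r_c = residual_from(m_amp_c, m_lag_c, offsets)
        err_c = float(np.linalg.norm(r_c))
        accepted = err_c < err
        log.append(
            dict(iteration=it, projection_error=err_c if accepted else err,
                 lam=lam, update_norm=upd, accepted=accepted)
        )
        if accepted:
            improvement = (err - err_c) / err
            mu_c, r, err = cand, r_c, err_c
            n_accepted += 1
            lam = max(lam / settings.lambda_decrease, 1e-12)
            if upd < settings.stop_tolerance:
                break
            if improvement < settings.stop_improvement:
                break
            if n_accepted % settings.jacobian_refresh == 0:
                phi_s, phi_d, ch, m_amp_k, m_lag_k = model_channels(
                    mu_c, with_fields=True
                )
                jac = compute_jacobian(
                    fine_mesh, phi_s, phi_d, ch, keep, prolong, workspace
                )
                jac_s, scale = scaled_jacobian(jac)
            normal = _NormalEquations(jac_s, r)
        else:
            lam = lam * settings.lambda_increase
            if lam > 1e12:
                break
    return mu_c, pd.DataFrame(log)


def reconstruct(
    meas: MeasurementSet,
    settings: ReconSettings | None = None,
    bulk=None,
    provenance_spacing: float | None = None,
    allow_inverse_crime: bool = False,
    wavelength_indices=None,
) -> ReconResult:
    """Levenberg-Marquardt absorption reconstruction, one wavelength at a time.

    ``meas`` must be calibrated and masked; ``bulk`` (one
    :class:`OpticalProperties` per wavelength) defaults to
    :func:`fdot.bulk_fit.estimate_bulk_all` on the data.  When the data come
    from the simulator, pass its ``mesh_spacing`` as ``provenance_spacing``:
    data generated on a mesh as fine as the reconstruction mesh are refused
    unless ``allow_inverse_crime`` is set.
    """
    settings = settings or ReconSettings()
    if (
        provenance_spacing is not None
        and abs(provenance_spacing - settings.fine_spacing) < 1e-9
        and not allow_inverse_crime
    ):
        raise ValueError(
            "inverse crime: data were simulated on a mesh with the same "
            "spacing as the reconstruction fine mesh; pass "
            "allow_inverse_crime=True to override"
        )
    geometry = meas.geometry
    if wavelength_indices is None:
        wavelength_indices = range(geometry.n_wavelengths)
    wavelength_indices = list(wavelength_indices)
    if bulk is None:
        # slab-geometry slope matching: unbiased on parallel-plate data
        bulk = bulk_fit.estimate_bulk_slab_all(meas)
    elif isinstance(bulk, OpticalProperties):
        bulk = [bulk] * geometry.n_wavelengths
    if settings.lateral_extent is not None:
        extent = tuple(settings.lateral_extent)
    else:
        span_x = 2.0 * np.abs(
            np.concatenate([geometry.source_positions[:, 0],
                            geometry.detector_positions[:, 0]])
        ).max()
        span_y = 2.0 * np.abs(
            np.concatenate([geometry.source_positions[:, 1],
                            geometry.detector_positions[:, 1]])
        ).max()
        extent = (span_x + 20.0, span_y + 20.0)
    fine_mesh = build_slab_mesh(extent, geometry.slab_thickness,
                                settings.fine_spacing)
    coarse_mesh = build_slab_mesh(extent, geometry.slab_thickness,
                                  settings.coarse_spacing)
    prolong = interpolation_matrix(coarse_mesh, fine_mesh)
    workspace = _JacobianWorkspace(fine_mesh, prolong)
    images = np.empty((len(wavelength_indices), coarse_mesh.n_nodes))
    logs = []
    for i, w in enumerate(wavelength_indices):
        mu_c, logdf = _reconstruct_wavelength(
            meas, w, bulk[w], settings, fine_mesh, coarse_mesh, prolong,
            workspace,
        )
        images[i] = mu_c
        logs.append(logdf)
    return ReconResult(
        mu_a_images=images,
        coarse_mesh=coarse_mesh,
        fine_mesh=fine_mesh,
        bulk=[bulk[w] for w in wavelength_indices],
        logs=logs,
        settings=settings,
    )


def absorption_peak_centroid(
    result: ReconResult,
    wavelength_index: int = 0,
    threshold: float = 0.5,
):
    """Centroid (mm) of the above-half-maximum absorption excess.

    The image background is taken as the median nodal value (robust to a
    biased bulk initialization).  Returns (centroid (3,), peak_mu_a,
    background_mu_a).
    """
    img = result.mu_a_images[wavelength_index]
    background = float(np.median(img))
    excess = img - background
    peak = float(excess.max())
    if peak <= 0:
        raise ValueError("image contains no absorption excess above background")
    sel = excess >= threshold * peak
    wgt = excess[sel]
    centroid = (result.coarse_mesh.nodes[sel] * wgt[:, None]).sum(0) / wgt.sum()
    return centroid, float(img.max()), background
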