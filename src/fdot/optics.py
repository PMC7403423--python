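"""Shared optical-physics primitives.

Units used throughout the package: lengths in mm, absorption ``mu_a`` and
reduced scattering ``mu_s_prime`` in mm^-1, angular modulation frequency
``omega`` in rad/s, speed of light in mm/s.

Sign convention: fields follow the frequency-domain diffusion equation

    -div(kappa grad Phi) + (mu_a + i omega / c_m) Phi = q0,

whose homogeneous-medium Green's function is ``exp(-k r) / (4 pi kappa r)``
with ``k = sqrt((mu_a + i omega/c_m) / kappa)`` (Re k > 0, Im k > 0).  The
instrument-facing *phase* is the demodulated lag ``theta = -arg(Phi)``, which
grows linearly with distance at slope +Im(k); all channel data in this package
store that lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "C_VACUUM_MM_S",
    "OpticalProperties",
    "complex_wavenumber",
    "effective_reflection",
    "robin_coefficient",
    "analytic_fluence",
    "slab_fluence",
]

#: Speed of light in vacuum, mm/s.
C_VACUUM_MM_S = 2.998e11


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption / reduced-scattering pair with derived diffusion quantities.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1.  Must be positive.
    mu_s_prime : float
        Reduced scattering coefficient, mm^-1.  Must be positive.
    refractive_index : float
        Tissue refractive index (default 1.4); sets the in-medium speed of
        light and the Robin boundary impedance.
    """

    mu_a: float
    mu_s_prime: float
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        if not (self.mu_a > 0 and np.isfinite(self.mu_a)):
            raise ValueError(f"mu_a must be positive and finite, got {self.mu_a}")
        if not (self.mu_s_prime > 0 and np.isfinite(self.mu_s_prime)):
            raise ValueError(
                f"mu_s_prime must be positive and finite, got {self.mu_s_prime}"
            )
        if not self.refractive_index >= 1.0:
            raise ValueError("refractive_index must be >= 1")
        if self.mu_s_prime < 10.0 * self.mu_a:
            warnings.warn(
                "mu_s_prime < 10 * mu_a: diffusion approximation is questionable",
                stacklevel=2,
            )

    @property
    def kappa(self) -> float:
        """Diffusion coefficient kappa = 1 / (3 (mu_a + mu_s')), mm."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))

    @property
    def c_medium(self) -> float:
        """Speed of light in the medium, mm/s."""
        return C_VACUUM_MM_S / self.refractive_index


def complex_wavenumber(props: OpticalProperties, omega: float) -> complex:
    """Complex attenuation wavenumber k = sqrt((mu_a + i omega/c_m)/kappa).

    The principal square root is taken, so Re(k) > 0 and Im(k) >= 0 for
    omega >= 0.  -Re(k) is the slope of ln(rho*Phi) versus rho in an infinite
    medium and +Im(k) the slope of the phase lag.
    """
    return complex(
        np.sqrt((props.mu_a + 1j * omega / props.c_medium) / props.kappa)
    )


def effective_reflection(refractive_index: float) -> float:
    """Effective internal reflection coefficient R_eff for a tissue-air boundary.

    Groenhuis polynomial fit in the refractive-index mismatch; R_eff = 0 for a
    matched boundary.
    """
    n = refractive_index
    if n == 1.0:
        return 0.0
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


def robin_coefficient(refractive_index: float) -> float:
    """Robin boundary impedance factor A = (1 + R_eff) / (1 - R_eff)."""
    r = effective_reflection(refractive_index)
    return (1.0 + r) / (1.0 - r)


def analytic_fluence(
    props: OpticalProperties,
    omega: float,
    source_pos,
    eval_pos,
    strength: complex = 1.0,
) -> np.ndarray | complex:
    """Infinite-medium frequency-domain Green's function.

    Phi = S exp(-k r) / (4 pi kappa r) with r = |eval - source|.  Accepts a
    single evaluation point or an (n, 3) array; r = 0 raises.
    """
    source = np.asarray(source_pos, dtype=float)
    pts = np.asarray(eval_pos, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    r = np.linalg.norm(pts - source, axis=1)
    if np.any(r == 0.0):
        raise ValueError("evaluation point coincides with the source (r = 0)")
    k = complex_wavenumber(props, omega)
    phi = strength * np.exp(-k * r) / (4.0 * np.pi * props.kappa * r)
    return complex(phi[0]) if single else phi


def slab_fluence(
    props: OpticalProperties,
    omega: float,
    source_pos,
    eval_pos,
    thickness: float,
    robin_a: float | None = None,
    strength: complex = 1.0,
    n_images: int = 7,
) -> np.ndarray | complex:
    """Homogeneous-slab fluence via the extrapolated-boundary image series.

    The slab occupies 0 <= z <= thickness; ``source_pos`` is the physical
    position of the isotropic source (already embedded at its scattering
    depth).  Extrapolated boundaries sit at z = -z_b and z = thickness + z_b
    with z_b = 2 A kappa, and the standard alternating image-source series is
    summed over ``n_images`` reflections on each side.

    This closed form is the homogeneous reference model used for calibration
    and channel selection; it agrees with the Robin-BC FEM solution to the
    accuracy of the extrapolated-boundary approximation (a few percent).
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    source = np.asarray(source_pos, dtype=float)
    pts = np.atleast_2d(np.asarray(eval_pos, dtype=float))
    single = np.asarray(eval_pos).ndim == 1
    if robin_a is None:
        robin_a = robin_coefficient(props.refractive_index)
    zb = 2.0 * robin_a * props.kappa
    period = 2.0 * (thickness + 2.0 * zb)
    z0 = source[2]
    k = complex_wavenumber(props, omega)
    lateral2 = np.sum((pts[:, :2] - source[:2]) ** 2, axis=1)
    phi = np.zeros(len(pts), dtype=complex)
    for m in range(-n_images, n_images + 1):
        z_plus = m * period + z0
        z_minus = m * period - 2.0 * zb - z0
        for z_img, sign in ((z_plus, 1.0), (z_minus, -1.0)):
            r = np.sqrt(lateral2 + (pts[:, 2] - z_img) ** 2)
            if np.any(r == 0.0):
                raise ValueError("evaluation point coincides with an image source")
            phi += sign * np.exp(-k * r) / r
    phi *= strength / (4.0 * np.pi * props.kappa)
    return complex(phi[0]) if single else phi
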