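"""Closed-form solutions for a homogeneous semi-infinite medium.

These are the standard diffusion-theory Green's functions used throughout
diffuse optics: continuous-wave / frequency-domain fluence, time-resolved
fluence and reflectance, and the diffuse-correlation (DCS) field
autocorrelation obtained by the absorption substitution
``mua -> mua + 2*alphaDb*musp*k0**2*tau``.

Three boundary treatments are supported:

``zbc``
    Zero boundary condition: the fluence vanishes on the physical surface
    (image source mirrored about z=0).
``ebc``
    Extrapolated boundary condition: the fluence vanishes on a plane a
    distance ``zb = 2*beta*kappa`` above the surface.
``pcb``
    Partial-current boundary: the exact Robin condition, which adds a
    continuous line-image integral to the two point images.

The boundary-reflection parameter ``beta`` encodes the refractive-index
mismatch at the tissue-air interface and can be computed three ways
(exact Fresnel integrals, a two-step Fresnel approximation, or Groenhuis's
empirical polynomial).

Geometry convention: the medium occupies z >= 0; the isotropic source sits
at depth ``z0 = 1/(mua + musp)``; ``rho`` is the radial source-detector
distance on the surface.  All lengths in mm, times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.special import erfcx

#: speed of light in vacuum, mm/s
C_VACUUM = 2.99792458e11

_BETA_METHODS = ("fresnel_exact", "fresnel_approx", "groenhuis")
_BC_KINDS = ("zbc", "ebc", "pcb")


def _fresnel_unpolarized(cos_t: np.ndarray, n_in: float, n_out: float) -> np.ndarray:
    """Unpolarized Fresnel reflection coefficient for internal incidence.

    Beyond the critical angle (n_in > n_out) the reflection is total.
    """
    cos_t = np.asarray(cos_t, dtype=float)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    sin_tp = n_in / n_out * sin_t
    total = sin_tp >= 1.0
    sin_tp = np.clip(sin_tp, 0.0, 1.0)
    cos_tp = np.sqrt(1.0 - sin_tp**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_s = (n_in * cos_t - n_out * cos_tp) / (n_in * cos_t + n_out * cos_tp)
        r_p = (n_in * cos_tp - n_out * cos_t) / (n_in * cos_tp + n_out * cos_t)
    rf = 0.5 * (r_p**2 + r_s**2)
    return np.where(total, 1.0, rf)


def boundary_beta(n_in: float, n_out: float = 1.0, method: str = "groenhuis") -> float:
    """Boundary-reflection parameter ``beta`` of the Robin condition.

    Parameters
    ----------
    n_in, n_out:
        Refractive indices inside the medium and of the surrounding
        (typically air, 1.0).
    method:
        ``"fresnel_exact"`` evaluates the angular Fresnel integrals
        R_phi = int 2 sin(t) cos(t) RF(t) dt and
        R_j = int 3 sin(t) cos^2(t) RF(t) dt over [0, pi/2] and forms
        Reff = (R_phi + R_j) / (2 - R_phi + R_j), beta = (1+Reff)/(1-Reff).
        ``"fresnel_approx"`` uses the two-step approximation
        beta = (2/(1-R0) - 1 + |cos tc|^3) / (1 - |cos tc|^2) with
        R0 = ((n-nout)/(n+nout))^2 and tc the critical angle (cos tc = 0
        when n_in <= n_out, i.e. no total internal reflection).
        ``"groenhuis"`` uses the empirical polynomial in nrel = n_in/n_out:
        Reff = -1.440 nrel^-2 + 0.710 nrel^-1 + 0.668 + 0.0636 nrel.
    """
    if n_in < 1.0 or n_out < 1.0:
        raise ValueError("refractive indices must be >= 1")
    if method == "groenhuis":
        nrel = n_in / n_out
        reff = -1.440 * nrel**-2 + 0.710 / nrel + 0.668 + 0.0636 * nrel
        return (1.0 + reff) / (1.0 - reff)
    if method == "fresnel_approx":
        r0 = ((n_in - n_out) / (n_in + n_out)) ** 2
        if n_in > n_out:
            cos_tc = np.sqrt(1.0 - (n_out / n_in) ** 2)
        else:
            cos_tc = 0.0
        return (2.0 / (1.0 - r0) - 1.0 + abs(cos_tc) ** 3) / (1.0 - cos_tc**2)
    if method == "fresnel_exact":
        def f_phi(theta: float) -> float:
            return 2.0 * np.sin(theta) * np.cos(theta) * float(
                _fresnel_unpolarized(np.cos(theta), n_in, n_out))

        def f_j(theta: float) -> float:
            return 3.0 * np.sin(theta) * np.cos(theta) ** 2 * float(
                _fresnel_unpolarized(np.cos(theta), n_in, n_out))

        r_phi, _ = integrate.quad(f_phi, 0.0, np.pi / 2, epsabs=1e-8, limit=200)
        r_j, _ = integrate.quad(f_j, 0.0, np.pi / 2, epsabs=1e-8, limit=200)
        reff = (r_phi + r_j) / (2.0 - r_phi + r_j)
        return (1.0 + reff) / (1.0 - reff)
    raise ValueError(f"unknown beta method {method!r}; use one of {_BETA_METHODS}")


@dataclass
class SemiInfiniteSetup:
    """Optical and geometric parameters of a semi-infinite problem.

    Attributes
    ----------
    mua, musp:
        Absorption and reduced scattering coefficients, mm^-1.
    ri_in, ri_out:
        Refractive index of the medium and of the outside.
    bc_kind:
        ``zbc`` | ``ebc`` | ``pcb``.
    beta_method:
        How ``beta`` is computed; see :func:`boundary_beta`.
    """

    mua: float
    musp: float
    ri_in: float = 1.33
    ri_out: float = 1.0
    bc_kind: str = "ebc"
    beta_method: str = "groenhuis"
    _beta: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mua <= 0 or self.musp <= 0:
            raise ValueError("mua and musp must be positive")
        if self.bc_kind not in _BC_KINDS:
            raise ValueError(f"bc_kind must be one of {_BC_KINDS}")

    @property
    def kappa(self) -> float:
        """Diffusion coefficient kappa = 1/(3(mua+musp)), mm."""
        return 1.0 / (3.0 * (self.mua + self.musp))

    @property
    def c(self) -> float:
        """Speed of light in the medium, mm/s."""
        return C_VACUUM / self.ri_in

    @property
    def z0(self) -> float:
        """Source depth: one transport mean free path 1/(mua+musp), mm."""
        return 1.0 / (self.mua + self.musp)

    @property
    def beta(self) -> float:
        if self._beta is None:
            self._beta = boundary_beta(self.ri_in, self.ri_out, self.beta_method)
        return self._beta

    @property
    def zb(self) -> float:
        """Image-plane offset: 0 for ZBC, 2*beta*kappa for EBC/PCB, mm."""
        if self.bc_kind == "zbc":
            return 0.0
        return 2.0 * self.beta * self.kappa


def semi_infinite_fd(setup: SemiInfiniteSetup, rho, z=0.0, omega: float = 0.0,
                     mua_override: float | None = None) -> np.ndarray:
    """Frequency-domain fluence phi(rho, z) for a unit point source.

    The complex diffusion wavenumber is k = sqrt((mua*c - i*omega)/(c*kappa)),
    which reduces to the CW effective attenuation sqrt(mua/kappa) at omega=0.

    ZBC/EBC use the two image terms
    ``phi = (exp(-k r1)/r1 - exp(-k rb)/rb) / (4 pi kappa)`` with
    r1 = sqrt((z-z0)^2 + rho^2) and rb = sqrt((z+z0+2 zb)^2 + rho^2);
    PCB adds the line-image integral over exp(-l/zb).

    ``mua_override`` replaces mua in the wavenumber only (used by the DCS
    substitution); kappa, z0 and zb keep their static values.
    """
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    if omega < 0:
        raise ValueError("omega must be >= 0")
    kappa, z0, zb, c = setup.kappa, setup.z0, setup.zb, setup.c
    mua_eff = setup.mua if mua_override is None else mua_override
    k = np.sqrt((mua_eff * c - 1j * omega) / (c * kappa))

    r1 = np.sqrt((z - z0) ** 2 + rho**2)
    if np.any(r1 == 0):
        raise ValueError("field point coincides with the source (singular)")
    phi = np.exp(-k * r1) / r1
    if setup.bc_kind in ("zbc", "ebc"):
        rb = np.sqrt((z + z0 + 2.0 * zb) ** 2 + rho**2)
        phi = phi - np.exp(-k * rb) / rb
    else:  # pcb
        r2 = np.sqrt((z + z0) ** 2 + rho**2)
        phi = phi + np.exp(-k * r2) / r2

        def tail(l, rho_s, z_s):
            rl = np.sqrt((z_s + z0 + l) ** 2 + rho_s**2)
            return np.exp(-l / zb) * np.real(np.exp(-k * rl)) / rl

        def tail_im(l, rho_s, z_s):
            rl = np.sqrt((z_s + z0 + l) ** 2 + rho_s**2)
            return np.exp(-l / zb) * np.imag(np.exp(-k * rl)) / rl

        it = np.nditer([rho + 0 * z, z + 0 * rho, None, None])
        with it:
            for rho_s, z_s, out_r, out_i in it:
                out_r[...] = integrate.quad(
                    tail, 0.0, 40.0 * zb, args=(float(rho_s), float(z_s)),
                    epsrel=1e-8, limit=200)[0]
                out_i[...] = integrate.quad(
                    tail_im, 0.0, 40.0 * zb, args=(float(rho_s), float(z_s)),
                    epsrel=1e-8, limit=200)[0] if omega > 0 else 0.0
            integral = it.operands[2] + 1j * it.operands[3]
        phi = phi - (2.0 / zb) * integral
    result = phi / (4.0 * np.pi * kappa)
    if omega == 0.0:
        result = np.real(result)
    return result[()] if result.ndim == 0 else result


def semi_infinite_tr(setup: SemiInfiniteSetup, rho, t,
                     z=0.0) -> tuple[np.ndarray, np.ndarray]:
    """Time-resolved fluence phi(rho, z, t) and reflectance R(rho, t).

    ZBC/EBC fluence:
    ``phi = c exp(-mua c t) / (4 pi kappa c t)^(3/2)
    [exp(-r1^2/(4 kappa c t)) - exp(-rb^2/(4 kappa c t))]``
    and the matching image-source reflectance; PCB uses the line-image
    fluence and the closed-form T_PCB(t) reflectance factor, evaluated with
    the scaled complementary error function for stability.

    Returns ``(phi, R)`` with shape broadcast over ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("all times must be strictly positive")
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    kappa, z0, zb, c, mua = setup.kappa, setup.z0, setup.zb, setup.c, setup.mua
    dcs_t = 4.0 * kappa * c * t
    decay = c * np.exp(-mua * c * t)
    norm = (np.pi * dcs_t) ** 1.5

    r1_sq = (z - z0) ** 2 + rho**2
    if setup.bc_kind in ("zbc", "ebc"):
        rb_sq = (z + z0 + 2.0 * zb) ** 2 + rho**2
        phi = decay / norm * (np.exp(-r1_sq / dcs_t) - np.exp(-rb_sq / dcs_t))
        refl = (0.5 * np.exp(-mua * c * t) / ((4.0 * np.pi * kappa * c) ** 1.5 * t**2.5)
                * (z0 * np.exp(-(z0**2 + rho**2) / dcs_t)
                   + (z0 + 2.0 * zb) * np.exp(-((z0 + 2.0 * zb) ** 2 + rho**2) / dcs_t)))
        return phi, refl

    # PCB
    r2_sq = (z + z0) ** 2 + rho**2
    base = np.exp(-r1_sq / dcs_t) + np.exp(-r2_sq / dcs_t)

    def tail(l, rho_s, z_s, dt_s):
        return np.exp(-l / zb) * np.exp(-((z_s + z0 + l) ** 2 + rho_s**2) / dt_s)

    shape = np.broadcast(rho, z, t).shape
    rho_b = np.broadcast_to(rho + 0 * z + 0 * t, shape).ravel()
    z_b = np.broadcast_to(z + 0 * rho + 0 * t, shape).ravel()
    dt_b = np.broadcast_to(dcs_t + 0 * rho + 0 * z, shape).ravel()
    integral = np.array([
        integrate.quad(tail, 0.0, 40.0 * zb, args=(r_s, z_s, d_s),
                       epsrel=1e-8, limit=200)[0]
        for r_s, z_s, d_s in zip(rho_b, z_b, dt_b)]).reshape(shape)
    phi = decay / norm * (base - (2.0 / zb) * integral)

    beta = setup.beta
    a = z0 * beta / (c * t)
    b = 4.0 * beta / 3.0
    x = (1.0 + a) / np.sqrt(a * b)
    t_pcb = (1.0 - np.sqrt(np.pi / (a * b)) * erfcx(x)) / a
    refl = (z0 * np.exp(-mua * c * t) / ((4.0 * np.pi * kappa * c) ** 1.5 * t**2.5)
            * np.exp(-(z0**2 + rho**2) / dcs_t) * t_pcb)
    return phi, refl


def semi_infinite_dcs(setup: SemiInfiniteSetup, rho, alpha_db: float,
                      wavelength_nm: float, tau_vector) -> np.ndarray:
    """Normalized field autocorrelation g1(tau) at radial distance rho.

    Uses the CW semi-infinite solution with the effective absorption
    ``mua + 2*alphaDb*musp*k0^2*tau`` (k0 = 2 pi / lambda, lambda in mm)
    substituted into the diffusion wavenumber, normalized by the tau=0
    (CW) value.
    """
    tau_vector = np.asarray(tau_vector, dtype=float)
    if np.any(tau_vector < 0):
        raise ValueError("delay times must be >= 0")
    if alpha_db < 0:
        raise ValueError("alphaDb must be >= 0")
    lam_mm = wavelength_nm * 1e-6
    k0 = 2.0 * np.pi / lam_mm
    g1 = np.empty(tau_vector.shape, dtype=float)
    phi0 = semi_infinite_fd(setup, rho, 0.0, 0.0)
    for i, tau in enumerate(tau_vector.ravel()):
        mua_eff = setup.mua + 2.0 * alpha_db * setup.musp * k0**2 * tau
        g1.flat[i] = semi_infinite_fd(setup, rho, 0.0, 0.0,
                                      mua_override=mua_eff) / phi0
    return g1
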