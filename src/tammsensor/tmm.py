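"""Dispersive transfer-matrix engine for stratified media.

Conventions (fixed throughout the package):

* time dependence exp(-i*omega*t); forward waves go as exp(+i*k_z*z);
  passive media have Im(epsilon) >= 0 and evanescent/absorbed branches take
  Im(k_z) >= 0 so that fields decay toward +z.
* k_z = (2*pi/lambda) * sqrt(eps - n_inc^2 sin^2(theta)), theta measured in
  the incident medium.
* the 2x2 matrix M relates amplitudes on the incidence side to the
  transmitted amplitude, [a_in, a_refl]^T = M [a_trans, 0]^T, so
  r = M21/M11 and t = 1/M11.  Reflectance R = |r|^2; transmittance is the
  power ratio T = Re(q_exit)/Re(q_inc) * |t|^2 with the polarization
  admittance q = k_z (TE) or k_z/eps (TM); absorptance A = 1 - R - T.

The per-interface factor is the textbook form

    T_{n-1,n} = 1/2 [[ (1+h) e^{-i phi},  (1-h) e^{+i phi} ],
                     [ (1-h) e^{-i phi},  (1+h) e^{+i phi} ]]

with h = q_n/q_{n-1} and phi = k_z,n * gamma_n the one-pass phase of layer n
(gamma = 0 for the final, semi-infinite exit medium).  At normal incidence
h reduces to sqrt(eps_n/eps_{n-1}) for TE and its reciprocal for TM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stack import StackSpec

__all__ = [
    "PlaneWave",
    "SpectralResult",
    "FieldProfile",
    "layer_matrix",
    "transfer_matrix",
    "rta",
    "spectrum",
    "field_profile",
    "angular_map",
    "amplitude_reflection",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PlaneWave:
    """Incident plane wave: vacuum wavelength (nm), angle (deg), polarization."""

    wavelength_nm: float
    theta_deg: float = 0.0
    polarization: str = "TE"

    def __post_init__(self):
        if not (0.0 <= self.theta_deg < 90.0):
            raise ValueError("incidence angle must satisfy 0 <= theta < 90 deg")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.polarization not in ("TE", "TM"):
            raise ValueError("polarization must be 'TE' or 'TM'")


@dataclass
class SpectralResult:
    """R/T/A sampled on a wavelength grid for one incidence condition."""

    wavelength_nm: np.ndarray
    R: np.ndarray
    T: np.ndarray
    A: np.ndarray
    theta_deg: float
    polarization: str
    stack_key: str = ""

    def __post_init__(self):
        for name in ("wavelength_nm", "R", "T", "A"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass
class FieldProfile:
    """Transverse field E(z) (TE: E_y; TM: H_y) for unit incident amplitude."""

    z_nm: np.ndarray
    E: np.ndarray
    index: np.ndarray  # complex refractive index at each z sample
    wavelength_nm: float
    theta_deg: float
    polarization: str

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.E) ** 2


def _kz_and_q(eps, k0_inv_nm, kx2, polarization):
    """k_z (1/nm) with the Im >= 0 branch, and the admittance factor q."""
    kz = k0_inv_nm * np.sqrt(eps - kx2 + 0j)
    kz = np.where(np.imag(kz) < 0, -kz, kz)
    # lossless propagating branch: keep Re >= 0 (sqrt already does, but the
    # sign flip above can produce Re < 0 for exactly-real negatives)
    kz = np.where((np.imag(kz) == 0) & (np.real(kz) < 0), -kz, kz)
    q = kz if polarization == "TE" else kz / eps
    return kz, q


def layer_matrix(eps_prev, eps_next, gamma_nm, wave: PlaneWave,
                 n_inc: float = 1.0) -> np.ndarray:
    """Single interface-plus-propagation factor T_{n-1,n}.

    ``gamma_nm`` is the thickness of the *next* layer (0 for the exit
    medium).  ``n_inc`` is the incident-medium index defining the conserved
    transverse wavevector at oblique incidence.
    """
    if gamma_nm < 0:
        raise ValueError("layer thickness must be >= 0")
    k0 = _TWO_PI / wave.wavelength_nm
    kx2 = (n_inc * np.sin(np.radians(wave.theta_deg))) ** 2
    _, q_prev = _kz_and_q(complex(eps_prev), k0, kx2, wave.polarization)
    kz_next, q_next = _kz_and_q(complex(eps_next), k0, kx2, wave.polarization)
    h = q_next / q_prev
    phi = kz_next * gamma_nm
    em, ep = np.exp(-1j * phi), np.exp(1j * phi)
    return 0.5 * np.array(
        [[(1 + h) * em, (1 - h) * ep],
         [(1 - h) * em, (1 + h) * ep]]
    )


def _chain(stack: StackSpec, lam_nm, theta_deg, polarization):
    """Vectorized over wavelength: per-interface factors and bookkeeping.

    Returns (M, kz_list, q0, qs) where M has shape (nlam, 2, 2), kz_list
    holds k_z per medium (incident, layers..., exit) and q0/qs the incident
    and exit admittances.
    """
    lam = np.atleast_1d(np.asarray(lam_nm, dtype=float))
    lam_um = lam / 1000.0
    k0 = _TWO_PI / lam  # 1/nm
    n_inc = stack.incident_medium.index(lam_um)
    if np.any(np.abs(np.imag(n_inc)) > 1e-12):
        raise ValueError("incident medium must be lossless")
    kx2 = (np.real(n_inc) * np.sin(np.radians(theta_deg))) ** 2

    media = [stack.incident_medium] + [ly.material for ly in stack.layers] + [stack.exit_medium]
    gammas = [ly.thickness_nm for ly in stack.layers] + [0.0]
    eps = [np.atleast_1d(m.permittivity(lam_um)) + 0j for m in media]

    kz, q = [], []
    for e in eps:
        kzi, qi = _kz_and_q(e, k0, kx2, polarization)
        kz.append(kzi)
        q.append(qi)

    nlam = lam.size
    M = np.zeros((nlam, 2, 2), dtype=complex)
    M[:, 0, 0] = 1.0
    M[:, 1, 1] = 1.0
    for j in range(len(gammas)):  # interface j | j+1, then phase of medium j+1
        h = q[j + 1] / q[j]
        phi = kz[j + 1] * gammas[j]
        em, ep = np.exp(-1j * phi), np.exp(1j * phi)
        a = 0.5 * (1 + h) * em
        b = 0.5 * (1 - h) * ep
        c = 0.5 * (1 - h) * em
        d = 0.5 * (1 + h) * ep
        m00 = M[:, 0, 0] * a + M[:, 0, 1] * c
        m01 = M[:, 0, 0] * b + M[:, 0, 1] * d
        m10 = M[:, 1, 0] * a + M[:, 1, 1] * c
        m11 = M[:, 1, 0] * b + M[:, 1, 1] * d
        M[:, 0, 0], M[:, 0, 1], M[:, 1, 0], M[:, 1, 1] = m00, m01, m10, m11
    return M, kz, q[0], q[-1]


def transfer_matrix(stack: StackSpec, wave: PlaneWave) -> np.ndarray:
    """Full-stack 2x2 transfer matrix at one wavelength/angle/polarization."""
    M, _, _, _ = _chain(stack, wave.wavelength_nm, wave.theta_deg, wave.polarization)
    out = M[0]
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite transfer matrix entries")
    return out


def rta(stack: StackSpec, wave: PlaneWave) -> tuple[float, float, float]:
    """Reflectance, transmittance, absorptance for one plane wave."""
    M, _, q0, qs = _chain(stack, wave.wavelength_nm, wave.theta_deg, wave.polarization)
    return tuple(float(x[0]) for x in _rta_from_chain(M, q0, qs))


def _rta_from_chain(M, q0, qs):
    M11 = M[:, 0, 0]
    if np.any(M11 == 0):
        raise FloatingPointError("singular transfer matrix (M11 = 0)")
    r = M[:, 1, 0] / M11
    t = 1.0 / M11
    R = np.abs(r) ** 2
    T = (np.real(qs) / np.real(q0)) * np.abs(t) ** 2
    return R, T, 1.0 - R - T


def amplitude_reflection(stack: StackSpec, lam_nm, theta_deg=0.0, polarization="TE"):
    """Complex amplitude reflection coefficient r (vectorized over lambda)."""
    M, _, _, _ = _chain(stack, lam_nm, theta_deg, polarization)
    r = M[:, 1, 0] / M[:, 0, 0]
    return r if np.asarray(lam_nm).ndim else complex(r[0])


def spectrum(stack: StackSpec, lam_nm, theta_deg: float = 0.0,
             polarization: str = "TE") -> SpectralResult:
    """R/T/A over a strictly increasing wavelength grid (nm)."""
    lam = np.asarray(lam_nm, dtype=float)
    if lam.ndim != 1 or lam.size == 0:
        raise ValueError("wavelength grid must be a non-empty 1-D array")
    if lam.size > 1 and np.any(np.diff(lam) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    M, _, q0, qs = _chain(stack, lam, theta_deg, polarization)
    R, T, A = _rta_from_chain(M, q0, qs)
    return SpectralResult(lam, R, T, A, theta_deg, polarization, stack.content_key())


def field_profile(stack: StackSpec, wave: PlaneWave, z_resolution_nm: float = 2.0,
                  pad_nm: float = 500.0) -> FieldProfile:
    """Transverse field E(z) through the stack for unit incident amplitude.

    Amplitudes per layer follow from peeling the transfer-matrix chain from
    the incidence side; the profile extends ``pad_nm`` into both
    semi-infinite media.
    """
    lam = wave.wavelength_nm
    lam_um = lam / 1000.0
    M, kz, q0, qs = _chain(stack, lam, wave.theta_deg, wave.polarization)
    r = complex(M[0, 1, 0] / M[0, 0, 0])

    media = [stack.incident_medium] + [ly.material for ly in stack.layers] + [stack.exit_medium]
    gammas = [0.0] + [ly.thickness_nm for ly in stack.layers] + [0.0]
    bounds = stack.boundaries_nm

    # amplitudes (a, b) at the left edge of each medium, peeled forward from
    # the incidence side with interface-continuity relations
    k0 = _TWO_PI / lam
    n_inc = complex(stack.incident_medium.index(lam_um))
    kx2 = (n_inc.real * np.sin(np.radians(wave.theta_deg))) ** 2
    eps = [complex(m.permittivity(lam_um)) for m in media]
    kzs, qs_ = [], []
    for e in eps:
        kzi, qi = _kz_and_q(np.array([e]), k0, kx2, wave.polarization)
        kzs.append(complex(kzi[0]))
        qs_.append(complex(qi[0]))
    amps = [(1.0 + 0j, r)]
    for j in range(1, len(media)):
        a_prev, b_prev = amps[-1]
        d_prev = gammas[j - 1]
        # phase-advance to the right edge of the previous medium
        ph = np.exp(1j * kzs[j - 1] * d_prev)
        a_r, b_r = a_prev * ph, b_prev / ph
        # continuity across the interface: D_prev [a,b] = D_next [a',b']
        qp, qn = qs_[j - 1], qs_[j]
        a_next = 0.5 * (a_r * (1 + qp / qn) + b_r * (1 - qp / qn))
        b_next = 0.5 * (a_r * (1 - qp / qn) + b_r * (1 + qp / qn))
        amps.append((a_next, b_next))

    z_chunks, E_chunks, n_chunks = [], [], []
    # incident medium
    nz = max(2, int(np.ceil(pad_nm / z_resolution_nm)))
    z = np.linspace(-pad_nm, 0.0, nz, endpoint=False)
    a0, b0 = amps[0]
    E_chunks.append(a0 * np.exp(1j * kzs[0] * z) + b0 * np.exp(-1j * kzs[0] * z))
    z_chunks.append(z)
    n_chunks.append(np.full(z.size, np.sqrt(eps[0])))
    for j, ly in enumerate(stack.layers, start=1):
        z0 = bounds[j - 1]
        nz = max(2, int(np.ceil(ly.thickness_nm / z_resolution_nm)))
        zl = np.linspace(0.0, ly.thickness_nm, nz, endpoint=False)
        a, b = amps[j]
        E_chunks.append(a * np.exp(1j * kzs[j] * zl) + b * np.exp(-1j * kzs[j] * zl))
        z_chunks.append(z0 + zl)
        n_chunks.append(np.full(zl.size, np.sqrt(eps[j])))
    # exit medium
    nz = max(2, int(np.ceil(pad_nm / z_resolution_nm)))
    zl = np.linspace(0.0, pad_nm, nz)
    a, b = amps[-1]
    E_chunks.append(a * np.exp(1j * kzs[-1] * zl))
    z_chunks.append(bounds[-1] + zl)
    n_chunks.append(np.full(zl.size, np.sqrt(eps[-1])))

    return FieldProfile(
        np.concatenate(z_chunks), np.concatenate(E_chunks),
        np.concatenate(n_chunks), lam, wave.theta_deg, wave.polarization,
    )


def angular_map(stack: StackSpec, lam_nm, theta_deg, polarization="TE") -> np.ndarray:
    """Reflectance R(theta, lambda), shape (len(theta), len(lambda))."""
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta >= 90):
        raise ValueError("angles must lie in [0, 90)")
    lam = np.asarray(lam_nm, dtype=float)
    out = np.empty((theta.size, lam.size))
    for i, th in enumerate(theta):
        M, _, q0, qs = _chain(stack, lam, float(th), polarization)
        R, _, _ = _rta_from_chain(M, q0, qs)
        out[i] = R
    return out
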