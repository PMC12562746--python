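"""Closed-form optical oracles, independent of the transfer-matrix engine.

These evaluate textbook formulas directly (Fresnel coefficients, the Airy
single-film summation, the quarter-wave Bragg-mirror peak reflectance, and
a synthetic Lorentzian dip generator) and exist solely so the test suite
can cross-check the matrix code against answers derived another way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "fresnel_rt",
    "airy_reflectance",
    "quarter_wave_dbr_reflectance",
    "lorentzian_dip",
    "etalon_fsr_nm",
    "OracleCase",
    "generate_oracles",
]


def fresnel_rt(n1, n2, theta1_deg=0.0, polarization="TE"):
    """Single-interface power reflectance/transmittance from Snell + Fresnel."""
    th1 = np.radians(theta1_deg)
    s2 = (n1 / n2) * np.sin(th1)
    c1 = np.cos(th1)
    c2 = np.sqrt(1.0 - s2**2 + 0j)
    if polarization == "TE":
        r = (n1 * c1 - n2 * c2) / (n1 * c1 + n2 * c2)
        t = 2 * n1 * c1 / (n1 * c1 + n2 * c2)
    elif polarization == "TM":
        r = (n2 * c1 - n1 * c2) / (n2 * c1 + n1 * c2)
        t = 2 * n1 * c1 / (n2 * c1 + n1 * c2)
    else:
        raise ValueError("polarization must be TE or TM")
    R = abs(r) ** 2
    T = np.real(n2 * c2) / np.real(n1 * c1) * abs(t) ** 2
    return float(R), float(T)


def airy_reflectance(n0, n1, n2, d_nm, lam_nm, theta0_deg=0.0, polarization="TE"):
    """Single-film reflectance from the Airy two-beam summation."""
    th0 = np.radians(theta0_deg)
    s1 = (n0 / n1) * np.sin(th0)
    c0, c1 = np.cos(th0), np.sqrt(1 - s1**2 + 0j)
    s2 = (n0 / n2) * np.sin(th0)
    c2 = np.sqrt(1 - s2**2 + 0j)

    def rf(na, ca, nb, cb):
        if polarization == "TE":
            return (na * ca - nb * cb) / (na * ca + nb * cb)
        return (nb * ca - na * cb) / (nb * ca + na * cb)

    r01 = rf(n0, c0, n1, c1)
    r12 = rf(n1, c1, n2, c2)
    beta = 2 * np.pi * n1 * c1 * d_nm / lam_nm
    r = (r01 + r12 * np.exp(2j * beta)) / (1 + r01 * r12 * np.exp(2j * beta))
    return np.abs(r) ** 2


def etalon_fsr_nm(lam_nm, n, d_nm):
    """Free spectral range of a plane etalon near lam: lam^2 / (2 n d)."""
    return lam_nm**2 / (2.0 * n * d_nm)


def quarter_wave_dbr_reflectance(n0, nH, nL, ns, periods):
    """Peak reflectance of an (HL)^N quarter-wave mirror (H on the incidence
    side, L against the substrate) at its design wavelength.

    Each quarter-wave layer maps the admittance Y -> n^2/Y, so N periods
    transform the substrate admittance to (nH/nL)^(2N) * ns.
    """
    Y = (nH / nL) ** (2 * periods) * ns
    r = (n0 - Y) / (n0 + Y)
    return float(r**2)


def lorentzian_dip(lam_nm, lam0_nm, fwhm_nm, depth=0.9, baseline=1.0):
    """Synthetic reflectance dip with exactly known center and width."""
    lam = np.asarray(lam_nm, dtype=float)
    half = fwhm_nm / 2.0
    return baseline - depth * half**2 / ((lam - lam0_nm) ** 2 + half**2)


@dataclass(frozen=True)
class OracleCase:
    """A named analytic scenario with its closed-form answer and tolerance."""

    name: str
    params: dict
    answer: Callable
    tolerance: float


def generate_oracles() -> list[OracleCase]:
    """The analytic cases used by the engine/resonance invariant suites."""
    return [
        OracleCase(
            "fresnel-glass", {"n1": 1.0, "n2": 1.5},
            lambda th=0.0, pol="TE": fresnel_rt(1.0, 1.5, th, pol), 1e-10,
        ),
        OracleCase(
            "airy-etalon",
            {"n0": 1.0, "n1": 2.0, "n2": 1.0, "d_nm": 150.0},
            lambda lam: airy_reflectance(1.0, 2.0, 1.0, 150.0, lam), 1e-8,
        ),
        OracleCase(
            "lossless-dbr",
            {"n0": 1.0, "nH": 2.4, "nL": 1.47, "ns": 1.5, "periods": 6},
            lambda: quarter_wave_dbr_reflectance(1.0, 2.4, 1.47, 1.5, 6), 1e-8,
        ),
        OracleCase(
            "lorentzian-dip",
            {"lam0_nm": 900.0, "fwhm_nm": 2.0, "depth": 0.9},
            lambda lam: lorentzian_dip(lam, 900.0, 2.0, 0.9), 1e-3,
        ),
    ]
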