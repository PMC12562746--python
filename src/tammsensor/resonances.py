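"""Resonance detection, characterization and eigenmode phase analysis.

Reflectance dips are located on a coarse grid, refined to sub-picometre
precision by bounded minimization of R(lambda), and measured with a
full width at the midpoint between the refined minimum R0 and the *local*
baseline (median reflectance in a window of +-10 linewidth-estimates around
the dip, excluding the dip itself) — robust when dips sit on a photonic-
bandgap plateau below unit reflectance.

Derived metrics:

* quality factor  Q = lambda0 / FWHM           (dimensionless)
* guidance factor G = (1 - R0) / FWHM          (FWHM in um, G in 1/um)

Modes are classified by where the electric-field intensity lives: a mode
holding more than half of the in-stack integral of \\|E\\|^2 inside the analyte
cavity is the cavity mode; otherwise it is a Tamm plasmon localized at the
PC1- or PC2-side metal film (TPP1 / TPP2), decided by the intensity
centroid; intermediate localization (anticrossing regime) is labelled
hybrid.

The cavity eigenfrequency can also be obtained independently of any
spectrum from the round-trip phase-matching condition
phi_1 + phi_2 + 4*pi*n_a*d_A*k = 2*pi*m, solved as a damped fixed point for
the wavenumber k = 1/lambda (1/um), with r_1, r_2 the half-stack amplitude
reflection coefficients seen from inside the cavity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.signal import find_peaks, peak_widths

from .stack import StackSpec
from .tmm import (PlaneWave, SpectralResult, amplitude_reflection,
                  field_profile, rta, spectrum)

__all__ = [
    "ResonanceMode",
    "PhaseSolveResult",
    "TPPCondition",
    "AnticrossingResult",
    "ConvergenceError",
    "find_resonances",
    "characterize",
    "q_factor",
    "g_factor",
    "classify_mode",
    "localization_fraction",
    "half_stack_reflection",
    "solve_phase_condition",
    "find_cavity_mode_by_phase",
    "tpp_phase_residual",
    "trace_branches",
    "find_anticrossing",
]

MODE_LABELS = ("TPP1", "cavity", "TPP2", "hybrid", "unknown")

# localization-fraction thresholds for the cavity / hybrid / Tamm decision;
# implementation choices, overridable per call
F_CAVITY = 0.5
F_HYBRID = 0.3


class ConvergenceError(RuntimeError):
    """Fixed-point phase solver failed to converge; carries the residual trace."""

    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace or []


@dataclass
class ResonanceMode:
    """One reflectance dip: position, width, depth and derived metrics."""

    lambda0_nm: float
    fwhm_nm: float
    r_min: float
    baseline: float = 1.0
    label: str = "unknown"
    f_analyte: float = float("nan")
    order: int | None = None
    flags: tuple[str, ...] = ()

    @property
    def q(self) -> float:
        return q_factor(self)

    @property
    def g_per_um(self) -> float:
        return g_factor(self)

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "lambda0_nm": self.lambda0_nm,
            "fwhm_nm": self.fwhm_nm,
            "r_min": self.r_min,
            "q": self.q,
            "g_per_um": self.g_per_um,
            "f_analyte": self.f_analyte,
            "order": self.order,
            "flags": list(self.flags),
        }


def q_factor(mode: ResonanceMode) -> float:
    """Q = lambda0/FWHM (same length unit top and bottom)."""
    if mode.fwhm_nm <= 0 or not np.isfinite(mode.fwhm_nm):
        raise ValueError("FWHM must be positive to define Q")
    return mode.lambda0_nm / mode.fwhm_nm

def g_factor(mode: ResonanceMode) -> float:
    """G = (1 - R0)/FWHM with FWHM in um, so G is in 1/um."""
    if mode.fwhm_nm <= 0 or not np.isfinite(mode.fwhm_nm):
        raise ValueError("FWHM must be positive to define G")
    return (1.0 - mode.r_min) / (mode.fwhm_nm / 1000.0)


def _local_baseline(lam, R, lam0, est_width, window=50.0):
    """Local plateau level: max reflectance within +-window*est_width.

    For dips sitting on a high plateau the window maximum is the plateau
    itself (neighbouring features are also dips, so they only lower R); a
    median would be biased low by the resonance's own tails, which for a
    Lorentzian decay only quadratically.
    """
    sel = np.abs(lam - lam0) <= window * est_width
    if not np.any(sel):
        return float(np.max(R))
    return float(np.max(R[sel]))


def find_resonances(
    spec: SpectralResult,
    prominence: float = 0.05,
    refine=None,
    refine_tol_nm: float = 1e-3,
) -> list[ResonanceMode]:
    """Detect reflectance dips in a spectrum and measure lambda0 / FWHM.

    ``refine`` is an optional callable R(lambda_nm) used for sub-grid
    refinement of the minimum (golden-section to ``refine_tol_nm``) and for
    root-finding the half-depth crossings; without it the grid resolution
    limits the precision.  An empty list (flat spectrum) is not an error.
    Dips whose half-width crossings fall off the grid are flagged
    ``"edge"`` with a NaN width instead of being dropped.
    """
    lam, R = spec.wavelength_nm, spec.R
    if lam.size < 5:
        return []
    step = float(np.median(np.diff(lam)))
    idx, props = find_peaks(-R, prominence=prominence)
    if idx.size == 0:
        return []
    widths = peak_widths(-R, idx, rel_height=0.5)[0] * step
    modes = []
    for j, i in enumerate(idx):
        lam0, R0 = float(lam[i]), float(R[i])
        est = max(widths[j], step)
        if refine is not None:
            lo = max(lam[0], lam0 - 3 * step)
            hi = min(lam[-1], lam0 + 3 * step)
            res = minimize_scalar(
                refine, bounds=(lo, hi), method="bounded",
                options={"xatol": refine_tol_nm / 10.0},
            )
            lam0, R0 = float(res.x), float(res.fun)
        base = _local_baseline(lam, R, lam0, est)
        half = 0.5 * (base + R0)
        flags: list[str] = []
        fwhm = np.nan
        gfun = refine if refine is not None else (
            lambda x: float(np.interp(x, lam, R))
        )
        try:
            left = _cross(gfun, lam0, -1, half, est, lam[0], lam[-1])
            right = _cross(gfun, lam0, +1, half, est, lam[0], lam[-1])
            fwhm = right - left
        except ValueError:
            flags.append("edge")
        modes.append(
            ResonanceMode(lam0, float(fwhm), R0, baseline=base,
                          flags=tuple(flags))
        )
    modes.sort(key=lambda m: m.lambda0_nm)
    return modes


def _cross(gfun, lam0, direction, level, est, lam_min, lam_max):
    """Nearest lambda in the given direction where R crosses ``level``."""
    span = max(est, 0.5)
    for _ in range(30):
        x = lam0 + direction * span
        if x < lam_min or x > lam_max:
            raise ValueError("half-width crossing off the grid")
        if gfun(x) >= level:
            a, b = (x, lam0) if direction < 0 else (lam0, x)
            return brentq(lambda t: gfun(t) - level, a, b, xtol=1e-6)
        span *= 1.6
    raise ValueError("no half-width crossing found")


def localization_fraction(profile, stack: StackSpec) -> float:
    """Share of the in-stack integral of |E|^2 inside the analyte layer."""
    span = stack.analyte_span_nm
    if span is None:
        return float("nan")
    z, I = profile.z_nm, profile.intensity
    finite = (z >= 0) & (z <= stack.total_thickness_nm)
    inside = finite & (z >= span[0]) & (z < span[1])
    total = np.trapezoid(I[finite], z[finite])
    if total == 0:
        return float("nan")
    # direct sums are adequate on the uniform sampling used here
    return float(np.trapezoid(I[inside], z[inside]) / total)


def classify_mode(
    mode: ResonanceMode,
    profile,
    stack: StackSpec,
    f_cavity: float = F_CAVITY,
    f_hybrid: float = F_HYBRID,
) -> str:
    """Label a mode cavity / hybrid / TPP1 / TPP2 from field localization.

    f_A > ``f_cavity`` -> cavity; ``f_hybrid`` <= f_A <= ``f_cavity`` ->
    hybrid; otherwise Tamm, with the side chosen by the in-stack intensity
    centroid relative to the analyte-layer midpoint.
    """
    fA = localization_fraction(profile, stack)
    mode.f_analyte = fA
    span = stack.analyte_span_nm
    if span is None or not np.isfinite(fA):
        mode.label = "unknown"
        return mode.label
    if fA > f_cavity:
        mode.label = "cavity"
    elif fA >= f_hybrid:
        mode.label = "hybrid"
    else:
        # Tamm side: the interface hosting the intensity maximum.  (A plain
        # centroid is diluted by the order-unity standing wave filling the
        # incidence-side mirror.)
        z, I = profile.z_nm, profile.intensity
        finite = (z >= 0) & (z <= stack.total_thickness_nm)
        z_peak = float(z[finite][np.argmax(I[finite])])
        mid = 0.5 * (span[0] + span[1])
        mode.label = "TPP1" if z_peak < mid else "TPP2"
    return mode.label


def characterize(
    stack: StackSpec,
    lam_window: tuple[float, float] = (750.0, 1100.0),
    theta_deg: float = 0.0,
    polarization: str = "TE",
    coarse_step_nm: float = 0.1,
    prominence: float = 0.05,
    classify: bool = True,
) -> list[ResonanceMode]:
    """Coarse scan + refined dip measurement + field-based classification."""
    lam = np.arange(lam_window[0], lam_window[1] + 1e-9, coarse_step_nm)
    sp = spectrum(stack, lam, theta_deg, polarization)

    def refine(l):
        return rta(stack, PlaneWave(float(l), theta_deg, polarization))[0]

    modes = find_resonances(sp, prominence=prominence, refine=refine)
    if classify and stack.analyte_index is not None:
        for m in modes:
            prof = field_profile(
                stack, PlaneWave(m.lambda0_nm, theta_deg, polarization), 2.0
            )
            classify_mode(m, prof, stack)
    return modes


# ---------------------------------------------------------------------------
# phase-matching analysis

def _half_stack(stack: StackSpec, side: str) -> StackSpec:
    ai = stack.analyte_index
    if ai is None:
        raise ValueError("stack has no analyte layer")
    analyte = stack.layers[ai].material
    if side == "PC1":
        layers = tuple(reversed(stack.layers[:ai]))
        exit_medium = stack.incident_medium
    elif side == "PC2":
        layers = stack.layers[ai + 1:]
        exit_medium = stack.exit_medium
    else:
        raise ValueError("side must be 'PC1' or 'PC2'")
    return StackSpec(analyte, layers, exit_medium, name=f"{stack.name}-{side}")


def half_stack_reflection(stack: StackSpec, side: str, lam_nm,
                          theta_deg: float = 0.0, polarization: str = "TE"):
    """Amplitude reflection coefficient seen from inside the analyte cavity
    toward the named mirror (metal film + DBR + substrate)."""
    return amplitude_reflection(_half_stack(stack, side), lam_nm,
                                theta_deg, polarization)


@dataclass
class PhaseSolveResult:
    """Converged solution of the round-trip phase-matching condition."""

    k_per_um: float
    lambda_nm: float
    m: int
    phi1: float
    phi2: float
    phi_a: float
    residual: float
    iterations: int


def solve_phase_condition(
    stack: StackSpec,
    m: int,
    lam_bracket: tuple[float, float] = (750.0, 1100.0),
    damping: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 300,
) -> PhaseSolveResult:
    """Solve k = [2 pi m - arg r1(k) - arg r2(k)] / (4 pi n_a d_A) for k (1/um).

    Damped fixed-point iteration starting from the bracket midpoint; the
    mirror reflection coefficients are re-evaluated at each iterate, so the
    converged k satisfies the full dispersive condition.  Raises
    :class:`ConvergenceError` (with the residual trace) if ``max_iter`` is
    exhausted.
    """
    ai = stack.analyte_index
    if ai is None:
        raise ValueError("stack has no analyte layer")
    layer = stack.layers[ai]
    n_a = float(np.real(layer.material.index(1.0)))
    d_um = layer.thickness_nm / 1000.0
    denom = 4.0 * np.pi * n_a * d_um

    k = 2.0 / (lam_bracket[0] / 1000.0 + lam_bracket[1] / 1000.0)
    k_lo = 1000.0 / (lam_bracket[1] * 1.2)
    k_hi = 1000.0 / (lam_bracket[0] / 1.2)
    trace = []
    for it in range(1, max_iter + 1):
        if not (k_lo <= k <= k_hi):
            raise ConvergenceError(
                f"phase iterate left the bracket for m={m} "
                f"(lambda -> {1000.0 / k:.1f} nm)", trace,
            )
        lam_nm = 1000.0 / k
        r1 = half_stack_reflection(stack, "PC1", lam_nm)
        r2 = half_stack_reflection(stack, "PC2", lam_nm)
        phi1, phi2 = float(np.angle(r1)), float(np.angle(r2))
        k_new = (2.0 * np.pi * m - phi1 - phi2) / denom
        resid = abs(k_new - k)
        trace.append(resid)
        k = k + damping * (k_new - k)
        if resid < tol:
            phi_a = denom * k
            phase_residual = abs(phi1 + phi2 + phi_a - 2.0 * np.pi * m)
            return PhaseSolveResult(
                k, 1000.0 / k, m, phi1, phi2, phi_a, phase_residual, it
            )
    raise ConvergenceError(
        f"phase solver did not converge for m={m} "
        f"(last residual {trace[-1]:.3e} 1/um)", trace,
    )


def find_cavity_mode_by_phase(
    stack: StackSpec,
    lam_window: tuple[float, float] = (750.0, 1100.0),
    m_range=range(1, 7),
) -> PhaseSolveResult:
    """Scan mode orders and keep the phase solution inside the window."""
    from .materials import MaterialRangeError

    best = None
    for m in m_range:
        try:
            sol = solve_phase_condition(stack, m, lam_bracket=lam_window)
        except (ConvergenceError, MaterialRangeError):
            continue
        if lam_window[0] <= sol.lambda_nm <= lam_window[1]:
            if best is None or sol.residual < best.residual:
                best = sol
    if best is None:
        raise ConvergenceError(
            f"no phase solution inside {lam_window} for m in {list(m_range)}"
        )
    return best


@dataclass
class TPPCondition:
    """Diagnostic evaluation of the Tamm phase condition at one wavelength."""

    phi_pc: float
    phi_metal: float
    phi_prop: float
    m: int
    residual: float


def tpp_phase_residual(stack: StackSpec, side: str, lam_nm: float) -> TPPCondition:
    """Round-trip phase defect of the Tamm condition at one wavelength.

    Evaluates arg(r_DBR) + arg(r_metal) + phi_prop, where both reflections
    are seen from inside the terminal DBR dielectric adjacent to the metal
    film on the given side (one looking into the rest of the DBR, one into
    the metal and everything beyond it) and phi_prop = 2 k_z n d is the
    round-trip propagation phase across that terminal layer, which
    references the two reflection phases to a common plane.  Reports the
    distance to the nearest 2 pi multiple — a diagnostic, not a solver; the
    residual is never zeroed.
    """
    ai = stack.analyte_index
    if ai is None:
        raise ValueError("stack has no analyte layer")
    if side == "PC1":
        term = ai - 2          # terminal dielectric, metal at ai-1
        dbr_layers = tuple(reversed(stack.layers[:term]))
        dbr_exit = stack.incident_medium
        metal_layers = stack.layers[ai - 1:]
        metal_exit = stack.exit_medium
    elif side == "PC2":
        term = ai + 2          # terminal dielectric, metal at ai+1
        dbr_layers = stack.layers[term + 1:]
        dbr_exit = stack.exit_medium
        metal_layers = tuple(reversed(stack.layers[:ai + 2]))
        metal_exit = stack.incident_medium
    else:
        raise ValueError("side must be 'PC1' or 'PC2'")
    ambient = stack.layers[term].material
    r_pc = amplitude_reflection(StackSpec(ambient, dbr_layers, dbr_exit), lam_nm)
    r_metal = amplitude_reflection(StackSpec(ambient, metal_layers, metal_exit), lam_nm)
    phi_pc, phi_metal = float(np.angle(r_pc)), float(np.angle(r_metal))
    n_term = float(np.real(ambient.index(lam_nm / 1000.0)))
    phi_prop = 2.0 * (2.0 * np.pi / lam_nm) * n_term * stack.layers[term].thickness_nm
    total = phi_pc + phi_metal + phi_prop
    m = int(np.round(total / (2.0 * np.pi)))
    return TPPCondition(phi_pc, phi_metal, phi_prop, m,
                        abs(total - 2.0 * np.pi * m))


# ---------------------------------------------------------------------------
# angular branch tracing / anticrossing

@dataclass
class AnticrossingResult:
    """Minimal-separation point of two resonance branches over angle."""

    theta_star_deg: float | None
    min_separation_nm: float
    separations_nm: np.ndarray
    flagged: bool
    reason: str = ""


def trace_branches(
    Rmap: np.ndarray,
    lam_nm: np.ndarray,
    theta_deg: np.ndarray,
    start_lambdas_nm,
    prominence: float = 0.02,
    max_jump_nm_per_deg: float = 10.0,
) -> np.ndarray:
    """Follow reflectance dips across angle by nearest-dip continuation.

    Returns an array of shape (n_branches, n_theta) of dip wavelengths; NaN
    where a branch is lost (no dip within the allowed jump).
    """
    theta = np.asarray(theta_deg, dtype=float)
    lam = np.asarray(lam_nm, dtype=float)
    step = float(np.median(np.diff(theta))) if theta.size > 1 else 1.0
    max_jump = max_jump_nm_per_deg * step
    out = np.full((len(start_lambdas_nm), theta.size), np.nan)
    current = list(map(float, start_lambdas_nm))
    for i in range(theta.size):
        idx, _ = find_peaks(-Rmap[i], prominence=prominence)
        dips = lam[idx]
        for b, lam_prev in enumerate(current):
            if np.isnan(lam_prev) or dips.size == 0:
                continue
            j = int(np.argmin(np.abs(dips - lam_prev)))
            if abs(dips[j] - lam_prev) <= max_jump:
                out[b, i] = dips[j]
                current[b] = float(dips[j])
            else:
                current[b] = np.nan
    return out


def find_anticrossing(
    branch_a: np.ndarray,
    branch_b: np.ndarray,
    theta_deg: np.ndarray,
    flat_tol: float = 0.02,
) -> AnticrossingResult:
    """Angle of minimal spectral separation between two traced branches.

    Flags (``theta_star = None``) when either trace is incomplete over the
    overlap or when the separation is constant to within ``flat_tol``
    relative variation (non-interacting parallel branches).
    """
    theta = np.asarray(theta_deg, dtype=float)
    sep = np.abs(np.asarray(branch_a) - np.asarray(branch_b))
    ok = np.isfinite(sep)
    if ok.sum() < 3:
        return AnticrossingResult(None, float("nan"), sep, True, "branch lost")
    smin, smax = float(np.nanmin(sep)), float(np.nanmax(sep))
    if smax > 0 and (smax - smin) / smax < flat_tol:
        return AnticrossingResult(None, smin, sep, True, "parallel branches")
    i = int(np.nanargmin(sep))
    flagged = not ok.all()
    return AnticrossingResult(
        float(theta[i]), smin, sep, flagged,
        "partial trace" if flagged else "",
    )
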