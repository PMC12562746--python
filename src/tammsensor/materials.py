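"""Material dispersion models: complex refractive index n + i*kappa and
permittivity epsilon = (n + i*kappa)**2 for every layer material.

Three dispersion rules are supported:

* :class:`CauchyModel` — the two-coefficient-plus-constant Cauchy form
  ``n(lambda) = A + B/lambda**2 + C/lambda**4`` (lambda in micrometres) used
  for the TiO2 and SiO2 Bragg-mirror dielectrics. Evaluation is restricted to
  the declared validity window; it is an error, not an extrapolation.
* :class:`TabulatedNK` — measured (lambda, n, kappa) rows, interpolated with a
  monotone piecewise-cubic (PCHIP) scheme by default. Used for the noble-metal
  films (Johnson & Christy 1972 data, vendored as text tables).
* constant complex index, for non-dispersive media such as the glass ambient
  and the analyte.

Sign convention: fields go as exp(-i*omega*t), so passive (absorbing) media
have kappa >= 0 and Im(epsilon) >= 0 everywhere.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator, interp1d

__all__ = [
    "CauchyModel",
    "TabulatedNK",
    "Material",
    "cauchy_index",
    "tabulated_index",
    "permittivity",
    "load_material_library",
    "load_nk_table",
    "default_library",
    "MaterialRangeError",
]


class MaterialRangeError(ValueError):
    """Wavelength outside a dispersion model's validity range."""


@dataclass(frozen=True)
class CauchyModel:
    """Cauchy dispersion n(lambda) = A + B/lambda^2 + C/lambda^4, lambda in um.

    A is dimensionless, B in um^2, C in um^4 (C may be negative, as it is for
    the TiO2 coefficient set).
    """

    A: float
    B: float
    C: float
    valid_range: tuple[float, float] = (0.30, 1.25)
    name: str = "cauchy"

    def index(self, lam_um) -> np.ndarray:
        return cauchy_index(self, lam_um)


def cauchy_index(model: CauchyModel, lam_um) -> Union[float, np.ndarray]:
    """Real refractive index of a Cauchy medium at vacuum wavelength lam_um."""
    lam = np.asarray(lam_um, dtype=float)
    lo, hi = model.valid_range
    if np.any(lam < lo) or np.any(lam > hi):
        raise MaterialRangeError(
            f"wavelength outside Cauchy validity range [{lo}, {hi}] um "
            f"for material '{model.name}'"
        )
    out = model.A + model.B / lam**2 + model.C / lam**4
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TabulatedNK:
    """Tabulated complex index (lambda_um, n, kappa), interpolated inside the span.

    ``scheme`` is ``"pchip"`` (monotone piecewise-cubic, the default — linear
    interpolation of coarsely sampled metal data shifts resonance positions
    at the sub-nanometre level) or ``"linear"``.
    """

    lam_um: np.ndarray
    n: np.ndarray
    k: np.ndarray
    provenance: str = ""
    scheme: str = "pchip"
    _interp_n: object = field(default=None, repr=False, compare=False)
    _interp_k: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        lam = np.asarray(self.lam_um, dtype=float)
        n = np.asarray(self.n, dtype=float)
        k = np.asarray(self.k, dtype=float)
        if lam.ndim != 1 or lam.size < 2:
            raise ValueError("TabulatedNK needs at least two rows")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("TabulatedNK wavelengths must be strictly increasing")
        if np.any(k < 0):
            raise ValueError("TabulatedNK kappa must be >= 0 (passive medium)")
        object.__setattr__(self, "lam_um", lam)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "k", k)
        if self.scheme == "pchip":
            fn, fk = PchipInterpolator(lam, n), PchipInterpolator(lam, k)
        elif self.scheme == "linear":
            fn = interp1d(lam, n)
            fk = interp1d(lam, k)
        else:
            raise ValueError(f"unknown interpolation scheme {self.scheme!r}")
        object.__setattr__(self, "_interp_n", fn)
        object.__setattr__(self, "_interp_k", fk)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.lam_um[0]), float(self.lam_um[-1])

    def index(self, lam_um):
        return tabulated_index(self, lam_um)


def tabulated_index(table: TabulatedNK, lam_um) -> Union[complex, np.ndarray]:
    """Interpolated complex index n + i*kappa; kappa clamped to >= 0."""
    lam = np.asarray(lam_um, dtype=float)
    lo, hi = table.span
    if np.any(lam < lo) or np.any(lam > hi):
        raise MaterialRangeError(
            f"wavelength outside tabulated span [{lo:.4f}, {hi:.4f}] um "
            f"for table '{table.provenance}'"
        )
    n = table._interp_n(lam)
    k = np.clip(table._interp_k(lam), 0.0, None)
    out = n + 1j * k
    return out if out.ndim else complex(out)


ModelType = Union[CauchyModel, TabulatedNK, complex]


@dataclass(frozen=True)
class Material:
    """A named optical material backed by one dispersion rule."""

    name: str
    model: ModelType

    def index(self, lam_um) -> Union[complex, np.ndarray]:
        """Complex refractive index n + i*kappa at vacuum wavelength lam_um (um)."""
        if isinstance(self.model, CauchyModel):
            try:
                return cauchy_index(self.model, lam_um) + 0j
            except MaterialRangeError as err:
                raise MaterialRangeError(f"{err} (material '{self.name}')") from None
        if isinstance(self.model, TabulatedNK):
            return tabulated_index(self.model, lam_um)
        lam = np.asarray(lam_um, dtype=float)
        val = complex(self.model)
        if lam.ndim:
            return np.full(lam.shape, val)
        return val

    def permittivity(self, lam_um):
        return permittivity(self, lam_um)

    def describe(self) -> str:
        if isinstance(self.model, CauchyModel):
            return f"cauchy(A={self.model.A}, B={self.model.B}, C={self.model.C})"
        if isinstance(self.model, TabulatedNK):
            return f"table({self.model.provenance}, {self.model.scheme})"
        return f"constant({self.model})"


def permittivity(material: Material, lam_um) -> Union[complex, np.ndarray]:
    """epsilon = (n + i*kappa)^2 under the exp(-i*omega*t) convention."""
    n = material.index(lam_um)
    return n * n


# ---------------------------------------------------------------------------
# library loading

def load_nk_table(path, provenance: str = "", scheme: str = "pchip") -> TabulatedNK:
    """Read a 3-column (lambda_um, n, k) text table; '#' lines are comments."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValueError(f"expected 3 columns (lambda_um, n, k) in {path}")
    return TabulatedNK(
        data[:, 0], data[:, 1], data[:, 2],
        provenance=provenance or str(path), scheme=scheme,
    )


def _data_dir() -> Path:
    return Path(importlib.resources.files("tammsensor") / "data")


def load_material_library(path=None, scheme: str = "pchip") -> dict[str, Material]:
    """Load a material library from a YAML mapping (default: packaged library).

    Each entry holds exactly one of ``cauchy: [A, B, C]``, ``table: <path>``,
    ``constant: [n, k]``. Table paths are resolved relative to the library
    file's directory.
    """
    if path is None:
        path = _data_dir() / "materials.yml"
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    lib: dict[str, Material] = {}
    for name, entry in raw.items():
        if not isinstance(entry, dict) or len(entry) != 1:
            raise ValueError(f"material '{name}': expected exactly one model key")
        (kind, val), = entry.items()
        if kind == "cauchy":
            A, B, C = (float(v) for v in val)
            model: ModelType = CauchyModel(A, B, C, name=name)
        elif kind == "table":
            tpath = Path(val)
            if not tpath.is_absolute():
                tpath = path.parent / tpath
            model = load_nk_table(tpath, provenance=f"{name}:{tpath.name}", scheme=scheme)
        elif kind == "constant":
            n, k = (float(v) for v in val)
            if k < 0:
                raise ValueError(f"material '{name}': kappa must be >= 0")
            model = complex(n, k)
        else:
            raise ValueError(f"material '{name}': unknown model kind '{kind}'")
        lib[name] = Material(name, model)
    return lib


_DEFAULT_LIB: dict[str, Material] | None = None


def default_library() -> dict[str, Material]:
    """The packaged library (TiO2, SiO2, glass, air, Ag, Au, Cu), cached."""
    global _DEFAULT_LIB
    if _DEFAULT_LIB is None:
        _DEFAULT_LIB = load_material_library()
    return _DEFAULT_LIB
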