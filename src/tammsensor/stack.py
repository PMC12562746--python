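"""Layered-structure description and the two sensor geometries.

A :class:`StackSpec` is an ordered list of finite layers between two
semi-infinite media, with z = 0 at the incident-medium/first-layer interface
and z increasing toward the exit medium.

Two builders produce the sensor geometries studied here, both of the form

    glass | PC1 | metal | analyte | metal | PC2 | glass

where PC1 and PC2 are TiO2/SiO2 (H/L) distributed Bragg reflectors.  In the
baseline design PC1 is quarter-wave at 760 nm (H 75 / L 130 nm) with the H
layer adjacent to the metal thinned to 65 nm (H'), PC2 is quarter-wave at
1000 nm (H 100 / L 150 nm), and both metal films are 30 nm.  The enhanced
design sharpens the cavity line: PC1 = (L 60 / H 47) x 6 + H 47, PC2 uses
H 120 / L 200 nm, and 60 nm silver films.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .materials import Material, default_library

__all__ = [
    "Layer",
    "StackSpec",
    "AnalyteSpec",
    "build_baseline",
    "build_enhanced",
    "index_profile",
    "save_stack",
    "load_stack",
]


@dataclass(frozen=True)
class Layer:
    """One finite layer: a material reference and its thickness in nm."""

    material: Material
    thickness_nm: float

    def __post_init__(self):
        t = float(self.thickness_nm)
        if not np.isfinite(t) or t <= 0:
            raise ValueError(
                f"layer thickness must be positive and finite, got {self.thickness_nm}"
            )


@dataclass(frozen=True)
class AnalyteSpec:
    """Central analyte layer: real refractive index n_a and thickness d_A (nm)."""

    n_a: float
    thickness_nm: float = 1000.0

    def __post_init__(self):
        if self.n_a < 1.0:
            raise ValueError(f"analyte index must be >= 1.0, got {self.n_a}")


@dataclass(frozen=True)
class StackSpec:
    """Ordered finite layers between two semi-infinite media.

    ``analyte_index`` marks which finite layer (0-based) is the analyte
    cavity, if any; the resonance classifier uses it to measure field
    localization.
    """

    incident_medium: Material
    layers: tuple[Layer, ...]
    exit_medium: Material
    analyte_index: int | None = None
    name: str = "stack"

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.analyte_index is not None and not (
            0 <= self.analyte_index < len(self.layers)
        ):
            raise ValueError("analyte_index out of range")

    @property
    def boundaries_nm(self) -> np.ndarray:
        """Interface z coordinates: z_0 = 0, ..., z_N = total thickness."""
        return np.concatenate(
            [[0.0], np.cumsum([ly.thickness_nm for ly in self.layers])]
        )

    @property
    def total_thickness_nm(self) -> float:
        return float(sum(ly.thickness_nm for ly in self.layers))

    @property
    def analyte_span_nm(self) -> tuple[float, float] | None:
        if self.analyte_index is None:
            return None
        b = self.boundaries_nm
        return float(b[self.analyte_index]), float(b[self.analyte_index + 1])

    def reversed(self) -> "StackSpec":
        """The same stack illuminated from the other side."""
        ai = None
        if self.analyte_index is not None:
            ai = len(self.layers) - 1 - self.analyte_index
        return StackSpec(
            self.exit_medium, tuple(reversed(self.layers)), self.incident_medium,
            analyte_index=ai, name=self.name + "-reversed",
        )

    def with_analyte(self, n_a: float) -> "StackSpec":
        """Copy of the stack with the analyte index replaced."""
        if self.analyte_index is None:
            raise ValueError("stack has no analyte layer")
        ly = self.layers[self.analyte_index]
        new = Layer(Material(f"analyte(n={n_a})", complex(n_a, 0.0)), ly.thickness_nm)
        layers = list(self.layers)
        layers[self.analyte_index] = new
        return replace(self, layers=tuple(layers))

    def content_key(self) -> str:
        """Deterministic short description used in output metadata."""
        parts = [self.incident_medium.name]
        parts += [f"{ly.material.name}:{ly.thickness_nm:g}" for ly in self.layers]
        parts.append(self.exit_medium.name)
        return "|".join(parts)


def _pc1_baseline(lib, d_H=75.0, d_L=130.0, d_Hp=65.0, periods=5):
    """(L H) x periods + L + H', substrate -> metal order; H' touches the metal."""
    H, L = lib["TiO2"], lib["SiO2"]
    out = []
    for _ in range(periods):
        out += [Layer(L, d_L), Layer(H, d_H)]
    out += [Layer(L, d_L), Layer(H, d_Hp)]
    return out


def _pc2(lib, d_H, d_L, periods=6):
    """(H L) x periods, metal -> substrate order; H touches the metal."""
    H, L = lib["TiO2"], lib["SiO2"]
    out = []
    for _ in range(periods):
        out += [Layer(H, d_H), Layer(L, d_L)]
    return out


def build_baseline(
    n_a: float,
    metal: str = "Ag",
    d_M: float = 30.0,
    d_A: float = 1000.0,
    library: dict[str, Material] | None = None,
) -> StackSpec:
    """Baseline PC1-M-A-M-PC2 sensor (27 finite layers).

    PC1 is quarter-wave at 760 nm (H 75 / L 130 nm, terminal H thinned to
    65 nm), PC2 quarter-wave at 1000 nm (H 100 / L 150 nm), both metal films
    ``d_M`` = 30 nm, analyte ``d_A`` = 1000 nm with real index ``n_a``.
    Light enters from the PC1 side through semi-infinite glass.
    """
    lib = library or default_library()
    if metal not in ("Ag", "Au", "Cu"):
        raise ValueError(f"unknown metal '{metal}': expected one of Ag, Au, Cu")
    if n_a < 1.0:
        raise ValueError(f"analyte index must be >= 1.0, got {n_a}")
    m = lib[metal]
    analyte = Material(f"analyte(n={n_a})", complex(n_a, 0.0))
    layers = (
        _pc1_baseline(lib)
        + [Layer(m, d_M), Layer(analyte, d_A), Layer(m, d_M)]
        + _pc2(lib, 100.0, 150.0)
    )
    return StackSpec(
        lib["glass"], tuple(layers), lib["glass"],
        analyte_index=13, name=f"baseline-{metal}",
    )


def build_enhanced(
    n_a: float,
    d_M: float = 60.0,
    d_A: float = 1000.0,
    library: dict[str, Material] | None = None,
) -> StackSpec:
    """Enhanced-FoM variant (28 finite layers): PC1 = (LH)^6 H with
    H 47 / L 60 nm, PC2 with H 120 / L 200 nm, 60 nm Ag films."""
    lib = library or default_library()
    if n_a < 1.0:
        raise ValueError(f"analyte index must be >= 1.0, got {n_a}")
    H, L = lib["TiO2"], lib["SiO2"]
    m = lib["Ag"]
    analyte = Material(f"analyte(n={n_a})", complex(n_a, 0.0))
    pc1 = []
    for _ in range(6):
        pc1 += [Layer(L, 60.0), Layer(H, 47.0)]
    pc1.append(Layer(H, 47.0))  # extra H of the (LH)^6 H recipe
    layers = (
        pc1
        + [Layer(m, d_M), Layer(analyte, d_A), Layer(m, d_M)]
        + _pc2(lib, 120.0, 200.0)
    )
    return StackSpec(
        lib["glass"], tuple(layers), lib["glass"],
        analyte_index=14, name="enhanced",
    )


def index_profile(stack: StackSpec, lam_um: float):
    """Piecewise-constant complex-index profile along z at one wavelength.

    Returns a list of ``(z_start_nm, z_end_nm, complex_index)`` covering the
    semi-infinite media (+-inf endpoints) and every finite layer, partitioning
    the z axis.
    """
    b = stack.boundaries_nm
    out = [(-np.inf, 0.0, complex(stack.incident_medium.index(lam_um)))]
    for i, ly in enumerate(stack.layers):
        out.append((float(b[i]), float(b[i + 1]), complex(ly.material.index(lam_um))))
    out.append((float(b[-1]), np.inf, complex(stack.exit_medium.index(lam_um))))
    return out


# ---------------------------------------------------------------------------
# config-format serialization

def _material_to_cfg(mat: Material):
    from .materials import CauchyModel, TabulatedNK

    if isinstance(mat.model, CauchyModel):
        return {"cauchy": [mat.model.A, mat.model.B, mat.model.C]}
    if isinstance(mat.model, TabulatedNK):
        return {"table": mat.model.provenance}
    c = complex(mat.model)
    return {"constant": [c.real, c.imag]}


def save_stack(stack: StackSpec, path) -> None:
    """Serialize a StackSpec to the structured-text stack-config format."""
    cfg = {
        "name": stack.name,
        "incident_medium": {stack.incident_medium.name: _material_to_cfg(stack.incident_medium)},
        "exit_medium": {stack.exit_medium.name: _material_to_cfg(stack.exit_medium)},
        "layers": [
            {"material": ly.material.name, "thickness_nm": float(ly.thickness_nm)}
            for ly in stack.layers
        ],
        "analyte_index": stack.analyte_index,
        "materials": {
            ly.material.name: _material_to_cfg(ly.material) for ly in stack.layers
        },
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def _material_from_cfg(name: str, cfg: dict, lib: dict[str, Material]) -> Material:
    from .materials import CauchyModel

    (kind, val), = cfg.items()
    if kind == "cauchy":
        return Material(name, CauchyModel(*(float(v) for v in val), name=name))
    if kind == "constant":
        return Material(name, complex(float(val[0]), float(val[1])))
    if kind == "table":
        if name in lib:
            return lib[name]  # tables resolve through the library by name
        raise ValueError(f"tabulated material '{name}' not in library")
    raise ValueError(f"unknown material kind '{kind}'")


def load_stack(path, library: dict[str, Material] | None = None) -> StackSpec:
    """Read a stack config written by :func:`save_stack`."""
    lib = library or default_library()
    cfg = yaml.safe_load(Path(path).read_text())
    mats = {
        name: _material_from_cfg(name, mcfg, lib)
        for name, mcfg in cfg.get("materials", {}).items()
    }
    (iname, icfg), = cfg["incident_medium"].items()
    (ename, ecfg), = cfg["exit_medium"].items()
    layers = tuple(
        Layer(mats[lcfg["material"]], float(lcfg["thickness_nm"]))
        for lcfg in cfg["layers"]
    )
    return StackSpec(
        _material_from_cfg(iname, icfg, lib),
        layers,
        _material_from_cfg(ename, ecfg, lib),
        analyte_index=cfg.get("analyte_index"),
        name=cfg.get("name", "stack"),
    )
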