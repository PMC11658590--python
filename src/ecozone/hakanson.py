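"""Potential ecological risk of soil heavy metals (Hakanson index).

For each metal *i* with measured topsoil concentration C_s and regional
background C_n, the contamination factor is C_f = C_s / C_n, the
single-metal potential ecological risk is E = T · C_f with T the metal's
toxicity response coefficient, and the integrated index is RI = Σ E over
the metals measured. With every metal exactly at background,
RI equals the sum of the toxicity coefficients: 30+2+5+5+1+10 = 53.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridLayer

__all__ = [
    "HakansonConstants",
    "MetalRiskResult",
    "contamination_factor",
    "single_metal_risk",
    "integrated_risk",
    "risk_grid",
]

METALS = ("Cd", "Cr", "Pb", "Cu", "Zn", "As")


def _default_background() -> dict[str, float]:
    return {"Cd": 0.119, "Cr": 18.0, "Pb": 24.6, "Cu": 18.7, "Zn": 57.5, "As": 7.09}


def _default_toxicity() -> dict[str, float]:
    return {"Cd": 30.0, "Cr": 2.0, "Pb": 5.0, "Cu": 5.0, "Zn": 1.0, "As": 10.0}


@dataclass(frozen=True)
class HakansonConstants:
    """Regional background concentrations (mg/kg) and toxicity coefficients."""

    background: dict[str, float] = field(default_factory=_default_background)
    toxicity: dict[str, float] = field(default_factory=_default_toxicity)

    def __post_init__(self) -> None:
        if set(self.background) != set(self.toxicity):
            raise ValueError("background and toxicity must cover the same metals")
        for metal in self.background:
            if self.background[metal] <= 0 or self.toxicity[metal] <= 0:
                raise ValueError(f"constants for {metal} must be positive")

    def check_metal(self, metal: str) -> None:
        if metal not in self.background:
            raise KeyError(f"unknown metal {metal!r}; known: {sorted(self.background)}")


@dataclass(frozen=True)
class MetalRiskResult:
    contamination: dict[str, float]  # C_f per metal
    single_risk: dict[str, float]  # E per metal
    ri: float  # integrated index


def contamination_factor(
    c_s: float, metal: str, constants: HakansonConstants | None = None
) -> float:
    """C_f = measured concentration / background concentration."""
    constants = constants or HakansonConstants()
    constants.check_metal(metal)
    if c_s < 0:
        raise ValueError("concentration must be non-negative")
    return c_s / constants.background[metal]


def single_metal_risk(
    c_f: float, metal: str, constants: HakansonConstants | None = None
) -> float:
    """E = toxicity coefficient × contamination factor."""
    constants = constants or HakansonConstants()
    constants.check_metal(metal)
    if c_f < 0:
        raise ValueError("contamination factor must be non-negative")
    return constants.toxicity[metal] * c_f


def integrated_risk(
    concentrations: dict[str, float], constants: HakansonConstants | None = None
) -> MetalRiskResult:
    """RI over the metals supplied; per-metal C_f and E are reported too."""
    constants = constants or HakansonConstants()
    if not concentrations:
        raise ValueError("at least one metal concentration required")
    cf = {m: contamination_factor(c, m, constants) for m, c in concentrations.items()}
    e = {m: single_metal_risk(v, m, constants) for m, v in cf.items()}
    return MetalRiskResult(cf, e, float(sum(e.values())))


def risk_grid(
    metal_layers: dict[str, GridLayer], constants: HakansonConstants | None = None
) -> GridLayer:
    """Cell-wise integrated risk index over aligned per-metal rasters.

    Any cell that is nodata in any metal layer is nodata in the output.
    """
    constants = constants or HakansonConstants()
    if not metal_layers:
        raise ValueError("at least one metal layer required")
    layers = list(metal_layers.values())
    first = layers[0]
    for layer in layers[1:]:
        first.require_aligned(layer)

    ri = np.zeros(first.values.shape, dtype=float)
    bad = np.zeros(first.values.shape, dtype=bool)
    for metal, layer in metal_layers.items():
        constants.check_metal(metal)
        bad |= layer.mask
        cf = layer.values / constants.background[metal]
        ri += constants.toxicity[metal] * np.where(layer.mask, 0.0, cf)
    out = np.where(bad, first.nodata, ri)
    return GridLayer(first.spec, out, nodata=first.nodata)
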