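"""Analytical eigenfrequencies of the implant modelled as a clamped-free beam.

The broach-plus-handle assembly is idealised as a uniform rectangular
Euler-Bernoulli cantilever (default cross-section 30 x 8 mm steel).  Its
natural frequencies per mode i follow

    omega_i = ((i - 1/2) * pi)^2 / L^2 * sqrt(E * I / mu)

with free length L, Young's modulus E, second moment of area I for the
bending direction, and mass per unit length mu = rho * A.  As the broach
is hammered deeper the free length shortens (350 mm at the start of
insertion, 325 mm at the end here), so every eigenfrequency shifts up —
the physical rationale for tracking resonant-peak drift.

Two conventions matter when comparing with hand-calculated reference
values for this geometry:

* the steel modulus must be E = 210 GPa (a figure of 210 MPa sometimes
  appears for this material and is three orders of magnitude off);
* the reference table is reproduced only when the result is read as
  angular frequency (rad/s), even where it is labelled Hz.  This module
  computes in rad/s by default and converts to Hz on request.

The ``(i - 1/2) * pi`` factor approximates the exact clamped-free
characteristic roots beta_i * L of cos(bL) cosh(bL) = -1; the exact roots
are available via :func:`exact_cantilever_frequency` as an internal
cross-check (the approximation is ~30% low for mode 1 and converges fast
for higher modes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError

__all__ = [
    "BeamSpec",
    "eigen_frequency",
    "eigen_table",
    "exact_cantilever_frequency",
    "reference_table_check",
    "round_sig",
    "REFERENCE_EIGEN_TABLE",
]


@dataclass(frozen=True)
class BeamSpec:
    """Geometry and material of the simplified implant beam (SI units).

    Direction convention: bending in *x* flexes about the stiff axis
    through the thin (8 mm) dimension — the compliant direction, using
    I_x = w t^3 / 12; *y* bends through the wide (30 mm) dimension with
    I_y = t w^3 / 12.
    """

    width: float = 0.030  # m, the 30 mm dimension
    thickness: float = 0.008  # m, the 8 mm dimension
    length: float = 0.350  # m, free length (start of insertion)
    youngs_modulus: float = 2.10e11  # Pa, structural steel
    density: float = 7850.0  # kg/m^3

    def __post_init__(self):
        for name in ("width", "thickness", "length", "youngs_modulus", "density"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"BeamSpec.{name} must be positive")

    @property
    def area(self) -> float:
        return self.width * self.thickness

    @property
    def mass_per_length(self) -> float:
        """mu = rho * A, kg/m."""
        return self.density * self.area

    def second_moment(self, direction: str) -> float:
        if direction == "x":
            return self.width * self.thickness**3 / 12.0
        if direction == "y":
            return self.thickness * self.width**3 / 12.0
        raise ConfigError(f"direction must be 'x' or 'y', got {direction!r}")


def eigen_frequency(
    beam: BeamSpec,
    mode: int,
    direction: str = "x",
    unit: str = "rad_per_s",
    length: float | None = None,
) -> float:
    """Eigenfrequency of mode ``mode`` for the given bending direction.

    ``unit='rad_per_s'`` returns the closed-form angular frequency;
    ``unit='hz'`` divides by 2*pi.  ``length`` overrides the beam's free
    length (m), e.g. to evaluate start vs end of insertion.
    """
    if mode < 1:
        raise ConfigError("mode must be >= 1")
    L = beam.length if length is None else length
    if L <= 0:
        raise ConfigError("length must be positive")
    I = beam.second_moment(direction)
    omega = ((mode - 0.5) * math.pi) ** 2 / L**2 * math.sqrt(
        beam.youngs_modulus * I / beam.mass_per_length
    )
    if unit == "rad_per_s":
        return omega
    if unit == "hz":
        return omega / (2 * math.pi)
    raise ConfigError(f"unit must be 'rad_per_s' or 'hz', got {unit!r}")


def eigen_table(
    beam: BeamSpec | None = None,
    L_start: float = 0.350,
    L_end: float = 0.325,
    modes: int = 4,
    unit: str = "rad_per_s",
) -> pd.DataFrame:
    """Eigenfrequencies per mode at start/end free lengths, both directions.

    Rows are modes 1..``modes``; columns are a MultiIndex
    (position in {start, end}) x (direction in {x, y}).
    """
    beam = beam or BeamSpec()
    if modes < 1:
        raise ConfigError("modes must be >= 1")
    cols = pd.MultiIndex.from_product(
        [["start", "end"], ["x", "y"]], names=["position", "direction"]
    )
    data = {
        (pos, d): [
            eigen_frequency(beam, i, direction=d, unit=unit, length=L)
            for i in range(1, modes + 1)
        ]
        for pos, L in (("start", L_start), ("end", L_end))
        for d in ("x", "y")
    }
    table = pd.DataFrame(data, index=pd.RangeIndex(1, modes + 1, name="mode"))
    return table[cols]


def _characteristic_root(mode: int) -> float:
    """Exact clamped-free root beta_i * L of cos(x) cosh(x) = -1."""
    f = lambda x: math.cos(x) * math.cosh(x) + 1.0
    # roots interlace (i - 1/2) * pi tightly; bracket around it
    center = (mode - 0.5) * math.pi
    lo, hi = center - 0.5, center + 0.5
    if mode == 1:
        lo = 1.0  # first root near 1.8751, below pi/2 + 0.5 bracket is fine
        hi = 2.5
    return brentq(f, lo, hi, xtol=1e-13)


def exact_cantilever_frequency(
    beam: BeamSpec,
    mode: int,
    direction: str = "x",
    unit: str = "rad_per_s",
    length: float | None = None,
) -> float:
    """Eigenfrequency using the exact characteristic roots.

    Serves as the reference for the (i - 1/2)*pi approximation used in
    :func:`eigen_frequency`: omega = (beta_i L)^2 / L^2 * sqrt(E I / mu).
    """
    if not 1 <= mode <= 6:
        raise ConfigError("exact roots tabulated for modes 1..6")
    L = beam.length if length is None else length
    bl = _characteristic_root(mode)
    omega = bl**2 / L**2 * math.sqrt(
        beam.youngs_modulus * beam.second_moment(direction) / beam.mass_per_length
    )
    if unit == "hz":
        return omega / (2 * math.pi)
    return omega


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


# Hand-calculated reference eigenvalues for the default beam (3 s.f.,
# rad/s scale), used only as a cross-check.  The (mode 1, end, y) entry
# of 105 is internally inconsistent with the closed form, which gives
# ~1050 — an order-of-magnitude transcription slip — and is flagged by
# reference_table_check.
REFERENCE_EIGEN_TABLE = {
    ("start", "x"): (241.0, 2170.0, 6010.0, 11800.0),
    ("start", "y"): (902.0, 8120.0, 22600.0, 44200.0),
    ("end", "x"): (279.0, 2510.0, 6980.0, 13700.0),
    ("end", "y"): (105.0, 9420.0, 26200.0, 51300.0),
}


def reference_table_check(
    beam: BeamSpec | None = None,
    L_start: float = 0.350,
    L_end: float = 0.325,
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """Compare the closed-form table against the reference values.

    Returns one row per (mode, position, direction) with the computed
    value, its 3-s.f. rounding, the reference, the relative deviation of
    the rounded value, and a ``consistent`` flag (deviation <= tolerance).
    Exactly one reference entry — mode 1, end, y — fails the check.
    """
    table = eigen_table(beam, L_start=L_start, L_end=L_end, modes=4, unit="rad_per_s")
    rows = []
    for (pos, d), refs in REFERENCE_EIGEN_TABLE.items():
        for mode, ref in enumerate(refs, start=1):
            value = float(table.loc[mode, (pos, d)])
            rounded = round_sig(value, 3)
            rel = abs(rounded - ref) / ref
            rows.append(
                {
                    "mode": mode,
                    "position": pos,
                    "direction": d,
                    "computed_rad_s": value,
                    "computed_3sf": rounded,
                    "reference": ref,
                    "rel_deviation": rel,
                    "consistent": rel <= tolerance,
                }
            )
    return pd.DataFrame(rows)
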