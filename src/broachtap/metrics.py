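"""Impact-energy and insertion bookkeeping.

The bench rig drives the broach with a swing hammer released from fixed
heights, so the energy delivered per blow is the potential energy
E = m g h (friction and other losses neglected).  These helpers track
per-blow and cumulative energy, the energy cost per millimetre of
advance, and the shape of the insertion curve — including the stopping
rule used to define the insertion end point: the broach counts as seated
once it advances less than 0.1 mm per blow over five consecutive blows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDataError
from .fit_stats import fit_linear

__all__ = [
    "ImpactSpec",
    "BlowRecord",
    "InsertionSummary",
    "impact_energy",
    "cumulative_energy",
    "energy_per_mm",
    "insertion_curve",
    "build_blow_records",
    "records_to_frame",
]

STOP_ADVANCE_MM = 0.1  # seated when advance/blow drops below this ...
STOP_CONSECUTIVE = 5  # ... for this many consecutive blows


@dataclass(frozen=True)
class ImpactSpec:
    """Swing-hammer blow: mass (kg), drop height (m), gravity (m/s^2)."""

    hammer_mass: float = 1.5
    drop_height: float = 0.016
    g: float = 9.81

    def __post_init__(self):
        if self.hammer_mass <= 0:
            raise ConfigError("hammer_mass must be positive")
        if self.drop_height < 0:
            raise ConfigError("drop_height must be non-negative")
        if self.g <= 0:
            raise ConfigError("g must be positive")


@dataclass(frozen=True)
class BlowRecord:
    """Bookkeeping row for one hammer blow."""

    blow_index: int
    insertion_depth: float  # mm, measured after the blow
    blow_energy: float  # J
    cumulative_energy: float  # J


@dataclass(frozen=True)
class InsertionSummary:
    """Shape summary of a depth-vs-blow insertion curve."""

    initial_slope: float  # mm per blow over the best linear prefix
    linear_prefix: int  # number of blows in that prefix
    end_depth: float  # mm, final measured depth (the plateau)
    stop_blow: int | None  # blow at which the seating rule fired, if it did


def impact_energy(spec: ImpactSpec) -> float:
    """Potential energy of one hammer blow, E = m g h, in joules."""
    return spec.hammer_mass * spec.g * spec.drop_height


def cumulative_energy(blow_energies) -> tuple[np.ndarray, float]:
    """Running sum of per-blow energies and the total (J).

    An empty series has total 0.
    """
    energies = np.asarray(blow_energies, dtype=float)
    if energies.size and (np.any(energies < 0) or not np.all(np.isfinite(energies))):
        raise ConfigError("blow energies must be finite and non-negative")
    running = np.cumsum(energies)
    total = float(running[-1]) if running.size else 0.0
    return running, total


def energy_per_mm(total_energy: float, depth_advance: float) -> float:
    """Energy spent per millimetre of broach advance (J/mm)."""
    if depth_advance <= 0:
        raise ConfigError("depth_advance must be positive")
    return total_energy / depth_advance


def build_blow_records(depths_mm, blow_energy_j: float) -> list[BlowRecord]:
    """Assemble per-blow records from a depth series and a constant blow energy."""
    depths = np.asarray(depths_mm, dtype=float)
    running, _ = cumulative_energy(np.full(len(depths), blow_energy_j))
    return [
        BlowRecord(j + 1, float(depths[j]), blow_energy_j, float(running[j]))
        for j in range(len(depths))
    ]


def records_to_frame(records: list[BlowRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "blow_index": [r.blow_index for r in records],
            "insertion_depth_mm": [r.insertion_depth for r in records],
            "blow_energy_j": [r.blow_energy for r in records],
            "cumulative_energy_j": [r.cumulative_energy for r in records],
        }
    )


def insertion_curve(
    records: list[BlowRecord] | np.ndarray,
    initial_depth: float | None = None,
) -> InsertionSummary:
    """Summarise an insertion depth curve.

    The curve typically rises linearly for the first ~10 mm of advance
    and then flattens to a plateau.  The initial slope is the OLS slope
    over the prefix of blows maximising R^2 (prefixes of length >= 3);
    the plateau is the final depth; and the seating rule fires at the
    first blow ending five consecutive blows of advance < 0.1 mm.

    ``initial_depth`` is the depth before the first blow; it defaults to
    the first recorded depth, making the first blow's advance zero.
    """
    if isinstance(records, (list, tuple)) and records and isinstance(records[0], BlowRecord):
        depths = np.array([r.insertion_depth for r in records], dtype=float)
    else:
        depths = np.asarray(records, dtype=float)
    if len(depths) < 5:
        raise InsufficientDataError("insertion_curve needs >= 5 blows")
    d0 = float(depths[0]) if initial_depth is None else float(initial_depth)
    advances = np.diff(np.concatenate([[d0], depths]))

    blows = np.arange(1, len(depths) + 1, dtype=float)
    best_r2, best_k = -np.inf, 3
    for k in range(3, len(depths) + 1):
        try:
            fit = fit_linear(blows[:k], depths[:k])
        except Exception:
            continue
        if fit.r_squared > best_r2:
            best_r2, best_k = fit.r_squared, k
    slope = fit_linear(blows[:best_k], depths[:best_k]).slope

    stop_blow = None
    below = advances < STOP_ADVANCE_MM
    for j in range(STOP_CONSECUTIVE - 1, len(depths)):
        if np.all(below[j - STOP_CONSECUTIVE + 1 : j + 1]):
            stop_blow = j + 1
            break
    return InsertionSummary(
        initial_slope=slope,
        linear_prefix=best_k,
        end_depth=float(depths[-1]),
        stop_blow=stop_blow,
    )
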