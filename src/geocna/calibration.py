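"""Multi-value calibration of raw neighborhood variables.

Calibration maps each raw continuous variable (percentages, Index of
Concentration at the Extremes values, vaccination rates per 10,000) to a
small ordered set of levels: 0 = low, 1 = medium, 2 = high for three-level
factors.  Every scheme is encoded as two ordered cut points ``(c1, c2)``
with a total, deterministic interval closure so that each finite value maps
to exactly one level:

* ``right-closed`` (default): low = (-inf, c1], medium = (c1, c2], high = (c2, inf)
* ``left-closed``:            low = (-inf, c1), medium = [c1, c2), high = [c2, inf)

The shipped :data:`DEFAULT_SCHEMES` encode the published Philadelphia
cut points for all eight social-condition factors and the three monthly
vaccination-rate categorizations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DegeneracyError, DomainError

__all__ = [
    "CalibrationScheme",
    "IceInputs",
    "OutcomeSeries",
    "compute_ice",
    "calibrate_fixed",
    "calibrate_series",
    "tertile_cuts",
    "dual_calibrate",
    "persistent_low_outcome",
    "DEFAULT_SCHEMES",
    "RAW_RANGES",
]


@dataclass(frozen=True)
class CalibrationScheme:
    """A three-level fixed-cut or tertile calibration scheme.

    Parameters
    ----------
    name : str
        Factor name the scheme produces.
    cuts : tuple of float
        ``(lower, upper)`` breakpoints in raw units, ``lower < upper``.
    mode : {"fixed", "tertile"}
        ``fixed`` uses :attr:`cuts` as-is; ``tertile`` recomputes cuts from
        the observed distribution via :func:`tertile_cuts` before use.
    boundary_rule : {"right-closed", "left-closed"}
        Interval-closure convention, see module docstring.
    labels : tuple of str
        Semantic names for levels 0, 1, 2.
    """

    name: str
    cuts: tuple[float, float]
    mode: str = "fixed"
    boundary_rule: str = "right-closed"
    labels: tuple[str, str, str] = ("low", "medium", "high")

    def __post_init__(self) -> None:
        c1, c2 = self.cuts
        if not (c1 < c2):
            raise DomainError(
                f"scheme {self.name!r}: cuts must be strictly ordered, got {self.cuts}"
            )
        if self.mode not in ("fixed", "tertile"):
            raise DomainError(f"scheme {self.name!r}: unknown mode {self.mode!r}")
        if self.boundary_rule not in ("right-closed", "left-closed"):
            raise DomainError(
                f"scheme {self.name!r}: unknown boundary_rule {self.boundary_rule!r}"
            )


@dataclass(frozen=True)
class IceInputs:
    """Inputs to the Index of Concentration at the Extremes.

    ``privileged`` and ``deprived`` are counts (or proportions) of the two
    extreme groups; ``total`` is the total population in the same units.
    """

    privileged: float
    deprived: float
    total: float

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise DomainError("ICE total must be positive")
        if self.privileged < 0 or self.deprived < 0:
            raise DomainError("ICE group counts must be non-negative")
        # small float tolerance for proportion inputs that sum to ~total
        if self.privileged + self.deprived > self.total * (1 + 1e-9):
            raise DomainError(
                "privileged + deprived exceeds total "
                f"({self.privileged} + {self.deprived} > {self.total})"
            )


@dataclass(frozen=True)
class OutcomeSeries:
    """Vaccination-rate levels at the three monthly observation dates."""

    levels: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise DomainError("OutcomeSeries requires exactly three monthly levels")
        for lv in self.levels:
            if lv not in (0, 1, 2):
                raise DomainError(f"monthly level {lv!r} outside {{0,1,2}}")


def compute_ice(inputs: IceInputs) -> float:
    """Index of Concentration at the Extremes: (privileged - deprived) / total.

    Returns a dimensionless value in [-1, 1]; -1 is extreme concentration of
    the deprived group, +1 extreme concentration of the privileged group.
    """
    return (inputs.privileged - inputs.deprived) / inputs.total


def calibrate_fixed(value: float, scheme: CalibrationScheme) -> int:
    """Map a finite raw value to level 0, 1 or 2 under ``scheme``'s closure."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise DomainError(f"cannot calibrate NaN for factor {scheme.name!r}")
    c1, c2 = scheme.cuts
    if scheme.boundary_rule == "right-closed":
        if value <= c1:
            return 0
        if value <= c2:
            return 1
        return 2
    # left-closed
    if value < c1:
        return 0
    if value < c2:
        return 1
    return 2


def calibrate_series(values: Iterable[float], scheme: CalibrationScheme) -> np.ndarray:
    """Calibrate a sequence of raw values; tertile schemes derive their cuts
    from the sequence itself before mapping."""
    vals = np.asarray(list(values), dtype=float)
    if scheme.mode == "tertile":
        c1, c2 = tertile_cuts(vals)
        scheme = CalibrationScheme(
            name=scheme.name,
            cuts=(c1, c2),
            mode="fixed",
            boundary_rule=scheme.boundary_rule,
            labels=scheme.labels,
        )
    return np.array([calibrate_fixed(v, scheme) for v in vals], dtype=int)


def tertile_cuts(values: Sequence[float], method: str = "linear") -> tuple[float, float]:
    """33rd and 67th percentile of the empirical distribution.

    ``method`` is passed to :func:`numpy.percentile` (``"linear"`` by
    default; ``"lower"`` gives nearest-rank-below behaviour).  The result is
    invariant under permutation of the inputs.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 3 or np.unique(vals).size < 3:
        raise DegeneracyError("tertile calibration requires at least 3 distinct values")
    if np.unique(vals).size == 1:  # pragma: no cover - subsumed above
        raise DegeneracyError("constant factor cannot be calibrated")
    c1 = float(np.percentile(vals, 33, method=method))
    c2 = float(np.percentile(vals, 67, method=method))
    return (c1, c2)


def dual_calibrate(levels: Iterable[int]) -> tuple[np.ndarray, np.ndarray]:
    """Meta-factor dual calibration of a three-level factor.

    Returns ``(high, low)`` binary arrays: ``high = 1`` iff the level is 2
    (highest tertile), ``low = 1`` iff the level is 0 (lowest tertile).  The
    pair loses no information: ``(0, 0)`` identifies the middle tertile.
    """
    lv = np.asarray(list(levels), dtype=int)
    bad = set(np.unique(lv)) - {0, 1, 2}
    if bad:
        raise DomainError(f"levels outside {{0,1,2}}: {sorted(bad)}")
    return (lv == 2).astype(int), (lv == 0).astype(int)


def persistent_low_outcome(series: OutcomeSeries) -> int:
    """1 iff the rate level was low (0) at all three monthly dates."""
    return int(all(lv == 0 for lv in series.levels))


# Published cut points for the Philadelphia study region.  Social-condition
# factors are tertile-derived in origin but shipped as fixed cuts; the three
# vaccination schemes follow the health-department reporting categories.
DEFAULT_SCHEMES: dict[str, CalibrationScheme] = {
    "EDU": CalibrationScheme("EDU", (20.0, 40.1)),
    "UNINS": CalibrationScheme("UNINS", (6.5, 9.7)),
    "LEP": CalibrationScheme("LEP", (2.2, 4.7)),
    "TRANSIT": CalibrationScheme("TRANSIT", (21.4, 29.5)),
    "SERVICE": CalibrationScheme("SERVICE", (7.9, 9.8)),
    "CROWD": CalibrationScheme("CROWD", (1.7, 2.4)),
    "ICEINC": CalibrationScheme("ICEINC", (-0.23, 0.07)),
    "ICEBLACK": CalibrationScheme("ICEBLACK", (-0.37, 0.47)),
    "VAX_MARCH": CalibrationScheme("VAX_MARCH", (1500.0, 2000.0)),
    "VAX_APRIL": CalibrationScheme("VAX_APRIL", (2500.0, 3400.0)),
    "VAX_MAY": CalibrationScheme("VAX_MAY", (3400.0, 4500.0)),
}

# Observed raw ranges per factor (used by the synthetic generator to back-fill
# realistic raw values).  ICE measures live on [-1, 1] by construction.
RAW_RANGES: dict[str, tuple[float, float]] = {
    "EDU": (4.5, 85.6),
    "UNINS": (2.7, 13.8),
    "LEP": (0.4, 25.1),
    "TRANSIT": (9.2, 45.3),
    "SERVICE": (1.9, 16.9),
    "CROWD": (0.0, 6.1),
    "ICEINC": (-1.0, 1.0),
    "ICEBLACK": (-1.0, 1.0),
    "VAX_MARCH": (500.0, 4000.0),
    "VAX_APRIL": (1000.0, 5500.0),
    "VAX_MAY": (1500.0, 6500.0),
}
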