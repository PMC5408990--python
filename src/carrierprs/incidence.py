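"""Piecewise-constant age-specific incidence (hazard) curves.

An :class:`IncidenceCurve` holds the average carrier incidence
``lambda_bar(t)`` (or a baseline hazard ``lambda_0(t)``) on an age grid.  The
hazard is piecewise constant: ``hazard[j]`` applies on
``[age[j], age[j+1])`` and ``hazard[-1]`` extends beyond the last grid
point.  Ages are in years; hazards in events per person-year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class IncidenceCurve:
    """Age grid plus per-year hazard, piecewise constant between grid points."""

    age: np.ndarray
    hazard: np.ndarray

    def __post_init__(self) -> None:
        age = np.asarray(self.age, dtype=float)
        hazard = np.asarray(self.hazard, dtype=float)
        if age.ndim != 1 or hazard.ndim != 1:
            raise ValueError("age and hazard must be one-dimensional")
        if age.shape != hazard.shape:
            raise ValueError(
                f"age grid has length {age.size} but hazard has length {hazard.size}"
            )
        if age.size < 1:
            raise ValueError("incidence curve needs at least one grid point")
        if np.any(np.diff(age) <= 0):
            raise ValueError("age grid must be strictly increasing")
        if np.any(~np.isfinite(hazard)) or np.any(hazard < 0):
            bad = int(np.flatnonzero(~np.isfinite(hazard) | (hazard < 0))[0])
            raise ValueError(
                f"hazard must be finite and nonnegative (offending row {bad}, "
                f"age {age[bad]:g}, value {hazard[bad]!r})"
            )
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "hazard", hazard)

    @property
    def start(self) -> float:
        return float(self.age[0])

    def hazard_at(self, t) -> np.ndarray:
        """Hazard at age(s) ``t``; zero before the grid starts."""
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.age, t, side="right") - 1, 0, None)
        out = self.hazard[idx]
        return np.where(t < self.age[0], 0.0, out)

    def cumulative_hazard(self, t) -> np.ndarray:
        """Integral of the hazard from the start of the grid to age(s) ``t``."""
        t = np.asarray(t, dtype=float)
        widths = np.diff(self.age)
        cum = np.concatenate([[0.0], np.cumsum(self.hazard[:-1] * widths)])
        idx = np.clip(np.searchsorted(self.age, t, side="right") - 1, 0, None)
        partial = cum[idx] + self.hazard[idx] * (t - self.age[idx])
        return np.where(t <= self.age[0], 0.0, partial)

    def cumulative_risk(self, t) -> np.ndarray:
        """F(t) = 1 - exp(-integral of hazard), the absolute risk by age t."""
        return 1.0 - np.exp(-self.cumulative_hazard(t))

    def rescaled(self, factor: float) -> "IncidenceCurve":
        return IncidenceCurve(self.age, self.hazard * float(factor))

    def resampled(self, grid: np.ndarray) -> "IncidenceCurve":
        """Hazard evaluated at the left edge of each interval of ``grid``."""
        grid = np.asarray(grid, dtype=float)
        return IncidenceCurve(grid, self.hazard_at(grid))
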