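"""Uniform temperature grids for DTG curves.

All curves in a study are interpolated onto one shared grid so that each
grid point is a regression variable common to every sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "DEFAULT_GRID"]


@dataclass(frozen=True)
class GridSpec:
    """A uniform temperature grid ``start, start+step, ..., <= stop``.

    Parameters
    ----------
    start, stop : float
        Grid limits in degrees Celsius. ``start`` is the beginning of the
        ramp analysis window (after the drying hold), ``stop`` the end of
        the heating program.
    step : float
        Grid spacing in degrees Celsius.

    Notes
    -----
    The number of points is ``floor((stop - start) / step) + 1``; the last
    point may fall short of ``stop`` when the span is not an exact multiple
    of the step.
    """

    start: float = 105.0
    stop: float = 900.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"grid step must be positive, got {self.step}")
        if self.stop <= self.start:
            raise ValueError(
                f"grid stop ({self.stop}) must exceed start ({self.start})"
            )

    @property
    def count(self) -> int:
        # tiny epsilon guards against 7950.0 landing at 7949.999... in floats
        return int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1

    def temperatures(self) -> np.ndarray:
        """Grid points in °C as a float array of length ``count``."""
        return self.start + self.step * np.arange(self.count)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.count


#: 105–900 °C at 0.1 °C: the interpolation grid used for full-resolution runs.
DEFAULT_GRID = GridSpec(105.0, 900.0, 0.1)
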