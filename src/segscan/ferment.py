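"""Fermentation kinetics: mass loss to cumulative CO2, rate estimation, and
checkpoint phenotype extraction.

The fermenter sits on a balance; CO2 escaping through the airlock is the
only mass change, so cumulative CO2 (g/L) is the mass drop divided by the
working volume.  The production rate is estimated, as in online monitoring
rigs, by fitting a second-order polynomial to a trailing window of the
cumulative curve and taking its analytic derivative at the window's end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError


@dataclass
class FermentationCurve:
    """Time-stamped cumulative CO2 (g/L), optionally with a derived rate.

    ``rate`` (g/L/h), when present, is aligned with ``time_h``; leading
    positions with no full fitting window are NaN.
    """

    time_h: np.ndarray
    co2_cumulative: np.ndarray
    rate: np.ndarray | None = None

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.co2_cumulative = np.asarray(self.co2_cumulative, dtype=float)
        if self.time_h.shape != self.co2_cumulative.shape:
            raise InputError("time and CO2 vectors must have the same length")
        if len(self.time_h) < 2:
            raise InputError("a fermentation curve needs at least 2 samples")
        if np.any(np.diff(self.time_h) <= 0):
            raise InputError("time must be strictly increasing")
        if self.rate is not None:
            self.rate = np.asarray(self.rate, dtype=float)
            if self.rate.shape != self.time_h.shape:
                raise InputError("rate vector must align with the time vector")

    def __len__(self) -> int:
        return len(self.time_h)


def co2_from_mass(
    time_h: np.ndarray,
    mass_g: np.ndarray,
    volume_L: float,
    precision_g: float = 0.1,
) -> FermentationCurve:
    """Cumulative CO2 from fermenter mass readings.

    co2(t) = (mass(0) - mass(t)) / volume.  Transient mass gains no larger
    than the weighing precision (condensation, draught on the balance) are
    clamped to the running maximum so the output is monotone; a gain larger
    than the precision indicates corrupted input and raises.
    """
    time_h = np.asarray(time_h, dtype=float)
    mass_g = np.asarray(mass_g, dtype=float)
    if len(time_h) < 2:
        raise InputError("need at least 2 mass samples")
    if np.any(np.diff(time_h) <= 0):
        raise InputError("time must be strictly increasing")
    if volume_L <= 0:
        raise InputError("volume_L must be positive")
    co2 = (mass_g[0] - mass_g) / volume_L
    running = np.maximum.accumulate(co2)
    excursion = running - co2
    tol = precision_g / volume_L
    if np.any(excursion > tol + 1e-12):
        i = int(np.argmax(excursion > tol + 1e-12))
        raise InputError(
            f"mass gain of {excursion[i] * volume_L:.3g} g at sample {i} exceeds "
            f"the weighing precision ({precision_g} g)"
        )
    return FermentationCurve(time_h=time_h, co2_cumulative=running)


def co2_rate(
    curve: FermentationCurve,
    window_points: int = 10,
    degree: int = 2,
) -> np.ndarray:
    """CO2 production rate by trailing-window polynomial fitting.

    At each sample i >= window_points - 1, a degree-``degree`` polynomial is
    least-squares fitted to the last ``window_points`` cumulative values and
    its first derivative evaluated at t_i.  The first window_points - 1
    entries are NaN: there is no full window, and zero-filling would fake a
    lag phase.
    """
    if window_points < degree + 1:
        raise InputError("window_points must be at least degree + 1")
    n = len(curve)
    if n < window_points:
        raise InputError(
            f"curve has {n} samples but the window needs {window_points}"
        )
    t, c = curve.time_h, curve.co2_cumulative
    rate = np.full(n, np.nan)
    for i in range(window_points - 1, n):
        sl = slice(i - window_points + 1, i + 1)
        # centre time on t_i so the linear coefficient is the derivative there
        coeffs = np.polynomial.polynomial.polyfit(t[sl] - t[i], c[sl], degree)
        rate[i] = coeffs[1]
    return rate


def phenotype_at(curve: FermentationCurve, checkpoint_h: float = 89.0) -> float:
    """Cumulative CO2 at the checkpoint, linearly interpolated between the
    bracketing samples (the 89-h value is the study's capacity phenotype)."""
    t = curve.time_h
    if not (t[0] <= checkpoint_h <= t[-1]):
        raise InputError(
            f"checkpoint {checkpoint_h} h outside the measured range "
            f"[{t[0]}, {t[-1]}] h"
        )
    return float(np.interp(checkpoint_h, t, curve.co2_cumulative))
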