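"""Spectral detection of movement stereotypy.

Repetitive return movements show up as periodic structure in the
per-frame importance curve (and in keypoint tracks).  The dominant
period is found from the one-sided power spectrum of the detrended
signal (DC excluded), refined by the autocorrelation peak near the
spectral estimate, and converted to seconds through the effective frame
rate — e.g. an 11-frame period at 3 frames/s is ~3.7 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = ["PeriodicityResult", "power_spectrum", "dominant_period", "segment_and_align"]


@dataclass
class PeriodicityResult:
    dominant_period_frames: float | None
    period_seconds: float | None
    power_spectrum: pd.DataFrame  # columns: frequency (cycles/frame), power
    peak_significance: float
    is_periodic: bool
    fps_effective: float


def _detrend(x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "linear":
        return sps.detrend(x, type="linear")
    if mode == "mean":
        return x - x.mean()
    if mode in (None, "none"):
        return x
    raise ValueError(f"unknown detrend mode {mode!r}")


def power_spectrum(signal_values, detrend: str = "linear") -> pd.DataFrame:
    """One-sided periodogram of the detrended signal.

    Subtracting the mean and linear trend first keeps strong aperiodic
    structure (e.g. a large first-frame importance spike) from leaking
    broadband power over the band of interest.
    """
    x = np.asarray(signal_values, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if x.size < 8:
        raise ValueError(f"signal too short for spectral analysis ({x.size} < 8 frames)")
    xd = _detrend(x, detrend)
    freqs, power = sps.periodogram(xd, fs=1.0, detrend=False)
    return pd.DataFrame({"frequency": freqs, "power": power})


def _autocorr(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return np.zeros(len(x))
    full = np.correlate(x, x, mode="full")[len(x) - 1 :]
    return full / denom


def _autocorr_peak(ac: np.ndarray, p_guess: float, min_period: int) -> tuple[float, float]:
    """Best integer autocorrelation lag near ``p_guess``, parabolically
    refined; returns (period, autocorrelation value)."""
    lo = max(min_period, int(np.floor(0.75 * p_guess)))
    hi = min(len(ac) - 1, int(np.ceil(1.33 * p_guess)))
    if hi <= lo:
        return float(p_guess), float(ac[int(round(min(p_guess, len(ac) - 1)))])
    lags = np.arange(lo, hi + 1)
    best = int(lags[np.argmax(ac[lo : hi + 1])])
    value = float(ac[best])
    if 1 <= best < len(ac) - 1:
        y0, y1, y2 = ac[best - 1], ac[best], ac[best + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        return float(best + np.clip(shift, -0.5, 0.5)), value
    return float(best), value


def dominant_period(
    signal_values,
    fps_effective: float,
    min_period: int = 2,
    max_period: int | None = None,
    detrend: str = "linear",
    significance_threshold: float = 12.0,
) -> PeriodicityResult:
    """Dominant period of a signal, in frames and seconds.

    The period comes from the spectral argmax over resolvable
    frequencies (DC excluded; periods capped at ``max_period``, default
    a third of the signal so at least three repetitions support the
    call), refined by the autocorrelation peak near the spectral
    estimate.  Because the spectral argmax of a non-sinusoidal cycle can
    land on a harmonic, the doubled period is also considered and wins
    if its autocorrelation peak is higher (standard octave correction).

    The peak is declared significant when its power is at least
    ``significance_threshold`` times the median power of the searched
    band; the default is calibrated so white noise is flagged periodic
    in well under 5% of runs.  Otherwise the result is flagged
    non-periodic and no period is reported.
    """
    x = np.asarray(signal_values, dtype=np.float64)
    spec = power_spectrum(x, detrend=detrend)
    if max_period is None:
        max_period = max(x.size // 3, min_period + 1)
    band = spec[(spec.frequency >= 1.0 / max_period) & (spec.frequency <= 1.0 / min_period)]
    if band.empty:
        raise ValueError("no frequencies available inside the period bounds")
    peak_row = band.loc[band.power.idxmax()]
    med = float(band.power.median())
    significance = float(peak_row.power / med) if med > 0 else np.inf
    if significance < significance_threshold:
        return PeriodicityResult(None, None, spec, significance, False, fps_effective)

    p_spec = 1.0 / peak_row.frequency
    ac = _autocorr(_detrend(x, detrend))
    candidates = [m * p_spec for m in (1, 2, 3) if m * p_spec <= max_period]
    period, _ = max(
        (_autocorr_peak(ac, c, min_period) for c in candidates),
        key=lambda pv: pv[1],
    )
    return PeriodicityResult(
        dominant_period_frames=period,
        period_seconds=period / fps_effective,
        power_spectrum=spec,
        peak_significance=significance,
        is_periodic=True,
        fps_effective=fps_effective,
    )


def segment_and_align(track_or_frames, period_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Cut a per-frame array into consecutive whole periods.

    Returns ``(segments, start_indices)`` where ``segments`` stacks the
    ``floor(T / period)`` period-length slices (trailing remainder
    dropped) and ``start_indices`` gives each segment's first frame —
    the alignment table used to montage period-aligned frames.
    """
    arr = np.asarray(track_or_frames)
    period = int(period_frames)
    if period < 2:
        raise ValueError("period_frames must be >= 2")
    n_seg = arr.shape[0] // period
    if n_seg < 2:
        raise ValueError(
            f"need at least 2 whole segments: {arr.shape[0]} frames give "
            f"{n_seg} segment(s) of period {period}"
        )
    segments = arr[: n_seg * period].reshape((n_seg, period) + arr.shape[1:])
    return segments, np.arange(n_seg) * period
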