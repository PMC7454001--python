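"""Spectral noise measurement: PSD estimation, de-embedding, band integration.

This is the measurement side of the noise verification chain.  A recording
made through the multiplexer carries electrode thermal noise, the recording
circuit's own noise, and quantization noise.  The circuit contribution is
removed by *de-embedding*: subtracting the power spectral density acquired
with the input grounded from the density of the actual recording.  The
remainder is band-integrated (500 Hz - 5 kHz by convention, the spike band
after filtering) and compared against the impedance-predicted thermal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "PsdEstimate",
    "NoiseComparison",
    "estimate_psd",
    "de_embed",
    "integrate_band",
    "percent_error",
    "compare_noise",
]


@dataclass(frozen=True)
class PsdEstimate:
    """One-sided power spectral density in V^2/Hz on an increasing frequency grid."""

    freq_hz: np.ndarray
    density: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        f = np.asarray(self.freq_hz, dtype=float)
        s = np.asarray(self.density, dtype=float)
        if f.ndim != 1 or s.ndim != 1 or f.size != s.size:
            raise ValueError("freq_hz and density must be 1-D arrays of equal length")
        if f.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(f) <= 0):
            raise ValueError("freq_hz must be strictly increasing")
        if not np.all(np.isfinite(s)):
            raise ValueError("density must be finite")
        object.__setattr__(self, "freq_hz", f)
        object.__setattr__(self, "density", s)

    def interp(self, f) -> np.ndarray:
        """Density at arbitrary frequencies; flat extension outside the grid."""
        return np.interp(np.asarray(f, dtype=float), self.freq_hz, self.density)

    def total_power(self) -> float:
        """Trapezoidal integral of the density over the tabulated grid (V^2)."""
        return float(np.trapezoid(self.density, self.freq_hz))


@dataclass(frozen=True)
class NoiseComparison:
    """Measured-vs-predicted band noise for one electrode."""

    electrode_id: int
    de_embedded_vrms: float
    predicted_vrms: float

    @property
    def percent_error(self) -> float:
        return percent_error(self.de_embedded_vrms, self.predicted_vrms)


def _samples_fs(stream, f_s):
    if f_s is None:
        return np.asarray(stream.samples, dtype=float), float(stream.f_s)
    return np.asarray(stream, dtype=float), float(f_s)


def estimate_psd(stream, segment_s: float = 0.25, overlap: float = 0.5,
                 f_s: float | None = None) -> PsdEstimate:
    """Welch estimate (Hann window, averaged modified periodograms) of a stream.

    ``stream`` is anything with ``.samples``/``.f_s`` attributes (a demultiplexed
    channel), or a plain array together with an explicit ``f_s``.
    """
    x, fs = _samples_fs(stream, f_s)
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    nperseg = int(round(segment_s * fs))
    if nperseg < 8:
        raise ValueError("segment too short for a meaningful periodogram")
    if x.size < 2 * nperseg:
        raise ValueError(
            f"stream too short: {x.size} samples < 2 segments of {nperseg}")
    noverlap = int(round(overlap * nperseg))
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
                     detrend="constant", return_onesided=True)
    meta = {"window": "hann", "nperseg": nperseg, "noverlap": noverlap,
            "f_s": fs, "n_samples": int(x.size)}
    return PsdEstimate(f, p, meta)


def de_embed(measured: PsdEstimate, grounded: PsdEstimate) -> PsdEstimate:
    """Subtract the grounded-input density from a measured density.

    Negative bins (measurement noise can push the difference below zero) are
    clipped at zero; the number of clipped bins is reported in the metadata.
    """
    if measured.freq_hz.size != grounded.freq_hz.size or not np.allclose(
            measured.freq_hz, grounded.freq_hz):
        raise ValueError("frequency grids do not match")
    diff = measured.density - grounded.density
    clipped = int(np.sum(diff < 0))
    meta = dict(measured.meta)
    meta["clipped_bins"] = clipped
    return PsdEstimate(measured.freq_hz, np.clip(diff, 0.0, None), meta)


def integrate_band(psd: PsdEstimate, f_lo: float = 500.0,
                   f_hi: float = 5000.0) -> float:
    """rms (volts) of the density integrated over [f_lo, f_hi].

    Band edges are linearly interpolated onto the grid before the trapezoidal
    integral, so the band need not align with tabulated points.
    """
    if not f_lo < f_hi:
        raise ValueError("require f_lo < f_hi")
    if f_lo < psd.freq_hz[0] - 1e-9 or f_hi > psd.freq_hz[-1] + 1e-9:
        raise ValueError(
            f"band [{f_lo}, {f_hi}] Hz outside tabulated grid "
            f"[{psd.freq_hz[0]}, {psd.freq_hz[-1]}] Hz")
    inside = (psd.freq_hz > f_lo) & (psd.freq_hz < f_hi)
    f = np.concatenate([[f_lo], psd.freq_hz[inside], [f_hi]])
    s = np.concatenate([[psd.interp(f_lo)], psd.density[inside], [psd.interp(f_hi)]])
    return float(np.sqrt(np.trapezoid(s, f)))


def percent_error(measured: float, predicted: float) -> float:
    """(measured - predicted)/predicted * 100."""
    if predicted <= 0:
        raise ValueError("predicted must be positive")
    return (measured - predicted) / predicted * 100.0


def compare_noise(measured: Mapping[int, float],
                  predicted: Mapping[int, float]) -> pd.DataFrame:
    """Per-electrode measured-vs-predicted table with a trailing mean row.

    Both mappings are electrode_id -> rms volts; the table prints uVrms and a
    percent-error column rounded to the nearest integer (column means are
    computed from the unrounded per-electrode values).
    """
    if set(measured) != set(predicted):
        raise ValueError("measured and predicted electrode ids do not match")
    if not measured:
        return pd.DataFrame(
            columns=["electrode", "de_embedded_uvrms", "predicted_uvrms",
                     "percent_error"])
    rows = []
    errors = []
    for e in sorted(measured):
        err = percent_error(measured[e], predicted[e])
        errors.append(err)
        rows.append({"electrode": e,
                     "de_embedded_uvrms": measured[e] * 1e6,
                     "predicted_uvrms": predicted[e] * 1e6,
                     "percent_error": round(err)})
    rows.append({"electrode": "mean",
                 "de_embedded_uvrms": float(np.mean([r["de_embedded_uvrms"] for r in rows])),
                 "predicted_uvrms": float(np.mean([r["predicted_uvrms"] for r in rows])),
                 "percent_error": float(np.mean(errors))})
    return pd.DataFrame(rows)
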