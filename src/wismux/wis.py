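"""Windowed integration sampling (WIS) theory.

A WIS front end acquires each sample as the average of the input over a
finite window T_int, so its frequency response is the boxcar magnitude
|sinc(f T_int)| with unity DC gain.  The noise-equivalent bandwidth of that
response is 1/(2 T_int) -- for the 1.5 us window used throughout, 333 kHz --
which is what a multiplexed sampler folds down to its per-channel Nyquist
frequency.  This module holds that transfer function, the NEB comparison
against settle-and-sample acquisition, PSD alias folding, and the
impedance-to-baseband noise prediction used to verify the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .electrode import K_BOLTZMANN, ImpedanceSpectrum
from .noise import PsdEstimate, integrate_band

__all__ = [
    "WisParams",
    "wis_gain",
    "neb_wis",
    "neb_wis_quadrature",
    "neb_settling",
    "neb_ratio",
    "fold_psd",
    "predict_baseband_noise",
]


@dataclass(frozen=True)
class WisParams:
    """Timing of one multiplexer slot.

    The slot T_slot is split into a settling dead-time (first
    ``settle_fraction`` of the slot, discarded) and the integration window
    T_int over which the boxcar average is taken.
    """

    t_int: float = 1.5e-6
    t_slot: float = 1.0 / 600e3
    settle_fraction: float = 0.10

    def __post_init__(self):
        if not 0 < self.t_int <= self.t_slot:
            raise ValueError("require 0 < t_int <= t_slot")
        if abs(self.t_int - self.t_slot * (1.0 - self.settle_fraction)) > 1e-9:
            raise ValueError("t_int must equal t_slot*(1 - settle_fraction)")

    @classmethod
    def from_mux(cls, f_mux: float, settle_fraction: float = 0.10) -> "WisParams":
        t_slot = 1.0 / f_mux
        return cls(t_int=t_slot * (1.0 - settle_fraction), t_slot=t_slot,
                   settle_fraction=settle_fraction)


def wis_gain(f, t_int: float):
    """Normalized boxcar integrator magnitude |sin(pi f T)/(pi f T)|."""
    if t_int <= 0:
        raise ValueError("t_int must be > 0")
    return np.abs(np.sinc(np.asarray(f, dtype=float) * t_int))


def neb_wis(t_int: float) -> float:
    """NEB of the unit-DC-gain boxcar: 1/(2 T_int)."""
    if t_int <= 0:
        raise ValueError("t_int must be > 0")
    return 1.0 / (2.0 * t_int)


def neb_wis_quadrature(t_int: float, n_lobes: int = 2000,
                       samples_per_lobe: int = 64) -> float:
    """Numerical NEB: integral of |H|^2 over [0, inf), by composite Simpson
    over the first ``n_lobes`` sinc lobes plus the analytic 1/(2 pi^2 x) tail."""
    if t_int <= 0:
        raise ValueError("t_int must be > 0")
    x = np.linspace(0.0, n_lobes, n_lobes * samples_per_lobe + 1)
    from scipy.integrate import simpson
    body = simpson(np.sinc(x) ** 2, x=x)
    tail = 1.0 / (2.0 * np.pi ** 2 * n_lobes)  # mean of sin^2 over the tail
    return (body + tail) / t_int


def neb_settling(t_slot: float, settle_tol: float) -> float:
    """NEB of a one-pole settle-and-sample acquisition.

    Settling to relative tolerance ``settle_tol`` within the slot fixes the
    pole time constant tau = t_slot/ln(1/tol); the sampled one-pole response
    has NEB = 1/(4 tau).
    """
    if t_slot <= 0:
        raise ValueError("t_slot must be > 0")
    if not 0 < settle_tol < 1:
        raise ValueError("settle_tol must be in (0, 1)")
    return np.log(1.0 / settle_tol) / (4.0 * t_slot)


def neb_ratio(settle_tol: float) -> float:
    """neb_settling / neb_wis for equal windows: ln(1/tol)/2."""
    if not 0 < settle_tol < 1:
        raise ValueError("settle_tol must be in (0, 1)")
    return np.log(1.0 / settle_tol) / 2.0


def fold_psd(psd: PsdEstimate, f_nyq: float, f_max: float,
             n_grid: int = 4097) -> PsdEstimate:
    """Alias-fold a density onto [0, f_nyq].

    S_folded(f) = sum_k S(2k f_nyq + f) + S(2(k+1) f_nyq - f), with S
    interpolated from the tabulation (flat beyond the last point) and taken
    as zero above f_max.  Total power over [0, f_nyq] equals the input power
    over [0, f_max].
    """
    if f_max < f_nyq:
        raise ValueError("f_max must be >= f_nyq")

    def s_at(f):
        out = np.interp(f, psd.freq_hz, psd.density)
        out[f > f_max] = 0.0
        return out

    f = np.linspace(0.0, f_nyq, n_grid)
    folded = np.zeros_like(f)
    k = 0
    while 2 * k * f_nyq <= f_max:
        folded += s_at(2 * k * f_nyq + f)
        folded += s_at(2 * (k + 1) * f_nyq - f)
        k += 1
    meta = {"kind": "folded", "f_nyq": float(f_nyq), "f_max": float(f_max),
            "n_folds": k}
    return PsdEstimate(f, folded, meta)


def predict_baseband_noise(imp: ImpedanceSpectrum, wis: WisParams, f_s: float,
                           n_ave: int, band: tuple[float, float] = (500.0, 5000.0),
                           temperature: float = 310.0,
                           f_max: float | None = None) -> float:
    """Impedance-predicted baseband noise (volts rms) after WIS acquisition.

    Chain: Johnson density 4kT Re(Z) -> multiply by the WIS |H|^2 ->
    alias-fold to f_s/2 -> divide by the number of averaged slices ->
    band-integrate.  Averaged slices are treated as independent (post-hoc
    averaging), which matches folding the per-slice density then dividing by
    n_ave.  Scales as 1/sqrt(n_ave) for white inputs.
    """
    if n_ave < 1:
        raise ValueError("n_ave must be >= 1")
    f_nyq = f_s / 2.0
    if not (0.0 <= band[0] < band[1] <= f_nyq):
        raise ValueError("band must lie within [0, f_s/2]")
    if f_max is None:
        f_max = 10.0 / wis.t_int  # covers >99.9% of the sinc^2 power
    # dense tabulation of the shaped input density; z_real_at handles log-f
    # interpolation inside the EIS band and flat extension outside it
    f_fine = np.linspace(0.0, f_max, (1 << 16) + 1)
    s_fine = (4.0 * K_BOLTZMANN * temperature * imp.z_real_at(f_fine)
              * wis_gain(f_fine, wis.t_int) ** 2)
    shaped = PsdEstimate(f_fine, s_fine)
    folded = fold_psd(shaped, f_nyq, f_max)
    per_sample = PsdEstimate(folded.freq_hz, folded.density / n_ave, folded.meta)
    return integrate_band(per_sample, band[0], band[1])
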