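"""Electrode-tissue interface: impedance, thermal noise, offsets, noise synthesis.

An extracellular microwire electrode in tissue (or saline) presents a complex,
frequency-dependent impedance Z(f).  Its real part generates Johnson noise
with one-sided density S(f) = 4 k_B T Re{Z(f)}, which is the dominant
electrode-side noise source that a wideband multiplexed front end aliases into
the signal band.  The interface also carries a DC half-cell offset of tens of
millivolts that drifts slowly (about 300 uV/s on chronically implanted
tungsten microwires), which is what the offset-cancellation DACs must track.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .noise import PsdEstimate

__all__ = [
    "K_BOLTZMANN",
    "ImpedanceSpectrum",
    "ElectrodeState",
    "InterfaceModel",
    "thermal_noise_psd",
    "evolve_offset",
    "synth_colored_noise",
    "fit_interface_model",
    "pbs_interface",
    "implanted_interface",
]

K_BOLTZMANN = 1.380649e-23  # J/K (exact, SI 2019)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Tabulated complex electrode impedance versus frequency.

    Inside the tabulated band the real part is interpolated linearly in
    log-frequency; outside it is held flat, since wideband behavior is needed
    for alias folding while impedance is typically measured only over the
    audio band.
    """

    freq_hz: np.ndarray
    z_real_ohm: np.ndarray
    z_imag_ohm: np.ndarray

    def __post_init__(self):
        f = np.atleast_1d(np.asarray(self.freq_hz, dtype=float))
        zr = np.atleast_1d(np.asarray(self.z_real_ohm, dtype=float))
        zi = np.atleast_1d(np.asarray(self.z_imag_ohm, dtype=float))
        if f.size == 0:
            raise ValueError("empty impedance spectrum")
        if not (f.size == zr.size == zi.size):
            raise ValueError("freq/real/imag lengths differ")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("freq_hz must be positive and strictly increasing")
        if np.any(zr < 0):
            raise ValueError("Re(Z) must be >= 0")
        object.__setattr__(self, "freq_hz", f)
        object.__setattr__(self, "z_real_ohm", zr)
        object.__setattr__(self, "z_imag_ohm", zi)

    @classmethod
    def from_resistance(cls, r_ohm: float, f_lo: float = 1.0,
                        f_hi: float = 1e7, n: int = 50) -> "ImpedanceSpectrum":
        """Purely resistive (white-noise) interface."""
        f = np.logspace(np.log10(f_lo), np.log10(f_hi), n)
        return cls(f, np.full(n, float(r_ohm)), np.zeros(n))

    def z_real_at(self, f) -> np.ndarray:
        """Re(Z) at arbitrary frequencies (log-f interpolation, flat ends)."""
        f = np.asarray(f, dtype=float)
        fc = np.clip(f, self.freq_hz[0], self.freq_hz[-1])
        return np.interp(np.log(fc), np.log(self.freq_hz), self.z_real_ohm)

    @property
    def z_mag_ohm(self) -> np.ndarray:
        return np.hypot(self.z_real_ohm, self.z_imag_ohm)

    def to_table(self, path) -> None:
        """Write as 3-column delimited text (freq_hz, z_real_ohm, z_imag_ohm)."""
        np.savetxt(path, np.column_stack([self.freq_hz, self.z_real_ohm,
                                          self.z_imag_ohm]),
                   header="freq_hz z_real_ohm z_imag_ohm")

    @classmethod
    def from_table(cls, path) -> "ImpedanceSpectrum":
        arr = np.atleast_2d(np.loadtxt(path))
        return cls(arr[:, 0], arr[:, 1], arr[:, 2])


@dataclass(frozen=True)
class ElectrodeState:
    """One electrode's slowly varying state.

    v_offset is the DC half-cell offset seen at the multiplexer input
    (nominal correction range +/-65 mV); drift_rate its linear drift in V/s.
    """

    electrode_id: int
    impedance: ImpedanceSpectrum
    v_offset: float = 0.0
    drift_rate: float = 300e-6
    temperature: float = 310.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if not np.isfinite(self.drift_rate):
            raise ValueError("drift_rate must be finite")


def thermal_noise_psd(imp: ImpedanceSpectrum, temperature: float) -> PsdEstimate:
    """One-sided Johnson density 4 k_B T Re{Z(f)} at the tabulated frequencies."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    density = 4.0 * K_BOLTZMANN * temperature * imp.z_real_ohm
    return PsdEstimate(imp.freq_hz, density,
                       {"kind": "thermal", "temperature_k": float(temperature)})


def evolve_offset(state: ElectrodeState, dt: float,
                  jitter_rms: float = 0.0,
                  rng: np.random.Generator | None = None) -> ElectrodeState:
    """Advance the DC offset by drift_rate*dt (plus optional seeded jitter)."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    dv = state.drift_rate * dt
    if jitter_rms > 0.0:
        if rng is None:
            raise ValueError("jitter requires an explicit rng")
        dv += jitter_rms * rng.standard_normal()
    return replace(state, v_offset=state.v_offset + dv)


def synth_colored_noise(psd: PsdEstimate, duration: float, f_sim: float,
                        seed) -> np.ndarray:
    """Zero-mean Gaussian sequence at rate f_sim whose PSD matches ``psd``.

    Frequency-domain shaping: independent complex Gaussian bins scaled by
    sqrt(S(f) f_sim N / 2) and inverse-rFFT'd.  The target density is
    interpolated onto the FFT grid and held flat beyond the last tabulated
    frequency, so alias folding in a downstream sampler emerges physically.
    Deterministic given the seed.
    """
    if f_sim * (1.0 + 1e-9) < 2.0 * psd.freq_hz[-1]:
        raise ValueError(
            f"f_sim={f_sim} too low to represent psd support up to "
            f"{psd.freq_hz[-1]} Hz")
    n = int(round(duration * f_sim))
    if n < 2:
        raise ValueError("duration*f_sim must be >= 2 samples")
    freqs = np.fft.rfftfreq(n, d=1.0 / f_sim)
    s = np.interp(freqs, psd.freq_hz, psd.density)  # flat ends
    rng = np.random.default_rng(seed)
    nf = freqs.size
    w = (rng.standard_normal(nf) + 1j * rng.standard_normal(nf)) / np.sqrt(2.0)
    amp = np.sqrt(s * f_sim * n / 2.0)
    x_f = amp * w
    x_f[0] = 0.0  # zero mean
    if n % 2 == 0:
        # Nyquist bin must be real; keep its variance
        x_f[-1] = amp[-1] * np.sqrt(2.0) * w[-1].real
    return np.fft.irfft(x_f, n=n)


@dataclass(frozen=True)
class InterfaceModel:
    """Series resistance + parallel RC: Z = R_s + R_p / (1 + j 2 pi f R_p C_p).

    A deliberately coarse stand-in for an electrode interface: R_s models
    spreading/solution resistance (the high-frequency plateau), the parallel
    RC the interfacial dispersion.  It reproduces measured |Z| anchors without
    asserting any particular electrochemistry.
    """

    r_series_ohm: float
    r_parallel_ohm: float
    c_parallel_f: float

    def impedance(self, f) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        zp = self.r_parallel_ohm / (
            1.0 + 1j * 2.0 * np.pi * f * self.r_parallel_ohm * self.c_parallel_f)
        return self.r_series_ohm + zp

    def spectrum(self, f_lo: float = 1.0, f_hi: float = 1e7,
                 n: int = 200) -> ImpedanceSpectrum:
        f = np.logspace(np.log10(f_lo), np.log10(f_hi), n)
        z = self.impedance(f)
        return ImpedanceSpectrum(f, z.real, z.imag)


def fit_interface_model(anchors, corner_hz: float | None = None) -> InterfaceModel:
    """Least-squares fit of (R_s, R_p) to |Z| anchors [(f_hz, zmag_ohm), ...].

    With only two magnitude anchors the three-parameter circuit is
    underdetermined, so C_p is tied to a fixed dispersion corner
    f_c = 1/(2 pi R_p C_p); by default the geometric mean of the anchor
    frequencies.
    """
    anchors = [(float(f), float(z)) for f, z in anchors]
    if len(anchors) < 2:
        raise ValueError("need at least two anchors")
    if corner_hz is None:
        corner_hz = float(np.exp(np.mean(np.log([f for f, _ in anchors]))))

    f = np.array([a[0] for a in anchors])
    zmag = np.array([a[1] for a in anchors])
    x = f / corner_hz  # normalized frequency; 1 + jx is the RC denominator

    def resid(p):
        rs, rp = np.exp(p)
        z = rs + rp / (1.0 + 1j * x)
        return (np.abs(z) - zmag) / zmag

    z0 = zmag[-1] * 0.8
    sol = least_squares(resid, x0=np.log([z0, max(zmag[0] - z0, 1.0)]))
    rs, rp = np.exp(sol.x)
    cp = 1.0 / (2.0 * np.pi * rp * corner_hz)
    return InterfaceModel(rs, rp, cp)


@lru_cache(maxsize=None)
def pbs_interface() -> InterfaceModel:
    """Interface fit to bench (saline) anchors: |Z| ~ 5 kOhm @ 1 kHz, 2 kOhm @ 30 kHz."""
    return fit_interface_model([(1e3, 5e3), (30e3, 2e3)])


@lru_cache(maxsize=None)
def implanted_interface() -> InterfaceModel:
    """Interface fit to implanted anchors: |Z| ~ 54 kOhm @ 1 kHz, 24 kOhm @ 30 kHz."""
    return fit_interface_model([(1e3, 54e3), (30e3, 24e3)])
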