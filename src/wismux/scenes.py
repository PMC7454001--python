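"""Ground-truth extracellular scene synthesis.

A "scene" is the continuous-time voltage presented to the multiplexer by each
electrode, built from four additive parts:

* the DC half-cell offset (with linear drift),
* local field potential: a large slow oscillation (~700 uVpp at 1-2 Hz, as
  seen under ketamine anesthesia) plus smaller 20-100 Hz components,
* multiunit spiking: a biphasic ~1.6 ms template placed at event times from a
  bursting point process (bursts recur at ~5-7 Hz, again the ketamine regime),
* electrode thermal noise colored by the measured impedance.

Every stochastic part is seeded independently per (scene seed, electrode,
source), so scenes compose additively: rendering two sources together equals
the sum of rendering each alone with the same seed.  The true spike times are
kept so detector output can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .electrode import ElectrodeState, synth_colored_noise, thermal_noise_psd
from .noise import PsdEstimate

__all__ = [
    "LfpConfig",
    "SpikeSceneConfig",
    "Scene",
    "default_template",
    "gen_lfp",
    "gen_spike_train",
    "render_scene",
]

# sub-seed codes so that each source draws from an independent stream
_SRC_LFP, _SRC_SPIKES, _SRC_NOISE = 11, 22, 33


@dataclass(frozen=True)
class LfpConfig:
    """LFP composition: slow oscillation plus small mid-band sinusoids.

    Defaults give a <300 Hz peak-to-peak in the 600-800 uV range typical of
    cortical LFP under ketamine.
    """

    components: tuple = ((30.0, 20e-6), (55.0, 15e-6), (85.0, 10e-6))
    slow_osc_pkpk_v: float = 700e-6
    slow_osc_freq_hz: float = 1.5

    def __post_init__(self):
        for f, a in self.components:
            if f <= 0 or a < 0:
                raise ValueError("component frequencies must be > 0, amplitudes >= 0")
        if self.slow_osc_pkpk_v < 0 or self.slow_osc_freq_hz <= 0:
            raise ValueError("invalid slow oscillation parameters")

    def max_freq(self) -> float:
        return max([self.slow_osc_freq_hz] + [f for f, _ in self.components])


def default_template(f_grid: float = 60e3, duration: float = 1.6e-3):
    """Biphasic multiunit template: negative trough then a smaller positive
    peak (trough:peak about 2:1), 1.6 ms support, unit peak-to-peak.

    Returns (time_s, value) arrays suitable for 2-column text serialization.
    """
    t = np.arange(int(round(duration * f_grid))) / f_grid
    # widths chosen so the 750-4000 Hz spike filter passes the shape with
    # <10% peak-to-peak droop (FWHM ~0.19 ms, typical of cortical multiunits)
    trough = -np.exp(-0.5 * ((t - 0.55e-3) / 0.08e-3) ** 2)
    peak = 0.5 * np.exp(-0.5 * ((t - 0.75e-3) / 0.08e-3) ** 2)
    w = trough + peak
    w -= w[0]  # anchor the edges near zero
    w /= w.max() - w.min()
    return t, w


@dataclass(frozen=True)
class SpikeSceneConfig:
    """Bursting multiunit spike generator settings.

    ``template_t/template_v`` is the unit-pkpk waveform (duration must match
    the snippet length used downstream); ``amplitude_pkpk_v`` scales it per
    electrode.  Events occur in bursts recurring at ``burst_rate_hz`` (each of
    ``burst_duration_s``, Poisson at ``within_burst_rate_hz`` inside), on top
    of a sparse Poisson baseline, with refractory dead-time deletion.
    """

    template_t: np.ndarray = None
    template_v: np.ndarray = None
    amplitude_pkpk_v: float = 16e-6
    burst_rate_hz: float = 6.0
    within_burst_rate_hz: float = 100.0
    burst_duration_s: float = 0.05
    baseline_rate_hz: float = 1.0
    refractory_s: float = 1e-3

    def __post_init__(self):
        if self.template_t is None:
            t, w = default_template()
            object.__setattr__(self, "template_t", t)
            object.__setattr__(self, "template_v", w)
        else:
            object.__setattr__(self, "template_t",
                               np.asarray(self.template_t, dtype=float))
            object.__setattr__(self, "template_v",
                               np.asarray(self.template_v, dtype=float))
        if self.refractory_s <= 0:
            raise ValueError("refractory_s must be > 0")
        for r in (self.burst_rate_hz, self.within_burst_rate_hz,
                  self.baseline_rate_hz):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.amplitude_pkpk_v < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def template_duration_s(self) -> float:
        return float(self.template_t[-1] - self.template_t[0]
                     + np.median(np.diff(self.template_t)))

    @property
    def trough_offset_s(self) -> float:
        """Time of the template trough relative to the template start."""
        return float(self.template_t[np.argmin(self.template_v)])


@dataclass
class Scene:
    """Per-electrode continuous-time signals at rate f_sim plus spike truth."""

    f_sim: float
    duration_s: float
    electrodes: list
    signals: list
    truth: dict = field(default_factory=dict)
    lfp_cfg: LfpConfig | None = None
    spike_cfg: SpikeSceneConfig | None = None

    def __post_init__(self):
        if not self.electrodes:
            raise ValueError("electrode list must not be empty")
        if len(self.signals) != len(self.electrodes):
            raise ValueError("one signal per electrode required")
        n = len(self.signals[0])
        if any(len(s) != n for s in self.signals):
            raise ValueError("all electrode signals must have equal length")
        for times in self.truth.values():
            t = np.asarray(times)
            if t.size and (t.min() < 0 or t.max() >= self.duration_s):
                raise ValueError("truth times must lie in [0, duration)")

    def signal_for(self, electrode_id: int) -> np.ndarray:
        for e, s in zip(self.electrodes, self.signals):
            if e.electrode_id == electrode_id:
                return s
        raise KeyError(electrode_id)

    def write_truth(self, path) -> None:
        """Truth table as delimited text (electrode_id, time_s)."""
        rows = [(e, t) for e in sorted(self.truth) for t in self.truth[e]]
        arr = np.array(rows, dtype=float).reshape(-1, 2)
        np.savetxt(path, arr, header="electrode_id time_s")


def gen_lfp(cfg: LfpConfig, duration: float, f_sim: float, seed) -> np.ndarray:
    """Slow oscillation plus mid-band sinusoids with seeded random phases."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if f_sim <= 2.0 * cfg.max_freq():
        raise ValueError("f_sim must exceed twice the highest LFP component")
    n = int(round(duration * f_sim))
    t = np.arange(n) / f_sim
    rng = np.random.default_rng(seed)
    out = (cfg.slow_osc_pkpk_v / 2.0) * np.sin(
        2.0 * np.pi * cfg.slow_osc_freq_hz * t + rng.uniform(0, 2 * np.pi))
    for f, a in cfg.components:
        out += a * np.sin(2.0 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return out


def gen_spike_train(cfg: SpikeSceneConfig, duration: float, seed) -> np.ndarray:
    """Event times (s) from the bursting process; min gap >= refractory_s.

    Burst onsets form a jittered renewal process (intervals uniform in
    [0.8, 1.2]/burst_rate_hz) so the realized burst rate is tightly centered
    on the configured value; events inside each burst are Poisson, plus a
    sparse Poisson baseline, then refractory deletion.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    events = []
    if cfg.burst_rate_hz > 0 and cfg.within_burst_rate_hz > 0:
        t = rng.uniform(0.0, 1.0 / cfg.burst_rate_hz)
        while t < duration:
            n_ev = rng.poisson(cfg.within_burst_rate_hz * cfg.burst_duration_s)
            events.append(t + np.sort(rng.uniform(0, cfg.burst_duration_s, n_ev)))
            t += rng.uniform(0.8, 1.2) / cfg.burst_rate_hz
    if cfg.baseline_rate_hz > 0:
        n_base = rng.poisson(cfg.baseline_rate_hz * duration)
        events.append(rng.uniform(0, duration, n_base))
    if not events:
        return np.empty(0)
    times = np.sort(np.concatenate(events))
    times = times[times < duration]
    keep = []
    last = -np.inf
    for t in times:
        if t - last >= cfg.refractory_s:
            keep.append(t)
            last = t
    return np.asarray(keep)


def _render_spikes(times: np.ndarray, cfg: SpikeSceneConfig, n: int,
                   f_sim: float) -> np.ndarray:
    """Place the template (trough at each event time) into an n-sample trace."""
    out = np.zeros(n)
    n_tpl = int(round(cfg.template_duration_s * f_sim))
    tpl = np.interp(np.arange(n_tpl) / f_sim, cfg.template_t, cfg.template_v)
    tpl = tpl * cfg.amplitude_pkpk_v
    trough = int(round(cfg.trough_offset_s * f_sim))
    for t in times:
        i0 = int(round(t * f_sim)) - trough
        if i0 < 0 or i0 + n_tpl > n:
            continue
        out[i0:i0 + n_tpl] += tpl
    return out


def render_scene(electrodes, lfp_cfg: LfpConfig | None,
                 spike_cfg: SpikeSceneConfig | None, duration: float,
                 f_sim: float = 12e6, seed=0, include_noise: bool = True,
                 include_offset: bool = True, include_drift: bool = True,
                 shared_lfp: bool = True) -> Scene:
    """Superpose offset + LFP + spikes + thermal noise for each electrode.

    The LFP realization is shared across electrodes by default (field
    potentials are spatially coherent at these pitches); spike trains and
    noise are independent per electrode.
    """
    electrodes = list(electrodes)
    if not electrodes:
        raise ValueError("electrode list must not be empty")
    n = int(round(duration * f_sim))
    lfp_shared = None
    if lfp_cfg is not None and shared_lfp:
        lfp_shared = gen_lfp(lfp_cfg, duration, f_sim, [seed, _SRC_LFP])

    signals, truth = [], {}
    for idx, e in enumerate(electrodes):
        sig = np.zeros(n)
        if include_offset:
            sig += e.v_offset
            if include_drift and e.drift_rate != 0.0:
                sig += e.drift_rate * (np.arange(n) / f_sim)
        if lfp_cfg is not None:
            sig += lfp_shared if shared_lfp else gen_lfp(
                lfp_cfg, duration, f_sim, [seed, idx, _SRC_LFP])
        if spike_cfg is not None:
            times = gen_spike_train(spike_cfg, duration,
                                    [seed, idx, _SRC_SPIKES])
            truth[e.electrode_id] = times
            sig += _render_spikes(times, spike_cfg, n, f_sim)
        else:
            truth[e.electrode_id] = np.empty(0)
        if include_noise:
            psd = thermal_noise_psd(e.impedance, e.temperature)
            # truncate the tabulation at the simulation Nyquist; the density
            # there is the flat-extended value, so no in-band power is lost
            if psd.freq_hz[-1] > f_sim / 2.0:
                mask = psd.freq_hz < f_sim / 2.0
                psd = PsdEstimate(
                    np.append(psd.freq_hz[mask], f_sim / 2.0),
                    np.append(psd.density[mask], psd.interp(f_sim / 2.0)),
                    psd.meta)
            sig += synth_colored_noise(psd, duration, f_sim,
                                       [seed, idx, _SRC_NOISE])
        signals.append(sig)
    return Scene(f_sim=f_sim, duration_s=duration, electrodes=electrodes,
                 signals=signals, truth=truth, lfp_cfg=lfp_cfg,
                 spike_cfg=spike_cfg)
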