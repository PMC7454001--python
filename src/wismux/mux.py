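"""Rapidly multiplexed acquisition engine.

Models the sampling side of a front end that switches many electrodes onto a
single recording chain at f_mux (600 kHz by default, 20 slots per frame, so
30 kS/s per channel).  Each 1.67 us slot discards its first 10% for settling
and averages the input over the remaining 1.5 us (windowed integration
sampling).  Per-electrode DC offsets are cancelled by a two-stage DAC
(4-bit coarse + 5-bit fine over +/-65 mV, +/-250 uV resolution) whose codes
are found by binary search and refreshed periodically to track drift.  The
ADC quantizes what is left; adjacent slots may couple through a single
crosstalk coefficient.  Demultiplexing averages an electrode's slices within
each frame back into a uniform per-channel stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .scenes import Scene
from .wis import WisParams

__all__ = [
    "IDLE",
    "MuxConfig",
    "DacCodes",
    "RawStream",
    "ChannelStream",
    "build_sequence",
    "search_dac_codes",
    "calibrate_offsets",
    "simulate_acquisition",
    "demultiplex",
    "save_streams",
    "load_streams",
]

IDLE = None  # idle-slot marker in slice sequences

COARSE_BITS, FINE_BITS = 4, 5
COARSE_STEP_V = 130e-3 / 16  # 8.125 mV
FINE_STEP_V = 500e-6
OFFSET_RANGE_V = 65e-3


@dataclass(frozen=True)
class DacCodes:
    """Two-stage offset-cancellation DAC setting for one electrode."""

    coarse: int
    fine: int
    saturated: bool = False

    def __post_init__(self):
        if not 0 <= self.coarse < 2 ** COARSE_BITS:
            raise ValueError("coarse code out of range")
        if not 0 <= self.fine < 2 ** FINE_BITS:
            raise ValueError("fine code out of range")

    @property
    def voltage(self) -> float:
        """Input-referred offset represented by the codes."""
        vc = (self.coarse - (2 ** COARSE_BITS - 1) / 2) * COARSE_STEP_V
        vf = (self.fine - (2 ** FINE_BITS - 1) / 2) * FINE_STEP_V
        return vc + vf


@dataclass(frozen=True)
class MuxConfig:
    """Multiplexer timing, slice allocation and converter parameters."""

    f_mux: float = 600e3
    n_tot: int = 20
    settle_fraction: float = 0.10
    slice_sequence: tuple = None
    recal_period_s: float = 3.5
    crosstalk_db: float | None = -60.0
    adc_bits: int = 10
    adc_range_v: float = 2.5e-3
    circuit_noise_rms: float = 5.5e-6  # input-referred, per slice

    def __post_init__(self):
        if self.f_mux <= 0 or self.n_tot < 1:
            raise ValueError("invalid f_mux or n_tot")
        if not 0 <= self.settle_fraction < 0.5:
            raise ValueError("settle_fraction out of range")
        if self.adc_bits < 2 or self.adc_range_v <= 0:
            raise ValueError("invalid ADC parameters")
        seq = self.slice_sequence
        if seq is None:
            seq = tuple(range(self.n_tot))  # one slice per electrode id 0..n_tot-1
        seq = tuple(seq)
        if len(seq) != self.n_tot:
            raise ValueError("slice_sequence length must equal n_tot")
        object.__setattr__(self, "slice_sequence", seq)

    @property
    def f_s(self) -> float:
        """Per-channel sampling rate: f_mux / n_tot."""
        return self.f_mux / self.n_tot

    @property
    def adc_lsb(self) -> float:
        return 2.0 * self.adc_range_v / 2 ** self.adc_bits

    def electrode_ids(self) -> list:
        seen = []
        for e in self.slice_sequence:
            if e is not IDLE and e not in seen:
                seen.append(e)
        return seen

    def positions(self, electrode_id) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.slice_sequence)
                         if e == electrode_id], dtype=int)


@dataclass
class ChannelStream:
    """Demultiplexed, uniformly sampled per-electrode stream (volts)."""

    electrode_id: int
    samples: np.ndarray
    f_s: float
    n_ave: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.f_s

    def with_samples(self, samples) -> "ChannelStream":
        return ChannelStream(self.electrode_id, samples, self.f_s, self.n_ave,
                             dict(self.meta))


@dataclass
class RawStream:
    """Interleaved per-slice ADC output: codes[frame, slot]."""

    codes: np.ndarray
    saturated: np.ndarray
    cfg: MuxConfig
    wis: WisParams
    dac_volts: np.ndarray  # offset voltage subtracted at each slice

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    def slice_times(self) -> np.ndarray:
        idx = np.arange(self.codes.size)
        return idx / self.cfg.f_mux

    def to_records(self):
        """Long-format per-slice records (slice_index, electrode_id, adc_code, time_s)."""
        import pandas as pd
        n = self.codes.size
        seq = self.cfg.slice_sequence
        eids = np.array([(-1 if e is IDLE else e) for e in seq], dtype=int)
        return pd.DataFrame({
            "slice_index": np.arange(n),
            "electrode_id": np.tile(eids, self.n_frames),
            "adc_code": self.codes.ravel(),
            "time_s": self.slice_times(),
        })


def build_sequence(allocation: Mapping[int, int], n_tot: int,
                   scheme: str = "contiguous", seed=0) -> tuple:
    """Slice sequence of length n_tot from an electrode -> slice-count map.

    Unassigned slots are idle.  ``scrambled`` applies a seed-deterministic
    permutation of all slots.
    """
    total = sum(allocation.values())
    if any(c < 0 for c in allocation.values()):
        raise ValueError("slice counts must be >= 0")
    if total > n_tot:
        raise ValueError(f"allocation sums to {total} > n_tot={n_tot}")
    seq = []
    for e in sorted(allocation):
        seq.extend([e] * allocation[e])
    seq.extend([IDLE] * (n_tot - total))
    if scheme == "contiguous":
        return tuple(seq)
    if scheme == "scrambled":
        rng = np.random.default_rng(seed)
        order = rng.permutation(n_tot)
        return tuple(seq[i] for i in order)
    raise ValueError(f"unknown scheme {scheme!r}")


def _quantize(v, cfg: MuxConfig):
    """Mid-tread quantization with saturation flags."""
    half = 2 ** (cfg.adc_bits - 1)
    code = np.rint(np.asarray(v) / cfg.adc_lsb).astype(np.int64) + half
    sat = (code < 0) | (code > 2 ** cfg.adc_bits - 1)
    return np.clip(code, 0, 2 ** cfg.adc_bits - 1), sat


def _code_to_volts(code, cfg: MuxConfig):
    return (np.asarray(code, dtype=float) - 2 ** (cfg.adc_bits - 1)) * cfg.adc_lsb


def search_dac_codes(v_target: float, measure=None) -> DacCodes:
    """Binary-search (SAR) the coarse then fine codes for an offset.

    ``measure(dac_voltage) -> float`` models the probe: it returns the
    observed residual for a trial DAC setting (by default the ideal
    ``v_target - dac_voltage``).  4 + 5 comparison rounds; each keeps a bit
    when the residual still exceeds half a step, which centers the final
    residual to within +/- half a fine step (250 uV) for offsets inside the
    +/-65 mV range.  Outside that range the codes pin and the result is
    flagged saturated.
    """
    if measure is None:
        def measure(dac_v):
            return v_target - dac_v

    def dac_c(c):
        return (c - (2 ** COARSE_BITS - 1) / 2) * COARSE_STEP_V

    def dac_f(f):
        return (f - (2 ** FINE_BITS - 1) / 2) * FINE_STEP_V

    coarse = 0
    for bit in (8, 4, 2, 1):
        trial = coarse | bit
        if measure(dac_c(trial)) >= -COARSE_STEP_V / 2:
            coarse = trial
    fine = 0
    for bit in (16, 8, 4, 2, 1):
        trial = fine | bit
        if measure(dac_c(coarse) + dac_f(trial)) >= -FINE_STEP_V / 2:
            fine = trial
    residual = measure(dac_c(coarse) + dac_f(fine))
    saturated = abs(residual) > FINE_STEP_V / 2 + 1e-9
    return DacCodes(coarse, fine, saturated)


def _require_scene_rate(scene: Scene, cfg: MuxConfig) -> int:
    spw = scene.f_sim / cfg.f_mux
    if abs(spw - round(spw)) > 1e-6:
        raise ValueError("scene f_sim must be an integer multiple of f_mux")
    spw = int(round(spw))
    if spw < 10:
        raise ValueError("scene rate too low: need f_sim >= 10*f_mux")
    return spw


def _slice_values(scene: Scene, cfg: MuxConfig, n_frames: int) -> np.ndarray:
    """Integrate the scene over every slot: (n_frames, n_tot) slice averages."""
    spw = _require_scene_rate(scene, cfg)
    settle_n = int(round(cfg.settle_fraction * spw))
    n_slices = n_frames * cfg.n_tot
    vals = np.zeros((n_frames, cfg.n_tot))
    for e in cfg.electrode_ids():
        pos = cfg.positions(e)
        sig = scene.signal_for(e)
        if sig.size < n_slices * spw:
            raise ValueError("scene shorter than requested acquisition")
        blocks = sig[: n_slices * spw].reshape(n_frames, cfg.n_tot, spw)
        vals[:, pos] = blocks[:, pos, settle_n:].mean(axis=2)
    return vals


def calibrate_offsets(scene: Scene, cfg: MuxConfig,
                      wis: WisParams | None = None,
                      probe_frames: int = 8) -> dict:
    """Binary-search DAC codes for every electrode from probe acquisitions.

    Each comparison uses the electrode's mean slice value over
    ``probe_frames`` frames, so electrode noise and in-band signal are
    averaged down before the 4+5 comparison rounds.
    """
    vals = _slice_values(scene, cfg, probe_frames)
    out = {}
    for e in cfg.electrode_ids():
        probe = float(vals[:, cfg.positions(e)].mean())
        out[e] = search_dac_codes(probe)
    return out


def simulate_acquisition(scene: Scene, cfg: MuxConfig,
                         wis: WisParams | None = None, seed=0,
                         dac_codes: Mapping[int, DacCodes] | None = None,
                         calibrate: bool = True,
                         probe_frames: int = 8) -> RawStream:
    """Run the multiplexer over a scene and return the per-slice ADC codes.

    Per slice: select the electrode from the sequence, discard the settling
    dead-time, boxcar-average the remaining window, subtract the electrode's
    DAC-represented offset (recalibrated every ``recal_period_s`` unless
    explicit ``dac_codes`` are given or ``calibrate`` is off), add the
    previous slice's value scaled by the crosstalk coefficient, add the
    chain's input-referred circuit noise, and quantize with saturation flags.
    """
    if wis is None:
        wis = WisParams.from_mux(cfg.f_mux, cfg.settle_fraction)
    n_frames = int(np.floor(scene.duration_s * cfg.f_s))
    if n_frames < 1:
        raise ValueError("scene shorter than one frame")
    vals = _slice_values(scene, cfg, n_frames)

    rng = np.random.default_rng(seed)
    if cfg.circuit_noise_rms > 0:
        vals = vals + cfg.circuit_noise_rms * rng.standard_normal(vals.shape)

    dac = np.zeros_like(vals)
    if dac_codes is not None:
        for e, codes in dac_codes.items():
            dac[:, cfg.positions(e)] = codes.voltage
    elif calibrate:
        block = max(1, int(round(cfg.recal_period_s * cfg.f_s)))
        for j0 in range(0, n_frames, block):
            j1 = min(j0 + block, n_frames)
            jp = min(j0 + probe_frames, n_frames)
            for e in cfg.electrode_ids():
                pos = cfg.positions(e)
                probe = float(vals[j0:jp, pos].mean())
                dac[j0:j1, pos] = search_dac_codes(probe).voltage

    corrected = vals - dac
    if cfg.crosstalk_db is not None:
        alpha = 10.0 ** (cfg.crosstalk_db / 20.0)
        flat = corrected.ravel()
        flat = flat + alpha * np.concatenate([[0.0], flat[:-1]])
        corrected = flat.reshape(corrected.shape)
    codes, sat = _quantize(corrected, cfg)
    return RawStream(codes=codes.astype(np.int32), saturated=sat, cfg=cfg,
                     wis=wis, dac_volts=dac)


def demultiplex(raw: RawStream, cfg: MuxConfig | None = None,
                restore_offset: bool = False) -> list:
    """Average each electrode's slices per frame into a 30 kS/s stream.

    Codes are converted back to input-referred volts; by default the
    DAC-cancelled offset stays removed (``offset_removed`` metadata flag),
    or is re-added for absolute reconstruction.
    """
    if cfg is None:
        cfg = raw.cfg
    elif cfg.slice_sequence != raw.cfg.slice_sequence:
        raise ValueError("sequence mismatch between raw stream and config")
    volts = _code_to_volts(raw.codes, cfg)
    if restore_offset:
        volts = volts + raw.dac_volts
    out = []
    for e in cfg.electrode_ids():
        pos = cfg.positions(e)
        samples = volts[:, pos].mean(axis=1)
        out.append(ChannelStream(
            electrode_id=e, samples=samples, f_s=cfg.f_s, n_ave=len(pos),
            meta={"offset_removed": not restore_offset,
                  "saturated_slices": int(raw.saturated[:, pos].sum())}))
    return out


def save_streams(path, streams: Sequence[ChannelStream], header: dict | None = None):
    """Columnar container (npz) with an embedded JSON header."""
    arrays = {}
    index = []
    for s in streams:
        arrays[f"samples_{s.electrode_id}"] = s.samples
        index.append({"electrode_id": s.electrode_id, "f_s": s.f_s,
                      "n_ave": s.n_ave, "meta": s.meta})
    arrays["header"] = np.frombuffer(
        json.dumps({"channels": index, **(header or {})}).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_streams(path) -> list:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"].tobytes()).decode())
        out = []
        for ch in header["channels"]:
            out.append(ChannelStream(
                electrode_id=ch["electrode_id"],
                samples=z[f"samples_{ch['electrode_id']}"],
                f_s=ch["f_s"], n_ave=ch["n_ave"], meta=ch.get("meta", {})))
    return out


def export_streams_text(path, streams: Sequence[ChannelStream]):
    """Delimited-text export: one column per electrode, sampled at f_s."""
    cols = [s.samples for s in streams]
    n = min(len(c) for c in cols)
    header = " ".join(f"e{s.electrode_id}_v" for s in streams)
    np.savetxt(path, np.column_stack([c[:n] for c in cols]), header=header)
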