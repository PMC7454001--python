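"""Published benchmark measurements for a rapidly multiplexed recording chip.

These are in vivo / in vitro characterization values for a 180 nm CMOS front
end that multiplexes a 16-channel tungsten microwire array (rat cortex) at
600 kHz with windowed integration sampling, recorded side by side with a
commercial bench-top system.  They serve as worked-example inputs and as the
operating point the synthetic scenes emulate: spike-band comparisons per
channel, the variable slice-allocation study, and the measured-vs-predicted
noise tables in vitro (saline) and in vivo.

All amplitudes are uV (uVrms for noise), offsets mV, at 30 kS/s/channel.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SYSTEM_SPECS",
    "spike_comparison_table",
    "slice_allocation_table",
    "noise_comparison_in_vitro",
    "noise_comparison_in_vivo",
]

# Bench system vs multiplexed test chip front-end figures
SYSTEM_SPECS = {
    "bench": {"input_noise_uvrms": 2.1, "bandwidth_hz": 4900.0,
              "highpass_hz": 1.0},
    "chip": {"input_noise_uvrms": 5.5, "bandwidth_hz": 15000.0,
             "highpass_hz": 0.2},
}

# Per-channel spike-filtered comparison (10 multiplexed electrodes, M = 10,
# 2 slices per channel): bench system vs chip, plus the chip-measured
# electrode offsets.
_SPIKE_ROWS = [
    # channel, bench_pkpk, chip_pkpk, bench_floor, chip_floor,
    # bench_snr, chip_snr, offset_mv
    (1, 17.32, 16.73, 3.37, 3.92, 2.71, 2.85, -20.2),
    (2, 10.50, 10.58, 2.09, 3.28, 3.24, 2.59, -4.1),
    (3, 15.68, 15.23, 3.11, 4.39, 2.87, 2.59, -10.9),
    (4, 17.87, 16.98, 3.46, 4.41, 3.18, 2.70, -13.2),
    (5, 19.03, 16.75, 3.28, 4.47, 3.21, 2.47, -10.5),
    (6, 21.07, 18.54, 3.62, 4.47, 3.76, 2.69, -11.4),
    (7, 19.15, 17.96, 3.72, 4.79, 2.82, 2.72, -13.8),
    (8, 16.32, 16.20, 3.34, 4.65, 2.81, 2.50, -13.6),
    (9, 14.73, 14.36, 3.02, 3.47, 2.90, 2.78, -11.1),
    (10, 12.06, 12.83, 2.64, 4.43, 3.18, 2.22, -13.2),
]

# Variable slice allocation study (M = 4, 16-slot sequence at 37.5 kS/s):
# electrode, slices, noise floor, pk-pk, SD_eps, SNR
_SLICE_ROWS = [
    (3, 2, 3.93, 15.12, 2.90, 2.61),
    (3, 3, 3.74, 14.95, 2.98, 2.51),
    (3, 5, 3.58, 14.90, 2.59, 2.88),
    (3, 6, 3.41, 14.88, 2.78, 2.68),
    (4, 2, 4.00, 17.11, 3.19, 2.68),
    (4, 3, 4.07, 17.06, 3.25, 2.63),
    (4, 5, 3.57, 17.24, 3.07, 2.80),
    (4, 6, 3.30, 16.82, 2.82, 2.99),
    (5, 2, 4.17, 16.84, 3.26, 2.59),
    (5, 3, 4.25, 17.06, 3.15, 2.71),
    (5, 5, 4.08, 16.17, 3.27, 2.48),
    (5, 6, 3.63, 16.56, 3.17, 2.61),
    (6, 2, 4.25, 18.62, 3.31, 2.81),
    (6, 3, 4.05, 18.11, 3.42, 2.65),
    (6, 5, 3.87, 18.18, 3.15, 2.71),
    (6, 6, 3.84, 18.86, 3.11, 3.04),
]

# In vitro (saline) de-embedded vs impedance-predicted noise, 500 Hz-5 kHz
_NOISE_VITRO = [
    (1, 1.7, 1.5), (2, 2.0, 1.6), (3, 2.1, 1.6), (4, 1.8, 1.5),
    (5, 2.0, 1.5), (6, 2.1, 1.6), (7, 1.7, 1.5), (8, 2.2, 1.4),
    (9, 2.2, 1.6), (10, 2.1, 1.6), (11, 1.7, 1.5), (12, 2.0, 1.5),
    (13, 1.8, 1.6), (14, 2.0, 1.5), (15, 1.7, 1.6), (16, 1.9, 1.6),
]

# In vivo de-embedded vs impedance-predicted noise, 500 Hz-5 kHz
_NOISE_VIVO = [
    (1, 5.8, 4.0), (2, 5.2, 4.0), (3, 5.0, 4.0), (4, 3.5, 2.5),
    (5, 4.2, 3.2), (6, 4.6, 3.2), (7, 5.1, 3.7), (8, 5.5, 4.0),
    (9, 4.0, 3.8), (10, 4.8, 3.5),
]


def spike_comparison_table() -> pd.DataFrame:
    return pd.DataFrame(_SPIKE_ROWS, columns=[
        "channel", "bench_pkpk_uv", "chip_pkpk_uv", "bench_floor_uvrms",
        "chip_floor_uvrms", "bench_snr", "chip_snr", "offset_mv"])


def slice_allocation_table() -> pd.DataFrame:
    return pd.DataFrame(_SLICE_ROWS, columns=[
        "electrode", "slices", "noise_floor_uvrms", "pkpk_uv", "sd_eps_uv",
        "snr"])


def noise_comparison_in_vitro() -> pd.DataFrame:
    return pd.DataFrame(_NOISE_VITRO, columns=[
        "electrode", "de_embedded_uvrms", "predicted_uvrms"])


def noise_comparison_in_vivo() -> pd.DataFrame:
    return pd.DataFrame(_NOISE_VIVO, columns=[
        "electrode", "de_embedded_uvrms", "predicted_uvrms"])
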