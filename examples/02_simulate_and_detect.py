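"""Simulate an in-vivo-like multiplexed recording and analyze spikes.

Renders two electrodes with measured-scale offsets, LFP, bursting multiunit
spikes (16 uVpp) and implanted-electrode thermal noise; acquires them at
600 kHz with 2 slices per channel; then runs the spike pipeline: 750-4000 Hz
zero-phase filtering, -3.0 sigma threshold crossings, 1.6 ms snippets, hoop
isolation, and the mean-waveform SNR summary.
"""

import wismux as wm

cfg = wm.ExperimentConfig.default(n_electrodes=2, n_ave=2, duration_s=2.0,
                                  seed=3)
result = wm.run_experiment(cfg)

print("per-channel spike-filtered summary (mean row at the bottom):")
print(result.summary.round(2).to_string(index=False))

for eid, snips in result.snippets.items():
    truth = result.scene.truth[eid]
    print(f"\nelectrode {eid}: {truth.size} true events, "
          f"{snips.n_events} isolated threshold crossings")

print("\npkpk_uv is the peak-to-peak of the mean multiunit waveform;"
      "\nnoise_floor_uvrms is the spike-band rms with event windows excised;"
      "\nsnr = pkpk / (2 * SD of the residual matrix).  At this operating"
      "\npoint the chain lands near the published values: ~4 uVrms floors"
      "\nand SNR in the 2.2-3.2 range for 16 uVpp multiunit events.")
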