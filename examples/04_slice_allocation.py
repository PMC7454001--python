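"""Non-uniform slice allocation: trading multiplexer time for noise.

Four electrodes share a 16-slot frame (37.5 kS/s) with budgets of 2, 3, 5
and 6 slices.  All four see the *same* underlying noise waveform, so the
spike-band floor isolates the effect of the budget: averaging N slices
divides the noise power by ~N.
"""

import numpy as np

import wismux as wm

imp = wm.implanted_interface().spectrum()
electrodes = [wm.ElectrodeState(i, imp, drift_rate=0.0, temperature=310.0)
              for i in (1, 2, 3, 4)]
base = wm.render_scene([electrodes[0]], None, None, 2.0, f_sim=6e6, seed=31)
scene = wm.Scene(f_sim=6e6, duration_s=2.0, electrodes=electrodes,
                 signals=[base.signals[0]] * 4)

budgets = {1: 2, 2: 3, 3: 5, 4: 6}
cfg = wm.MuxConfig(f_mux=600e3, n_tot=16,
                   slice_sequence=wm.build_sequence(budgets, 16))
streams = wm.demultiplex(wm.simulate_acquisition(scene, cfg, seed=32))

print("slices  noise floor (uVrms, 750-4000 Hz)")
for s in sorted(streams, key=lambda s: s.electrode_id):
    floor = np.sqrt(np.mean(wm.spike_filter(s).samples ** 2))
    print(f"  {budgets[s.electrode_id]}     {floor * 1e6:6.2f}")

print("\nLarger budgets monotonically lower the floor, mirroring the"
      "\npublished variable-allocation study (3.9 -> 3.4 uVrms from 2 to 6"
      "\nslices): time slices are a per-electrode noise dial that costs no"
      "\ncircuit area.")
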