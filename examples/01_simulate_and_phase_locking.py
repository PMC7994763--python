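"""Simulate one alpha-rTMS block over the visual site and measure phase
locking at the stimulated electrode.

Prints the inter-trial ZPLF at Oz before and during/after the 5-pulse
11 Hz train, and the frequency at which the post-train response peaks.
Because the visual oscillator's natural frequency (10.5 Hz) sits inside
the synchronisation region of the 11 Hz drive, the peak lands at the
stimulation frequency and ZPLF rises well above its uniform-phase
expectation of ~1.
"""

import numpy as np

import entrainlock as el

protocol = el.StimProtocol(site="visual", n_pulses=5, train_freq_hz=11.0,
                           n_trials=20)
trials = el.simulate_trialset(protocol, fs_hz=500.0, seed=7)
print(f"simulated {trials.n_trials} trials x {len(trials.channels)} "
      f"channels x {trials.n_times} samples at {trials.fs_hz:g} Hz")

cfg = el.PreprocConfig(target_fs_hz=500.0, run_ica=False)
clean, report = el.preprocess(trials, cfg, seed=7)
print("preprocessing stages:", " -> ".join(report["stages"]))

zmap = el.zplf(el.plf(el.morlet_transform(clean)))
oz = zmap.channel_index("Oz")
t, f = zmap.times_s, zmap.freqs_hz
fi = zmap.freq_index(11.0)

pre = (t >= -1.0) & (t <= -0.2)
post = (t >= 0.0) & (t <= protocol.train_duration_s + 2 / 11.0)
print(f"ZPLF at Oz, 11 Hz: baseline {np.nanmean(zmap.values[oz, fi, pre]):.2f}"
      f" -> train/post {np.nanmean(zmap.values[oz, fi, post]):.2f}"
      " (uniform-phase expectation ~1)")

peak = el.peak_response_frequency(zmap.values, f, t,
                                  (0.0, protocol.train_duration_s + 2 / 11),
                                  oz)
print(f"peak response frequency at Oz: {peak:g} Hz "
      f"(stimulation frequency 11 Hz, natural frequency 10.5 Hz)")
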