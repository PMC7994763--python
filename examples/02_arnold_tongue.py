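"""Map the synchronisation region (Arnold tongue) of the pulsed
phase-oscillator model.

For each coupling strength kappa and detuning (natural frequency minus
drive frequency) the script reports the across-trial phase-locking
factor right after the last pulse of a 5-pulse 11 Hz train.  Locking is
strongest at zero detuning and the locked region widens as kappa grows —
the hallmark of entrainment by a periodic force.
"""

from entrainlock import SourceSpec, StimProtocol, arnold_map

base = SourceSpec("Oz", 11.0, phase_noise_sd=1.0)
protocol = StimProtocol(site="visual", n_pulses=5, train_freq_hz=11.0,
                        n_trials=30, epoch_pre_s=0.5, epoch_post_s=0.5)
table = arnold_map(kappa_grid=[0.0, 0.2, 0.4, 0.8],
                   detuning_grid=[-6.0, -2.0, 0.0, 2.0, 6.0],
                   base=base, protocol=protocol, n_rep=10, seed=0,
                   fs_hz=500.0)
print("post-train PLF (rows: kappa, columns: detuning in Hz)")
print(table.round(2).to_string())
print("\nchance level at N=30 trials is ~%.2f" % (1 / 30**0.5))
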