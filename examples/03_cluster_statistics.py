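"""Cluster-based permutation test on a small synthetic cohort.

Eight synthetic participants each contribute a real (entraining) and a
sham ZPLF map; the test thresholds the paired t-map at uncorrected
p<0.05, clusters suprathreshold samples over montage-adjacent electrodes
and contiguous frequency/time bins, and compares summed-t cluster scores
with the permutation null from within-participant condition flips.
"""

import warnings

import numpy as np

from entrainlock import cluster_permutation, count_significant_electrodes
from entrainlock.montage import make_montage
from entrainlock.pipeline import (ConditionSpec, RunConfig, StatsConfig,
                                  participant_zplf)
from entrainlock.preprocess import PreprocConfig

cond = ConditionSpec("visual-11Hz", "visual", 5, 11.0)
cfg = RunConfig(n_participants=8, seed=1, fs_hz=500.0, n_trials=8,
                conditions=[cond],
                preproc=PreprocConfig(target_fs_hz=500.0, run_ica=False),
                stats=StatsConfig(n_perm=500, window_s=(-0.5, 1.2),
                                  time_step_s=0.02))
montage = make_montage()
real, sham = [], []
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for pid in range(cfg.n_participants):
        real.append(participant_zplf(cfg, montage, pid, cond, 0))
        sham.append(participant_zplf(cfg, montage, pid, cond, 1,
                                     sham=True))

res = cluster_permutation(np.stack([m.values for m in real]),
                          np.stack([m.values for m in sham]),
                          montage.adjacency, n_perm=500, seed=1,
                          channels=real[0].channels,
                          freqs_hz=real[0].freqs_hz,
                          times_s=real[0].times_s)
print(f"paired t threshold (df={res.df}): |t| > {res.t_crit:.2f}")
print(f"{len(res.clusters)} clusters found "
      f"({sum(c.significant for c in res.clusters)} significant)")
for i, c in enumerate(sorted(res.clusters, key=lambda c: c.p)[:5]):
    print(f"  cluster {i}: sign={c.sign:+d} size={len(c.indices):5d} "
          f"sum_t={c.sum_t:9.1f} p={c.p:.4f} "
          f"{'*' if c.significant else ''}")
counts = count_significant_electrodes(res)
fi = int(np.argmin(np.abs(real[0].freqs_hz - 11.0)))
print(f"max electrodes simultaneously significant at 11 Hz: "
      f"{counts.counts[fi].max()} of {counts.n_channels}")
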