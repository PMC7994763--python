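"""End-to-end cohort runs: simulate -> preprocess -> TFR -> phase locking
-> statistics, from a single config.

A cohort run produces, per stimulation condition and its site-matched
sham partner: the masked t-value time-frequency map at the stimulated
electrode, per-pulse ZPLF_norm frequency profiles with ANOVA / Dunnett /
Pearson-trend results, significant-electrode count maps with binomial
frequency-specificity tests, and (on request) between-frequency condition
contrasts.  Every artifact is listed in a JSON manifest with SHA-256
checksums; identical configs and seeds give identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import container
from .montage import Montage, make_montage
from .phaselock import plf_from_phases  # noqa: F401  (re-export convenience)
from .phaselock import ZPLFMap, pulse_profile, zplf_norm_freq
from .preprocess import PreprocConfig, preprocess
from .protocol import StimProtocol, pulse_times
from .stats import (ClusterResult, binomial_freq_test, anova_pulse,
                    cluster_permutation, count_significant_electrodes,
                    dunnett_vs_ctrl, pearson_trend)
from .synth import NoiseConfig, default_sources, simulate_trialset
from .tfr import WaveletSpec, morlet_coeffs

STIM_ELECTRODE = {"motor": "C3", "visual": "Oz"}


@dataclass
class ConditionSpec:
    name: str
    site: str
    n_pulses: int = 5
    train_freq_hz: float = 11.0

    def protocol(self, n_trials: int, epoch_pre_s: float,
                 epoch_post_s: float, site: str | None = None
                 ) -> StimProtocol:
        return StimProtocol(site=site or self.site, n_pulses=self.n_pulses,
                            train_freq_hz=self.train_freq_hz,
                            n_trials=n_trials, epoch_pre_s=epoch_pre_s,
                            epoch_post_s=epoch_post_s)


@dataclass
class StatsConfig:
    n_perm: int = 500
    p_thresh: float = 0.05
    alpha_percentile: float = 97.5
    window_s: tuple[float, float] = (-0.5, 1.5)   # stats matrix extent
    time_step_s: float = 0.010                    # stats time resolution
    count_window_cycles: float = 4.0              # electrode-count average


@dataclass
class RunConfig:
    """Everything a cohort run needs; round-trips through YAML."""

    n_participants: int = 14
    seed: int = 0
    out_dir: str = "runs/cohort"
    fs_hz: float = 5000.0
    n_trials: int = 30
    epoch_pre_s: float = 2.0
    epoch_post_s: float = 3.0
    conditions: list[ConditionSpec] = field(default_factory=lambda: [
        ConditionSpec("visual-11Hz", "visual", 5, 11.0),
        ConditionSpec("motor-23Hz", "motor", 5, 23.0),
    ])
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    wavelet_m: float = 3.0
    wavelet_fmin_hz: float = 3.0
    wavelet_fmax_hz: float = 45.0
    wavelet_df_hz: float = 1.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    coupling_kappa: float = 0.4
    figures: bool = False

    def wavelet_spec(self) -> WaveletSpec:
        return WaveletSpec(m=self.wavelet_m, freqs_hz=np.arange(
            self.wavelet_fmin_hz, self.wavelet_fmax_hz + self.wavelet_df_hz,
            self.wavelet_df_hz))

    # -- config (de)serialisation -----------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stats"]["window_s"] = list(d["stats"]["window_s"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["conditions"] = [ConditionSpec(**c) for c in d.get(
            "conditions", [])]
        if "preproc" in d:
            d["preproc"] = PreprocConfig(**d["preproc"])
        if "noise" in d:
            d["noise"] = NoiseConfig(**d["noise"])
        if "stats" in d:
            s = dict(d["stats"])
            if "window_s" in s:
                s["window_s"] = tuple(s["window_s"])
            d["stats"] = StatsConfig(**s)
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _participant_seed(config: RunConfig, pid: int, cond_key: int) -> int:
    ss = np.random.SeedSequence(entropy=config.seed,
                                spawn_key=(pid, cond_key))
    return int(ss.generate_state(1)[0] % (2**31))


def _cohort_sources(config: RunConfig, site: str):
    sources = default_sources(site)
    for s in sources:
        s.coupling_kappa = config.coupling_kappa
    return sources


def participant_zplf(config: RunConfig, montage: Montage, pid: int,
                     cond: ConditionSpec, cond_key: int,
                     sham: bool = False) -> ZPLFMap:
    """One participant x condition block, simulated and fully analysed.

    Returns the ZPLF map cropped to the stats window and decimated to the
    stats time resolution.  Channel-by-channel streaming keeps the wavelet
    stage within memory bounds.
    """
    site = "sham" if sham else cond.site
    proto = cond.protocol(config.n_trials, config.epoch_pre_s,
                          config.epoch_post_s, site=site)
    seed = _participant_seed(config, pid, cond_key)
    trials = simulate_trialset(proto, sources=_cohort_sources(config, site),
                               montage=montage, noise=config.noise,
                               fs_hz=config.fs_hz, seed=seed,
                               participant_id=f"P{pid:02d}")
    clean, _ = preprocess(trials, config.preproc, seed=seed)

    spec = config.wavelet_spec()
    times = clean.times_s
    lo, hi = config.stats.window_s
    step = max(int(round(config.stats.time_step_s * clean.fs_hz)), 1)
    sel = np.flatnonzero((times >= lo) & (times <= hi))[::step]
    n_ch = len(clean.channels)
    values = np.empty((n_ch, len(spec.freqs_hz), len(sel)))
    for c in range(n_ch):
        coeffs, _ = morlet_coeffs(clean.data[:, c, :], clean.fs_hz,
                                  spec.freqs_hz, spec.m)
        amp = np.abs(coeffs)
        with np.errstate(invalid="ignore", divide="ignore"):
            phasors = np.where(amp > 0, coeffs / amp, np.nan + 0j)
        p = np.abs(phasors.mean(axis=0))       # (n_f, n_t)
        values[c] = p[:, sel]
    n = clean.n_trials
    return ZPLFMap(values=n * values**2, n_trials=n,
                   channels=list(clean.channels), freqs_hz=spec.freqs_hz,
                   times_s=times[sel],
                   meta={"participant": pid, "condition": cond.name,
                         "sham": sham, "seed": seed})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(path: Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _cluster_table(result: ClusterResult) -> pd.DataFrame:
    rows = [{"cluster": i, "sign": c.sign, "size": len(c.indices),
             "sum_t": c.sum_t, "p": c.p, "significant": c.significant}
            for i, c in enumerate(result.clusters)]
    return pd.DataFrame(rows, columns=["cluster", "sign", "size", "sum_t",
                                       "p", "significant"])


def _condition_stats(config: RunConfig, montage: Montage,
                     cond: ConditionSpec, real_maps: list[ZPLFMap],
                     sham_maps: list[ZPLFMap], out: Path,
                     seed: int) -> dict:
    """Cluster test, pulse profiles and electrode counts for one pair."""
    artifacts = {}
    a = np.stack([m.values for m in real_maps])
    b = np.stack([m.values for m in sham_maps])
    ref = real_maps[0]
    result = cluster_permutation(
        a, b, montage.adjacency, n_perm=config.stats.n_perm, seed=seed,
        p_thresh=config.stats.p_thresh,
        alpha_percentile=config.stats.alpha_percentile,
        channels=ref.channels, freqs_hz=ref.freqs_hz, times_s=ref.times_s)

    np.save(out / f"{cond.name}_masked_t.npy", result.masked_t_map)
    artifacts["masked_t"] = f"{cond.name}_masked_t.npy"
    _write_tsv(out / f"{cond.name}_clusters.tsv", _cluster_table(result))
    artifacts["clusters"] = f"{cond.name}_clusters.tsv"

    # Per-pulse ZPLF_norm profiles at the stimulated electrode
    electrode = STIM_ELECTRODE.get(cond.site, "Cz")
    proto = cond.protocol(config.n_trials, config.epoch_pre_s,
                          config.epoch_post_s)
    fi = ref.freq_index(cond.train_freq_hz)
    table = np.empty((len(real_maps), 1 + cond.n_pulses))
    prof_rows = []
    for i, m in enumerate(real_maps):
        prof = pulse_profile(zplf_norm_freq(m), proto, electrode)
        table[i, 0] = prof.ctrl[fi]
        table[i, 1:] = prof.values[:, fi]
        for k in range(cond.n_pulses):
            prof_rows.append({"participant": i, "pulse": k + 1,
                              **{f"{f:g}Hz": prof.values[k, j]
                                 for j, f in enumerate(prof.freqs_hz)}})
    _write_tsv(out / f"{cond.name}_pulse_profiles.tsv",
               pd.DataFrame(prof_rows))
    artifacts["pulse_profiles"] = f"{cond.name}_pulse_profiles.tsv"

    f_stat, df1, df2, p_anova = anova_pulse(table)
    p_dunnett = dunnett_vs_ctrl(table, seed=seed)
    pulses = np.repeat(np.arange(1, cond.n_pulses + 1), len(real_maps))
    vals = table[:, 1:].T.ravel()
    r, p_r = pearson_trend(pulses, vals)
    summary = pd.DataFrame([{
        "condition": cond.name, "electrode": electrode,
        "stim_freq_hz": cond.train_freq_hz,
        "anova_F": f_stat, "anova_df1": df1, "anova_df2": df2,
        "anova_p": p_anova, "pearson_r": r, "pearson_p": p_r,
        **{f"dunnett_p_pulse{k + 1}": p_dunnett[k]
           for k in range(cond.n_pulses)}}])
    _write_tsv(out / f"{cond.name}_stats_summary.tsv", summary)
    artifacts["stats_summary"] = f"{cond.name}_stats_summary.tsv"

    # Significant-electrode counts and frequency-specificity binomials
    counts = count_significant_electrodes(result)
    cdf = pd.DataFrame(counts.counts, index=[f"{f:g}" for f in
                                             ref.freqs_hz])
    cdf.insert(0, "freq_hz", ref.freqs_hz)
    _write_tsv(out / f"{cond.name}_sig_counts.tsv", cdf)
    artifacts["sig_counts"] = f"{cond.name}_sig_counts.tsv"

    t_last = pulse_times(proto)[-1]
    w = config.stats.count_window_cycles / cond.train_freq_hz
    mean_counts = counts.mean_over_window(0.0, min(t_last + w,
                                                   ref.times_s[-1]))
    other_freqs = [c.train_freq_hz for c in config.conditions
                   if c.train_freq_hz != cond.train_freq_hz]
    binom_rows = []
    for f_other in dict.fromkeys(other_freqs):
        k_stim = int(round(mean_counts[fi]))
        k_other = int(round(mean_counts[ref.freq_index(f_other)]))
        p_b = (binomial_freq_test(k_stim, k_other)
               if (k_stim + k_other) else float("nan"))
        binom_rows.append({"stim_freq_hz": cond.train_freq_hz,
                           "other_freq_hz": f_other,
                           "count_stim": k_stim, "count_other": k_other,
                           "binomial_p": p_b})
    if binom_rows:
        _write_tsv(out / f"{cond.name}_binomial.tsv",
                   pd.DataFrame(binom_rows))
        artifacts["binomial"] = f"{cond.name}_binomial.tsv"

    if config.figures:
        _render_tmap_figure(result, ref, electrode,
                            out / f"{cond.name}_tmap.png")
        artifacts["tmap_figure"] = f"{cond.name}_tmap.png"
    return artifacts


def _render_tmap_figure(result: ClusterResult, ref: ZPLFMap,
                        electrode: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ci = ref.channel_index(electrode)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.pcolormesh(ref.times_s, ref.freqs_hz,
                       result.masked_t_map[ci], shading="nearest",
                       cmap="RdBu_r")
    ax.set(xlabel="time (s)", ylabel="frequency (Hz)",
           title=f"masked t at {electrode}")
    fig.colorbar(im, ax=ax, label="t")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_cohort(config: RunConfig) -> dict:
    """Run the full synthetic cohort and return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = make_montage()
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stage_order": ["simulate", "preprocess", "tfr",
                                "phaselock", "stats"],
                "conditions": {}}
    (out / "config.yaml").write_text(config.to_yaml())

    for key, cond in enumerate(config.conditions):
        real_maps, sham_maps = [], []
        for pid in range(config.n_participants):
            real = participant_zplf(config, montage, pid, cond, 2 * key)
            sham = participant_zplf(config, montage, pid, cond,
                                    2 * key + 1, sham=True)
            real_maps.append(real)
            sham_maps.append(sham)
            for m, tag in ((real, "real"), (sham, "sham")):
                path = out / f"{cond.name}_P{pid:02d}_{tag}_zplf.h5"
                container.save_map(path, m.values, m.channels, m.freqs_hz,
                                   m.times_s, m.n_trials, m.meta)
        stats_seed = _participant_seed(config, 10_000, key)
        artifacts = _condition_stats(config, montage, cond, real_maps,
                                     sham_maps, out, stats_seed)
        manifest["conditions"][cond.name] = {
            "artifacts": {k: {"path": v, "sha256": _sha256(out / v)}
                          for k, v in artifacts.items()},
            "n_participants": config.n_participants,
        }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_condition_maps(config: RunConfig, cond_name: str,
                        tag: str = "real") -> list[ZPLFMap]:
    out = Path(config.out_dir)
    maps = []
    for pid in range(config.n_participants):
        maps.append(container.load_map(
            out / f"{cond_name}_P{pid:02d}_{tag}_zplf.h5"))
    return maps


def compare_conditions(config: RunConfig, contrast: tuple[str, str],
                       seed: int | None = None) -> ClusterResult:
    """Real-vs-real cluster permutation between two conditions of a
    completed run (between-frequency contrast)."""
    names = [c.name for c in config.conditions]
    for n in contrast:
        if n not in names:
            raise ValueError(f"condition {n!r} not in the run config")
    maps_a = load_condition_maps(config, contrast[0])
    maps_b = load_condition_maps(config, contrast[1])
    montage = make_montage()
    ref = maps_a[0]
    return cluster_permutation(
        np.stack([m.values for m in maps_a]),
        np.stack([m.values for m in maps_b]),
        montage.adjacency, n_perm=config.stats.n_perm,
        seed=config.seed if seed is None else seed,
        p_thresh=config.stats.p_thresh,
        alpha_percentile=config.stats.alpha_percentile,
        channels=ref.channels, freqs_hz=ref.freqs_hz, times_s=ref.times_s)
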