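"""Inter-trial phase-locking measures: PLF, ZPLF and standardized profiles.

The phase-locking factor at electrode m is

    PLF_m(f, t) = | (1/N) * sum_n exp(i * phi_{m,n}(f, t)) |

over N trials.  PLF is biased upward at small N (its expectation under
uniform phase is ~1/sqrt(N)); the Rayleigh-Z transform

    ZPLF = N * PLF^2

has expectation ~1 under uniform phase for every N, so blocks that lost
different numbers of trials to artifact rejection remain comparable.
ZPLF_norm standardizes ZPLF across frequencies (per-pulse frequency
profiles) or across time (individual-alpha analyses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .protocol import StimProtocol, pulse_times
from .tfr import TFRStack


@dataclass
class PLFMap:
    """Phase-locking factor, channel x frequency x time, in [0, 1]."""

    values: np.ndarray
    n_trials: int
    channels: list[str]
    freqs_hz: np.ndarray
    times_s: np.ndarray
    meta: dict = field(default_factory=dict)

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)

    def freq_index(self, f_hz: float) -> int:
        return int(np.argmin(np.abs(self.freqs_hz - f_hz)))


@dataclass
class ZPLFMap(PLFMap):
    """Rayleigh-Z transformed map (N * PLF^2), or a standardization of it."""


@dataclass
class PulseProfile:
    """Per-pulse frequency profile of standardized phase locking.

    ``values[k, i]`` is ZPLF_norm averaged over +/-0.5 cycles of frequency
    ``freqs_hz[i]`` around pulse k; ``ctrl[i]`` is the baseline mean over
    -5..-2 stimulation-frequency cycles before the first pulse.
    """

    values: np.ndarray
    ctrl: np.ndarray
    freqs_hz: np.ndarray
    pulse_times_s: np.ndarray
    stim_freq_hz: float
    channel: str


def plf(tfr: TFRStack) -> PLFMap:
    """Across-trial phase consistency per (channel, frequency, time).

    Masked (NaN) samples propagate as NaN; zero-amplitude samples have
    undefined phase and likewise propagate.
    """
    if tfr.n_trials < 2:
        raise ValueError("PLF requires at least 2 trials")
    # accumulate the mean phasor trial by trial to bound peak memory
    acc = np.zeros(tfr.coeffs.shape[1:], dtype=complex)
    for n in range(tfr.n_trials):
        c = tfr.coeffs[n]
        amp = np.abs(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc += np.where(amp > 0, c / amp, np.nan + 0j)
    values = np.abs(acc) / tfr.n_trials
    return PLFMap(values=values, n_trials=tfr.n_trials,
                  channels=list(tfr.channels), freqs_hz=tfr.freqs_hz,
                  times_s=tfr.times_s)


def plf_from_phases(phases: np.ndarray, trial_axis: int = 0) -> np.ndarray:
    """PLF of raw phase angles along ``trial_axis`` (helper for oracles)."""
    return np.abs(np.exp(1j * np.asarray(phases)).mean(axis=trial_axis))


def zplf(plf_map: PLFMap) -> ZPLFMap:
    """Rayleigh-Z bias correction: elementwise N * PLF^2."""
    return ZPLFMap(values=plf_map.n_trials * plf_map.values**2,
                   n_trials=plf_map.n_trials,
                   channels=list(plf_map.channels),
                   freqs_hz=plf_map.freqs_hz, times_s=plf_map.times_s,
                   meta=dict(plf_map.meta, derivation="N*PLF^2"))


def _standardize(values: np.ndarray, axis: int, what: str) -> np.ndarray:
    mu = np.nanmean(values, axis=axis, keepdims=True)
    sd = np.nanstd(values, axis=axis, ddof=0, keepdims=True)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"zero-SD slices in {what} standardization masked",
                      RuntimeWarning, stacklevel=3)
        sd = np.where(degenerate, np.nan, sd)
    with np.errstate(invalid="ignore"):
        return (values - mu) / sd


def zplf_norm_freq(zplf_map: ZPLFMap) -> ZPLFMap:
    """Standardize across the frequency axis, per (channel, time)."""
    if len(zplf_map.freqs_hz) < 3:
        raise ValueError("need >= 3 frequencies to standardize")
    out = _standardize(zplf_map.values, axis=1, what="frequency")
    return ZPLFMap(values=out, n_trials=zplf_map.n_trials,
                   channels=list(zplf_map.channels),
                   freqs_hz=zplf_map.freqs_hz, times_s=zplf_map.times_s,
                   meta=dict(zplf_map.meta, standardized="freq"))


def zplf_norm_time(zplf_map: ZPLFMap) -> ZPLFMap:
    """Standardize across the time axis, per (channel, frequency)."""
    out = _standardize(zplf_map.values, axis=2, what="time")
    return ZPLFMap(values=out, n_trials=zplf_map.n_trials,
                   channels=list(zplf_map.channels),
                   freqs_hz=zplf_map.freqs_hz, times_s=zplf_map.times_s,
                   meta=dict(zplf_map.meta, standardized="time"))


def _window_mean(row: np.ndarray, times: np.ndarray, lo: float, hi: float,
                 label: str) -> float:
    sel = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if not sel.any():
        raise ValueError(f"{label}: window [{lo:.3f}, {hi:.3f}] s has no "
                         "samples")
    vals = row[sel]
    if np.isnan(vals).any():
        raise ValueError(f"{label}: window [{lo:.3f}, {hi:.3f}] s exceeds "
                         "the valid (unmasked) region")
    return float(vals.mean())


def pulse_profile(zplf_norm: ZPLFMap, protocol: StimProtocol,
                  channel: str) -> PulseProfile:
    """Per-pulse frequency profile at one electrode.

    For pulse k at time t_k and each analysis frequency f, averages the
    standardized map over [t_k - 0.5/f, t_k + 0.5/f]; the baseline (ctrl)
    is the mean over [-5/f_stim, -2/f_stim] before the first pulse, with
    the window always in stimulation-frequency cycles.
    """
    ci = zplf_norm.channel_index(channel)
    f_stim = protocol.train_freq_hz
    t_pulses = pulse_times(protocol)
    freqs = zplf_norm.freqs_hz
    times = zplf_norm.times_s
    vals = np.empty((len(t_pulses), len(freqs)))
    ctrl = np.empty(len(freqs))
    for i, f in enumerate(freqs):
        row = zplf_norm.values[ci, i]
        half = 0.5 / f
        for k, tk in enumerate(t_pulses):
            vals[k, i] = _window_mean(row, times, tk - half, tk + half,
                                      f"pulse {k + 1} at {f:g} Hz")
        ctrl[i] = _window_mean(row, times, -5.0 / f_stim, -2.0 / f_stim,
                               f"ctrl at {f:g} Hz")
    return PulseProfile(values=vals, ctrl=ctrl, freqs_hz=freqs,
                        pulse_times_s=t_pulses, stim_freq_hz=f_stim,
                        channel=channel)


def persistence_cycles(source, protocol: StimProtocol, channel: str,
                       freq_hz: float, threshold: float | None = None
                       ) -> float:
    """Duration of sustained phase locking after the last pulse, in
    stimulation-frequency cycles.

    ``source`` is either a map (with ``threshold`` defining the criterion
    ``values > threshold``) or a boolean significance mask with the same
    (channel, frequency, time) axes packaged as a ZPLFMap-like object.
    The longest criterion-true run starting at the last pulse is converted
    to cycles of the stimulation frequency.
    """
    ci = source.channel_index(channel)
    fi = source.freq_index(freq_hz)
    row = source.values[ci, fi]
    crit = row if row.dtype == bool else (row > threshold)
    f_stim = protocol.train_freq_hz if protocol.n_pulses > 1 else freq_hz
    t_last = pulse_times(protocol)[-1]
    times = source.times_s
    start = int(np.searchsorted(times, t_last))
    n_run = 0
    for v in crit[start:]:
        if not v:
            break
        n_run += 1
    if n_run == 0:
        return 0.0
    dt = float(np.median(np.diff(times)))
    return n_run * dt * f_stim


#: default channels for the individual-alpha-frequency estimate
IAF_CHANNELS = ("O1", "O2", "Oz", "PO3", "PO4", "POz", "PO7", "PO8")

IAF_BAND_HZ = (8.0, 13.0)
IAF_PROMINENCE = 1.20  # peak must exceed the 1/f trend by 20%


def estimate_iaf(trials, channels=IAF_CHANNELS) -> float | None:
    """Individual alpha frequency from pre-stimulus data, or None.

    Takes the trial-averaged amplitude spectrum of the pre-stimulus
    segment over posterior channels, fits a log-log linear 1/f trend over
    3-30 Hz (excluding 7-14 Hz), and returns the frequency of the 8-13 Hz
    amplitude maximum if it exceeds the trend by the prominence margin;
    otherwise None ("no prominent peak").  Ties resolve to the lower
    frequency.
    """
    from scipy import signal as sps

    t0 = int(trials.pulse_samples[0, 0])
    if t0 / trials.fs_hz < 2.0:
        raise ValueError("need >= 2 s of pre-stimulus data")
    chans = [c for c in channels if c in trials.channels]
    if not chans:
        raise ValueError("none of the requested channels present")
    idx = [trials.channel_index(c) for c in chans]
    seg = trials.data[:, idx, :t0]
    nper = min(seg.shape[-1], int(2 * trials.fs_hz))
    f, psd = sps.welch(seg, fs=trials.fs_hz, nperseg=nper, axis=-1)
    amp = np.sqrt(psd).mean(axis=(0, 1))

    fit_sel = (f >= 3) & (f <= 30) & ~((f > 7) & (f < 14))
    coef = np.polyfit(np.log(f[fit_sel]), np.log(amp[fit_sel]), 1)

    band = (f >= IAF_BAND_HZ[0]) & (f <= IAF_BAND_HZ[1])
    trend_band = np.exp(np.polyval(coef, np.log(f[band])))
    k = int(np.argmax(amp[band]))  # argmax takes the first (lowest) freq
    f_peak = f[band][k]
    if amp[band][k] > IAF_PROMINENCE * trend_band[k]:
        return float(f_peak)
    return None
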