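"""Stimulation protocols: single pulses and 5-pulse trains at 5/11/23 Hz."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SITES = ("motor", "visual", "sham")


@dataclass(frozen=True)
class StimProtocol:
    """One stimulation block: site, train layout and epoching.

    A trial is an epoch from ``epoch_pre_s`` before the first pulse to
    ``epoch_post_s`` after the last pulse.  ``train_freq_hz`` is ignored
    when ``n_pulses == 1`` (single-pulse stimulation).

    ``iti_s`` is the inter-train interval (mean, jitter) in seconds; it
    matters only for continuous-session bookkeeping, not for epoched
    simulation.
    """

    site: str = "motor"
    n_pulses: int = 5
    train_freq_hz: float = 11.0
    n_trials: int = 30
    iti_s: tuple[float, float] = (10.0, 1.5)
    epoch_pre_s: float = 2.0
    epoch_post_s: float = 3.0

    def __post_init__(self):
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.n_pulses > 1 and not self.train_freq_hz > 0:
            raise ValueError("train_freq_hz must be > 0 for pulse trains")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def train_duration_s(self) -> float:
        """First-to-last pulse interval: (n_pulses - 1) / f."""
        if self.n_pulses == 1:
            return 0.0
        return (self.n_pulses - 1) / self.train_freq_hz

    @property
    def epoch_duration_s(self) -> float:
        return self.epoch_pre_s + self.train_duration_s + self.epoch_post_s


def pulse_times(protocol: StimProtocol) -> np.ndarray:
    """Pulse onset times in seconds relative to the first pulse.

    Returns ``[0, 1/f, ..., (n_pulses-1)/f]``; for a 5-pulse train at 5 Hz
    the last pulse falls at 800 ms, at 11 Hz at ~364 ms, at 23 Hz at ~174 ms.
    """
    if protocol.n_pulses == 1:
        return np.zeros(1)
    return np.arange(protocol.n_pulses) / protocol.train_freq_hz


def pulse_sample_indices(protocol: StimProtocol, fs_hz: float) -> np.ndarray:
    """Pulse onsets as sample indices within the epoch (first pulse at
    ``round(epoch_pre_s * fs)``)."""
    t = pulse_times(protocol) + protocol.epoch_pre_s
    return np.round(t * fs_hz).astype(np.int64)


def epoch_n_samples(protocol: StimProtocol, fs_hz: float) -> int:
    return int(round(protocol.epoch_duration_s * fs_hz))
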