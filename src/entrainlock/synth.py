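"""Synthetic rTMS-EEG generator with known phase-entrainment ground truth.

The generator realises three regimes at the level of cortical phase
oscillators:

* sham — pulses never touch oscillator phase (only an optional evoked
  kernel, mimicking the coil click);
* single-pulse phase reset — a full-strength pulse update (kappa = 1)
  aligns phase across trials instantly;
* progressive entrainment — partial updates (0 < kappa < 1) pull the
  oscillator toward the pulse phase a little on every pulse, so inter-trial
  phase locking grows over the train and persists briefly afterwards.

Each source is a noisy phase oscillator

    phi(t + dt) = phi(t) + 2*pi*f0*dt + eps,   eps ~ N(0, sd^2 * dt)

and a pulse pulls the oscillator toward the fixed pulse-target phase
``psi_p = 0`` by the circular vector-pull update

    phi <- phi + arg((1 - kappa) + kappa * exp(i*(psi_p - phi)))

which behaves as the circle map ``phi + kappa*sin(psi_p - phi)`` for small
kappa and collapses to an exact one-pulse phase reset at kappa = 1.  Pulse
updates propagate to remote sources (scaled by a gain, after a lag) only
when the remote natural frequency is within 3 Hz of the local one,
encoding frequency-specific large-scale coupling.

Sensor signals are a Gaussian-leadfield projection of ``a*cos(phi)`` plus
1/f background noise, an optional fixed-latency evoked kernel per pulse,
and a large exponentially decaying pulse artifact confined to the first
few milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage, make_montage
from .protocol import (StimProtocol, epoch_n_samples, pulse_sample_indices,
                       pulse_times)

#: remote sources receive the pulse update only within this detuning
FREQ_GATE_HZ = 3.0

#: Gaussian leadfield full width at half maximum, degrees of arc
LEADFIELD_FWHM_DEG = 60.0

_FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SourceSpec:
    """One cortical phase oscillator.

    ``location`` is a channel label (projected through the montage) or a
    unit 3-vector.  ``phase_noise_sd`` is the Wiener phase-increment SD in
    rad/sqrt(s); ``coupling_kappa`` in [0, 1] sets the pulse update from
    full reset (1) through partial entrainment to none (0).
    ``propagation`` lists (target source index, gain in [0, 1], lag_s).
    """

    location: str | np.ndarray
    natural_freq_hz: float
    amplitude_uv: float = 5.0
    phase_noise_sd: float = 1.5
    coupling_kappa: float = 0.4
    propagation: list[tuple[int, float, float]] = field(default_factory=list)
    stimulated: bool = False

    def __post_init__(self):
        if not 0.0 <= self.coupling_kappa <= 1.0:
            raise ValueError("coupling_kappa must be in [0, 1]")
        if not self.natural_freq_hz > 0:
            raise ValueError("natural_freq_hz must be > 0")
        for tgt, gain, lag in self.propagation:
            if not 0.0 <= gain <= 1.0:
                raise ValueError("propagation gains must be in [0, 1]")


@dataclass
class NoiseConfig:
    """Background and pulse-locked nuisance components, amplitudes in uV."""

    pink_amp_uv: float = 5.0          # SD of the 1/f background
    pink_exponent: float = 1.0        # spectral slope of the background
    evoked_amp_uv: float = 2.0        # fixed-latency evoked kernel per pulse
    evoked_freq_hz: float = 10.0
    evoked_decay_s: float = 0.1
    evoked_latency_s: float = 0.03
    evoked_attenuation: float = 1.0   # per-pulse amplitude multiplier
    artifact_amp_factor: float = 10.0  # decay artifact, x stimulated amplitude
    artifact_tau_s: float = 0.002


@dataclass
class TrialSet:
    """Epoched multi-trial EEG: trial x channel x time voltages.

    ``data`` is in uV (uV/m^2 after the surface-Laplacian transform; see
    ``units``).  ``pulse_samples`` holds per-trial pulse onset sample
    indices, shape (n_trials, n_pulses).  The time axis origin (t = 0) is
    the first pulse.
    """

    data: np.ndarray
    fs_hz: float
    montage: Montage
    channels: list[str]
    pulse_samples: np.ndarray
    protocol: StimProtocol
    participant_id: str = "sim"
    condition: str = ""
    units: str = "uV"

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel labels")
        if self.pulse_samples.shape != (self.data.shape[0],
                                        self.protocol.n_pulses):
            raise ValueError("pulse_samples must be (n_trials, n_pulses)")
        if (self.pulse_samples < 0).any() or \
                (self.pulse_samples >= self.data.shape[2]).any():
            raise ValueError("pulse sample indices outside the time axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_s(self) -> np.ndarray:
        """Time axis in seconds, first pulse at 0."""
        t0 = int(self.pulse_samples[0, 0])
        return (np.arange(self.n_times) - t0) / self.fs_hz

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)

    def copy_with(self, **kw) -> "TrialSet":
        return replace(self, **kw)


def _resolve_location(loc, montage: Montage) -> np.ndarray:
    if isinstance(loc, str):
        return montage.positions[montage.index(loc)]
    v = np.asarray(loc, dtype=float)
    return v / np.linalg.norm(v)


def gaussian_leadfield(source_pos: np.ndarray, montage: Montage,
                       fwhm_deg: float = LEADFIELD_FWHM_DEG) -> np.ndarray:
    """Smooth forward projection: Gaussian falloff in arc distance."""
    arc = np.arccos(np.clip(montage.positions @ source_pos, -1.0, 1.0))
    sd = np.deg2rad(fwhm_deg) * _FWHM_TO_SD
    return np.exp(-0.5 * (arc / sd) ** 2)


def simulate_phases(f0_hz: float, phase_noise_sd: float, n_trials: int,
                    n_times: int, fs_hz: float, rng: np.random.Generator,
                    events: list[tuple[int, float]] | None = None,
                    psi_p: float = 0.0) -> np.ndarray:
    """Integrate the noisy phase oscillator with pulse updates.

    ``events`` is a list of (sample index, effective kappa); at each event
    phase jumps by ``arg((1 - kappa) + kappa * exp(i*(psi_p - phi)))`` —
    a partial pull toward ``psi_p`` that reduces to ``kappa *
    sin(psi_p - phi)`` for small kappa and to an exact reset at kappa = 1.
    Returns unwrapped phase, shape (n_trials, n_times).  Initial phase is
    uniform across trials.
    """
    dt = 1.0 / fs_hz
    inc = np.full((n_trials, n_times), 2.0 * np.pi * f0_hz * dt)
    if phase_noise_sd > 0:
        inc += rng.normal(0.0, phase_noise_sd * np.sqrt(dt),
                          size=(n_trials, n_times))
    inc[:, 0] = rng.uniform(-np.pi, np.pi, size=n_trials)
    phi = np.cumsum(inc, axis=1)
    if events:
        for s, kappa in sorted(events, key=lambda e: e[0]):
            if kappa == 0.0 or not 0 <= s < n_times:
                continue
            delta = np.angle((1.0 - kappa)
                             + kappa * np.exp(1j * (psi_p - phi[:, s])))
            phi[:, s:] += delta[:, None]
    return phi


def _source_events(sources: list[SourceSpec], protocol: StimProtocol,
                   pulse_idx: np.ndarray, fs_hz: float
                   ) -> list[list[tuple[int, float]]]:
    """Per-source pulse-update event lists, with gated propagation."""
    events: list[list[tuple[int, float]]] = [[] for _ in sources]
    if protocol.site == "sham":
        return events
    for i, src in enumerate(sources):
        if not src.stimulated:
            continue
        for s in pulse_idx:
            events[i].append((int(s), src.coupling_kappa))
        for tgt, gain, lag in src.propagation:
            if abs(sources[tgt].natural_freq_hz - src.natural_freq_hz) \
                    > FREQ_GATE_HZ:
                continue
            lag_n = int(round(lag * fs_hz))
            for s in pulse_idx:
                events[tgt].append((int(s) + lag_n,
                                    gain * src.coupling_kappa))
    return events


def _pink_noise(rng: np.random.Generator, shape: tuple, fs_hz: float,
                sd_uv: float, exponent: float) -> np.ndarray:
    """1/f^exponent Gaussian noise along the last axis, scaled to sd_uv."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1) * gain
    x = np.fft.irfft(spec, n=n, axis=-1)
    s = x.std()
    if s > 0:
        x *= sd_uv / s
    return x


def _evoked_kernel(n_times: int, fs_hz: float, cfg: NoiseConfig) -> np.ndarray:
    """Damped sinusoid with fixed latency and polarity (one pulse)."""
    t = np.arange(n_times) / fs_hz
    tau = t - cfg.evoked_latency_s
    k = np.where(tau >= 0,
                 np.exp(-np.maximum(tau, 0) / cfg.evoked_decay_s)
                 * np.sin(2 * np.pi * cfg.evoked_freq_hz
                          * np.maximum(tau, 0)),
                 0.0)
    return cfg.evoked_amp_uv * k


def _artifact_kernel(n_times: int, fs_hz: float, amp_uv: float,
                     tau_s: float) -> np.ndarray:
    t = np.arange(n_times) / fs_hz
    return amp_uv * np.exp(-t / tau_s)


def simulate_trialset(protocol: StimProtocol,
                      sources: list[SourceSpec] | None = None,
                      montage: Montage | None = None,
                      noise: NoiseConfig | None = None,
                      fs_hz: float = 5000.0,
                      seed: int = 0,
                      participant_id: str = "sim",
                      condition: str | None = None) -> TrialSet:
    """Simulate one epoched stimulation block.

    Identical (protocol, sources, montage, noise, fs, seed) give
    bit-identical output.

    Raises
    ------
    ValueError
        If the source list is empty or ``fs_hz`` is below four times the
        highest natural frequency.
    """
    if sources is None:
        sources = default_sources(protocol.site)
    if not sources:
        raise ValueError("source list must not be empty")
    if montage is None:
        montage = make_montage()
    noise = noise or NoiseConfig()
    fmax = max(s.natural_freq_hz for s in sources)
    if fs_hz < 4.0 * fmax:
        raise ValueError(
            f"fs_hz={fs_hz} violates the sampling requirement: need "
            f">= 4x the highest natural frequency ({fmax} Hz)")

    rng = np.random.default_rng(seed)
    n_times = epoch_n_samples(protocol, fs_hz)
    pulse_idx = pulse_sample_indices(protocol, fs_hz)
    n_trials = protocol.n_trials
    n_ch = len(montage.labels)

    events = _source_events(sources, protocol, pulse_idx, fs_hz)
    data = np.zeros((n_trials, n_ch, n_times))
    for src, ev in zip(sources, events):
        phi = simulate_phases(src.natural_freq_hz, src.phase_noise_sd,
                              n_trials, n_times, fs_hz, rng, events=ev)
        w = gaussian_leadfield(_resolve_location(src.location, montage),
                               montage)
        sig = src.amplitude_uv * np.cos(phi)
        data += w[None, :, None] * sig[:, None, :]

    if noise.pink_amp_uv > 0:
        data += _pink_noise(rng, (n_trials, n_ch, n_times), fs_hz,
                            noise.pink_amp_uv, noise.pink_exponent)

    if noise.evoked_amp_uv > 0:
        # the click/evoked response is common to real and sham stimulation
        centre = montage.positions[montage.index("Cz")]
        w_ev = gaussian_leadfield(centre, montage)
        kern = _evoked_kernel(n_times, fs_hz, noise)
        for k, s in enumerate(pulse_idx):
            seg = (noise.evoked_attenuation ** k) * kern[: n_times - s]
            data[:, :, s:] += w_ev[None, :, None] * seg[None, None, :]

    if noise.artifact_amp_factor > 0 and protocol.site != "sham":
        stim = [s for s in sources if s.stimulated]
        amp = noise.artifact_amp_factor * (
            stim[0].amplitude_uv if stim else 5.0)
        loc = (_resolve_location(stim[0].location, montage) if stim
               else montage.positions[montage.index("Cz")])
        w_art = gaussian_leadfield(loc, montage)
        kern = _artifact_kernel(n_times, fs_hz, amp, noise.artifact_tau_s)
        for s in pulse_idx:
            data[:, :, s:] += w_art[None, :, None] * kern[: n_times - s]

    pulse_samples = np.tile(pulse_idx, (n_trials, 1))
    if condition is None:
        if protocol.n_pulses == 1:
            condition = f"{protocol.site}-sp"
        else:
            condition = f"{protocol.site}-{protocol.train_freq_hz:g}Hz"
    return TrialSet(data=data, fs_hz=fs_hz, montage=montage,
                    channels=list(montage.labels),
                    pulse_samples=pulse_samples, protocol=protocol,
                    participant_id=participant_id, condition=condition)


def default_sources(site: str) -> list[SourceSpec]:
    """Study-default source layout.

    A visual oscillator at Oz (10.5 Hz, the intrinsic alpha band) and a
    motor oscillator at C3 (21 Hz, low beta), each propagating to one
    remote partner within the 3 Hz frequency gate (left occipitoparietal
    alpha, right-motor beta).  Which oscillator the pulses drive follows
    the stimulation site; under sham neither does.
    """
    visual = SourceSpec("Oz", 10.5, amplitude_uv=5.0, phase_noise_sd=1.5,
                        coupling_kappa=0.4, propagation=[(2, 0.6, 0.012)],
                        stimulated=(site == "visual"))
    motor = SourceSpec("C3", 21.0, amplitude_uv=5.0, phase_noise_sd=1.5,
                       coupling_kappa=0.4, propagation=[(3, 0.5, 0.010)],
                       stimulated=(site == "motor"))
    remote_alpha = SourceSpec("PO7", 10.0, amplitude_uv=3.0,
                              phase_noise_sd=1.5, coupling_kappa=0.4)
    remote_beta = SourceSpec("C4", 20.0, amplitude_uv=3.0,
                             phase_noise_sd=1.5, coupling_kappa=0.4)
    return [visual, motor, remote_alpha, remote_beta]


def arnold_map(kappa_grid, detuning_grid, base: SourceSpec,
               protocol: StimProtocol, n_rep: int = 10, seed: int = 0,
               fs_hz: float = 1000.0):
    """Entrainment degree over the (kappa, detuning) plane.

    For each coupling strength kappa and detuning (f0 - f_stim), runs
    ``n_rep`` repetitions of the phase recursion alone (no sensor layer)
    and measures the across-trial phase-locking factor immediately after
    the last pulse.  The widening of the high-PLF region with kappa is the
    synchronisation region (Arnold tongue).

    Returns a pandas DataFrame (rows kappa, columns detuning) with the
    master seed in ``attrs``.
    """
    import pandas as pd

    kappa_grid = np.atleast_1d(np.asarray(kappa_grid, dtype=float))
    detuning_grid = np.atleast_1d(np.asarray(detuning_grid, dtype=float))
    if kappa_grid.size == 0 or detuning_grid.size == 0:
        raise ValueError("kappa and detuning grids must be non-empty")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")

    n_times = epoch_n_samples(protocol, fs_hz)
    pulse_idx = pulse_sample_indices(protocol, fs_hz)
    last = int(pulse_idx[-1])
    ss = np.random.SeedSequence(seed)
    out = np.zeros((kappa_grid.size, detuning_grid.size))
    for i, kappa in enumerate(kappa_grid):
        for j, df in enumerate(detuning_grid):
            f0 = protocol.train_freq_hz + df
            rng = np.random.default_rng(ss.spawn(1)[0])
            vals = []
            for _ in range(n_rep):
                ev = [(int(s), float(kappa)) for s in pulse_idx]
                phi = simulate_phases(f0, base.phase_noise_sd,
                                      protocol.n_trials, n_times, fs_hz,
                                      rng, events=ev)
                vals.append(np.abs(np.mean(np.exp(1j * phi[:, last]))))
            out[i, j] = np.mean(vals)
    table = pd.DataFrame(out, index=kappa_grid, columns=detuning_grid)
    table.index.name = "kappa"
    table.columns.name = "detuning_hz"
    table.attrs["seed"] = seed
    return table
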