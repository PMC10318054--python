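"""Ground-truthed synthetic polysomnography sessions.

The generator emulates the statistical structure of a rodent sleep recording:

* a four-state hypnogram (wake / NREM / intermediate sleep / REM) produced by
  a per-epoch Markov chain in which REM is reachable only through IS;
* two EEG channels with state-dependent band power (NREM delta + spindles,
  REM theta with phasic theta bursts, IS mixed delta/theta) over a 1/f
  background, and an EMG with state-dependent tone plus P-wave-locked
  twitches;
* a pontine LFP pair (primary/reference sharing common-mode noise) carrying
  biphasic P-waves at state-dependent rates, with a configurable clustered
  fraction and von Mises coupling of event times to the theta phase;
* a two-colour photometry pair (465/405 nm) in which the calcium-dependent
  channel carries a REM-selective baseline elevation plus per-P-wave
  transients, both channels share multiplicative photobleaching and motion
  noise, and the 405 nm channel is calcium-independent;
* laser protocols: open-loop 10 Hz trains, isolated brief pulses with
  state-dependent evoked-P-wave success (latency mode ~30 ms), or closed-loop
  stimulation of a random half of REM episodes.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` sub-streams, so identical configs give
bit-identical sessions. The generator is deliberately phenomenological — it
reproduces band powers, rates, and event statistics, not biophysics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .core import (
    EPOCH_S,
    STATES,
    Channel,
    Hypnogram,
    LaserProtocol,
    Recording,
)

_STATE_IDX = {s: i for i, s in enumerate(STATES)}


def default_transition_matrix() -> np.ndarray:
    """Per-epoch (2.5 s) transition probabilities, state order W, N, I, R.

    Self-transition probabilities encode geometric dwell times with means of
    roughly 60 s (wake), 120 s (NREM), 20 s (IS) and 75 s (REM). REM is
    entered only from IS.
    """
    m = np.array(
        [
            # W        N        I        R
            [0.95833, 0.04167, 0.0, 0.0],
            [0.00625, 0.97917, 0.01458, 0.0],
            [0.01875, 0.02500, 0.87500, 0.08125],
            [0.02667, 0.00667, 0.0, 0.96666],
        ]
    )
    return m / m.sum(axis=1, keepdims=True)


@dataclass
class SimConfig:
    """All knobs of the synthetic session; defaults are the study conditions."""

    duration_s: float = 7200.0
    epoch_s: float = EPOCH_S
    rate_ephys_hz: float = 1000.0
    rate_photo_hz: float = 1500.0
    seed: int = 0

    # hypnogram
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    initial_state: str = "W"
    # optional semi-Markov minimum dwell per state, in epochs (1 = plain chain)
    min_epochs: dict[str, int] = field(
        default_factory=lambda: {s: 1 for s in STATES}
    )

    # EEG amplitudes (uV) per state
    eeg_pink_uv: float = 20.0
    delta_amp_uv: dict[str, float] = field(
        default_factory=lambda: {"W": 5.0, "N": 60.0, "I": 32.0, "R": 6.0}
    )
    theta_amp_uv: dict[str, float] = field(
        default_factory=lambda: {"W": 8.0, "N": 4.0, "I": 22.0, "R": 42.0}
    )
    theta_freq_hz: float = 7.5
    theta_burst_rate_hz: float = 0.06  # bursts per second of REM
    theta_burst_dur_s: tuple[float, float] = (1.0, 2.5)
    theta_burst_amp_gain: float = 1.8
    theta_burst_freq_boost_hz: float = 1.8
    spindle_amp_uv: dict[str, float] = field(
        default_factory=lambda: {"W": 0.0, "N": 10.0, "I": 18.0, "R": 0.0}
    )
    spindle_rate_hz: float = 0.08  # per second of N/I
    emg_tone_uv: dict[str, float] = field(
        default_factory=lambda: {"W": 30.0, "N": 8.0, "I": 8.0, "R": 4.0}
    )
    emg_twitch_amp_uv: float = 45.0
    emg_twitch_dur_ms: float = 50.0

    # P-waves / LFP
    pwave_rates: dict[str, float] = field(
        default_factory=lambda: {"W": 0.01, "N": 0.02, "I": 0.15, "R": 0.6}
    )
    cluster_prob: float = 0.25
    cluster_extra_range: tuple[int, int] = (1, 3)
    cluster_isi_range_s: tuple[float, float] = (0.12, 0.40)
    pwave_amp_sd: float = 6.0  # trough depth in units of raw LFP noise SD
    pwave_halfwidth_ms: float = 30.0
    lfp_noise_sd_mv: float = 0.015
    lfp_shared_noise_frac: float = 0.5  # variance fraction common to both tips
    theta_coupling_kappa: float = 1.5
    theta_coupling_mu: float = -np.pi / 2  # rising phase of theta
    min_event_gap_s: float = 0.1

    # photometry
    photo_baseline_dff: dict[str, float] = field(
        default_factory=lambda: {"W": 0.0, "N": 0.0, "I": 0.02, "R": 0.06}
    )
    transient_amp_dff: float = 0.02
    transient_peak_s: float = 0.5
    transient_rise_sd_s: float = 0.35
    transient_decay_s: float = 0.8
    bleach_tau_s: float = 6000.0
    motion_noise_sd: float = 0.003
    f465_base: float = 2.0
    f405_base: float = 1.0

    # laser
    laser_mode: str | None = None  # open_loop | brief_pulse | closed_loop
    closed_loop_p_on: float = 0.5
    evoked_success_by_state: dict[str, float] = field(
        default_factory=lambda: {"W": 0.34, "N": 0.91, "I": 0.91, "R": 0.66}
    )
    evoked_latency_mode_ms: float = 30.0
    evoked_latency_shape: float = 9.0  # gamma shape; mode = (shape-1)*scale

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        m = self.transition_matrix
        if m.shape != (4, 4):
            raise ValueError("transition_matrix must be 4x4 (W, N, I, R)")
        if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition_matrix rows must be probabilities summing to 1")
        if m[_STATE_IDX["W"], _STATE_IDX["R"]] > 0 or m[_STATE_IDX["N"], _STATE_IDX["R"]] > 0:
            raise ValueError("REM must be reachable only via IS (W->R and N->R must be 0)")
        if any(r < 0 for r in self.pwave_rates.values()):
            raise ValueError("pwave_rates must be non-negative")
        if self.bleach_tau_s <= 0:
            raise ValueError("bleach_tau_s must be positive")
        if self.laser_mode not in (None, "open_loop", "brief_pulse", "closed_loop"):
            raise ValueError(f"unknown laser_mode {self.laser_mode!r}")
        if m[_STATE_IDX["I"], _STATE_IDX["R"]] == 0:
            warnings.warn("P(IS->REM) is 0: REM is unreachable under this config")

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_s / self.epoch_s))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["transition_matrix"] = self.transition_matrix.tolist()
        return d


@dataclass
class GroundTruth:
    """Everything the generator knows that a detector must recover."""

    hypnogram: Hypnogram
    pwave_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    pwave_cluster_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    pwave_provenance: np.ndarray = field(default_factory=lambda: np.empty(0, "U16"))
    laser: LaserProtocol | None = None
    evoked_flags: np.ndarray | None = None  # per laser pulse
    calcium_true: np.ndarray | None = None  # noiseless dF/F-scale trace


def _substream(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(salt,)))


# salts for named sub-streams (fixed; order-independent determinism)
_SALT_HYP, _SALT_EEG, _SALT_LFP, _SALT_PHOTO, _SALT_LASER, _SALT_EVOKED = range(6)


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of an ergodic chain by eigen-decomposition."""
    vals, vecs = np.linalg.eig(matrix.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    return pi / pi.sum()


def simulate_hypnogram(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> Hypnogram:
    """Simulate the per-epoch state chain (optionally with dwell minima)."""
    rng = rng or _substream(cfg.seed, _SALT_HYP)
    m = cfg.transition_matrix
    n = cfg.n_epochs
    labels = np.empty(n, dtype="U1")
    state = cfg.initial_state
    mins = {s: max(1, int(cfg.min_epochs.get(s, 1))) for s in STATES}
    i = 0
    while i < n:
        hold = mins[state]
        run = 1
        labels[i] = state
        i += 1
        while i < n:
            if run < hold:
                labels[i] = state
                i += 1
                run += 1
                continue
            nxt = STATES[rng.choice(4, p=m[_STATE_IDX[state]])]
            if nxt != state:
                state = nxt
                break
            labels[i] = state
            i += 1
            run += 1
    return Hypnogram(labels, cfg.epoch_s)


def pink_noise(n: int, rng: np.random.Generator, exponent: float = 1.0) -> np.ndarray:
    """Unit-SD 1/f**exponent Gaussian noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _state_gain(hyp: Hypnogram, per_state: dict[str, float], rate_hz: float, n: int) -> np.ndarray:
    gains = np.array([per_state[s] for s in hyp.labels])
    reps = int(round(hyp.epoch_s * rate_hz))
    g = np.repeat(gains, reps)
    if g.size < n:
        g = np.pad(g, (0, n - g.size), mode="edge")
    return g[:n]


def _bandlimited_noise(n: int, rate: float, lo: float, hi: float, rng) -> np.ndarray:
    x = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y / y.std()


def synth_eeg_emg(
    hyp: Hypnogram,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Synthesize parietal/frontal EEG and EMG for a hypnogram.

    Returns ``(channels, aux)`` where ``channels`` holds ``eeg_parietal``,
    ``eeg_frontal`` and ``emg`` (uV) and ``aux`` carries the exact theta phase
    and instantaneous frequency used (needed to place phase-coupled P-waves).
    """
    rng = rng or _substream(cfg.seed, _SALT_EEG)
    rate = cfg.rate_ephys_hz
    n = int(round(hyp.duration_s * rate))
    t = np.arange(n) / rate

    rem_mask = hyp.sample_mask("R", rate, n)

    # theta oscillator: integrate a slowly wandering instantaneous frequency,
    # accelerated inside phasic bursts during REM
    drift = _bandlimited_noise(n, rate, 0.05, 0.4, rng) * 0.4
    burst_env = np.zeros(n)
    rem_epochs = np.flatnonzero(hyp.labels == "R")
    if rem_epochs.size:
        rem_dur = rem_epochs.size * hyp.epoch_s
        n_bursts = rng.poisson(cfg.theta_burst_rate_hz * rem_dur)
        rem_t0 = rem_epochs * hyp.epoch_s
        for _ in range(n_bursts):
            e = rng.choice(rem_t0)
            start = e + rng.uniform(0, hyp.epoch_s)
            dur = rng.uniform(*cfg.theta_burst_dur_s)
            i0, i1 = int(start * rate), min(n, int((start + dur) * rate))
            if i1 > i0:
                w = np.hanning(i1 - i0)
                burst_env[i0:i1] = np.maximum(burst_env[i0:i1], w)
    freq = cfg.theta_freq_hz + drift + cfg.theta_burst_freq_boost_hz * burst_env
    phase = np.cumsum(2 * np.pi * freq / rate)
    phase -= phase[0]
    theta_amp = _state_gain(hyp, cfg.theta_amp_uv, rate, n)
    theta_amp = theta_amp * (1.0 + (cfg.theta_burst_amp_gain - 1.0) * burst_env * rem_mask)
    theta = theta_amp * np.cos(phase)

    delta = _bandlimited_noise(n, rate, 0.5, 4.0, rng) * _state_gain(
        hyp, cfg.delta_amp_uv, rate, n
    )

    # sleep spindles: 12-14 Hz packets during NREM/IS (stronger frontally)
    spindle = np.zeros(n)
    ni_epochs = np.flatnonzero((hyp.labels == "N") | (hyp.labels == "I"))
    if ni_epochs.size:
        ni_dur = ni_epochs.size * hyp.epoch_s
        for _ in range(rng.poisson(cfg.spindle_rate_hz * ni_dur)):
            e = rng.choice(ni_epochs) * hyp.epoch_s
            start = e + rng.uniform(0, hyp.epoch_s)
            dur = rng.uniform(0.5, 1.2)
            i0, i1 = int(start * rate), min(n, int((start + dur) * rate))
            if i1 > i0:
                w = np.hanning(i1 - i0)
                f_sp = rng.uniform(12.0, 14.0)
                spindle[i0:i1] += w * np.sin(2 * np.pi * f_sp * t[i0:i1])
    spindle_gain = _state_gain(hyp, cfg.spindle_amp_uv, rate, n)

    pink_p = pink_noise(n, rng) * cfg.eeg_pink_uv
    pink_f = pink_noise(n, rng) * cfg.eeg_pink_uv
    eeg_parietal = pink_p + delta + theta + 0.5 * spindle_gain * spindle
    eeg_frontal = (
        pink_f + 0.9 * delta + 0.5 * theta + spindle_gain * spindle
    )

    emg = rng.standard_normal(n) * _state_gain(hyp, cfg.emg_tone_uv, rate, n)

    channels = {"eeg_parietal": eeg_parietal, "eeg_frontal": eeg_frontal, "emg": emg}
    aux = {"theta_phase": phase, "theta_freq": freq, "rate_hz": rate}
    return channels, aux


def inject_emg_twitches(
    emg: np.ndarray,
    rate_hz: float,
    event_times: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add brief high-amplitude bursts to the EMG at the given event times."""
    emg = emg.copy()
    half = int(cfg.emg_twitch_dur_ms / 1000.0 * rate_hz / 2)
    w = np.hanning(2 * half) if half > 0 else np.ones(1)
    for te in event_times:
        i = int(round(te * rate_hz))
        i0, i1 = max(0, i - half), min(emg.size, i + half)
        seg = w[: i1 - i0]
        emg[i0:i1] += cfg.emg_twitch_amp_uv * seg * rng.standard_normal(i1 - i0)
    return emg


def pwave_template(cfg: SimConfig, rate_hz: float) -> np.ndarray:
    """Difference-of-Gaussians biphasic waveform; trough depth 1, at index
    ``len(template)//2``."""
    s = cfg.pwave_halfwidth_ms / 1000.0 / 2.355  # FWHM -> Gaussian sigma
    tt = np.arange(-4 * s, 10 * s, 1.0 / rate_hz)
    w = -np.exp(-(tt**2) / (2 * s**2)) + 0.35 * np.exp(
        -((tt - 2.2 * s) ** 2) / (2 * (1.6 * s) ** 2)
    )
    trough = int(np.argmin(w))
    # centre the trough so injection indexes are symmetric
    pad = max(0, (w.size - 1) - 2 * trough)
    w = np.concatenate([np.zeros(pad), w])
    return w / abs(w.min())


def _draw_spontaneous_times(
    hyp: Hypnogram, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson base events per epoch plus clustered companions.

    ``pwave_rates`` are total expected event rates per state; the base
    (cluster-seed) rate is deflated by the expected cluster multiplicity so
    the realized rate matches the configured one.
    """
    lo, hi = cfg.cluster_extra_range
    mean_extra = (lo + hi) / 2.0
    times: list[float] = []
    cluster_ids: list[int] = []
    cid = 0
    for k, s in enumerate(hyp.labels):
        total_rate = cfg.pwave_rates.get(s, 0.0)
        base_rate = total_rate / (1.0 + cfg.cluster_prob * mean_extra)
        n_ev = rng.poisson(base_rate * hyp.epoch_s)
        for _ in range(n_ev):
            t0 = (k + rng.uniform()) * hyp.epoch_s
            times.append(t0)
            cluster_ids.append(cid)
            if rng.uniform() < cfg.cluster_prob:
                tc = t0
                for _ in range(rng.integers(lo, hi + 1)):
                    tc += rng.uniform(*cfg.cluster_isi_range_s)
                    if tc < hyp.duration_s:
                        times.append(tc)
                        cluster_ids.append(cid)
            cid += 1
    return np.asarray(times), np.asarray(cluster_ids, dtype=int)


def _couple_to_theta(
    times: np.ndarray,
    hyp: Hypnogram,
    aux: dict,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shift REM events to a von Mises-drawn theta phase (<= one cycle)."""
    if aux is None or cfg.theta_coupling_kappa <= 0 or times.size == 0:
        return times
    rate = aux["rate_hz"]
    phase, freq = aux["theta_phase"], aux["theta_freq"]
    out = times.copy()
    in_rem = hyp.state_at(times) == "R"
    targets = rng.vonmises(cfg.theta_coupling_mu, cfg.theta_coupling_kappa, times.size)
    for j in np.flatnonzero(in_rem):
        i = min(int(round(out[j] * rate)), phase.size - 1)
        cur = np.mod(phase[i] + np.pi, 2 * np.pi) - np.pi
        dphi = np.mod(targets[j] - cur + np.pi, 2 * np.pi) - np.pi
        out[j] = out[j] + dphi / (2 * np.pi * freq[i])
    return out


def synth_lfp(
    hyp: Hypnogram,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    eeg_aux: dict | None = None,
    laser: LaserProtocol | None = None,
    evoked_rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Synthesize the primary/reference LFP pair with injected P-waves.

    Returns the channel dict (mV) and a :class:`GroundTruth` whose
    ``pwave_times`` are the exact trough times of the injected waveforms.
    """
    rng = rng or _substream(cfg.seed, _SALT_LFP)
    evoked_rng = evoked_rng or _substream(cfg.seed, _SALT_EVOKED)
    rate = cfg.rate_ephys_hz
    n = int(round(hyp.duration_s * rate))

    shared_sd = cfg.lfp_noise_sd_mv * np.sqrt(cfg.lfp_shared_noise_frac)
    indep_sd = cfg.lfp_noise_sd_mv * np.sqrt(1 - cfg.lfp_shared_noise_frac)
    shared = pink_noise(n, rng) * shared_sd
    primary = shared + pink_noise(n, rng) * indep_sd
    reference = shared + pink_noise(n, rng) * indep_sd

    times, cluster_ids = _draw_spontaneous_times(hyp, cfg, rng)
    times = _couple_to_theta(times, hyp, eeg_aux, cfg, rng)
    provenance = np.array(["spontaneous"] * times.size, dtype="U16")

    evoked_flags = None
    if laser is not None and len(laser) > 0:
        evoked_flags = np.zeros(len(laser), dtype=bool)
        scale = cfg.evoked_latency_mode_ms / (cfg.evoked_latency_shape - 1.0)
        ev_times = []
        states = hyp.state_at(laser.onsets_s)
        for k, (onset, st) in enumerate(zip(laser.onsets_s, states)):
            p = cfg.evoked_success_by_state.get(st, 0.0)
            if evoked_rng.uniform() < p:
                lat = np.clip(
                    evoked_rng.gamma(cfg.evoked_latency_shape, scale), 2.0, 98.0
                )
                ev_times.append(onset + lat / 1000.0)
                evoked_flags[k] = True
        if ev_times:
            ev_times = np.asarray(ev_times)
            times = np.concatenate([times, ev_times])
            cluster_ids = np.concatenate(
                [cluster_ids, -np.ones(ev_times.size, dtype=int)]
            )
            provenance = np.concatenate(
                [provenance, np.array(["laser_triggered"] * ev_times.size, dtype="U16")]
            )

    # sort and enforce a minimal gap (evoked events win ties)
    order = np.argsort(times, kind="stable")
    times, cluster_ids, provenance = times[order], cluster_ids[order], provenance[order]
    keep = np.ones(times.size, dtype=bool)
    last = -np.inf
    for j in range(times.size):
        if times[j] - last < cfg.min_event_gap_s:
            if provenance[j] == "laser_triggered" and j > 0 and keep[j - 1]:
                keep[j - 1] = False  # prefer the evoked event
                last = times[j]
            else:
                keep[j] = False
                continue
        else:
            last = times[j]
    times, cluster_ids, provenance = times[keep], cluster_ids[keep], provenance[keep]
    inside = (times > 0.5) & (times < hyp.duration_s - 0.5)
    times, cluster_ids, provenance = times[inside], cluster_ids[inside], provenance[inside]

    amp = cfg.pwave_amp_sd * cfg.lfp_noise_sd_mv
    if times.size and amp < 3.0 * cfg.lfp_noise_sd_mv:
        warnings.warn("P-wave amplitude close to the noise floor; detection will degrade")
    w = pwave_template(cfg, rate) * amp
    half = w.size // 2
    # snap truth to the sample grid so trough times are exactly representable
    idx = np.round(times * rate).astype(int)
    times = idx / rate
    for i in idx:
        i0, i1 = i - half, i - half + w.size
        if i0 >= 0 and i1 <= n:
            primary[i0:i1] += w

    gt = GroundTruth(
        hypnogram=hyp,
        pwave_times=times,
        pwave_cluster_ids=cluster_ids,
        pwave_provenance=provenance,
        laser=laser,
        evoked_flags=evoked_flags,
    )
    return {"lfp_primary": primary, "lfp_reference": reference}, gt


def calcium_kernel(cfg: SimConfig, rate_hz: float) -> tuple[np.ndarray, int]:
    """Asymmetric transient: Gaussian rise to a peak ``transient_peak_s`` after
    the event (climbing from ~0.4 s before), exponential decay afterwards.

    Returns (kernel, index of the event time within the kernel).
    """
    pre = 1.5
    post = cfg.transient_peak_s + 5 * cfg.transient_decay_s
    tt = np.arange(-pre, post, 1.0 / rate_hz)
    k = np.where(
        tt <= cfg.transient_peak_s,
        np.exp(-((tt - cfg.transient_peak_s) ** 2) / (2 * cfg.transient_rise_sd_s**2)),
        np.exp(-(tt - cfg.transient_peak_s) / cfg.transient_decay_s),
    )
    return k, int(round(pre * rate_hz))


def synth_photometry(
    hyp: Hypnogram,
    pwave_times: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Synthesize the 465/405 nm photometry pair.

    ``465 = f465 * (1 + calcium_true) * bleach * (1 + motion)`` and
    ``405 = f405 * bleach * (1 + motion)`` with shared multiplicative bleaching
    ``exp(-t/tau)`` and shared motion noise, so the isosbestic regression is
    exactly the right correction model. Returns the channels and
    ``calcium_true`` (noiseless dF/F-scale trace).
    """
    rng = rng or _substream(cfg.seed, _SALT_PHOTO)
    rate = cfg.rate_photo_hz
    n = int(round(hyp.duration_s * rate))
    t = np.arange(n) / rate

    baseline = _state_gain(hyp, cfg.photo_baseline_dff, rate, n)
    # smooth state steps with a ~2 s boxcar: calcium dynamics are slow
    box = int(2.0 * rate)
    baseline = np.convolve(baseline, np.ones(box) / box, mode="same")

    calcium = baseline.copy()
    if len(pwave_times):
        k, k0 = calcium_kernel(cfg, rate)
        for te in np.asarray(pwave_times):
            i = int(round(te * rate)) - k0
            j0, j1 = max(0, i), min(n, i + k.size)
            if j1 > j0:
                calcium[j0:j1] += cfg.transient_amp_dff * k[j0 - i : j1 - i]

    bleach = np.exp(-t / cfg.bleach_tau_s)
    motion = rng.standard_normal(n) * cfg.motion_noise_sd
    sig465 = cfg.f465_base * (1.0 + calcium) * bleach * (1.0 + motion)
    sig405 = cfg.f405_base * bleach * (1.0 + motion)
    return {"photo_465": sig465, "photo_405": sig405}, calcium


def synth_laser(
    hyp: Hypnogram,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> LaserProtocol:
    """Generate the laser protocol for the configured mode."""
    rng = rng or _substream(cfg.seed, _SALT_LASER)
    dur = hyp.duration_s
    mode = cfg.laser_mode
    if mode == "open_loop":
        onsets, durs, train_ids = [], [], []
        t = rng.uniform(60.0, 180.0)
        tid = 0
        while t + 120.0 <= dur:
            p = t + np.arange(1200) * 0.1
            onsets.extend(p)
            durs.extend([10.0] * 1200)
            train_ids.extend([tid] * 1200)
            tid += 1
            t = t + 120.0 + rng.uniform(15 * 60.0, 25 * 60.0)
        return LaserProtocol(
            np.asarray(onsets), np.asarray(durs), "open_loop",
            train_ids=np.asarray(train_ids, dtype=int),
        )
    if mode == "brief_pulse":
        onsets, durs = [], []
        t = rng.uniform(10.0, 60.0)
        while t < dur - 0.2:
            onsets.append(t)
            durs.append(rng.uniform(10.0, 20.0))
            t += rng.uniform(10.0, 60.0)
        return LaserProtocol(np.asarray(onsets), np.asarray(durs), "brief_pulse")
    if mode == "closed_loop":
        onsets, durs, train_ids = [], [], []
        episode_on: dict[float, bool] = {}
        for tid, ep in enumerate(hyp.episodes_of("R")):
            on = bool(rng.uniform() < cfg.closed_loop_p_on)
            episode_on[ep.onset_s] = on
            if on:
                p = np.arange(ep.onset_s, ep.offset_s - 0.01, 0.1)
                onsets.extend(p)
                durs.extend([10.0] * p.size)
                train_ids.extend([tid] * p.size)
        return LaserProtocol(
            np.asarray(onsets), np.asarray(durs), "closed_loop",
            train_ids=np.asarray(train_ids, dtype=int), episode_on=episode_on,
        )
    raise ValueError(f"unknown laser mode {mode!r}")


def simulate_session(cfg: SimConfig) -> tuple[Recording, GroundTruth]:
    """Generate a full synthetic session: all channels plus ground truth."""
    hyp = simulate_hypnogram(cfg)
    eeg, aux = synth_eeg_emg(hyp, cfg)
    laser = synth_laser(hyp, cfg) if cfg.laser_mode else None
    lfp, gt = synth_lfp(hyp, cfg, eeg_aux=aux, laser=laser)
    rem_events = gt.pwave_times[hyp.state_at(gt.pwave_times) == "R"]
    emg_rng = _substream(cfg.seed, _SALT_EEG + 100)
    eeg["emg"] = inject_emg_twitches(
        eeg["emg"], cfg.rate_ephys_hz, rem_events, cfg, emg_rng
    )
    photo, calcium = synth_photometry(hyp, gt.pwave_times, cfg)
    gt.calcium_true = calcium

    channels = {
        "eeg_parietal": Channel(eeg["eeg_parietal"], cfg.rate_ephys_hz, "uV"),
        "eeg_frontal": Channel(eeg["eeg_frontal"], cfg.rate_ephys_hz, "uV"),
        "emg": Channel(eeg["emg"], cfg.rate_ephys_hz, "uV"),
        "lfp_primary": Channel(lfp["lfp_primary"], cfg.rate_ephys_hz, "mV"),
        "lfp_reference": Channel(lfp["lfp_reference"], cfg.rate_ephys_hz, "mV"),
        "photo_465": Channel(photo["photo_465"], cfg.rate_photo_hz, "a.u."),
        "photo_405": Channel(photo["photo_405"], cfg.rate_photo_hz, "a.u."),
    }
    rec = Recording(channels, metadata={"seed": cfg.seed, "synthetic": True})
    return rec, gt
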