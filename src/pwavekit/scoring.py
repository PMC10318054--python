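"""Sleep-state scoring, closed-loop REM detection, and transition utilities.

The offline scorer is an automated emulation of manual scoring criteria:
wake = high EMG tone (EMG veto takes precedence), REM = high theta/delta ratio
with atonia, NREM = dominant delta, IS = intermediate theta/delta with sigma
(spindle) power. Thresholds default to data-driven two-cluster splits of the
per-epoch feature distributions (log EMG amplitude, log theta/delta), with
explicit overrides; manual scoring cannot be reproduced, only emulated, and
this is documented behaviour rather than a claim of scorer equivalence.

The closed-loop detector is a causal hysteresis state machine on the
theta/delta ratio: REM onset when the ratio exceeds a *hard* threshold
(calibration mean + 1 SD), offset when it drops below a *soft* threshold
(calibration mean) or when the EMG amplitude exceeds its own threshold
(mean + 0.5 SD). Calibration statistics come from prior recordings of the
same animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EPOCH_S, Episode, Hypnogram
from . import spectral
from .spectral import Spectrogram, band, band_power, theta_delta_ratio


def _two_means_threshold(x: np.ndarray) -> float:
    """Midpoint threshold from a 1-D two-cluster split (k-means on a line)."""
    x = np.asarray(x, float)
    lo, hi = np.percentile(x, [10, 90])
    c = np.array([lo, hi], dtype=float)
    for _ in range(100):
        assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        new = np.array(
            [x[assign == k].mean() if np.any(assign == k) else c[k] for k in (0, 1)]
        )
        if np.allclose(new, c):
            break
        c = new
    return float(c.mean())


@dataclass
class ScoringParams:
    """Thresholds for the rule-based scorer; None = derive from the data."""

    emg_threshold: float | None = None        # on EMG amplitude
    theta_delta_threshold: float | None = None  # REM if ratio above
    is_theta_delta_threshold: float | None = None  # IS if ratio above (else NREM)
    smooth_epochs: int = 3                    # majority filter width (odd)


def score_states(
    eeg_spec_parietal: Spectrogram,
    emg_amp: np.ndarray,
    params: ScoringParams | None = None,
    eeg_spec_frontal: Spectrogram | None = None,
) -> Hypnogram:
    """Rule-based epoch scoring from hypnogram-preset spectrograms.

    Decision order per epoch: wake (EMG veto) -> REM (theta/delta high) ->
    IS (intermediate theta/delta, supported by frontal sigma power when the
    frontal channel is available) -> NREM. A short majority filter removes
    isolated single-epoch labels.
    """
    params = params or ScoringParams()
    spec = eeg_spec_parietal
    n = min(spec.power.shape[1], emg_amp.size)
    td = theta_delta_ratio(spec)[:n]
    emg = np.asarray(emg_amp, float)[:n]

    emg_thr = params.emg_threshold
    if emg_thr is None:
        emg_thr = np.exp(_two_means_threshold(np.log(emg + 1e-12)))
    sleep = emg < emg_thr
    log_td = np.log(td + 1e-12)
    # hierarchical split of the sleep theta/delta distribution: the first
    # two-means boundary separates delta-dominated NREM from the mixed/theta
    # group (IS + REM); the second splits that group into IS vs REM
    is_thr = params.is_theta_delta_threshold
    if is_thr is None:
        base = log_td[sleep] if sleep.any() else log_td
        is_thr = np.exp(_two_means_threshold(base))
    td_thr = params.theta_delta_threshold
    if td_thr is None:
        upper = log_td[sleep & (td >= is_thr)]
        td_thr = (
            np.exp(_two_means_threshold(upper)) if upper.size > 10 else 2.0 * is_thr
        )

    sigma = None
    if eeg_spec_frontal is not None:
        sigma = band_power(eeg_spec_frontal, band("sigma"))[:n]

    labels = np.empty(n, dtype="U1")
    for k in range(n):
        if emg[k] >= emg_thr:
            labels[k] = "W"
        elif td[k] >= td_thr:
            labels[k] = "R"
        elif td[k] >= is_thr:
            labels[k] = "I"
        else:
            labels[k] = "N"

    w = params.smooth_epochs
    if w >= 3 and n >= w:
        half = w // 2
        sm = labels.copy()
        for k in range(half, n - half):
            window = labels[k - half : k + half + 1]
            vals, counts = np.unique(window, return_counts=True)
            if counts.max() > half:
                sm[k] = vals[counts.argmax()]
        labels = sm
    return Hypnogram(labels, spec.step_s)


@dataclass
class ClosedLoopCalibration:
    """theta/delta and EMG-amplitude statistics from prior recordings."""

    theta_delta_mean: float
    theta_delta_sd: float
    emg_amp_mean: float
    emg_amp_sd: float

    def __post_init__(self) -> None:
        if self.theta_delta_sd < 0 or self.emg_amp_sd < 0:
            raise ValueError("calibration SDs must be non-negative")

    @property
    def hard_threshold(self) -> float:
        return self.theta_delta_mean + self.theta_delta_sd

    @property
    def soft_threshold(self) -> float:
        return self.theta_delta_mean

    @property
    def emg_threshold(self) -> float:
        return self.emg_amp_mean + 0.5 * self.emg_amp_sd

    @classmethod
    def from_recording(
        cls, eeg: np.ndarray, emg: np.ndarray, rate_hz: float
    ) -> "ClosedLoopCalibration":
        spec = spectral.spectrogram(eeg, rate_hz, preset="hypnogram")
        td = theta_delta_ratio(spec)
        _, amp = spectral.emg_amplitude(emg, rate_hz, mode="state")
        return cls(float(td.mean()), float(td.std()), float(amp.mean()), float(amp.std()))


def closed_loop_step_machine(
    theta_delta: np.ndarray,
    emg_amp: np.ndarray,
    calibration: ClosedLoopCalibration,
    step_s: float = EPOCH_S,
    onset_debounce: int = 1,
) -> tuple[list[tuple[float, float]], np.ndarray]:
    """Causal hysteresis state machine on precomputed per-step features.

    Feature value ``k`` summarizes the trailing window ending at time
    ``(k+1)*step_s``; decisions are made at window ends, so a step change at
    ``t0`` is first seen at ``t0 + step``. Returns (intervals, per-step
    boolean decisions); an interval is ``[onset, offset)`` in seconds.
    """
    if calibration is None:
        raise ValueError("closed-loop detection requires a calibration")
    td = np.asarray(theta_delta, float)
    emg = np.asarray(emg_amp, float)
    n = min(td.size, emg.size)
    in_rem = np.zeros(n, dtype=bool)
    intervals: list[tuple[float, float]] = []
    state = False
    onset = 0.0
    consecutive = 0
    for k in range(n):
        t_end = (k + 1) * step_s
        if not state:
            if td[k] > calibration.hard_threshold and emg[k] <= calibration.emg_threshold:
                consecutive += 1
                if consecutive >= onset_debounce:
                    state = True
                    onset = t_end
            else:
                consecutive = 0
        else:
            if td[k] < calibration.soft_threshold or emg[k] > calibration.emg_threshold:
                state = False
                consecutive = 0
                intervals.append((onset, t_end))
        in_rem[k] = state
    if state:
        intervals.append((onset, n * step_s))
    return intervals, in_rem


def closed_loop_rem(
    eeg: np.ndarray,
    emg: np.ndarray,
    rate_hz: float,
    calibration: ClosedLoopCalibration,
    window_s: float = 5.0,
    step_s: float = EPOCH_S,
    onset_debounce: int = 1,
) -> tuple[list[tuple[float, float]], np.ndarray]:
    """Online REM detection from raw EEG/EMG.

    theta/delta and EMG amplitude are computed on trailing ``window_s``
    windows stepped by ``step_s`` — each decision uses only past samples.
    """
    nwin = int(window_s * rate_hz)
    nstep = int(step_s * rate_hz)
    n_steps = (min(eeg.size, emg.size) - nwin) // nstep + 1
    if n_steps < 1:
        raise ValueError("signal shorter than one online window")
    freqs = np.fft.rfftfreq(nwin, 1.0 / rate_hz)
    taper = np.hanning(nwin)
    th_rows = (freqs >= 6.0) & (freqs <= 10.0)
    de_rows = (freqs >= 0.5) & (freqs <= 4.0)
    emg_rows = (freqs >= 10.0) & (freqs <= 500.0)
    df = freqs[1] - freqs[0]
    td = np.empty(n_steps)
    emg_a = np.empty(n_steps)
    for k in range(n_steps):
        sl = slice(k * nstep, k * nstep + nwin)
        e = eeg[sl] - eeg[sl].mean()
        p = np.abs(np.fft.rfft(e * taper)) ** 2
        td[k] = p[th_rows].mean() / max(p[de_rows].mean(), np.finfo(float).tiny)
        m = emg[sl] - emg[sl].mean()
        pm = np.abs(np.fft.rfft(m * taper)) ** 2
        emg_a[k] = np.sqrt(pm[emg_rows].sum() * df / (taper**2).sum() / rate_hz * 2)
    # feature k summarizes the trailing window ending at k*step + window; the
    # decision becomes available there but labels the last full epoch of that
    # window, so intervals are reported on the epoch-onset clock
    intervals, decisions = closed_loop_step_machine(
        td, emg_a, calibration, step_s=step_s, onset_debounce=onset_debounce
    )
    lag = window_s - 2 * step_s
    intervals = [(a + lag, b + lag) for a, b in intervals]
    return intervals, decisions


def assign_laser_episodes(
    rem_intervals: list[tuple[float, float]],
    p_on: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> list[bool]:
    """Independent Bernoulli(p_on) laser-on designation per REM episode."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [bool(rng.uniform() < p_on) for _ in rem_intervals]


@dataclass
class TransitionSpec:
    from_state: str
    to_state: str
    min_durations_s: dict[str, float] = field(
        default_factory=lambda: {"W": 15.0, "N": 40.0, "I": 15.0, "R": 40.0}
    )
    pre_s: float = 60.0
    post_s: float = 60.0


def find_transitions(hyp: Hypnogram, spec: TransitionSpec) -> list[tuple[Episode, Episode]]:
    """All X->Y episode pairs whose flanking episodes meet the duration minima."""
    eps = hyp.episodes
    out = []
    for a, b in zip(eps[:-1], eps[1:]):
        if (
            a.state == spec.from_state
            and b.state == spec.to_state
            and a.duration_s >= spec.min_durations_s.get(a.state, 0.0)
            and b.duration_s >= spec.min_durations_s.get(b.state, 0.0)
        ):
            out.append((a, b))
    return out


def time_normalize_sequence(
    hyp: Hypnogram,
    signal: np.ndarray,
    signal_rate_hz: float,
    sequence: tuple[str, ...] = ("N", "I", "R", "W"),
    bins_per_state: int = 20,
    min_durations_s: dict[str, float] | None = None,
) -> tuple[np.ndarray, int]:
    """Average a signal over N->I->R->W sequences on normalized time axes.

    Each matched episode's samples are mapped onto ``bins_per_state``
    fractional-time bins, making episodes of unequal duration comparable.
    Returns (mean trace of length ``len(sequence) * bins_per_state``, number
    of sequences averaged).
    """
    mins = min_durations_s or {"W": 15.0, "N": 40.0, "I": 15.0, "R": 40.0}
    eps = hyp.episodes
    traces = []
    k = len(sequence)
    for i in range(len(eps) - k + 1):
        run = eps[i : i + k]
        if tuple(e.state for e in run) != tuple(sequence):
            continue
        if any(e.duration_s < mins.get(e.state, 0.0) for e in run):
            continue
        parts = []
        ok = True
        for e in run:
            i0 = int(round(e.onset_s * signal_rate_hz))
            i1 = int(round(e.offset_s * signal_rate_hz))
            seg = np.asarray(signal[i0:i1], float)
            if seg.size < bins_per_state:
                ok = False
                break
            # fractional-time binning: mean of samples falling in each bin
            edges = np.linspace(0, seg.size, bins_per_state + 1).astype(int)
            parts.append(
                np.array([seg[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
            )
        if ok:
            traces.append(np.concatenate(parts))
    if not traces:
        return np.full(k * bins_per_state, np.nan), 0
    return np.mean(traces, axis=0), len(traces)
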