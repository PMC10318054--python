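"""Event-aligned EEG spectral summaries, theta-phase coupling and EMG twitches.

Event spectrograms are collected over a -3..+3 s slab around each event on
the 100 ms event grid, locally normalized (each frequency by its mean power
within the slab), and averaged across events. Theta-phase coupling uses the
analytic-signal (Hilbert) phase of the 6-12 Hz filtered parietal EEG inside
REM episodes of at least 30 s, tested for non-uniformity with the Rayleigh
test.

Phase convention: phase 0 at the oscillation peak of the band-passed signal;
the rising phase is -pi..0 (so a trough is +/-pi and the steepest rise is
-pi/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .core import Episode
from . import spectral
from .spectral import Spectrogram, normalize_local, normalize_recording_mean


@dataclass
class EventSpectralSummary:
    """Mean locally-normalized event spectrogram and derived traces."""

    mean_power: np.ndarray  # freq x lag
    freqs_hz: np.ndarray
    lags_s: np.ndarray
    n_events: int
    n_dropped: int
    event_class: str = "spontaneous"

    def band_trace(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        rows = (self.freqs_hz >= lo_hz) & (self.freqs_hz <= hi_hz)
        return self.mean_power[rows].mean(axis=0)

    def central_profile(
        self, window_s: tuple[float, float], f_max_hz: float = 20.0
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-frequency mean normalized power inside a central lag window."""
        cols = (self.lags_s >= window_s[0]) & (self.lags_s <= window_s[1])
        rows = self.freqs_hz <= f_max_hz
        return self.freqs_hz[rows], self.mean_power[np.ix_(rows, cols)].mean(axis=1)


def event_spectrogram(
    eeg: np.ndarray,
    rate_hz: float,
    event_times_s: np.ndarray,
    span_s: float = 6.0,
    event_class: str = "spontaneous",
    spec: Spectrogram | None = None,
) -> EventSpectralSummary:
    """Locally-normalized mean spectrogram around events.

    The whole-recording spectrogram is computed once on the event preset
    (2 s windows, 95% overlap -> 100 ms steps); a ``span_s`` slab is cut per
    event, normalized within the slab, and averaged. Events whose slab would
    be truncated at a recording edge are dropped (and counted).
    """
    if spec is None:
        spec = spectral.spectrogram(eeg, rate_hz, preset="event")
    slabs = []
    dropped = 0
    lags = None
    for te in np.asarray(event_times_s, float):
        slab = spec.slab(te, span_s)
        if slab is None:
            dropped += 1
            continue
        slabs.append(normalize_local(slab).power)
        if lags is None:
            lags = slab.times_s
    if not slabs:
        n_cols = int(round(span_s / spec.step_s)) + 1
        lags = (np.arange(n_cols) - n_cols // 2) * spec.step_s
        return EventSpectralSummary(
            np.full((spec.freqs_hz.size, n_cols), np.nan),
            spec.freqs_hz, lags, 0, dropped, event_class,
        )
    return EventSpectralSummary(
        np.mean(slabs, axis=0), spec.freqs_hz, lags, len(slabs), dropped, event_class
    )


def profile_8_20(summary: EventSpectralSummary, window_s: tuple[float, float]) -> float:
    """Mean normalized power over 8-20 Hz inside the central window.

    Central windows: +/-0.5 s for P-waves and random controls, 0..+1 s for
    failed laser pulses.
    """
    freqs, prof = summary.central_profile(window_s, f_max_hz=20.0)
    rows = (freqs >= 8.0) & (freqs <= 20.0)
    return float(prof[rows].mean())


def random_control_times(
    rem_episodes: list[Episode],
    n: int,
    exclude_times_s: np.ndarray | None = None,
    exclusion_s: float = 0.5,
    seed: int | np.random.Generator = 0,
    edge_margin_s: float = 3.0,
) -> np.ndarray:
    """Uniform random control time points inside REM episodes, avoiding
    +/-``exclusion_s`` around real events."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = [e for e in rem_episodes if e.duration_s > 2 * edge_margin_s]
    if not eps:
        return np.empty(0)
    weights = np.array([e.duration_s - 2 * edge_margin_s for e in eps])
    weights = weights / weights.sum()
    exclude = np.sort(exclude_times_s) if exclude_times_s is not None else np.empty(0)
    out: list[float] = []
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        ep = eps[rng.choice(len(eps), p=weights)]
        t = rng.uniform(ep.onset_s + edge_margin_s, ep.offset_s - edge_margin_s)
        if exclude.size:
            j = np.searchsorted(exclude, t)
            near = []
            if j > 0:
                near.append(abs(t - exclude[j - 1]))
            if j < exclude.size:
                near.append(abs(exclude[j] - t))
            if near and min(near) < exclusion_s:
                continue
        out.append(t)
    return np.sort(np.asarray(out))


def theta_phase_of_events(
    eeg: np.ndarray,
    rate_hz: float,
    event_times_s: np.ndarray,
    rem_episodes: list[Episode],
    band_hz: tuple[float, float] = (6.0, 12.0),
    min_episode_s: float = 30.0,
) -> np.ndarray:
    """Instantaneous 6-12 Hz phase at each event within qualifying REM episodes.

    The parietal EEG is band-pass filtered per episode and the phase is the
    angle of the analytic (Hilbert) signal, in (-pi, pi].
    """
    sos = sps.butter(4, band_hz, btype="bandpass", fs=rate_hz, output="sos")
    times = np.asarray(event_times_s, float)
    phases: list[float] = []
    for ep in rem_episodes:
        if ep.duration_s < min_episode_s:
            continue
        i0 = int(round(ep.onset_s * rate_hz))
        i1 = int(round(ep.offset_s * rate_hz))
        seg = sps.sosfiltfilt(sos, eeg[i0:i1])
        phase = np.angle(sps.hilbert(seg))
        ev = times[(times >= ep.onset_s) & (times < ep.offset_s)]
        idx = np.minimum(((ev - ep.onset_s) * rate_hz).round().astype(int), seg.size - 1)
        phases.extend(phase[idx].tolist())
    return np.asarray(phases)


def phase_histogram(
    phases: np.ndarray, n_bins: int = 18
) -> tuple[np.ndarray, np.ndarray]:
    """Percentage of events per phase bin over (-pi, pi]."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    pct = 100.0 * counts / max(phases.size, 1)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, pct


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh test for circular non-uniformity.

    Returns (R, p) where R is the mean resultant length; z = n R^2 and the
    p-value uses the standard small-sample series correction, clipped to
    [0, 1].
    """
    phases = np.asarray(phases, float)
    n = phases.size
    if n == 0:
        raise ValueError("no phases supplied")
    C = np.cos(phases).sum()
    S = np.sin(phases).sum()
    R = np.hypot(C, S) / n
    z = n * R**2
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return float(R), float(min(max(p, 0.0), 1.0))


def spectral_centroid(
    freqs_hz: np.ndarray, psd: np.ndarray, lo_hz: float = 6.0, hi_hz: float = 12.0
) -> float:
    """Power-weighted mean frequency (center of mass) over [lo, hi]."""
    freqs_hz = np.asarray(freqs_hz, float)
    psd = np.asarray(psd, float)
    rows = (freqs_hz >= lo_hz) & (freqs_hz <= hi_hz)
    if not rows.any():
        raise ValueError("no PSD bins inside the requested band")
    p = psd[rows]
    f = freqs_hz[rows]
    tot = p.sum()
    if tot <= 0:
        raise ValueError("non-positive total band power")
    return float((f * p).sum() / tot)


def laser_success_correlates(
    pulses: pd.DataFrame,
    eeg: np.ndarray,
    rate_hz: float,
    pre_window_s: float = 3.0,
    band_hz: tuple[float, float] = (6.0, 12.0),
    rem_mask_fn=None,
) -> pd.DataFrame:
    """Point-biserial correlation of per-pulse success with preceding theta.

    For each pulse the recording-mean-normalized event-grid spectrogram is
    averaged over the ``pre_window_s`` interval immediately before onset;
    predictors are the mean 6-12 Hz power and the spectral centroid of that
    mean PSD slice. Returns one row per predictor with r and p.
    """
    spec = normalize_recording_mean(
        spectral.spectrogram(eeg, rate_hz, preset="event")
    )
    rows = spec.band_rows(*band_hz)
    power, centroid, outcome = [], [], []
    for onset, succ in zip(pulses["onset_s"], pulses["success"]):
        cols = (spec.times_s >= onset - pre_window_s) & (spec.times_s < onset)
        if not cols.any():
            continue
        mean_psd = spec.power[:, cols].mean(axis=1)
        power.append(mean_psd[rows].mean())
        centroid.append(spectral_centroid(spec.freqs_hz, mean_psd, *band_hz))
        outcome.append(bool(succ))
    outcome = np.asarray(outcome, float)
    out = []
    for name, x in (("theta_power", power), ("theta_centroid", centroid)):
        r, p = stats.pointbiserialr(outcome, np.asarray(x))
        out.append({"predictor": name, "r": float(r), "p": float(p), "n": outcome.size})
    return pd.DataFrame(out)


def emg_twitch_metrics(
    emg: np.ndarray,
    rate_hz: float,
    event_times_by_class: dict[str, np.ndarray],
    event_window_s: tuple[float, float] = (-0.05, 0.05),
    baseline_window_s: tuple[float, float] = (-0.15, -0.05),
) -> pd.DataFrame:
    """Twitch-locked EMG amplitude analysis.

    The twitch-mode EMG amplitude (100 ms half-overlapping windows, 10-100 Hz)
    is collected over +/-1 s around each event and z-scored within the slab;
    the mean z over the event window is compared with the preceding baseline
    window by a paired t-test across events, per event class.
    """
    times, amp = spectral.emg_amplitude(emg, rate_hz, mode="twitch")
    step = times[1] - times[0]
    half = int(round(1.0 / step))
    out = []
    for cls, ev in event_times_by_class.items():
        evs, base = [], []
        for te in np.asarray(ev, float):
            c = np.searchsorted(times, te)
            if c - half < 0 or c + half + 1 > amp.size:
                continue
            slab = amp[c - half : c + half + 1]
            sd = slab.std()
            z = (slab - slab.mean()) / (sd if sd > 0 else 1.0)
            lag = times[c - half : c + half + 1] - te
            evw = (lag >= event_window_s[0]) & (lag <= event_window_s[1])
            bsw = (lag >= baseline_window_s[0]) & (lag < baseline_window_s[1])
            if evw.any() and bsw.any():
                evs.append(z[evw].mean())
                base.append(z[bsw].mean())
        if len(evs) >= 2:
            t_stat, p = stats.ttest_rel(evs, base)
        else:
            t_stat, p = np.nan, np.nan
        out.append(
            {
                "event_class": cls,
                "n": len(evs),
                "event_z": float(np.mean(evs)) if evs else np.nan,
                "baseline_z": float(np.mean(base)) if base else np.nan,
                "t": float(t_stat),
                "p": float(p),
            }
        )
    return pd.DataFrame(out)
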