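"""P-wave detection and event bookkeeping on the pontine LFP.

Detection recipe: band-pass both LFP tips at 1-50 Hz, subtract the reference
from the primary (primary-only when no usable reference exists), threshold at
``mean - 4.5 * SD`` of the whole trace, take the trough of each sub-threshold
run as the event time, then discard artifact-like candidates (trough depth
> 0.5 mV or half-width > 80 ms). Events are classified by their
nearest-neighbour inter-event interval: < 520 ms clustered, > 780 ms single,
in between unclassified (the two printed thresholds leave a gap, which we do
not force into either bin). The 520/780 ms defaults are the 10th/15th
percentiles of pooled inter-event intervals and can be re-derived on new data
with :func:`isi_percentiles`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import Hypnogram, LaserProtocol, STATES


@dataclass
class DetectionParams:
    bandpass_hz: tuple[float, float] = (1.0, 50.0)
    threshold_k: float = 4.5
    amp_cap_mv: float = 0.5
    halfwidth_cap_ms: float = 80.0
    cluster_max_isi_ms: float = 520.0
    single_min_isi_ms: float = 780.0
    merge_gap_ms: float = 50.0  # supra-threshold gaps shorter than this join runs

    def __post_init__(self) -> None:
        if self.amp_cap_mv <= 0 or self.halfwidth_cap_ms <= 0:
            raise ValueError("caps must be positive")
        if not self.cluster_max_isi_ms < self.single_min_isi_ms:
            raise ValueError("cluster_max_isi_ms must be below single_min_isi_ms")


class PWaveSet:
    """Detected P-waves as a DataFrame-backed container.

    Columns: ``t_peak_s``, ``amplitude_mv`` (trough depth, positive),
    ``half_width_ms``, ``label`` (single/clustered/unclassified),
    ``provenance`` (spontaneous/laser_triggered), ``latency_ms`` (NaN unless
    laser-triggered).
    """

    def __init__(self, df: pd.DataFrame):
        need = {"t_peak_s", "amplitude_mv", "half_width_ms"}
        if not need.issubset(df.columns):
            raise ValueError(f"missing columns: {sorted(need - set(df.columns))}")
        df = df.sort_values("t_peak_s").reset_index(drop=True)
        for col, default in (
            ("label", "unclassified"),
            ("provenance", "spontaneous"),
            ("latency_ms", np.nan),
        ):
            if col not in df.columns:
                df[col] = default
        self.df = df

    @classmethod
    def from_arrays(cls, t_peak_s, amplitude_mv, half_width_ms) -> "PWaveSet":
        return cls(
            pd.DataFrame(
                {
                    "t_peak_s": np.asarray(t_peak_s, float),
                    "amplitude_mv": np.asarray(amplitude_mv, float),
                    "half_width_ms": np.asarray(half_width_ms, float),
                }
            )
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["t_peak_s"].to_numpy()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PWaveSet":
        return cls(pd.read_csv(path))


def preprocess_lfp(
    primary: np.ndarray,
    reference: np.ndarray | None,
    rate_hz: float,
    bandpass_hz: tuple[float, float] = (1.0, 50.0),
) -> np.ndarray:
    """Zero-phase 1-50 Hz band-pass, then subtract the reference tip.

    When ``reference`` is None (e.g. the reference channel carries its own
    P-waves or artifacts) the filtered primary alone is returned.
    """
    if rate_hz < 100:
        raise ValueError("LFP sampling rate must be at least 100 Hz")
    primary = np.asarray(primary, float)
    if not np.all(np.isfinite(primary)):
        raise ValueError("primary LFP contains non-finite samples")
    # order-8 Butterworth (zero-phase): >= 25 dB rejection of 60 Hz mains
    sos = sps.butter(8, bandpass_hz, btype="bandpass", fs=rate_hz, output="sos")
    out = sps.sosfiltfilt(sos, primary)
    if reference is not None:
        reference = np.asarray(reference, float)
        if reference.shape != primary.shape:
            raise ValueError("primary and reference LFP must have equal length")
        out = out - sps.sosfiltfilt(sos, reference)
    return out


def _half_width_ms(
    trace: np.ndarray, rate_hz: float, i_trough: int, baseline: float
) -> float:
    """Width (ms) at half trough depth, linear interpolation between samples."""
    depth = baseline - trace[i_trough]
    half_level = baseline - depth / 2.0
    # walk left
    i = i_trough
    while i > 0 and trace[i] < half_level:
        i -= 1
    if trace[i] >= half_level and i < i_trough:
        frac = (half_level - trace[i]) / (trace[i + 1] - trace[i])
        left = i + frac
    else:
        left = float(i)
    j = i_trough
    nmax = trace.size - 1
    while j < nmax and trace[j] < half_level:
        j += 1
    if trace[j] >= half_level and j > i_trough:
        frac = (half_level - trace[j]) / (trace[j - 1] - trace[j])
        right = j - frac
    else:
        right = float(j)
    return (right - left) / rate_hz * 1000.0


def detect_pwaves(
    trace: np.ndarray,
    rate_hz: float,
    params: DetectionParams | None = None,
) -> PWaveSet:
    """Threshold detection on a preprocessed LFP trace.

    The threshold is ``mean - k * SD`` of the entire trace (all states
    included). Contiguous sub-threshold runs — merged across supra-threshold
    gaps shorter than ``merge_gap_ms`` — form candidates; the run minimum is
    the event time. Candidates deeper than ``amp_cap_mv`` or wider than
    ``halfwidth_cap_ms`` are discarded as artifacts.
    """
    params = params or DetectionParams()
    trace = np.asarray(trace, float)
    sd = trace.std()
    if sd == 0:
        warnings.warn("zero-variance trace: no P-waves detectable")
        return PWaveSet.from_arrays([], [], [])
    mean = trace.mean()
    thresh = mean - params.threshold_k * sd

    below = trace < thresh
    if not below.any():
        return PWaveSet.from_arrays([], [], [])
    d = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if below[0]:
        starts = np.concatenate([[0], starts])
    if below[-1]:
        ends = np.concatenate([ends, [below.size]])

    # merge runs separated by a short supra-threshold gap (one multiphasic event)
    gap = int(params.merge_gap_ms / 1000.0 * rate_hz)
    m_starts, m_ends = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - m_ends[-1] < gap:
            m_ends[-1] = e
        else:
            m_starts.append(s)
            m_ends.append(e)

    t_peak, amp, hw = [], [], []
    for s, e in zip(m_starts, m_ends):
        i = s + int(np.argmin(trace[s:e]))
        depth = mean - trace[i]
        width = _half_width_ms(trace, rate_hz, i, mean)
        if depth > params.amp_cap_mv or width > params.halfwidth_cap_ms:
            continue
        t_peak.append(i / rate_hz)
        amp.append(depth)
        hw.append(width)
    return PWaveSet.from_arrays(t_peak, amp, hw)


def classify_isi(pwaves: PWaveSet, params: DetectionParams | None = None) -> PWaveSet:
    """Label events single / clustered / unclassified by nearest-neighbour ISI."""
    params = params or DetectionParams()
    t = pwaves.times
    n = t.size
    labels = np.full(n, "unclassified", dtype=object)
    if n == 1:
        labels[0] = "single"
    elif n > 1:
        gaps = np.diff(t)
        nn = np.empty(n)
        nn[0] = gaps[0]
        nn[-1] = gaps[-1]
        if n > 2:
            nn[1:-1] = np.minimum(gaps[:-1], gaps[1:])
        nn_ms = nn * 1000.0
        labels[nn_ms < params.cluster_max_isi_ms] = "clustered"
        labels[nn_ms > params.single_min_isi_ms] = "single"
    df = pwaves.df.copy()
    df["label"] = labels.astype(str)
    return PWaveSet(df)


def isi_percentiles(
    pwave_sets: list[PWaveSet], q: tuple[float, float] = (10.0, 15.0)
) -> tuple[float, float]:
    """Pooled consecutive-interval percentiles (s); re-derives the 520/780 ms
    defaults on new data the way they were originally obtained."""
    intervals = np.concatenate(
        [np.diff(ps.times) for ps in pwave_sets if len(ps) > 1]
    )
    if intervals.size == 0:
        raise ValueError("no inter-event intervals available")
    lo, hi = np.percentile(intervals, q)
    return float(lo), float(hi)


def rate_timecourse(
    pwaves: PWaveSet, hyp: Hypnogram, bin_s: float | None = None
) -> np.ndarray:
    """Events/s in each hypnogram-aligned time bin (default one per epoch)."""
    bin_s = bin_s or hyp.epoch_s
    n_bins = int(round(hyp.duration_s / bin_s))
    counts, _ = np.histogram(pwaves.times, bins=n_bins, range=(0, n_bins * bin_s))
    return counts / bin_s


def rate_by_state(pwaves: PWaveSet, hyp: Hypnogram) -> dict[str, float]:
    """Mean per-state event rate: epoch counts / epoch length, averaged over
    that state's epochs."""
    rates = rate_timecourse(pwaves, hyp)
    out = {}
    for s in STATES:
        mask = hyp.epoch_mask(s)[: rates.size]
        out[s] = float(rates[mask].mean()) if mask.any() else 0.0
    return out


def match_events(
    detected_s: np.ndarray, truth_s: np.ndarray, tol_s: float = 0.01
) -> dict:
    """Greedy one-to-one matching of detected to true event times.

    Returns sensitivity, false-discovery rate, and the RMS timing error (s)
    of the matched pairs.
    """
    detected_s = np.sort(np.asarray(detected_s, float))
    truth_s = np.sort(np.asarray(truth_s, float))
    used = np.zeros(detected_s.size, dtype=bool)
    errors = []
    hits = 0
    for t in truth_s:
        lo = np.searchsorted(detected_s, t - tol_s)
        hi = np.searchsorted(detected_s, t + tol_s)
        cands = [j for j in range(lo, hi) if not used[j]]
        if cands:
            j = min(cands, key=lambda j: abs(detected_s[j] - t))
            used[j] = True
            hits += 1
            errors.append(detected_s[j] - t)
    sens = hits / truth_s.size if truth_s.size else np.nan
    fdr = 1.0 - used.sum() / detected_s.size if detected_s.size else np.nan
    rms = float(np.sqrt(np.mean(np.square(errors)))) if errors else np.nan
    return {"sensitivity": float(sens), "fdr": float(fdr), "rms_error_s": rms,
            "n_detected": int(detected_s.size), "n_true": int(truth_s.size)}


def classify_laser_outcomes(
    pwaves: PWaveSet,
    laser: LaserProtocol,
    window_ms: float = 100.0,
) -> tuple[pd.DataFrame, PWaveSet]:
    """Per-pulse success bookkeeping and per-event provenance.

    A pulse is *successful* iff at least one event falls in the half-open
    window ``(onset, onset + window_ms]`` (an event exactly at onset is not
    attributed to the pulse). The first in-window event is laser-triggered
    with ``latency_ms`` = time from pulse onset to its negative peak; all
    other events are spontaneous.
    """
    t = pwaves.times
    w = window_ms / 1000.0
    provenance = np.full(len(pwaves), "spontaneous", dtype=object)
    latency = np.full(len(pwaves), np.nan)
    success = np.zeros(len(laser), dtype=bool)
    first_latency = np.full(len(laser), np.nan)
    for k, onset in enumerate(laser.onsets_s):
        lo = np.searchsorted(t, onset, side="right")
        hi = np.searchsorted(t, onset + w, side="right")
        if hi > lo:
            success[k] = True
            j = lo
            provenance[j] = "laser_triggered"
            latency[j] = (t[j] - onset) * 1000.0
            first_latency[k] = latency[j]
    pulses = pd.DataFrame(
        {
            "onset_s": laser.onsets_s,
            "duration_ms": laser.durations_ms,
            "success": success,
            "latency_ms": first_latency,
        }
    )
    df = pwaves.df.copy()
    df["provenance"] = provenance.astype(str)
    df["latency_ms"] = latency
    return pulses, PWaveSet(df)


def shuffle_pulses(
    laser: LaserProtocol,
    hyp: Hypnogram,
    jitter_s: float = 5.0,
    restrict: str = "R",
    seed: int | np.random.Generator = 0,
) -> LaserProtocol:
    """Surrogate pulses: each pulse in the restricted state jittered by
    U(-jitter, +jitter) s, re-clipped to episodes of that state."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    episodes = hyp.episodes_of(restrict)
    in_state = hyp.state_at(laser.onsets_s) == restrict
    onsets = laser.onsets_s[in_state].copy()
    durs = laser.durations_ms[in_state].copy()
    if jitter_s > 0:
        for j in range(onsets.size):
            t0 = onsets[j]
            ep = next(
                (e for e in episodes if e.onset_s <= t0 < e.offset_s), None
            )
            t = t0 + rng.uniform(-jitter_s, jitter_s)
            if ep is not None:
                t = min(max(t, ep.onset_s), ep.offset_s - durs[j] / 1000.0)
            onsets[j] = t
    order = np.argsort(onsets)
    onsets, durs = onsets[order], durs[order]
    # drop overlaps introduced by jittering
    keep = np.ones(onsets.size, dtype=bool)
    for j in range(1, onsets.size):
        prev = np.flatnonzero(keep[:j])
        if prev.size and onsets[j] <= onsets[prev[-1]] + durs[prev[-1]] / 1000.0:
            keep[j] = False
    return LaserProtocol(onsets[keep], durs[keep], mode=laser.mode + "_shuffled")
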