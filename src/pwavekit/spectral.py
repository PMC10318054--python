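"""Spectrogram / PSD estimation, normalization schemes and band powers.

Three window presets are used throughout the package:

``hypnogram``
    5 s Hann windows, 50% overlap -> 2.5 s steps (one column per hypnogram
    epoch); used for sleep scoring and minutes-scale state analyses.
``event``
    2 s windows, 95% overlap -> 100 ms steps; used for spectral summaries
    around millisecond-scale events (P-waves, brief laser pulses).
``field``
    2 s windows, 80% overlap -> 400 ms steps; the grid of the spectrotemporal
    (spectral-field) regression.

Two normalization schemes:

* ``recording_mean`` — each frequency row divided by its own mean over the
  whole recording (relative power; used for minutes-scale plots and the
  spectral-field model).
* ``local_window`` — each frequency row divided by its mean within a short
  event-centred slab only (used for event-triggered summaries).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

PRESETS: dict[str, tuple[float, float]] = {
    "hypnogram": (5.0, 0.5),
    "event": (2.0, 0.95),
    "field": (2.0, 0.8),
}

#: EEG frequency bands (Hz, inclusive bounds on bin centers).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (6.0, 10.0),
    "sigma": (11.0, 15.0),
    "beta": (15.5, 20.0),
    "gamma": (55.0, 99.0),
    "high_theta": (8.0, 15.0),
}


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ValueError("band requires lo < hi")


def band(name: str) -> BandDefinition:
    lo, hi = BANDS[name]
    return BandDefinition(name, lo, hi)


@dataclass
class Spectrogram:
    """Power (freq x time), window-center times, and normalization tag."""

    power: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    window_s: float
    step_s: float
    normalization: str = "raw"

    def band_rows(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        """Indices of frequency bins whose centers fall in [lo, hi]."""
        return np.flatnonzero((self.freqs_hz >= lo_hz) & (self.freqs_hz <= hi_hz))

    def slab(self, center_s: float, span_s: float) -> "Spectrogram | None":
        """Extract a time slab of total width ``span_s`` centred on ``center_s``.

        Returns ``None`` when the slab would be truncated by a recording edge
        (truncated slabs are dropped from averages rather than zero-padded).
        """
        n_half = int(round(span_s / 2.0 / self.step_s))
        ic = int(np.argmin(np.abs(self.times_s - center_s)))
        if ic - n_half < 0 or ic + n_half >= self.times_s.size:
            return None
        sel = np.arange(ic - n_half, ic + n_half + 1)
        # lags on the canonical grid (events need not be grid-aligned)
        lags = np.arange(-n_half, n_half + 1) * self.step_s
        return Spectrogram(
            self.power[:, sel],
            self.freqs_hz,
            lags,
            self.window_s,
            self.step_s,
            self.normalization,
        )


def spectrogram(
    x: np.ndarray,
    rate_hz: float,
    window_s: float | None = None,
    overlap_frac: float | None = None,
    preset: str | None = None,
) -> Spectrogram:
    """Consecutive Hann-windowed FFT power estimates (one-sided density).

    Each window is mean-subtracted before tapering; no further detrending.
    ``times_s`` are window centers.
    """
    if preset is not None:
        window_s, overlap_frac = PRESETS[preset]
    if window_s is None or overlap_frac is None:
        raise ValueError("give window_s and overlap_frac, or a preset name")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    x = np.asarray(x, dtype=np.float64)
    nper = int(round(window_s * rate_hz))
    if nper < 2:
        raise ValueError("window too short: fewer than 2 samples")
    if x.size < nper:
        raise ValueError("signal shorter than one window")
    step = max(1, int(round(nper * (1 - overlap_frac))))
    freqs, times, power = sps.spectrogram(
        x,
        fs=rate_hz,
        window="hann",
        nperseg=nper,
        noverlap=nper - step,
        detrend="constant",
        scaling="density",
        mode="psd",
    )
    return Spectrogram(power, freqs, times, window_s, step / rate_hz)


def welch_psd(
    x: np.ndarray, rate_hz: float, window_s: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD: Hann window, half-overlapping ``window_s`` segments."""
    x = np.asarray(x, dtype=np.float64)
    nper = int(round(window_s * rate_hz))
    if x.size < nper:
        raise ValueError("signal shorter than one window")
    freqs, power = sps.welch(
        x, fs=rate_hz, window="hann", nperseg=nper, noverlap=nper // 2,
        detrend="constant", scaling="density",
    )
    return freqs, power


def normalize_recording_mean(spec: Spectrogram) -> Spectrogram:
    """Divide each frequency row by its mean power across the recording.

    Idempotent; row means of the output equal 1.
    """
    mean = spec.power.mean(axis=1, keepdims=True)
    mean[mean == 0] = 1.0
    return replace(spec, power=spec.power / mean, normalization="recording_mean")


def normalize_local(spec: Spectrogram) -> Spectrogram:
    """Divide each frequency row by its mean within this (event-centred) slab."""
    mean = spec.power.mean(axis=1, keepdims=True)
    mean[mean == 0] = 1.0
    return replace(spec, power=spec.power / mean, normalization="local_window")


def band_power(spec: Spectrogram, b: BandDefinition) -> np.ndarray:
    """Per-window mean (not sum) power over in-band frequency bins."""
    rows = spec.band_rows(b.lo_hz, b.hi_hz)
    if rows.size == 0:
        raise ValueError(f"no frequency bins inside band {b.name} [{b.lo_hz}, {b.hi_hz}] Hz")
    return spec.power[rows].mean(axis=0)


def emg_amplitude(
    emg: np.ndarray, rate_hz: float, mode: str = "state"
) -> tuple[np.ndarray, np.ndarray]:
    """EMG amplitude time series: sqrt of band-integrated spectrogram power.

    ``state`` mode integrates 10-500 Hz on the hypnogram preset (2.5 s steps);
    ``twitch`` mode integrates 10-100 Hz on 100 ms half-overlapping windows
    (50 ms steps). Integration is sum(power)*df. Returns (times_s, amplitude).
    """
    if mode == "state":
        spec = spectrogram(emg, rate_hz, preset="hypnogram")
        lo, hi = 10.0, 500.0
    elif mode == "twitch":
        spec = spectrogram(emg, rate_hz, window_s=0.1, overlap_frac=0.5)
        lo, hi = 10.0, 100.0
    else:
        raise ValueError(f"unknown EMG mode {mode!r}")
    if mode == "twitch" and rate_hz < 2 * hi:
        raise ValueError("sampling rate below Nyquist for the 10-100 Hz band")
    rows = spec.band_rows(lo, min(hi, rate_hz / 2))
    df = spec.freqs_hz[1] - spec.freqs_hz[0]
    integrated = spec.power[rows].sum(axis=0) * df
    return spec.times_s, np.sqrt(integrated)


def theta_delta_ratio(spec: Spectrogram) -> np.ndarray:
    """Per-window theta (6-10 Hz) over delta (0.5-4 Hz) mean power."""
    th = band_power(spec, band("theta"))
    de = band_power(spec, band("delta"))
    return th / np.maximum(de, np.finfo(float).tiny)
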