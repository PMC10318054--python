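"""Core data model: recordings, hypnograms, event series and laser protocols.

Time convention: seconds from recording start (float64). Hypnogram epoch ``k``
covers the half-open interval ``[k*epoch_s, (k+1)*epoch_s)``; an event exactly
on a boundary belongs to the later epoch (``floor(t / epoch_s)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Canonical brain-state labels: wake, NREM sleep, intermediate sleep, REM sleep.
STATES = ("W", "N", "I", "R")

#: Default hypnogram epoch length in seconds.
EPOCH_S = 2.5


@dataclass
class Channel:
    """One named 1-D signal with its sampling rate and units."""

    data: np.ndarray
    rate_hz: float
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 1:
            raise ValueError("channel data must be 1-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("channel data must be finite")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.data.size / self.rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.data.size) / self.rate_hz


@dataclass
class Recording:
    """A multichannel session: any subset of the canonical channel names.

    Canonical names: ``eeg_parietal``, ``eeg_frontal``, ``emg``,
    ``lfp_primary``, ``lfp_reference``, ``photo_465``, ``photo_405``.
    Channels may have different sampling rates (e.g. 1000 Hz electrophysiology,
    1500 Hz photometry).
    """

    channels: dict[str, Channel]
    start_time: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.channels) == 0:
            raise ValueError("recording must contain at least one channel")

    def __getitem__(self, name: str) -> Channel:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"recording has no channel {name!r}; available: "
                f"{sorted(self.channels)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def require(self, *names: str) -> list[Channel]:
        """Return the named channels, raising a helpful error on any miss."""
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(
                f"analysis requires channel(s) {missing}; recording has "
                f"{sorted(self.channels)}"
            )
        return [self.channels[n] for n in names]

    @property
    def duration_s(self) -> float:
        return max(c.duration_s for c in self.channels.values())


@dataclass(frozen=True)
class Episode:
    """A maximal run of one state: (state, onset s, duration s)."""

    state: str
    onset_s: float
    duration_s: float

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


class Hypnogram:
    """Per-epoch state labels at fixed epoch resolution (default 2.5 s)."""

    def __init__(self, labels: Sequence[str], epoch_s: float = EPOCH_S):
        labels = np.asarray(labels, dtype="U1")
        bad = set(labels.tolist()) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")
        if epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        self.labels = labels
        self.epoch_s = float(epoch_s)

    def __len__(self) -> int:
        return self.labels.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Hypnogram)
            and self.epoch_s == other.epoch_s
            and np.array_equal(self.labels, other.labels)
        )

    @property
    def duration_s(self) -> float:
        return len(self) * self.epoch_s

    @property
    def episodes(self) -> list[Episode]:
        return episodes_from_labels(self.labels, self.epoch_s)

    def episodes_of(self, state: str, min_duration_s: float = 0.0) -> list[Episode]:
        return [
            e
            for e in self.episodes
            if e.state == state and e.duration_s >= min_duration_s
        ]

    def state_at(self, t_s: float | np.ndarray) -> np.ndarray:
        """State label(s) at time(s) ``t_s``; boundary events go to the later epoch."""
        idx = np.floor(np.asarray(t_s, dtype=float) / self.epoch_s).astype(int)
        idx = np.clip(idx, 0, len(self) - 1)
        return self.labels[idx]

    def fractions(self) -> dict[str, float]:
        return {s: float(np.mean(self.labels == s)) for s in STATES}

    def epoch_mask(self, state: str) -> np.ndarray:
        return self.labels == state

    def sample_mask(self, state: str, rate_hz: float, n_samples: int) -> np.ndarray:
        """Boolean per-sample mask for a state at an arbitrary sampling rate."""
        t = np.arange(n_samples) / rate_hz
        return self.state_at(t) == state


def episodes_from_labels(labels: Sequence[str], epoch_s: float = EPOCH_S) -> list[Episode]:
    """Segment a label sequence into maximal same-state runs."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [
        Episode(str(labels[s]), s * epoch_s, (e - s) * epoch_s)
        for s, e in zip(starts, ends)
    ]


def labels_from_episodes(episodes: Sequence[Episode], epoch_s: float = EPOCH_S) -> np.ndarray:
    """Inverse of :func:`episodes_from_labels`."""
    out: list[str] = []
    for ep in episodes:
        n = int(round(ep.duration_s / epoch_s))
        out.extend([ep.state] * n)
    return np.asarray(out, dtype="U1")


@dataclass
class EventSeries:
    """Point events (strictly increasing times in s) with optional attributes."""

    times: np.ndarray
    attrs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        for k, v in self.attrs.items():
            v = np.asarray(v)
            if v.shape[0] != self.times.size:
                raise ValueError(f"attribute {k!r} length mismatch")
            self.attrs[k] = v

    def __len__(self) -> int:
        return self.times.size


@dataclass
class LaserProtocol:
    """Laser pulses (onsets s, durations ms), optionally grouped into trains.

    ``episode_on`` maps closed-loop REM episode onsets (s) to their laser-on /
    laser-off designation.
    """

    onsets_s: np.ndarray
    durations_ms: np.ndarray
    mode: str = "brief_pulse"
    train_ids: np.ndarray | None = None
    episode_on: dict[float, bool] | None = None

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=np.float64)
        self.durations_ms = np.asarray(self.durations_ms, dtype=np.float64)
        if self.onsets_s.shape != self.durations_ms.shape:
            raise ValueError("onsets and durations must have equal length")
        if self.onsets_s.size > 1:
            gaps = np.diff(self.onsets_s) - self.durations_ms[:-1] / 1000.0
            if np.any(np.diff(self.onsets_s) <= 0) or np.any(gaps < 0):
                raise ValueError("pulses must be sorted and non-overlapping")
        if self.train_ids is not None:
            self.train_ids = np.asarray(self.train_ids)
            if self.train_ids.shape != self.onsets_s.shape:
                raise ValueError("train_ids length mismatch")

    def __len__(self) -> int:
        return self.onsets_s.size
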