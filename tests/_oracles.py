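"""Shared independent reference implementations used by the test suite."""

import numpy as np

from pwavekit.pwave import DetectionParams


def brute_force_detect(trace, rate_hz, params=None):
    """Explicit sample-scan reference detector (slow loops, no vectorization)."""
    params = params or DetectionParams()
    mean = trace.mean()
    sd = trace.std()
    thr = mean - params.threshold_k * sd
    runs = []
    start = None
    for i, v in enumerate(trace):
        if v < thr and start is None:
            start = i
        elif v >= thr and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, trace.size))
    gap = int(params.merge_gap_ms / 1000.0 * rate_hz)
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    out = []
    for s, e in merged:
        i_min = s
        for j in range(s, e):
            if trace[j] < trace[i_min]:
                i_min = j
        depth = mean - trace[i_min]
        level = mean - depth / 2.0
        i = i_min
        while i > 0 and trace[i] < level:
            i -= 1
        if trace[i] >= level and i < i_min:
            left = i + (level - trace[i]) / (trace[i + 1] - trace[i])
        else:
            left = float(i)
        j = i_min
        while j < trace.size - 1 and trace[j] < level:
            j += 1
        if trace[j] >= level and j > i_min:
            right = j - (level - trace[j]) / (trace[j - 1] - trace[j])
        else:
            right = float(j)
        width_ms = (right - left) / rate_hz * 1000.0
        if depth <= params.amp_cap_mv and width_ms <= params.halfwidth_cap_ms:
            out.append(i_min / rate_hz)
    return np.asarray(out)


def biphasic(rate_hz, depth_mv, halfwidth_ms):
    """A simple biphasic test waveform with the given trough depth/half-width."""
    s = halfwidth_ms / 1000.0 / 2.355
    t = np.arange(-4 * s, 8 * s, 1 / rate_hz)
    w = -np.exp(-(t**2) / (2 * s**2)) + 0.3 * np.exp(
        -((t - 2 * s) ** 2) / (2 * (1.5 * s) ** 2)
    )
    return w / abs(w.min()) * depth_mv
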