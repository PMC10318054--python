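"""Fiber-photometry dF/F, event-triggered statistics, and the spectral field.

dF/F recipe: both channels are low-pass filtered at 2 Hz (4th-order
Butterworth, zero-phase), the calcium-independent 405 nm channel is fitted to
the 465 nm channel by linear regression, and dF/F = (465 - fit) / fit. The
regression absorbs shared photobleaching, motion artifacts, and any common
multiplicative gain.

The spectral field is a linear kernel H(f, lag) mapping the recording-mean
normalized EEG spectrogram onto the neural response:

    r_hat(t_j) = r0 + sum_l sum_i E(f_i, t_{j+l}) * H(f_i, t_l)

with frequencies 0.5-25 Hz and lags -4..+4 s on a 400 ms grid. H is the
ridge-regression solution; the penalty weight lambda is chosen by k-fold
cross-validation over contiguous time blocks (respecting autocorrelation),
then the model is refit on all masked (REM) bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .core import Episode, Hypnogram
from .pwave import PWaveSet
from .spectral import Spectrogram


@dataclass
class PhotometryTrace:
    dff: np.ndarray
    rate_hz: float
    fit_slope: float
    fit_intercept: float
    lowpass_hz: float = 2.0

    def times(self) -> np.ndarray:
        return np.arange(self.dff.size) / self.rate_hz


def compute_dff(
    sig465: np.ndarray,
    sig405: np.ndarray,
    rate_hz: float,
    lowpass_hz: float = 2.0,
) -> PhotometryTrace:
    """Isosbestic-corrected dF/F from the 465/405 nm pair."""
    sig465 = np.asarray(sig465, float)
    sig405 = np.asarray(sig405, float)
    if sig465.shape != sig405.shape:
        raise ValueError("465 and 405 channels must have equal length")
    sos = sps.butter(4, lowpass_hz, btype="lowpass", fs=rate_hz, output="sos")
    f465 = sps.sosfiltfilt(sos, sig465)
    f405 = sps.sosfiltfilt(sos, sig405)
    slope, intercept = np.polyfit(f405, f465, 1)
    fit = slope * f405 + intercept
    if np.abs(fit).min() < 1e-3 * np.abs(fit).mean():
        raise ValueError(
            "linear fit of the 405 channel approaches zero; dF/F undefined "
            "(check channel scaling / bleaching model)"
        )
    dff = (f465 - fit) / fit
    return PhotometryTrace(dff, rate_hz, float(slope), float(intercept))


def event_triggered(
    dff: np.ndarray,
    rate_hz: float,
    event_times_s: np.ndarray,
    window_s: tuple[float, float] = (-10.0, 10.0),
    z_score: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-event dF/F windows aligned at t=0.

    Events whose window would cross a recording edge are dropped. Returns
    (matrix [events x samples], time axis, mean trace). With ``z_score`` each
    row is z-scored within its own collected window.
    """
    dff = np.asarray(dff, float)
    pre = int(round(-window_s[0] * rate_hz))
    post = int(round(window_s[1] * rate_hz))
    rows = []
    for te in np.asarray(event_times_s, float):
        i = int(round(te * rate_hz))
        if i - pre < 0 or i + post > dff.size:
            continue
        rows.append(dff[i - pre : i + post])
    if not rows:
        n = pre + post
        t = (np.arange(n) - pre) / rate_hz
        return np.empty((0, n)), t, np.full(n, np.nan)
    mat = np.asarray(rows)
    if z_score:
        mu = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        mat = (mat - mu) / sd
    t = (np.arange(mat.shape[1]) - pre) / rate_hz
    return mat, t, mat.mean(axis=0)


def consecutive_bin_test(
    event_matrix: np.ndarray,
    times_s: np.ndarray,
    baseline_window_s: tuple[float, float],
    bin_s: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Consecutive paired t-tests of post-baseline bins against the baseline.

    Each unit's (event's / subject's) dF/F is averaged inside the baseline
    window and inside every subsequent non-overlapping ``bin_s`` bin; each bin
    is compared with the baseline by a paired t-test, Bonferroni-corrected by
    the number of bins tested. Returns per-bin onset/offset, t, p, and the
    corrected significance decision.
    """
    rate = 1.0 / (times_s[1] - times_s[0])
    b0 = np.searchsorted(times_s, baseline_window_s[0])
    b1 = np.searchsorted(times_s, baseline_window_s[1])
    if b1 <= b0:
        raise ValueError("empty baseline window")
    baseline = event_matrix[:, b0:b1].mean(axis=1)
    nbin = int(round(bin_s * rate))
    start = b1
    rows = []
    while start + nbin <= event_matrix.shape[1]:
        rows.append((times_s[start], event_matrix[:, start : start + nbin].mean(axis=1)))
        start += nbin
    k = len(rows)
    out = []
    for t0, vals in rows:
        t_stat, p = stats.ttest_rel(vals, baseline)
        out.append(
            {
                "bin_start_s": t0,
                "bin_end_s": t0 + bin_s,
                "mean_diff": float(np.mean(vals - baseline)),
                "t": float(t_stat),
                "p": float(p),
                "significant": bool(p < alpha / max(k, 1)),
            }
        )
    return pd.DataFrame(out)


def crosscorr_dff_pwaves(
    dff: np.ndarray,
    rate_hz: float,
    pwaves: PWaveSet | np.ndarray,
    rem_episodes: list[Episode],
    max_lag_s: float = 1.0,
    bin_s: float = 0.005,
    min_episode_s: float = 30.0,
    return_episodes: bool = False,
):
    """Per-episode cross-correlation of dF/F with the binary P-wave train.

    The event train is discretized in 5 ms bins; dF/F is resampled onto the
    same grid. For each qualifying REM episode, the full linear
    cross-correlation is computed and divided by the number of events in the
    sequence; lags in [-max_lag, +max_lag] are retained (negative lag = dF/F
    leads) and averaged across episodes. Returns (lags_s, mean trace).
    """
    times = pwaves.times if isinstance(pwaves, PWaveSet) else np.asarray(pwaves, float)
    grid_hz = 1.0 / bin_s
    n_lags = int(round(max_lag_s / bin_s))
    lags = np.arange(-n_lags, n_lags + 1) * bin_s
    per_episode = []
    for ep in rem_episodes:
        if ep.duration_s < min_episode_s:
            continue
        n_bins = int(round(ep.duration_s / bin_s))
        ev = times[(times >= ep.onset_s) & (times < ep.offset_s)] - ep.onset_s
        if ev.size == 0:
            continue
        train = np.zeros(n_bins)
        idx = np.minimum((ev / bin_s).astype(int), n_bins - 1)
        np.add.at(train, idx, 1.0)
        # resample the (already 2 Hz low-passed) dF/F onto the 5 ms grid
        i0 = int(round(ep.onset_s * rate_hz))
        i1 = int(round(ep.offset_s * rate_hz))
        seg = np.asarray(dff[i0:i1], float)
        t_grid = (np.arange(n_bins) + 0.5) * bin_s
        sig = np.interp(t_grid, np.arange(seg.size) / rate_hz, seg)
        # full cross-correlation; index so that C[k] = sum_t sig(t + k) train(t)
        full = np.correlate(sig, train, mode="full")
        center = sig.size - 1  # lag 0
        sel = np.arange(center - n_lags, center + n_lags + 1)
        valid = (sel >= 0) & (sel < full.size)
        cc = np.full(lags.size, np.nan)
        cc[valid] = full[sel[valid]] / ev.size
        per_episode.append(cc)
    if not per_episode:
        import warnings

        warnings.warn("no qualifying REM episode for cross-correlation")
        empty = np.full(lags.size, np.nan)
        return (lags, empty, np.empty((0, lags.size))) if return_episodes else (lags, empty)
    mat = np.asarray(per_episode)
    mean = np.nanmean(mat, axis=0)
    return (lags, mean, mat) if return_episodes else (lags, mean)


@dataclass
class SpectralField:
    """Kernel H(f, lag) with offset r0, chosen lambda, and CV performance."""

    H: np.ndarray  # (n_freq, 2*n_lag + 1)
    r0: float
    freqs_hz: np.ndarray
    lags_s: np.ndarray
    lambda_: float
    cv_r2: np.ndarray  # per-fold test R^2 at the chosen lambda

    @property
    def n_lags(self) -> int:
        return (self.H.shape[1] - 1) // 2


def _lagged_design(E: np.ndarray, n_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Design rows X[j] = E[:, j-n_lag : j+n_lag+1] flattened, for all j with
    full lag context. Returns (X, valid time indices)."""
    n_f, n_t = E.shape
    valid = np.arange(n_lag, n_t - n_lag)
    X = np.empty((valid.size, n_f * (2 * n_lag + 1)))
    for c, l in enumerate(range(-n_lag, n_lag + 1)):
        X[:, c * n_f : (c + 1) * n_f] = E[:, valid + l].T
    return X, valid


def _ridge_path(X, y, lambdas):
    """Ridge solutions for every lambda from one eigendecomposition of X'X.

    X and y must already be centred. Returns (n_lambda, n_param) coefficients.
    """
    xtx = X.T @ X
    xty = X.T @ y
    vals, vecs = np.linalg.eigh(xtx)
    proj = vecs.T @ xty
    coefs = np.empty((len(lambdas), X.shape[1]))
    for i, lam in enumerate(lambdas):
        coefs[i] = vecs @ (proj / (vals + lam))
    return coefs


def fit_spectral_field(
    spec: Spectrogram,
    response: np.ndarray,
    mask: np.ndarray | None = None,
    n_lag: int = 10,
    freq_lo_hz: float = 0.5,
    freq_hi_hz: float = 25.0,
    lambdas: np.ndarray | None = None,
    folds: int = 5,
) -> SpectralField:
    """Estimate the spectral field by cross-validated ridge regression.

    ``spec`` must be recording-mean normalized on the field grid (400 ms);
    ``response`` is the neural trace downsampled to the same grid; ``mask``
    selects the time bins entering the fit (typically REM). Lags span
    ``-n_lag .. +n_lag`` grid steps. Folds are contiguous blocks of the
    masked bins.
    """
    if spec.normalization != "recording_mean":
        raise ValueError("spectrogram must be recording_mean normalized")
    response = np.asarray(response, float)
    if response.size != spec.power.shape[1]:
        raise ValueError("response length must match the spectrogram time axis")
    rows = spec.band_rows(freq_lo_hz, freq_hi_hz)
    E = spec.power[rows]
    freqs = spec.freqs_hz[rows]
    X_all, valid = _lagged_design(E, n_lag)
    y_all = response[valid]
    if mask is not None:
        keep = np.asarray(mask, bool)[valid]
        X_all, y_all = X_all[keep], y_all[keep]
    n, p = X_all.shape
    if lambdas is None:
        lambdas = np.logspace(-3, 4, 12)
    lambdas = np.asarray(lambdas, float)
    if n <= p and np.all(lambdas <= 0):
        raise np.linalg.LinAlgError(
            "fewer masked bins than parameters with lambda = 0; "
            "use a positive ridge penalty"
        )

    # contiguous-block folds over the masked bins
    edges = np.linspace(0, n, folds + 1).astype(int)
    cv_scores = np.zeros((len(lambdas), folds))
    for f in range(folds):
        te = np.zeros(n, bool)
        te[edges[f] : edges[f + 1]] = True
        Xtr, ytr = X_all[~te], y_all[~te]
        Xte, yte = X_all[te], y_all[te]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        coefs = _ridge_path(Xtr - xm, ytr - ym, lambdas)
        pred = (Xte - xm) @ coefs.T + ym
        ss_res = ((yte[:, None] - pred) ** 2).sum(axis=0)
        ss_tot = ((yte - yte.mean()) ** 2).sum()
        cv_scores[:, f] = 1.0 - ss_res / max(ss_tot, np.finfo(float).tiny)
    best = int(np.argmax(cv_scores.mean(axis=1)))
    lam = float(lambdas[best])

    xm, ym = X_all.mean(axis=0), y_all.mean()
    coef = _ridge_path(X_all - xm, y_all - ym, [lam])[0]
    r0 = float(ym - xm @ coef)
    n_f = freqs.size
    H = coef.reshape(2 * n_lag + 1, n_f).T
    lags = np.arange(-n_lag, n_lag + 1) * spec.step_s
    return SpectralField(H, r0, freqs, lags, lam, cv_r2=cv_scores[best])


def predict_response(field: SpectralField, spec: Spectrogram) -> tuple[np.ndarray, np.ndarray]:
    """r_hat(t_j) = r0 + sum_l sum_i E(f_i, t_{j+l}) H(f_i, t_l).

    Edge bins lacking full lag context are dropped. Returns (valid time
    indices into the spectrogram grid, predicted series).
    """
    rows = spec.band_rows(field.freqs_hz[0], field.freqs_hz[-1])
    E = spec.power[rows]
    if E.shape[0] != field.H.shape[0]:
        raise ValueError("spectrogram frequency axis does not match the field")
    X, valid = _lagged_design(E, field.n_lags)
    coef = field.H.T.reshape(-1)
    return valid, field.r0 + X @ coef


def downsample_to_grid(
    x: np.ndarray, rate_hz: float, grid_times_s: np.ndarray, window_s: float
) -> np.ndarray:
    """Average a fast series inside each grid window (for the field grid)."""
    x = np.asarray(x, float)
    out = np.empty(grid_times_s.size)
    half = window_s / 2.0
    for k, tc in enumerate(grid_times_s):
        i0 = max(0, int(round((tc - half) * rate_hz)))
        i1 = min(x.size, int(round((tc + half) * rate_hz)))
        out[k] = x[i0:i1].mean() if i1 > i0 else np.nan
    return out
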