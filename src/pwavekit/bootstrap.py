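"""Hierarchical bootstrap over mice and episodes, with shuffled-label nulls.

The resampling scheme mirrors nested experimental structure: mice are drawn
with replacement, then within each drawn mouse the per-condition observations
(episode durations, or per-trial P-wave frequencies) are drawn with
replacement — ``m_on`` and ``m_off`` separately — and the across-mice mean of
per-mouse condition differences forms one bootstrap iterate. 10,000 iterates
give the sampling distribution, its mean, and the equal-tail 95% CI.

The shuffled-designation null reassigns condition labels within each mouse
(preserving the per-condition counts) before bootstrapping, estimating the
difference expected if the condition had no effect.

Two distributions are compared with the equal-tail bootstrap p-value on the
paired per-iteration differences, with the (r+1)/(n+1) add-one correction so
p is never exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class HierarchicalSample:
    """Per-mouse observations under two conditions.

    ``data`` maps mouse id -> {condition -> 1-D array of observations}.
    Every mouse must have at least one observation per condition.
    """

    data: dict[str, dict[str, np.ndarray]]
    conditions: tuple[str, str] = ("on", "off")

    def __post_init__(self) -> None:
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions required")
        for mouse, d in self.data.items():
            for c in self.conditions:
                arr = np.asarray(d.get(c, []), dtype=float)
                if arr.size == 0:
                    raise ValueError(
                        f"mouse {mouse!r} has no observations in condition {c!r}"
                    )
                d[c] = arr

    @property
    def mice(self) -> list[str]:
        return list(self.data)

    def observed_diff(self) -> float:
        """Across-mice mean of per-mouse condition-mean differences."""
        a, b = self.conditions
        return float(
            np.mean([d[a].mean() - d[b].mean() for d in self.data.values()])
        )


@dataclass
class BootstrapResult:
    distribution: np.ndarray
    n_iter: int
    seed: int | None = None
    label: str = ""

    mean: float = field(init=False)
    ci95: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.distribution = np.asarray(self.distribution, float)
        self.mean = float(self.distribution.mean())
        lo, hi = np.percentile(self.distribution, [2.5, 97.5])
        self.ci95 = (float(lo), float(hi))

    def ci_excludes(self, value: float = 0.0) -> bool:
        lo, hi = self.ci95
        return value < lo or value > hi

    def summary(self) -> dict:
        return {
            "label": self.label,
            "mean": self.mean,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "n_iter": self.n_iter,
        }


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def bootstrap_condition_diff(
    sample: HierarchicalSample,
    n_iter: int = 10_000,
    seed: int | np.random.Generator = 0,
    resample_episodes: bool = True,
) -> BootstrapResult:
    """Sampling distribution of the mean condition difference.

    Each iteration draws mice with replacement; for each drawn mouse the
    per-condition observations are resampled with replacement (sizes
    ``m_i,on`` / ``m_i,off``) and the per-mouse mean difference is averaged
    across the drawn mice. ``resample_episodes=False`` resamples mice only
    (used when the per-mouse values are already condition means).
    """
    rng = _rng(seed)
    a, b = sample.conditions
    mice = sample.mice
    n_mice = len(mice)
    arrs_a = [sample.data[m][a] for m in mice]
    arrs_b = [sample.data[m][b] for m in mice]

    mouse_idx = rng.integers(0, n_mice, size=(n_iter, n_mice))
    if not resample_episodes:
        per_mouse = np.array([x.mean() - y.mean() for x, y in zip(arrs_a, arrs_b)])
        dist = per_mouse[mouse_idx].mean(axis=1)
        return BootstrapResult(dist, n_iter, None)

    # per-mouse bootstrap means, drawn in bulk per source mouse, then gathered
    boot_a = np.empty((n_iter, n_mice))
    boot_b = np.empty((n_iter, n_mice))
    for m in range(n_mice):
        use = mouse_idx == m  # iterations x slots where mouse m was drawn
        k = int(use.sum())
        if k == 0:
            continue
        xa, xb = arrs_a[m], arrs_b[m]
        boot_a[use] = xa[rng.integers(0, xa.size, size=(k, xa.size))].mean(axis=1)
        boot_b[use] = xb[rng.integers(0, xb.size, size=(k, xb.size))].mean(axis=1)
    dist = (boot_a - boot_b).mean(axis=1)
    return BootstrapResult(dist, n_iter, None)


def shuffle_designations(
    sample: HierarchicalSample, seed: int | np.random.Generator = 0
) -> HierarchicalSample:
    """Randomly reassign condition labels within each mouse, preserving the
    per-condition counts exactly."""
    rng = _rng(seed)
    a, b = sample.conditions
    shuffled: dict[str, dict[str, np.ndarray]] = {}
    for mouse, d in sample.data.items():
        pooled = np.concatenate([d[a], d[b]])
        perm = rng.permutation(pooled.size)
        na = d[a].size
        shuffled[mouse] = {a: pooled[perm[:na]], b: pooled[perm[na:]]}
    return HierarchicalSample(shuffled, sample.conditions)


def shuffled_designation_null(
    sample: HierarchicalSample,
    n_iter: int = 10_000,
    seed: int | np.random.Generator = 0,
    resample_episodes: bool = True,
) -> BootstrapResult:
    """Bootstrap distribution after one random within-mouse label shuffle."""
    rng = _rng(seed)
    shuffled = shuffle_designations(sample, rng)
    res = bootstrap_condition_diff(
        shuffled, n_iter=n_iter, seed=rng, resample_episodes=resample_episodes
    )
    res.label = "shuffled"
    return res


def equal_tail_p(dist_a: np.ndarray, dist_b: np.ndarray | float = 0.0) -> float:
    """Equal-tail bootstrap p for the paired per-iteration difference.

    ``p = 2 * min(P(d <= 0), P(d >= 0))`` with the add-one correction
    ``(r + 1) / (n + 1)``, capped at 1. ``dist_b`` may be a scalar (test
    against a constant).
    """
    dist_a = np.asarray(dist_a, float)
    d = dist_a - np.asarray(dist_b, float)
    n = d.size
    lo = (np.sum(d <= 0) + 1) / (n + 1)
    hi = (np.sum(d >= 0) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))
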