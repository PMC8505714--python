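"""Grand-average MRCP curves, sample-wise contrasts, topographic frames.

Grand averages pool kept trials across subjects (not subject means) with a
t-based 95% confidence band. Condition contrasts are two-sided Wilcoxon
rank-sum (Mann–Whitney) tests per time sample — exact enumeration for small
groups, normal approximation with tie correction otherwise — reported
without multiple-comparison correction, matching how sample-wise MRCP
significance is conventionally displayed (a Bonferroni/FDR switch exists
but is off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import EpochSet, Montage, default_montage

__all__ = [
    "GrandAverage",
    "SignificanceTrack",
    "grand_average",
    "samplewise_ranksum",
    "topographic_frame",
    "concat_epochs",
]


@dataclass
class GrandAverage:
    """Pointwise mean waveform with its 95% CI, per channel."""

    condition: int
    mean: np.ndarray  # (n_channels, n_samples) μV
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_trials: int
    time_axis: np.ndarray
    channel_labels: list[str]

    def channel(self, label: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = self.channel_labels.index(label)
        return self.mean[i], self.ci_lower[i], self.ci_upper[i]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lab in enumerate(self.channel_labels):
            rows.append(
                pd.DataFrame(
                    {
                        "condition": self.condition,
                        "channel": lab,
                        "time_s": self.time_axis,
                        "mean": self.mean[i],
                        "lo": self.ci_lower[i],
                        "hi": self.ci_upper[i],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class SignificanceTrack:
    """Per-sample two-sided p-values for one channel contrast."""

    channel: str
    contrast: tuple[int, int]
    time_axis: np.ndarray
    p: np.ndarray
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.p < self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": self.channel,
                "condition_a": self.contrast[0],
                "condition_b": self.contrast[1],
                "time_s": self.time_axis,
                "p": self.p,
                "significant": self.significant,
            }
        )


def concat_epochs(epoch_sets: list[EpochSet]) -> EpochSet:
    """Pool kept trials of several subjects onto one epoch set."""
    if not epoch_sets:
        raise ValueError("nothing to concatenate")
    first = epoch_sets[0]
    kept = [e.kept() for e in epoch_sets]
    for e in kept:
        if e.channel_labels != first.channel_labels or len(e.time_axis) != len(
            first.time_axis
        ):
            raise ValueError("epoch sets are not alignable")
    return EpochSet(
        np.concatenate([e.data for e in kept]),
        first.time_axis,
        list(first.channel_labels),
        first.sampling_rate_hz,
        labels=np.concatenate([e.labels for e in kept]),
        subject_id="pooled",
    )


def grand_average(
    epochs: EpochSet, condition: int, alpha: float = 0.05
) -> GrandAverage:
    """Pointwise mean over kept trials of one condition, CI = mean ± t·SE."""
    if epochs.labels is None:
        raise ValueError("epochs carry no condition labels")
    sel = epochs.kept()
    m = sel.labels == condition
    n = int(m.sum())
    if n < 2:
        raise ValueError(f"need ≥ 2 kept trials for condition {condition}, got {n}")
    x = sel.data[m]
    mean = x.mean(axis=0)
    se = x.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    return GrandAverage(
        condition=condition,
        mean=mean,
        ci_lower=mean - tcrit * se,
        ci_upper=mean + tcrit * se,
        n_trials=n,
        time_axis=sel.time_axis,
        channel_labels=list(sel.channel_labels),
    )


def samplewise_ranksum(
    epochs_a: EpochSet,
    epochs_b: EpochSet,
    channel: str,
    contrast: tuple[int, int] = (0, 0),
    alpha: float = 0.05,
    exact_max_n: int = 20,
    min_trials: int = 5,
) -> SignificanceTrack:
    """Two-sided Mann–Whitney/Wilcoxon rank-sum per time sample.

    Exact enumeration when n_a + n_b ≤ ``exact_max_n`` and the sample has no
    ties; normal approximation with tie correction otherwise. A sample where
    all values coincide gets p = 1.
    """
    ia = epochs_a.channel_labels.index(channel)
    ib = epochs_b.channel_labels.index(channel)
    a = epochs_a.kept().data[:, ia, :]
    b = epochs_b.kept().data[:, ib, :]
    n_a, n_b = a.shape[0], b.shape[0]
    if min(n_a, n_b) < min_trials:
        raise ValueError(f"need at least {min_trials} trials per group")
    n_s = a.shape[1]
    p = np.ones(n_s)
    small = n_a + n_b <= exact_max_n
    for s in range(n_s):
        xa, xb = a[:, s], b[:, s]
        pooled = np.concatenate([xa, xb])
        if np.all(pooled == pooled[0]):
            p[s] = 1.0
            continue
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (small and not has_ties) else "asymptotic"
        p[s] = stats.mannwhitneyu(
            xa, xb, alternative="two-sided", method=method
        ).pvalue
    return SignificanceTrack(
        channel=channel,
        contrast=contrast,
        time_axis=epochs_a.time_axis,
        p=p,
        alpha=alpha,
    )


def topographic_frame(
    grand_averages: dict[int, GrandAverage],
    time_window: tuple[float, float],
    montage: Montage | None = None,
) -> pd.DataFrame:
    """Per-channel mean amplitude over a time window, with coordinates.

    Returns a tidy frame (condition, channel, x, y, amplitude) suitable for
    rendering a scalp map.
    """
    lo, hi = time_window
    if hi < lo:
        raise ValueError("empty time window")
    rows = []
    for cond, ga in grand_averages.items():
        mask = (ga.time_axis >= lo) & (ga.time_axis <= hi)
        if not mask.any():
            raise ValueError("time window outside the epoch")
        mont = montage or default_montage(ga.channel_labels)
        amps = ga.mean[:, mask].mean(axis=1)
        for lab, amp in zip(ga.channel_labels, amps):
            x, y = mont[lab]
            rows.append(dict(condition=cond, channel=lab, x=x, y=y, amplitude=amp))
    return pd.DataFrame(rows)
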