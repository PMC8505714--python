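"""Movement timing from auxiliary channels, and the duration statistics.

Reaction time (RT) is the delay from the "Go" cue to the first button
release; the per-subject *virtual movement onset* is the Go sample plus the
subject's mean RT over retained grasp trials (RT > 2 s trials are screened
out first). Grasp start and release come from threshold crossings of the
force-transducer trace; per-condition mean durations feed a one-way
repeated-measures ANOVA with Mauchly's sphericity test (Greenhouse–Geisser
correction applied only when sphericity is rejected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import EventTable

__all__ = [
    "BehavioralSummary",
    "RmAnovaResult",
    "compute_rt",
    "compute_virtual_onsets",
    "detect_grasp_interval",
    "behavioral_summary",
    "duration_anova",
]


@dataclass
class RmAnovaResult:
    f: float
    df: tuple[int, int]
    p: float
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    p_gg_corrected: float
    gg_applied: bool

    def to_dict(self) -> dict:
        return {
            "F": self.f,
            "df_num": self.df[0],
            "df_den": self.df[1],
            "p": self.p,
            "mauchly_w": self.mauchly_w,
            "mauchly_p": self.mauchly_p,
            "gg_epsilon": self.gg_epsilon,
            "p_gg_corrected": self.p_gg_corrected,
            "gg_applied": self.gg_applied,
        }


@dataclass
class BehavioralSummary:
    """Per-trial timing table plus subject-level aggregates."""

    trials: pd.DataFrame  # trial_id, condition, go_sample, rt_s, flag, ...
    mean_rt_s: float
    sd_rt_s: float

    def per_condition_duration(self) -> pd.Series:
        ok = self.trials["duration_s"].notna()
        return self.trials[ok].groupby("condition")["duration_s"].mean()

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)


def compute_rt(
    events: EventTable, sampling_rate_hz: float, no_movement_code: int = 6
) -> pd.DataFrame:
    """Per-trial RT table from the event stream.

    One row per trial (delimited by ``trial_start`` events), with the
    trial's condition, Go sample, first button release after Go, and
    ``rt_s``. No-movement trials get NaN RT (undefined); grasp trials with
    no release before the trial's end are flagged ``missing_release``.
    """
    starts = events.of_kind("trial_start").sample
    if len(starts) == 0:
        raise ValueError("event table holds no trial_start events")
    bounds = np.append(starts, np.iinfo(np.int64).max)
    gos = events.of_kind("go").sample
    conds = events.of_kind("condition_marker")
    releases = events.of_kind("button_release").sample

    rows = []
    for i in range(len(starts)):
        lo, hi = bounds[i], bounds[i + 1]
        go_in = gos[(gos >= lo) & (gos < hi)]
        cond_in = conds.code[(conds.sample >= lo) & (conds.sample < hi)]
        if len(go_in) != 1 or len(cond_in) != 1:
            raise ValueError(f"trial {i}: expected exactly one go and condition marker")
        go = int(go_in[0])
        cond = int(cond_in[0])
        rel = releases[(releases > go) & (releases < hi)]
        rt = np.nan
        flag = ""
        if cond != no_movement_code:
            if len(rel):
                rt = (int(rel[0]) - go) / sampling_rate_hz
            else:
                flag = "missing_release"
        rows.append(
            dict(trial_id=i, condition=cond, t0_sample=int(lo), go_sample=go,
                 rt_s=rt, flag=flag)
        )
    return pd.DataFrame(rows)


def compute_virtual_onsets(
    trials: pd.DataFrame,
    sampling_rate_hz: float,
    rt_threshold_s: float = 2.0,
) -> tuple[np.ndarray, float]:
    """Virtual movement onset per trial: Go sample + round(mean RT × fs).

    The mean RT pools all retained grasp trials (RT defined, not flagged,
    RT ≤ threshold) across conditions; the same offset applies to every
    trial, no-movement included. Returns (onset samples, mean RT in s).
    """
    rt = trials["rt_s"].to_numpy(dtype=float)
    ok = np.isfinite(rt) & (rt <= rt_threshold_s) & (rt >= 0)
    if "flag" in trials:
        ok &= trials["flag"].fillna("").eq("").to_numpy()
    if not ok.any():
        raise ValueError("no retained RTs for this subject")
    mean_rt = float(rt[ok].mean())
    offset = int(round(mean_rt * sampling_rate_hz))
    onsets = trials["go_sample"].to_numpy(dtype=np.int64) + offset
    return onsets, mean_rt


def detect_grasp_interval(
    force: np.ndarray,
    sampling_rate_hz: float,
    threshold_frac: float = 0.1,
) -> tuple[float, float, float] | None:
    """Threshold crossings of one trial's force trace.

    ``force`` is the trace from movement onset to trial end (≥ 0). Grasp
    start is the first upward crossing of ``threshold_frac × max``, release
    the last downward crossing; returns (grasp_start_s, release_s,
    duration_s) relative to the trace start, or None when no supra-threshold
    episode exists (trial flagged by the caller).
    """
    force = np.asarray(force, dtype=float)
    if force.size == 0:
        return None
    if force.min() < 0:
        raise ValueError("force trace must be non-negative")
    peak = force.max()
    if peak <= 0:
        return None
    above = force >= threshold_frac * peak
    idx = np.flatnonzero(above)
    g0, g1 = idx[0], idx[-1]
    fs = sampling_rate_hz
    return g0 / fs, g1 / fs, (g1 - g0) / fs


def behavioral_summary(
    trials: pd.DataFrame,
    onsets: np.ndarray,
    force: np.ndarray,
    trial_end_samples: np.ndarray,
    sampling_rate_hz: float,
    no_movement_code: int = 6,
    threshold_frac: float = 0.1,
) -> BehavioralSummary:
    """Assemble the per-trial behavioral table for one subject."""
    fs = sampling_rate_hz
    out = trials.copy()
    out["virtual_onset_sample"] = np.asarray(onsets, dtype=np.int64)
    grasp_start = np.full(len(out), np.nan)
    release = np.full(len(out), np.nan)
    duration = np.full(len(out), np.nan)
    flags = out.get("flag", pd.Series([""] * len(out))).fillna("").tolist()
    for i, row in out.iterrows():
        if row["condition"] == no_movement_code:
            continue
        a = int(row["virtual_onset_sample"])
        b = int(trial_end_samples[i])
        res = detect_grasp_interval(force[a:b], fs, threshold_frac)
        if res is None:
            flags[i] = (flags[i] + ";no_force_episode").strip(";")
            continue
        grasp_start[i], release[i], duration[i] = res
    out["grasp_start_s"] = grasp_start
    out["release_s"] = release
    out["duration_s"] = duration
    out["flag"] = flags
    rts = out["rt_s"].to_numpy(dtype=float)
    ok = np.isfinite(rts)
    return BehavioralSummary(
        trials=out,
        mean_rt_s=float(rts[ok].mean()) if ok.any() else np.nan,
        sd_rt_s=float(rts[ok].std(ddof=1)) if ok.sum() > 1 else np.nan,
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------


def duration_anova(table: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on an n_subjects × k table.

    F = MS_condition / MS_(condition × subject) with df (k−1, (k−1)(n−1)).
    Mauchly's W is computed from the covariance of the within-subject data
    under an orthonormal contrast basis, with the standard chi-square
    approximation; the Greenhouse–Geisser corrected p is reported and
    applied (as the headline p) only when Mauchly's test rejects sphericity
    at 0.05.
    """
    y = np.asarray(table, dtype=float)
    if y.ndim != 2:
        raise ValueError("table must be n_subjects × k")
    n, k = y.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 conditions")
    if not np.all(np.isfinite(y)):
        raise ValueError("missing cells in the table")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    resid = y - subj_means[:, None] - cond_means[None, :] + grand
    ss_err = (resid**2).sum()
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    f = ms_cond / ms_err if ms_err > 0 else 0.0
    p = float(stats.f.sf(f, df1, df2)) if ms_err > 0 else 1.0

    # Mauchly's sphericity test on the contrast-space covariance
    S = np.cov(y, rowvar=False)  # k × k across subjects
    C = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1].T  # orthonormal contrasts
    A = C @ S @ C.T
    eig = np.linalg.eigvalsh(A)
    eig = np.clip(eig, 1e-300, None)
    w = float(np.exp(np.sum(np.log(eig)) - (k - 1) * np.log(eig.mean())))
    d = 1.0 - (2 * (k - 1) ** 2 + (k - 1) + 2) / (6.0 * (k - 1) * (n - 1))
    chi2 = -(n - 1) * d * np.log(max(w, 1e-300))
    df_m = k * (k - 1) // 2 - 1
    mauchly_p = float(stats.chi2.sf(chi2, df_m)) if df_m > 0 else 1.0

    tr_a = float(np.trace(A))
    eps = tr_a**2 / ((k - 1) * float(np.trace(A @ A))) if tr_a > 0 else 1.0
    eps = min(max(eps, 1.0 / (k - 1)), 1.0)
    p_gg = float(stats.f.sf(f, df1 * eps, df2 * eps)) if ms_err > 0 else 1.0
    gg_applied = mauchly_p < 0.05
    return RmAnovaResult(
        f=float(f),
        df=(df1, df2),
        p=p_gg if gg_applied else p,
        mauchly_w=w,
        mauchly_p=mauchly_p,
        gg_epsilon=float(eps),
        p_gg_corrected=p_gg,
        gg_applied=gg_applied,
    )
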