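"""Trial- and component-level artifact handling.

Four screens feed one :class:`RejectionReport`:

* reaction-time screening (RT strictly greater than 2 s);
* amplitude thresholding (any retained channel/sample beyond ±200 μV);
* statistical outlier screening — per channel, a trial's joint probability
  (mean negative log of the channel's pooled 50-bin empirical amplitude
  density over the trial's samples) and its sample kurtosis, each z-scored
  across trials within channel; a trial falls if any channel's |z| exceeds
  3 for either statistic;
* ICA-based ocular cleanup: components are estimated on a 1-Hz high-passed
  copy of the data, flagged when their time course correlates with an EOG
  reference or their scalp weights concentrate on frontal channels, zeroed,
  and the rest projected back.

The ICA estimation itself is delegated to FastICA; the flagging and
reconstruction contracts are this module's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA

from .io import ContinuousRecording, EpochSet
from .preprocess import HIGHPASS_ICA, apply_filter

__all__ = [
    "RejectionReport",
    "ICADecomposition",
    "IcaConvergenceError",
    "reject_high_rt",
    "reject_by_amplitude",
    "reject_statistical_outliers",
    "remove_ocular_components",
]

REASONS = ("rt_gt_2s", "amplitude", "joint_probability", "kurtosis", "channel_noise")


class IcaConvergenceError(RuntimeError):
    """FastICA hit its iteration cap; carries the iteration diagnostics."""

    def __init__(self, n_iter: int, max_iter: int, tol: float):
        self.n_iter, self.max_iter, self.tol = n_iter, max_iter, tol
        super().__init__(
            f"ICA did not converge: {n_iter}/{max_iter} iterations at tol={tol}"
        )


@dataclass
class RejectionReport:
    """Per-trial kept flags with their reasons, plus summary accessors."""

    table: pd.DataFrame  # columns: trial_id, kept, reasons

    def __post_init__(self) -> None:
        required = {"trial_id", "kept", "reasons"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"report table needs columns {sorted(required)}")

    @classmethod
    def from_reasons(cls, trial_ids, reasons_per_trial) -> "RejectionReport":
        rows = [
            dict(
                trial_id=tid,
                kept=not rs,
                reasons=";".join(sorted(set(rs))),
            )
            for tid, rs in zip(trial_ids, reasons_per_trial)
        ]
        return cls(pd.DataFrame(rows, columns=["trial_id", "kept", "reasons"]))

    @property
    def kept_mask(self) -> np.ndarray:
        return self.table["kept"].to_numpy(dtype=bool)

    @property
    def n_total(self) -> int:
        return len(self.table)

    @property
    def n_rejected(self) -> int:
        return int((~self.kept_mask).sum())

    @property
    def fraction_rejected(self) -> float:
        return self.n_rejected / self.n_total if self.n_total else 0.0

    def merge(self, other: "RejectionReport") -> "RejectionReport":
        """Combine two screens over the same trials (union of reasons)."""
        a = self.table.set_index("trial_id")
        b = other.table.set_index("trial_id")
        if not a.index.equals(b.index):
            raise ValueError("reports cover different trials")
        reasons = [
            ";".join(sorted(set(filter(None, (ra.split(";") + rb.split(";"))))))
            for ra, rb in zip(a["reasons"], b["reasons"])
        ]
        out = pd.DataFrame(
            {
                "trial_id": a.index.to_numpy(),
                "kept": [not r for r in reasons],
                "reasons": reasons,
            }
        )
        return RejectionReport(out)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class ICADecomposition:
    """Unmixing/mixing pair with per-component ocular flags and scores."""

    unmixing: np.ndarray  # (components, channels)
    mixing: np.ndarray  # (channels, components)
    channel_labels: list[str]
    eye_flags: np.ndarray  # bool per component
    corr_scores: np.ndarray
    frontal_scores: np.ndarray
    n_iter: int = 0

    def flags_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(len(self.eye_flags)),
                "eye_flag": self.eye_flags,
                "eog_corr": self.corr_scores,
                "frontal_fraction": self.frontal_scores,
            }
        )


# ---------------------------------------------------------------------------
# trial-level screens
# ---------------------------------------------------------------------------


def reject_high_rt(
    trial_ids: np.ndarray,
    rt_s: np.ndarray,
    threshold_s: float = 2.0,
) -> RejectionReport:
    """Discard trials whose RT strictly exceeds the threshold.

    ``rt_s`` is NaN for no-movement trials, which pass vacuously; an RT of
    exactly the threshold is kept. Negative RTs are impossible behavior and
    are flagged as a channel_noise-style data error.
    """
    reasons: list[list[str]] = []
    for rt in np.asarray(rt_s, dtype=float):
        if np.isnan(rt):
            reasons.append([])
        elif rt < 0:
            reasons.append(["channel_noise"])
        elif rt > threshold_s:
            reasons.append(["rt_gt_2s"])
        else:
            reasons.append([])
    return RejectionReport.from_reasons(trial_ids, reasons)


def reject_by_amplitude(epochs: EpochSet, limit_uv: float = 200.0) -> RejectionReport:
    """Reject a trial iff any channel/sample strictly exceeds ±limit μV."""
    over = np.abs(epochs.data) > limit_uv
    bad = over.any(axis=(1, 2))
    ids = np.arange(epochs.n_trials)
    return RejectionReport.from_reasons(
        ids, [["amplitude"] if b else [] for b in bad]
    )


def _joint_probability(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-trial mean negative log empirical probability for one channel.

    ``values`` is (n_trials, n_samples); the density is a histogram over the
    channel's pooled samples, so every observed sample has positive mass.
    """
    flat = values.ravel()
    counts, edges = np.histogram(flat, bins=n_bins)
    p = counts / flat.size
    idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, n_bins - 1)
    return -np.log(p[idx]).mean(axis=1)


def _zscore_trials(stat: np.ndarray) -> np.ndarray:
    """z across trials within channel; constant columns give z = 0."""
    mu = stat.mean(axis=0, keepdims=True)
    sd = stat.std(axis=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (stat - mu) / sd


def reject_statistical_outliers(
    epochs: EpochSet,
    z_limit: float = 3.0,
    n_bins: int = 50,
    min_trials: int = 10,
) -> tuple[RejectionReport, pd.DataFrame]:
    """Joint-probability and kurtosis outlier screening.

    Returns the report and a per-trial statistics frame (the maximum |z|
    over channels for each statistic). With fewer than ``min_trials``
    trials the histogram estimate is unstable; a warning is raised and
    everything is kept.
    """
    n_tr, n_ch, _ = epochs.data.shape
    ids = np.arange(n_tr)
    if n_tr < min_trials:
        warnings.warn(
            f"only {n_tr} trials (<{min_trials}); statistical screening skipped",
            stacklevel=2,
        )
        report = RejectionReport.from_reasons(ids, [[] for _ in ids])
        return report, pd.DataFrame({"trial_id": ids})

    jp = np.empty((n_tr, n_ch))
    for c in range(n_ch):
        jp[:, c] = _joint_probability(epochs.data[:, c, :], n_bins)
    kurt = stats.kurtosis(epochs.data, axis=2, fisher=True)  # (n_tr, n_ch)

    z_jp = _zscore_trials(jp)
    z_k = _zscore_trials(kurt)
    reasons = []
    for i in range(n_tr):
        r = []
        if np.abs(z_jp[i]).max() > z_limit:
            r.append("joint_probability")
        if np.abs(z_k[i]).max() > z_limit:
            r.append("kurtosis")
        reasons.append(r)
    detail = pd.DataFrame(
        {
            "trial_id": ids,
            "max_abs_z_joint_probability": np.abs(z_jp).max(axis=1),
            "max_abs_z_kurtosis": np.abs(z_k).max(axis=1),
        }
    )
    return RejectionReport.from_reasons(ids, reasons), detail


# ---------------------------------------------------------------------------
# ICA ocular cleanup
# ---------------------------------------------------------------------------


def _frontal_indices(labels: list[str]) -> list[int]:
    fp_af = [i for i, la in enumerate(labels) if la.upper().startswith(("FP", "AF"))]
    if fp_af:
        return fp_af
    # fronto-ocular rows already excluded: fall back to the F row
    return [
        i
        for i, la in enumerate(labels)
        if la.upper().startswith("F") and not la.upper().startswith("FC")
    ]


def remove_ocular_components(
    recording: ContinuousRecording,
    eog_reference: np.ndarray,
    corr_threshold: float = 0.7,
    frontal_threshold: float = 0.6,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 5e-3,
    fit_decim: int | None = None,
    strict_convergence: bool = True,
) -> tuple[ContinuousRecording, ICADecomposition]:
    """Zero eye-related independent components and project the rest back.

    The decomposition is fit on a 1-Hz high-passed copy (optionally
    decimated for speed — ICA spatial filters need no high sampling rate)
    and applied to the analysis data. A component is flagged when
    |corr(component, EOG reference)| ≥ ``corr_threshold`` or when the
    frontal share of its absolute scalp weights is ≥ ``frontal_threshold``.
    With no flagged components the output equals the input exactly.
    """
    X = recording.data
    n_ch, n_samp = X.shape
    if n_samp < 2 * n_ch:
        raise ValueError("need at least 2× more samples than channels")
    if fit_decim is None:
        fit_decim = max(1, n_samp // 60_000)

    # decimate before the fit-only 1-Hz high-pass: spatial filters need
    # many samples, not a high sampling rate
    decim = recording.copy_with(
        data=recording.data[:, ::fit_decim],
        sampling_rate_hz=recording.sampling_rate_hz / fit_decim,
        aux={},
    )
    hp = apply_filter(decim, HIGHPASS_ICA).data
    ica = FastICA(
        n_components=n_ch,
        whiten="unit-variance",
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence handled explicitly below
        ica.fit(hp.T)
    if ica.n_iter_ >= max_iter:
        if strict_convergence:
            raise IcaConvergenceError(ica.n_iter_, max_iter, tol)
        warnings.warn(
            f"ICA stopped at the iteration cap ({max_iter}); proceeding",
            stacklevel=2,
        )

    unmixing = ica.components_  # (comp, ch)
    mixing = np.linalg.pinv(unmixing)  # (ch, comp)

    sources_fit = unmixing @ hp  # flag on the same data ICA saw
    ref = np.asarray(eog_reference, dtype=float)[::fit_decim]
    ref = ref - ref.mean()
    ref_sd = ref.std()
    corr = np.zeros(n_ch)
    if ref_sd > 0:
        sc = sources_fit - sources_fit.mean(axis=1, keepdims=True)
        denom = sc.std(axis=1) * ref_sd * sc.shape[1]
        nz = denom > 0
        corr[nz] = np.abs((sc @ ref))[nz] / denom[nz]

    fr_idx = _frontal_indices(recording.channel_labels)
    absw = np.abs(mixing)
    total = absw.sum(axis=0)
    total = np.where(total > 0, total, 1.0)
    frontal = absw[fr_idx].sum(axis=0) / total

    flags = (corr >= corr_threshold) | (frontal >= frontal_threshold)
    decomp = ICADecomposition(
        unmixing=unmixing,
        mixing=mixing,
        channel_labels=list(recording.channel_labels),
        eye_flags=flags,
        corr_scores=corr,
        frontal_scores=frontal,
        n_iter=int(ica.n_iter_),
    )
    if not flags.any():
        return recording.copy_with(data=X.copy()), decomp

    sources = unmixing @ X
    cleaned = X - mixing[:, flags] @ sources[flags]
    return recording.copy_with(data=cleaned), decomp
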