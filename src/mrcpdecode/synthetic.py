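"""Paradigm-faithful synthetic reach-and-grasp EEG.

Emulates the study design the pipeline targets: sessions of 60 cue-guided
trials (10 per condition in randomized order; conditions 1–5 are palmar,
pinch, push, twist and plug grasps, 6 is no-movement), 10-s trials with an
auditory target cue at 3 s and a "Go" cue at 5 s, a 40-channel fronto-
parietal 10–20 montage sampled at 1,000 Hz, a pressure button marking the
moment the hand leaves the start position, and a force transducer trace per
grasped device.

The EEG content is a movement-related cortical potential (MRCP) template —
a negative ramp starting ~0.5 s before movement onset that peaks at onset,
followed by a condition-dependent positive rebound (large near 1.2 s for the
push and plug grasps, weak within 0.2–0.5 s for the others) — projected
through a centro-medial spatial map (largest at Cz/FCz/C1, contralateral
dominant), summed with 1/f background noise, 50-Hz line interference,
stereotyped frontal blinks and occasional high-amplitude channel bursts so
that every rejection rule downstream has something to catch. Every trial's
true onset, behavior and injected artifacts are recorded in a ground-truth
table.

All randomness flows from a single integer seed; identical inputs give
bit-identical recordings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_EXCLUDED,
    MONTAGE_40,
    ContinuousRecording,
    EventTable,
    default_montage,
)

__all__ = [
    "ExperimentConfig",
    "MRCPTemplateSet",
    "NoiseAndArtifactModel",
    "BehaviorModel",
    "SyntheticSubjectRecording",
    "build_default_config",
    "generate_templates",
    "simulate_subject",
    "CONDITION_NAMES",
]

CONDITION_NAMES = {
    1: "palmar",
    2: "pinch",
    3: "push",
    4: "twist",
    5: "plug",
    6: "no-movement",
}
GRASP_CODES = (1, 2, 3, 4, 5)
NO_MOVEMENT = 6


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Paradigm timing and session structure."""

    n_sessions: int = 8
    trials_per_condition_per_session: int = 10
    trial_duration_s: float = 10.0
    cue_time_s: float = 3.0
    go_time_s: float = 5.0
    sampling_rate_hz: float = 1000.0
    montage: list[str] = field(default_factory=lambda: list(MONTAGE_40))
    condition_codes: list[int] = field(default_factory=lambda: list(range(1, 7)))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cue_time_s < self.go_time_s < self.trial_duration_s):
            raise ValueError("need 0 < cue < go < trial duration")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.condition_codes) != 6:
            raise ValueError("exactly 6 condition codes expected")

    @property
    def trials_per_session(self) -> int:
        return 6 * self.trials_per_condition_per_session

    @property
    def n_trials(self) -> int:
        return self.n_sessions * self.trials_per_session

    @property
    def trials_per_condition(self) -> int:
        return self.n_sessions * self.trials_per_condition_per_session

    @property
    def trial_samples(self) -> int:
        return int(round(self.trial_duration_s * self.sampling_rate_hz))


def build_default_config(**overrides) -> ExperimentConfig:
    """The study's default design: 8 sessions × 60 trials (10/condition),
    10-s trials, cue at 3 s, Go at 5 s, 1,000 Hz, 40 channels → 480 trials
    per subject, 80 per condition."""
    return ExperimentConfig(**overrides)


# ---------------------------------------------------------------------------
# MRCP templates
# ---------------------------------------------------------------------------

# Per-condition morphology parameters (μV and seconds). ramp_uv deepens the
# pre-onset negativity beyond the shared component; the rebound bump is the
# condition's post-onset signature. Push (3) and plug (5) carry the large
# late rebound near 1.2 s; the other grasps a weak early one.
_COND_PARAMS = {
    1: dict(ramp_uv=4.0, tau_s=0.40, rebound_uv=1.2, rebound_t_s=0.30, rebound_w_s=0.12),
    2: dict(ramp_uv=3.2, tau_s=0.50, rebound_uv=1.5, rebound_t_s=0.40, rebound_w_s=0.12),
    3: dict(ramp_uv=3.6, tau_s=0.45, rebound_uv=5.0, rebound_t_s=1.20, rebound_w_s=0.25),
    4: dict(ramp_uv=2.8, tau_s=0.55, rebound_uv=1.0, rebound_t_s=0.25, rebound_w_s=0.10),
    5: dict(ramp_uv=4.4, tau_s=0.35, rebound_uv=5.5, rebound_t_s=1.25, rebound_w_s=0.30),
    6: dict(ramp_uv=0.0, tau_s=0.40, rebound_uv=0.0, rebound_t_s=0.30, rebound_w_s=0.12),
}

#: Shared (condition-independent) negativity reached at onset, μV.
_SHARED_RAMP_UV = 3.0
#: The shared component returns to baseline this long after onset (s); the
#: no-movement waveform is flat from then on.
_SHARED_RECOVERY_S = 0.15


@dataclass
class MRCPTemplateSet:
    """Per-condition temporal waveforms × a spatial channel map.

    ``temporal`` is (6, n_times) μV on ``times`` (seconds relative to
    movement onset, covering [−1.5, 3.0]); ``spatial`` is a dimensionless
    per-channel gain. The full per-condition, per-channel template is the
    outer product, exposed by :meth:`array`.
    """

    times: np.ndarray
    temporal: np.ndarray  # (6, n_times), condition order 1..6
    spatial: np.ndarray  # (n_channels,)
    channel_labels: list[str]
    effect_scale: float = 1.0

    def array(self) -> np.ndarray:
        """(6, n_channels, n_times) template array."""
        return self.temporal[:, None, :] * self.spatial[None, :, None]

    def condition(self, code: int) -> np.ndarray:
        return self.temporal[code - 1][None, :] * self.spatial[:, None]


def spatial_map(channel_labels: list[str]) -> np.ndarray:
    """Centro-medial Gaussian gain centred between Cz, FCz and C1.

    Peaks over the sensorimotor midline with the contralateral (left,
    odd-numbered) side favoured over the ipsilateral side.
    """
    mont = default_montage(channel_labels)
    anchors = np.array([mont["Cz"], mont["FCz"], mont["C1"]])
    center = anchors.mean(axis=0)
    pos = np.array([mont[lab] for lab in channel_labels])
    d2 = ((pos - center) ** 2).sum(axis=1)
    return np.exp(-d2 / (2 * 0.5**2))


def generate_templates(
    config: ExperimentConfig, effect_scale: float = 1.0, seed: int | None = None
) -> MRCPTemplateSet:
    """Build the six condition templates on [−1.5, 3.0] s.

    ``effect_scale`` multiplies the whole evoked waveform: 0 is the null
    generator (no evoked signal at all, hence identical templates), 1 the
    default morphology. ``seed`` is accepted for interface symmetry; the
    templates are a deterministic function of the configuration.
    """
    if effect_scale < 0:
        raise ValueError("effect_scale must be non-negative")
    fs = config.sampling_rate_hz
    t = np.arange(int(round(-1.5 * fs)), int(round(3.0 * fs)) + 1) / fs

    # shared component: ramp from −0.5 s to −_SHARED_RAMP_UV at onset, then
    # linear return to baseline, flat afterwards
    shared = np.zeros_like(t)
    ramp = (t >= -0.5) & (t <= 0)
    shared[ramp] = -_SHARED_RAMP_UV * (t[ramp] + 0.5) / 0.5
    rec = (t > 0) & (t < _SHARED_RECOVERY_S)
    shared[rec] = -_SHARED_RAMP_UV * (1 - t[rec] / _SHARED_RECOVERY_S)

    temporal = np.zeros((6, len(t)))
    for code in range(1, 7):
        p = _COND_PARAMS[code]
        delta = np.zeros_like(t)
        delta[ramp] = -p["ramp_uv"] * (t[ramp] + 0.5) / 0.5
        post = t > 0
        delta[post] = -p["ramp_uv"] * np.exp(-t[post] / p["tau_s"])
        if p["rebound_uv"]:
            delta += p["rebound_uv"] * np.exp(
                -((t - p["rebound_t_s"]) ** 2) / (2 * p["rebound_w_s"] ** 2)
            )
        temporal[code - 1] = effect_scale * (shared + delta)

    return MRCPTemplateSet(
        times=t,
        temporal=temporal,
        spatial=spatial_map(config.montage),
        channel_labels=list(config.montage),
        effect_scale=effect_scale,
    )


# ---------------------------------------------------------------------------
# noise / artifact and behavior models
# ---------------------------------------------------------------------------


@dataclass
class NoiseAndArtifactModel:
    """Background and artifact generators.

    Background is 1/f^exponent-shaped noise normalized per channel to
    ``background_rms_uv`` (broadband). Blinks are stereotyped biphasic
    waveforms projected through a fixed frontal map at Poisson times;
    bursts are rare focal high-amplitude events placed inside the analysis
    epoch of randomly chosen trials to exercise the ±200 μV rule.
    """

    background_rms_uv: float = 12.0
    background_exponent: float = 1.0
    #: Gaussian scalp-distance kernel width mixing the per-channel noise
    #: sources, emulating volume conduction (neighboring electrodes in real
    #: low-frequency EEG correlate ~0.7–0.9); 0 gives independent channels.
    spatial_smoothing_radius: float = 0.9
    line_freq_hz: float = 50.0
    line_amp_uv: float = 1.5
    blink_rate_per_min: float = 8.0
    blink_amp_uv: float = 90.0
    burst_prob_per_trial: float = 0.05
    burst_amp_range_uv: tuple[float, float] = (260.0, 400.0)

    def __post_init__(self) -> None:
        for name in (
            "background_rms_uv",
            "line_amp_uv",
            "blink_rate_per_min",
            "blink_amp_uv",
            "burst_prob_per_trial",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def blink_spatial_profile(channel_labels: list[str]) -> np.ndarray:
    """Frontally concentrated blink projection (FP ≫ AF > F rows)."""
    w = np.zeros(len(channel_labels))
    for i, lab in enumerate(channel_labels):
        u = lab.upper()
        if u.startswith("FP"):
            w[i] = 1.0
        elif u.startswith("AF"):
            w[i] = 0.55
        elif u.startswith("FC"):
            w[i] = 0.08
        elif u.startswith("F"):
            w[i] = 0.25
        else:
            w[i] = 0.02
    return w


@dataclass
class BehaviorModel:
    """Reaction-time, grasp-timing and force-profile model.

    RT is a truncated normal (> 0); with probability ``slow_prob`` the trial
    is drawn from a slow component so that some RTs exceed the 2-s screening
    threshold. Grasp start (relative to movement onset) has a per-condition
    mean inside [0.98, 1.18] s; durations share one distribution across
    conditions (the null of the duration ANOVA) with a between-subject
    offset.
    """

    rt_mean_s: float = 0.5
    rt_sd_s: float = 0.15
    slow_prob: float = 0.05
    slow_rt_mean_s: float = 2.3
    slow_rt_sd_s: float = 0.3
    grasp_start_mean_s: tuple[float, ...] = (1.00, 1.05, 1.08, 1.12, 1.16)
    grasp_start_sd_s: float = 0.04
    duration_mean_s: float = 1.5
    duration_sd_between_s: float = 0.12
    duration_sd_within_s: float = 0.15
    condition_duration_offset_s: tuple[float, ...] = (0.0,) * 5
    force_rise_s: float = 0.1

    def __post_init__(self) -> None:
        lo = min(self.grasp_start_mean_s)
        hi = max(self.grasp_start_mean_s)
        if not (0.9 <= lo and hi <= 1.25):
            raise ValueError("grasp-start means must stay near [0.98, 1.18] s")
        if self.duration_mean_s <= 0:
            raise ValueError("durations must be positive")

    def draw_rt(self, rng: np.random.Generator) -> tuple[float, bool]:
        slow = bool(rng.random() < self.slow_prob)
        mean, sd = (
            (self.slow_rt_mean_s, self.slow_rt_sd_s)
            if slow
            else (self.rt_mean_s, self.rt_sd_s)
        )
        rt = rng.normal(mean, sd)
        while rt <= 0.05:
            rt = rng.normal(mean, sd)
        return float(rt), slow


@dataclass
class SyntheticSubjectRecording:
    """A full simulated subject: EEG, events, aux traces and ground truth."""

    recording: ContinuousRecording
    events: EventTable
    ground_truth: pd.DataFrame
    config: ExperimentConfig
    subject_id: str = "sim"

    def write_ground_truth(self, path: str | Path) -> None:
        self.ground_truth.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def one_over_f_noise(
    n_channels: int,
    n_samples: int,
    fs: float,
    rms_uv: float,
    exponent: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random-phase spectrally shaped noise, RMS-normalized per channel.

    Equivalent to a dense sum of sinusoids with 1/f^(exponent/2) amplitudes
    and uniform phases, realized via FFT shaping of white noise. Below
    0.1 Hz the spectrum rolls off quadratically, mimicking the second-order
    acquisition high-pass of an EEG amplifier (a recording chain passes no
    DC wander), which keeps trial-to-trial baseline offsets realistic.
    """
    if rms_uv == 0:
        return np.zeros((n_channels, n_samples))
    f_lo = 0.1
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], f_lo) ** (-exponent / 2.0)
    below = nz & (freqs < f_lo)
    shape[below] *= (freqs[below] / f_lo) ** 2
    out = np.empty((n_channels, n_samples))
    for c in range(n_channels):
        spec = np.fft.rfft(rng.standard_normal(n_samples))
        x = np.fft.irfft(spec * shape, n=n_samples)
        out[c] = x * (rms_uv / np.sqrt(np.mean(x**2)))
    return out


def _blink_waveform(fs: float) -> np.ndarray:
    t = np.arange(int(round(0.4 * fs))) / fs
    return np.exp(-((t - 0.10) ** 2) / (2 * 0.03**2)) - 0.35 * np.exp(
        -((t - 0.22) ** 2) / (2 * 0.05**2)
    )


def simulate_subject(
    config: ExperimentConfig,
    templates: MRCPTemplateSet,
    behavior: BehaviorModel | None = None,
    noise: NoiseAndArtifactModel | None = None,
    seed: int = 0,
    subject_id: str = "sim",
) -> SyntheticSubjectRecording:
    """Generate one subject's continuous recording, events and ground truth.

    Trials are laid back to back (``n_sessions × trials_per_session``
    segments of ``trial_duration_s``). Condition order is re-randomized per
    session. Each grasp trial's true movement onset is Go + drawn RT; the
    condition's MRCP template is inserted time-locked to it (no-movement
    trials receive their — possibly null — template at a drawn pseudo-onset
    so pre-cue anticipation is matched). The button aux channel emits a
    100-ms pulse at hand lift; the force aux channel a smoothed trapezoid
    from grasp start to release.
    """
    behavior = behavior if behavior is not None else BehaviorModel()
    noise = noise if noise is not None else NoiseAndArtifactModel()
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate_hz
    if templates.times[0] > -1.5 or templates.times[-1] < 2.5:
        raise ValueError("template time axis shorter than the analysis epoch")
    n_ch = len(config.montage)
    if len(templates.channel_labels) != n_ch:
        raise ValueError("template channel set does not match the montage")
    trial_len = config.trial_samples
    n_total = config.n_trials * trial_len

    data = one_over_f_noise(
        n_ch, n_total, fs, noise.background_rms_uv, noise.background_exponent, rng
    )
    if noise.background_rms_uv > 0 and noise.spatial_smoothing_radius > 0:
        # volume conduction: mix the independent sources through a scalp-
        # distance kernel, then restore the per-channel RMS
        mont = default_montage(config.montage)
        pos = np.array([mont[lab] for lab in config.montage])
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
        mix = np.exp(-d2 / (2 * noise.spatial_smoothing_radius**2))
        mix /= np.sqrt((mix**2).sum(axis=1, keepdims=True))
        data = mix @ data

    # line interference, common waveform with per-channel gain and phase
    if noise.line_amp_uv > 0:
        tt = np.arange(n_total) / fs
        gains = rng.uniform(0.5, 1.5, n_ch)
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        for c in range(n_ch):
            data[c] += (
                noise.line_amp_uv
                * gains[c]
                * np.sin(2 * np.pi * noise.line_freq_hz * tt + phases[c])
            )

    # blinks: Poisson events through the frontal map
    if noise.blink_rate_per_min > 0 and noise.blink_amp_uv > 0:
        minutes = n_total / fs / 60.0
        n_blinks = rng.poisson(noise.blink_rate_per_min * minutes)
        wf = _blink_waveform(fs) * noise.blink_amp_uv
        profile = blink_spatial_profile(config.montage)
        starts = np.sort(rng.integers(0, n_total - len(wf), n_blinks))
        for s0 in starts:
            data[:, s0 : s0 + len(wf)] += profile[:, None] * wf[None, :]

    # analysis channels eligible for focal bursts
    burst_channels = [
        i for i, lab in enumerate(config.montage) if lab not in DEFAULT_EXCLUDED
    ]
    burst_len = int(round(0.2 * fs))
    burst_shape = 0.5 * (1 - np.cos(2 * np.pi * np.arange(burst_len) / burst_len))

    tmpl_offset = int(round(templates.times[0] * fs))  # negative
    tmpl_len = templates.temporal.shape[1]
    cond_templates = templates.array()  # (6, n_ch, n_t)

    ev_sample: list[int] = []
    ev_kind: list[str] = []
    ev_code: list[int] = []
    gt_rows: list[dict] = []
    button = np.zeros(n_total)
    force = np.zeros(n_total)
    pulse_len = int(round(0.1 * fs))
    subj_duration_offset = rng.normal(0.0, behavior.duration_sd_between_s)

    trial_id = 0
    for sess in range(config.n_sessions):
        order = np.repeat(
            config.condition_codes, config.trials_per_condition_per_session
        )
        order = rng.permutation(order)
        for cond in order:
            cond = int(cond)
            t0 = trial_id * trial_len
            cue = t0 + int(round(config.cue_time_s * fs))
            go = t0 + int(round(config.go_time_s * fs))
            ev_sample += [t0, cue, cue, go]
            ev_kind += ["trial_start", "cue", "condition_marker", "go"]
            ev_code += [0, 0, cond, 0]

            rt, slow = behavior.draw_rt(rng)
            onset = go + int(round(rt * fs))
            is_grasp = cond != NO_MOVEMENT

            # insert the condition template time-locked to (pseudo-)onset
            a = onset + tmpl_offset
            b = a + tmpl_len
            src_lo = max(0, -a)
            src_hi = tmpl_len - max(0, b - n_total)
            if src_hi > src_lo:
                data[:, a + src_lo : a + src_hi] += cond_templates[
                    cond - 1, :, src_lo:src_hi
                ]

            grasp_start_s = np.nan
            duration_s = np.nan
            if is_grasp:
                ev_sample.append(onset)
                ev_kind.append("button_release")
                ev_code.append(0)
                button[onset : min(onset + pulse_len, n_total)] = 1.0
                grasp_start_s = rng.normal(
                    behavior.grasp_start_mean_s[cond - 1], behavior.grasp_start_sd_s
                )
                duration_s = -1.0
                while duration_s <= 0.2:
                    duration_s = rng.normal(
                        behavior.duration_mean_s
                        + behavior.condition_duration_offset_s[cond - 1]
                        + subj_duration_offset,
                        behavior.duration_sd_within_s,
                    )
                g0 = onset + int(round(grasp_start_s * fs))
                g1 = g0 + int(round(duration_s * fs))
                rise = int(round(behavior.force_rise_s * fs))
                prof_t = np.arange(g0, min(g1 + rise, t0 + trial_len))
                if len(prof_t):
                    ramp_up = np.clip((prof_t - g0) / max(rise, 1), 0, 1)
                    ramp_dn = np.clip((g1 - prof_t) / max(rise, 1) + 1, 0, 1)
                    force[prof_t] = np.maximum(
                        force[prof_t], np.minimum(ramp_up, ramp_dn)
                    )

            injected = False
            if noise.burst_prob_per_trial > 0 and rng.random() < noise.burst_prob_per_trial:
                # place the burst inside the analysis epoch around the onset
                ch = int(rng.choice(burst_channels))
                lo = go + int(round(-0.6 * fs))
                hi = go + int(round(2.6 * fs)) - burst_len
                s0 = int(rng.integers(lo, hi))
                amp = rng.uniform(*noise.burst_amp_range_uv) * rng.choice([-1.0, 1.0])
                data[ch, s0 : s0 + burst_len] += amp * burst_shape
                injected = True

            gt_rows.append(
                dict(
                    trial_id=trial_id,
                    session=sess,
                    trial_in_session=trial_id - sess * config.trials_per_session,
                    condition=cond,
                    t0_sample=t0,
                    cue_sample=cue,
                    go_sample=go,
                    true_onset_sample=onset if is_grasp else -1,
                    rt_s=rt if is_grasp else np.nan,
                    slow=slow if is_grasp else False,
                    grasp_start_s=grasp_start_s,
                    duration_s=duration_s,
                    injected_artifact=injected,
                )
            )
            trial_id += 1

    events = EventTable(
        np.array(ev_sample, dtype=np.int64),
        np.array(ev_kind, dtype=object),
        np.array(ev_code, dtype=np.int64),
    )
    recording = ContinuousRecording(
        data,
        list(config.montage),
        fs,
        aux={"button": button, "force": force},
    )
    gt = pd.DataFrame(gt_rows)
    return SyntheticSubjectRecording(recording, events, gt, config, subject_id)
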