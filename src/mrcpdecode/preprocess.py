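"""Deterministic signal conditioning.

Channel selection, IIR filtering (zero-phase Butterworth, notch),
common-average re-referencing and decimation. Operations are linear and
return new :class:`~mrcpdecode.io.ContinuousRecording` objects; auxiliary
channels are carried through untouched (except for decimation, which keeps
them sample-aligned).

Analysis order (enforced by the pipeline): artifact-marked trials removed →
ICA ocular cleanup → CAR → 0.3–3 Hz zero-phase band-pass → downsample to
100 Hz → epoch [−1.5, 2.5) s around the virtual movement onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import DEFAULT_EXCLUDED, ContinuousRecording, EventTable

__all__ = [
    "FilterSpec",
    "select_channels",
    "apply_filter",
    "common_average_reference",
    "downsample",
]


@dataclass(frozen=True)
class FilterSpec:
    """IIR filter description.

    ``order`` is the total pole count of the designed Butterworth filter
    (so a 4th-order band-pass is realized as ``scipy.signal.butter(2,
    band, 'bandpass')``). Zero-phase filters run forward and backward,
    doubling the effective magnitude order and cancelling group delay.
    """

    kind: str  # bandpass | lowpass | highpass | notch
    order: int
    band_hz: tuple[float, ...]
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "lowpass", "highpass", "notch"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "bandpass" and (self.order % 2 or len(self.band_hz) != 2):
            raise ValueError("bandpass needs an even order and two corners")

    def design_sos(self, fs: float) -> np.ndarray:
        nyq = fs / 2.0
        if any(not (0 < c < nyq) for c in self.band_hz):
            raise ValueError(
                f"corner(s) {self.band_hz} outside (0, {nyq}) at fs={fs}"
            )
        if self.kind == "bandpass":
            return signal.butter(
                self.order // 2, self.band_hz, btype="bandpass", fs=fs, output="sos"
            )
        if self.kind == "notch":
            b, a = signal.iirnotch(self.band_hz[0], Q=30.0, fs=fs)
            return signal.tf2sos(b, a)
        return signal.butter(
            self.order, self.band_hz[0], btype=self.kind.replace("pass", ""), fs=fs,
            output="sos",
        )


#: The study's analysis filters.
LOWPASS_40 = FilterSpec("lowpass", 4, (40.0,))
BANDPASS_MRCP = FilterSpec("bandpass", 4, (0.3, 3.0))
HIGHPASS_ICA = FilterSpec("highpass", 4, (1.0,))
#: Acquisition-side filters (amplifier description; off by default).
HARDWARE_BANDPASS = FilterSpec("bandpass", 4, (0.05, 100.0))
NOTCH_50 = FilterSpec("notch", 2, (50.0,))


def select_channels(
    recording: ContinuousRecording,
    exclude: list[str] | None = None,
    strict: bool = True,
) -> ContinuousRecording:
    """Drop the listed channels, preserving the order of the rest.

    The default exclusion list removes the seven fronto-ocular channels,
    taking the 40-channel montage to the 33 analysis channels.
    """
    exclude = DEFAULT_EXCLUDED if exclude is None else list(exclude)
    labels = recording.channel_labels
    unknown = [la for la in exclude if la not in labels]
    if unknown and strict:
        raise KeyError(f"channels not in recording: {unknown}")
    keep = [i for i, la in enumerate(labels) if la not in exclude]
    if not keep:
        raise ValueError("channel selection would remove every channel")
    return recording.copy_with(
        data=recording.data[keep], channel_labels=[labels[i] for i in keep]
    )


def apply_filter(
    recording: ContinuousRecording, spec: FilterSpec
) -> ContinuousRecording:
    """Filter every EEG channel; zero-phase runs filtfilt (odd padding)."""
    if not np.all(np.isfinite(recording.data)):
        raise ValueError("non-finite samples in recording")
    sos = spec.design_sos(recording.sampling_rate_hz)
    if spec.zero_phase:
        out = signal.sosfiltfilt(sos, recording.data, axis=1)
    else:
        out = signal.sosfilt(sos, recording.data, axis=1)
    return recording.copy_with(data=out)


def common_average_reference(recording: ContinuousRecording) -> ContinuousRecording:
    """Subtract the instantaneous mean across retained EEG channels."""
    if recording.n_channels < 2:
        raise ValueError("CAR needs at least two channels")
    out = recording.data - recording.data.mean(axis=0, keepdims=True)
    return recording.copy_with(data=out)


def downsample(
    recording: ContinuousRecording,
    target_hz: float,
    events: EventTable | None = None,
) -> ContinuousRecording | tuple[ContinuousRecording, EventTable]:
    """Decimate to ``target_hz`` by integer-factor sample picking.

    No extra anti-alias stage is applied: in the analysis chain the 40-Hz
    low-pass and the 0.3–3 Hz band-pass already band-limit the signal well
    below any new Nyquist. Event sample indices are rescaled by integer
    division when an event table is supplied.
    """
    fs = recording.sampling_rate_hz
    factor = fs / target_hz
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"{fs} Hz is not an integer multiple of {target_hz} Hz")
    factor = int(round(factor))
    n_keep = recording.n_samples // factor  # floor(n / factor) samples
    out = recording.copy_with(
        data=recording.data[:, ::factor][:, :n_keep],
        sampling_rate_hz=target_hz,
        aux={k: v[::factor][:n_keep] for k, v in recording.aux.items()},
    )
    if events is None:
        return out
    new_events = EventTable(events.sample // factor, events.kind, events.code)
    return out, new_events
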