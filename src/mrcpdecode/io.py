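"""Shared data model and file formats.

Holds the in-memory containers used across the pipeline — continuous
recordings, sample-indexed event tables, onset-locked epoch sets and the
scalp montage — together with readers/writers for the package's HDF5
container, an events CSV, and a BrainVision-dialect (.vhdr/.vmrk/.eeg)
triplet.

Conventions (fixed package-wide):

* amplitudes are microvolts (μV);
* time is 0-based sample-indexed; epoch windows are half-open
  ``[onset + round(lo*fs), onset + round(hi*fs))`` in samples, so a
  (−1.5, 2.5) s window at 100 Hz is exactly 400 samples and includes the
  t = 0 sample;
* BrainVision marker positions are 1-based on disk and converted on read.
"""

from __future__ import annotations

import configparser
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ContinuousRecording",
    "EventTable",
    "EpochSet",
    "Montage",
    "default_montage",
    "EVENT_KINDS",
    "read_brainvision",
    "write_brainvision",
    "read_container",
    "write_container",
    "epoch",
    "BrainVisionError",
]

EVENT_KINDS = (
    "trial_start",
    "cue",
    "go",
    "button_release",
    "condition_marker",
    "other",
)

# Stimulus codes used by the package's BrainVision dialect for non-condition
# events; condition markers keep their native codes 1..6.
_KIND_TO_STIM = {"trial_start": 20, "cue": 21, "go": 22, "button_release": 23}
_STIM_TO_KIND = {v: k for k, v in _KIND_TO_STIM.items()}


class BrainVisionError(ValueError):
    """Structural or dialect problem in a BrainVision triplet."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class EventTable:
    """Typed, sample-indexed markers, sorted by sample.

    ``code`` carries the condition number 1–6 for ``condition_marker`` rows
    and is 0 for rows where no code applies.
    """

    sample: np.ndarray  # int64, 0-based
    kind: np.ndarray  # str
    code: np.ndarray  # int64

    def __post_init__(self) -> None:
        self.sample = np.asarray(self.sample, dtype=np.int64)
        self.kind = np.asarray(self.kind, dtype=object)
        self.code = np.asarray(self.code, dtype=np.int64)
        if not (len(self.sample) == len(self.kind) == len(self.code)):
            raise ValueError("event columns must have equal length")
        order = np.argsort(self.sample, kind="stable")
        self.sample = self.sample[order]
        self.kind = self.kind[order]
        self.code = self.code[order]
        cond = self.code[self.kind == "condition_marker"]
        if cond.size and (cond.min() < 1 or cond.max() > 6):
            raise ValueError("condition codes must lie in 1..6")

    def __len__(self) -> int:
        return len(self.sample)

    def of_kind(self, kind: str) -> "EventTable":
        m = self.kind == kind
        return EventTable(self.sample[m], self.kind[m], self.code[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.sample, "kind": self.kind, "code": self.code}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTable":
        df = pd.read_csv(path)
        return cls(
            df["sample"].to_numpy(),
            df["kind"].to_numpy(dtype=object),
            df["code"].to_numpy(),
        )

    def __eq__(self, other: object) -> bool:  # type: ignore[override]
        if not isinstance(other, EventTable):
            return NotImplemented
        return (
            np.array_equal(self.sample, other.sample)
            and np.array_equal(self.kind, other.kind)
            and np.array_equal(self.code, other.code)
        )


@dataclass
class ContinuousRecording:
    """channels × samples EEG in μV plus sample-aligned auxiliary channels."""

    data: np.ndarray  # (n_channels, n_samples), μV
    channel_labels: list[str]
    sampling_rate_hz: float
    reference_label: str = "left mastoid"
    aux: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        self.channel_labels = list(self.channel_labels)
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} "
                "data rows"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        for name, tr in self.aux.items():
            if len(tr) != self.n_samples:
                raise ValueError(f"aux channel {name!r} not sample-aligned")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "ContinuousRecording":
        out = {
            "data": self.data,
            "channel_labels": list(self.channel_labels),
            "sampling_rate_hz": self.sampling_rate_hz,
            "reference_label": self.reference_label,
            "aux": dict(self.aux),
        }
        out.update(kw)
        return ContinuousRecording(**out)


@dataclass
class EpochSet:
    """trials × channels × samples, time-locked to per-trial onset (t = 0)."""

    data: np.ndarray  # (n_trials, n_channels, n_samples), μV
    time_axis: np.ndarray  # seconds relative to onset
    channel_labels: list[str]
    sampling_rate_hz: float
    labels: np.ndarray | None = None  # condition code per trial
    subject_id: str = ""
    kept_mask: np.ndarray | None = None
    reject_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials × channels × samples")
        self.time_axis = np.asarray(self.time_axis, dtype=np.float64)
        if len(self.time_axis) != self.data.shape[2]:
            raise ValueError("time axis length mismatch")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel label count mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.n_trials:
                raise ValueError("labels length must equal trial count")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.n_trials, dtype=bool)
            self.reject_reasons = [""] * self.n_trials
        else:
            self.kept_mask = np.asarray(self.kept_mask, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def kept(self) -> "EpochSet":
        """Sub-set to the trials whose kept flag is True."""
        m = self.kept_mask
        return EpochSet(
            self.data[m],
            self.time_axis,
            list(self.channel_labels),
            self.sampling_rate_hz,
            labels=None if self.labels is None else self.labels[m],
            subject_id=self.subject_id,
        )

    def time_index(self, t: float) -> int:
        """Index of the sample at time ``t`` (must be on the grid)."""
        idx = int(round((t - self.time_axis[0]) * self.sampling_rate_hz))
        if not (0 <= idx < len(self.time_axis)) or abs(
            self.time_axis[idx] - t
        ) > 0.5 / self.sampling_rate_hz:
            raise ValueError(f"time {t} s not on the epoch time axis")
        return idx


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------


@dataclass
class Montage:
    """Channel label → 2-D scalp coordinate on the unit head circle (+y nose)."""

    positions: dict[str, tuple[float, float]]

    def __contains__(self, label: str) -> bool:
        return label in self.positions

    def __getitem__(self, label: str) -> tuple[float, float]:
        return self.positions[label]

    def require(self, labels: list[str]) -> None:
        missing = [la for la in labels if la not in self.positions]
        if missing:
            raise KeyError(f"channels missing from montage: {missing}")


_ROW_Y = {
    "FP": 0.90,
    "AF": 0.70,
    "F": 0.50,
    "FC": 0.25,
    "C": 0.00,
    "CP": -0.25,
    "P": -0.50,
}
_NUM_X = {0: 0.0, 1: 0.20, 2: 0.20, 3: 0.45, 4: 0.45, 5: 0.70, 6: 0.70, 7: 0.90, 8: 0.90}

#: 40-electrode fronto-parietal subset of the 10–20/10-10 system used by the
#: acquisition montage. "AF5" is the montage's spelling of the 10-10 AF7 site
#: and both labels resolve to the same coordinate.
MONTAGE_40 = [
    "FP1", "FP2", "AF3", "AF4", "AF5", "F5", "F6",
    "F3", "F1", "Fz", "F2", "F4",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P5", "P3", "P1", "Pz", "P2", "P4", "P6",
]

#: Fronto-ocular channels excluded before analysis (highly blink-correlated).
DEFAULT_EXCLUDED = ["FP1", "FP2", "AF3", "AF4", "AF5", "F5", "F6"]


def _grid_position(label: str) -> tuple[float, float]:
    lab = label.upper()
    if lab in ("AF5", "AF7"):
        lab = "AF7"
    row = "".join(ch for ch in lab if ch.isalpha() and ch not in "Zz")
    row = {"FPZ": "FP", "AFZ": "AF"}.get(lab, row)
    if lab.endswith("Z"):
        num = 0
        row = lab[:-1]
    else:
        num = int("".join(ch for ch in lab if ch.isdigit()))
        row = "".join(ch for ch in lab if ch.isalpha())
    if row not in _ROW_Y:
        raise KeyError(f"unknown 10–20 row for channel {label!r}")
    x = _NUM_X[num]
    if num % 2 == 1:  # odd numbers sit over the left hemisphere
        x = -x
    return (x, _ROW_Y[row])


def default_montage(labels: list[str] | None = None) -> Montage:
    """Schematic 2-D 10–20 montage (rows by y, lateralization by x)."""
    labels = list(labels) if labels is not None else list(MONTAGE_40)
    pos = {lab: _grid_position(lab) for lab in labels}
    if "AF5" in pos:
        pos.setdefault("AF7", pos["AF5"])
    return Montage(pos)


# ---------------------------------------------------------------------------
# epoch extraction
# ---------------------------------------------------------------------------


def epoch(
    recording: ContinuousRecording,
    onsets: np.ndarray,
    window: tuple[float, float] = (-1.5, 2.5),
    labels: np.ndarray | None = None,
    subject_id: str = "",
) -> EpochSet:
    """Cut trials × channels × samples around per-trial onset samples.

    Half-open convention: samples ``[onset + round(lo*fs), onset +
    round(hi*fs))``. Trials whose window would leave the recording are kept
    in the set but flagged (``kept_mask`` False, reason ``edge``) with
    zero-filled data, never silently dropped.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must satisfy lo < hi")
    fs = recording.sampling_rate_hz
    onsets = np.asarray(onsets, dtype=np.int64)
    off_lo = int(round(lo * fs))
    off_hi = int(round(hi * fs))
    n_samp = off_hi - off_lo
    n_trials = len(onsets)
    data = np.zeros((n_trials, recording.n_channels, n_samp))
    kept = np.ones(n_trials, dtype=bool)
    reasons = [""] * n_trials
    for i, on in enumerate(onsets):
        a, b = on + off_lo, on + off_hi
        if a < 0 or b > recording.n_samples:
            kept[i] = False
            reasons[i] = "edge"
            continue
        data[i] = recording.data[:, a:b]
    time_axis = (np.arange(off_lo, off_hi)) / fs
    return EpochSet(
        data,
        time_axis,
        list(recording.channel_labels),
        fs,
        labels=labels,
        subject_id=subject_id,
        kept_mask=kept,
        reject_reasons=reasons,
    )


# ---------------------------------------------------------------------------
# internal HDF5 container
# ---------------------------------------------------------------------------


def write_container(
    path: str | Path, recording: ContinuousRecording, events: EventTable
) -> None:
    """Self-describing HDF5 container: data, labels, rate, aux, events."""
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg/data", data=recording.data)
        f["eeg"].attrs["sampling_rate_hz"] = recording.sampling_rate_hz
        f["eeg"].attrs["reference_label"] = recording.reference_label
        f.create_dataset(
            "eeg/channel_labels",
            data=np.array(recording.channel_labels, dtype="S16"),
        )
        for name, tr in recording.aux.items():
            f.create_dataset(f"aux/{name}", data=np.asarray(tr))
        f.create_dataset("events/sample", data=events.sample)
        f.create_dataset(
            "events/kind", data=np.array(events.kind, dtype="S24")
        )
        f.create_dataset("events/code", data=events.code)


def read_container(path: str | Path) -> tuple[ContinuousRecording, EventTable]:
    with h5py.File(path, "r") as f:
        data = f["eeg/data"][()]
        labels = [s.decode() for s in f["eeg/channel_labels"][()]]
        fs = float(f["eeg"].attrs["sampling_rate_hz"])
        ref = str(f["eeg"].attrs["reference_label"])
        aux = {}
        if "aux" in f:
            for name in f["aux"]:
                aux[name] = f[f"aux/{name}"][()]
        events = EventTable(
            f["events/sample"][()],
            np.array([s.decode() for s in f["events/kind"][()]], dtype=object),
            f["events/code"][()],
        )
    rec = ContinuousRecording(data, labels, fs, reference_label=ref, aux=aux)
    return rec, events


# ---------------------------------------------------------------------------
# BrainVision dialect (.vhdr / .vmrk / .eeg)
# ---------------------------------------------------------------------------


def write_brainvision(
    header_path: str | Path,
    recording: ContinuousRecording,
    events: EventTable,
    binary_format: str = "IEEE_FLOAT_32",
    resolution_uv: float = 0.1,
) -> None:
    """Write a BrainVision triplet (multiplexed binary, little-endian).

    ``binary_format`` is ``IEEE_FLOAT_32`` (values stored in μV) or
    ``INT_16`` (stored value × ``resolution_uv`` = μV).
    """
    header_path = Path(header_path)
    stem = header_path.stem
    eeg_path = header_path.with_suffix(".eeg")
    vmrk_path = header_path.with_suffix(".vmrk")
    n_ch = recording.n_channels
    interval_us = 1e6 / recording.sampling_rate_hz

    if binary_format == "IEEE_FLOAT_32":
        flat = recording.data.T.astype("<f4")
        res = 1.0
    elif binary_format == "INT_16":
        res = resolution_uv
        flat = np.round(recording.data.T / res).astype("<i2")
    else:
        raise BrainVisionError(f"unsupported binary format {binary_format!r}")
    flat.tofile(eeg_path)

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; written by mrcpdecode",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={interval_us:.6g}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(recording.channel_labels, start=1):
        lines.append(f"Ch{i}={lab},,{res:.6g},µV")
    header_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    for j in range(len(events)):
        kind = events.kind[j]
        if kind == "condition_marker":
            code = int(events.code[j])
        else:
            code = _KIND_TO_STIM.get(kind, 99)
        # marker positions are 1-based on disk
        mlines.append(
            f"Mk{j + 2}=Stimulus,S{code:>3d},{int(events.sample[j]) + 1},1,0"
        )
    vmrk_path.write_text("\n".join(mlines) + "\n", encoding="utf-8")


def _read_ini(path: Path) -> configparser.ConfigParser:
    cp = configparser.ConfigParser(
        strict=False, interpolation=None, comment_prefixes=(";",)
    )
    cp.optionxform = str  # keep key case (Ch1 vs ch1 matters for ordering)
    text = path.read_text(encoding="utf-8", errors="replace")
    # drop the non-INI banner line
    body = "\n".join(
        ln for ln in text.splitlines() if not ln.startswith("Brain Vision")
    )
    cp.read_file(_stdio.StringIO(body))
    return cp


def read_brainvision(header_path: str | Path) -> tuple[ContinuousRecording, EventTable]:
    """Read a BrainVision triplet into the package data model.

    Supports multiplexed binary data in IEEE float32 or int16 + per-channel
    resolution; anything else raises :class:`BrainVisionError`. Stimulus
    markers with codes 1–6 become condition markers, the package's dialect
    codes 20–23 map back to trial_start/cue/go/button_release, and unknown
    markers are preserved with kind ``other``.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    cp = _read_ini(header_path)
    common = cp["Common Infos"]
    data_file = header_path.parent / common["DataFile"]
    marker_file = header_path.parent / common.get("MarkerFile", "")
    if not data_file.exists():
        raise BrainVisionError(f"missing companion data file {data_file}")
    if common.get("DataFormat", "BINARY") != "BINARY":
        raise BrainVisionError("only BINARY DataFormat is supported")
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise BrainVisionError("only MULTIPLEXED orientation is supported")
    n_ch = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])

    fmt = cp["Binary Infos"]["BinaryFormat"]
    if fmt == "IEEE_FLOAT_32":
        dtype = np.dtype("<f4")
    elif fmt == "INT_16":
        dtype = np.dtype("<i2")
    else:
        raise BrainVisionError(f"unsupported binary format {fmt!r}")

    labels: list[str] = []
    resolutions: list[float] = []
    chinfo = cp["Channel Infos"]
    for i in range(1, n_ch + 1):
        if f"Ch{i}" not in chinfo:
            raise BrainVisionError(f"header missing Ch{i} entry")
        parts = chinfo[f"Ch{i}"].split(",")
        labels.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))

    raw = np.fromfile(data_file, dtype=dtype)
    if raw.size % n_ch != 0:
        raise BrainVisionError(
            f"data length {raw.size} not divisible by {n_ch} channels"
        )
    data = raw.reshape(-1, n_ch).T.astype(np.float64)
    data *= np.asarray(resolutions)[:, None]

    samples: list[int] = []
    kinds: list[str] = []
    codes: list[int] = []
    if marker_file.exists():
        mcp = _read_ini(marker_file)
        minfo = mcp["Marker Infos"]
        for key in minfo:
            parts = minfo[key].split(",")
            if len(parts) < 3:
                continue
            mtype, desc, pos = parts[0], parts[1], parts[2]
            if mtype != "Stimulus":
                continue
            dtok = desc.split()
            code = None
            if dtok and dtok[0].upper().startswith("S"):
                # "S  12", "S12", "s 12" — arbitrary internal whitespace
                tail = desc.upper().split("S", 1)[1].strip()
                if tail.isdigit():
                    code = int(tail)
            sample0 = int(pos) - 1
            if code is None:
                kinds.append("other")
                codes.append(0)
            elif 1 <= code <= 6:
                kinds.append("condition_marker")
                codes.append(code)
            elif code in _STIM_TO_KIND:
                kinds.append(_STIM_TO_KIND[code])
                codes.append(0)
            else:
                kinds.append("other")
                codes.append(code)
            samples.append(sample0)
    events = EventTable(
        np.array(samples, dtype=np.int64),
        np.array(kinds, dtype=object),
        np.array(codes, dtype=np.int64),
    )
    rec = ContinuousRecording(data, labels, fs)
    return rec, events
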