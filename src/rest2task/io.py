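"""Recording / trial containers, standard-format readers and state-segment extraction.

A session is a continuous multichannel EEG recording (microvolts) with an
event table giving trial onsets and class labels.  Trials follow a fixed
timeline: the first two seconds are a blank-screen resting period, the cue
appears at 2 s, and the 2.5-4.5 s window is taken as the motor-imagery
state.  Resting-state and imagery-state training matrices are built by
concatenating the corresponding window of every trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

logger = logging.getLogger(__name__)

#: default state windows in seconds relative to trial onset, half-open [start, end)
STATE_WINDOWS: dict[str, tuple[float, float]] = {
    "rest": (0.0, 2.0),
    "imagery": (2.5, 4.5),
}

#: default analysis band (Hz)
DEFAULT_BAND = (2.0, 30.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signals in microvolts, one row per channel.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Channel names (10-20 system), unique, one per data row.
    montage : ndarray, shape (n_channels, 3), optional
        Electrode positions on the unit sphere (head frame).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    montage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.montage is not None:
            self.montage = np.asarray(self.montage, dtype=float)
            if self.montage.shape != (self.data.shape[0], 3):
                raise ValueError("montage must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EventTable:
    """Trial onsets (samples, strictly increasing) and class labels."""

    onsets: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        if self.onsets.ndim != 1 or len(self.onsets) != len(self.labels):
            raise ValueError("onsets and labels must have equal length")
        if len(self.onsets) > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EventTable":
        """Read a TSV with header ``onset_sample<TAB>label``."""
        lines = Path(path).read_text().strip().splitlines()
        if not lines or lines[0].split("\t")[:2] != ["onset_sample", "label"]:
            raise ValueError(f"{path}: expected header 'onset_sample\\tlabel'")
        onsets, labels = [], []
        for ln in lines[1:]:
            onset, label = ln.split("\t")[:2]
            onsets.append(int(onset))
            labels.append(label)
        return cls(np.array(onsets, dtype=int), labels)

    def to_tsv(self, path: str | Path) -> None:
        rows = "\n".join(f"{o}\t{l}" for o, l in zip(self.onsets, self.labels))
        Path(path).write_text("onset_sample\tlabel\n" + rows + "\n")


@dataclass
class TrialSet:
    """Epoched trials with class labels and named state windows.

    ``windows`` maps state names to half-open ``[start, end)`` second ranges
    relative to trial onset.  Window edges are converted to samples by
    rounding ``seconds * fs`` to the nearest integer.
    """

    trials: np.ndarray  # (n_trials, n_channels, n_samples)
    labels: np.ndarray  # (n_trials,) of str
    fs: float
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(STATE_WINDOWS)
    )
    channel_labels: list[str] | None = None
    montage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.trials.ndim != 3:
            raise ValueError("trials must be 3-D (trial x channel x sample)")
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError("one label per trial required")
        n = self.trials.shape[2]
        for name, (lo, hi) in self.windows.items():
            if self.window_samples(name)[1] > n:
                raise ValueError(f"window '{name}' [{lo}, {hi}) s exceeds trial length")
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) and counts.min() < 1:  # pragma: no cover - unique guarantees >=1
            raise ValueError("every class needs at least one trial")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    def window_samples(self, state: str) -> tuple[int, int]:
        if state not in self.windows:
            raise KeyError(f"state window '{state}' not defined")
        lo, hi = self.windows[state]
        return int(round(lo * self.fs)), int(round(hi * self.fs))

    def state_trials(self, state: str) -> np.ndarray:
        """Per-trial slice of the given state window, shape (trial, channel, sample)."""
        a, b = self.window_samples(state)
        return self.trials[:, :, a:b]


# ---------------------------------------------------------------------------
# montage files
# ---------------------------------------------------------------------------

def read_montage(path: str | Path, normalize: bool = True) -> tuple[list[str], np.ndarray]:
    """Read an SFP-style montage: whitespace-separated ``name x y z`` lines.

    Lines starting with ``#`` are ignored.  With ``normalize`` each position
    is scaled to unit radius (head-frame convention used throughout).
    """
    names: list[str] = []
    pos: list[list[float]] = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) != 4:
            raise ValueError(f"montage line not 'name x y z': {ln!r}")
        names.append(parts[0])
        pos.append([float(v) for v in parts[1:]])
    arr = np.asarray(pos, dtype=float)
    if normalize:
        arr = arr / np.linalg.norm(arr, axis=1, keepdims=True)
    return names, arr


def write_montage(path: str | Path, names: list[str], pos: np.ndarray) -> None:
    lines = [f"{n} {x:.6f} {y:.6f} {z:.6f}" for n, (x, y, z) in zip(names, pos)]
    Path(path).write_text("\n".join(lines) + "\n")


def match_montage(
    channel_labels: list[str], names: list[str], pos: np.ndarray
) -> np.ndarray:
    """Order montage rows to the recording's channels, matching names
    case-insensitively.  A recorded channel missing from the montage is a
    hard error naming the channel."""
    lookup = {n.lower(): i for i, n in enumerate(names)}
    rows = []
    for ch in channel_labels:
        if ch.lower() not in lookup:
            raise KeyError(f"channel '{ch}' missing from montage")
        rows.append(lookup[ch.lower()])
    return pos[rows]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, montage_path: str | Path | None = None) -> Recording:
    """Read an EDF/BDF (or plain-text fixture) recording.

    EDF and BDF (24-bit BioSemi dialect) go through :mod:`mne`; ``.txt``
    fixtures use :func:`read_recording_text`.  Units are converted to
    microvolts and channel order is preserved from the file.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".txt":
        rec = read_recording_text(path)
    elif suffix in (".edf", ".bdf"):
        import mne

        reader = mne.io.read_raw_bdf if suffix == ".bdf" else mne.io.read_raw_edf
        try:
            raw = reader(path, preload=True, verbose="error")
        except Exception as exc:  # unreadable header and friends
            raise IOError(f"cannot read {path}: {exc}") from exc
        if len(raw.ch_names) < 2:
            raise ValueError(f"{path}: fewer than 2 channels")
        data = raw.get_data() * 1e6  # volts -> microvolts
        rec = Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))
    else:
        raise ValueError(f"unsupported recording format: {path.suffix}")
    if montage_path is not None:
        names, pos = read_montage(montage_path)
        rec = replace(rec, montage=match_montage(rec.channel_labels, names, pos))
    return rec


_TEXT_HEADER = "# rest2task recording v1"


def write_recording_text(rec: Recording, path: str | Path) -> None:
    """Write a recording as a documented delimited text file.

    Format: a version line, ``# fs: <Hz>``, ``# channels: <tab-joined>``,
    then one tab-separated row of microvolt samples per channel.
    """
    with open(path, "w") as fh:
        fh.write(_TEXT_HEADER + "\n")
        fh.write(f"# fs: {rec.fs!r}\n")
        fh.write("# channels: " + "\t".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data, fmt="%.10g", delimiter="\t")


def read_recording_text(path: str | Path) -> Recording:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != _TEXT_HEADER:
            raise IOError(f"{path}: not a rest2task text recording")
        fs = float(fh.readline().split(":", 1)[1])
        channels = fh.readline().split(":", 1)[1].strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return Recording(data, fs, channels)


def write_bdf(rec: Recording, path: str | Path, physical_range: float = 3200.0) -> None:
    """Write a minimal 24-bit BioSemi BDF file (synthetic fixtures only).

    One-second data records, all channels at the recording rate, physical
    units microvolts over ``+-physical_range``.  The written signal is
    quantized to the 24-bit grid, so round-trips agree to the quantization
    step ``2*physical_range / 2**24``.
    """
    n_ch = rec.n_channels
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("BDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((n_ch, n_rec * fs))
    data[:, : rec.n_samples] = rec.data

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")
        if len(b) > width:
            raise ValueError(f"header field too long: {s!r}")
        return b.ljust(width)

    hdr = b"\xffBIOSEMI"
    hdr += pad("", 80) + pad("", 80)                     # subject / recording id
    hdr += pad("01.01.00", 8) + pad("00.00.00", 8)       # date / time
    hdr += pad(str(256 * (n_ch + 1)), 8)
    hdr += pad("24BIT", 44)
    hdr += pad(str(n_rec), 8) + pad("1", 8) + pad(str(n_ch), 4)
    hdr += b"".join(pad(ch, 16) for ch in rec.channel_labels)
    hdr += pad("active electrode", 80) * n_ch
    hdr += pad("uV", 8) * n_ch
    hdr += pad(str(-physical_range), 8) * n_ch + pad(str(physical_range), 8) * n_ch
    hdr += pad("-8388608", 8) * n_ch + pad("8388607", 8) * n_ch
    hdr += pad("", 80) * n_ch
    hdr += pad(str(fs), 8) * n_ch
    hdr += pad("", 32) * n_ch

    scale = 2 * physical_range / 2**24
    digital = np.clip(np.round(data / scale), -8388608, 8388607).astype(np.int32)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            block = digital[:, r * fs : (r + 1) * fs]
            raw = block.astype("<i4").tobytes()
            # drop the high byte of each little-endian int32 -> 24-bit
            fh.write(np.frombuffer(raw, dtype=np.uint8).reshape(-1, 4)[:, :3].tobytes())


# ---------------------------------------------------------------------------
# filtering and epoching
# ---------------------------------------------------------------------------

def bandpass(
    rec: Recording,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
) -> Recording:
    """Zero-phase band-pass filter (4th-order Butterworth, forward-backward).

    Forward-backward application removes group delay so ERD/ERS timing is
    preserved; the effective magnitude response is squared.
    """
    nyq = rec.fs / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz invalid for fs={rec.fs}")
    sos = butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return replace(rec, data=sosfiltfilt(sos, rec.data, axis=1))


def bandpass_array(x: np.ndarray, fs: float, low: float, high: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass on a bare array (last axis = time)."""
    nyq = fs / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz invalid for fs={fs}")
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x, axis=-1)


def epoch(rec: Recording, events: EventTable, trial_len: float = 8.0) -> TrialSet:
    """Cut fixed-length trials at each event onset.

    Trial ``t`` sample ``k`` equals recording sample ``onset_t + k``; labels
    are carried over.  Overlapping trials are allowed (logged); a trial
    running past the end of the recording is an error.
    """
    if len(events) == 0:
        raise ValueError("no trials: empty event table")
    n = int(round(trial_len * rec.fs))
    if np.any(events.onsets + n > rec.n_samples) or np.any(events.onsets < 0):
        bad = int(np.argmax(events.onsets + n > rec.n_samples))
        raise ValueError(
            f"trial at onset {events.onsets[bad]} exceeds recording length {rec.n_samples}"
        )
    if len(events) > 1 and np.any(np.diff(events.onsets) < n):
        logger.warning("overlapping trials in event table")
    trials = np.stack([rec.data[:, o : o + n] for o in events.onsets])
    return TrialSet(
        trials,
        np.asarray(events.labels),
        rec.fs,
        channel_labels=list(rec.channel_labels),
        montage=rec.montage,
    )


def state_segments(ts: TrialSet, state: str) -> np.ndarray:
    """Concatenate the given state window of every trial, trial order preserved.

    Returns a channels x samples matrix: the unsupervised training matrix
    for that state (e.g. 240 trials x 2 s of rest at 256 Hz -> 122880 samples).
    """
    segs = ts.state_trials(state)
    return np.concatenate(list(segs), axis=1)
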