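"""Call audio ingest: WAV reading, Audacity label tracks, pre-emphasis, framing, silence.

Telephone calls arrive as mono 8 kHz recordings (32-bit float or 16-bit
PCM).  The preprocessing chain quantizes to the 16-bit PCM grid, removes
the DC offset, applies a first-order pre-emphasis filter, cuts the signal
into 50 %-overlapping 40-ms Blackman-windowed frames, and masks frames
whose RMS falls below a dBFS floor (treated as silence and excluded from
every downstream table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile

__all__ = [
    "AudioRecording",
    "SegmentAnnotation",
    "FrameSeries",
    "read_wav",
    "write_wav",
    "read_audacity_labels",
    "to_pcm16",
    "normalize_preemphasize",
    "frame_signal",
    "detect_silence",
    "DEFAULT_PREEMPHASIS",
    "DEFAULT_SILENCE_DBFS",
    "DEFAULT_CUTOFF",
]

DEFAULT_PREEMPHASIS = 0.97
DEFAULT_SILENCE_DBFS = -50.0
#: distress-thermometer clinical cutoff: rating >= 4 counts as high distress
DEFAULT_CUTOFF = 4


@dataclass
class AudioRecording:
    """A mono call recording with caller metadata.

    samples are dimensionless amplitudes in [-1, 1]; rate in Hz.
    """

    samples: np.ndarray
    rate: int
    encoding: str = "float32"  # {"float32", "pcm16"}
    call_id: str = ""
    caller_id: str = ""
    sex: str = ""  # {"male", "female"} or "" when unknown

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class SegmentAnnotation:
    """One rater-annotated span of caller speech with its distress rating."""

    segment_id: str
    call_id: str
    start_s: float
    end_s: float
    distress_rating: int
    distress_label: str  # "low" | "high"
    note: str = ""  # free-text presentation note, passed through to reports


@dataclass
class FrameSeries:
    """Windowed analysis frames cut from one recording or segment."""

    frames: np.ndarray  # (n_frames, frame_len), window already applied
    frame_len: int
    hop: int
    rate: int
    window: str = "blackman"
    times: np.ndarray = field(default_factory=lambda: np.empty(0))  # frame centers, s
    silent_mask: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    raw_frames: np.ndarray | None = None  # pre-window frames (for RMS/autocorr)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def read_wav(path) -> AudioRecording:
    """Read a mono RIFF/WAVE file, scaling samples to [-1, 1].

    16-bit PCM is divided by 32768; float data is taken as-is.  Multi-channel
    files are rejected: the study's calls are mono and channel mixing would
    silently corrupt the features.
    """
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"unreadable WAV header in {path!r}: {exc}") from exc
    if data.ndim != 1:
        raise ValueError(
            f"{path!r} has {data.shape[1]} channels; only mono input is supported"
        )
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
        encoding = "pcm16"
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
        encoding = "float32"
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
        encoding = "float32"
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype} in {path!r}")
    if rate != 8000:
        warnings.warn(
            f"{path!r} sampled at {rate} Hz (telephone calls are 8000 Hz); "
            "features will use the band [0, rate/2]",
            stacklevel=2,
        )
    return AudioRecording(samples=samples, rate=int(rate), encoding=encoding)


def write_wav(path, rec: AudioRecording) -> None:
    """Write a recording; pcm16 encodings round-trip bit-exactly."""
    if rec.encoding == "pcm16":
        ints = np.clip(np.round(rec.samples * 32768.0), -32768, 32767).astype(np.int16)
        wavfile.write(path, rec.rate, ints)
    else:
        wavfile.write(path, rec.rate, rec.samples.astype(np.float32))


def read_audacity_labels(path, cutoff: int = DEFAULT_CUTOFF, call_id: str = "") -> list[SegmentAnnotation]:
    """Parse an Audacity label track (TSV: start, end, label) into annotations.

    The label field carries the 0-10 distress-thermometer rating, optionally
    followed by ``|free text`` with the rater's presentation note.  Ratings at
    or above *cutoff* are labelled high distress.
    """
    out: list[SegmentAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path!r} line {i + 1}: expected start<TAB>end<TAB>label")
            start_s, end_s = float(parts[0]), float(parts[1])
            if end_s <= start_s:
                raise ValueError(
                    f"{path!r} line {i + 1}: segment end {end_s} <= start {start_s}"
                )
            label_field, _, note = parts[2].partition("|")
            try:
                rating = int(label_field.strip())
            except ValueError as exc:
                raise ValueError(
                    f"{path!r} line {i + 1}: label {parts[2]!r} is not an integer rating"
                ) from exc
            if not 0 <= rating <= 10:
                raise ValueError(f"{path!r} line {i + 1}: rating {rating} outside 0-10")
            out.append(
                SegmentAnnotation(
                    segment_id=f"{call_id}_s{i:03d}" if call_id else f"s{i:03d}",
                    call_id=call_id,
                    start_s=start_s,
                    end_s=end_s,
                    distress_rating=rating,
                    distress_label="high" if rating >= cutoff else "low",
                    note=note.strip(),
                )
            )
    return out


def write_audacity_labels(path, annotations) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ann in annotations:
            label = str(ann.distress_rating)
            if ann.note:
                label += f"|{ann.note}"
            fh.write(f"{ann.start_s:.6f}\t{ann.end_s:.6f}\t{label}\n")


def to_pcm16(rec: AudioRecording) -> AudioRecording:
    """Quantize samples to the 16-bit PCM grid (idempotent on pcm16 input)."""
    if rec.encoding == "pcm16":
        return rec
    grid = np.clip(np.round(rec.samples * 32768.0), -32768, 32767) / 32768.0
    return replace(rec, samples=grid, encoding="pcm16")


def normalize_preemphasize(rec: AudioRecording, alpha: float = DEFAULT_PREEMPHASIS) -> AudioRecording:
    """Remove the DC mean then apply pre-emphasis y[t] = x'[t] - alpha*x'[t-1].

    Pre-emphasis flattens the spectral tilt of voiced speech, lifting the
    higher formants that carry most of the discriminative detail on the
    telephone band.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"pre-emphasis alpha must be in [0, 1), got {alpha}")
    x = rec.samples - rec.samples.mean()
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - alpha * x[:-1]
    return replace(rec, samples=y)


def frame_signal(rec: AudioRecording, frame_ms: float = 40.0, overlap: float = 0.5) -> FrameSeries:
    """Cut the signal into overlapping Blackman-windowed frames.

    frame_len = round(frame_ms/1000 * rate); hop = frame_len * (1 - overlap).
    Trailing samples that do not fill a whole frame are discarded.
    """
    frame_len = int(round(frame_ms / 1000.0 * rec.rate))
    hop = int(round(frame_len * (1.0 - overlap)))
    n = len(rec.samples)
    if n < frame_len:
        raise ValueError(
            f"signal of {n} samples is shorter than one {frame_len}-sample frame"
        )
    n_frames = (n - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    raw = rec.samples[idx]
    win = np.blackman(frame_len)
    times = (np.arange(n_frames) * hop + frame_len / 2.0) / rec.rate
    return FrameSeries(
        frames=raw * win,
        frame_len=frame_len,
        hop=hop,
        rate=rec.rate,
        times=times,
        silent_mask=np.zeros(n_frames, dtype=bool),
        raw_frames=raw,
    )


def detect_silence(series: FrameSeries, threshold_dbfs: float = DEFAULT_SILENCE_DBFS) -> FrameSeries:
    """Mark frames silent when their (pre-window) RMS in dBFS is below threshold."""
    if series.n_frames == 0:
        raise ValueError("frame series is empty")
    raw = series.raw_frames if series.raw_frames is not None else series.frames
    rms = np.sqrt(np.mean(raw**2, axis=1))
    with np.errstate(divide="ignore"):
        dbfs = 20.0 * np.log10(rms)
    series.silent_mask = dbfs < threshold_dbfs
    return series
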