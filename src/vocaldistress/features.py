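"""Per-frame acoustic features for telephone-band speech.

Each 40-ms windowed frame yields 21 vocal characteristics: amplitude (RMS
dB), eight spectral-shape statistics, three LPC formant frequency/width
pairs, two harmonicity measures, psychoacoustic loudness, and three
sequence-context features computed across neighbouring frames within the
same annotated segment.  The fundamental frequency itself is deliberately
absent: it lies below the 300 Hz telephone passband, but f0 remains
recoverable from harmonic spacing for the harmonicity measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, hilbert
from statsmodels.regression.linear_model import burg

from .audio_io import (
    AudioRecording,
    FrameSeries,
    SegmentAnnotation,
    detect_silence,
    frame_signal,
)

__all__ = [
    "FEATURE_NAMES",
    "FrameSpectrum",
    "frame_spectrum",
    "amplitude_rms_db",
    "spectral_shape",
    "formants_lpc",
    "harmonicity",
    "loudness_sone",
    "sequence_features",
    "extract_feature_table",
    "ExtractionConfig",
]

#: canonical feature-column order of the frame table
FEATURE_NAMES = [
    "rms_db",
    "dominant_freq",
    "entropy",
    "f1_freq",
    "f1_width",
    "f2_freq",
    "f2_width",
    "f3_freq",
    "f3_width",
    "spectral_flux",
    "noise_to_harmonics",
    "loudness",
    "spectral_novelty",
    "peak_freq",
    "q25_freq",
    "q50_freq",
    "q75_freq",
    "roughness",
    "spectral_centroid",
    "spectral_slope",
    "subharmonic_depth",
]

DEFAULT_NFFT = 512
DEFAULT_LPC_ORDER = 10  # 2 + rate/1000 at 8 kHz
PITCH_FLOOR = 75.0
PITCH_CEILING = 300.0
SEQ_WINDOW_FRAMES = 5


@dataclass
class FrameSpectrum:
    """One-sided power spectrum of a windowed frame."""

    freqs: np.ndarray
    power: np.ndarray  # linear power; sums to the frame's time-domain energy
    rate: int

    @property
    def magnitude_db(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(self.power)


def frame_spectrum(frame: np.ndarray, rate: int, nfft: int = DEFAULT_NFFT) -> FrameSpectrum:
    """One-sided power spectrum, Parseval-scaled to time-domain energy."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValueError("empty frame")
    if nfft < frame.size:
        raise ValueError(f"nfft={nfft} < frame length {frame.size}")
    spec = np.fft.rfft(frame, n=nfft)
    power = np.abs(spec) ** 2 / nfft
    # fold negative frequencies so sum(power) == sum(frame**2)
    power[1:] *= 2.0
    if nfft % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    return FrameSpectrum(freqs=freqs, power=power, rate=rate)


def amplitude_rms_db(frame: np.ndarray) -> float:
    """RMS amplitude in dB relative to full scale (1.0)."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValueError("empty frame")
    rms = np.sqrt(np.mean(frame**2))
    if rms == 0.0:
        return -np.inf
    return 20.0 * np.log10(rms)


def spectral_shape(spec: FrameSpectrum, prominence_frac: float = 0.10) -> dict[str, float]:
    """Centroid, peak/dominant frequency, power quantiles, slope and entropy.

    dominant_freq is the lowest spectral peak whose height reaches
    *prominence_frac* of the global maximum — the lowest dominant band, as
    distinct from the global argmax peak_freq.  Entropy is Wiener entropy
    (geometric over arithmetic mean of power), 0 for a line spectrum and 1
    for an ideally flat one.
    """
    p = spec.power
    total = p.sum()
    if total <= 0.0:
        raise ValueError("zero spectrum: spectral shape undefined")
    f = spec.freqs
    centroid = float((f * p).sum() / total)
    peak_freq = float(f[int(np.argmax(p))])

    floor = prominence_frac * p.max()
    pk, _ = find_peaks(p, height=floor)
    if pk.size:
        dominant = float(f[pk[0]])
    else:  # monotone spectrum (e.g. DC-dominated): fall back to argmax
        dominant = peak_freq
    cum = np.cumsum(p) / total
    q25 = float(f[int(np.searchsorted(cum, 0.25))])
    q50 = float(f[int(np.searchsorted(cum, 0.50))])
    q75 = float(f[int(np.searchsorted(cum, 0.75))])

    # least-squares slope of dB magnitude vs frequency, in dB/kHz
    nz = p > 0
    mag_db = 10.0 * np.log10(p[nz])
    fk = f[nz] / 1000.0
    slope = float(np.polyfit(fk, mag_db, 1)[0]) if nz.sum() >= 2 else 0.0

    # Wiener entropy: geometric over arithmetic mean of power (floored to
    # avoid log(0) from exact-zero bins)
    pc = np.maximum(p, p.max() * 1e-12)
    entropy = float(np.clip(np.exp(np.mean(np.log(pc))) / pc.mean(), 0.0, 1.0))

    return {
        "spectral_centroid": centroid,
        "peak_freq": peak_freq,
        "dominant_freq": dominant,
        "q25_freq": q25,
        "q50_freq": q50,
        "q75_freq": q75,
        "spectral_slope": slope,
        "entropy": entropy,
    }


def formants_lpc(
    frame: np.ndarray, rate: int, order: int = DEFAULT_LPC_ORDER, bw_max: float = 400.0
) -> dict[str, float]:
    """First three formant frequencies and bandwidths from Burg LPC poles.

    Roots of the LPC polynomial with positive imaginary part map to
    f = angle * rate / (2*pi) and bandwidth b = -(rate/pi) * ln|r|; formants
    are the first three root frequencies inside (90, rate/2 - 50) Hz with
    bandwidth below bw_max (wider poles model spectral tilt or noise, not
    resonances), sorted ascending.  Missing formants come back as NaN.
    Expects pre-emphasized input; without tilt compensation the weak upper
    formants are routinely missed.
    """
    if order < 8:
        raise ValueError(f"LPC order must be >= 8, got {order}")
    out = {k: np.nan for k in ("f1_freq", "f1_width", "f2_freq", "f2_width", "f3_freq", "f3_width")}
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size <= order or np.allclose(frame, 0.0):
        return out
    try:
        ar, _ = burg(frame, order=order, demean=True)
    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
        return out
    if not np.all(np.isfinite(ar)):
        return out
    roots = np.roots(np.concatenate(([1.0], -ar)))
    roots = roots[np.imag(roots) > 0.0]
    freqs = np.angle(roots) * rate / (2.0 * np.pi)
    bws = -(rate / np.pi) * np.log(np.maximum(np.abs(roots), 1e-12))
    order_ix = np.argsort(freqs)
    freqs, bws = freqs[order_ix], bws[order_ix]
    keep = (freqs > 90.0) & (freqs < rate / 2.0 - 50.0) & (bws < bw_max)
    freqs, bws = freqs[keep], bws[keep]
    # successive formants must be distinct resonances, not split poles of one
    picked: list[int] = []
    for i in range(freqs.size):
        if not picked or freqs[i] - freqs[picked[-1]] >= 200.0:
            picked.append(i)
        if len(picked) == 3:
            break
    for j, i in enumerate(picked):
        out[f"f{j + 1}_freq"] = float(freqs[i])
        out[f"f{j + 1}_width"] = float(bws[i])
    return out


def harmonicity(
    frame: np.ndarray,
    rate: int,
    pitch_floor: float = PITCH_FLOOR,
    pitch_ceiling: float = PITCH_CEILING,
) -> dict[str, float]:
    """Noise-to-harmonics ratio and subharmonic depth from autocorrelation.

    r* is the peak normalized autocorrelation over lags [rate/ceiling,
    rate/floor]; NHR = (1 - r*)/r* clipped to [0, 10].  Subharmonic depth
    measures period doubling ("rough" phonation): with period candidate T*
    it is the dB excess of the autocorrelation at lag 2T* over lag T*,
    floored at 0.  (A 40-ms frame cannot spectrally resolve components at
    f0/2 offsets, so the period-2 component is read in the time domain;
    acf(2T) > acf(T) iff alternate periods differ.)
    """
    frame = np.asarray(frame, dtype=np.float64)
    out = {"noise_to_harmonics": np.nan, "subharmonic_depth": np.nan}
    energy = float(np.dot(frame, frame))
    if energy <= 0.0:
        return out
    x = frame - frame.mean()
    e0 = float(np.dot(x, x))
    if e0 <= 0.0:
        return out
    lag_min = max(1, int(np.floor(rate / pitch_ceiling)))
    lag_max = min(frame.size - 1, int(np.ceil(rate / pitch_floor)))
    if lag_max <= lag_min:
        return out
    full = np.correlate(x, x, mode="full")[x.size - 1 :]
    # normalize by the shrinking overlap so long lags are not penalized
    overlap = np.arange(x.size, 0, -1, dtype=np.float64)
    acf = (full / overlap) / (e0 / x.size)
    band = acf[lag_min : lag_max + 1]
    rel = int(np.argmax(band))
    r_star = float(band[rel])
    if r_star <= 0.0:
        out["noise_to_harmonics"] = 10.0
        out["subharmonic_depth"] = 0.0
        return out
    r_star = min(r_star, 1.0)
    out["noise_to_harmonics"] = float(np.clip((1.0 - r_star) / max(r_star, 1e-6), 0.0, 10.0))

    lag_star = lag_min + rel
    depth = 0.0
    if 2 * lag_star + 2 < x.size:
        # search +/- 2 lags around the doubled period for its acf peak
        lo, hi = 2 * lag_star - 2, 2 * lag_star + 3
        r2 = float(acf[lo:hi].max())
        if r2 > 1e-3 and r_star > 1e-3:
            depth = max(0.0, 20.0 * np.log10(min(r2, 1.0) / r_star))
    out["subharmonic_depth"] = float(depth)
    return out


# Traunmueller critical-band (bark) scale
def _hz_to_bark(f: np.ndarray) -> np.ndarray:
    return 26.81 * f / (1960.0 + f) - 0.53


def loudness_sone(spec: FrameSpectrum) -> float:
    """Psychoacoustic loudness: bark-band powers through Stevens' law.

    Power is pooled into 1-bark critical bands over [0, rate/2]; each band
    contributes intensity**0.3 (specific loudness), and bands sum.  Doubling
    every band's power multiplies the result by 2**0.3 exactly.
    """
    p = spec.power
    if p.sum() <= 0.0:
        return 0.0
    bark = _hz_to_bark(spec.freqs)
    band = np.clip(bark.astype(int), 0, None)
    nb = band.max() + 1
    band_power = np.bincount(band, weights=p, minlength=nb)
    return float(np.sum(band_power**0.3))


def _unit_rows(spectra: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(spectra, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return spectra / norms


def sequence_features(
    spectra: np.ndarray,
    raw_frames: np.ndarray,
    rate: int,
    window_frames: int = SEQ_WINDOW_FRAMES,
) -> pd.DataFrame:
    """Spectral flux, novelty and roughness along one segment's frame sequence.

    flux: Euclidean distance between consecutive unit-normalized power
    spectra, scaled by 1/sqrt(2) into [0, 1]; first frame gets 0.
    novelty: checkerboard-kernel score on the local cosine self-similarity
    matrix (window_frames wide, edges padded by replication).
    roughness: fraction of amplitude-envelope modulation energy in
    30-150 Hz, the psychoacoustic roughness band, over the local sample span.
    Context never crosses the segment boundary: callers feed one segment's
    frames at a time.
    """
    n = spectra.shape[0]
    if n == 0:
        return pd.DataFrame(columns=["spectral_flux", "spectral_novelty", "roughness"])
    if n == 1:
        return pd.DataFrame(
            {"spectral_flux": [0.0], "spectral_novelty": [0.0], "roughness": [0.0]}
        )
    u = _unit_rows(spectra)
    flux = np.zeros(n)
    flux[1:] = np.linalg.norm(u[1:] - u[:-1], axis=1) / np.sqrt(2.0)

    # self-similarity + checkerboard (Foote) kernel; the center row/column is
    # excluded and taper mass balances across the diagonal, so a constant
    # similarity field scores exactly 0
    half = window_frames // 2
    pad_ix = np.clip(np.arange(-half, n + half), 0, n - 1)
    up = u[pad_ix]
    sim = up @ up.T
    offs = np.concatenate([np.arange(-half, 0), np.arange(1, half + 1)])
    sign = np.sign(offs)
    taper = np.exp(-0.5 * (offs / max(half, 1)) ** 2)
    kvec = sign * taper
    kernel = np.outer(kvec, kvec)
    novelty = np.empty(n)
    for t in range(n):
        block = sim[np.ix_(t + half + offs, t + half + offs)]
        novelty[t] = max(0.0, float(np.sum(kernel * block)))
    if novelty.max() > 0:
        novelty = novelty / (kernel.size / 2.0)  # scale-free normalization

    # roughness from the local amplitude envelope
    frame_len = raw_frames.shape[1]
    hop = frame_len // 2
    rough = np.zeros(n)
    for t in range(n):
        lo, hi = max(0, t - half), min(n, t + half + 1)
        seg = np.concatenate(
            [raw_frames[lo]] + [raw_frames[j][hop:] for j in range(lo + 1, hi)]
        )
        env = np.abs(hilbert(seg - seg.mean()))
        env = env - env.mean()
        if not np.any(env):
            continue
        mod = np.abs(np.fft.rfft(env)) ** 2
        mf = np.fft.rfftfreq(env.size, d=1.0 / rate)
        total = mod[1:].sum()
        if total > 0:
            band = (mf >= 30.0) & (mf <= 150.0)
            rough[t] = float(mod[band].sum() / total)
    return pd.DataFrame(
        {"spectral_flux": flux, "spectral_novelty": novelty, "roughness": rough}
    )


@dataclass
class ExtractionConfig:
    frame_ms: float = 40.0
    overlap: float = 0.5
    nfft: int = DEFAULT_NFFT
    lpc_order: int = DEFAULT_LPC_ORDER
    silence_dbfs: float = -50.0
    pitch_floor: float = PITCH_FLOOR
    pitch_ceiling: float = PITCH_CEILING
    seq_window: int = SEQ_WINDOW_FRAMES


def _segment_features(series: FrameSeries, cfg: ExtractionConfig) -> pd.DataFrame:
    """Feature rows for the non-silent frames of one segment's FrameSeries."""
    keep = ~series.silent_mask
    if not np.any(keep):
        return pd.DataFrame(columns=FEATURE_NAMES + ["time_s"])
    frames = series.frames[keep]
    raw = (series.raw_frames if series.raw_frames is not None else series.frames)[keep]
    nf = frames.shape[0]
    spectra = np.empty((nf, cfg.nfft // 2 + 1))
    rows = []
    for i in range(nf):
        spec = frame_spectrum(frames[i], series.rate, nfft=cfg.nfft)
        spectra[i] = spec.power
        row = {"rms_db": amplitude_rms_db(raw[i])}
        row.update(spectral_shape(spec))
        row.update(formants_lpc(frames[i], series.rate, order=cfg.lpc_order))
        row.update(harmonicity(raw[i], series.rate, cfg.pitch_floor, cfg.pitch_ceiling))
        row["loudness"] = loudness_sone(spec)
        rows.append(row)
    df = pd.DataFrame(rows)
    seq = sequence_features(spectra, raw, series.rate, window_frames=cfg.seq_window)
    df = pd.concat([df.reset_index(drop=True), seq.reset_index(drop=True)], axis=1)
    df["time_s"] = series.times[keep]
    return df[FEATURE_NAMES + ["time_s"]]


def extract_feature_table(
    recordings: list[AudioRecording],
    annotations: list[SegmentAnnotation],
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Build the frame table: one row per non-silent frame in an annotated segment.

    Each segment's binary distress label is broadcast to all of its frames;
    caller id and sex come from the recording.  Columns: caller_id, sex,
    call_id, segment_id, time_s, the 21 features, distress_rating, label
    (1 = high distress).
    """
    cfg = config or ExtractionConfig()
    by_call = {rec.call_id: rec for rec in recordings}
    bad = [
        ann.segment_id
        for ann in annotations
        if ann.call_id not in by_call
        or ann.end_s > by_call[ann.call_id].duration_s + 1e-9
        or ann.start_s < 0
    ]
    if bad:
        raise ValueError(f"annotations outside audio bounds: {bad}")
    parts = []
    for ann in annotations:
        rec = by_call[ann.call_id]
        i0 = int(round(ann.start_s * rec.rate))
        i1 = int(round(ann.end_s * rec.rate))
        seg_rec = AudioRecording(
            samples=rec.samples[i0:i1],
            rate=rec.rate,
            encoding=rec.encoding,
            call_id=rec.call_id,
            caller_id=rec.caller_id,
            sex=rec.sex,
        )
        try:
            series = frame_signal(seg_rec, frame_ms=cfg.frame_ms, overlap=cfg.overlap)
        except ValueError:
            warnings.warn(f"segment {ann.segment_id} shorter than one frame; skipped", stacklevel=2)
            continue
        detect_silence(series, threshold_dbfs=cfg.silence_dbfs)
        df = _segment_features(series, cfg)
        if df.empty:
            warnings.warn(f"segment {ann.segment_id} fully silent; no rows", stacklevel=2)
            continue
        df.insert(0, "segment_id", ann.segment_id)
        df.insert(0, "call_id", ann.call_id)
        df.insert(0, "sex", rec.sex)
        df.insert(0, "caller_id", rec.caller_id)
        df["time_s"] = df["time_s"] + ann.start_s
        df["distress_rating"] = ann.distress_rating
        df["label"] = int(ann.distress_label == "high")
        parts.append(df)
    if not parts:
        return pd.DataFrame(
            columns=["caller_id", "sex", "call_id", "segment_id"]
            + FEATURE_NAMES
            + ["time_s", "distress_rating", "label"]
        )
    return pd.concat(parts, ignore_index=True)
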