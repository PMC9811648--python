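"""Synthetic helpline-call data at two levels: feature tables and raw audio.

The study's recordings are confidential, so every pipeline stage is
exercised on generated data that reproduces the *structure* of the corpus:
~120 callers (87 female / 33 male), segments per call with mean ~7.7 and
SD ~4.2, ~100 40-ms frames per segment, an 11-point distress rating per
segment dichotomized at 4, caller-level random effects, within-segment
AR(1) feature noise, and sex-moderated feature-distress relationships
whose signs follow the significant terms of the selection model (male:
louder, lower first formant, shallower subharmonics with distress; female:
higher entropy, noise-to-harmonics, median frequency and spectral slope,
shallower subharmonics).  A latent two-mode phonation state, persistent
within segments and partially distress-driven, gives the frame cloud the
two-cluster structure the clustering stage is meant to find.

The audio generator synthesizes the same structure as telephone-band
waveforms: a glottal pulse train through three formant resonators plus
aspiration noise, with distress shifting gain, F1, tilt, noise and
period-doubling in the configured directions, band-limited to 300-3400 Hz
at 8 kHz, written as WAV + Audacity label TSV + metadata CSV.  It aims at
a testable acoustic structure, not perceptually realistic speech.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .audio_io import AudioRecording, SegmentAnnotation, write_audacity_labels, write_wav
from .features import FEATURE_NAMES

__all__ = ["SimConfig", "GroundTruth", "simulate_feature_table", "synthesize_call_audio", "make_fixture"]

#: plausible telephone-speech units (offset, scale) for each standardized feature
FEATURE_UNITS = {
    "rms_db": (-28.0, 6.0),
    "dominant_freq": (350.0, 120.0),
    "entropy": (0.45, 0.12),
    "f1_freq": (540.0, 80.0),
    "f1_width": (90.0, 25.0),
    "f2_freq": (1550.0, 150.0),
    "f2_width": (120.0, 30.0),
    "f3_freq": (2600.0, 180.0),
    "f3_width": (180.0, 40.0),
    "spectral_flux": (0.25, 0.08),
    "noise_to_harmonics": (0.9, 0.5),
    "loudness": (12.0, 3.0),
    "spectral_novelty": (0.30, 0.10),
    "peak_freq": (500.0, 200.0),
    "q25_freq": (420.0, 90.0),
    "q50_freq": (900.0, 180.0),
    "q75_freq": (1800.0, 300.0),
    "roughness": (0.20, 0.07),
    "spectral_centroid": (1200.0, 250.0),
    "spectral_slope": (-18.0, 4.0),
    "subharmonic_depth": (6.0, 3.0),
}

#: distress effects, (feature, sex) -> (kind, signed magnitude in z-units):
#: directions follow the significant sex-moderated terms of the selection model
DEFAULT_EFFECT_MAP = {
    ("rms_db", "male"): ("monotone", 1.3),
    ("f1_freq", "male"): ("monotone_nonlin", -1.3),
    ("subharmonic_depth", "male"): ("monotone", -1.17),
    ("entropy", "female"): ("monotone_nonlin", 1.3),
    ("noise_to_harmonics", "female"): ("monotone", 1.17),
    ("q50_freq", "female"): ("monotone", 1.3),
    ("spectral_slope", "female"): ("monotone", 1.17),
    ("subharmonic_depth", "female"): ("monotone", -1.17),
}

#: latent phonation-mode direction: which features the second mode elevates
MODE_SHIFT = {
    "entropy": 0.9,
    "noise_to_harmonics": 0.8,
    "q50_freq": 0.7,
    "spectral_slope": 0.7,
    "subharmonic_depth": -0.8,
    "f1_freq": 0.5,
}


@dataclass
class SimConfig:
    """Study-shaped generator settings; defaults mirror the corpus structure."""

    n_callers: int = 120
    n_female: int = 87
    segments_per_call_mean: float = 7.7
    segments_per_call_sd: float = 4.22
    frames_per_segment_mean: float = 100.0
    frames_per_segment_disp: float = 3.0  # NB dispersion (smaller = more variable)
    cutoff: int = 4
    rating_mean: float = 4.92  # distress-thermometer marginal mean / SD 2.13
    rating_concentration: float = 10.0  # beta-binomial concentration
    caller_intercept_sd: float = 1.0  # logit shift of a caller's rating propensity
    caller_feature_sd: float = 0.4  # caller voice-identity offset per feature
    within_segment_ar1_rho: float = 0.6
    effect_map: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_MAP))
    mode_distress_beta: float = 0.9  # logit link of phonation mode to distress
    mode_shift_scale: float = 1.0
    # audio parameters
    rate: int = 8000
    f0_male: tuple = (110.0, 135.0)
    f0_female: tuple = (185.0, 225.0)
    formants_male: tuple = (500.0, 1500.0, 2500.0)
    formants_female: tuple = (560.0, 1650.0, 2750.0)
    formant_bw: tuple = (80.0, 110.0, 150.0)
    noise_floor: float = 0.02  # aspiration gain at zero distress
    silence_fraction: float = 0.5
    segment_duration_s: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.within_segment_ar1_rho < 1:
            raise ValueError("within_segment_ar1_rho must be in [0, 1)")
        if not 0 < self.n_female <= self.n_callers:
            raise ValueError("n_female must be in (0, n_callers]")
        if not 0 <= self.cutoff <= 10:
            raise ValueError("cutoff must be in [0, 10]")
        if not 0 <= self.silence_fraction < 1:
            raise ValueError("silence_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    caller_intercepts: dict
    segment_ratings: dict
    frame_labels: np.ndarray
    frame_modes: np.ndarray
    effect_map: dict


def _rating_t(rating: np.ndarray) -> np.ndarray:
    """Distress ratings rescaled to a centered unit-ish working coordinate."""
    return (np.asarray(rating, float) - 4.5) / 3.0


def _effect_value(kind: str, magnitude: float, t: np.ndarray) -> np.ndarray:
    if kind == "monotone":
        return magnitude * t
    if kind == "monotone_nonlin":  # monotone with curvature (edf > 1 recoverable)
        return magnitude * (t + 0.3 * t * np.abs(t))
    if kind == "quadratic":
        return magnitude * (t**2 - np.mean(t**2) if t.size > 1 else t**2)
    raise ValueError(f"unknown effect kind {kind!r}")


def _draw_ratings(rng, n: int, intercept: float, cfg: SimConfig) -> np.ndarray:
    """Beta-binomial(10) ratings; the caller intercept shifts the mean propensity."""
    p0 = cfg.rating_mean / 10.0
    logit = np.log(p0 / (1 - p0)) + intercept
    p = 1.0 / (1.0 + np.exp(-logit))
    a = max(p * cfg.rating_concentration, 1e-3)
    b = max((1 - p) * cfg.rating_concentration, 1e-3)
    return rng.binomial(10, rng.beta(a, b, size=n))


def simulate_feature_table(config: SimConfig | None = None, seed: int | None = None):
    """Draw a frame table with the study's nesting and planted effects.

    Returns (table, GroundTruth).  The table has the same columns the audio
    feature extractor emits: caller/sex/call/segment ids, the 21 features
    in plausible units, time_s, distress_rating and the binary label.
    Byte-identical for equal (config, seed).
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_seg_r = cfg.segments_per_call_mean**2 / max(
        cfg.segments_per_call_sd**2 - cfg.segments_per_call_mean, 0.5
    )
    rows_caller, rows_sex, rows_call, rows_seg = [], [], [], []
    ratings_all, labels_all, modes_all = [], [], []
    z_blocks = []
    caller_intercepts, segment_ratings = {}, {}
    p_feat = len(FEATURE_NAMES)
    feat_idx = {f: i for i, f in enumerate(FEATURE_NAMES)}
    mode_vec = np.zeros(p_feat)
    for f, m in MODE_SHIFT.items():
        mode_vec[feat_idx[f]] = m * cfg.mode_shift_scale

    for i in range(cfg.n_callers):
        caller = f"c{i:03d}"
        sex = "female" if i < cfg.n_female else "male"
        u = rng.normal(0.0, cfg.caller_intercept_sd)
        caller_intercepts[caller] = u
        voice = rng.normal(0.0, cfg.caller_feature_sd, size=p_feat)
        n_seg = max(1, rng.negative_binomial(n_seg_r, n_seg_r / (n_seg_r + cfg.segments_per_call_mean)))
        ratings = _draw_ratings(rng, n_seg, u, cfg)
        for s in range(n_seg):
            seg_id = f"{caller}_s{s:03d}"
            rating = int(ratings[s])
            segment_ratings[seg_id] = rating
            t = _rating_t(np.array([rating]))[0]
            nf_disp = cfg.frames_per_segment_disp
            nf = max(
                2,
                rng.negative_binomial(nf_disp, nf_disp / (nf_disp + cfg.frames_per_segment_mean)),
            )
            # persistent phonation mode, partially distress-driven
            p_mode = 1.0 / (1.0 + np.exp(-cfg.mode_distress_beta * t))
            mode = int(rng.random() < p_mode)
            # AR(1) noise with unit stationary variance, per feature
            eps = rng.normal(size=(nf, p_feat))
            rho = cfg.within_segment_ar1_rho
            noise = np.empty_like(eps)
            noise[0] = eps[0]
            for k in range(1, nf):
                noise[k] = rho * noise[k - 1] + np.sqrt(1 - rho**2) * eps[k]
            z = noise + voice[None, :] + mode * mode_vec[None, :]
            for (feat, fsex), (kind, mag) in cfg.effect_map.items():
                if fsex == sex or fsex == "all":
                    z[:, feat_idx[feat]] += _effect_value(kind, mag, np.full(nf, t))
            z_blocks.append(z)
            rows_caller.extend([caller] * nf)
            rows_sex.extend([sex] * nf)
            rows_call.extend([f"call_{caller}"] * nf)
            rows_seg.extend([seg_id] * nf)
            ratings_all.extend([rating] * nf)
            labels_all.extend([int(rating >= cfg.cutoff)] * nf)
            modes_all.extend([mode] * nf)

    z = np.concatenate(z_blocks, axis=0)
    table = pd.DataFrame(
        {
            "caller_id": rows_caller,
            "sex": rows_sex,
            "call_id": rows_call,
            "segment_id": rows_seg,
        }
    )
    for f in FEATURE_NAMES:
        off, scale = FEATURE_UNITS[f]
        table[f] = off + scale * z[:, feat_idx[f]]
    table["time_s"] = table.groupby("segment_id").cumcount() * 0.02 + 0.02
    table["distress_rating"] = ratings_all
    table["label"] = labels_all
    truth = GroundTruth(
        caller_intercepts=caller_intercepts,
        segment_ratings=segment_ratings,
        frame_labels=np.asarray(labels_all),
        frame_modes=np.asarray(modes_all),
        effect_map=dict(cfg.effect_map),
    )
    return table, truth


# ---------------------------------------------------------------- audio level


def _glottal_source(rng, n: int, rate: int, f0: float, alt_depth: float, jitter: float = 0.01) -> np.ndarray:
    """Impulse train with period jitter; alternate periods scaled for subharmonics."""
    x = np.zeros(n)
    pos = 0.0
    k = 0
    while pos < n:
        amp = 1.0 - alt_depth * (k % 2)
        x[int(pos)] = amp
        period = rate / (f0 * (1.0 + jitter * rng.standard_normal()))
        pos += max(period, 8.0)
        k += 1
    # one-pole lowpass gives the pulse a glottal-ish -12 dB/oct roll-off
    return sps.lfilter([1.0], [1.0, -0.9], x)


def _formant_filter(x: np.ndarray, rate: int, formants, bws) -> np.ndarray:
    for fc, bw in zip(formants, bws):
        r = np.exp(-np.pi * bw / rate)
        theta = 2.0 * np.pi * fc / rate
        x = sps.lfilter([1.0 - r], [1.0, -2.0 * r * np.cos(theta), r**2], x)
    return x


def synthesize_call_audio(
    config: SimConfig | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    n_callers: int | None = None,
    segments_per_call: int | None = None,
):
    """Source-filter synthesis of calls with distress-shifted acoustics.

    Returns (recordings, annotations, metadata rows); when out_dir is given
    also writes one WAV + one Audacity label TSV per call and a metadata
    CSV.  High distress shifts, per the effect directions: males get louder
    (+6 dB full range) with a lower first formant and *less* period
    alternation; females get more aspiration noise, a shallower spectral
    tilt, more high-frequency energy and less alternation.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    nc = n_callers if n_callers is not None else cfg.n_callers
    nf_callers = int(round(nc * cfg.n_female / cfg.n_callers))
    recordings, annotations, meta = [], [], []
    for i in range(nc):
        caller = f"a{i:03d}"
        call_id = f"call_{caller}"
        sex = "female" if i < nf_callers else "male"
        u = rng.normal(0.0, 0.3 * cfg.caller_intercept_sd)
        f0_lo, f0_hi = cfg.f0_female if sex == "female" else cfg.f0_male
        f0_base = rng.uniform(f0_lo, f0_hi)
        # caller voice identity: vocal-tract length, habitual loudness and
        # breathiness vary mildly between callers (the caller random effect)
        formant_scale = rng.normal(1.0, 0.02)
        caller_gain_db = rng.normal(0.0, 1.0)
        caller_noise = rng.lognormal(0.0, 0.15)
        n_seg = segments_per_call if segments_per_call is not None else max(
            1, int(rng.normal(cfg.segments_per_call_mean, cfg.segments_per_call_sd))
        )
        ratings = _draw_ratings(rng, n_seg, u, cfg)
        # raters annotated a diversity of distress levels within each call;
        # ensure both sides of the cutoff appear when there are >= 2 segments
        if n_seg >= 2:
            if (ratings >= cfg.cutoff).all():
                ratings[rng.integers(n_seg)] = rng.integers(max(cfg.cutoff - 2, 0), cfg.cutoff)
            elif (ratings < cfg.cutoff).all():
                ratings[rng.integers(n_seg)] = rng.integers(cfg.cutoff, min(cfg.cutoff + 3, 10) + 1)
        gap = cfg.silence_fraction / max(1 - cfg.silence_fraction, 1e-6) * cfg.segment_duration_s
        pieces = [np.zeros(int(0.5 * gap * cfg.rate))]
        anns = []
        t_cursor = len(pieces[0]) / cfg.rate
        for s in range(n_seg):
            rating = int(ratings[s])
            t = _rating_t(np.array([rating]))[0]
            dur = cfg.segment_duration_s * rng.uniform(0.8, 1.25)
            n = int(dur * cfg.rate)
            if sex == "male":
                gain_db = caller_gain_db + 3.0 * t  # louder with distress
                f1_shift = -60.0 * t  # lower F1 with distress
                noise_gain = cfg.noise_floor * caller_noise
                tilt = 0.0
                alt = np.clip(0.35 - 0.25 * t, 0.0, 0.6)  # less period doubling
            else:
                gain_db = caller_gain_db
                f1_shift = 0.0
                # aspiration ~ +7 dB per unit distress coordinate
                noise_gain = cfg.noise_floor * caller_noise * 10.0 ** (0.35 * t)
                tilt = 0.35 * t  # larger -> stronger HF emphasis -> shallower slope
                alt = np.clip(0.35 - 0.25 * t, 0.0, 0.6)
            formants = [f * formant_scale for f in (cfg.formants_male if sex == "male" else cfg.formants_female)]
            formants[0] = max(formants[0] + f1_shift, 250.0)
            src = _glottal_source(rng, n, cfg.rate, f0_base * (1 + 0.03 * rng.standard_normal()), alt)
            src = src + noise_gain * rng.standard_normal(n)
            voiced = _formant_filter(src, cfg.rate, formants, cfg.formant_bw)
            if tilt != 0.0:
                voiced = sps.lfilter([1.0, -(0.5 + np.clip(tilt, -0.45, 0.45))], [1.0], voiced)
            rmsv = np.sqrt(np.mean(voiced**2))
            voiced = voiced / max(rmsv, 1e-9) * 0.1 * 10.0 ** (gain_db / 20.0)
            pieces.append(voiced)
            anns.append((t_cursor, t_cursor + n / cfg.rate, rating))
            t_cursor += n / cfg.rate
            sil = np.zeros(int(gap * cfg.rate * rng.uniform(0.6, 1.4)))
            pieces.append(sil)
            t_cursor += len(sil) / cfg.rate
        x = np.concatenate(pieces)
        sos = sps.butter(4, [300.0, 3400.0], btype="bandpass", fs=cfg.rate, output="sos")
        x = sps.sosfilt(sos, x)
        peak = np.abs(x).max()
        if peak > 0.95:
            x = x * (0.95 / peak)
        rec = AudioRecording(
            samples=x.astype(np.float64), rate=cfg.rate, encoding="float32",
            call_id=call_id, caller_id=caller, sex=sex,
        )
        recordings.append(rec)
        for j, (a, b, rating) in enumerate(anns):
            annotations.append(
                SegmentAnnotation(
                    segment_id=f"{call_id}_s{j:03d}", call_id=call_id,
                    start_s=a, end_s=min(b, rec.duration_s),
                    distress_rating=rating,
                    distress_label="high" if rating >= cfg.cutoff else "low",
                )
            )
        meta.append({"call_id": call_id, "caller_id": caller, "sex": sex})

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            write_wav(out / f"{rec.call_id}.wav", rec)
            anns = [a for a in annotations if a.call_id == rec.call_id]
            write_audacity_labels(out / f"{rec.call_id}.txt", anns)
        with open(out / "metadata.csv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["call_id", "caller_id", "sex"])
            w.writeheader()
            w.writerows(meta)
    return recordings, annotations, meta


def make_fixture(kind: str, seed: int = 0, out_dir=None):
    """Small deterministic datasets for tests and examples.

    tiny_features: 10 callers / ~40 segments / ~2,000 rows feature table.
    null_features: same shape, every planted effect and mode link zeroed.
    tiny_audio:    6 callers, 3 segments each, <= 20 s of synthetic audio.
    """
    if kind == "tiny_features":
        cfg = SimConfig(
            n_callers=10, n_female=7, segments_per_call_mean=4.0, segments_per_call_sd=1.5,
            frames_per_segment_mean=50.0, seed=seed,
        )
        return simulate_feature_table(cfg)
    if kind == "null_features":
        cfg = SimConfig(
            n_callers=10, n_female=7, segments_per_call_mean=4.0, segments_per_call_sd=1.5,
            frames_per_segment_mean=50.0, effect_map={}, mode_distress_beta=0.0, seed=seed,
        )
        return simulate_feature_table(cfg)
    if kind == "tiny_audio":
        cfg = SimConfig(segment_duration_s=0.8, silence_fraction=0.3, seed=seed)
        return synthesize_call_audio(
            cfg, out_dir=out_dir, n_callers=6, segments_per_call=3
        )
    raise ValueError(f"unknown fixture kind {kind!r}")
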