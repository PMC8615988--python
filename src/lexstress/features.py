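"""Syllable-level acoustic stress features.

For each aligned syllable the extractor computes eight measures known to
covary with lexical stress prominence:

* f1 - peak-to-peak Teager energy amplitude over the syllable nucleus
* f2 - mean Teager energy over the nucleus
* f3 - maximum Teager energy over the nucleus
* f4 - nucleus duration (s)
* f5 - syllable duration (s)
* f6 - maximum f0 over the nucleus (Hz, autocorrelation tracker)
* f7 - mean f0 over the nucleus (Hz)
* f8 - log Mel filterbank energies, one 27-band row per nucleus frame

The Teager energy operator is the discrete Teager-Kaiser operator
``psi(n) = x(n)^2 - x(n-1) x(n+1)``; for a pure sinusoid ``A cos(Omega n)``
it equals ``A^2 sin^2(Omega)``, giving an amplitude- and frequency-sensitive
instantaneous energy estimate that is robust to additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft

from .core_io import SyllableSpan, Waveform, resample

__all__ = [
    "TeoProfile",
    "PitchTrack",
    "PitchConfig",
    "MelConfig",
    "FeatureConfig",
    "SyllableFeatureSet",
    "teager_energy_profile",
    "estimate_pitch_track",
    "mel_band_energies",
    "extract_syllable_features",
]


@dataclass
class TeoProfile:
    """Per-sample Teager energy, valid over interior samples 1..L-2."""

    values: np.ndarray


@dataclass
class PitchConfig:
    """Autocorrelation pitch tracker settings.

    The 100-600 Hz search range covers child voices; voicing requires the
    best normalized autocorrelation peak to exceed ``voicing_threshold``.
    """

    frame_length: float = 0.040
    hop: float = 0.010
    f0_min: float = 100.0
    f0_max: float = 600.0
    voicing_threshold: float = 0.45
    rate: int = 16000


@dataclass
class MelConfig:
    """27-band triangular Mel filterbank over 50 Hz .. Nyquist."""

    frame_length: float = 0.025
    hop: float = 0.010
    n_bands: int = 27
    f_min: float = 50.0
    f_max: float | None = None  # None -> Nyquist
    log_floor: float = 1e-10
    rate: int = 16000


@dataclass
class FeatureConfig:
    pitch: PitchConfig = field(default_factory=PitchConfig)
    mel: MelConfig = field(default_factory=MelConfig)
    rate: int = 16000


@dataclass
class PitchTrack:
    times: np.ndarray   # frame centers, seconds
    f0: np.ndarray      # Hz, 0 where unvoiced
    voiced: np.ndarray  # bool

    @property
    def n_voiced(self) -> int:
        return int(np.count_nonzero(self.voiced))


@dataclass
class SyllableFeatureSet:
    f1: float
    f2: float
    f3: float
    f4: float
    f5: float
    f6: float
    f7: float
    f8: np.ndarray  # n x 27 log Mel energies
    n: int
    voiced_frames: int = 0

    def scalars(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3, self.f4,
                         self.f5, self.f6, self.f7])


# ---------------------------------------------------------------------------
# Teager energy
# ---------------------------------------------------------------------------

def teager_energy_profile(signal: np.ndarray) -> TeoProfile:
    """Discrete Teager-Kaiser energy psi(n) = x(n)^2 - x(n-1) x(n+1)."""
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 3:
        raise ValueError("Teager energy needs at least 3 samples")
    psi = x[1:-1] ** 2 - x[:-2] * x[2:]
    return TeoProfile(psi)


# ---------------------------------------------------------------------------
# pitch
# ---------------------------------------------------------------------------

def _frame_signal(x: np.ndarray, flen: int, hop: int) -> np.ndarray:
    """Frame without padding: floor((L - flen)/hop) + 1 frames, or empty."""
    if x.size < flen:
        return np.empty((0, flen))
    n = (x.size - flen) // hop + 1
    idx = np.arange(flen)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def estimate_pitch_track(
    wave: Waveform,
    interval: tuple[float, float],
    config: PitchConfig | None = None,
) -> PitchTrack:
    """Normalized-autocorrelation f0 track over ``interval``.

    Per frame the best autocorrelation peak within the lag range
    ``[rate/f0_max, rate/f0_min]`` is found; the frame is voiced iff the
    normalized peak exceeds the voicing threshold, and the lag is refined by
    parabolic interpolation.  An interval shorter than one frame yields an
    empty (not erroneous) track.
    """
    config = config or PitchConfig()
    w = resample(wave, config.rate)
    x = w.segment(*interval)
    flen = int(round(config.frame_length * config.rate))
    hop = int(round(config.hop * config.rate))
    frames = _frame_signal(x, flen, hop)
    lag_min = max(2, int(np.floor(config.rate / config.f0_max)))
    lag_max = min(flen - 1, int(np.ceil(config.rate / config.f0_min)))
    times, f0s, voiced = [], [], []
    for i, frame in enumerate(frames):
        frame = frame - frame.mean()
        energy = float(np.dot(frame, frame))
        t = interval[0] + (i * hop + flen / 2) / config.rate
        times.append(t)
        if energy <= 0:
            f0s.append(0.0)
            voiced.append(False)
            continue
        # normalized autocorrelation r(tau) = sum x_t x_{t+tau} / sqrt(E0 E_tau)
        full = np.correlate(frame, frame, mode="full")[frame.size - 1:]
        csum = np.concatenate(([0.0], np.cumsum(frame**2)))
        lags = np.arange(lag_min, lag_max + 1)
        e_head = csum[flen - lags] - csum[0]
        e_tail = csum[flen] - csum[lags]
        denom = np.sqrt(e_head * e_tail)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, full[lag_min:lag_max + 1] / denom, 0.0)
        rmax = float(np.max(r))
        # subharmonics of a periodic signal score ~equally; take the
        # shortest lag within 1% of the best peak to avoid octave errors
        k = int(np.flatnonzero(r >= rmax - 0.01 * abs(rmax))[0])
        peak = float(r[k])
        if peak <= config.voicing_threshold:
            f0s.append(0.0)
            voiced.append(False)
            continue
        lag = float(lags[k])
        if 0 < k < r.size - 1:  # parabolic refinement around the peak
            a, b, c = r[k - 1], r[k], r[k + 1]
            denom2 = a - 2 * b + c
            if denom2 < 0:
                lag += 0.5 * (a - c) / denom2
        f0s.append(config.rate / lag)
        voiced.append(True)
    f0_arr = np.array(f0s)
    voiced_arr = np.array(voiced, dtype=bool)
    # median over voiced neighbours (+/- 2 frames) removes isolated octave
    # errors without distorting slowly varying contours
    smoothed = f0_arr.copy()
    for i in np.flatnonzero(voiced_arr):
        window = [f0_arr[j] for j in range(i - 2, i + 3)
                  if 0 <= j < f0_arr.size and voiced_arr[j]]
        smoothed[i] = np.median(window)
    return PitchTrack(np.array(times), smoothed, voiced_arr)


# ---------------------------------------------------------------------------
# Mel filterbank energies
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_bands: int, n_fft: int, rate: int,
                   f_min: float, f_max: float) -> np.ndarray:
    """Triangular filters on the Mel scale: (n_bands, n_fft//2 + 1)."""
    mel_pts = np.linspace(_hz_to_mel(f_min), _hz_to_mel(f_max), n_bands + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_bands, bins.size))
    for b in range(n_bands):
        lo, mid, hi = hz_pts[b], hz_pts[b + 1], hz_pts[b + 2]
        up = (bins - lo) / max(mid - lo, 1e-12)
        down = (hi - bins) / max(hi - mid, 1e-12)
        fb[b] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mel_band_energies(
    wave: Waveform,
    nucleus: tuple[float, float],
    config: MelConfig | None = None,
) -> np.ndarray:
    """Log Mel filterbank energies per 25 ms frame of the nucleus (n x 27)."""
    config = config or MelConfig()
    w = resample(wave, config.rate)
    x = w.segment(*nucleus)
    flen = int(round(config.frame_length * config.rate))
    hop = int(round(config.hop * config.rate))
    frames = _frame_signal(x, flen, hop)
    if frames.shape[0] == 0:
        raise ValueError(
            f"nucleus [{nucleus[0]:.3f},{nucleus[1]:.3f}) shorter than one "
            f"{config.frame_length * 1e3:.0f} ms frame"
        )
    n_fft = 1 << (flen - 1).bit_length()
    window = np.hamming(flen)
    spec = np.abs(rfft(frames * window, n=n_fft, axis=1)) ** 2
    f_max = config.f_max if config.f_max is not None else config.rate / 2
    fb = mel_filterbank(config.n_bands, n_fft, config.rate, config.f_min, f_max)
    energies = spec @ fb.T
    return np.log(energies + config.log_floor)


# ---------------------------------------------------------------------------
# per-syllable extraction
# ---------------------------------------------------------------------------

def extract_syllable_features(
    wave: Waveform,
    syllable: SyllableSpan,
    config: FeatureConfig | None = None,
) -> SyllableFeatureSet:
    """Compute f1..f8 for one aligned syllable.

    Energy features come from the Teager profile of the nucleus samples,
    durations from the alignment, f6/f7 from voiced frames of the nucleus
    pitch track (0 if fully unvoiced), and f8 from the Mel filterbank.
    """
    config = config or FeatureConfig()
    if syllable.nucleus.end > wave.duration + 1e-6 or syllable.nucleus.start < -1e-9:
        raise ValueError("syllable nucleus lies outside the waveform")
    w = resample(wave, config.rate)
    nucleus = (syllable.nucleus.start, syllable.nucleus.end)
    x = w.segment(*nucleus)
    psi = teager_energy_profile(x).values
    track = estimate_pitch_track(w, nucleus, config.pitch)
    voiced_f0 = track.f0[track.voiced]
    f8 = mel_band_energies(w, nucleus, config.mel)
    return SyllableFeatureSet(
        f1=float(psi.max() - psi.min()),
        f2=float(psi.mean()),
        f3=float(psi.max()),
        f4=syllable.nucleus_duration,
        f5=syllable.syllable_duration,
        f6=float(voiced_f0.max()) if voiced_f0.size else 0.0,
        f7=float(voiced_f0.mean()) if voiced_f0.size else 0.0,
        f8=f8,
        n=f8.shape[0],
        voiced_frames=track.n_voiced,
    )
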