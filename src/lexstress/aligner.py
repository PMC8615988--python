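"""Monophone GMM-HMM forced alignment.

Each phone is a 3-state left-to-right HMM (no skips) with diagonal-covariance
Gaussian-mixture emissions over 39-dimensional MFCC+delta+delta-delta frames.
Training is hard-EM (Viterbi training): flat-start from uniform state
segmentation of the labelled phone intervals, then alternating constrained
Viterbi re-segmentation and mixture re-estimation, which gives a monotone
non-decreasing total alignment log-likelihood.

Forced alignment constrains decoding to the expected phoneme sequence of a
word, optionally preceded/followed by a silence phone, and reads phone
boundaries off the maximum-likelihood state path.  In multiple-pronunciation
mode every dictionary variant is aligned and the best-scoring one is kept,
emulating a knowledge-driven dictionary primed with expected mispronunciations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.fft import rfft
from scipy.fftpack import dct
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .core_io import (
    SILENCE_LABEL,
    AlignmentResult,
    PhonemeInterval,
    PronEntry,
    SyllableSpan,
    Waveform,
    base_phone,
    is_vowel_symbol,
    resample,
)
from .features import mel_filterbank

__all__ = [
    "FrontendConfig",
    "FrameMatrix",
    "AcousticModel",
    "MonophoneAligner",
    "InfeasibleAlignmentError",
    "ModelCoverageError",
    "compute_mfcc",
    "train_monophone_model",
    "viterbi_align",
    "align_word",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class InfeasibleAlignmentError(ValueError):
    """More HMM states than frames: every state needs at least one frame."""


class ModelCoverageError(KeyError):
    """A phoneme in the requested sequence has no trained model."""


@dataclass
class FrontendConfig:
    rate: int = 16000
    frame_length: float = 0.025
    hop: float = 0.010
    pre_emphasis: float = 0.97
    n_mfcc: int = 13
    n_mels: int = 26
    f_min: float = 50.0
    log_floor: float = 1e-10
    delta_window: int = 2


@dataclass
class FrameMatrix:
    """Per-frame coefficient vectors with their timing metadata."""

    data: np.ndarray       # (T, D)
    frame_length: float    # seconds
    hop: float             # seconds
    origin: float = 0.0    # seconds offset of frame 0 center
    duration: float = 0.0  # seconds of the source token

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def _delta(x: np.ndarray, window: int) -> np.ndarray:
    """Regression-based delta coefficients with edge replication."""
    denom = 2.0 * sum(k * k for k in range(1, window + 1))
    padded = np.concatenate([np.repeat(x[:1], window, axis=0), x,
                             np.repeat(x[-1:], window, axis=0)])
    out = np.zeros_like(x)
    for k in range(1, window + 1):
        out += k * (padded[window + k:window + k + x.shape[0]]
                    - padded[window - k:window - k + x.shape[0]])
    return out / denom


def compute_mfcc(wave: Waveform, config: FrontendConfig | None = None) -> FrameMatrix:
    """13 MFCCs + deltas + delta-deltas per 25 ms frame at 10 ms hop."""
    config = config or FrontendConfig()
    w = resample(wave, config.rate)
    flen = int(round(config.frame_length * config.rate))
    hop = int(round(config.hop * config.rate))
    if w.samples.size < flen:
        raise ValueError(
            f"signal of {w.samples.size} samples shorter than one frame ({flen})"
        )
    x = np.append(w.samples[0], w.samples[1:] - config.pre_emphasis * w.samples[:-1])
    n = (x.size - flen) // hop + 1
    idx = np.arange(flen)[None, :] + hop * np.arange(n)[:, None]
    frames = x[idx] * np.hamming(flen)
    n_fft = 1 << (flen - 1).bit_length()
    spec = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(config.n_mels, n_fft, config.rate,
                        config.f_min, config.rate / 2)
    logmel = np.log(spec @ fb.T + config.log_floor)
    mfcc = dct(logmel, type=2, axis=1, norm="ortho")[:, : config.n_mfcc]
    d1 = _delta(mfcc, config.delta_window)
    d2 = _delta(d1, config.delta_window)
    data = np.hstack([mfcc, d1, d2])
    return FrameMatrix(data, config.frame_length, config.hop,
                       origin=config.frame_length / 2, duration=w.duration)


# ---------------------------------------------------------------------------
# acoustic model
# ---------------------------------------------------------------------------

@dataclass
class PhoneHmm:
    """Left-to-right HMM for one phone: per-state GMMs and self-loop probs."""

    weights: np.ndarray    # (S, M)
    means: np.ndarray      # (S, M, D)
    variances: np.ndarray  # (S, M, D)
    self_loop: np.ndarray  # (S,)


@dataclass
class AcousticModel:
    """Trained monophone inventory plus the frontend normalization."""

    phones: dict[str, PhoneHmm]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    n_states: int
    frontend: FrontendConfig = field(default_factory=FrontendConfig)

    def emission_logprob(self, phone: str, frames: np.ndarray) -> np.ndarray:
        """(S, T) log GMM densities for standardized frames."""
        hmm = self.phones[phone]
        S, M, D = hmm.means.shape
        x = frames[None, None, :, :]                       # 1,1,T,D
        mu = hmm.means[:, :, None, :]                      # S,M,1,D
        var = hmm.variances[:, :, None, :]
        ll = -0.5 * (((x - mu) ** 2 / var) + np.log(var) + _LOG2PI).sum(axis=3)
        return logsumexp(ll + np.log(hmm.weights)[:, :, None], axis=1)

    def standardize(self, frames: np.ndarray) -> np.ndarray:
        return (frames - self.feature_mean) / self.feature_scale

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "n_states": self.n_states,
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "frontend": vars(self.frontend),
            "phones": {
                p: {
                    "weights": h.weights.tolist(),
                    "means": h.means.tolist(),
                    "variances": h.variances.tolist(),
                    "self_loop": h.self_loop.tolist(),
                }
                for p, h in self.phones.items()
            },
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AcousticModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        phones = {
            p: PhoneHmm(
                np.array(d["weights"]), np.array(d["means"]),
                np.array(d["variances"]), np.array(d["self_loop"]),
            )
            for p, d in doc["phones"].items()
        }
        return cls(phones, np.array(doc["feature_mean"]),
                   np.array(doc["feature_scale"]), doc["n_states"],
                   FrontendConfig(**doc["frontend"]))


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

def _chain_arrays(model: AcousticModel, phones: list[str], frames_std: np.ndarray):
    """Concatenate the per-phone state chains for a phone sequence."""
    emis, log_self, log_adv = [], [], []
    for phone in phones:
        if phone not in model.phones:
            raise ModelCoverageError(f"no acoustic model for phone {phone!r}")
        emis.append(model.emission_logprob(phone, frames_std))
        p_self = np.clip(model.phones[phone].self_loop, 1e-3, 1 - 1e-3)
        log_self.append(np.log(p_self))
        log_adv.append(np.log1p(-p_self))
    return (np.concatenate(emis, axis=0), np.concatenate(log_self),
            np.concatenate(log_adv))


def _viterbi_states(emis, log_self, log_adv):
    """Constrained left-to-right Viterbi; returns (state path, log-likelihood).

    Score = emission(s_0) + sum_t [transition + emission] + final exit
    probability from the last state.
    """
    S, T = emis.shape
    if S > T:
        raise InfeasibleAlignmentError(
            f"{S} states cannot each take >= 1 of {T} frames"
        )
    NEG = -np.inf
    delta = np.full((T, S), NEG)
    back = np.zeros((T, S), dtype=bool)  # True: advanced from s-1
    delta[0, 0] = emis[0, 0]
    for t in range(1, T):
        stay = delta[t - 1] + log_self
        adv = np.full(S, NEG)
        adv[1:] = delta[t - 1, :-1] + log_adv[:-1]
        advance = adv > stay
        delta[t] = np.where(advance, adv, stay) + emis[:, t]
        back[t] = advance
    ll = delta[T - 1, S - 1] + log_adv[S - 1]
    states = np.zeros(T, dtype=int)
    s = S - 1
    states[T - 1] = s
    for t in range(T - 1, 0, -1):
        if back[t, s]:
            s -= 1
        states[t - 1] = s
    return states, float(ll)


def _states_to_intervals(states: np.ndarray, phones: list[str],
                         n_states: int, hop: float,
                         duration: float) -> list[PhonemeInterval]:
    """Phone boundaries from the state path, tiling [0, duration] exactly."""
    phone_idx = states // n_states
    bounds = [0.0]
    for t in range(1, states.size):
        if phone_idx[t] != phone_idx[t - 1]:
            bounds.append(t * hop)
    bounds.append(max(duration, states.size * hop))
    out = []
    for j, phone in enumerate(phones):
        out.append(PhonemeInterval(phone, bounds[j], bounds[j + 1],
                                   is_vowel=is_vowel_symbol(phone)))
    return out


def viterbi_align(frames: FrameMatrix, phonemes: list[str],
                  model: AcousticModel) -> AlignmentResult:
    """Force-align a frame matrix against an expected phoneme sequence."""
    frames_std = model.standardize(frames.data)
    emis, log_self, log_adv = _chain_arrays(model, phonemes, frames_std)
    states, ll = _viterbi_states(emis, log_self, log_adv)
    duration = frames.duration or frames.n_frames * frames.hop
    intervals = _states_to_intervals(states, phonemes, model.n_states,
                                     frames.hop, duration)
    return AlignmentResult(intervals, [], log_likelihood=ll)


def _syllables_from_variant(intervals: list[PhonemeInterval],
                            variant) -> list[SyllableSpan]:
    word_iv = [p for p in intervals if p.label != SILENCE_LABEL]
    spans, k = [], 0
    for syl in variant.syllables:
        members = word_iv[k:k + len(syl)]
        k += len(syl)
        vowels = [p for p in members if p.is_vowel]
        spans.append(SyllableSpan(members, vowels[0]))
    return spans


def align_word(wave: Waveform | FrameMatrix, entry: PronEntry,
               model: AcousticModel, mode: str = "single",
               use_sil: bool = True) -> AlignmentResult:
    """Align one word token against its dictionary entry.

    ``mode='single'`` uses only the canonical first variant; ``'multiple'``
    aligns every variant and keeps the highest-likelihood one (ties to the
    lowest variant index).  ``variant_used`` is the 1-based variant index.
    """
    if mode not in ("single", "multiple"):
        raise ValueError(f"mode must be 'single' or 'multiple', got {mode!r}")
    frames = wave if isinstance(wave, FrameMatrix) else compute_mfcc(wave, model.frontend)
    variants = entry.variants[:1] if mode == "single" else entry.variants
    best: AlignmentResult | None = None
    for vi, variant in enumerate(variants, start=1):
        phones = variant.flat_phones
        if use_sil:
            phones = [SILENCE_LABEL] + phones + [SILENCE_LABEL]
        result = viterbi_align(frames, phones, model)
        result.variant_used = vi
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    best.syllables = _syllables_from_variant(
        best.phonemes, entry.variants[best.variant_used - 1]
    )
    return best


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class MonophoneAligner(BaseEstimator):
    """Hard-EM trained monophone forced aligner (sklearn-style estimator).

    Parameters
    ----------
    n_states : states per phone (left-to-right, no skips).
    n_mix : diagonal Gaussian components per state.
    n_iter : Viterbi re-estimation rounds after the flat start.
    var_floor, weight_floor : floors applied after each update (features are
        standardized, so the variance floor is on unit scale).
    min_phone_count : minimum labelled occurrences required per phone.

    Attributes
    ----------
    model_ : AcousticModel
    history_ : total alignment log-likelihood per training round.
    """

    def __init__(self, n_states: int = 3, n_mix: int = 2, n_iter: int = 5,
                 var_floor: float = 1e-3, weight_floor: float = 1e-3,
                 min_phone_count: int = 5, use_sil: bool = True,
                 frontend: FrontendConfig | None = None,
                 random_state: int | None = None):
        self.n_states = n_states
        self.n_mix = n_mix
        self.n_iter = n_iter
        self.var_floor = var_floor
        self.weight_floor = weight_floor
        self.min_phone_count = min_phone_count
        self.use_sil = use_sil
        self.frontend = frontend
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------
    def _frames(self, x: Waveform | FrameMatrix) -> FrameMatrix:
        if isinstance(x, FrameMatrix):
            return x
        return compute_mfcc(x, self.frontend or FrontendConfig())

    def _fit_gmm_init(self, frames: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Deterministic 2-way mean split around the sample statistics."""
        mu = frames.mean(axis=0)
        var = np.maximum(frames.var(axis=0), self.var_floor)
        offsets = np.linspace(-0.2, 0.2, self.n_mix)[:, None] * np.sqrt(var)
        means = mu[None, :] + offsets
        variances = np.tile(var, (self.n_mix, 1))
        weights = np.full(self.n_mix, 1.0 / self.n_mix)
        return weights, means, variances

    def _gmm_em_step(self, hmm: PhoneHmm, s: int, frames: np.ndarray) -> None:
        """One warm-started EM step for state ``s`` on its assigned frames."""
        w, mu, var = hmm.weights[s], hmm.means[s], hmm.variances[s]
        ll = -0.5 * (((frames[None] - mu[:, None]) ** 2 / var[:, None])
                     + np.log(var[:, None]) + _LOG2PI).sum(axis=2)
        logr = ll + np.log(w)[:, None]
        logr -= logsumexp(logr, axis=0, keepdims=True)
        r = np.exp(logr)                      # (M, T)
        nk = r.sum(axis=1)
        w_new = np.maximum(nk / frames.shape[0], self.weight_floor)
        hmm.weights[s] = w_new / w_new.sum()
        safe = np.maximum(nk, 1e-8)[:, None]
        mu_new = (r @ frames) / safe
        var_new = (r @ (frames ** 2)) / safe - mu_new ** 2
        hmm.means[s] = mu_new
        hmm.variances[s] = np.maximum(var_new, self.var_floor)

    # -- fit ----------------------------------------------------------------
    def fit(self, X, y):
        """Train on labelled utterances.

        X : list of Waveform or FrameMatrix; y : list of AlignmentResult with
        ground-truth phone intervals (silence intervals included if present).
        """
        mats = [self._frames(x) for x in X]
        seqs = [[p.label for p in ali.phonemes] for ali in y]
        counts: dict[str, int] = {}
        for seq in seqs:
            for p in seq:
                counts[p] = counts.get(p, 0) + 1
        rare = [p for p, c in counts.items() if c < self.min_phone_count]
        if rare:
            raise ValueError(
                f"phones with < {self.min_phone_count} occurrences: {sorted(rare)}"
            )
        allf = np.vstack([m.data for m in mats])
        mean = allf.mean(axis=0)
        scale = np.maximum(allf.std(axis=0), 1e-8)
        std_mats = [(m.data - mean) / scale for m in mats]
        hop = mats[0].hop

        # flat start: uniform state segmentation inside labelled intervals
        assign: dict[tuple[str, int], list[np.ndarray]] = {}
        for m_std, mat, ali in zip(std_mats, mats, y):
            centers = (np.arange(mat.n_frames) + 0.5) * hop
            for iv in ali.phonemes:
                in_iv = np.flatnonzero((centers >= iv.start) & (centers < iv.end))
                for s, chunk in enumerate(np.array_split(in_iv, self.n_states)):
                    if chunk.size:
                        assign.setdefault((iv.label, s), []).append(m_std[chunk])
        phones_set = sorted(counts)
        model = AcousticModel({}, mean, scale, self.n_states,
                              self.frontend or FrontendConfig())
        for phone in phones_set:
            W = np.zeros((self.n_states, self.n_mix))
            MU = np.zeros((self.n_states, self.n_mix, allf.shape[1]))
            VAR = np.ones_like(MU)
            for s in range(self.n_states):
                chunks = assign.get((phone, s))
                frames = np.vstack(chunks) if chunks else (allf - mean) / scale
                W[s], MU[s], VAR[s] = self._fit_gmm_init(frames)
            model.phones[phone] = PhoneHmm(
                W, MU, VAR, np.full(self.n_states, 0.5)
            )

        history = []
        for _ in range(self.n_iter):
            total = 0.0
            state_frames: dict[tuple[str, int], list[np.ndarray]] = {}
            stay_counts: dict[str, np.ndarray] = {
                p: np.zeros(self.n_states) for p in phones_set}
            adv_counts: dict[str, np.ndarray] = {
                p: np.zeros(self.n_states) for p in phones_set}
            for m_std, seq in zip(std_mats, seqs):
                emis, log_self, log_adv = _chain_arrays(model, seq, m_std)
                states, ll = _viterbi_states(emis, log_self, log_adv)
                total += ll
                for t, st in enumerate(states):
                    phone = seq[st // self.n_states]
                    s = st % self.n_states
                    state_frames.setdefault((phone, s), []).append(m_std[t])
                    if t + 1 < states.size:
                        if states[t + 1] == st:
                            stay_counts[phone][s] += 1
                        else:
                            adv_counts[phone][s] += 1
                    else:
                        adv_counts[phone][s] += 1
            history.append(total)
            for (phone, s), frames in state_frames.items():
                self._gmm_em_step(model.phones[phone], s, np.vstack(frames))
            for phone in phones_set:
                tot = stay_counts[phone] + adv_counts[phone]
                with np.errstate(invalid="ignore"):
                    p_self = np.where(tot > 0, stay_counts[phone] / np.maximum(tot, 1), 0.5)
                model.phones[phone].self_loop = np.clip(p_self, 1e-3, 1 - 1e-3)

        self.model_ = model
        self.history_ = np.array(history)
        return self

    # -- inference ----------------------------------------------------------
    def align(self, x: Waveform | FrameMatrix, phonemes: list[str]) -> AlignmentResult:
        return viterbi_align(self._frames(x), phonemes, self.model_)

    def align_word(self, x: Waveform | FrameMatrix, entry: PronEntry,
                   mode: str = "single") -> AlignmentResult:
        return align_word(x, entry, self.model_, mode=mode, use_sil=self.use_sil)


def train_monophone_model(corpus, seed: int | None = None,
                          **kwargs) -> AcousticModel:
    """Train a monophone model from (waveform/frames, alignment) pairs."""
    X = [c[0] for c in corpus]
    y = [c[1] for c in corpus]
    est = MonophoneAligner(random_state=seed, **kwargs).fit(X, y)
    return est.model_
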