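"""Synthetic child-speech corpus generator.

Source-filter synthesis of isolated pseudo-words of 2-5 syllables whose
syllables realise lexical stress on the three classic cue dimensions:
stressed vowels are longer, louder and higher in fundamental frequency than
unstressed ones.  A single contrast scalar ``c`` in [0, 1] interpolates the
three cue ratios between 1.0 (no contrast, emulating inappropriately
equalized stress) and their full literature-typical values (duration x1.6,
amplitude x2.0 = +6 dB, f0 x1.3).

Each token carries its ground-truth phone/syllable alignment, so the
generator doubles as the labelled training corpus for the forced aligner and
the stress classifier, and as the oracle for boundary-recovery tests.
Production errors can be injected: weak-syllable deletion (the token then
fails the syllable-structure filter) and stress equalization (rendered at
c = 0 while keeping the canonical dictionary label).  Simulated Likert
ratings map a signed latent stress contrast plus Gaussian rater noise
through fixed thresholds onto the 5-point perceptual scale.

Voices are child-like only in their coarse settings (f0 around 240-310 Hz,
raised formants); no developmental articulation is modelled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .core_io import (
    SILENCE_LABEL,
    AlignmentResult,
    PhonemeInterval,
    PronEntry,
    PronVariant,
    SyllableSpan,
    TokenRecord,
    Waveform,
    write_textgrid,
    write_wav,
)

__all__ = [
    "VOWEL_FORMANTS",
    "ONSET_CLASS",
    "SyllableSpec",
    "ContrastConfig",
    "SynthToken",
    "Corpus",
    "synth_syllable",
    "synth_word",
    "build_lexicon",
    "generate_corpus",
    "simulate_ratings",
]

#: Child-like (raised) first/second formant targets, Hz.
VOWEL_FORMANTS = {
    "aa": (900.0, 1400.0),
    "iy": (400.0, 3000.0),
    "uw": (450.0, 1150.0),
    "eh": (700.0, 2300.0),
    "ao": (750.0, 1100.0),
}

ONSET_CLASS = {
    "p": "plosive", "t": "plosive", "k": "plosive",
    "s": "fricative", "f": "fricative",
    "m": "nasal", "n": "nasal",
    "l": "liquid", "r": "liquid",
}

_ONSET_DURATION = {"plosive": 0.030, "fricative": 0.040,
                   "nasal": 0.035, "liquid": 0.030}

EDGE_SILENCE = 0.05  # leading/trailing silence per token, seconds


@dataclass
class SyllableSpec:
    vowel: str
    onset: str | None
    duration: float     # whole syllable, seconds
    amplitude: float    # linear gain of the vowel
    f0_peak: float      # Hz

    def __post_init__(self) -> None:
        if self.duration < 0.06:
            raise ValueError("syllable duration must be >= 0.06 s")
        if not 100.0 <= self.f0_peak <= 600.0:
            raise ValueError("f0_peak must lie in [100, 600] Hz")


@dataclass
class ContrastConfig:
    """Stress-contrast parameterization.

    At ``c = 1`` a stressed syllable is ``duration_ratio`` x longer,
    ``amplitude_ratio`` x louder and ``f0_ratio`` x higher-pitched than an
    unstressed one; the effective ratio is ``ratio ** c``, so ``c = 0``
    removes all contrast.  Jitter/shimmer are multiplicative Gaussian noise
    on the glottal period and pulse amplitude.
    """

    c: float = 1.0
    duration_ratio: float = 1.6
    amplitude_ratio: float = 2.0
    f0_ratio: float = 1.3
    jitter_sd: float = 0.02
    shimmer_sd: float = 0.05
    base_duration: float = 0.15
    base_amplitude: float = 0.25
    base_f0: float = 240.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("contrast c must lie in [0, 1]")

    def ratio(self, name: str) -> float:
        return getattr(self, f"{name}_ratio") ** self.c


@dataclass
class SynthToken:
    word: str
    waveform: Waveform
    alignment: AlignmentResult  # ground truth, tiles the waveform
    label: str                  # canonical SW / WS / SS
    error: str | None = None    # None, "syllable_deletion", "stress_equalization"
    variant_index: int = 1
    effective_contrast: float = 1.0
    child_id: str = "child01"
    group: str = "TD"

    @property
    def produced_syllables(self) -> int:
        return len(self.alignment.syllables)


# ---------------------------------------------------------------------------
# source-filter synthesis
# ---------------------------------------------------------------------------

def _resonator(x: np.ndarray, freq: float, bandwidth: float, rate: int) -> np.ndarray:
    r = np.exp(-np.pi * bandwidth / rate)
    theta = 2.0 * np.pi * freq / rate
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    b = [1.0 - r]
    return lfilter(b, a, x)


def _raised_cosine_envelope(n: int, edge: int) -> np.ndarray:
    env = np.ones(n)
    edge = min(edge, n // 2)
    if edge > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(edge) / edge))
        env[:edge] = ramp
        env[-edge:] = ramp[::-1]
    return env


def _synth_vowel(vowel: str, duration: float, amplitude: float, f0_peak: float,
                 rate: int, rng: np.random.Generator,
                 jitter_sd: float, shimmer_sd: float) -> np.ndarray:
    """Impulse train through two formant resonators.

    The f0 contour rises linearly from 0.85 x peak to the peak, holds a
    mid-vowel plateau (40-60% of the vowel, so at least one analysis frame
    sees the peak), and falls back to 0.85 x peak, with per-period
    multiplicative jitter and per-pulse shimmer.
    """
    n = int(round(duration * rate))
    source = np.zeros(n)
    t = 0.0
    while True:
        frac = min(t / duration, 1.0)
        if frac < 0.4:
            contour = 0.85 + 0.15 * frac / 0.4
        elif frac <= 0.6:
            contour = 1.0
        else:
            contour = 1.0 - 0.15 * (frac - 0.6) / 0.4
        f0 = f0_peak * contour
        period = (1.0 / f0) * (1.0 + jitter_sd * rng.standard_normal())
        idx = int(round(t * rate))
        if idx >= n:
            break
        source[idx] = 1.0 + shimmer_sd * rng.standard_normal()
        t += max(period, 1e-4)
    f1, f2 = VOWEL_FORMANTS[vowel]
    out = _resonator(source, f1, 90.0, rate) + 0.6 * _resonator(source, f2, 120.0, rate)
    out *= _raised_cosine_envelope(n, int(round(0.010 * rate)))
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= amplitude / peak
    return out


def _synth_onset(onset: str, rate: int, rng: np.random.Generator,
                 amplitude: float) -> np.ndarray:
    kind = ONSET_CLASS[onset]
    n = int(round(_ONSET_DURATION[kind] * rate))
    if kind == "plosive":
        out = np.zeros(n)
        burst = rng.standard_normal(n // 3)
        out[-burst.size:] = burst * np.exp(-np.arange(burst.size) / (0.003 * rate))
    elif kind == "fricative":
        noise = rng.standard_normal(n)
        out = _resonator(noise, 4500.0, 2000.0, rate)
        out *= _raised_cosine_envelope(n, int(round(0.005 * rate)))
    elif kind == "nasal":
        src = np.zeros(n)
        period = int(round(rate / 240.0))
        src[::period] = 1.0
        out = _resonator(src, 280.0, 120.0, rate)
        out *= _raised_cosine_envelope(n, int(round(0.005 * rate)))
    else:  # liquid: low formant glide
        src = np.zeros(n)
        period = int(round(rate / 240.0))
        src[::period] = 1.0
        freq = np.linspace(350.0, 600.0, 2)
        out = sum(_resonator(src, f, 120.0, rate) for f in freq)
        out *= _raised_cosine_envelope(n, int(round(0.005 * rate)))
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= 0.35 * amplitude / peak
    return out


def synth_syllable(
    spec: SyllableSpec, rate: int = 16000,
    rng: np.random.Generator | None = None,
    jitter_sd: float = 0.02, shimmer_sd: float = 0.05,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Render one syllable; returns (samples, nucleus interval in seconds
    relative to the syllable start)."""
    rng = rng or np.random.default_rng(0)
    if spec.onset is not None:
        onset = _synth_onset(spec.onset, rate, rng, spec.amplitude)
    else:
        onset = np.zeros(0)
    onset_dur = onset.size / rate
    nucleus_dur = spec.duration - onset_dur
    vowel = _synth_vowel(spec.vowel, nucleus_dur, spec.amplitude, spec.f0_peak,
                         rate, rng, jitter_sd, shimmer_sd)
    return np.concatenate([onset, vowel]), (onset_dur, onset_dur + vowel.size / rate)


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------

@dataclass
class LexWord:
    word: str
    pattern: str                 # SW / WS / SS
    syllables: list[tuple[str, str]]  # (onset, vowel) per syllable
    alt_vowel: str               # first-syllable vowel of variant 2

    def stress_digits(self) -> list[int]:
        if self.pattern == "SW":
            digits = [1, 0]
        elif self.pattern == "WS":
            digits = [0, 1]
        else:
            digits = [1, 2]
        return digits + [0] * (len(self.syllables) - 2)

    def pron_entry(self) -> PronEntry:
        digits = self.stress_digits()

        def make(vowel_override: str | None) -> PronVariant:
            syls = []
            for i, (onset, vowel) in enumerate(self.syllables):
                v = vowel_override if (i == 0 and vowel_override) else vowel
                syls.append([onset, f"{v}{digits[i]}"])
            return PronVariant(syls)

        return PronEntry(self.word, [make(None), make(self.alt_vowel)])


def build_lexicon(pattern_mix: dict[str, int], seed: int = 0,
                  n_syllables: tuple[int, int] = (3, 5)) -> list[LexWord]:
    """Deterministic pseudo-word lexicon with the given pattern counts."""
    rng = np.random.default_rng(seed)
    vowels = sorted(VOWEL_FORMANTS)
    onsets = sorted(ONSET_CLASS)
    out = []
    idx = 0
    for pattern in ("SW", "WS", "SS"):
        for _ in range(pattern_mix.get(pattern, 0)):
            n_syl = int(rng.integers(n_syllables[0], n_syllables[1] + 1))
            syls = [(onsets[int(rng.integers(len(onsets)))],
                     vowels[int(rng.integers(len(vowels)))])
                    for _ in range(n_syl)]
            first_vowel = syls[0][1]
            alt = vowels[(vowels.index(first_vowel) + 1) % len(vowels)]
            out.append(LexWord(f"{pattern.lower()}word{idx:02d}", pattern, syls, alt))
            idx += 1
    return out


# ---------------------------------------------------------------------------
# word and corpus synthesis
# ---------------------------------------------------------------------------

def _word_specs(lex: LexWord, contrast: ContrastConfig,
                variant: int) -> list[SyllableSpec]:
    digits = lex.stress_digits()
    specs = []
    for i, (onset, vowel) in enumerate(lex.syllables):
        if variant == 2 and i == 0:
            vowel = lex.alt_vowel
        strong = digits[i] > 0
        dur = contrast.base_duration * (contrast.ratio("duration") if strong else 1.0)
        amp = contrast.base_amplitude * (contrast.ratio("amplitude") if strong else 1.0)
        f0 = contrast.base_f0 * (contrast.ratio("f0") if strong else 1.0)
        specs.append(SyllableSpec(vowel, onset, dur, amp, f0))
    return specs


def synth_word(
    pattern: str,
    n_syllables: int = 3,
    contrast: ContrastConfig | None = None,
    seed: int = 0,
    rate: int = 16000,
    lex_word: LexWord | None = None,
    variant: int = 1,
    error: str | None = None,
) -> SynthToken:
    """Synthesize one word token with its ground-truth alignment.

    ``error='stress_equalization'`` renders the token at c = 0 but keeps its
    canonical label; ``error='syllable_deletion'`` drops the last weak
    syllable.  Bit-identical output for identical (arguments, seed).
    """
    contrast = contrast or ContrastConfig()
    rng = np.random.default_rng(seed)
    if lex_word is None:
        mix = {pattern: 1}
        lex_word = build_lexicon(mix, seed=int(rng.integers(2**31)),
                                 n_syllables=(n_syllables, n_syllables))[0]
    effective = contrast
    if error == "stress_equalization":
        effective = ContrastConfig(
            c=0.0, duration_ratio=contrast.duration_ratio,
            amplitude_ratio=contrast.amplitude_ratio, f0_ratio=contrast.f0_ratio,
            jitter_sd=contrast.jitter_sd, shimmer_sd=contrast.shimmer_sd,
            base_duration=contrast.base_duration,
            base_amplitude=contrast.base_amplitude, base_f0=contrast.base_f0,
        )
    specs = _word_specs(lex_word, effective, variant)
    syllable_names = [lex_word.syllables[i] for i in range(len(specs))]
    if error == "syllable_deletion":
        digits = lex_word.stress_digits()
        weak = [i for i, d in enumerate(digits) if d == 0]
        if weak:
            drop = weak[-1]
            specs = [s for i, s in enumerate(specs) if i != drop]
            syllable_names = [s for i, s in enumerate(syllable_names) if i != drop]

    sil = np.zeros(int(round(EDGE_SILENCE * rate)))
    pieces = [sil]
    phonemes: list[PhonemeInterval] = [
        PhonemeInterval(SILENCE_LABEL, 0.0, EDGE_SILENCE)
    ]
    syllables: list[SyllableSpan] = []
    t = EDGE_SILENCE
    for spec in specs:
        samples, (nuc_s, nuc_e) = synth_syllable(
            spec, rate, rng, effective.jitter_sd, effective.shimmer_sd)
        pieces.append(samples)
        syl_end = t + samples.size / rate
        members = []
        if spec.onset is not None:
            members.append(PhonemeInterval(spec.onset, t, t + nuc_s))
        nucleus = PhonemeInterval(spec.vowel, t + nuc_s, syl_end, is_vowel=True)
        members.append(nucleus)
        phonemes.extend(members)
        syllables.append(SyllableSpan(members, nucleus))
        t = syl_end
    pieces.append(sil)
    phonemes.append(PhonemeInterval(SILENCE_LABEL, t, t + EDGE_SILENCE))
    samples = np.concatenate(pieces)
    wave = Waveform(samples, rate)
    alignment = AlignmentResult(phonemes, syllables)
    return SynthToken(
        word=lex_word.word, waveform=wave, alignment=alignment,
        label=lex_word.pattern, error=error, variant_index=variant,
        effective_contrast=effective.c,
    )


@dataclass
class Corpus:
    tokens: list[SynthToken]
    lexicon: list[LexWord]
    entries: dict[str, PronEntry] = field(init=False)

    def __post_init__(self) -> None:
        self.entries = {w.word: w.pron_entry() for w in self.lexicon}

    def records(self) -> list[TokenRecord]:
        out = []
        for i, tok in enumerate(self.tokens):
            out.append(TokenRecord(
                child_id=tok.child_id, word=tok.word, group=tok.group,
                audio_path=f"{i:05d}_{tok.word}.wav",
                alignment=tok.alignment,
                produced_syllables=tok.produced_syllables,
                target_syllables=self.entries[tok.word].n_syllables,
            ))
        return out

    def write(self, out_dir: str | Path) -> Path:
        """Write WAVs, TextGrids, the dictionary and the manifest CSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, tok in enumerate(self.tokens):
            stem = f"{i:05d}_{tok.word}"
            write_wav(tok.waveform, out_dir / f"{stem}.wav")
            write_textgrid(tok.alignment, out_dir / f"{stem}.TextGrid", tok.word)
            rows.append([tok.child_id, tok.word, tok.group, f"{stem}.wav", "",
                         tok.label, tok.error or "", tok.variant_index,
                         tok.produced_syllables,
                         self.entries[tok.word].n_syllables])
        dict_lines = []
        for word, entry in self.entries.items():
            for variant in entry.variants:
                pron = " . ".join(" ".join(s) for s in variant.syllables)
                dict_lines.append(f"{word}\t{pron}")
        (out_dir / "lexicon.dict").write_text("\n".join(dict_lines) + "\n")
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["child_id", "word", "group", "audio_path", "rating",
                             "label", "error", "variant", "produced_syllables",
                             "target_syllables"])
            writer.writerows(rows)
        return out_dir


def generate_corpus(
    n_tokens: int,
    pattern_mix: dict[str, int] | None = None,
    contrast: ContrastConfig | None = None,
    error_rates: dict[str, float] | None = None,
    seed: int = 0,
    rate: int = 16000,
    n_syllables: tuple[int, int] = (3, 5),
    group: str = "TD",
    n_children: int = 10,
    out_dir: str | Path | None = None,
) -> Corpus:
    """Generate a labelled corpus of synthetic word tokens.

    ``pattern_mix`` gives the number of lexicon words per stress pattern
    (default 28 SW / 12 WS / 10 SS, the stimulus proportions the generator
    emulates); tokens cycle through the lexicon.  ``error_rates`` holds
    ``p_deletion`` (weak-syllable deletion; such tokens fail the syllable
    structure filter) and ``p_equalization`` (rendered without stress
    contrast but keeping the canonical label).
    """
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    pattern_mix = pattern_mix or {"SW": 28, "WS": 12, "SS": 10}
    contrast = contrast or ContrastConfig()
    rates = {"p_deletion": 0.0, "p_equalization": 0.0, **(error_rates or {})}
    for k, v in rates.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{k} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lexicon = build_lexicon(pattern_mix, seed=seed, n_syllables=n_syllables)
    tokens = []
    for i in range(n_tokens):
        lex = lexicon[i % len(lexicon)]
        error = None
        u = rng.random()
        if u < rates["p_deletion"]:
            error = "syllable_deletion"
        elif u < rates["p_deletion"] + rates["p_equalization"]:
            error = "stress_equalization"
        tok = synth_word(
            lex.pattern, contrast=contrast, seed=int(rng.integers(2**31)),
            rate=rate, lex_word=lex, variant=1, error=error,
        )
        tok.child_id = f"child{(i % n_children) + 1:02d}"
        tok.group = group
        tokens.append(tok)
    corpus = Corpus(tokens, lexicon)
    if out_dir is not None:
        corpus.write(out_dir)
    return corpus


# ---------------------------------------------------------------------------
# simulated perceptual ratings
# ---------------------------------------------------------------------------

_PATTERN_SIGN = {"SW": 1.0, "WS": -1.0, "SS": 0.0}

#: Default rater noise SD, calibrated once by simulation so that two
#: independent simulated raters reach linear weighted kappa around 0.7 at
#: the default thresholds (the regime of experienced human raters).
DEFAULT_RATER_NOISE_SD = 0.40

DEFAULT_THRESHOLDS = (-0.6, -0.2, 0.2, 0.6)


def simulate_ratings(
    tokens: list[SynthToken],
    rater_noise_sd: float = DEFAULT_RATER_NOISE_SD,
    thresholds: tuple[float, float, float, float] = DEFAULT_THRESHOLDS,
    seed: int = 0,
    n_raters: int = 1,
) -> list[list]:
    """Simulated 5-point Likert ratings, one list per rater.

    The latent score is the signed effective stress contrast of the token
    (positive for SW, negative for WS, 0 for SS or equalized productions)
    plus independent Gaussian rater noise, cut at ``thresholds`` into
    ratings 1..5 (1 = unambiguously WS ... 5 = unambiguously SW).
    """
    from .evaluate import RatingRecord

    th = np.asarray(thresholds, dtype=np.float64)
    if th.size != 4 or np.any(np.diff(th) <= 0):
        raise ValueError("thresholds must be 4 strictly increasing values")
    rng = np.random.default_rng(seed)
    latent = np.array([
        _PATTERN_SIGN[tok.label] * tok.effective_contrast for tok in tokens
    ])
    raters = []
    for r in range(n_raters):
        noisy = latent + rater_noise_sd * rng.standard_normal(latent.size)
        likert = np.searchsorted(th, noisy) + 1
        raters.append([
            RatingRecord(token_id=i, likert=int(l))
            for i, l in enumerate(likert)
        ])
    return raters
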