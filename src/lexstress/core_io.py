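"""Domain types and file I/O for the lexical stress classification tool.

Audio is exchanged as RIFF PCM WAV, phoneme alignments as Praat long-format
TextGrids (tiers ``phones``, ``syllables``, ``words``), and pronunciations as a
TAB-separated dictionary with ARPAbet phonemes, ``.``-separated syllables and
stress digits on vowels.  All times are seconds over half-open intervals
``[start, end)``; frame indexing is 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "VOWELS",
    "Waveform",
    "PhonemeInterval",
    "SyllableSpan",
    "AlignmentResult",
    "PronVariant",
    "PronEntry",
    "TokenRecord",
    "FormatError",
    "StructureError",
    "DictionaryParseError",
    "read_wav",
    "write_wav",
    "resample",
    "read_textgrid",
    "write_textgrid",
    "load_pronunciation_dict",
    "parse_pronunciation_lines",
    "syllable_structure_filter",
    "read_manifest",
]

#: ARPAbet vowel symbols (without stress digits).  A dictionary phone is a
#: vowel iff its base symbol is in this set; in TextGrids (where stress digits
#: are stripped) the same set identifies syllable nuclei.
VOWELS = frozenset(
    "aa ae ah ao aw ax ay eh er ey ih iy ow oy uh uw".split()
)

SILENCE_LABEL = "sil"


class FormatError(ValueError):
    """Unreadable or unsupported file content."""


class StructureError(ValueError):
    """Structurally invalid alignment (tiers, overlap, nucleus count)."""


class DictionaryParseError(ValueError):
    """Malformed pronunciation dictionary line."""


def base_phone(symbol: str) -> str:
    """Strip a trailing stress digit from an ARPAbet symbol."""
    return symbol[:-1] if symbol and symbol[-1].isdigit() else symbol


def is_vowel_symbol(symbol: str) -> bool:
    return base_phone(symbol) in VOWELS


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Waveform:
    """Mono audio: float samples in [-1, 1] at ``rate`` Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform must be mono (1-D samples)")
        if self.samples.size < 1:
            raise ValueError("Waveform needs at least one sample")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def segment(self, start: float, end: float) -> np.ndarray:
        """Samples of the half-open interval [start, end) seconds."""
        i0 = max(0, int(round(start * self.rate)))
        i1 = min(self.samples.size, int(round(end * self.rate)))
        return self.samples[i0:i1]


@dataclass
class PhonemeInterval:
    label: str
    start: float
    end: float
    is_vowel: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.label!r}"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SyllableSpan:
    """One syllable: its phonemes and the unique vowel nucleus."""

    phonemes: list[PhonemeInterval]
    nucleus: PhonemeInterval

    def __post_init__(self) -> None:
        if self.nucleus not in self.phonemes:
            raise StructureError("nucleus must be one of the syllable's phonemes")

    @property
    def start(self) -> float:
        return self.phonemes[0].start

    @property
    def end(self) -> float:
        return self.phonemes[-1].end

    @property
    def syllable_duration(self) -> float:
        return self.end - self.start

    @property
    def nucleus_duration(self) -> float:
        return self.nucleus.duration


@dataclass
class AlignmentResult:
    """Per-phoneme intervals plus syllable structure for one word token.

    ``phonemes`` may include leading/trailing silence intervals (label
    ``sil``); those belong to no syllable.
    """

    phonemes: list[PhonemeInterval]
    syllables: list[SyllableSpan]
    log_likelihood: float | None = None
    variant_used: int | None = None

    def __post_init__(self) -> None:
        for a, b in zip(self.phonemes, self.phonemes[1:]):
            if b.start < a.end - 1e-9:
                raise StructureError(
                    f"overlapping intervals: {a.label} [{a.start},{a.end}) vs "
                    f"{b.label} [{b.start},{b.end})"
                )

    @property
    def word_phonemes(self) -> list[PhonemeInterval]:
        return [p for p in self.phonemes if p.label != SILENCE_LABEL]


@dataclass
class PronVariant:
    """One pronunciation: syllables of ARPAbet phones, vowels stress-digited."""

    syllables: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.syllables) < 2:
            raise DictionaryParseError("a variant needs at least 2 syllables")
        for syl in self.syllables:
            marked = [p for p in syl if p[-1].isdigit() and is_vowel_symbol(p)]
            if len(marked) != 1:
                raise DictionaryParseError(
                    f"syllable {' '.join(syl)!r} must have exactly one "
                    "stress-marked vowel"
                )

    @property
    def flat_phones(self) -> list[str]:
        """Phones with stress digits stripped, syllable structure flattened."""
        return [base_phone(p) for syl in self.syllables for p in syl]

    @property
    def stress_digits(self) -> list[int]:
        out = []
        for syl in self.syllables:
            for p in syl:
                if p[-1].isdigit() and is_vowel_symbol(p):
                    out.append(int(p[-1]))
        return out

    @property
    def n_syllables(self) -> int:
        return len(self.syllables)


@dataclass
class PronEntry:
    word: str
    variants: list[PronVariant]
    canonical_stress: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.variants:
            raise DictionaryParseError(f"{self.word}: entry needs >= 1 variant")
        d1, d2 = self.variants[0].stress_digits[:2]
        s1 = "S" if d1 in (1, 2) else "W"
        s2 = "S" if d2 in (1, 2) else "W"
        stress = s1 + s2
        if stress == "WW":
            raise DictionaryParseError(
                f"{self.word}: first two syllables are both unstressed"
            )
        self.canonical_stress = stress

    @property
    def n_syllables(self) -> int:
        return self.variants[0].n_syllables


@dataclass
class TokenRecord:
    """One recorded production of a target word by one child."""

    child_id: str
    word: str
    group: str  # "TD" or "CAS"
    audio_path: str | None = None
    rating: int | None = None
    alignment: AlignmentResult | None = None
    produced_syllables: int | None = None
    target_syllables: int | None = None


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

def read_wav(path: str | Path) -> Waveform:
    """Read a PCM/float WAV as a mono [-1, 1] Waveform (stereo is averaged)."""
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with filename
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(max(abs(np.iinfo(data.dtype).min), np.iinfo(data.dtype).max))
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return Waveform(samples, int(rate))


def write_wav(wave: Waveform, path: str | Path) -> Path:
    """Write 16-bit PCM mono WAV.  Out-of-range samples raise, never clip."""
    if wave.samples.size == 0:
        raise ValueError("cannot write empty waveform")
    peak = float(np.max(np.abs(wave.samples)))
    if peak > 1.0 + 1e-12:
        raise ValueError(
            f"samples exceed [-1, 1] (peak {peak:.4g}); rescale before writing"
        )
    path = Path(path)
    pcm = np.clip(np.round(wave.samples * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, wave.rate, pcm)
    return path


def resample(wave: Waveform, rate: int) -> Waveform:
    """Polyphase resampling to ``rate`` Hz (identity if already there)."""
    if wave.rate == rate:
        return wave
    from math import gcd

    g = gcd(wave.rate, rate)
    out = resample_poly(wave.samples, rate // g, wave.rate // g)
    return Waveform(np.clip(out, -1.0, 1.0), rate)


# ---------------------------------------------------------------------------
# TextGrid I/O (Praat long format)
# ---------------------------------------------------------------------------

_TG_HEADER = (
    'File type = "ooTextFile"\n'
    'Object class = "TextGrid"\n'
    "\n"
)


def write_textgrid(alignment: AlignmentResult, path: str | Path,
                   word: str = "") -> Path:
    """Write ``phones``/``syllables``/``words`` interval tiers.

    Gaps between listed intervals are filled with empty-label intervals so
    every tier tiles [xmin, xmax], as Praat requires.
    """
    path = Path(path)
    phones = alignment.phonemes
    if not phones:
        raise StructureError("alignment has no phoneme intervals")
    xmin = 0.0
    xmax = max(p.end for p in phones)

    def tile(intervals: list[tuple[float, float, str]]) -> list[tuple[float, float, str]]:
        out: list[tuple[float, float, str]] = []
        cur = xmin
        for s, e, lab in intervals:
            if s > cur + 1e-9:
                out.append((cur, s, ""))
            out.append((s, e, lab))
            cur = e
        if cur < xmax - 1e-9:
            out.append((cur, xmax, ""))
        return out

    tiers = [
        ("phones", tile([(p.start, p.end, p.label) for p in phones])),
        ("syllables", tile([(s.start, s.end, f"syl{i + 1}")
                            for i, s in enumerate(alignment.syllables)])),
        ("words", tile([(alignment.syllables[0].start,
                         alignment.syllables[-1].end, word)]
                       if alignment.syllables else [])),
    ]

    lines = [_TG_HEADER]
    lines.append(f"xmin = {xmin:.7f}\nxmax = {xmax:.7f}\n")
    lines.append("tiers? <exists>\n")
    lines.append(f"size = {len(tiers)}\n")
    lines.append("item []:\n")
    for i, (name, intervals) in enumerate(tiers, start=1):
        lines.append(f"    item [{i}]:\n")
        lines.append('        class = "IntervalTier"\n')
        lines.append(f'        name = "{name}"\n')
        lines.append(f"        xmin = {xmin:.7f}\n")
        lines.append(f"        xmax = {xmax:.7f}\n")
        lines.append(f"        intervals: size = {len(intervals)}\n")
        for j, (s, e, lab) in enumerate(intervals, start=1):
            lines.append(f"        intervals [{j}]:\n")
            lines.append(f"            xmin = {s:.7f}\n")
            lines.append(f"            xmax = {e:.7f}\n")
            lines.append(f'            text = "{lab}"\n')
    path.write_text("".join(lines))
    return path


_NUM = r"(-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)"


def _parse_textgrid_tiers(text: str) -> dict[str, list[tuple[float, float, str]]]:
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    item_re = re.compile(r"item \[\d+\]:")
    chunks = item_re.split(text)[1:]
    for chunk in chunks:
        m = re.search(r'name = "([^"]*)"', chunk)
        if m is None:
            continue
        name = m.group(1)
        intervals = []
        for im in re.finditer(
            rf'intervals \[\d+\]:\s*xmin = {_NUM}\s*xmax = {_NUM}\s*text = "([^"]*)"',
            chunk,
        ):
            s, e, lab = float(im.group(1)), float(im.group(2)), im.group(3)
            if lab.strip():
                intervals.append((s, e, lab.strip()))
        tiers[name] = intervals
    return tiers


def read_textgrid(path: str | Path) -> AlignmentResult:
    """Parse a long-format TextGrid into an AlignmentResult.

    Requires tiers named ``phones`` and ``syllables``; the nucleus of each
    syllable is its unique vowel phone (membership in :data:`VOWELS`).
    """
    path = Path(path)
    tiers = _parse_textgrid_tiers(path.read_text())
    for needed in ("phones", "syllables"):
        if needed not in tiers:
            raise StructureError(f"{path}: missing tier {needed!r}")
    phone_iv = tiers["phones"]
    if not phone_iv:
        raise StructureError(f"{path}: empty 'phones' tier")
    phonemes = [
        PhonemeInterval(lab, s, e, is_vowel=is_vowel_symbol(lab))
        for s, e, lab in phone_iv
    ]
    syllables = []
    for s, e, _lab in tiers["syllables"]:
        members = [p for p in phonemes
                   if p.start >= s - 1e-6 and p.end <= e + 1e-6
                   and p.label != SILENCE_LABEL]
        vowels = [p for p in members if p.is_vowel]
        if len(vowels) != 1:
            raise StructureError(
                f"{path}: syllable [{s:.3f},{e:.3f}) has {len(vowels)} vowels"
            )
        syllables.append(SyllableSpan(members, vowels[0]))
    return AlignmentResult(phonemes, syllables)


# ---------------------------------------------------------------------------
# pronunciation dictionary
# ---------------------------------------------------------------------------

def parse_pronunciation_lines(lines: list[str],
                              source: str = "<memory>") -> dict[str, PronEntry]:
    """Parse ``WORD<TAB>phones`` lines; syllables separated by ``.``."""
    variants: dict[str, list[PronVariant]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(None, 1)
        if len(parts) != 2:
            raise DictionaryParseError(
                f"{source}:{lineno}: expected 'WORD<TAB>phonemes'"
            )
        word, pron = parts[0].strip(), parts[1].strip()
        syllables = [syl.split() for syl in pron.split(".")]
        try:
            variant = PronVariant([s for s in syllables if s])
        except DictionaryParseError as exc:
            raise DictionaryParseError(f"{source}:{lineno}: {exc}") from exc
        if word not in variants:
            order.append(word)
        variants.setdefault(word, []).append(variant)
    return {w: PronEntry(w, variants[w]) for w in order}


def load_pronunciation_dict(path: str | Path) -> dict[str, PronEntry]:
    path = Path(path)
    return parse_pronunciation_lines(path.read_text().splitlines(), str(path))


# ---------------------------------------------------------------------------
# token filtering and manifests
# ---------------------------------------------------------------------------

def syllable_structure_filter(
    tokens: list[TokenRecord],
) -> tuple[list[TokenRecord], list[TokenRecord], dict[str, float]]:
    """Exclude productions whose syllable count differs from the target.

    Mirrors the manual pre-filter applied before automated analysis: a token
    is kept iff its produced syllable count equals the dictionary target
    count.  Returns (kept, excluded, per-group exclusion fraction).
    """
    kept: list[TokenRecord] = []
    excluded: list[TokenRecord] = []
    for tok in tokens:
        if tok.produced_syllables is None or tok.target_syllables is None:
            raise ValueError(
                f"token {tok.child_id}/{tok.word} lacks syllable counts"
            )
        (kept if tok.produced_syllables == tok.target_syllables
         else excluded).append(tok)
    fractions: dict[str, float] = {}
    for group in sorted({t.group for t in tokens}):
        n_all = sum(1 for t in tokens if t.group == group)
        n_exc = sum(1 for t in excluded if t.group == group)
        fractions[group] = n_exc / n_all
    return kept, excluded, fractions


MANIFEST_COLUMNS = ["child_id", "word", "group", "audio_path", "rating"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a token manifest CSV (``child_id,word,group,audio_path,rating``).

    Extra columns written by the synthetic corpus generator (label, error,
    variant, produced/target syllable counts) are preserved if present.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    return df
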