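"""End-to-end classification chain and corpus-level training helpers.

``classify_recording`` runs the full tool on one token: forced alignment of
the waveform against its dictionary entry, feature extraction for the first
two syllables, pair-vector construction and the DNN stress call, returning
all intermediates for audit.  Tokens that fail the syllable-structure
precondition get an explicit ``excluded`` status, never a silent guess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aligner import AcousticModel, align_word
from .classifier import StressCall, StressClassifier
from .core_io import AlignmentResult, PronEntry, Waveform
from .features import FeatureConfig, SyllableFeatureSet, extract_syllable_features
from .synthgen import SynthToken
from .vectorize import PairVectorizer, StressVector, VectorConfig, build_pair_vector

__all__ = [
    "ClassificationOutput",
    "classify_recording",
    "token_feature_pair",
    "corpus_to_pairs",
    "train_pipeline_classifier",
]


@dataclass
class ClassificationOutput:
    status: str  # "ok" or "excluded"
    call: StressCall | None
    alignment: AlignmentResult | None
    vector: StressVector | None


def token_feature_pair(
    wave: Waveform,
    alignment: AlignmentResult,
    config: FeatureConfig | None = None,
    pair_index: int = 0,
) -> tuple[SyllableFeatureSet, SyllableFeatureSet]:
    """Features of one adjacent syllable pair (default: first two)."""
    config = config or FeatureConfig()
    s1 = extract_syllable_features(wave, alignment.syllables[pair_index], config)
    s2 = extract_syllable_features(wave, alignment.syllables[pair_index + 1], config)
    return s1, s2


def classify_recording(
    wave: Waveform,
    word: str,
    pron_dict: dict[str, PronEntry],
    acoustic_model: AcousticModel,
    dnn: StressClassifier,
    mode: str = "single",
    vector_config: VectorConfig | None = None,
    feature_config: FeatureConfig | None = None,
    produced_syllables: int | None = None,
    pair_index: int = 0,
) -> ClassificationOutput:
    """Full chain: align -> extract -> vectorize -> classify.

    ``produced_syllables``, when known (e.g. from transcription), enforces
    the syllable-structure pre-filter before any alignment is attempted.
    """
    if word not in pron_dict:
        raise KeyError(f"word {word!r} not in pronunciation dictionary")
    entry = pron_dict[word]
    if produced_syllables is not None and produced_syllables != entry.n_syllables:
        return ClassificationOutput("excluded", None, None, None)
    alignment = align_word(wave, entry, acoustic_model, mode=mode)
    s1, s2 = token_feature_pair(wave, alignment, feature_config, pair_index)
    vector = build_pair_vector(s1, s2, vector_config, word=word,
                               pair_index=pair_index)
    call = dnn.call(vector)
    return ClassificationOutput("ok", call, alignment, vector)


def corpus_to_pairs(
    tokens: list[SynthToken],
    config: FeatureConfig | None = None,
) -> tuple[list[tuple[SyllableFeatureSet, SyllableFeatureSet]], np.ndarray]:
    """Ground-truth-aligned feature pairs and binary labels for training.

    SS-labelled tokens and tokens with a deleted syllable are skipped (the
    classifier is binary and deletions fail the structure filter).
    """
    pairs, labels = [], []
    for tok in tokens:
        if tok.label not in ("SW", "WS") or tok.error == "syllable_deletion":
            continue
        pairs.append(token_feature_pair(tok.waveform, tok.alignment, config))
        labels.append(tok.label)
    return pairs, np.array(labels)


def train_pipeline_classifier(
    train_tokens: list[SynthToken],
    valid_tokens: list[SynthToken],
    N: int = 10,
    seed: int | None = None,
    feature_config: FeatureConfig | None = None,
    **hyper,
) -> tuple[StressClassifier, PairVectorizer]:
    """Fit the vectorizer + classifier on ground-truth-aligned corpora."""
    pairs_tr, y_tr = corpus_to_pairs(train_tokens, feature_config)
    pairs_va, y_va = corpus_to_pairs(valid_tokens, feature_config)
    vec = PairVectorizer(N=N).fit(pairs_tr)
    X_tr = vec.transform(pairs_tr)
    X_va = vec.transform(pairs_va)
    clf = StressClassifier(random_state=seed, **hyper)
    clf.fit(X_tr, y_tr, validation_data=(X_va, y_va))
    return clf, vec
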