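# Methods

This note documents the models, parameter choices and known limits of the
`lexstress` pipeline: what each stage assumes, which knobs matter, what the
synthetic corpus does and does not emulate, and where the design was
genuinely open.

## Forced alignment

Each phone is a 3-state left-to-right HMM without skips; emissions are
2-component diagonal-covariance Gaussian mixtures over standardized
39-dimensional frames (13 MFCCs from a 26-band Mel filterbank, 25 ms
Hamming frames, 10 ms hop, pre-emphasis 0.97, plus delta and delta-delta).
A silence phone `sil` is prepended and appended by default.  Times are
seconds, intervals half-open `[start, end)`, frame indexing 0-based.  Any
input sample rate is accepted; audio is resampled internally to 16 kHz (the
standard ASR band) while files on disk keep their recorded rate.

Training is hard-EM (Viterbi training) rather than Baum–Welch: flat-start
parameters come from a uniform state segmentation of the labelled phone
intervals; each round then re-segments every utterance by constrained
Viterbi and applies one warm-started EM step per state mixture plus
maximum-likelihood transition re-estimation.  Both half-steps are monotone,
so the total alignment log-likelihood is non-decreasing per round (the
`history_` attribute records it; the suite asserts it).  Hard-EM was chosen
because it is simpler, deterministic given the data, and sufficient for
synthetic training material.  Numerical floors: variance 1e-3 (features are
standardized, so this is on unit scale), mixture weights 1e-3 renormalized,
self-loop probabilities clipped to [1e-3, 1−1e-3].

Phone boundaries are read off the maximum-likelihood state path with the
convention that frame *t* represents the slice `[t·hop, (t+1)·hop)`; the
last phone extends to the token end, so boundaries tile the token exactly.
Alignment requires at least one frame per state; shorter tokens raise an
explicit infeasibility error.

In multiple-pronunciation mode every dictionary variant is aligned and the
highest-likelihood one returned (ties to the lowest index).  Because the
variant set in single mode is a subset, the multiple-mode likelihood is
never lower — a property the tests check.

## Acoustic features

The Teager energy operator is the discrete Teager–Kaiser form
ψ(n) = x(n)² − x(n−1)x(n+1); for a sinusoid A·cos(Ωn) it equals
A²sin²(Ω), which the suite verifies to 1e-6 relative error.  f1 is read as
max−min of the ψ profile over the nucleus (the main open reading; an
envelope-based alternative would need an extra smoothing choice).

The pitch tracker uses 40 ms frames at 10 ms hop, normalized
autocorrelation with a 100–600 Hz search range (child voices), voicing
threshold 0.45, and parabolic lag interpolation.  Two robustness measures
address octave errors: among peaks within 1% of the global maximum the
shortest lag wins (suppresses subharmonic picks on strongly periodic
frames), and voiced f0 values are median-filtered over a ±2-frame
neighbourhood (suppresses isolated octave-up errors at vowel onsets).  A
fully unvoiced nucleus yields f6 = f7 = 0 and a `voiced_frames` count of 0
in the feature metadata; the interval shorter than one frame yields an
empty track, not an error.

Mel energies use 27 triangular filters from 50 Hz to Nyquist on 25 ms
frames, log-compressed with floor 1e-10.  Log compression conditions the
classifier input; linear output is a config switch.

## Vectorization

The classifier input for a syllable pair is
`[f1..f7, flat(N x 27 Mel)]` per syllable, first syllable first, total
length 2 × (7 + 27 × N).  N defaults to 10 (≈100 ms of vowel at the 10 ms
hop — enough to cover a typical weak nucleus exactly and the middle of a
long one).  Nuclei longer than N frames keep their middle N; shorter ones
are zero-padded symmetrically with the extra row at the end for odd
deficits, keeping the vowel centered, mirroring the symmetry of the
middle-N truncation.  Per-dimension standardization (sd floored at 1e-8)
is fitted on training vectors only.  The default pair is syllables 1–2;
other adjacent pairs are selectable via `pair_index`.

## Classifier

A numpy feed-forward network: two ReLU hidden layers of 64 and 32 units,
softmax output, cross-entropy loss, He-initialized from the seed.
Minibatch SGD with batch 32 and initial learning rate 0.01; the rate is
halved after 5 epochs without validation improvement, training stops after
15, caps at 200 epochs, and the best-validation-loss snapshot is returned.
All constants are constructor parameters.  Training is bit-reproducible
from the seed.  The label set is binary {SW, WS}; strong–strong words
still receive a binary call, as the deployed tool's did.  Confidence is
the softmax posterior of the predicted class (hence ≥ 0.5); an exact tie
resolves to SW because argmax takes the first index — documented rather
than randomized so predictions stay a pure function of (model, vector).

## Synthetic corpus generator

Source-filter synthesis: each syllable is an optional onset consonant
(10–40 ms; silence+burst plosives, shaped-noise fricatives, low-pass
murmur nasals, formant-glide liquids) followed by a vowel rendered as an
impulse train through two resonators at child-like (raised) formants, with
a 10 ms raised-cosine amplitude envelope.  The f0 contour rises from
0.85 × peak, holds a plateau over the middle 40–60% of the vowel — so at
least one 40 ms analysis frame observes the synthesis peak, making the
round-trip pitch check well-defined — and falls symmetrically.
Multiplicative jitter (sd 0.02) perturbs glottal periods and shimmer
(sd 0.05) the pulse amplitudes.

Stress is realized on exactly the three classic cue dimensions.  At full
contrast (c = 1) a stressed syllable is 1.6× longer, 2.0× louder (+6 dB)
and 1.3× higher-pitched than the unstressed base (0.15 s, amplitude 0.25,
240 Hz); the effective ratio is `ratio**c`, so c = 0 removes all contrast,
emulating inappropriately equalized stress.  Injected production errors:
weak-syllable deletion (the token then fails the syllable-structure
filter, which keeps a token only when produced and target syllable counts
match) and stress equalization (rendered at c = 0, canonical label kept,
so classifier-vs-perception disagreement analyses can be simulated).

The default lexicon mix is 28 SW / 12 WS / 10 SS words of 3–5 syllables,
matching the stimulus proportions of the assessment protocol the package
models.  For classifier-recovery experiments the corpora use a balanced
100-word SW/WS lexicon so that a 100-token validation set contains each
word about once: predictions at zero contrast cluster by word identity,
and distinct words keep the chance-level accuracy binomially calibrated
instead of inflating its variance.

Simulated Likert ratings map a latent score — signed effective contrast
(+ for SW, − for WS, 0 for SS or equalized) plus Gaussian rater noise —
through thresholds (−0.6, −0.2, 0.2, 0.6) onto the 1–5 scale.  The default
noise sd of 0.40 was calibrated once by simulation at n = 1000 so two
independent raters land at linear weighted kappa ≈ 0.70, the regime of
experienced human raters on this task.

What the generator does *not* emulate: coarticulation and transition
dynamics, developmental articulation error patterns beyond deletion and
equalization, room acoustics/noise, and natural spectral diversity.
Passing tests therefore demonstrate internal consistency and recoverability
of the modelled cues, not performance on real child speech; in particular
the near-perfect end-to-end accuracies reflect the clean separation of the
synthetic classes.

## Evaluation statistics

Kappa statistics, Mann–Whitney and Hedges' g are implemented from their
closed forms, because the package pins exact conventions: weighted kappa
uses linear weights |i−j|/(k−1) by default (quadratic by flag) and with two
categories reduces exactly to the unweighted kappa; Mann–Whitney reports
U = min(U1, U2) from midranks and the magnitude of the tie- and
continuity-corrected normal deviate; Hedges' g uses
J = 1 − 3/(4(n1+n2) − 9).  scikit-learn's kappa and scipy's Mann–Whitney
serve as independent cross-checks in the tests.  Correlations and p-values
go through scipy directly.

Conventions where sources were silent: tokens whose collapsed human rating
is "equal" cannot match a binary call and count as disagreements (the
conservative reading); the 2×2 chi-square omits the Yates correction
(the corrected statistic does not reproduce the published sex-ratio value,
the uncorrected one does); the group t statistic is the pooled-variance
form, which reproduces the published PPC and PVC values to within rounding
of their 1-dp input summaries (the published PCC t is reproduced by
neither pooled nor Welch forms from the printed summaries and is not
asserted).  Phoneme accuracy (PCC/PVC/PPC) uses global alignment with
costs match 0 / substitution 1 / indel 1 / vowel↔consonant substitution 2;
a target phoneme is correct only when aligned to an identical produced
phoneme.  Undefined statistics (zero variance, chance agreement 1) return
NaN rather than raising.

## Problem sizes

The test and acceptance runs use deliberately small instances: a 150-token
corpus over a 12-word lexicon for aligner training, 400/100 train/validation
tokens for classifier recovery, 100 tokens for end-to-end and
variant-recovery checks, 500 tokens for rate-recovery and 1000 for the
rating simulation.  These sizes give stable statistics for every assertion
while keeping a full run of suite plus acceptance script in the low minutes
on one CPU.

## Known limitations

* The aligner is monophone with no context modelling; liquid/glide
  boundaries — the hardest case for real speech — are easy in the synthetic
  corpus, so boundary-error figures here are optimistic.
* The classifier is binary; equal-stress productions are forced into SW/WS,
  exactly the failure mode the evaluation statistics are designed to
  quantify.
* Mixture training is hard-EM with one EM step per round; likelihood
  monotonicity holds up to the variance floor.
* The acoustic model and classifier are trained on the same generator
  distribution; no dialect, speaker or channel mismatch is modelled.
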