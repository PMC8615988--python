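"""Agreement and effect-size statistics for tool-vs-human evaluation.

Implements the evaluation toolkit around the stress classifier: collapsing
5-point Likert stress ratings to WS/equal/SW, percent agreement, Cohen's and
weighted kappa, Mann-Whitney U with normal approximation, Hedges' g,
correlation variants, phoneme accuracy metrics (PCC/PVC/PPC) from relational
transcription comparison, and the summary-statistic group tests (pooled
two-sample t from printed summaries, Pearson chi-square on a 2x2 table).

Conventions pinned here: tokens whose collapsed human rating is "equal"
cannot match a binary tool call and count as disagreements; weighted kappa
uses linear weights by default; the chi-square omits the Yates correction;
Mann-Whitney reports U = min(U1, U2) and the magnitude of the tie- and
continuity-corrected normal deviate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import VOWELS, base_phone

__all__ = [
    "RatingRecord",
    "AgreementReport",
    "EffectSizeResult",
    "PhonemeAccuracy",
    "collapse_likert",
    "percent_agreement",
    "cohens_kappa",
    "weighted_kappa",
    "mann_whitney",
    "hedges_g",
    "correlation",
    "phoneme_accuracy",
    "summary_two_sample_t",
    "chi_square_2x2",
    "correctness_partition",
    "build_agreement_report",
]

WS, EQUAL, SW = "WS", "equal", "SW"


@dataclass
class RatingRecord:
    """One 5-point Likert stress rating (1 = unambiguously WS ... 5 = SW)."""

    token_id: int | str
    likert: int
    rater: str = "rater1"

    def __post_init__(self) -> None:
        if self.likert not in (1, 2, 3, 4, 5):
            raise ValueError(f"likert rating must be 1..5, got {self.likert}")

    @property
    def collapsed(self) -> str:
        return collapse_likert(self.likert)


@dataclass
class AgreementReport:
    n: int
    percent_agreement: float
    kappa: float
    weighted_kappa: float | None = None
    stratum: dict = field(default_factory=dict)


@dataclass
class EffectSizeResult:
    U: float
    z: float
    p: float
    g: float


@dataclass
class PhonemeAccuracy:
    PCC: float
    PVC: float
    PPC: float


def collapse_likert(likert: int) -> str:
    """Collapse the 5-point scale: {1,2}->WS, {3}->equal, {4,5}->SW."""
    if likert in (1, 2):
        return WS
    if likert == 3:
        return EQUAL
    if likert in (4, 5):
        return SW
    raise ValueError(f"likert rating must be 1..5, got {likert}")


def percent_agreement(tool, human) -> float:
    """100 x exact matches / n (an 'equal' rating never matches a call)."""
    tool = list(tool)
    human = list(human)
    if len(tool) != len(human):
        raise ValueError("label sequences differ in length")
    if not tool:
        raise ValueError("need at least one token")
    matches = sum(a == b for a, b in zip(tool, human))
    return 100.0 * matches / len(tool)


def _contingency(a, b) -> tuple[np.ndarray, list]:
    a, b = list(a), list(b)
    if len(a) != len(b):
        raise ValueError("label sequences differ in length")
    if not a:
        raise ValueError("need at least one token")
    cats = sorted(set(a) | set(b), key=str)
    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    return table / table.sum(), cats


def cohens_kappa(a, b) -> float:
    """Chance-corrected agreement (p_o - p_e)/(1 - p_e); NaN if p_e = 1."""
    table, _ = _contingency(a, b)
    p_o = np.trace(table)
    p_e = float(table.sum(axis=1) @ table.sum(axis=0))
    if abs(1.0 - p_e) < 1e-12:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def weighted_kappa(a, b, weights: str = "linear") -> float:
    """Weighted kappa for ordinal ratings: 1 - sum(w o)/sum(w e).

    Linear weights |i-j|/(k-1) by default; ``weights='quadratic'`` squares
    the distance term.  With 2 categories and linear weights this equals the
    unweighted kappa exactly.
    """
    table, cats = _contingency(a, b)
    k = len(cats)
    if k == 1:
        return float("nan")
    i, j = np.indices((k, k))
    w = np.abs(i - j) / (k - 1)
    if weights == "quadratic":
        w = w**2
    elif weights != "linear":
        raise ValueError("weights must be 'linear' or 'quadratic'")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0))
    denom = float((w * expected).sum())
    if denom < 1e-12:
        return float("nan")
    return float(1.0 - (w * table).sum() / denom)


def mann_whitney(g1, g2) -> tuple[float, float, float]:
    """Mann-Whitney U with normal approximation.

    Returns (U, z, p): U = min(U1, U2) from midrank rank sums, z the
    magnitude of the tie- and continuity-corrected normal deviate, p the
    two-sided asymptotic probability.
    """
    x = np.asarray(g1, dtype=np.float64)
    y = np.asarray(g2, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u), 0.0, 1.0
    z = max(0.0, (mu - u - 0.5)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(z)
    return float(u), float(z), float(min(p, 1.0))


def hedges_g(g1, g2) -> float:
    """Bias-corrected standardized mean difference J * (m1 - m2)/s_pooled
    with J = 1 - 3/(4(n1+n2) - 9); NaN when the pooled SD is zero."""
    x = np.asarray(g1, dtype=np.float64)
    y = np.asarray(g2, dtype=np.float64)
    n1, n2 = x.size, y.size
    if n1 + n2 < 3:
        raise ValueError("need at least 3 observations in total")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        return float("nan") if x.mean() != y.mean() else 0.0
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(J * (x.mean() - y.mean()) / np.sqrt(sp2))


def correlation(x, y, method: str = "pearson") -> float:
    """Pearson / Spearman (midranks) / point-biserial correlation."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length sequences of >= 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "point_biserial":
        binary, cont = (x, y) if np.isin(x, (0, 1)).all() else (y, x)
        if not np.isin(binary, (0, 1)).all():
            raise ValueError("point_biserial requires one binary variable")
        return float(stats.pointbiserialr(binary.astype(int), cont).statistic)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# phoneme accuracy (relational analysis)
# ---------------------------------------------------------------------------

def _align_costs(a: str, b: str) -> float:
    if a == b:
        return 0.0
    av = base_phone(a) in VOWELS
    bv = base_phone(b) in VOWELS
    return 2.0 if av != bv else 1.0


def phoneme_accuracy(target: list[str], produced: list[str]) -> PhonemeAccuracy:
    """PCC/PVC/PPC from a global alignment of produced against target.

    Costs: match 0, substitution 1 (2 across the vowel/consonant boundary),
    insertion/deletion 1.  A target phoneme counts as correct iff it aligns
    to an identical produced phoneme.
    """
    if not target:
        raise ValueError("target phoneme sequence must be non-empty")
    n, m = len(target), len(produced)
    D = np.zeros((n + 1, m + 1))
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = min(
                D[i - 1, j - 1] + _align_costs(target[i - 1], produced[j - 1]),
                D[i - 1, j] + 1.0,
                D[i, j - 1] + 1.0,
            )
    correct = np.zeros(n, dtype=bool)
    i, j = n, m
    while i > 0 and j > 0:
        sub = D[i - 1, j - 1] + _align_costs(target[i - 1], produced[j - 1])
        if abs(D[i, j] - sub) < 1e-12:
            correct[i - 1] = target[i - 1] == produced[j - 1]
            i, j = i - 1, j - 1
        elif abs(D[i, j] - (D[i - 1, j] + 1.0)) < 1e-12:
            i -= 1
        else:
            j -= 1
    is_vowel = np.array([base_phone(p) in VOWELS for p in target])

    def pct(mask: np.ndarray) -> float:
        return 100.0 * correct[mask].sum() / mask.sum() if mask.any() else float("nan")

    return PhonemeAccuracy(
        PCC=pct(~is_vowel), PVC=pct(is_vowel),
        PPC=100.0 * correct.sum() / n,
    )


# ---------------------------------------------------------------------------
# summary-statistic group tests
# ---------------------------------------------------------------------------

def summary_two_sample_t(m1: float, sd1: float, n1: int,
                         m2: float, sd2: float, n2: int) -> float:
    """Pooled-variance two-sample t statistic from printed group summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if sp2 <= 0:
        return float("nan")
    return float((m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))


def chi_square_2x2(counts) -> float:
    """Pearson chi-square without continuity correction on a 2x2 table."""
    t = np.asarray(counts, dtype=np.float64)
    if t.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in the 2x2 table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    return float(((t - expected) ** 2 / expected).sum())


# ---------------------------------------------------------------------------
# rating partitions and stratified agreement
# ---------------------------------------------------------------------------

def correctness_partition(
    ratings: list[RatingRecord], canonical: list[str],
) -> tuple[list[RatingRecord], list[RatingRecord], list[RatingRecord]]:
    """Split rated tokens into perceptually correct vs incorrect productions.

    A production is incorrect iff its collapsed rating is "equal" or points
    opposite to the dictionary-defined canonical pattern.  SS-canonical
    tokens are excluded (third return value): the binary rule is undefined
    for them.
    """
    if len(ratings) != len(canonical):
        raise ValueError("ratings and canonical labels differ in length")
    correct, incorrect, skipped = [], [], []
    for rec, canon in zip(ratings, canonical):
        if canon not in (SW, WS):
            skipped.append(rec)
            continue
        col = rec.collapsed
        (correct if col == canon else incorrect).append(rec)
    return correct, incorrect, skipped


def build_agreement_report(
    df: pd.DataFrame,
    strata: tuple[str, ...] = ("group", "stress", "mode"),
) -> dict:
    """Stratified tool-vs-human agreement.

    ``df`` needs columns ``call`` (tool label SW/WS) and ``likert`` (1-5),
    plus the stratification keys.  Tokens collapsing to "equal" count as
    disagreements.  Returns {"pooled": AgreementReport, "strata": {...}};
    empty strata are absent from the mapping.
    """
    for col in ("call", "likert", *strata):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    df = df.copy()
    df["collapsed"] = df["likert"].map(collapse_likert)

    def report(sub: pd.DataFrame, keys: dict) -> AgreementReport:
        return AgreementReport(
            n=len(sub),
            percent_agreement=percent_agreement(sub["call"], sub["collapsed"]),
            kappa=cohens_kappa(sub["call"], sub["collapsed"]),
            stratum=keys,
        )

    out = {"pooled": report(df, {}), "strata": {}}
    if strata:
        for keys, sub in df.groupby(list(strata)):
            if len(sub) == 0:
                continue
            keys = keys if isinstance(keys, tuple) else (keys,)
            out["strata"][keys] = report(sub, dict(zip(strata, keys)))
    return out
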