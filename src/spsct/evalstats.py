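"""Diagnostic-performance statistics for the reader-study protocol.

Covers the scoring rules of a PE reader study (Sørensen–Dice overlap,
non-diagnostic handling, TP/FP/TN/FN assignment, accuracy/sensitivity/
specificity), the nonparametric testing protocol (Shapiro–Wilk normality
gate, two-sided Wilcoxon signed-rank), DeLong AUC machinery with 95% CIs
and the paired two-sided DeLong test, and the dose arithmetic relating
sparse-view protocols to effective dose.

Classification rules: a case rated "not diagnostic" (quality 0) counts as
FN if truly positive else FP; an evaluable positive case is TP iff the
reader's segmentation overlaps the gold standard (Dice > 0) — marking
extra healthy vessels does not spoil a TP — else FN; an evaluable negative
case is TN iff the reader drew no segmentation, else FP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "ReaderRecord",
    "CaseClassification",
    "ConfusionSummary",
    "ROCResult",
    "dice",
    "classify_case",
    "confusion_summary",
    "wilcoxon_signed_rank",
    "shapiro_wilk",
    "delong_auc",
    "delong_test",
    "effective_dose",
    "dose_fraction",
    "read_reader_csv",
    "CHEST_DOSE_FACTOR",
    "FULL_VIEWS",
]

#: Conversion factor from dose-length product (mGy*cm) to effective dose
#: (mSv) for chest CT.
CHEST_DOSE_FACTOR = 0.014

#: View count of a full (non-sparse) acquisition.
FULL_VIEWS = 2048

QUALITY_MAX = 5      # 0 = not diagnostic ... 5 = very high
CONFIDENCE_MAX = 4   # 0 = not confident at all ... 4 = surely confident
ARTIFACTS_MAX = 3    # 0 = a lot of artifacts ... 3 = no artifacts


@dataclass
class ReaderRecord:
    """One reader's assessment of one case."""

    case_id: str
    truth_positive: bool
    quality: int
    confidence: int
    artifacts: int
    segmentation: np.ndarray | None = None

    def __post_init__(self):
        if not 0 <= self.quality <= QUALITY_MAX:
            raise ValueError(f"quality must be in [0, {QUALITY_MAX}]")
        if not 0 <= self.confidence <= CONFIDENCE_MAX:
            raise ValueError(f"confidence must be in [0, {CONFIDENCE_MAX}]")
        if not 0 <= self.artifacts <= ARTIFACTS_MAX:
            raise ValueError(f"artifacts must be in [0, {ARTIFACTS_MAX}]")
        if self.segmentation is not None:
            self.segmentation = np.asarray(self.segmentation).astype(bool)
            if not self.segmentation.any():
                self.segmentation = None  # an empty drawing is no drawing


@dataclass
class CaseClassification:
    outcome: str  # TP | FP | TN | FN
    sdc: float | None
    non_diagnostic: bool

    def __post_init__(self):
        if self.outcome not in ("TP", "FP", "TN", "FN"):
            raise ValueError(f"invalid outcome {self.outcome!r}")


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ROCResult:
    auc: float
    ci95: tuple
    variance: float

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.auc <= hi):
            raise ValueError("CI must bracket the AUC")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Sørensen–Dice coefficient ``2|a∩b| / (|a|+|b|)``.

    Two empty masks agree on absence and score 1; exactly one empty mask
    scores 0.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def classify_case(rec: ReaderRecord, gold: np.ndarray) -> CaseClassification:
    """Apply the reader-study outcome rules to one record.

    ``gold`` is the consensus ground-truth mask; it must be non-empty
    exactly for truly positive cases.
    """
    gold = np.asarray(gold).astype(bool)
    if bool(gold.any()) != bool(rec.truth_positive):
        raise ValueError(
            "gold mask inconsistent with truth label "
            f"(case {rec.case_id}: truth_positive={rec.truth_positive}, "
            f"gold has {int(gold.sum())} pixels)"
        )
    seg = rec.segmentation
    sdc = dice(seg, gold) if seg is not None else None
    if rec.quality == 0:
        outcome = "FN" if rec.truth_positive else "FP"
        return CaseClassification(outcome=outcome, sdc=sdc, non_diagnostic=True)
    if rec.truth_positive:
        outcome = "TP" if (seg is not None and dice(seg, gold) > 0.0) else "FN"
    else:
        outcome = "TN" if seg is None else "FP"
    return CaseClassification(outcome=outcome, sdc=sdc, non_diagnostic=False)


def confusion_summary(classifications) -> ConfusionSummary:
    """Accuracy, sensitivity and specificity from case classifications.

    Ratios with a zero denominator are reported as ``None`` rather than
    NaN-propagated.
    """
    classifications = list(classifications)
    if not classifications:
        raise ValueError("need at least one classification")
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for c in classifications:
        outcome = c.outcome if isinstance(c, CaseClassification) else str(c)
        counts[outcome] += 1
    tp, fp, tn, fn = counts["TP"], counts["FP"], counts["TN"], counts["FN"]
    n = tp + fp + tn + fn
    acc = (tp + tn) / n if n else None
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn,
                            accuracy=acc, sensitivity=sens, specificity=spec)


def _exact_signrank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided sign-flip p-value for the signed-rank statistic.

    Works with midranks (ties): doubling every rank makes all values
    integral, and the 2^n sign-flip distribution of W+ is built by
    polynomial convolution over those integers.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    coeffs = np.zeros(total + 1, dtype=np.float64)
    coeffs[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(coeffs)
        shifted[r:] = coeffs[: coeffs.size - r]
        coeffs = coeffs + shifted
    coeffs /= 2.0 ** len(r2)
    w2 = int(np.rint(2.0 * w_plus))
    cdf = float(coeffs[: w2 + 1].sum())
    sf = float(coeffs[w2:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_signed_rank(x, y, exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped. For up to ``exact_max_n`` non-zero pairs
    the p-value is computed from the exact sign-flip distribution (valid
    under ties via midranks); beyond that, the normal approximation with
    tie correction is used. Returns ``(W+, p)``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test is degenerate")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_signrank_p(ranks, w_plus)
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        z = (w_plus - mu) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return w_plus, p


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro–Wilk normality test (gate for the nonparametric protocol)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0.0:
        raise ValueError("constant sample; normality test is degenerate")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and DeLong structural components V10 (positives), V01 (negatives)."""
    pos = scores[labels]
    neg = scores[~labels]
    # psi(x, y) = 1[x > y] + 0.5 * 1[x == y], vectorized over all pairs
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(np.float64) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(v10.mean()), v10, v01


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return scores, labels


def delong_auc(scores, labels) -> ROCResult:
    """Empirical AUC with DeLong variance and a Wald 95% CI.

    Ties between a positive and a negative score count one half. The CI
    is truncated to [0, 1].
    """
    scores, labels = _check_scores_labels(scores, labels)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = v10.size, v01.size
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = stats.norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    return ROCResult(
        auc=auc,
        ci95=(max(0.0, auc - half), min(1.0, auc + half)),
        variance=var,
    )


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired two-sided DeLong comparison of two AUCs on the same cases.

    Returns ``(z, p)``. Identical score vectors give z=0, p=1.
    """
    scores_a, labels = _check_scores_labels(scores_a, labels)
    scores_b, labels_b = _check_scores_labels(scores_b, labels)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors must cover the same cases")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    if m > 1:
        s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    delta = auc_a - auc_b
    if var_diff <= 0.0:
        if delta == 0.0:
            return 0.0, 1.0
        return float(np.sign(delta) * np.inf), 0.0
    z = delta / np.sqrt(var_diff)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return float(z), p


def effective_dose(dlp: float) -> float:
    """Effective dose (mSv) from dose-length product (mGy*cm) via the
    chest conversion factor 0.014."""
    if dlp < 0:
        raise ValueError("DLP must be non-negative")
    return dlp * CHEST_DOSE_FACTOR


def dose_fraction(n_views: int, full_views: int = FULL_VIEWS) -> float:
    """Dose of an ``n_views`` protocol relative to the full acquisition,
    assuming dose scales linearly with the number of views."""
    if not 1 <= n_views <= full_views:
        raise ValueError(f"n_views must be in [1, {full_views}]")
    return n_views / full_views


def read_reader_csv(path: str | Path, mask_root: str | Path | None = None):
    """Ingest reader records from CSV.

    Expected columns: ``case_id, truth_positive, quality, confidence,
    artifacts`` and optionally ``mask_path`` pointing at a ``.npy`` mask
    (resolved against ``mask_root`` when relative).
    """
    import pandas as pd

    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        seg = None
        mask_path = row.get("mask_path")
        if isinstance(mask_path, str) and mask_path:
            p = Path(mask_path)
            if mask_root is not None and not p.is_absolute():
                p = Path(mask_root) / p
            seg = np.load(p)
        records.append(
            ReaderRecord(
                case_id=str(row["case_id"]),
                truth_positive=bool(row["truth_positive"]),
                quality=int(row["quality"]),
                confidence=int(row["confidence"]),
                artifacts=int(row["artifacts"]),
                segmentation=seg,
            )
        )
    return records
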