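"""Screening-test evaluation statistics for calcium-score cohorts.

This module reproduces the evaluation stack used to assess a calcium
score as a screening test for chronic mesenteric ischemia (CMI):

* interobserver agreement via the intraclass correlation coefficient
  (two-way random effects, single rater, absolute agreement — ICC(2,1) —
  by default, with F-distribution confidence intervals);
* ROC curves with trapezoidal AUC (equal to the tie-corrected
  Mann–Whitney statistic) and DeLong confidence intervals;
* cutoff selection by Youden's J with the midpoint convention;
* 2×2 screening metrics (sensitivity, specificity, PPV, NPV) and the
  fraction of the whole cohort correctly ruled out;
* nonparametric group comparisons (Wilcoxon rank-sum, chi-square /
  Fisher's exact) and the exact paired sign test;
* median (IQR) summaries with linear-interpolation quartiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .agatston import MacsProfile

logger = logging.getLogger(__name__)

SCORE_FIELDS = ("ca", "sma", "ima", "ca_sma", "total")

GROUP_DISEASED = "CMI"
GROUP_HEALTHY = "non-CMI"


@dataclass
class CohortRecord:
    """One patient: identifier, disease label and MACS profile."""

    patient_id: str
    group: str  # "CMI" or "non-CMI"
    profile: MacsProfile
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in (GROUP_DISEASED, GROUP_HEALTHY):
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def diseased(self) -> bool:
        return self.group == GROUP_DISEASED


# ---------------------------------------------------------------------------
# intraclass correlation

ICC_BANDS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (math.inf, "excellent"))


def icc_band(value: float) -> str:
    """Qualitative agreement band: <0.5 poor, 0.5–0.75 moderate,
    0.75–0.9 good, ≥0.9 excellent."""
    for upper, name in ICC_BANDS:
        if value < upper:
            return name
    return "excellent"


@dataclass
class IccResult:
    icc: float
    ci95: tuple[float, float]
    model: str
    n_subjects: int
    n_raters: int

    @property
    def band(self) -> str:
        return icc_band(self.icc)


def icc(ratings: np.ndarray, model: str = "ICC2", alpha: float = 0.05) -> IccResult:
    """Intraclass correlation of a subjects × raters rating matrix.

    Models
    ------
    ``"ICC2"`` (default): two-way random effects, single rater, absolute
    agreement — the interobserver-agreement model when raters are a
    random sample and systematic rater offsets count as disagreement.
    ``"ICC3"``: two-way mixed, single rater, consistency.

    Confidence intervals use the standard F-distribution construction
    (Shrout–Fleiss / McGraw–Wong); degenerate perfect-agreement tables
    collapse the interval onto the point estimate.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2D subjects × raters matrix")
    n, k = ratings.shape
    if n < 5:
        raise ValueError(f"need at least 5 subjects, got {n}")
    if k < 2:
        raise ValueError(f"need at least 2 raters, got {k}")
    if np.isnan(ratings).any():
        raise ValueError("ratings contain missing cells")

    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((ratings - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)            # between-subject mean square
    msc = ss_cols / (k - 1)            # between-rater mean square
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)  # residual

    if msr <= 0:
        raise ValueError(
            "ratings are constant across subjects; ICC is undefined"
        )

    if model == "ICC2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom <= 0:
            raise ValueError("degenerate ANOVA table; ICC undefined")
        value = (msr - mse) / denom
        ci = _icc2_ci(value, msr, msc, mse, n, k, alpha)
    elif model == "ICC3":
        denom = msr + (k - 1) * mse
        if denom <= 0:
            raise ValueError("degenerate ANOVA table; ICC undefined")
        value = (msr - mse) / denom
        ci = _icc3_ci(msr, mse, n, k, alpha)
    else:
        raise ValueError(f"unknown ICC model {model!r}")

    lo = min(max(ci[0], -1.0), value)
    hi = max(min(ci[1], 1.0), value)
    return IccResult(icc=float(value), ci95=(float(lo), float(hi)),
                     model=model, n_subjects=n, n_raters=k)


def _icc2_ci(value, msr, msc, mse, n, k, alpha):
    if mse == 0 and msc == 0:
        return (value, value)  # perfect agreement: no residual variance
    a = (k * value) / (n * (1 - value)) if value < 1 else math.inf
    b = 1 + (k * value * (n - 1)) / (n * (1 - value)) if value < 1 else math.inf
    if not math.isfinite(a) or not math.isfinite(b):
        return (value, value)
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else (n - 1) * (k - 1)
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (n * (msr - f_l * mse)
             / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
    upper = (n * (f_u * msr - mse)
             / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    return (lower, upper)


def _icc3_ci(msr, mse, n, k, alpha):
    if mse == 0:
        return (1.0, 1.0)
    f_obs = msr / mse
    df2 = (n - 1) * (k - 1)
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, n - 1)
    return ((f_l - 1) / (f_l + k - 1), (f_u - 1) / (f_u + k - 1))


# ---------------------------------------------------------------------------
# ROC / AUC

AUC_BANDS = (
    (0.7, "no/poor discrimination"),
    (0.8, "acceptable"),
    (0.9, "excellent"),
    (math.inf, "outstanding"),
)


def auc_band(value: float) -> str:
    """Discriminative-ability band: 0.7–0.8 acceptable, 0.8–0.9
    excellent, ≥0.9 outstanding; 0.5 means no discrimination."""
    for upper, name in AUC_BANDS:
        if value < upper:
            return name
    return "outstanding"


@dataclass
class RocResult:
    thresholds: np.ndarray  # descending candidate cutoffs (first is +inf)
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_ci95: tuple[float, float]
    n_diseased: int
    n_healthy: int
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    @property
    def discrimination_band(self) -> str:
        return auc_band(self.auc)


def roc(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """ROC curve, trapezoidal AUC and DeLong 95% CI.

    ``labels`` are truthy for diseased.  A test is positive when its
    score is at or above a threshold.  The trapezoidal AUC over all
    unique thresholds equals the Mann–Whitney statistic with ties
    counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D and equal length")
    n_dis = int(labels.sum())
    n_hea = int((~labels).sum())
    if n_dis == 0 or n_hea == 0:
        raise ValueError("both diseased and healthy subjects are required")

    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    ci = _delong_ci(scores, labels)
    return RocResult(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc, auc_ci95=ci,
        n_diseased=n_dis, n_healthy=n_hea, scores=scores, labels=labels,
    )


def _delong_ci(scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05):
    """DeLong variance of the AUC via midrank placements."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (all_ranks[:m] - pos_ranks) / n          # placements of diseased
    v10 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # placements of healthy
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s01 / m + s10 / n)
    z = stats.norm.ppf(1 - alpha / 2)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def select_cutoff(roc_result: RocResult) -> float:
    """Cutoff maximising Youden's J = sensitivity + specificity − 1.

    Ties are broken toward higher sensitivity (the screening use case
    favours not missing disease).  The returned cutoff is the midpoint
    between the selected threshold and the next lower observed score,
    so perfectly separated classes yield the midpoint of the gap.  If
    every score is identical, J is 0 everywhere and the minimum score
    is returned with a warning.
    """
    thr = roc_result.thresholds
    j = roc_result.tpr - roc_result.fpr
    # skip the +inf sentinel; candidates are the observed unique scores
    finite = np.isfinite(thr)
    if not finite.any() or np.all(np.isclose(j[finite], 0.0)):
        unique = np.unique(roc_result.scores)
        if len(unique) == 1:
            logger.warning("all scores identical; no discriminating cutoff exists")
            return float(unique[0])
    cand = np.nonzero(finite)[0]
    best_j = j[cand].max()
    best = [i for i in cand if np.isclose(j[i], best_j)]
    # thresholds are descending: the last tied index has the lowest
    # cutoff and therefore the highest sensitivity
    i = best[-1]
    chosen = thr[i]
    lower = thr[i + 1] if i + 1 < len(thr) else None
    if lower is not None and np.isfinite(lower):
        return float((chosen + lower) / 2.0)
    return float(chosen)


# ---------------------------------------------------------------------------
# screening metrics

@dataclass
class ScreeningMetrics:
    """2×2 confusion counts and derived screening percentages.

    Percentages are stored unrounded; :meth:`rounded` gives the
    one-decimal reporting form.  ``ppv``/``npv`` are ``None`` when their
    denominator is empty.  ``negative_fraction_non_cmi`` is the share of
    the *whole* cohort that tests negative and is disease-free — the
    fraction of patients in whom further workup could be avoided.
    """

    cutoff: Optional[float]
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppv: Optional[float] = field(init=False)
    npv: Optional[float] = field(init=False)
    negative_fraction_non_cmi: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.fn == 0:
            raise ValueError("no diseased subjects (tp + fn = 0)")
        if self.tn + self.fp == 0:
            raise ValueError("no healthy subjects (tn + fp = 0)")
        self.sensitivity = 100.0 * self.tp / (self.tp + self.fn)
        self.specificity = 100.0 * self.tn / (self.tn + self.fp)
        self.ppv = (100.0 * self.tp / (self.tp + self.fp)
                    if self.tp + self.fp > 0 else None)
        self.npv = (100.0 * self.tn / (self.tn + self.fn)
                    if self.tn + self.fn > 0 else None)
        total = self.tp + self.fp + self.tn + self.fn
        self.negative_fraction_non_cmi = 100.0 * self.tn / total

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def rounded(self) -> dict:
        """One-decimal reporting form (fractions of the cohort to integer %)."""
        r1 = lambda v: None if v is None else round(v, 1)
        cutoff = self.cutoff
        if cutoff is not None and math.isfinite(cutoff):
            cutoff = round(cutoff, 2)
        return {
            "cutoff": cutoff,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": r1(self.sensitivity),
            "specificity": r1(self.specificity),
            "ppv": r1(self.ppv),
            "npv": r1(self.npv),
            "negative_fraction_non_cmi": round(self.negative_fraction_non_cmi),
        }


def classification_metrics(tp: int, fp: int, tn: int, fn: int,
                           cutoff: Optional[float] = None) -> ScreeningMetrics:
    """Screening metrics from a 2×2 confusion table."""
    return ScreeningMetrics(cutoff=cutoff, tp=tp, fp=fp, tn=tn, fn=fn)


def cohort_scores(cohort: Sequence[CohortRecord], score_field: str) -> np.ndarray:
    if score_field.lower() not in SCORE_FIELDS:
        raise ValueError(f"unknown score field {score_field!r}; "
                         f"choose from {SCORE_FIELDS}")
    return np.array([rec.profile.score(score_field) for rec in cohort], dtype=float)


def apply_cutoff(cohort: Sequence[CohortRecord], score_field: str,
                 cutoff: float) -> ScreeningMetrics:
    """Dichotomise a cohort at a cutoff (positive iff score ≥ cutoff)."""
    scores = cohort_scores(cohort, score_field)
    diseased = np.array([rec.diseased for rec in cohort], dtype=bool)
    if diseased.all() or not diseased.any():
        raise ValueError("cohort must contain both groups")
    positive = scores >= cutoff
    return ScreeningMetrics(
        cutoff=float(cutoff),
        tp=int((positive & diseased).sum()),
        fp=int((positive & ~diseased).sum()),
        tn=int((~positive & ~diseased).sum()),
        fn=int((~positive & diseased).sum()),
    )


# ---------------------------------------------------------------------------
# group comparisons

@dataclass
class GroupComparison:
    test: str
    statistic: float
    pvalue: float
    note: str = ""


def compare_groups(values_a: Sequence, values_b: Sequence,
                   kind: str = "continuous") -> GroupComparison:
    """Two-group comparison as used for baseline and score tables.

    ``continuous``: two-sided Wilcoxon rank-sum (Mann–Whitney U, exact
    for small tie-free samples, tie-corrected normal approximation
    otherwise).  ``categorical``: values are category labels; a group ×
    category contingency table is tested with chi-square, switching to
    Fisher's exact when any expected cell count is below 5 (2×2 only).
    """
    if len(values_a) == 0 or len(values_b) == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "continuous":
        res = stats.mannwhitneyu(values_a, values_b, alternative="two-sided",
                                 method="auto")
        return GroupComparison("wilcoxon-rank-sum", float(res.statistic),
                               float(res.pvalue))
    if kind == "categorical":
        a = pd.Series(list(values_a), dtype="object")
        b = pd.Series(list(values_b), dtype="object")
        table = pd.crosstab(
            pd.Series(["a"] * len(a) + ["b"] * len(b)),
            pd.concat([a, b], ignore_index=True),
        ).to_numpy()
        return contingency_test(table)
    raise ValueError(f"unknown comparison kind {kind!r}")


def contingency_test(table: np.ndarray) -> GroupComparison:
    """Chi-square test of a contingency table, Fisher's exact for sparse 2×2.

    The switch to the exact test fires when any expected cell count is 5
    or fewer — the conservative reading of the small-expected-count rule
    (the exact test is never invalid for a 2×2 table).
    """
    table = np.asarray(table)
    expected = stats.contingency.expected_freq(table)
    if (expected <= 5).any():
        if table.shape == (2, 2):
            odds, p = stats.fisher_exact(table)
            return GroupComparison("fisher-exact", float(odds), float(p))
        note = "expected cell < 5 but table larger than 2x2; chi-square kept"
        logger.warning(note)
    else:
        note = ""
    chi2, p, _, _ = stats.chi2_contingency(table)
    return GroupComparison("chi-square", float(chi2), float(p), note=note)


@dataclass
class SignTestResult:
    pvalue: float
    n_positive: int
    n_negative: int
    n_zero: int

    @property
    def n_informative(self) -> int:
        return self.n_positive + self.n_negative


def sign_test(paired_a: Sequence[float], paired_b: Sequence[float]) -> SignTestResult:
    """Exact two-sided sign test on paired measurements.

    Tests whether ``b`` tends to exceed ``a`` using only the sign of the
    within-pair differences; zero differences are dropped (their count
    is reported).  The p-value is the exact two-sided binomial tail.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("paired samples must be 1D, equal length, non-empty")
    diff = b - a
    n_pos = int((diff > 0).sum())
    n_neg = int((diff < 0).sum())
    n_zero = int((diff == 0).sum())
    n = n_pos + n_neg
    if n == 0:
        logger.warning("all paired differences are zero; sign test uninformative")
        return SignTestResult(pvalue=1.0, n_positive=0, n_negative=0, n_zero=n_zero)
    p = stats.binomtest(n_pos, n, 0.5, alternative="two-sided").pvalue
    return SignTestResult(pvalue=float(p), n_positive=n_pos,
                          n_negative=n_neg, n_zero=n_zero)


# ---------------------------------------------------------------------------
# summaries

@dataclass
class MedianIqr:
    median: float
    q1: float
    q3: float
    n: int

    def __str__(self) -> str:
        return f"{self.median:g} ({self.q1:g}–{self.q3:g})"


def median_iqr(values: Sequence[float]) -> MedianIqr:
    """Median and interquartile range, quartiles by linear interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return MedianIqr(median=float(med), q1=float(q1), q3=float(q3), n=int(v.size))


def summarize_scores(cohort: Sequence[CohortRecord],
                     score_field: str) -> dict[str, MedianIqr]:
    """Per-group median (IQR) of one score field, keyed by group name."""
    scores = cohort_scores(cohort, score_field)
    out: dict[str, MedianIqr] = {}
    for group in (GROUP_DISEASED, GROUP_HEALTHY):
        sel = [s for s, rec in zip(scores, cohort) if rec.group == group]
        if sel:
            out[group] = median_iqr(sel)
    return out


# ---------------------------------------------------------------------------
# cohort table I/O

def cohort_from_frame(frame: pd.DataFrame) -> list[CohortRecord]:
    """Build cohort records from a table with columns ``patient_id``,
    ``group`` and ``macs_ca``/``macs_sma``/``macs_ima`` (combined fields
    are computed, never stored)."""
    from .agatston import ArteryScore

    required = {"patient_id", "group", "macs_ca", "macs_sma", "macs_ima"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns {sorted(missing)}")
    if frame["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in cohort table")
    records = []
    for row in frame.itertuples(index=False):
        profile = MacsProfile(
            ca=ArteryScore("CA", float(row.macs_ca)),
            sma=ArteryScore("SMA", float(row.macs_sma)),
            ima=ArteryScore("IMA", float(row.macs_ima)),
        )
        records.append(CohortRecord(patient_id=str(row.patient_id),
                                    group=str(row.group), profile=profile))
    return records


def load_cohort(path: str) -> list[CohortRecord]:
    return cohort_from_frame(pd.read_csv(path))


def cohort_to_frame(cohort: Sequence[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in cohort],
            "group": [r.group for r in cohort],
            "macs_ca": [r.profile.ca.macs for r in cohort],
            "macs_sma": [r.profile.sma.macs for r in cohort],
            "macs_ima": [r.profile.ima.macs for r in cohort],
        }
    )
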