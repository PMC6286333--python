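"""Screening statistics: ROC/Youden cut-off, repeatability CV, ICC, and
Fisher comparison of correlations.

These are the evaluation tools of the screening system: ROC analysis of the
asymmetry index against radiographic Cobb-angle classes with a Youden-index
cut-off and the usual confusion-matrix metrics; coefficient-of-variation
repeatability with the conventional grading bands; two-way absolute-agreement
single-measure ICC for test-retest reliability; and Pearson correlations
compared through the Fisher r-to-z transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ScreeningRecord",
    "ScreeningDataset",
    "ROCResult",
    "ReliabilityResult",
    "roc_with_youden",
    "screening_metrics",
    "coefficient_of_variation",
    "icc_two_way",
    "pearson_with_fisher_comparison",
    "grade_auc",
    "grade_cv",
    "grade_icc",
]


@dataclass(frozen=True)
class ScreeningRecord:
    subject_id: str
    i_asym: float
    cobb: float
    curve_type: str = "single_thoracic"
    age: float | None = None
    bmi: float | None = None
    sex: str | None = None
    seed: int | None = None


@dataclass
class ScreeningDataset:
    """Paired (asymmetry index, Cobb angle) records."""

    records: list[ScreeningRecord]

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        for r in self.records:
            if r.i_asym < 0 or r.cobb < 0:
                raise ValueError("i_asym and cobb must be non-negative")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def i_asym(self) -> np.ndarray:
        return np.array([r.i_asym for r in self.records])

    @property
    def cobb(self) -> np.ndarray:
        return np.array([r.cobb for r in self.records])

    def stratify(self, curve_type: str) -> "ScreeningDataset":
        return ScreeningDataset([r for r in self.records if r.curve_type == curve_type])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScreeningDataset":
        df = pd.read_csv(path)
        required = {"subject_id", "i_asym", "cobb"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort CSV lacks columns: {sorted(missing)}")
        records = []
        for row_number, row in enumerate(df.itertuples(index=False), start=2):
            d = row._asdict()
            try:
                records.append(
                    ScreeningRecord(
                        subject_id=str(d["subject_id"]),
                        i_asym=float(d["i_asym"]),
                        cobb=float(d["cobb"]),
                        curve_type=str(d.get("curve_type", "single_thoracic")),
                        seed=None if pd.isna(d.get("seed", None)) else int(d["seed"]),
                    )
                )
            except (TypeError, ValueError) as e:
                raise ValueError(f"cohort CSV row {row_number}: {e}") from e
        return cls(records)


def grade_auc(auc: float) -> str:
    if auc >= 0.9:
        return "outstanding"
    if auc >= 0.8:
        return "excellent"
    if auc >= 0.7:
        return "acceptable"
    return "no discrimination"


def grade_cv(cv_percent: float) -> str:
    if cv_percent < 10:
        return "very good"
    if cv_percent <= 20:
        return "good"
    if cv_percent <= 30:
        return "fair/moderate"
    return "poor"


def grade_icc(icc: float) -> str:
    if icc > 0.90:
        return "excellent"
    if icc > 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


@dataclass
class ScreeningMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    plr: float
    nlr: float


def _safe_ratio(num: float, den: float) -> float:
    """num/den with the screening-table conventions: inf for x/0 (x > 0), NaN for 0/0."""
    if den == 0:
        return np.inf if num > 0 else np.nan
    return num / den


def screening_metrics(tp: int, fp: int, tn: int, fn: int) -> ScreeningMetrics:
    """Confusion-matrix screening metrics with infinity conventions.

    A likelihood ratio with a zero denominator and positive numerator is
    reported as infinity (a perfectly specific or perfectly insensitive
    test); 0/0 cases are flagged NaN.
    """
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise ValueError("counts must be non-negative with a positive total")
    sens = _safe_ratio(tp, tp + fn)
    spec = _safe_ratio(tn, tn + fp)
    return ScreeningMetrics(
        sensitivity=sens,
        specificity=spec,
        ppv=_safe_ratio(tp, tp + fp),
        npv=_safe_ratio(tn, tn + fn),
        accuracy=(tp + tn) / (tp + fp + tn + fn),
        plr=_safe_ratio(sens, 1.0 - spec),
        nlr=_safe_ratio(1.0 - sens, spec),
    )


@dataclass
class ROCResult:
    auc: float
    auc_ci_95: tuple[float, float]
    cutoff: float
    metrics: ScreeningMetrics
    discrimination: str
    cobb_threshold: float
    n_positive: int
    n_negative: int

    def to_dict(self) -> dict:
        return {
            "cobb_threshold_deg": self.cobb_threshold,
            "cutoff_mm": self.cutoff,
            "auc": self.auc,
            "auc_ci_95": list(self.auc_ci_95),
            "discrimination": self.discrimination,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            **self.metrics.__dict__,
        }


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float, level: float = 0.95):
    """DeLong variance of the AUC and a Wald confidence interval."""
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = 0.0
    if len(pos) > 1:
        var += np.var(v10, ddof=1) / len(pos)
    if len(neg) > 1:
        var += np.var(v01, ddof=1) / len(neg)
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def _bootstrap_ci(scores, labels, n_boot: int = 2000, seed: int = 0, level: float = 0.95):
    rng = np.random.default_rng(seed)
    n = len(scores)
    aucs = []
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        s, y = scores[idx], labels[idx]
        if y.all() or not y.any():
            continue
        aucs.append(_trapezoid_auc(s, y)[0])
    lo, hi = np.percentile(aucs, [50 * (1 - level), 50 * (1 + level)])
    return float(lo), float(hi)


def _trapezoid_auc(scores: np.ndarray, labels: np.ndarray):
    """Trapezoidal AUC plus the ROC points at every candidate cut-off.

    Cut-offs are midpoints between consecutive distinct scores, bracketed by
    sentinels below the minimum and above the maximum; a subject is predicted
    positive when its score is >= the cut-off.
    """
    distinct = np.unique(scores)
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    cutoffs = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    pred = scores[None, :] >= cutoffs[:, None]
    tpr = (pred & labels[None, :]).sum(axis=1) / n_pos
    fpr = (pred & ~labels[None, :]).sum(axis=1) / n_neg
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return auc, cutoffs, tpr, fpr


def roc_with_youden(
    data: ScreeningDataset,
    cobb_threshold: float,
    ci_method: str = "delong",
    bootstrap_seed: int = 0,
) -> ROCResult:
    """ROC analysis of the asymmetry index against a Cobb-angle class.

    Disease-positive means Cobb angle strictly greater than
    ``cobb_threshold``.  The cut-off maximizing the Youden index
    (sensitivity + specificity - 1) is selected, ties breaking toward the
    lower cut-off so a screening test keeps its sensitivity.
    """
    scores = data.i_asym
    labels = data.cobb > cobb_threshold
    if labels.all() or not labels.any():
        raise ValueError("both Cobb classes must be non-empty")
    auc, cutoffs, tpr, fpr = _trapezoid_auc(scores, labels)
    youden = tpr - fpr
    best = int(np.argmax(youden))  # argmax takes the first = lowest cut-off
    cutoff = float(cutoffs[best])

    pred = scores >= cutoff
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    metrics = screening_metrics(tp, fp, tn, fn)

    if ci_method == "delong":
        ci = _delong_ci(scores[labels], scores[~labels], auc)
    elif ci_method == "bootstrap":
        ci = _bootstrap_ci(scores, labels, seed=bootstrap_seed)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return ROCResult(
        auc=auc,
        auc_ci_95=ci,
        cutoff=cutoff,
        metrics=metrics,
        discrimination=grade_auc(auc),
        cobb_threshold=cobb_threshold,
        n_positive=int(labels.sum()),
        n_negative=int((~labels).sum()),
    )


def sample_with_moments(mean: float, sd: float, n: int = 10) -> np.ndarray:
    """Deterministic sample with exactly the given sample mean and SD.

    Useful for reproducing repeatability summaries reported only as
    mean +/- SD: any downstream statistic that depends on the data solely
    through those two moments (such as the CV) is recovered exactly.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    base = np.arange(n, dtype=float)
    base -= base.mean()
    base /= base.std(ddof=1)
    return mean + sd * base


def coefficient_of_variation(values) -> tuple[float, str]:
    """CV as a percentage (sample SD over mean times 100) with its grade."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("mean must be positive")
    cv = 100.0 * values.std(ddof=1) / mean
    return float(cv), grade_cv(cv)


@dataclass
class ReliabilityResult:
    icc: float
    icc_ci_95: tuple[float, float]
    icc_grade: str


def icc_two_way(measurements: np.ndarray, level: float = 0.95) -> ReliabilityResult:
    """Two-way absolute-agreement single-measure ICC from an n x k table.

    Rows are subjects, columns repeated measurements.  The estimate follows
    the two-way mean-squares decomposition

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with the F-distribution confidence interval of the absolute-agreement
    single-measure form.  Model choice matters: a consistency or averaged
    variant would give different values.
    """
    X = np.asarray(measurements, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need an n x k table with n >= 2 subjects and k >= 2 repeats")
    if np.isnan(X).any():
        raise ValueError("missing cells are not supported")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((X - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return ReliabilityResult(icc=np.nan, icc_ci_95=(np.nan, np.nan), icc_grade="degenerate")
    icc = (msr - mse) / denom

    alpha = 1 - level
    if 1 - icc <= 0 or mse <= 0:
        ci = (icc, icc)
    else:
        # F-distribution interval for the absolute-agreement single-measure
        # form (Satterthwaite degrees of freedom for the denominator)
        fj = msc / mse
        vn = (n - 1) * (k - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
        ci = (float(lower), float(upper))
    return ReliabilityResult(icc=float(icc), icc_ci_95=ci, icc_grade=grade_icc(icc))


def pearson_with_fisher_comparison(x1, y1, x2, y2) -> tuple[float, float, float, float]:
    """Pearson r in two groups and the Fisher r-to-z test of their difference.

    Returns ``(r1, r2, z, p)`` with
    ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))`` and a two-sided
    normal p-value.
    """
    x1, y1, x2, y2 = (np.asarray(a, dtype=float) for a in (x1, y1, x2, y2))
    n1, n2 = len(x1), len(x2)
    if n1 < 4 or n2 < 4:
        raise ValueError("each group needs at least 4 pairs")
    for a in (x1, y1, x2, y2):
        if np.std(a) == 0:
            raise ValueError("zero variance: correlation undefined")
    r1 = float(sps.pearsonr(x1, y1).statistic)
    r2 = float(sps.pearsonr(x2, y2).statistic)
    if abs(r1) >= 1.0 - 1e-12 or abs(r2) >= 1.0 - 1e-12:
        raise ValueError("|r| = 1: Fisher transform diverges")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * sps.norm.sf(abs(z))
    return r1, r2, float(z), float(p)
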