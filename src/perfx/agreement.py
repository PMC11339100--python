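"""Paired-volume agreement statistics.

Everything needed to compare two volumetric measurement methods across
subjects: Pearson correlation with Fisher confidence interval, intraclass
correlation from a subject-random-intercept model (REML, with the one-way
ANOVA estimator as fallback and for its F-based confidence interval),
Bland-Altman bias and limits of agreement, the fixed method effect from a
mixed model ("difference in contrast", DC), Wilcoxon-Mann-Whitney tests and
median/IQR summaries.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PairedVolumes:
    """Per-subject volumes measured by two methods (A and B), in ml."""

    subject: np.ndarray
    a: np.ndarray
    b: np.ndarray
    method_a: str = "A"
    method_b: str = "B"
    covariate: np.ndarray | None = None

    def __post_init__(self):
        self.subject = np.asarray(self.subject)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (len(self.subject) == len(self.a) == len(self.b)):
            raise ValueError("subject, a and b must have equal length")
        if np.any(~np.isfinite(self.a)) or np.any(~np.isfinite(self.b)):
            raise ValueError("paired rows must be complete and finite")

    def __len__(self) -> int:
        return len(self.a)

    @classmethod
    def from_arrays(cls, a, b, **kw) -> "PairedVolumes":
        a = np.asarray(a, dtype=float)
        return cls(subject=np.arange(len(a)), a=a, b=np.asarray(b, dtype=float), **kw)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, method_a: str, method_b: str,
                   subject_col: str = "subject", method_col: str = "method",
                   value_col: str = "volume_ml") -> "PairedVolumes":
        """Build pairs from a long table with subject/method/value columns."""
        wide = df.pivot_table(index=subject_col, columns=method_col,
                              values=value_col, aggfunc="mean")
        wide = wide.dropna(subset=[method_a, method_b])
        return cls(subject=wide.index.to_numpy(), a=wide[method_a].to_numpy(),
                   b=wide[method_b].to_numpy(), method_a=method_a, method_b=method_b)

    def to_long(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": np.concatenate([self.subject, self.subject]),
            "method": [self.method_a] * len(self) + [self.method_b] * len(self),
            "volume_ml": np.concatenate([self.a, self.b]),
        })


@dataclasses.dataclass
class AgreementReport:
    """Agreement battery for one paired-volume comparison."""

    n: int
    r: float
    r_ci: tuple[float, float]
    r_p: float
    r2: float
    icc: float
    icc_ci: tuple[float, float]
    bias: float
    bias_ci: tuple[float, float]
    loa: tuple[float, float]
    dc: float
    dc_ci: tuple[float, float]
    dc_p: float
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in out.items()}


def pearson_ci(pairs: PairedVolumes, alpha: float = 0.05):
    """Pearson r with Fisher-z confidence interval, two-sided p and r^2."""
    n = len(pairs)
    if n < 4:
        raise ValueError("need at least 4 pairs for a correlation CI")
    if np.std(pairs.a) == 0 or np.std(pairs.b) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(pairs.a, pairs.b)
    ci = res.confidence_interval(1 - alpha)
    r = float(res.statistic)
    return r, (float(ci.low), float(ci.high)), float(res.pvalue), r * r


def _anova_icc(a: np.ndarray, b: np.ndarray, alpha: float = 0.05):
    """One-way random-effects ICC(1,1) with its F-distribution interval."""
    y = np.stack([a, b], axis=1)
    n, k = y.shape
    grand = y.mean()
    msb = k * np.sum((y.mean(axis=1) - grand) ** 2) / (n - 1)
    msw = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2) / (n * (k - 1))
    icc = (msb - msw) / (msb + (k - 1) * msw)
    if msw == 0:
        return 1.0, (1.0, 1.0)
    f0 = msb / msw
    fl = f0 / stats.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
    fu = f0 * stats.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
    lo = (fl - 1) / (fl + k - 1)
    hi = (fu - 1) / (fu + k - 1)
    return float(icc), (float(lo), float(hi))


def icc_mixed(pairs: PairedVolumes, method: str = "reml", alpha: float = 0.05):
    """ICC from a subject-random-intercept model.

    ``method='reml'`` estimates the variance components with statsmodels
    MixedLM (falling back to the ANOVA estimator on non-convergence);
    ``method='anova'`` uses the closed-form one-way estimator directly. On
    balanced data the two coincide. The confidence interval is the exact
    F-distribution interval for ICC(1,1) in both cases.
    """
    n = len(pairs)
    if n < 5:
        raise ValueError("need at least 5 complete pairs for the ICC")
    icc_a, ci = _anova_icc(pairs.a, pairs.b, alpha)
    if method == "anova":
        return icc_a, ci
    import statsmodels.api as sm

    long = pairs.to_long()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(long["volume_ml"].to_numpy(),
                               np.ones((2 * n, 1)),
                               groups=long["subject"].to_numpy())
            fit = model.fit(reml=True)
        var_subj = float(fit.cov_re.iloc[0, 0])
        var_resid = float(fit.scale)
        icc = var_subj / (var_subj + var_resid)
    except Exception as exc:
        logger.warning("REML ICC failed (%s); using ANOVA estimator", exc)
        icc = icc_a
    return float(icc), ci


def bland_altman(pairs: PairedVolumes, alpha: float = 0.05):
    """Bland-Altman bias and 95% limits of agreement for diff = A - B.

    Returns ``(bias, (lo, hi) limits, (lo, hi) bias CI)``. The limits are
    bias +/- 1.96 sd(diff); the bias CI uses the normal standard error.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    d = pairs.a - pairs.b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    z = stats.norm.ppf(1 - alpha / 2)
    loa = (bias - z * sd, bias + z * sd)
    half = z * sd / np.sqrt(len(d))
    return bias, loa, (bias - half, bias + half)


def method_contrast(pairs: PairedVolumes, alpha: float = 0.05):
    """Fixed method effect (B - A) from a subject-random-intercept model.

    On balanced paired data the point estimate equals the paired mean
    difference; the paired-t closed form is the fallback when the mixed
    model does not converge. Returns ``(dc, (lo, hi), p)``.
    """
    import statsmodels.api as sm

    n = len(pairs)
    long = pairs.to_long()
    exog = np.column_stack([np.ones(2 * n),
                            (long["method"] == pairs.method_b).to_numpy(float)])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(long["volume_ml"].to_numpy(), exog,
                             groups=long["subject"].to_numpy()).fit(reml=True)
        dc = float(fit.params[1])
        se = float(fit.bse[1])
        z = stats.norm.ppf(1 - alpha / 2)
        ci = (dc - z * se, dc + z * se)
        p = float(2 * stats.norm.sf(abs(dc / se))) if se > 0 else (1.0 if dc == 0 else 0.0)
    except Exception as exc:
        logger.warning("mixed-model contrast failed (%s); using paired t", exc)
        d = pairs.b - pairs.a
        dc = float(d.mean())
        se = float(d.std(ddof=1) / np.sqrt(n))
        tq = stats.t.ppf(1 - alpha / 2, n - 1)
        ci = (dc - tq * se, dc + tq * se)
        p = float(2 * stats.t.sf(abs(dc / se), n - 1)) if se > 0 else (1.0 if dc == 0 else 0.0)
    return dc, ci, p


def wilcoxon_mwu(group_a, group_b):
    """Two-sided Wilcoxon-Mann-Whitney U test.

    Exact null distribution (full enumeration) when the combined sample has
    at most 12 observations and no ties; the tie-corrected normal
    approximation otherwise. Returns ``(U, p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    small = a.size + b.size <= 12 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if small else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def summarize(values):
    """Median and interquartile range (linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return float(med), (float(q1), float(q3))


def compare_pair(pairs: PairedVolumes) -> AgreementReport:
    """Run the full agreement battery on one paired-volume table."""
    r, r_ci, r_p, r2 = pearson_ci(pairs)
    icc, icc_ci = icc_mixed(pairs)
    bias, loa, bias_ci = bland_altman(pairs)
    dc, dc_ci, dc_p = method_contrast(pairs)
    med_a, iqr_a = summarize(pairs.a)
    med_b, iqr_b = summarize(pairs.b)
    return AgreementReport(n=len(pairs), r=r, r_ci=r_ci, r_p=r_p, r2=r2,
                           icc=icc, icc_ci=icc_ci, bias=bias, bias_ci=bias_ci,
                           loa=loa, dc=dc, dc_ci=dc_ci, dc_p=dc_p,
                           median_a=med_a, iqr_a=iqr_a, median_b=med_b, iqr_b=iqr_b)
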