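"""Method-agreement and reliability statistics for paired pull-test metrics.

Concurrent validity of a measurement method against a reference is
summarised per metric by Pearson's r, Bland-Altman bias and
reproducibility coefficient (RPC = 1.96 × SD of the paired differences),
and the two-way single-measure intraclass correlation for absolute
agreement, ICC(A,1) (McGraw-Wong; equivalently Shrout-Fleiss ICC(2,1)):

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))

with MS_R the between-subjects, MS_C the between-raters and MS_E the
residual mean squares of the two-way ANOVA decomposition. Test-retest /
inter-rater reliability uses the one-way random single-measure ICC(1,1)

    ICC(1,1) = (MS_B − MS_W) / (MS_B + (k−1)·MS_W)

and the standard error of measurement SEM = SD_pooled · sqrt(1 − ICC).
ICC point estimates are labelled with the conventional bands: poor
(<0.5), moderate (0.5-0.75), good (0.75-0.9), excellent (>0.9); values
exactly on a boundary take the lower band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "ReliabilityReport",
    "bland_altman",
    "icc_two_way_absolute",
    "icc_two_way_consistency",
    "icc_one_way_random",
    "sem",
    "icc_category",
    "agreement_report",
    "reliability_report",
    "compare_groups",
    "correlate",
    "agreement_table",
    "reliability_table",
]


@dataclass
class PairedMeasurements:
    """Two methods' (or raters') values aligned by subject."""

    subject_ids: list
    method_a: np.ndarray
    method_b: np.ndarray

    def __post_init__(self) -> None:
        self.method_a = np.asarray(self.method_a, dtype=float)
        self.method_b = np.asarray(self.method_b, dtype=float)
        if len(self.subject_ids) != len(self.method_a) or len(self.method_a) != len(
            self.method_b
        ):
            raise ValueError("subject_ids, method_a and method_b must align")
        if len(self.method_a) < 3:
            raise ValueError("need at least 3 paired subjects")

    @property
    def n(self) -> int:
        return len(self.method_a)

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([self.method_a, self.method_b])


@dataclass(frozen=True)
class AgreementReport:
    """Concurrent-validity summary for one metric (Table-1 style columns)."""

    pearson_r: float
    bias: float
    rpc: float
    icc: float  # ICC(A,1), two-way absolute agreement, single measure
    icc_category: str
    n: int


@dataclass(frozen=True)
class ReliabilityReport:
    """Inter-rater reliability summary for one metric (Table-2 style)."""

    icc_1_1: float
    sem: float
    n: int


# ---------------------------------------------------------------------------
# Core estimators
# ---------------------------------------------------------------------------


def bland_altman(p: PairedMeasurements) -> tuple[float, float]:
    """Bias and reproducibility coefficient of paired differences.

    bias = mean(a − b); RPC = 1.96 × sample SD(a − b) (ddof 1). A non-zero
    bias indicates a systematic offset between the methods; RPC bounds the
    typical disagreement.
    """
    d = p.method_a - p.method_b
    return float(np.mean(d)), float(1.96 * np.std(d, ddof=1))


def _anova_mean_squares(data: np.ndarray):
    """Two-way (subjects × raters) mean squares; no replication, no missing."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be an n × k matrix")
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 raters/methods")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing cells are not supported (no imputation)")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return n, k, ms_rows, ms_cols, ms_err


def icc_two_way_absolute(data: np.ndarray) -> float:
    """Single-measure two-way absolute-agreement ICC(A,1).

    Returns NaN (with a warning) for the degenerate all-equal matrix where
    the ratio is 0/0.
    """
    n, k, ms_r, ms_c, ms_e = _anova_mean_squares(data)
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        warnings.warn("ICC undefined: zero variance everywhere", RuntimeWarning)
        return float("nan")
    return float((ms_r - ms_e) / denom)


def icc_two_way_consistency(data: np.ndarray) -> float:
    """Single-measure two-way consistency ICC (Shrout-Fleiss 3,1), for
    comparison with the absolute-agreement form."""
    n, k, ms_r, ms_c, ms_e = _anova_mean_squares(data)
    denom = ms_r + (k - 1) * ms_e
    if denom == 0:
        warnings.warn("ICC undefined: zero variance everywhere", RuntimeWarning)
        return float("nan")
    return float((ms_r - ms_e) / denom)


def icc_one_way_random(data: np.ndarray) -> float:
    """Single-measure one-way random-effects ICC(1,1)."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be an n × k matrix")
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 raters/methods")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing cells are not supported (no imputation)")
    grand = data.mean()
    row_means = data.mean(axis=1)
    ss_between = k * np.sum((row_means - grand) ** 2)
    ss_within = np.sum((data - row_means[:, None]) ** 2)
    ms_b = ss_between / (n - 1)
    ms_w = ss_within / (n * (k - 1))
    denom = ms_b + (k - 1) * ms_w
    if denom == 0:
        warnings.warn("ICC undefined: zero variance everywhere", RuntimeWarning)
        return float("nan")
    return float((ms_b - ms_w) / denom)


def sem(data: np.ndarray, icc: float) -> float:
    """Standard error of measurement: SD_pooled × sqrt(1 − ICC)."""
    if icc > 1:
        raise ValueError(f"icc must be <= 1, got {icc}")
    data = np.asarray(data, dtype=float)
    sd_pooled = float(np.std(data.ravel(), ddof=1))
    return sd_pooled * float(np.sqrt(1.0 - icc))


def icc_category(icc: float) -> str:
    """Conventional interpretation band of an ICC point estimate."""
    if not np.isfinite(icc):
        raise ValueError("icc must be finite")
    if icc < 0.5:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def agreement_report(p: PairedMeasurements) -> AgreementReport:
    """Full concurrent-validity panel for one metric."""
    r = float(sps.pearsonr(p.method_a, p.method_b).statistic)
    bias, rpc = bland_altman(p)
    icc = icc_two_way_absolute(p.matrix)
    return AgreementReport(
        pearson_r=r,
        bias=bias,
        rpc=rpc,
        icc=icc,
        icc_category=icc_category(icc) if np.isfinite(icc) else "undefined",
        n=p.n,
    )


def reliability_report(p: PairedMeasurements) -> ReliabilityReport:
    """Inter-rater reliability panel for one metric."""
    icc = icc_one_way_random(p.matrix)
    return ReliabilityReport(
        icc_1_1=icc,
        sem=sem(p.matrix, icc) if np.isfinite(icc) else float("nan"),
        n=p.n,
    )


# ---------------------------------------------------------------------------
# Group comparisons and correlations
# ---------------------------------------------------------------------------


def compare_groups(values_a, values_b, kind: str = "numeric"):
    """Two-group comparison: Welch t-test (numeric) or Pearson chi-squared.

    For ``kind="numeric"`` pass two value vectors; for
    ``kind="categorical"`` pass two count vectors over the same category
    order (rows of the 2 × c contingency table). Returns
    ``(statistic, p_value)``. Degenerate numeric input (zero variance in
    both groups) raises; expected counts below 5 trigger a warning
    recommending an exact test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if kind == "numeric":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 values per group")
        if np.std(a) == 0 and np.std(b) == 0:
            raise ValueError("zero variance in both groups: t-test undefined")
        res = sps.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if kind == "categorical":
        table = np.vstack([a, b])
        if np.any(table < 0):
            raise ValueError("contingency counts must be non-negative")
        res = sps.chi2_contingency(table, correction=False)
        if np.any(res.expected_freq < 5):
            warnings.warn(
                "expected counts < 5: consider an exact test", RuntimeWarning
            )
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown kind {kind!r}")


def correlate(x, y, kind: str = "numeric-numeric"):
    """Pearson (numeric-numeric) or Spearman (numeric-ordinal) correlation.

    Returns ``(coefficient, p_value)`` with the standard two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if kind == "numeric-numeric":
        res = sps.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)
    if kind == "numeric-ordinal":
        res = sps.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# Table-style reports over joined result tables
# ---------------------------------------------------------------------------


def _paired_metric(df_a: pd.DataFrame, df_b: pd.DataFrame, metric: str):
    """Join two per-subject result tables on subject_id for one metric,
    dropping subjects with a missing value in either table (listwise per
    metric)."""
    a = df_a[["subject_id", metric]].rename(columns={metric: "a"})
    b = df_b[["subject_id", metric]].rename(columns={metric: "b"})
    j = a.merge(b, on="subject_id").dropna()
    if len(j) < 3:
        raise ValueError(
            f"fewer than 3 joined subjects with values for {metric!r}"
        )
    return PairedMeasurements(list(j["subject_id"]), j["a"].to_numpy(), j["b"].to_numpy())


def _mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"


def agreement_table(
    df_a: pd.DataFrame, df_b: pd.DataFrame, metrics: list[str]
) -> pd.DataFrame:
    """Concurrent-validity table (one row per metric) from two result tables."""
    rows = []
    for m in metrics:
        p = _paired_metric(df_a, df_b, m)
        rep = agreement_report(p)
        rows.append(
            {
                "metric": m,
                "method_a": _mean_sd(p.method_a),
                "method_b": _mean_sd(p.method_b),
                "n": rep.n,
                "pearson_r": rep.pearson_r,
                "bias": rep.bias,
                "rpc": rep.rpc,
                "icc_a1_two_way": rep.icc,
                "icc_category": rep.icc_category,
            }
        )
    return pd.DataFrame(rows)


def reliability_table(
    df_a: pd.DataFrame, df_b: pd.DataFrame, metrics: list[str]
) -> pd.DataFrame:
    """Inter-rater reliability table (one row per metric)."""
    rows = []
    for m in metrics:
        p = _paired_metric(df_a, df_b, m)
        rep = reliability_report(p)
        rows.append(
            {
                "metric": m,
                "rater_1": _mean_sd(p.method_a),
                "rater_2": _mean_sd(p.method_b),
                "n": rep.n,
                "sem": rep.sem,
                "icc_1_1_one_way": rep.icc_1_1,
            }
        )
    return pd.DataFrame(rows)
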