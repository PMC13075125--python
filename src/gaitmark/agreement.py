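"""Two-system agreement statistics for paired kinematic summaries.

Given per-subject kinematic parameters from a reference system (e.g. an
IMU suite) and an estimated system (e.g. a video/pose pipeline), this
module computes, per parameter:

* descriptive mean +/- SD for each system;
* a normality-gated paired location test: Shapiro-Wilk on the differences
  at alpha, then a paired two-sided t-test if normal, otherwise the
  Wilcoxon signed-rank test (zeros dropped; exact null for n <= 25 without
  ties, normal approximation with continuity correction otherwise);
* Spearman rank correlation rho;
* ICC(2,1) — two-way random effects, absolute agreement, single measure —
  from the two-way ANOVA mean squares;
* Bland-Altman bias, limits of agreement bias +/- 1.96*SD of the
  differences, and the bias confidence interval bias +/- 1.96*SD/sqrt(n)
  (normal multiplier, not t);
* mean absolute error (MAE);
* interpretation bands for rho and ICC:
  poor (< 0.500), moderate (0.500-0.750), good (0.750-0.900),
  excellent (> 0.900).

The difference direction defaults to estimated - reference and is
configurable; it affects only the signs in the Bland-Altman table. No
multiple-testing correction is applied (alpha holds per test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    DegenerateStatisticError,
    UndefinedCorrelationError,
    ValidationError,
)

Z95 = 1.96  # normal 95% multiplier used throughout

_BANDS = (
    (0.5, "poor"),       # value < 0.5
    (0.75, "moderate"),  # 0.5 <= value <= 0.75 (boundary handled below)
)


@dataclass(frozen=True)
class PairedSample:
    """Per-subject paired values (reference, estimated) for one parameter."""

    parameter: str
    reference: np.ndarray
    estimated: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        est = np.asarray(self.estimated, dtype=float)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "estimated", est)
        if ref.shape != est.shape or ref.ndim != 1:
            raise ValidationError(
                f"{self.parameter}: reference and estimated must be equal-length 1-D arrays"
            )
        if len(ref) < 3:
            raise ValidationError(f"{self.parameter}: need n >= 3 subjects, got {len(ref)}")
        if not (np.isfinite(ref).all() and np.isfinite(est).all()):
            raise ValidationError(f"{self.parameter}: values must be finite")

    @property
    def n(self) -> int:
        return len(self.reference)

    def differences(self, direction: str = "est_minus_ref") -> np.ndarray:
        if direction == "est_minus_ref":
            return self.estimated - self.reference
        if direction == "ref_minus_est":
            return self.reference - self.estimated
        raise ValidationError(f"unknown difference direction {direction!r}")


@dataclass(frozen=True)
class BAResult:
    """Bland-Altman summary for one parameter."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_low: float
    ci_high: float
    n: int


def mae(sample: PairedSample) -> float:
    """Mean absolute error between the two systems, in degrees."""
    return float(np.mean(np.abs(sample.estimated - sample.reference)))


def bland_altman(sample: PairedSample, direction: str = "est_minus_ref") -> BAResult:
    """Bias, 95% limits of agreement and bias CI of the paired differences.

    SD of the differences uses the n-1 denominator. Limits of agreement are
    bias +/- 1.96*SD; the bias CI is bias +/- 1.96*SD/sqrt(n).
    """
    d = sample.differences(direction)
    n = sample.n
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half_loa = Z95 * sd
    half_ci = Z95 * sd / math.sqrt(n)
    return BAResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - half_loa,
        loa_high=bias + half_loa,
        ci_low=bias - half_ci,
        ci_high=bias + half_ci,
        n=n,
    )


def ci_from_limits(bias: float, loa_high: float, n: int) -> tuple[float, float]:
    """Reconstruct the bias CI from a published bias and upper LoA.

    Useful for checking reported Bland-Altman tables: the SD of the
    differences is (loa_high - bias)/1.96 and the CI is
    bias +/- 1.96*SD/sqrt(n).
    """
    if n < 3:
        raise ValidationError(f"need n >= 3, got {n}")
    sd = (loa_high - bias) / Z95
    half = Z95 * sd / math.sqrt(n)
    return bias - half, bias + half


def spearman_rho(sample: PairedSample) -> float:
    """Spearman rank correlation (Pearson correlation of mean ranks)."""
    ref_ranks = stats.rankdata(sample.reference)
    est_ranks = stats.rankdata(sample.estimated)
    if np.ptp(ref_ranks) == 0 or np.ptp(est_ranks) == 0:
        raise UndefinedCorrelationError(
            f"{sample.parameter}: a system has zero rank variance"
        )
    return float(stats.spearmanr(sample.reference, sample.estimated).statistic)


def icc_from_matrix(Y: np.ndarray) -> float:
    """ICC(2,1) from the two-way ANOVA mean squares of an n x k matrix.

    Two-way random effects, absolute agreement, single measure:

        ICC = (MSR - MSE) / (MSR + (k-1)*MSE + k*(MSC - MSE)/n)

    where MSR, MSC, MSE are the rows (subjects), columns (raters) and
    residual mean squares.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 3 or Y.shape[1] < 2:
        raise ValidationError(f"need an n>=3 by k>=2 matrix, got shape {Y.shape}")
    n, k = Y.shape
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((Y - grand) ** 2)
    sse = sst - ssr - ssc
    if sst <= 0:
        raise DegenerateStatisticError("zero total variance: ICC undefined")
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise DegenerateStatisticError("degenerate ANOVA decomposition: ICC undefined")
    return float((msr - mse) / denom)


def icc(sample: PairedSample) -> float:
    """ICC(2,1) between the two systems (absolute agreement, single measure)."""
    return icc_from_matrix(np.column_stack([sample.reference, sample.estimated]))


def wilcoxon_signed_rank(differences: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value.

    Zero differences are dropped; tied magnitudes receive mean ranks. The
    exact null distribution is used for n <= 25 without ties, otherwise the
    normal approximation with continuity correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateStatisticError("all differences are zero: test undefined")
    has_ties = len(np.unique(np.abs(d))) < len(d)
    if len(d) <= 25 and not has_ties:
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(
            d, zero_method="wilcox", alternative="two-sided", method="approx", correction=True
        )
    return float(res.pvalue)


def paired_location_test(sample: PairedSample, alpha: float = 0.05) -> tuple[float, str]:
    """Normality-gated paired location test.

    Shapiro-Wilk on the differences at ``alpha``: if normality is not
    rejected, a two-sided paired t-test; otherwise the Wilcoxon signed-rank
    test. Returns ``(p_value, test_used)`` with test_used in
    {"paired_t", "wilcoxon"}.
    """
    d = sample.estimated - sample.reference
    if np.all(d == 0):
        raise DegenerateStatisticError(
            f"{sample.parameter}: all differences are zero, location test undefined"
        )
    if sample.n < 4:
        raise ValidationError(f"{sample.parameter}: normality gate needs n >= 4")
    if np.ptp(d) == 0:
        # a perfectly constant nonzero shift: normality is meaningless and
        # the t denominator vanishes; the signed-rank test stays defined
        return wilcoxon_signed_rank(d), "wilcoxon"
    shapiro_p = float(stats.shapiro(d).pvalue)
    if shapiro_p > alpha:
        p = float(stats.ttest_rel(sample.estimated, sample.reference).pvalue)
        return p, "paired_t"
    return wilcoxon_signed_rank(d), "wilcoxon"


def classify_band(value: float) -> str:
    """Interpretation band for a correlation/ICC value in [-1, 1]."""
    if not (-1.0 - 1e-12 <= value <= 1.0 + 1e-12):
        raise ValidationError(f"value {value} outside [-1, 1]")
    if value < 0.5:
        return "poor"
    if value <= 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class AgreementRow:
    """One parameter's full two-system comparison."""

    joint: str
    side: str
    parameter: str
    ref_mean: float
    ref_sd: float
    est_mean: float
    est_sd: float
    p_value: float
    test_used: str
    rho: float
    rho_category: str
    icc: float
    icc_category: str
    mae_deg: float
    ba: BAResult


@dataclass
class AgreementReport:
    """Per-parameter agreement rows plus subject-level plot data."""

    rows: list[AgreementRow]
    plot_data: pd.DataFrame
    direction: str

    def to_frame(self) -> pd.DataFrame:
        """Comparison table: descriptives, test, rho, ICC, MAE per row."""
        return pd.DataFrame(
            [
                {
                    "joint": r.joint,
                    "side": r.side,
                    "parameter": r.parameter,
                    "ref_mean": r.ref_mean,
                    "ref_sd": r.ref_sd,
                    "est_mean": r.est_mean,
                    "est_sd": r.est_sd,
                    "p_value": r.p_value,
                    "test_used": r.test_used,
                    "rho": r.rho,
                    "rho_category": r.rho_category,
                    "icc": r.icc,
                    "icc_category": r.icc_category,
                    "mae_deg": r.mae_deg,
                }
                for r in self.rows
            ]
        )

    def ba_frame(self) -> pd.DataFrame:
        """Bland-Altman table: bias, bias CI bounds, limits of agreement."""
        return pd.DataFrame(
            [
                {
                    "joint": r.joint,
                    "side": r.side,
                    "parameter": r.parameter,
                    "bias": r.ba.bias,
                    "bias_ci_low": r.ba.ci_low,
                    "bias_ci_high": r.ba.ci_high,
                    "loa_low": r.ba.loa_low,
                    "loa_high": r.ba.loa_high,
                    "sd_diff": r.ba.sd_diff,
                    "n": r.ba.n,
                }
                for r in self.rows
            ]
        )

    def formatted(self, decimals: int = 2) -> pd.DataFrame:
        """Report table rounded half-up, as printed tables round."""
        df = self.to_frame()
        num = df.select_dtypes(include=[float]).columns
        df[num] = df[num].map(lambda x: round_half_up(x, decimals))
        return df


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at the given number of decimals."""
    if not math.isfinite(x):
        return x
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _pivot(df: pd.DataFrame) -> pd.DataFrame:
    required = {"subject", "joint", "side", "parameter", "value_deg"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValidationError(f"summary table missing column(s): {missing}")
    return df


def compare_systems(
    reference: pd.DataFrame,
    estimated: pd.DataFrame,
    *,
    direction: str = "est_minus_ref",
    alpha: float = 0.05,
) -> AgreementReport:
    """Full agreement battery over two tidy subject-summary tables.

    Both tables carry columns ``subject, joint, side, parameter,
    value_deg``; subjects and parameters must match exactly. Parameters
    where the two systems are identical get ``test_used="degenerate"`` and
    a NaN p-value rather than a spurious one.
    """
    ref = _pivot(reference)
    est = _pivot(estimated)
    ref_subj = set(ref["subject"])
    est_subj = set(est["subject"])
    if ref_subj != est_subj:
        only_ref = sorted(ref_subj - est_subj)
        only_est = sorted(est_subj - ref_subj)
        raise AlignmentError(
            f"subject mismatch: only in reference {only_ref}, only in estimated {only_est}"
        )
    keys = ["joint", "side", "parameter"]
    ref_groups = {k: g for k, g in ref.groupby(keys)}
    est_groups = {k: g for k, g in est.groupby(keys)}
    if set(ref_groups) != set(est_groups):
        raise AlignmentError(
            f"parameter mismatch: reference has {sorted(set(ref_groups) - set(est_groups))} "
            f"extra, estimated has {sorted(set(est_groups) - set(ref_groups))} extra"
        )

    rows: list[AgreementRow] = []
    plot_records = []
    for key in sorted(ref_groups):
        joint, side, parameter = key
        r = ref_groups[key].sort_values("subject")
        e = est_groups[key].sort_values("subject")
        if list(r["subject"]) != list(e["subject"]):
            raise AlignmentError(f"{key}: subject sets differ between systems")
        sample = PairedSample(
            parameter=f"{side}_{joint}_{parameter}",
            reference=r["value_deg"].to_numpy(),
            estimated=e["value_deg"].to_numpy(),
        )
        d = sample.differences(direction)
        ba = bland_altman(sample, direction)
        if sample.n < 4:
            p_value, test_used = float("nan"), "insufficient_n"
        else:
            try:
                p_value, test_used = paired_location_test(sample, alpha)
            except DegenerateStatisticError:
                p_value, test_used = float("nan"), "degenerate"
        try:
            rho = spearman_rho(sample)
            rho_cat = classify_band(max(-1.0, min(1.0, rho)))
        except UndefinedCorrelationError:
            rho, rho_cat = float("nan"), "undefined"
        try:
            icc_value = icc(sample)
            icc_cat = classify_band(max(-1.0, min(1.0, icc_value)))
        except DegenerateStatisticError:
            icc_value, icc_cat = float("nan"), "undefined"
        rows.append(
            AgreementRow(
                joint=joint,
                side=side,
                parameter=parameter,
                ref_mean=float(np.mean(sample.reference)),
                ref_sd=float(np.std(sample.reference, ddof=1)),
                est_mean=float(np.mean(sample.estimated)),
                est_sd=float(np.std(sample.estimated, ddof=1)),
                p_value=p_value,
                test_used=test_used,
                rho=rho,
                rho_category=rho_cat,
                icc=icc_value,
                icc_category=icc_cat,
                mae_deg=mae(sample),
                ba=ba,
            )
        )
        means = (sample.reference + sample.estimated) / 2.0
        for subj, m, diff in zip(r["subject"], means, d):
            plot_records.append(
                {
                    "subject": subj,
                    "joint": joint,
                    "side": side,
                    "parameter": parameter,
                    "mean": float(m),
                    "difference": float(diff),
                }
            )
    plot_df = pd.DataFrame(
        plot_records, columns=["subject", "joint", "side", "parameter", "mean", "difference"]
    )
    return AgreementReport(rows=rows, plot_data=plot_df, direction=direction)
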