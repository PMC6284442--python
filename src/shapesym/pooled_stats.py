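"""Side-pooled analyses of shape parameters.

* normality screening of per-mode scores (KS with estimated parameters,
  i.e. a Lilliefors-corrected p-value);
* age-adjusted sex comparison per mode (ANCOVA: score ~ age + sex) with a
  Bonferroni-adjusted family threshold;
* intra- vs inter-subject agreement per mode via the single-measurement,
  absolute-agreement, two-way random-effects intraclass correlation
  ICC(2,1) with an F-based confidence interval.

ICC conventions: 1 means the two sides of a subject agree perfectly (all
variation is between subjects); 0 means within-subject variation is as
large as between-subject. Negative estimates are reported as computed, and
a mode is flagged "not significantly symmetrical" when its CI contains 0.
"""
from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from typing import List, NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "KsResult",
    "ModeAncova",
    "AncovaResult",
    "IccResult",
    "ks_normality",
    "ancova_sex",
    "ancova_table",
    "bonferroni_alpha",
    "icc_2_1",
]


class KsResult(NamedTuple):
    statistic: float
    p_value: float


@dataclasses.dataclass
class ModeAncova:
    p_value: float
    f_statistic: float
    sex_coefficient: float       # shift of F relative to M, score units
    age_coefficient: float
    n_used: int
    n_excluded_missing_age: int


@dataclasses.dataclass
class AncovaResult:
    per_mode: List[ModeAncova]
    alpha_family: float
    n_tests: int
    alpha_adjusted_exact: float
    alpha_adjusted_rounded: float
    significant_modes: List[int]   # 1-based mode indices

    @property
    def p_values(self) -> np.ndarray:
        return np.array([m.p_value for m in self.per_mode])


@dataclasses.dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    msr: float                    # rows = subjects mean square
    msc: float                    # columns = sides mean square
    mse: float
    n_subjects: int
    n_raters: int = 2
    conf_level: float = 0.95

    @property
    def significantly_symmetric(self) -> bool:
        """False when the CI contains zero (intra ~ inter variation)."""
        return not (self.ci_low <= 0.0 <= self.ci_high)


def ks_normality(scores: Sequence[float]) -> KsResult:
    """One-sample KS test against a normal law with estimated mean/SD.

    Because the parameters are estimated from the sample, the naive KS
    p-value would be anti-conservative; the Lilliefors small-sample null
    distribution is used instead (statsmodels table/approximation).
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or x.shape[0] < 8:
        raise ValueError("need a 1-D sample with n >= 8")
    if np.ptp(x) == 0:
        raise ValueError("constant input: normality test undefined")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return KsResult(statistic=float(stat), p_value=float(p))


def ancova_sex(scores, sex, age) -> ModeAncova:
    """ANCOVA for one mode: score ~ intercept + age + sex.

    The sex p-value is the F-test (1 numerator df, equivalently t²) of the
    sex term after adjusting for age as a linear covariate, no interaction.
    Samples with missing age are excluded and counted.
    """
    y = np.asarray(scores, dtype=float)
    sex = np.asarray(sex)
    age = np.asarray(age, dtype=float)
    if not (y.shape == sex.shape == age.shape):
        raise ValueError("scores, sex and age must have equal lengths")
    keep = np.isfinite(age) & np.isfinite(y)
    n_excluded = int(y.shape[0] - keep.sum())
    y, sex, age = y[keep], sex[keep], age[keep]
    groups = set(sex.tolist())
    if len(groups) < 2:
        raise ValueError(f"both sexes must be present, got only {sorted(groups)}")
    female = (sex == "F").astype(float)
    X = np.column_stack([np.ones_like(y), age, female])
    n, p = X.shape
    if n <= p:
        raise ValueError("too few complete cases for the ANCOVA model")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - p
    sigma2 = resid @ resid / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    se_sex = np.sqrt(sigma2 * xtx_inv[2, 2])
    f_stat = (beta[2] / se_sex) ** 2
    p_value = float(stats.f.sf(f_stat, 1, df_resid))
    return ModeAncova(p_value=p_value, f_statistic=float(f_stat),
                      sex_coefficient=float(beta[2]),
                      age_coefficient=float(beta[1]),
                      n_used=n, n_excluded_missing_age=n_excluded)


def bonferroni_alpha(alpha_family: float, n_tests: int):
    """Per-test threshold ``alpha_family / n_tests``.

    Returns ``(exact, rounded)`` where the rounded value is half-up to three
    decimals, the convention used when printing adjusted levels.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha_family <= 1:
        raise ValueError("alpha_family must lie in (0, 1]")
    exact = alpha_family / n_tests
    rounded = float(
        (Decimal(str(alpha_family)) / Decimal(n_tests))
        .quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))
    return exact, rounded


def ancova_table(scores_matrix, sex, age, alpha_family: float = 0.05) -> AncovaResult:
    """Run the per-mode ANCOVA across the columns of a score matrix and
    apply the Bonferroni family adjustment."""
    scores_matrix = np.atleast_2d(np.asarray(scores_matrix, dtype=float))
    n_tests = scores_matrix.shape[1]
    per_mode = [ancova_sex(scores_matrix[:, j], sex, age)
                for j in range(n_tests)]
    exact, rounded = bonferroni_alpha(alpha_family, n_tests)
    significant = [j + 1 for j, m in enumerate(per_mode) if m.p_value < exact]
    return AncovaResult(per_mode=per_mode, alpha_family=alpha_family,
                        n_tests=n_tests, alpha_adjusted_exact=exact,
                        alpha_adjusted_rounded=rounded,
                        significant_modes=significant)


def icc_2_1(left_scores, right_scores, conf_level: float = 0.95) -> IccResult:
    """ICC(2,1): single-measurement, absolute-agreement, two-way random.

    Subjects are rows, the two sides are the "raters" (k = 2). With mean
    squares MSR (subjects), MSC (sides) and MSE (error),

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

    and the confidence interval is the F-based construction of the two-way
    random-effects framework (the one SPSS prints). Estimates below zero
    are reported as computed.
    """
    L = np.asarray(left_scores, dtype=float)
    R = np.asarray(right_scores, dtype=float)
    if L.shape != R.shape or L.ndim != 1:
        raise ValueError("left and right must be 1-D arrays paired by subject")
    n = L.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects")
    k = 2
    # two-rater decomposition via pair means and differences; exact when the
    # sides agree (d = 0 gives MSC = MSE = 0 in floating point, so the
    # perfect-agreement case yields ICC = 1.0 exactly)
    row_means = (L + R) / 2.0
    d = L - R
    dbar = d.mean()
    ss_rows = k * float(((row_means - row_means.mean()) ** 2).sum())
    ss_cols = n * dbar ** 2 / 2.0
    ss_err = float(((d - dbar) ** 2).sum()) / 2.0
    if ss_rows + ss_cols + ss_err == 0:
        raise ValueError("zero total variance: ICC undefined")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    icc = (msr - mse) / denom

    alpha = 1.0 - conf_level
    if mse == 0.0 and msc == 0.0:
        lo = hi = icc  # degenerate: sides agree exactly
    else:
        a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
        num_v = (a * msc + b * mse) ** 2
        den_v = ((a * msc) ** 2 / (k - 1)
                 + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        v = num_v / den_v if den_v > 0 else np.inf
        f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = (n * (msr - f_lo * mse)
              / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr))
        hi = (n * (f_hi * msr - mse)
              / (k * msc + (k * n - k - n) * mse + n * f_hi * msr))
    return IccResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi),
                     msr=float(msr), msc=float(msc), mse=float(mse),
                     n_subjects=n, n_raters=k, conf_level=conf_level)
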