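"""Agreement, correlation, regression and bootstrap predictive accuracy.

Calcium scores are heavily right-skewed, so all regression work happens on
the square-root scale (variance-stabilizing for count-like quantities).
Predictive accuracy of a derived score for the reference score is estimated
with a bootstrap: resample patients with replacement, fit ordinary least
squares on the sqrt scale, predict the reference for every original patient,
back-transform (clipping negative sqrt-scale predictions to zero), and take
the mean absolute error; the distribution of MAEs over replicates is
summarized by its median and quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class RegressionFit:
    slope: float       # sqrt scale
    intercept: float   # sqrt scale
    r_squared: float
    n: int


@dataclass
class BootstrapSummary:
    mae_median: float
    mae_q25: float
    mae_q75: float
    n_boot: int
    seed: int
    n_redrawn: int = 0
    maes: np.ndarray | None = field(default=None, repr=False)

    def validate(self) -> None:
        if not (0 <= self.mae_q25 <= self.mae_median <= self.mae_q75):
            raise ValueError("bootstrap quartiles out of order or negative")


@dataclass
class ICCResult:
    icc3: float
    n_subjects: int
    n_raters: int


@dataclass
class PairedTestResult:
    test_used: str          # "paired_t" or "wilcoxon"
    statistic: float
    p_value: float
    normality_p: float      # Shapiro-Wilk p of the paired differences
    degenerate: bool = False


def icc3_single(ratings: np.ndarray) -> ICCResult:
    """ICC(3,1): two-way mixed effects, consistency, single fixed raters.

    ``ratings`` is a subjects x raters table with no missing cells.  From the
    two-way ANOVA decomposition::

        ICC(3,1) = (MS_subjects - MS_error) / (MS_subjects + (k - 1) MS_error)

    Consistency form: a fixed offset between raters does not lower the
    coefficient.  A table constant across all cells leaves the coefficient
    undefined and raises.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters table")
    n, k = x.shape
    if k < 2:
        raise ValueError("need >= 2 raters")
    if n < 3:
        raise ValueError("need >= 3 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must have no missing cells")
    grand = x.mean()
    ss_subjects = k * float(((x.mean(axis=1) - grand) ** 2).sum())
    ss_raters = n * float(((x.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_raters
    ms_subjects = ss_subjects / (n - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))
    denom = ms_subjects + (k - 1) * ms_error
    if denom <= 0:
        raise ValueError("ICC undefined: no variance in the ratings table")
    return ICCResult(icc3=float((ms_subjects - ms_error) / denom),
                     n_subjects=n, n_raters=k)


def _check_pairs(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("calcium quantities must be nonnegative")
    return x, y


def sqrt_regression(x, y) -> RegressionFit:
    """OLS of sqrt(y) on sqrt(x); r^2 reported on the transformed scale."""
    x, y = _check_pairs(x, y, min_n=3)
    sx, sy = np.sqrt(x), np.sqrt(y)
    if np.ptp(sx) == 0:
        raise ValueError("degenerate design: x is constant")
    fit = sps.linregress(sx, sy)
    return RegressionFit(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue ** 2), n=int(x.size))


def _fit_predict_mae(sx_fit, sy_fit, sx_all, y_all):
    """Vectorized per-row OLS fit and back-transformed MAE (rows = replicates)."""
    mx = sx_fit.mean(axis=1, keepdims=True)
    my = sy_fit.mean(axis=1, keepdims=True)
    dx = sx_fit - mx
    var = (dx ** 2).sum(axis=1)
    slope = (dx * (sy_fit - my)).sum(axis=1) / var
    intercept = my[:, 0] - slope * mx[:, 0]
    pred_sqrt = intercept[:, None] + slope[:, None] * sx_all[None, :]
    pred = np.clip(pred_sqrt, 0.0, None) ** 2
    return np.abs(pred - y_all[None, :]).mean(axis=1)


def bootstrap_mae(x, y, n_boot: int = 10_000, seed: int = 0) -> BootstrapSummary:
    """Bootstrap distribution of the back-transformed mean absolute error.

    Per replicate: resample patient pairs with replacement, fit OLS on
    ``(sqrt x, sqrt y)``, predict sqrt(y) for *all original* patients, clip
    negative predictions to 0, square, and average ``|prediction - y|``.
    Degenerate resamples (constant sqrt x) are redrawn and counted.
    Summary: median and quartiles (linear interpolation) of the replicate
    MAEs.  Deterministic given ``seed``.
    """
    x, y = _check_pairs(x, y, min_n=5)
    sx, sy = np.sqrt(x), np.sqrt(y)
    if np.ptp(sx) == 0:
        raise ValueError("degenerate input: x is constant, no regression possible")
    rng = np.random.default_rng(seed)
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    n_redrawn = 0
    for _attempt in range(1000):
        bad = np.flatnonzero(np.ptp(sx[idx], axis=1) == 0)
        if bad.size == 0:
            break
        n_redrawn += bad.size
        idx[bad] = rng.integers(0, n, size=(bad.size, n))
    else:
        raise RuntimeError("could not draw non-degenerate bootstrap resamples")
    maes = _fit_predict_mae(sx[idx], sy[idx], sx, y)
    q25, med, q75 = np.percentile(maes, [25, 50, 75], method="linear")
    out = BootstrapSummary(mae_median=float(med), mae_q25=float(q25),
                           mae_q75=float(q75), n_boot=int(n_boot), seed=int(seed),
                           n_redrawn=n_redrawn, maes=maes)
    out.validate()
    return out


def paired_difference_test(a, b, alpha_normality: float = 0.05) -> PairedTestResult:
    """Paired comparison with a Shapiro-Wilk normality gate on the differences.

    Normal-looking differences (Shapiro p > alpha) go to the paired t-test,
    otherwise to the Wilcoxon signed-rank test (zero differences dropped, the
    signed-rank convention).  All-zero differences yield p = 1 with a
    degenerate-input flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D and equal length")
    if a.size < 4:
        raise ValueError("need at least 4 pairs")
    d = a - b
    if np.all(d == 0):
        return PairedTestResult(test_used="paired_t", statistic=0.0, p_value=1.0,
                                normality_p=float("nan"), degenerate=True)
    normality_p = float(sps.shapiro(d).pvalue)
    if normality_p > alpha_normality:
        res = sps.ttest_rel(a, b)
        return PairedTestResult("paired_t", float(res.statistic), float(res.pvalue),
                                normality_p)
    res = sps.wilcoxon(a, b, zero_method="wilcox")
    return PairedTestResult("wilcoxon", float(res.statistic), float(res.pvalue),
                            normality_p)


def correlate(a, b, method: str = "pearson") -> float:
    """Pearson or Spearman correlation coefficient in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need 1D paired samples of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        return float(sps.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(sps.spearmanr(a, b).statistic)
    raise ValueError(f"unknown method {method!r} (expected 'pearson' or 'spearman')")
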