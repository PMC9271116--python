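"""Method-agreement and reliability statistics.

The battery used to compare two measurement methods (e.g. free-breathing
real-time volumetry against breath-hold cine volumetry) and two raters:
Bland-Altman bias and limits of agreement, ordinary least-squares
regression, a Shapiro-Wilk-guided choice between the paired t test and
the Wilcoxon signed-rank test, intraclass correlation with the
poor/fair/good/excellent bands (0.5 / 0.75 / 0.9), and Spearman rank
correlation with Cohen's small/medium/strong bands (0.1 / 0.3 / 0.5).

Sign convention: differences are always first argument minus second
(method A minus method B).  Descriptive SDs default to the population
divisor n; Bland-Altman uses the sample divisor n-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bland_altman",
    "bland_altman_plot",
    "linear_regression",
    "icc",
    "spearman_rho",
    "paired_tests",
    "descriptives",
    "classify_icc",
    "classify_rho",
    "AgreementReport",
    "agreement_report",
]

ICC_CUTS = (0.5, 0.75, 0.9)
RHO_CUTS = (0.1, 0.3, 0.5)


def classify_icc(value: float) -> str:
    """poor < 0.5 <= fair < 0.75 <= good < 0.9 <= excellent (bounds go up)."""
    if value < ICC_CUTS[0]:
        return "poor"
    if value < ICC_CUTS[1]:
        return "fair"
    if value < ICC_CUTS[2]:
        return "good"
    return "excellent"


def classify_rho(value: float) -> str:
    """Cohen effect-size bands on |rho|; boundary values take the higher band."""
    r = abs(value)
    if r < RHO_CUTS[0]:
        return "negligible"
    if r < RHO_CUTS[1]:
        return "small"
    if r < RHO_CUTS[2]:
        return "medium"
    return "strong"


def bland_altman(a, b) -> dict:
    """Bias, SD of differences (divisor n-1) and 1.96-SD limits of agreement.

    Differences are a - b.  Returns dict with keys ``bias``, ``sd_diff``,
    ``loa_low``, ``loa_high``, ``n``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs differ in length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "sd_diff": sd,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "n": int(a.size),
    }


def bland_altman_plot(a, b, path, labels=("method A", "method B")) -> dict:
    """Write a Bland-Altman figure: differences (a - b) against pair means,
    with solid bias line and dashed bias ± 1.96 SD limits.  Returns the
    underlying statistics."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(a, b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2.0, a - b, s=18, color="k")
    ax.axhline(res["bias"], color="k")
    for y in (res["loa_low"], res["loa_high"]):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xlabel(f"mean of {labels[0]} and {labels[1]}")
    ax.set_ylabel(f"{labels[0]} - {labels[1]}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return res


def linear_regression(x, y) -> dict:
    """Ordinary least squares: slope, intercept, R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("x is degenerate (zero variance)")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
    }


def icc(ratings: np.ndarray, model: str = "twoway_single_absolute") -> tuple[float, str]:
    """Intraclass correlation of a subjects x raters grid, with its band.

    Models (all single-measure):

    * ``twoway_single_absolute`` — two-way model, absolute agreement
      (default; the usual choice for inter-rater agreement)
    * ``twoway_single_consistency`` — two-way mixed, consistency
    * ``oneway_single`` — one-way random

    Requires >= 5 subjects, >= 2 raters and a complete grid.
    """
    grid = np.asarray(ratings, dtype=float)
    if grid.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters grid")
    n_subj, n_raters = grid.shape
    if n_subj < 5 or n_raters < 2:
        raise ValueError("need >= 5 subjects and >= 2 raters")
    if np.isnan(grid).any():
        raise ValueError("missing cells in ratings grid")
    import pingouin as pg

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subj), n_raters),
            "rater": np.tile(np.arange(n_raters), n_subj),
            "score": grid.ravel(),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # perfect agreement degenerates pingouin's F statistics; the ICC
        # point estimate itself is still well defined
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
    candidates = {
        "twoway_single_absolute": ("ICC2", "ICC(A,1)"),
        "twoway_single_consistency": ("ICC3", "ICC(C,1)"),
        "oneway_single": ("ICC1", "ICC(1,1)"),
    }.get(model)
    if candidates is None:
        raise ValueError(f"unknown ICC model {model!r}")
    key = next(k for k in candidates if k in table.index)
    value = float(table.loc[key, "ICC"])
    return value, classify_icc(value)


def spearman_rho(x, y) -> tuple[float, str, float]:
    """Spearman rank correlation (average ranks for ties), its band and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need paired inputs with n >= 5")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input has no rank correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), classify_rho(float(rho)), float(p)


@dataclass
class PairedTestResult:
    p_shapiro: float
    p_t: float
    p_wilcoxon: float
    chosen_test: str        # "paired_t", "wilcoxon", or "not_applicable"
    p_chosen: float


def paired_tests(
    a, b, alpha_normality: float = 0.05, wilcoxon_variant: str = "signed_rank"
) -> PairedTestResult:
    """Shapiro-Wilk-guided paired comparison.

    Normality of the paired differences is tested with Shapiro-Wilk; if
    not rejected (p >= ``alpha_normality``) the paired t test decides,
    otherwise the Wilcoxon test on the pairs.  Both p-values are
    reported regardless of which test is chosen.  ``wilcoxon_variant``
    selects the paired-correct signed-rank test (default) or the
    rank-sum test on the two samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need paired inputs with n >= 5")
    d = a - b
    if np.all(d == 0):
        return PairedTestResult(math.nan, math.nan, math.nan, "not_applicable", math.nan)
    p_shapiro = float(stats.shapiro(d).pvalue)
    p_t = float(stats.ttest_rel(a, b).pvalue)
    if wilcoxon_variant == "signed_rank":
        p_w = float(stats.wilcoxon(a, b).pvalue)
    elif wilcoxon_variant == "rank_sum":
        p_w = float(stats.ranksums(a, b).pvalue)
    else:
        raise ValueError(f"unknown wilcoxon variant {wilcoxon_variant!r}")
    if p_shapiro >= alpha_normality:
        return PairedTestResult(p_shapiro, p_t, p_w, "paired_t", p_t)
    return PairedTestResult(p_shapiro, p_t, p_w, "wilcoxon", p_w)


def descriptives(values, divisor: str = "n") -> tuple[float, float]:
    """Mean and SD with an explicit divisor (``"n"`` or ``"n-1"``)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if v.size < 2:
        raise ValueError("SD undefined for a single value")
    ddof = {"n": 0, "n-1": 1}.get(divisor)
    if ddof is None:
        raise ValueError("divisor must be 'n' or 'n-1'")
    return float(v.mean()), float(v.std(ddof=ddof))


@dataclass
class AgreementReport:
    """Full two-method agreement summary (differences are a - b)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    slope: float
    intercept: float
    r_squared: float
    p_shapiro: float
    p_paired_t: float
    p_wilcoxon: float
    chosen_test: str
    icc: float
    icc_class: str
    rho: float
    rho_class: str
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def agreement_report(a, b, icc_model: str = "twoway_single_absolute") -> AgreementReport:
    """Run the whole battery on two paired measurement vectors."""
    ba = bland_altman(a, b)
    reg = linear_regression(b, a)  # reference method on x, test method on y
    tests = paired_tests(a, b)
    grid = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    icc_val, icc_cls = icc(grid, icc_model)
    rho, rho_cls, _ = spearman_rho(a, b)
    return AgreementReport(
        bias=ba["bias"],
        sd_diff=ba["sd_diff"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
        slope=reg["slope"],
        intercept=reg["intercept"],
        r_squared=reg["r_squared"],
        p_shapiro=tests.p_shapiro,
        p_paired_t=tests.p_t,
        p_wilcoxon=tests.p_wilcoxon,
        chosen_test=tests.chosen_test,
        icc=icc_val,
        icc_class=icc_cls,
        rho=rho,
        rho_class=rho_cls,
        n=ba["n"],
    )
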