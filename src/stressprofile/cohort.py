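"""Cohort-level evaluation of pre/post RSI values.

Given a table of per-subject RSI values measured before and after an
intervention, this module produces the standard evaluation battery:
descriptive statistics, Tukey boxplot five-number summaries, the fraction
of subjects who improved, Welch's unequal-variance t-test on the group
means, and the Wilcoxon signed-rank test on the paired differences.

Conventions were fixed by calibrating each statistic against a published
38-subject student cohort (shipped as the package's reference fixture):

* Quartiles use the inclusive-median rule (Tukey hinges): each half of
  the sorted sample, including the median position for odd halves, is
  summarized by its own median.  This is the convention that reproduces
  the reference boxplot values; linear interpolation does not.
* Welch's t is oriented pre minus post, degrees of freedom by
  Welch–Satterthwaite, p-values from the t distribution at the raw
  (non-integer) df; the df rounded to the nearest integer is also
  reported to mirror spreadsheet output.
* The signed-rank sum R+ collects the ranks of pairs where the pre value
  exceeds the post value; zero differences are dropped and tied absolute
  differences share average ranks.  The default p-value is the large-
  sample normal approximation without continuity correction; the
  continuity-corrected and exact (enumeration) variants are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .protocol import CohortTable

__all__ = [
    "BoxplotStats",
    "WelchResult",
    "WilcoxonResult",
    "CohortReport",
    "descriptives",
    "boxplot_stats",
    "improvement_fraction",
    "welch_t",
    "wilcoxon_signed_rank",
    "cohort_report",
]


def descriptives(values: np.ndarray) -> tuple[float, float, float]:
    """Mean, sample SD and sample variance (divisor n-1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("descriptives need at least 2 observations")
    var = float(x.var(ddof=1))
    return float(x.mean()), float(np.sqrt(var)), var


def _hinges(sorted_x: np.ndarray) -> tuple[float, float]:
    """Inclusive-median quartiles: median of each half, halves sharing the
    median position when n is odd."""
    n = sorted_x.size
    half = (n + 1) // 2
    return float(np.median(sorted_x[:half])), float(np.median(sorted_x[-half:]))


def _quartiles(x: np.ndarray, method: str) -> tuple[float, float]:
    s = np.sort(np.asarray(x, dtype=float))
    if method == "inclusive":
        return _hinges(s)
    if method == "exclusive":
        q1, q3 = np.quantile(s, [0.25, 0.75], method="weibull")
        return float(q1), float(q3)
    if method == "linear":
        q1, q3 = np.quantile(s, [0.25, 0.75], method="linear")
        return float(q1), float(q3)
    raise ValueError(f"unknown quartile method {method!r}")


@dataclass(frozen=True)
class BoxplotStats:
    """Tukey five-number summary: whiskers at the most extreme data points
    within 1.5 IQR of the quartiles, points beyond listed as outliers."""

    lower_whisker: float
    lower_quartile: float
    median: float
    upper_quartile: float
    upper_whisker: float
    outliers: tuple[float, ...] = ()

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (
            self.lower_whisker,
            self.lower_quartile,
            self.median,
            self.upper_quartile,
            self.upper_whisker,
        )


def boxplot_stats(values: np.ndarray, method: str = "inclusive") -> BoxplotStats:
    """Five-number summary with Tukey whiskers.

    ``method`` selects the quartile convention: "inclusive" (Tukey hinges,
    the calibrated default), "exclusive" or "linear".
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 5:
        raise ValueError("boxplot_stats needs at least 5 observations")
    q1, q3 = _quartiles(x, method)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    # With a non-degenerate IQR the fences always bracket the quartiles,
    # so `inside` is non-empty; a zero-IQR sample collapses to the median.
    lower = float(inside.min()) if inside.size else q1
    upper = float(inside.max()) if inside.size else q3
    outliers = tuple(float(v) for v in x[(x < lo_fence) | (x > hi_fence)])
    return BoxplotStats(lower, q1, float(np.median(x)), q3, upper, outliers)


def improvement_fraction(table: CohortTable) -> float:
    """Percent of subjects whose RSI strictly increased (post > pre).

    Zero differences count as not improved.
    """
    if table.n == 0:
        raise ValueError("empty cohort table")
    return 100.0 * float((table.differences > 0).sum()) / table.n


@dataclass(frozen=True)
class WelchResult:
    """Welch's two-sample t-test assuming unequal variances.

    ``df`` is the raw Welch–Satterthwaite value; ``df_int`` is its nearest
    integer, as spreadsheets report it.  p-values come from the t
    distribution at the raw df; one-tail is for the observed direction.
    """

    mean_pre: float
    mean_post: float
    var_pre: float
    var_post: float
    n_pre: int
    n_post: int
    t_stat: float
    df: float
    df_int: int
    p_one_tail: float
    p_two_tail: float
    t_crit_one_tail: float
    t_crit_two_tail: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def welch_t(pre: np.ndarray, post: np.ndarray, alpha: float = 0.05) -> WelchResult:
    """Welch's t-test of mean(pre) vs mean(post), oriented pre minus post."""
    x, y = np.asarray(pre, dtype=float), np.asarray(post, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("welch_t needs at least 2 observations per group")
    m1, _, v1 = descriptives(x)
    m2, _, v2 = descriptives(y)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        raise ValueError("zero variance in both groups")
    t_stat = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p_one = float(stats.t.sf(abs(t_stat), df))
    df_int = int(np.floor(df + 0.5))
    return WelchResult(
        mean_pre=m1,
        mean_post=m2,
        var_pre=v1,
        var_post=v2,
        n_pre=n1,
        n_post=n2,
        t_stat=float(t_stat),
        df=float(df),
        df_int=df_int,
        p_one_tail=p_one,
        p_two_tail=min(1.0, 2.0 * p_one),
        t_crit_one_tail=float(stats.t.ppf(1 - alpha, df_int)),
        t_crit_two_tail=float(stats.t.ppf(1 - alpha / 2, df_int)),
    )


@dataclass(frozen=True)
class WilcoxonResult:
    """Wilcoxon signed-rank test on paired pre/post values.

    r_plus is the rank sum of pairs with pre > post; r_minus of pairs with
    post > pre.  n_effective counts the non-zero differences actually
    ranked.  p_value is two-sided under the selected method.
    """

    r_plus: float
    r_minus: float
    n_effective: int
    p_value: float
    method: str
    p_one_tail: float | None = None
    z: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _signed_rank_sums(pre: np.ndarray, post: np.ndarray) -> tuple[float, float, np.ndarray]:
    d = np.asarray(pre, dtype=float) - np.asarray(post, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), float(ranks[d < 0].sum()), d


def _exact_signed_rank_cdf(m: int, w: int) -> float:
    """P(W <= w) for the signed-rank null distribution with ranks 1..m,
    by dynamic programming over the 2^m equiprobable sign assignments."""
    max_w = m * (m + 1) // 2
    w = min(w, max_w)
    if w < 0:
        return 0.0
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, m + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return float(counts[: w + 1].sum() / 2.0**m)


def wilcoxon_signed_rank(
    pre: np.ndarray, post: np.ndarray, method: str = "normal_approx"
) -> WilcoxonResult:
    """Paired signed-rank test of pre against post.

    Methods: "normal_approx" (large-sample z, no continuity correction —
    the calibrated default), "normal_approx_cc" (with the 0.5 continuity
    correction), "exact" (full enumeration of the null distribution;
    requires untied absolute differences).
    """
    x, y = np.asarray(pre, dtype=float), np.asarray(post, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pre and post must be paired (equal length)")
    r_plus, r_minus, d = _signed_rank_sums(x, y)
    m = d.size
    w_small = min(r_plus, r_minus)

    if method == "exact":
        if not float(w_small).is_integer() or np.unique(np.abs(d)).size != m:
            raise ValueError("exact method requires untied absolute differences")
        p_one = _exact_signed_rank_cdf(m, int(w_small))
        return WilcoxonResult(
            r_plus=r_plus,
            r_minus=r_minus,
            n_effective=m,
            p_value=min(1.0, 2.0 * p_one),
            method="exact",
            p_one_tail=p_one,
        )

    if method not in ("normal_approx", "normal_approx_cc"):
        raise ValueError(f"unknown wilcoxon method {method!r}")
    mu = m * (m + 1) / 4.0
    sigma = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0)
    cc = 0.5 if method == "normal_approx_cc" else 0.0
    z = (w_small - mu + cc) / sigma
    p_one = float(stats.norm.cdf(z))
    return WilcoxonResult(
        r_plus=r_plus,
        r_minus=r_minus,
        n_effective=m,
        p_value=min(1.0, 2.0 * p_one),
        method=method,
        p_one_tail=p_one,
        z=float(z),
    )


@dataclass(frozen=True)
class CohortReport:
    """All cohort statistics in one object, renderable as JSON or text."""

    n: int
    descriptives_pre: tuple[float, float, float]  # mean, sd, variance
    descriptives_post: tuple[float, float, float]
    boxplot_pre: BoxplotStats
    boxplot_post: BoxplotStats
    improvement_percent: float
    welch: WelchResult
    wilcoxon: WilcoxonResult

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pre": dict(zip(("mean", "sd", "variance"), self.descriptives_pre)),
            "post": dict(zip(("mean", "sd", "variance"), self.descriptives_post)),
            "boxplot_pre": {
                **dict(
                    zip(
                        ("lower_whisker", "lower_quartile", "median", "upper_quartile", "upper_whisker"),
                        self.boxplot_pre.as_tuple(),
                    )
                ),
                "outliers": list(self.boxplot_pre.outliers),
            },
            "boxplot_post": {
                **dict(
                    zip(
                        ("lower_whisker", "lower_quartile", "median", "upper_quartile", "upper_whisker"),
                        self.boxplot_post.as_tuple(),
                    )
                ),
                "outliers": list(self.boxplot_post.outliers),
            },
            "improvement_percent": self.improvement_percent,
            "welch": self.welch.to_dict(),
            "wilcoxon": self.wilcoxon.to_dict(),
        }

    def render_text(self) -> str:
        bp, ba = self.boxplot_pre, self.boxplot_post
        w, wx = self.welch, self.wilcoxon
        lines = [
            f"Cohort report (n = {self.n} paired subjects)",
            "",
            "Boxplot values",
            "          LowerWhisk  Q1      Median  Q3      UpperWhisk",
            f"Pre-test  {bp.lower_whisker:<10.2f}{bp.lower_quartile:<8.2f}"
            f"{bp.median:<8.2f}{bp.upper_quartile:<8.2f}{bp.upper_whisker:.2f}",
            f"Post-test {ba.lower_whisker:<10.2f}{ba.lower_quartile:<8.2f}"
            f"{ba.median:<8.2f}{ba.upper_quartile:<8.2f}{ba.upper_whisker:.2f}",
            "",
            f"Improved subjects: {self.improvement_percent:.1f}%",
            "",
            "Welch's t-test (two-sample, unequal variances)",
            f"  Mean      {w.mean_pre:.8f}  {w.mean_post:.8f}",
            f"  Variance  {w.var_pre:.7f}  {w.var_post:.8f}",
            f"  Observations  {w.n_pre}  {w.n_post}",
            f"  df  {w.df_int}  (raw {w.df:.4f})",
            f"  t Stat  {w.t_stat:.7f}",
            f"  P(T<=t) one-tail  {w.p_one_tail:.7f}",
            f"  t Critical one-tail  {w.t_crit_one_tail:.8f}",
            f"  P(T<=t) two-tail  {w.p_two_tail:.6f}",
            f"  t Critical two-tail  {w.t_crit_two_tail:.8f}",
            "",
            "Wilcoxon signed-rank test",
            f"  R+ {wx.r_plus:.0f}  R- {wx.r_minus:.0f}  (n effective {wx.n_effective})",
            f"  p-value {wx.p_value:.5f}  [{wx.method}]",
        ]
        return "\n".join(lines)


def cohort_report(
    table: CohortTable,
    *,
    quartile_method: str = "inclusive",
    wilcoxon_method: str = "normal_approx",
) -> CohortReport:
    """Assemble the full statistical battery for a pre/post cohort."""
    pre, post = table.pre, table.post
    return CohortReport(
        n=table.n,
        descriptives_pre=descriptives(pre),
        descriptives_post=descriptives(post),
        boxplot_pre=boxplot_stats(pre, quartile_method),
        boxplot_post=boxplot_stats(post, quartile_method),
        improvement_percent=improvement_fraction(table),
        welch=welch_t(pre, post),
        wilcoxon=wilcoxon_signed_rank(pre, post, wilcoxon_method),
    )


def plot_boxplot(table: CohortTable, path: str) -> None:
    """Side-by-side pre/post RSI boxplot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot([table.pre, table.post], tick_labels=["Pre-test", "Post-test"], whis=1.5)
    ax.set_ylabel("RSI")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
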