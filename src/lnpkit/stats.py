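"""Group-comparison decision tree for population data.

Summary convention: large groups are reported as median +- IQR, small groups
(n below a configurable threshold) as mean +- sd. Hypothesis testing follows
a fixed decision tree: per-group Lilliefors normality testing whenever
n >= 4 (with Monte-Carlo critical values); non-normal data are compared with
the Kruskal-Wallis test (more than two groups) or the Wilcoxon rank-sum test
(two groups); when every group is small (n <= 5) one-way ANOVA is used
instead (normality testing at such n is uninformative, and this small-n rule
takes precedence); significant omnibus tests are followed by Tukey-Kramer
pairwise comparisons at alpha = 0.05 (on rank-transformed data after a
Kruskal-Wallis omnibus). Every branch taken is recorded in an audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "summarize",
    "compare_groups",
    "lilliefors_statistic",
    "lilliefors_mc",
    "StatsReport",
]

# cached null distributions of the Lilliefors statistic, keyed by (n, n_mc)
_LILLIEFORS_NULL: dict[tuple[int, int], np.ndarray] = {}


def lilliefors_statistic(x: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance to the normal fitted to the sample."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return 1.0
    cdf = scipy.stats.norm.cdf(x, mu, sd)
    up = np.arange(1, n + 1) / n - cdf
    down = cdf - np.arange(0, n) / n
    return float(max(up.max(), down.max()))


def _null_distribution(n: int, n_mc: int, seed: int) -> np.ndarray:
    key = (n, n_mc)
    if key not in _LILLIEFORS_NULL:
        # seed the null simulation from (seed, n) so the cached table does
        # not depend on the order in which sample sizes are first seen
        rng = np.random.default_rng(np.random.SeedSequence((seed, n)))
        stats = np.empty(n_mc)
        for i in range(n_mc):
            stats[i] = lilliefors_statistic(rng.normal(size=n))
        _LILLIEFORS_NULL[key] = np.sort(stats)
    return _LILLIEFORS_NULL[key]


def lilliefors_mc(x: np.ndarray, seed: int = 0, n_mc: int = 10000
                  ) -> tuple[float, float]:
    """Lilliefors normality test with a Monte-Carlo null.

    The null distribution of the statistic (KS distance after estimating
    mean and sd) is simulated once per sample size and cached. Returns
    (statistic, p-value).
    """
    stat = lilliefors_statistic(x)
    null = _null_distribution(len(np.asarray(x)), n_mc, seed)
    # p = P(null >= stat), with the +1 correction for a valid MC p-value
    n_ge = len(null) - np.searchsorted(null, stat, side="left")
    return stat, float((n_ge + 1) / (len(null) + 1))


def summarize(groups: dict[str, np.ndarray],
              small_n_threshold: int = 10) -> pd.DataFrame:
    """Per-group location/spread following the reporting rule.

    Groups with n >= ``small_n_threshold`` are summarised as median +- IQR,
    smaller groups as mean +- sd; the rule applied is recorded per row.
    """
    rows = []
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        if len(values) == 0:
            raise ValueError(f"group {name!r} is empty")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"group {name!r} has non-finite values")
        if len(values) >= small_n_threshold:
            q25, q50, q75 = np.percentile(values, [25, 50, 75])
            rows.append({"group": name, "n": len(values), "center": q50,
                         "spread": q75 - q25, "rule": "median±IQR"})
        else:
            sd = values.std(ddof=1) if len(values) > 1 else 0.0
            rows.append({"group": name, "n": len(values),
                         "center": values.mean(), "spread": sd,
                         "rule": "mean±sd"})
    return pd.DataFrame(rows)


@dataclass
class StatsReport:
    """Decision-tree outcome with a full audit trail."""

    branch: str  # 'anova' | 'anova-small-n' | 'kruskal-wallis' | 'rank-sum'
    omnibus_test: str
    statistic: float
    p_value: float
    significant: bool
    alpha: float
    normality: dict[str, dict]  # per-group {stat, p, normal | None}
    posthoc: pd.DataFrame | None
    audit: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"omnibus: {self.omnibus_test}  stat = {self.statistic:.4g}  "
                 f"p = {self.p_value:.4g}  "
                 f"{'SIGNIFICANT' if self.significant else 'n.s.'} "
                 f"(alpha = {self.alpha})"]
        lines += [f"  - {step}" for step in self.audit]
        if self.posthoc is not None:
            lines.append(self.posthoc.to_string(index=False))
        return "\n".join(lines)


def _tukey_kramer(values: np.ndarray, labels: np.ndarray,
                  alpha: float) -> pd.DataFrame:
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:],
                         columns=res.summary().data[0])
    return frame


def compare_groups(groups: dict[str, np.ndarray], alpha: float = 0.05,
                   seed: int = 0, n_mc: int = 10000,
                   small_n: int = 5) -> StatsReport:
    """Run the full group-comparison decision tree.

    Parameters
    ----------
    groups : mapping of group label to 1-D array of observations (>= 2 groups).
    alpha : significance level for normality, omnibus and post-hoc tests.
    seed, n_mc : Monte-Carlo control for the Lilliefors null distribution.
    small_n : groups are "small" at or below this size; when *all* groups are
        small the ANOVA branch is taken regardless of normality.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, v in arrays.items():
        if len(v) == 0:
            raise ValueError(f"group {name!r} is empty")
    audit: list[str] = []

    # normality assessment where possible (n >= 4)
    normality: dict[str, dict] = {}
    for name, v in arrays.items():
        if len(v) >= 4:
            stat, p = lilliefors_mc(v, seed=seed, n_mc=n_mc)
            normality[name] = {"stat": stat, "p": p, "normal": p >= alpha}
            audit.append(f"Lilliefors({name}, n={len(v)}): stat={stat:.4f} "
                         f"p={p:.4f} -> {'normal' if p >= alpha else 'non-normal'}")
        else:
            normality[name] = {"stat": None, "p": None, "normal": None}
            audit.append(f"Lilliefors({name}, n={len(v)}): not testable (n < 4)")

    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])

    all_small = all(len(v) <= small_n for v in arrays.values())
    any_nonnormal = any(r["normal"] is False for r in normality.values())

    posthoc = None
    if all_small:
        branch = "anova-small-n"
        audit.append(f"all groups n <= {small_n}: one-way ANOVA branch "
                     "(small-n rule takes precedence)")
        if all(np.ptp(v) == 0 for v in arrays.values()):
            audit.append("zero-variance groups: ANOVA degenerate, "
                         "falling back to rank-based omnibus")
            branch, stat, p = _nonparametric(arrays, audit)
        else:
            stat, p = scipy.stats.f_oneway(*arrays.values())
            test = "one-way ANOVA"
            audit.append(f"{test}: F={stat:.4g} p={p:.4g}")
    elif any_nonnormal:
        branch, stat, p = _nonparametric(arrays, audit)
    else:
        branch = "anova"
        audit.append("all testable groups normal: one-way ANOVA")
        stat, p = scipy.stats.f_oneway(*arrays.values())
        audit.append(f"one-way ANOVA: F={stat:.4g} p={p:.4g}")

    test_name = {"anova": "one-way ANOVA", "anova-small-n": "one-way ANOVA",
                 "kruskal-wallis": "Kruskal-Wallis",
                 "rank-sum": "Wilcoxon rank-sum"}[branch]
    significant = bool(p < alpha)

    if significant and len(arrays) > 2:
        if branch == "kruskal-wallis":
            ranks = scipy.stats.rankdata(values)
            posthoc = _tukey_kramer(ranks, labels, alpha)
            audit.append("post-hoc: Tukey-Kramer on rank-transformed data")
        else:
            posthoc = _tukey_kramer(values, labels, alpha)
            audit.append("post-hoc: Tukey-Kramer")

    return StatsReport(branch=branch, omnibus_test=test_name,
                       statistic=float(stat), p_value=float(p),
                       significant=significant, alpha=alpha,
                       normality=normality, posthoc=posthoc, audit=audit)


def _nonparametric(arrays: dict[str, np.ndarray], audit: list[str]
                   ) -> tuple[str, float, float]:
    if len(arrays) > 2:
        stat, p = scipy.stats.kruskal(*arrays.values())
        audit.append(f"Kruskal-Wallis: H={stat:.4g} p={p:.4g}")
        return "kruskal-wallis", float(stat), float(p)
    a, b = arrays.values()
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    audit.append(f"Wilcoxon rank-sum: U={res.statistic:.4g} p={res.pvalue:.4g}")
    return "rank-sum", float(res.statistic), float(res.pvalue)
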