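"""Nonparametric statistical battery for the detection/tACS analyses.

Paired contrasts (hit vs miss power, pre vs post features) use the
Wilcoxon signed-rank test; independent-group contrasts (alpha vs sham) use
the Mann-Whitney U test; the three task blocks are compared with a
Friedman test followed by pairwise Wilcoxon post hocs at a Bonferroni-
corrected level of 0.05/3; distribution equality is checked with the
two-sample Kolmogorov-Smirnov test; the baseline-dependence of
stimulation-induced power change is an ordinary least-squares regression
of the pre-to-post change on baseline power.

At the study's sample sizes (6-12 per group) asymptotic rank tests are
unreliable, so exact p-values are computed by complete enumeration
whenever the (combined) sample size is at most 12: all 2^n sign
assignments for the signed-rank test, all C(n1+n2, n1) group labelings for
the U test. Larger samples fall back to the normal approximation with tie
correction. Z values are reported alongside in the convention of standard
statistics packages (signed-rank: z of the smaller rank sum, hence always
negative under any effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sstats

from .errors import ConfigError, DegenerateDataError

__all__ = [
    "StatsResult",
    "RegressionResult",
    "wilcoxon_sr",
    "mann_whitney_u",
    "friedman_posthoc",
    "ks_two_sample",
    "linregress_baseline",
    "EXACT_N_MAX",
]

# exact enumeration whenever the (combined) n is at most this
EXACT_N_MAX = 12


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    sem = x.std(ddof=1) / np.sqrt(x.size) if x.size > 1 else 0.0
    return float(x.mean()), float(sem)


@dataclass
class StatsResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    z_value: float
    p_two_sided: float
    n: int
    method: str = "exact"
    group_summaries: dict[str, tuple[float, float]] = field(default_factory=dict)
    posthoc: dict[str, "StatsResult"] | None = None
    posthoc_alpha: float | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_two_sided) or 0.0 <= self.p_two_sided <= 1.0):
            raise ConfigError("p-value outside [0, 1]")


@dataclass
class RegressionResult:
    """Ordinary least-squares fit of y on x."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int
    zero_crossing: float
    caveat: str | None = None


def _signed_ranks(diff: np.ndarray) -> np.ndarray:
    """Midranks of |diff| (zeros already removed)."""
    return sstats.rankdata(np.abs(diff))


def wilcoxon_sr(a, b, label_a: str = "a", label_b: str = "b") -> StatsResult:
    """Two-sided Wilcoxon signed-rank test of paired samples.

    Zero differences are discarded before ranking (Wilcoxon's original
    treatment). Exact p by enumeration of all sign assignments for
    effective n <= 12; normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ConfigError("paired samples must have equal length")
    diff = b - a
    diff = diff[diff != 0.0]
    n = diff.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = _signed_ranks(diff)
    w_pos = ranks[diff > 0].sum()
    w_neg = ranks[diff < 0].sum()
    t_stat = min(w_pos, w_neg)

    # normal approximation z (tie-corrected), reported for all n
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (t_stat - mu) / sigma if sigma > 0 else 0.0

    if n <= EXACT_N_MAX:
        # all 2^n sign assignments of the observed ranks
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
        w_all = (signs * ranks).sum(axis=1)
        t_all = np.minimum(w_all, ranks.sum() - w_all)
        p = float((t_all <= t_stat + 1e-12).mean())
        method = "exact"
    else:
        p = float(2.0 * sstats.norm.cdf(z))
        method = "asymptotic"
    return StatsResult(
        test="wilcoxon_sr",
        statistic=float(t_stat),
        z_value=float(z),
        p_two_sided=min(p, 1.0),
        n=int(n),
        method=method,
        group_summaries={label_a: _mean_sem(a), label_b: _mean_sem(b)},
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x relative to y via joint midranks."""
    ranks = sstats.rankdata(np.concatenate([x, y]))
    r_x = ranks[: x.size].sum()
    return r_x - x.size * (x.size + 1) / 2.0


def mann_whitney_u(
    group_a, group_b, label_a: str = "a", label_b: str = "b"
) -> StatsResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    Exact p by enumeration of all group labelings for combined n <= 12
    (valid with ties); tie-corrected normal approximation otherwise. The
    reported statistic is min(U_a, U_b).
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    u_a = _u_statistic(x, y)
    u = min(u_a, n1 * n2 - u_a)

    pooled = np.concatenate([x, y])
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    nn = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (nn * (nn - 1)) if nn > 1 else 0.0
    sigma = np.sqrt(n1 * n2 / 12.0 * (nn + 1 - tie_term))
    z = (u - mu) / sigma if sigma > 0 else 0.0

    if nn <= EXACT_N_MAX:
        stat_obs = abs(u_a - mu)
        count = 0
        total = 0
        idx = np.arange(nn)
        for comb in combinations(idx, n1):
            sel = np.zeros(nn, dtype=bool)
            sel[list(comb)] = True
            u_perm = _u_statistic(pooled[sel], pooled[~sel])
            if abs(u_perm - mu) >= stat_obs - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "exact"
    else:
        p = float(2.0 * sstats.norm.cdf(z))
        method = "asymptotic"
    return StatsResult(
        test="mann_whitney_u",
        statistic=float(u),
        z_value=float(z),
        p_two_sided=min(p, 1.0),
        n=int(nn),
        method=method,
        group_summaries={label_a: _mean_sem(x), label_b: _mean_sem(y)},
    )


def friedman_posthoc(
    blocks: np.ndarray,
    block_names: tuple[str, ...] = ("pre", "during", "post"),
    alpha: float = 0.05,
) -> StatsResult:
    """Friedman test over k=3 repeated measures plus pairwise signed-rank
    post hocs at the Bonferroni-corrected level alpha / 3.

    ``blocks``: (k, n) array, one row per condition, one column per
    subject; missing values are not allowed.
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2 or blocks.shape[0] != len(block_names):
        raise ConfigError(f"expected a ({len(block_names)}, n) block matrix")
    if np.isnan(blocks).any():
        raise ConfigError("missing cells are not allowed in the Friedman test")
    k, n = blocks.shape
    if n < 2:
        raise ConfigError("Friedman test needs at least 2 subjects")
    if np.all(blocks == blocks[0]):
        # every subject constant across conditions: no evidence either way
        chi2, p = 0.0, 1.0
    else:
        chi2, p = sstats.friedmanchisquare(*blocks)
    n_pairs = k * (k - 1) // 2
    posthoc: dict[str, StatsResult] = {}
    for i, j in combinations(range(k), 2):
        key = f"{block_names[i]}_vs_{block_names[j]}"
        try:
            posthoc[key] = wilcoxon_sr(
                blocks[i], blocks[j], label_a=block_names[i], label_b=block_names[j]
            )
        except DegenerateDataError:
            posthoc[key] = StatsResult(
                test="wilcoxon_sr", statistic=np.nan, z_value=0.0,
                p_two_sided=np.nan, n=n, method="degenerate",
            )
    return StatsResult(
        test="friedman",
        statistic=float(chi2),
        z_value=np.nan,
        p_two_sided=float(p),
        n=int(n),
        method="asymptotic",
        group_summaries={
            name: _mean_sem(blocks[i]) for i, name in enumerate(block_names)
        },
        posthoc=posthoc,
        posthoc_alpha=alpha / n_pairs,
    )


def ks_two_sample(a, b, label_a: str = "a", label_b: str = "b") -> StatsResult:
    """Two-sided two-sample Kolmogorov-Smirnov test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigError("both samples must be nonempty")
    res = sstats.ks_2samp(a, b, alternative="two-sided", method="auto")
    return StatsResult(
        test="ks",
        statistic=float(res.statistic),
        z_value=np.nan,
        p_two_sided=float(res.pvalue),
        n=int(a.size + b.size),
        method="auto",
        group_summaries={label_a: _mean_sem(a), label_b: _mean_sem(b)},
    )


_RTM_CAVEAT = (
    "Baseline power enters both the predictor and the response "
    "(change = post - pre), so regression to the mean alone produces a "
    "negative slope; interpret the baseline dependence with this in mind."
)


def linregress_baseline(pre_power, delta_power) -> RegressionResult:
    """OLS regression of the pre-to-post power change on baseline power.

    Reports slope, intercept, R^2, the F test of the slope, and the
    baseline value at which the predicted change crosses zero. The result
    carries a regression-to-the-mean caveat because the baseline appears
    on both axes.
    """
    x = np.asarray(pre_power, dtype=float)
    y = np.asarray(delta_power, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ConfigError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ConfigError("zero variance in the predictor")
    fit = sstats.linregress(x, y)
    r2 = fit.rvalue**2
    n = x.size
    # F test of the slope with (1, n-2) df; equals the square of the t stat
    f_stat = np.inf if r2 >= 1.0 else r2 * (n - 2) / (1.0 - r2)
    crossing = -fit.intercept / fit.slope if fit.slope != 0 else np.nan
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        f_statistic=float(f_stat),
        p_value=float(fit.pvalue),
        n=int(n),
        zero_crossing=float(crossing),
        caveat=_RTM_CAVEAT,
    )
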