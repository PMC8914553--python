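"""Supporting statistical tests and effect sizes.

Nonparametric tests used throughout the analysis: an exact one-sample
binomial bound for above-chance categorization, Cohen's g for one-sample
proportions, Spearman rank correlations, the Mann-Whitney U comparison of
confidence ratings, and the Wilcoxon signed-rank test comparing per-image
observed ambiguity with its permutation chance level.  All tests are
two-sided unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TestOutcome",
    "chance_accuracy",
    "binomial_exceed_chance",
    "cohens_g",
    "spearman_ranks",
    "compare_confidence",
    "wilcoxon_paired",
    "pooled_cohens_d",
    "DegenerateDataError",
]


class DegenerateDataError(ValueError):
    pass


@dataclass(frozen=True)
class TestOutcome:
    """One reported statistical test: statistic, p, effect size, sample size."""

    statistic_name: str
    statistic_value: float
    p_value: float
    effect_size_name: str
    effect_size_value: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def chance_accuracy(n_options: int) -> float:
    """Guessing accuracy with ``n_options`` equally likely categories."""
    if n_options < 2:
        raise ValueError("need at least 2 options")
    return 1.0 / n_options


def binomial_exceed_chance(successes: int, n: int, alpha: float = 0.05) -> float:
    """Exact one-sided lower confidence bound for a binomial proportion.

    Clopper-Pearson construction: the lower 1-alpha bound is the Beta
    quantile ``Beta(alpha; x, n - x + 1)``; for x = n it reduces to the
    closed form ``alpha**(1/n)``.  Used for the probability that observed
    categorization accuracy exceeds chance, given that ``successes`` of
    ``n`` participants individually exceeded it.
    """
    if not 0 <= successes <= n or n < 1:
        raise ValueError(f"invalid counts: {successes}/{n}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if successes == 0:
        return 0.0
    if successes == n:
        return float(alpha ** (1.0 / n))
    return float(stats.beta.ppf(alpha, successes, n - successes + 1))


def cohens_g(observed_prop: float, reference_prop: float) -> float:
    """Effect size for a one-sample proportion test: the raw difference."""
    for p in (observed_prop, reference_prop):
        if not 0 <= p <= 1:
            raise ValueError(f"proportion outside [0, 1]: {p}")
    return observed_prop - reference_prop


def spearman_ranks(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (midrank ties) with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def pooled_cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d from group means and the pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def compare_confidence(group_a: Sequence[float], group_b: Sequence[float]) -> TestOutcome:
    """Two-sided Mann-Whitney U on per-participant mean confidences.

    The U statistic reported is that of the first group; the effect size is
    pooled-SD Cohen's d on the per-participant means.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return TestOutcome(
        statistic_name="mann_whitney_U",
        statistic_value=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size_name="cohens_d",
        effect_size_value=abs(pooled_cohens_d(a, b)),
        n=int(a.size + b.size),
    )


def wilcoxon_paired(
    observed: Sequence[float],
    chance: Sequence[float],
    exact_max_n: int = 25,
) -> TestOutcome:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; T is the smaller of the positive- and
    negative-rank sums.  The exact null distribution is used up to
    ``exact_max_n`` non-zero differences, the normal approximation with
    continuity correction above.  The effect size is the paired Cohen's d,
    mean(diff) / sd(diff).
    """
    obs = np.asarray(observed, dtype=float)
    cha = np.asarray(chance, dtype=float)
    if obs.size != cha.size or obs.size < 6:
        raise ValueError("need equal-length samples with at least 6 pairs")
    diff = obs - cha
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    method = "exact" if nonzero.size <= exact_max_n else "approx"
    res = stats.wilcoxon(
        obs, cha, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    sd = diff.std(ddof=1)
    d = 0.0 if sd == 0 else float(diff.mean() / sd)
    return TestOutcome(
        statistic_name="wilcoxon_T",
        statistic_value=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size_name="paired_cohens_d",
        effect_size_value=d,
        n=int(nonzero.size),
    )
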