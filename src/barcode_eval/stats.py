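"""Statistical battery: Wilson intervals, Scheffé contrasts, rank and
point-biserial correlations, and McNemar's test for paired binary outcomes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .records import BarcodeEvalError


class StatsError(BarcodeEvalError):
    pass


@dataclass(frozen=True)
class WilsonCI:
    k: int
    n: int
    level: float
    lower: float
    upper: float

    @property
    def proportion(self) -> float:
        return self.k / self.n


def wilson_ci(k: int, n: int, level: float = 0.95) -> WilsonCI:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise StatsError("n must be >= 1")
    if not 0 <= k <= n:
        raise StatsError("k must be in [0, n]")
    lower, upper = proportion_confint(k, n, alpha=1 - level, method="wilson")
    return WilsonCI(k=k, n=n, level=level, lower=float(lower), upper=float(upper))


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    labels: tuple = ()
    significant: bool | None = None
    extra: dict = field(default_factory=dict)


def scheffe(
    groups: Sequence,
    distribution: str = "gaussian",
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> list[TestResult]:
    """All pairwise contrasts under Scheffé's simultaneous criterion.

    ``gaussian``: groups are numeric samples; the contrast statistic is
    ``(mean_i - mean_j)^2 / (MSE * (1/n_i + 1/n_j))`` with the pooled
    within-group mean square, judged against ``(g-1) * F_{1-alpha}(g-1, N-g)``
    (p-value from F with the statistic divided by g-1).

    ``binomial``: groups are (k, n) success counts; the variance of each
    proportion is approximated by ``p(1-p)/n`` and the contrast statistic
    ``(p_i - p_j)^2 / (v_i + v_j)`` is judged against chi-square with g-1
    degrees of freedom (large-sample Scheffé criterion).

    Degenerate contrasts (zero pooled variance) are flagged in ``extra``.
    """
    g = len(groups)
    if g < 2:
        raise StatsError("need at least two groups")
    if labels is None:
        labels = [f"group{i}" for i in range(g)]
    results: list[TestResult] = []
    if distribution == "gaussian":
        arrs = [np.asarray(x, dtype=float) for x in groups]
        if any(a.size == 0 for a in arrs):
            raise StatsError("empty group")
        ns = np.array([a.size for a in arrs])
        N = int(ns.sum())
        if N - g < 1:
            raise StatsError("not enough observations for within-group variance")
        means = np.array([a.mean() for a in arrs])
        sse = sum(((a - a.mean()) ** 2).sum() for a in arrs)
        mse = sse / (N - g)
        fcrit = sps.f.ppf(1 - alpha, g - 1, N - g)
        for i, j in itertools.combinations(range(g), 2):
            diff = means[i] - means[j]
            denom = mse * (1 / ns[i] + 1 / ns[j])
            if denom == 0:
                degenerate = True
                stat = np.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            else:
                degenerate = False
                stat = diff**2 / denom
                p = float(sps.f.sf(stat / (g - 1), g - 1, N - g))
            results.append(
                TestResult(
                    name="scheffe",
                    statistic=float(stat),
                    p_value=p,
                    labels=(labels[i], labels[j]),
                    significant=bool(stat > (g - 1) * fcrit) if not degenerate else diff != 0,
                    extra={"diff": float(diff), "degenerate": degenerate},
                )
            )
    elif distribution == "binomial":
        props, variances = [], []
        for k, n in groups:
            if n < 1 or not 0 <= k <= n:
                raise StatsError("binomial groups must be (k, n) with 0 <= k <= n")
            p_hat = k / n
            props.append(p_hat)
            variances.append(p_hat * (1 - p_hat) / n)
        crit = sps.chi2.ppf(1 - alpha, g - 1)
        for i, j in itertools.combinations(range(g), 2):
            diff = props[i] - props[j]
            denom = variances[i] + variances[j]
            if denom == 0:
                degenerate = True
                stat = np.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            else:
                degenerate = False
                stat = diff**2 / denom
                p = float(sps.chi2.sf(stat, g - 1))
            results.append(
                TestResult(
                    name="scheffe",
                    statistic=float(stat),
                    p_value=p,
                    labels=(labels[i], labels[j]),
                    significant=bool(stat > crit) if not degenerate else diff != 0,
                    extra={"diff": float(diff), "degenerate": degenerate},
                )
            )
    else:
        raise StatsError(f"unknown distribution {distribution!r}")
    return results


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsError("length mismatch")
    if x.size < 3:
        raise StatsError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatsError("constant vector: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return TestResult(name="spearman", statistic=float(rho), p_value=float(p))


def point_biserial(binary: Sequence[int], numeric: Sequence[float]) -> TestResult:
    """Point-biserial correlation (Pearson r of a 0/1 vector with a numeric
    vector), two-sided p via the t transform."""
    b = np.asarray(binary, dtype=float)
    y = np.asarray(numeric, dtype=float)
    if b.size != y.size:
        raise StatsError("length mismatch")
    if not set(np.unique(b)) <= {0.0, 1.0}:
        raise StatsError("binary vector must contain only 0 and 1")
    if len(np.unique(b)) < 2:
        raise StatsError("binary vector has a single class")
    if np.all(y == y[0]):
        raise StatsError("numeric vector is constant: correlation undefined")
    r, p = sps.pointbiserialr(b, y)
    return TestResult(name="point_biserial", statistic=float(r), p_value=float(p))


def mcnemar(b: int, c: int, mode: str = "exact") -> TestResult:
    """McNemar's test on the discordant cell counts of a paired 2x2 table.

    ``exact``: two-sided binomial test of b successes in b+c trials at 0.5
    (doubled smaller tail, capped at 1; p = 1 when b + c = 0).
    ``chi2``: statistic (b - c)^2 / (b + c) against chi-square(1).
    """
    if b < 0 or c < 0:
        raise StatsError("discordant counts must be non-negative")
    n = b + c
    if mode == "exact":
        if n == 0:
            return TestResult(name="mcnemar_exact", statistic=0.0, p_value=1.0)
        p = min(1.0, 2 * float(sps.binom.cdf(min(b, c), n, 0.5)))
        return TestResult(name="mcnemar_exact", statistic=float(min(b, c)), p_value=p)
    if mode == "chi2":
        if n == 0:
            raise StatsError("chi-square McNemar undefined with no discordant pairs")
        stat = (b - c) ** 2 / n
        return TestResult(
            name="mcnemar_chi2", statistic=float(stat), p_value=float(sps.chi2.sf(stat, 1))
        )
    raise StatsError(f"unknown mode {mode!r}")
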