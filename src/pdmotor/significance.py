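"""Statistical comparison of classifiers across repeated training runs.

Deep models are compared on the score distributions of repeated training
runs (ten repetitions by convention).  Because such score distributions
are rarely normal, comparison uses *almost stochastic order* (ASO):
algorithm A stochastically dominates B when A's empirical CDF lies below
B's everywhere; ASO relaxes this by measuring the violation ratio

    eps = ( integral over {t : q_A(t) < q_B(t)} of (q_B - q_A)^2 dt )
          / ( integral over [0,1] of (q_A - q_B)^2 dt )

on the quantile functions q (an optimal-transport decomposition of the
squared Wasserstein distance).  eps = 0 means full dominance of A, eps = 1
full dominance of B, and the two directions are complementary
(eps_AB + eps_BA = 1 whenever the distributions differ).  A bootstrap
(resampling both sides with replacement) yields a (1 - alpha) upper
confidence bound on eps; dominance is declared when that bound is below
0.2.

A bootstrap power analysis estimates the probability that a comparison of
samples this size reaches significance, and Bonferroni correction adjusts
alpha for families of comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

QUANTILE_GRID_SIZE = 1000
DOMINANCE_THRESHOLD = 0.2


@dataclass
class RunScores:
    model: str
    metric: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or len(self.scores) < 2:
            raise ValueError("RunScores needs >= 2 scalar scores")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


@dataclass
class AsoResult:
    eps_min: float        # point estimate of the violation ratio
    upper_bound: float    # (1 - alpha) upper confidence bound
    alpha: float
    n_bootstrap: int
    dominant: bool        # upper_bound < DOMINANCE_THRESHOLD
    degenerate: bool = False


def _quantiles(x: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.quantile(x, grid, method="inverted_cdf")


def violation_ratio(a: np.ndarray, b: np.ndarray,
                    grid_size: int = QUANTILE_GRID_SIZE) -> float:
    """eps in [0, 1]; 0 when A fully dominates B.  0.5 for identical samples."""
    grid = (np.arange(grid_size) + 0.5) / grid_size
    qa, qb = _quantiles(a, grid), _quantiles(b, grid)
    diff = qa - qb
    total = np.sum(diff**2)
    if total <= 0:
        return 0.5
    violation = np.sum(diff[diff < 0] ** 2)
    return float(violation / total)


def aso(a: RunScores | np.ndarray, b: RunScores | np.ndarray,
        alpha: float = 0.05, n_bootstrap: int = 1000, seed: int = 0) -> AsoResult:
    """Almost-stochastic-order comparison: is A better than B?

    The returned upper bound follows the asymptotic bootstrap construction:
    eps_hat + z_{1-alpha} * sd(sqrt(nm/(n+m)) * (eps* - eps_hat)) / sqrt(nm/(n+m)),
    clipped to [0, 1].  Identical constant samples on both sides are
    flagged degenerate (self-comparison cannot dominate).
    """
    xa = a.scores if isinstance(a, RunScores) else np.asarray(a, float)
    xb = b.scores if isinstance(b, RunScores) else np.asarray(b, float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("each side needs >= 2 scores")
    rng = np.random.default_rng(seed)
    eps_hat = violation_ratio(xa, xb)
    const = np.sqrt(len(xa) * len(xb) / (len(xa) + len(xb)))
    boot = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        ra = rng.choice(xa, size=len(xa), replace=True)
        rb = rng.choice(xb, size=len(xb), replace=True)
        boot[i] = violation_ratio(ra, rb)
    sigma = np.std(const * (boot - eps_hat))
    degenerate = np.ptp(xa) == 0 and np.ptp(xb) == 0 and np.all(xa[0] == xb)
    z = stats.norm.ppf(1 - alpha)
    upper = float(np.clip(eps_hat + z * sigma / const, 0.0, 1.0))
    if degenerate:
        upper = max(upper, 0.5)
    return AsoResult(
        eps_min=eps_hat, upper_bound=upper, alpha=alpha,
        n_bootstrap=n_bootstrap,
        dominant=bool(upper < DOMINANCE_THRESHOLD) and not degenerate,
        degenerate=bool(degenerate),
    )


def bootstrap_power(a: RunScores | np.ndarray, b: RunScores | np.ndarray,
                    n_iterations: int = 5000, alpha: float = 0.05,
                    seed: int = 0) -> float:
    """Fraction of bootstrap resamples whose comparison reaches significance.

    Each iteration resamples both score sets with replacement (preserving
    group sizes) and applies a two-sided Welch t-test at level alpha.
    """
    xa = a.scores if isinstance(a, RunScores) else np.asarray(a, float)
    xb = b.scores if isinstance(b, RunScores) else np.asarray(b, float)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_iterations):
        ra = rng.choice(xa, size=len(xa), replace=True)
        rb = rng.choice(xb, size=len(xb), replace=True)
        if np.ptp(ra) == 0 and np.ptp(rb) == 0:
            hits += int(ra[0] != rb[0])
            continue
        _, p = stats.ttest_ind(ra, rb, equal_var=False)
        hits += int(np.isfinite(p) and p < alpha)
    return hits / n_iterations


def bonferroni(alpha: float, m: int) -> float:
    """Corrected per-comparison significance level alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    return alpha / m


def compare_models(
    runs: dict[str, RunScores],
    alpha: float = 0.05,
    n_bootstrap: int = 1000,
    n_power: int = 5000,
    seed: int = 0,
) -> list[dict]:
    """All ordered pairwise ASO comparisons with Bonferroni-corrected alpha."""
    names = sorted(runs)
    pairs = [(i, j) for i in names for j in names if i != j]
    corrected = bonferroni(alpha, len(pairs)) if pairs else alpha
    report = []
    for k, (name_a, name_b) in enumerate(pairs):
        result = aso(runs[name_a], runs[name_b], alpha=corrected,
                     n_bootstrap=n_bootstrap, seed=seed + k)
        power = bootstrap_power(runs[name_a], runs[name_b],
                                n_iterations=n_power, alpha=corrected,
                                seed=seed + 10_000 + k)
        report.append(
            {
                "a": name_a, "b": name_b,
                "metric": runs[name_a].metric,
                "eps_min": result.eps_min,
                "upper_bound": result.upper_bound,
                "corrected_alpha": corrected,
                "power": power,
                "dominant": result.dominant,
                "degenerate": result.degenerate,
            }
        )
    return report
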