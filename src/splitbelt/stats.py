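"""Bootstrap confidence intervals and FDR-adjusted significance.

Group-level inference follows a resampling scheme: percentile CIs of the
group mean from 10,000 bootstrap samples of participants (resampled with
replacement), within or between groups. Families of related tests are
corrected with an adaptive false-discovery-rate rule that shrinks the
significance level to α·R/m, where m is the family size and R the number of
significant tests — resolved here by a downward fixed-point iteration
starting from R = m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_N_BOOT = 10_000


@dataclass
class BootstrapCI:
    """Percentile bootstrap CI of a group mean (or mean difference)."""

    mean: float
    ci_lower: float
    ci_upper: float
    alpha_nominal: float = 0.05
    alpha_corrected: float = 0.05
    n_boot: int = DEFAULT_N_BOOT
    seed: int = 0
    significant: bool | None = None
    distribution: np.ndarray | None = field(default=None, repr=False)

    @property
    def excludes_zero(self) -> bool:
        return self.ci_lower > 0 or self.ci_upper < 0

    @property
    def half_width(self) -> float:
        return (self.ci_upper - self.ci_lower) / 2


def _percentile_ci(dist: np.ndarray, alpha: float) -> tuple[float, float]:
    lo, hi = np.quantile(dist, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def bootstrap_group_ci(
    values,
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = 0.05,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile CI of the mean, resampling participants with replacement."""
    values = np.asarray(values, float)
    n = len(values)
    if n < 1:
        raise ValueError("need at least one value")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    dist = values[idx].mean(axis=1)
    lo, hi = _percentile_ci(dist, alpha)
    return BootstrapCI(
        mean=float(values.mean()), ci_lower=lo, ci_upper=hi,
        alpha_nominal=alpha, alpha_corrected=alpha,
        n_boot=n_boot, seed=seed, distribution=dist,
    )


def bootstrap_between_groups(
    values_a,
    values_b,
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = 0.05,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile CI of the mean difference Δµ = µ_a − µ_b.

    Each bootstrap sample resamples the two groups independently with
    replacement at their own sizes (e.g. 12 and 8) and takes the difference of
    the resampled group means.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    rng = np.random.default_rng(seed)
    mu_a = a[rng.integers(0, len(a), size=(n_boot, len(a)))].mean(axis=1)
    mu_b = b[rng.integers(0, len(b), size=(n_boot, len(b)))].mean(axis=1)
    dist = mu_a - mu_b
    lo, hi = _percentile_ci(dist, alpha)
    return BootstrapCI(
        mean=float(a.mean() - b.mean()), ci_lower=lo, ci_upper=hi,
        alpha_nominal=alpha, alpha_corrected=alpha,
        n_boot=n_boot, seed=seed, distribution=dist,
    )


def fdr_adjust(family: list[BootstrapCI], alpha: float = 0.05) -> list[BootstrapCI]:
    """FDR-adjusted CIs for a family of bootstrap tests against zero.

    Iterates the adaptive rule α_corr = α·R/m to its largest self-consistent
    fixed point, starting from R = m: at each step, CIs are recomputed at the
    current α_corr and R set to the number whose CI excludes zero; iteration
    stops when R stops changing (R = 0 leaves the nominal-α CIs in place,
    flagged non-significant). Returns new BootstrapCI objects with corrected
    intervals and ``alpha_corrected`` set.
    """
    m = len(family)
    if m < 1:
        raise ValueError("family must contain at least one test")
    for ci in family:
        if ci.distribution is None:
            raise ValueError("fdr_adjust needs BootstrapCI objects with stored distributions")

    def at_level(level: float) -> list[BootstrapCI]:
        out = []
        for ci in family:
            lo, hi = _percentile_ci(ci.distribution, level)
            out.append(
                BootstrapCI(
                    mean=ci.mean, ci_lower=lo, ci_upper=hi,
                    alpha_nominal=ci.alpha_nominal, alpha_corrected=level,
                    n_boot=ci.n_boot, seed=ci.seed, distribution=ci.distribution,
                )
            )
        return out

    R = m
    corrected = at_level(alpha)
    for _ in range(m + 1):
        level = alpha * R / m if R > 0 else alpha
        corrected = at_level(level)
        R_new = sum(ci.excludes_zero for ci in corrected) if R > 0 else 0
        if R_new == R:
            break
        R = R_new
    if R == 0:  # nothing significant: report nominal-α CIs
        corrected = at_level(alpha)
        for ci in corrected:
            ci.alpha_corrected = alpha
    for ci in corrected:
        ci.significant = bool(R > 0 and ci.excludes_zero)
    return corrected
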