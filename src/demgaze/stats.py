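"""Statistical machinery for the DEM analyses.

Pearson and age-partialled correlations, paired t tests, Williams' t for
comparing two dependent (overlapping) correlations, Benjamini-Hochberg FDR,
and the sample-size computations: minimal n for a paired t test via
noncentral-t power, and minimal n for detecting a correlation either from the
exact sampling distribution of r under a bivariate normal or from the
Fisher-z approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "PowerQuery",
    "pearson",
    "partial_corr",
    "paired_t",
    "compare_dependent_correlations",
    "bh_fdr",
    "required_n_paired_t",
    "required_n_correlation",
    "correlation_power_exact",
]


class UndefinedCorrelationError(ValueError):
    pass


class InconsistentCorrelationsError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    df: int
    p: float


@dataclass(frozen=True)
class PowerQuery:
    """A sample-size question: effect size, alpha, target power, sidedness."""

    effect_size: float  # rho for correlations, dz for the paired t
    alpha: float = 0.05
    power: float = 0.80
    one_sided: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.power < 1 and self.effect_size > 0):
            raise ValueError("need 0<alpha<1, 0<power<1, effect size > 0")


def pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Product-moment correlation with the usual t-based two-sided p (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=len(x), df=len(x) - 2, p=float(p))


def partial_corr(x: np.ndarray, y: np.ndarray, covariate: np.ndarray) -> CorrelationResult:
    """First-order partial correlation of x and y controlling for one covariate.

    Computed as the Pearson correlation of the residuals of the linear
    regressions of x and y on the covariate; the p-value uses n-3 degrees of
    freedom.
    """
    x, y, c = (np.asarray(v, dtype=float) for v in (x, y, covariate))
    n = len(x)
    if not (len(y) == len(c) == n) or n < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    design = np.column_stack([np.ones(n), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise UndefinedCorrelationError("a variable is an exact function of the covariate")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 3
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(r=r, n=n, df=df, p=p)


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Paired-sample t test on a - b; returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        return float(np.inf) * np.sign(d.mean()), n - 1, 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), n - 1, float(res.pvalue)


def compare_dependent_correlations(
    r_xy: float, r_xz: float, r_yz: float, n: int
) -> tuple[float, float]:
    """Williams' t for two overlapping dependent correlations sharing x.

    Tests H0: rho_xy = rho_xz given the correlation r_yz between y and z;
    df = n - 3, two-sided p.  Swapping r_xy and r_xz negates the statistic
    and leaves p unchanged.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if max(abs(r_xy), abs(r_xz), abs(r_yz)) >= 1:
        raise ValueError("correlations must satisfy |r| < 1")
    detR = 1 - r_xy**2 - r_xz**2 - r_yz**2 + 2 * r_xy * r_xz * r_yz
    if detR <= 0:
        raise InconsistentCorrelationsError(
            "the three correlations do not form a positive-definite matrix"
        )
    rbar = (r_xy + r_xz) / 2.0
    denom = 2 * (n - 1) / (n - 3) * detR + rbar**2 * (1 - r_yz) ** 3
    if denom <= 0:
        raise InconsistentCorrelationsError("degenerate configuration")
    t = (r_xy - r_xz) * np.sqrt((n - 1) * (1 + r_yz) / denom)
    p = float(2.0 * stats.t.sf(abs(t), n - 3))
    return float(t), p


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask at level q)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def _paired_t_power(n: int, dz: float, alpha: float, one_sided: bool) -> float:
    df = n - 1
    ncp = dz * np.sqrt(n)
    if one_sided:
        crit = stats.t.ppf(1 - alpha, df)
        return float(stats.nct.sf(crit, df, ncp))
    crit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))


def required_n_paired_t(query: PowerQuery, n_max: int = 100_000) -> int:
    """Smallest n whose paired-t power (noncentral t, ncp = dz*sqrt(n)) meets the target."""
    for n in range(2, n_max + 1):
        if _paired_t_power(n, query.effect_size, query.alpha, query.one_sided) >= query.power:
            return n
    raise RuntimeError(f"target power not reachable below n = {n_max}")


def _r_log_density(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Log density of the sample correlation under a bivariate normal, size n."""
    r = np.asarray(r, dtype=float)
    lg = (
        np.log(n - 2)
        + special.gammaln(n - 1)
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        + (n - 1) / 2 * np.log1p(-(rho**2))
        + (n - 4) / 2 * np.log1p(-(r**2))
        - (n - 1.5) * np.log1p(-rho * r)
    )
    return lg + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2))


def correlation_power_exact(n: int, rho: float, alpha: float, one_sided: bool = True) -> float:
    """Power of the t test of H0: rho = 0 from the exact distribution of r.

    The critical r comes from the t transform with n-2 df; the rejection
    probability integrates the exact bivariate-normal sampling density of r
    (Hotelling's series via the Gauss hypergeometric function).
    """
    if n < 4:
        return 0.0
    df = n - 2
    a = alpha if one_sided else alpha / 2
    t_crit = stats.t.ppf(1 - a, df)
    r_crit = t_crit / np.sqrt(t_crit**2 + df)

    def dens(r: float) -> float:
        return float(np.exp(_r_log_density(np.array(r), rho, n)))

    upper, _ = integrate.quad(dens, r_crit, 1.0, limit=200)
    if one_sided:
        return float(upper)
    lower, _ = integrate.quad(dens, -1.0, -r_crit, limit=200)
    return float(upper + lower)


def required_n_correlation(query: PowerQuery, mode: str = "exact", n_max: int = 10_000) -> int:
    """Smallest n detecting H0: rho = 0 vs. the query's rho at the target power.

    ``mode='exact'`` integrates the exact sampling distribution of r;
    ``mode='fisher-z'`` uses the normal approximation
    n = ((z_alpha + z_beta)/atanh(rho))^2 + 3, rounded up and floored at 4.
    """
    rho, alpha, power = query.effect_size, query.alpha, query.power
    if mode == "fisher-z":
        za = stats.norm.ppf(1 - (alpha if query.one_sided else alpha / 2))
        zb = stats.norm.ppf(power)
        n = int(np.ceil(((za + zb) / np.arctanh(rho)) ** 2 + 3))
        return max(n, 4)
    if mode != "exact":
        raise ValueError("mode must be 'exact' or 'fisher-z'")
    for n in range(4, n_max + 1):
        if correlation_power_exact(n, rho, alpha, query.one_sided) >= power:
            return n
    raise RuntimeError(f"target power not reachable below n = {n_max}")
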