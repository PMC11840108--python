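"""Parametric Pearson-correlation statistics and Fisher-z power machinery.

Two distinct parametric routes are used deliberately:

* P values and significance cutoffs for observed correlations come from the
  exact null distribution of the sample correlation, via the t statistic
  ``t = r * sqrt((n - 2) / (1 - r**2))`` with ``n - 2`` degrees of freedom.
* Power analysis (analytical power curves and the inverse power analysis that
  turns a target power level into an effect size) uses the Fisher
  z approximation, under which ``atanh(r)`` is normal with standard deviation
  ``1 / sqrt(n - 3)``.

Keeping the two routes separate mirrors standard practice in correlation-based
association studies: significance decisions are exact, power book-keeping is
done on the z scale where it has a closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PowerCurve",
    "analytical_power",
    "bonferroni_alpha",
    "critical_r",
    "fisher_z",
    "fisher_z_inv",
    "p_two_tailed",
    "r_critical_for_power",
]

#: Smallest positive subnormal double, returned when a P value underflows.
_TINY = np.nextafter(0.0, 1.0)


def fisher_z(r):
    """Fisher z-transformation ``z = atanh(r)``.

    Accepts scalars or arrays; every element must satisfy ``|r| < 1``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inv(z):
    """Inverse Fisher transformation ``r = tanh(z)``."""
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return float(out) if out.ndim == 0 else out


def p_two_tailed(r, n: int):
    """Two-tailed P value of a Pearson correlation under the parametric null.

    Uses the exact t distribution with ``n - 2`` degrees of freedom.
    ``p_two_tailed(0, n) == 1``. For ``|r| == 1`` the P value underflows; the
    smallest positive representable double is returned and a warning issued.

    Parameters
    ----------
    r : float or array-like
        Observed correlation(s), ``|r| <= 1``.
    n : int
        Sample size the correlation was computed at, ``n >= 4``.
    """
    n = int(n)
    if n < 4:
        raise ValueError(f"n must be >= 4, got n={n}")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise ValueError("p_two_tailed requires |r| <= 1")
    degenerate = np.abs(r) == 1.0
    if np.any(degenerate):
        warnings.warn(
            "correlation of magnitude 1: two-tailed P value underflows, "
            "returning the smallest positive double",
            RuntimeWarning,
            stacklevel=2,
        )
    r_safe = np.where(degenerate, 0.0, r)
    with np.errstate(divide="ignore"):
        t = r_safe * np.sqrt((n - 2) / (1.0 - r_safe**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.minimum(p, 1.0)
    p = np.where(degenerate, _TINY, p)
    p = np.maximum(p, _TINY)
    return float(p) if p.ndim == 0 else p


def critical_r(n: int, alpha: float) -> float:
    """Smallest non-negative correlation significant at ``alpha`` (two-tailed).

    Inverts the t quantile: ``|r| > critical_r(n, alpha)`` if and only if
    ``p_two_tailed(r, n) < alpha`` (with equality on the boundary).
    """
    n = int(n)
    if n < 4:
        raise ValueError(f"n must be >= 4, got n={n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    t = stats.t.isf(alpha / 2.0, n - 2)
    return float(t / np.sqrt(n - 2 + t * t))


def r_critical_for_power(n: int, alpha: float, power: float) -> float:
    """Effect size reaching a target power at ``(n, alpha)`` (inverse power analysis).

    On the Fisher z scale the minimal detectable effect is
    ``tanh((z_{1-alpha/2} + z_power) / sqrt(n - 3))`` where ``z_q`` is the
    standard normal quantile. Equivalently written with the type-II error
    deviate ``Z_beta = -z_power``, the numerator is ``Z_alpha - Z_beta``.
    """
    n = int(n)
    if n < 4:
        raise ValueError(f"n must be >= 4, got n={n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if not 0.0 < power < 1.0:
        raise ValueError(f"power must lie in (0, 1), got {power}")
    z_alpha = stats.norm.isf(alpha / 2.0)
    z_power = stats.norm.ppf(power)
    return float(np.tanh((z_alpha + z_power) / np.sqrt(n - 3)))


def analytical_power(rho, n: int, alpha: float):
    """Analytical power of the two-tailed correlation test, on the Fisher z scale.

    ``power = Phi(sqrt(n-3)*atanh(|rho|) - z_{1-alpha/2})
            + Phi(-sqrt(n-3)*atanh(|rho|) - z_{1-alpha/2})``

    The second term is the wrong-tail rejection probability; it is negligible
    at realistic effect sizes but makes the limit exact: power -> alpha as
    rho -> 0. This is the exact complement of ``r_critical_for_power``: for
    effect sizes produced by the inverse power analysis the round trip
    recovers the requested power up to the wrong-tail term.
    """
    n = int(n)
    if n < 4:
        raise ValueError(f"n must be >= 4, got n={n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError("analytical_power requires |rho| < 1")
    z_alpha = stats.norm.isf(alpha / 2.0)
    s = np.sqrt(n - 3) * np.arctanh(np.abs(rho))
    out = stats.norm.cdf(s - z_alpha) + stats.norm.cdf(-s - z_alpha)
    return float(out) if out.ndim == 0 else out


def bonferroni_alpha(alpha: float, n_comparisons: int) -> float:
    """Family-wise corrected per-test threshold ``alpha / m``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons


@dataclass(frozen=True)
class PowerCurve:
    """Analytical power across sample sizes for one effect size and threshold."""

    rho: float
    alpha: float
    sizes: np.ndarray
    power: np.ndarray = field(repr=False)

    @classmethod
    def compute(cls, rho: float, alpha: float, sizes) -> "PowerCurve":
        sizes = np.asarray(sizes, dtype=int)
        power = np.array([analytical_power(rho, n, alpha) for n in sizes])
        return cls(rho=float(rho), alpha=float(alpha), sizes=sizes, power=power)
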