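"""Effect sizes, interval estimates, and a-priori ANOVA power planning."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ValidationError


@dataclass(frozen=True)
class EffectSize:
    """Cliff's delta between two samples.

    delta = (#{a_i > b_j} - #{a_i < b_j}) / (n_a * n_b), in [-1, 1];
    ties contribute 0.  A positive delta means sample ``a`` tends to
    dominate sample ``b``.
    """

    delta: float
    n_a: int
    n_b: int

    def __post_init__(self):
        if not -1.0 <= self.delta <= 1.0:
            raise ValidationError(f"delta out of range: {self.delta}")


def cliffs_delta(a, b) -> EffectSize:
    """Cliff's dominance effect size of ``a`` over ``b``.

    Computed in O((n+m) log m) by counting, for each a_i, how many b_j fall
    strictly below / strictly above it against a sorted copy of ``b``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("cliffs_delta requires two non-empty samples")
    bs = np.sort(b)
    n_below = np.searchsorted(bs, a, side="left")     # b_j < a_i
    n_at_or_below = np.searchsorted(bs, a, side="right")
    n_above = b.size - n_at_or_below                   # b_j > a_i
    delta = (n_below.sum() - n_above.sum()) / (a.size * b.size)
    return EffectSize(delta=float(delta), n_a=int(a.size), n_b=int(b.size))


def mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with a t-distribution confidence interval.

    Returns ``(mean, ci_low, ci_high)``.  A constant vector yields a
    zero-width interval at the constant.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValidationError("mean_ci requires at least 2 values")
    if not 0.0 < level < 1.0:
        raise ValidationError("level must lie in (0, 1)")
    m = float(values.mean())
    sem = float(values.std(ddof=1)) / np.sqrt(values.size)
    half = float(sps.t.ppf(0.5 + level / 2.0, values.size - 1)) * sem
    return m, m - half, m + half


def anova_power(n_total: int, effect_size_f: float, k_groups: int, alpha: float = 0.05) -> float:
    """Power of the one-way ANOVA omnibus F test for total sample size N.

    Noncentrality is lambda = f^2 * N with df1 = k-1 and df2 = N-k, the
    parameterization used by standard a-priori power software.
    """
    df1, df2 = k_groups - 1, n_total - k_groups
    if df2 < 1:
        return 0.0
    f_crit = sps.f.ppf(1.0 - alpha, df1, df2)
    return float(1.0 - sps.ncf.cdf(f_crit, df1, df2, effect_size_f**2 * n_total))


def anova_required_sample_size(
    effect_size_f: float,
    k_groups: int,
    alpha: float = 0.05,
    power: float = 0.80,
    n_cap: int = 1_000_000,
) -> int:
    """Smallest balanced total N reaching the target ANOVA power.

    N is restricted to multiples of ``k_groups`` (equal allocation).  The
    defaults alpha = .05 and power = .80 are the conventional planning
    values.
    """
    if effect_size_f <= 0:
        raise ValidationError("effect_size_f must be > 0")
    if k_groups < 2:
        raise ValidationError("k_groups must be >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("alpha and power must lie in (0, 1)")
    n = k_groups
    while n <= n_cap:
        n += k_groups
        if anova_power(n, effect_size_f, k_groups, alpha) >= power:
            return n
    raise ValidationError(f"target power not attainable with N <= {n_cap}")
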