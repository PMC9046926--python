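"""Two-sample t-test power arithmetic (noncentral t).

Why this lives in a DE package: differential expression pipelines control
the false *positive* rate (via BH/FDR) but say nothing about false
negatives. At realistic sample sizes the false negative rate is large —
a two-sided t-test at alpha = 0.05 needs about 26 samples per group to
reach 80% power even for a large effect (Cohen's d = 0.8), and about 394
per group for a small one (d = 0.2). Those false negatives are exactly
what turns "significant in one group, not the other" into an artifact
generator.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.stats import nct, t as t_dist

from degvenn.errors import ConfigError

_N_MAX = 1e7


def ttest_power(
    n_per_group: float, d: float, alpha: float = 0.05, alternative: str = "two-sided"
) -> float:
    """Power of the equal-n two-sample pooled-variance t-test.

    Computed from the noncentral t distribution with ``df = 2n - 2`` and
    noncentrality ``d * sqrt(n / 2)``. ``n_per_group`` may be fractional
    (used by the sample-size root-finder).
    """
    if n_per_group < 2:
        raise ConfigError("need at least 2 samples per group")
    if not 0 < alpha < 1:
        raise ConfigError("alpha must lie in (0, 1)")
    if d < 0:
        raise ConfigError("effect size d must be nonnegative")
    df = 2.0 * n_per_group - 2.0
    ncp = d * np.sqrt(n_per_group / 2.0)
    if alternative == "two-sided":
        crit = t_dist.ppf(1.0 - alpha / 2.0, df)
        return float(nct.sf(crit, df, ncp) + nct.cdf(-crit, df, ncp))
    if alternative == "one-sided":
        crit = t_dist.ppf(1.0 - alpha, df)
        return float(nct.sf(crit, df, ncp))
    raise ConfigError(f"unknown alternative {alternative!r}")


def required_n(
    d: float, alpha: float = 0.05, power: float = 0.8, alternative: str = "two-sided"
) -> tuple[float, int]:
    """Per-group sample size achieving the target power.

    Returns ``(fractional, integer)``: the real-valued n solving
    ``power(n) = power`` by root-finding, and the smallest whole n with
    ``power(n) >= power``.
    """
    if d <= 0:
        raise ConfigError("effect size d must be positive")
    if not 0 < power < 1:
        raise ConfigError("power must lie in (0, 1)")
    if power <= ttest_power(2, d, alpha, alternative):
        # target at or below the power already achieved at the minimum n
        import warnings

        warnings.warn("power target achieved at the minimal n = 2", stacklevel=2)
        return 2.0, 2
    hi = 4.0
    while ttest_power(hi, d, alpha, alternative) < power:
        hi *= 2.0
        if hi > _N_MAX:
            raise ConfigError("requested power unreachable for this effect size")
    frac = brentq(
        lambda n: ttest_power(n, d, alpha, alternative) - power,
        max(2.0, hi / 2.0),
        hi,
        xtol=1e-9,
    )
    n_int = int(np.ceil(frac - 1e-9))
    while ttest_power(n_int, d, alpha, alternative) < power:  # guard rounding
        n_int += 1
    return float(frac), n_int


def fnr_from_power(power: float) -> float:
    """False negative rate = 1 - power."""
    if not 0.0 <= power <= 1.0:
        raise ConfigError("power must lie in [0, 1]")
    return 1.0 - power
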