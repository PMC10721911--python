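"""Trial-design calculations: exact t-test sizing and truncated-Hochberg power.

Two-sample sizing uses the exact noncentral-t power of the two-sided pooled
t-test.  The truncated Hochberg procedure is the step-up multiple-testing
procedure whose critical constants interpolate between Hochberg (gamma = 1)
and Bonferroni (gamma = 0):

.. math::  c_i = \\left(\\frac{\\gamma}{m - i + 1} + \\frac{1-\\gamma}{m}\\right)\\alpha

for the *i*-th smallest p-value.  Its power for the canonical three-arm
shared-control design is estimated by simulating the full trial (all three
arms drawn, both t-tests computed per replicate), so the shared-control
correlation between the two comparisons arises naturally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PowerSpec",
    "HochbergSpec",
    "HochbergPowerResult",
    "two_sample_power",
    "two_sample_n",
    "truncated_hochberg",
    "hochberg_critical_constants",
    "hochberg_power_sim",
]


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample sizing inputs; give (delta, sd) or the standardized d."""

    delta: float | None = None
    sd: float | None = None
    d: float | None = None
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.d is None:
            if self.delta is None or self.sd is None or self.sd <= 0:
                raise ValueError("provide d, or delta with a positive sd")
        elif self.d <= 0:
            raise ValueError("standardized effect d must be positive")

    @property
    def standardized(self) -> float:
        return self.d if self.d is not None else abs(self.delta) / self.sd


@dataclass(frozen=True)
class HochbergSpec:
    gamma: float
    alpha: float = 0.05
    m: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.m < 1:
            raise ValueError("need at least one hypothesis")


def two_sample_power(n_per_group: int, d: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided pooled two-sample t-test."""
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    crit = stats.t.ppf(1 - alpha / 2, df)
    nc = d * np.sqrt(n_per_group / 2.0)
    return float(stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))


def two_sample_n(spec: PowerSpec) -> int:
    """Smallest per-group n whose exact noncentral-t power meets the target."""
    d = spec.standardized
    # normal-approximation start, then walk to the exact answer
    za = stats.norm.ppf(1 - spec.alpha / 2)
    zb = stats.norm.ppf(spec.power)
    n = max(int(np.floor(2 * ((za + zb) / d) ** 2)) - 2, 2)
    while two_sample_power(n, d, spec.alpha) < spec.power:
        n += 1
    while n > 2 and two_sample_power(n - 1, d, spec.alpha) >= spec.power:
        n -= 1
    return n


def hochberg_critical_constants(spec: HochbergSpec) -> np.ndarray:
    """c_i for the i-th smallest p-value, i = 1..m (nonincreasing in rank m..1)."""
    i = np.arange(1, spec.m + 1)
    return (spec.gamma / (spec.m - i + 1) + (1.0 - spec.gamma) / spec.m) * spec.alpha


def truncated_hochberg(p_values, spec: HochbergSpec) -> set[int]:
    """Indices (into the input) rejected by the truncated Hochberg step-up.

    Scanning from the largest p-value down, the first ordered p(i) at or below
    its critical constant rejects hypotheses 1..i; the rejection set is
    therefore closed downward in p.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return set()
    if p.size != spec.m:
        raise ValueError(f"expected {spec.m} p-values, got {p.size}")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    c = hochberg_critical_constants(spec)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    for i in range(spec.m, 0, -1):
        if sorted_p[i - 1] <= c[i - 1]:
            return set(order[:i].tolist())
    return set()


@dataclass(frozen=True)
class HochbergPowerResult:
    power_at_least_one: float
    power_both: float
    mc_se_at_least_one: float
    mc_se_both: float
    n_sims: int
    # rejection rate of the first comparison at the unadjusted level, for
    # cross-checking the simulation against the noncentral-t closed form
    power_per_comparison_unadjusted: float = float("nan")


def hochberg_power_sim(
    n_per_arm: int,
    d: float,
    gamma: float = 0.9,
    alpha: float = 0.05,
    n_sims: int = 100_000,
    seed: int = 0,
    chunk: int = 20_000,
) -> HochbergPowerResult:
    """Simulated truncated-Hochberg power for a three-arm shared-control trial.

    Each replicate draws all three normal arms (control at mean 0, both active
    arms shifted by ``d`` standard deviations), computes the two shared-control
    two-sided pooled t-tests, and applies the truncated Hochberg procedure with
    ``m = 2``.  Reports the proportion of replicates with at least one and with
    both rejections, plus binomial Monte-Carlo standard errors.
    """
    if n_per_arm < 2:
        raise ValueError("n_per_arm must be >= 2")
    spec = HochbergSpec(gamma=gamma, alpha=alpha, m=2)
    c1, c2 = hochberg_critical_constants(spec)
    rng = np.random.default_rng(seed)
    df = 2 * n_per_arm - 2

    n_any = 0
    n_both = 0
    n_unadj = 0
    done = 0
    while done < n_sims:
        b = min(chunk, n_sims - done)
        control = rng.standard_normal((b, n_per_arm))
        active1 = rng.standard_normal((b, n_per_arm)) + d
        active2 = rng.standard_normal((b, n_per_arm)) + d

        cm, cv = control.mean(axis=1), control.var(axis=1, ddof=1)
        p_pair = []
        for active in (active1, active2):
            am, av = active.mean(axis=1), active.var(axis=1, ddof=1)
            sp2 = (cv + av) / 2.0
            t = (am - cm) / np.sqrt(sp2 * 2.0 / n_per_arm)
            p_pair.append(2.0 * stats.t.sf(np.abs(t), df))
        p_lo = np.minimum(p_pair[0], p_pair[1])
        p_hi = np.maximum(p_pair[0], p_pair[1])
        # step-up with m=2: p_hi <= c2 rejects both; else p_lo <= c1 rejects one
        both = p_hi <= c2
        any_rej = both | (p_lo <= c1)
        n_both += int(both.sum())
        n_any += int(any_rej.sum())
        n_unadj += int((p_pair[0] <= alpha).sum())
        done += b

    p_any = n_any / n_sims
    p_both = n_both / n_sims
    return HochbergPowerResult(
        power_at_least_one=p_any,
        power_both=p_both,
        mc_se_at_least_one=float(np.sqrt(p_any * (1 - p_any) / n_sims)),
        mc_se_both=float(np.sqrt(p_both * (1 - p_both) / n_sims)),
        n_sims=n_sims,
        power_per_comparison_unadjusted=n_unadj / n_sims,
    )
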