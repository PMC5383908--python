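"""Statistical power for repeated-measures and Pearson correlation designs.

Power is obtained from the Pearson-correlation machinery with the rmcorr
error degrees of freedom substituted in: df = N(k-1) - 1 for k >= 2, or
N - 2 for the one-observation Pearson design (k = 1).  The default
analytic path evaluates the exact noncentral-t power of the two-sided
test of rho = 0 (the computation behind standard power software for
correlations),

    power = P(|T_{df, delta}| > t_{alpha/2, df}),
    delta = rho * sqrt(df + 1) / sqrt(1 - rho^2),

which returns alpha exactly under the null.  The lighter Fisher-z normal
approximation,

    power = Phi(|arctanh(rho)| * sqrt(df - 1) - z_{1-alpha/2})
          + Phi(-|arctanh(rho)| * sqrt(df - 1) - z_{1-alpha/2}),

is exposed separately; it agrees with the exact path at large df but is
visibly conservative for large effects at small df.  A Monte-Carlo
simulation path (generate data at the requested within-correlation, fit,
test at alpha) serves as an independent check on both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import core, simulate
from .errors import ConfigurationError, DataInsufficiencyError

__all__ = [
    "PowerSpec",
    "power_analytic",
    "power_fisher_z",
    "power_simulated",
    "power_curves",
]

DEFAULT_EFFECT_SIZES = (0.10, 0.3, 0.50)  # small / medium / large conventions
POWER_REFERENCE = 0.80


@dataclass(frozen=True)
class PowerSpec:
    """A power query: effect size, design, alpha and evaluation method."""

    effect_size: float
    N: int
    k: int = 1
    alpha: float = 0.05
    method: str = "analytic"
    nsims: int = 2000
    seed: int | None = None

    def __post_init__(self):
        if not -1.0 < self.effect_size < 1.0:
            raise ConfigurationError(
                f"effect_size must be in (-1, 1), got {self.effect_size}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.N < 2:
            raise ConfigurationError(f"N must be >= 2, got {self.N}")
        if self.k < 1:
            raise ConfigurationError(f"k must be >= 1, got {self.k}")
        if self.method not in ("analytic", "simulation"):
            raise ConfigurationError(f"unknown method {self.method!r}")

    def evaluate(self):
        if self.method == "analytic":
            return power_analytic(self.effect_size, self.N, self.k, self.alpha)
        return power_simulated(
            self.effect_size, self.N, self.k, self.alpha, nsims=self.nsims, seed=self.seed
        )


def _design_df(N: int, k: float) -> int:
    """df of the correlation test: N - 2 for k = 1, else N(k-1) - 1."""
    if k == 1:
        return N - 2
    return core.error_df(N, k)


def _validate_effect_alpha(effect_size: float, alpha: float) -> None:
    if not -1.0 < effect_size < 1.0:
        raise ConfigurationError(f"effect_size must be in (-1, 1), got {effect_size}")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")


def power_analytic(effect_size: float, N: int, k: int = 1, alpha: float = 0.05) -> float:
    """Exact noncentral-t power of the two-sided test of rho = 0.

    ``k = 1`` gives the ordinary Pearson design (df = N - 2); ``k >= 2``
    the repeated-measures design (df = N(k-1) - 1).  Returns ``alpha``
    exactly when ``effect_size`` is 0.
    """
    _validate_effect_alpha(effect_size, alpha)
    df = _design_df(N, k)
    if df - 1 < 1:
        raise DataInsufficiencyError(f"design too small for a power analysis (df = {df})")
    if effect_size == 0.0:
        return alpha
    rho = abs(effect_size)
    delta = rho * math.sqrt(df + 1) / math.sqrt(1.0 - rho * rho)
    t_crit = stats.t.isf(alpha / 2.0, df)
    p = float(stats.nct.sf(t_crit, df, delta) + stats.nct.cdf(-t_crit, df, delta))
    if not math.isfinite(p):
        # scipy's noncentral t loses accuracy at very large df/delta; the
        # Fisher-z approximation is indistinguishable from exact there.
        p = power_fisher_z(effect_size, N, k, alpha)
    return min(1.0, max(0.0, p))


def power_fisher_z(effect_size: float, N: int, k: int = 1, alpha: float = 0.05) -> float:
    """Fisher-z normal approximation to :func:`power_analytic`.

    The quick hand formula behind correlation power lookup tables;
    conservative for large effects at small df, converging to the exact
    value as df grows.
    """
    _validate_effect_alpha(effect_size, alpha)
    df = _design_df(N, k)
    if df - 1 < 1:
        raise DataInsufficiencyError(f"design too small for a power analysis (df = {df})")
    if effect_size == 0.0:
        return alpha
    z = abs(math.atanh(effect_size))
    scale = math.sqrt(df - 1)
    z_crit = stats.norm.isf(alpha / 2.0)
    return float(stats.norm.cdf(z * scale - z_crit) + stats.norm.cdf(-z * scale - z_crit))


def power_simulated(
    effect_size: float,
    N: int,
    k: int,
    alpha: float = 0.05,
    nsims: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo power: fraction of simulated datasets with p < alpha.

    Datasets are drawn from the generative model at the requested
    within-correlation.  Returns (power estimate, binomial Monte-Carlo
    standard error); reproducible from ``seed``.
    """
    if nsims < 100:
        raise ConfigurationError(f"nsims must be >= 100, got {nsims}")
    if k < 2:
        raise ConfigurationError("simulation path requires k >= 2 repeated measures")
    spec = simulate.spec_for_correlation(effect_size, N=N, k=k)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(nsims):
        codes, n_groups, x, y = simulate._generate_arrays(spec, rng)
        if core._fit_arrays(codes, n_groups, x, y).p_value < alpha:
            hits += 1
    p_hat = hits / nsims
    se = math.sqrt(p_hat * (1.0 - p_hat) / nsims)
    return p_hat, se


def power_curves(
    effect_sizes=DEFAULT_EFFECT_SIZES,
    N_grid=tuple(range(10, 201, 10)),
    k_grid=(1, 2, 3, 5, 10),
    alpha: float = 0.05,
    make_figure: bool = True,
):
    """Power over a grid of effect sizes, sample sizes and repeat counts.

    Returns a long-format table with columns (effect, N, k, power) and,
    unless ``make_figure`` is false, a matplotlib figure with one panel
    per effect size, one curve per k, and a dotted reference line at 80%
    power.  Designs too small for the approximation are skipped.
    """
    import pandas as pd

    if not len(effect_sizes) or not len(N_grid) or not len(k_grid):
        raise ConfigurationError("effect_sizes, N_grid and k_grid must be non-empty")
    rows = []
    for eff in effect_sizes:
        for n in N_grid:
            for k in k_grid:
                try:
                    p = power_analytic(eff, n, k, alpha)
                except DataInsufficiencyError:
                    continue
                rows.append({"effect": eff, "N": n, "k": k, "power": p})
    table = pd.DataFrame(rows)

    fig = None
    if make_figure:
        import matplotlib.pyplot as plt

        n_panels = len(effect_sizes)
        fig, axes = plt.subplots(
            1, n_panels, figsize=(4 * n_panels, 3.5), sharey=True, squeeze=False
        )
        for ax, eff in zip(axes[0], effect_sizes):
            sub = table[table["effect"] == eff]
            for k, grp in sub.groupby("k"):
                label = "k = 1 (Pearson)" if k == 1 else f"k = {k}"
                ax.plot(grp["N"], grp["power"], marker=".", label=label)
            ax.axhline(POWER_REFERENCE, color="black", linestyle=":", linewidth=1)
            ax.set_title(f"effect size r = {eff:g}")
            ax.set_xlabel("N (participants)")
            ax.set_ylim(0, 1.02)
        axes[0][0].set_ylabel("power")
        axes[0][-1].legend(fontsize=8)
        fig.tight_layout()
    return table, fig
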