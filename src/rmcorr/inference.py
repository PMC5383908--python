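"""Confidence intervals for r_rm: analytic (Fisher z) and bootstrap.

The analytic interval applies the Fisher transformation z = arctanh(r)
with standard error 1/sqrt(df_error - 1) — the Pearson 1/sqrt(n - 3)
convention with the rmcorr error df substituted for n - 2 — and
back-transforms by tanh.

The bootstrap resamples observations with replacement *within* each
participant (each participant keeps their own number of rows and is
never dropped or mixed with another), refits rmcorr on every resample,
and forms a percentile interval from the resulting distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import core
from .data import PairedRepeatedData
from .errors import ConfigurationError, DataInsufficiencyError, DegenerateDesignError

__all__ = ["BootstrapResult", "analytic_ci", "bootstrap_ci"]


def _check_level(level: float) -> None:
    if not 0.0 < level < 1.0:
        raise ConfigurationError(f"confidence level must be in (0, 1), got {level}")


def analytic_ci(r_rm: float, df_error: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-transformation confidence interval for r_rm.

    Parameters
    ----------
    r_rm : float
        Point estimate, |r_rm| <= 1.
    df_error : int
        Error degrees of freedom of the rmcorr fit (>= 2).
    level : float
        Coverage, in (0, 1).

    Returns
    -------
    (low, high) clipped to [-1, 1].  For |r_rm| = 1 the interval
    degenerates to [r_rm, r_rm] with a warning.
    """
    _check_level(level)
    if df_error < 2:
        raise DataInsufficiencyError(
            f"analytic interval requires df_error >= 2, got {df_error}"
        )
    if abs(r_rm) >= 1.0:
        r = max(-1.0, min(1.0, r_rm))
        warnings.warn(
            "|r_rm| = 1: Fisher interval degenerates to a point", stacklevel=2
        )
        return (r, r)
    z = math.atanh(r_rm)
    half_width = stats.norm.ppf(0.5 + level / 2.0) / math.sqrt(df_error - 1)
    lo = math.tanh(z - half_width)
    hi = math.tanh(z + half_width)
    return (max(-1.0, lo), min(1.0, hi))


@dataclass(frozen=True)
class BootstrapResult:
    """Within-individual bootstrap distribution of r_rm.

    ``r_rm_boot`` is the median of the resampled estimates; ``ci_boot``
    is a percentile interval whose endpoints are order statistics of the
    estimates.
    """

    estimates: np.ndarray | None
    r_rm_boot: float
    ci_boot: tuple[float, float]
    nreps: int
    seed: int | None
    level: float
    keep_estimates: bool
    n_redraws: int = 0


def bootstrap_ci(
    data: PairedRepeatedData,
    nreps: int = 100,
    level: float = 0.95,
    seed: int | None = None,
    keep_estimates: bool = True,
    max_retries: int = 100,
) -> BootstrapResult:
    """Percentile bootstrap CI for r_rm via within-individual resampling.

    Each resample draws, independently for every participant, that
    participant's own number of rows with replacement from their rows,
    then refits rmcorr.  Resamples that land on a degenerate design (no
    within-participant covariate variance anywhere) are redrawn, up to
    ``max_retries`` times each.  Fully reproducible from ``seed``.
    """
    if not isinstance(nreps, (int, np.integer)) or nreps < 1:
        raise ConfigurationError(f"nreps must be a positive integer, got {nreps!r}")
    _check_level(level)
    rng = np.random.default_rng(seed)

    codes = data.codes
    x, y = data.measure2, data.measure1
    L, N = data.L, data.N
    # Group rows once; resampling then maps each row slot to a random row
    # of the same participant.
    order = np.argsort(codes, kind="stable")
    codes_sorted = np.ascontiguousarray(codes[order])
    counts = data.counts
    group_start = np.concatenate(([0], np.cumsum(counts)[:-1]))
    slot_start = group_start[codes_sorted]
    slot_n = counts[codes_sorted]

    estimates = np.empty(nreps)
    n_redraws = 0
    for b in range(nreps):
        for _attempt in range(max_retries + 1):
            pos = slot_start + (rng.random(L) * slot_n).astype(np.intp)
            sel = order[pos]
            try:
                estimates[b] = core._fit_arrays(codes_sorted, N, x[sel], y[sel]).r
                break
            except DegenerateDesignError:
                n_redraws += 1
                continue
        else:
            raise DegenerateDesignError(
                f"resample {b} degenerate after {max_retries} redraws"
            )

    alpha = (1.0 - level) / 2.0
    lo = float(np.quantile(estimates, alpha, method="lower"))
    hi = float(np.quantile(estimates, 1.0 - alpha, method="higher"))
    return BootstrapResult(
        estimates=estimates if keep_estimates else None,
        r_rm_boot=float(np.median(estimates)),
        ci_boot=(lo, hi),
        nreps=int(nreps),
        seed=seed,
        level=level,
        keep_estimates=keep_estimates,
        n_redraws=n_redraws,
    )
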