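"""Core estimator: ANCOVA decomposition, r_rm, degrees of freedom, F test.

The repeated-measures correlation is the common within-individual linear
association between two paired measures.  It is estimated from the
varying-intercept, common-slope linear model

    measure1_ij = mean1_j + beta * (measure2_ij - mean2_j) + eps_ij

with the participant as a categorical factor and one measure as the
covariate.  Writing S_xx, S_yy, S_xy for the within-participant
(mean-centered) sums of squares and cross-products pooled over
participants, the common slope is beta = S_xy / S_xx, and

    r_rm = sign(beta) * sqrt(SS_measure / (SS_measure + SS_error))
         = S_xy / sqrt(S_xx * S_yy),

tested against F(1, L - N - 1) where L is the total number of rows and N
the number of participants.  The fit is carried out by within-group
centering rather than by materializing N - 1 dummy columns, which is
numerically stable up to very large N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import special, stats

from .data import PairedRepeatedData
from .errors import (
    ConfigurationError,
    ConsistencyError,
    DataInsufficiencyError,
    DegenerateDesignError,
)

__all__ = [
    "AncovaTable",
    "RmcorrResult",
    "PearsonCorr",
    "PearsonBaselines",
    "ParticipantLine",
    "fit_rmcorr",
    "error_df",
    "approx_df",
    "predicted_lines",
    "pearson_baselines",
]

# Residual SS below this fraction of the within-participant SS of the
# response is treated as an exact zero (perfect parallel-line fit), so
# noise-free constructions report r_rm = +/-1 exactly.
_PERFECT_FIT_RTOL = 1e-12


def error_df(N: int, k: float) -> int:
    """Error degrees of freedom of the rmcorr test, N(k - 1) - 1.

    ``k`` may be fractional for unbalanced designs (k = L/N), in which
    case the value equals L - N - 1 exactly.
    """
    if N < 2:
        raise DataInsufficiencyError(f"need at least 2 participants, got N={N}")
    if k <= 1:
        raise DataInsufficiencyError(f"need more than one repeat per participant, got k={k}")
    df = N * (k - 1) - 1
    dfi = int(round(df))
    if dfi < 1:
        raise DataInsufficiencyError(f"error degrees of freedom N(k-1)-1 = {dfi} < 1")
    return dfi


def approx_df(N: int, k: float) -> int:
    """Approximate rmcorr df: (k - 1) multiples of the Pearson df (N - 2).

    A convenience for power shortcuts; the ratio to :func:`error_df`
    tends to 1 as N grows at fixed k.
    """
    if N < 3:
        raise ConfigurationError(f"approximation requires N >= 3, got N={N}")
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got k={k}")
    return int(round((k - 1) * (N - 2)))


class _FitStats(NamedTuple):
    beta: float
    r: float
    ss_measure: float
    ss_error: float
    f_ratio: float
    p_value: float
    sxx: float
    syy: float
    xmeans: np.ndarray
    ymeans: np.ndarray


def _fit_arrays(codes: np.ndarray, n_groups: int, x: np.ndarray, y: np.ndarray) -> _FitStats:
    """Fast fitting core on raw arrays; shared by bootstrap and power paths."""
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    xmeans = np.bincount(codes, weights=x, minlength=n_groups) / counts
    ymeans = np.bincount(codes, weights=y, minlength=n_groups) / counts
    xc = x - xmeans[codes]
    yc = y - ymeans[codes]
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    if sxx <= 0.0:
        raise DegenerateDesignError(
            "no within-participant variance in the covariate for any participant"
        )
    df_error = x.shape[0] - n_groups - 1
    beta = sxy / sxx
    ss_measure = sxy * sxy / sxx
    ss_error = syy - ss_measure
    if ss_error < _PERFECT_FIT_RTOL * syy:
        ss_error = 0.0
    if beta == 0.0:
        r, f_ratio, p = 0.0, 0.0, 1.0
    elif ss_error == 0.0:
        r = math.copysign(1.0, beta)
        f_ratio, p = math.inf, 0.0
    else:
        r = math.copysign(math.sqrt(ss_measure / (ss_measure + ss_error)), beta)
        f_ratio = ss_measure / (ss_error / df_error)
        p = float(special.fdtrc(1.0, float(df_error), f_ratio))
    return _FitStats(beta, r, ss_measure, ss_error, f_ratio, p, sxx, syy, xmeans, ymeans)


@dataclass(frozen=True)
class AncovaTable:
    """Sums of squares, df, mean squares and F ratio of the rmcorr ANCOVA.

    Rows: Participants (between-participant variation, df N - 1),
    Measure (the covariate, df 1), Error (df N(k-1) - 1, i.e. L - N - 1),
    Total (df L - 1).  SS and df are additive across rows.
    """

    ss_participants: float
    ss_measure: float
    ss_error: float
    ss_total: float
    df_participants: int
    df_measure: int
    df_error: int
    df_total: int
    f_ratio: float
    p_value: float

    @property
    def ms_participants(self) -> float:
        return self.ss_participants / self.df_participants

    @property
    def ms_measure(self) -> float:
        return self.ss_measure / self.df_measure

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df_participants, self.df_measure, self.df_error, self.df_total],
                "SS": [self.ss_participants, self.ss_measure, self.ss_error, self.ss_total],
                "MS": [self.ms_participants, self.ms_measure, self.ms_error, np.nan],
                "F": [np.nan, self.f_ratio, np.nan, np.nan],
                "p": [np.nan, self.p_value, np.nan, np.nan],
            },
            index=["Participants", "Measure", "Error", "Total"],
        )

    def to_text(self) -> str:
        """Aligned plain-text rendition of the table."""
        frame = self.to_frame()
        lines = [f"{'Source':<14}{'df':>6}{'SS':>14}{'MS':>14}{'F':>12}{'p':>12}"]
        for name, row in frame.iterrows():
            ms = f"{row['MS']:.6g}" if np.isfinite(row["MS"]) else ""
            fv = f"{row['F']:.6g}" if np.isfinite(row["F"]) else ""
            pv = f"{row['p']:.4g}" if np.isfinite(row["p"]) else ""
            lines.append(
                f"{name:<14}{int(row['df']):>6}{row['SS']:>14.6g}{ms:>14}{fv:>12}{pv:>12}"
            )
        return "\n".join(lines)

    def to_csv(self, path, delimiter: str = ",") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index_label="Source")


@dataclass(frozen=True)
class RmcorrResult:
    """Fitted repeated-measures correlation.

    ``intercepts`` holds each participant's fitted intercept, so that the
    predicted line for participant j is ``intercepts[j] + slope * x``.
    """

    r_rm: float
    slope: float
    df_error: int
    f_ratio: float
    p_value: float
    ci: tuple[float, float]
    ci_level: float
    ci_method: str
    intercepts: pd.Series
    table: AncovaTable
    n_obs: int
    n_participants: int
    participant_levels: np.ndarray
    measure1_name: str = "measure1"
    measure2_name: str = "measure2"

    @property
    def ci_low(self) -> float:
        return self.ci[0]

    @property
    def ci_high(self) -> float:
        return self.ci[1]

    @property
    def k(self) -> float:
        return self.n_obs / self.n_participants

    def report_string(self) -> str:
        """Recommended reporting format: r_rm(df) with CI and p."""
        lo, hi = self.ci
        return (
            f"r_rm({self.df_error}) = {self.r_rm:.2f}, "
            f"{self.ci_level:.0%} CI [{lo:.2f}, {hi:.2f}], "
            f"p = {self.p_value:.3g}"
        )


def fit_rmcorr(data: PairedRepeatedData, ci_level: float = 0.95) -> RmcorrResult:
    """Fit the repeated-measures correlation by least squares.

    Parameters
    ----------
    data : PairedRepeatedData
        Validated long-format dataset.
    ci_level : float
        Coverage of the analytic (Fisher-transformation) confidence
        interval attached to the result.

    Returns
    -------
    RmcorrResult

    Raises
    ------
    DataInsufficiencyError
        If the error df L - N - 1 < 1.
    DegenerateDesignError
        If no participant shows within-participant variance in the
        covariate.
    """
    L, N = data.L, data.N
    df_err = L - N - 1
    if df_err < 1:
        raise DataInsufficiencyError(f"error degrees of freedom L - N - 1 = {df_err} < 1")
    s = _fit_arrays(data.codes, N, data.measure2, data.measure1)

    y = data.measure1
    grand = float(y.mean())
    counts = data.counts.astype(float)
    ss_participants = float(counts @ (s.ymeans - grand) ** 2)
    ss_total = float(((y - grand) ** 2).sum())
    table = AncovaTable(
        ss_participants=ss_participants,
        ss_measure=s.ss_measure,
        ss_error=s.ss_error,
        ss_total=ss_total,
        df_participants=N - 1,
        df_measure=1,
        df_error=df_err,
        df_total=L - 1,
        f_ratio=s.f_ratio,
        p_value=s.p_value,
    )

    from .inference import analytic_ci  # local import to avoid a cycle

    import warnings as _warnings

    if abs(s.r) >= 1.0:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            ci = analytic_ci(s.r, max(df_err, 2), level=ci_level)
    elif df_err >= 2:
        ci = analytic_ci(s.r, df_err, level=ci_level)
    else:
        # With a single error df no analytic interval is available; report
        # the vacuous full-range interval.
        _warnings.warn(
            "df_error < 2: analytic confidence interval unavailable, "
            "reporting [-1, 1]",
            stacklevel=2,
        )
        ci = (-1.0, 1.0)

    intercepts = pd.Series(
        s.ymeans - s.beta * s.xmeans,
        index=pd.Index(data.participant_levels, name=data.participant_name),
        name="intercept",
    )
    return RmcorrResult(
        r_rm=s.r,
        slope=s.beta,
        df_error=df_err,
        f_ratio=s.f_ratio,
        p_value=s.p_value,
        ci=ci,
        ci_level=ci_level,
        ci_method="analytic",
        intercepts=intercepts,
        table=table,
        n_obs=L,
        n_participants=N,
        participant_levels=data.participant_levels,
        measure1_name=data.measure1_name,
        measure2_name=data.measure2_name,
    )


class ParticipantLine(NamedTuple):
    participant: str
    x: np.ndarray
    y_hat: np.ndarray


def predicted_lines(result: RmcorrResult, data: PairedRepeatedData) -> list[ParticipantLine]:
    """Per-participant fitted values: intercept_j + slope * x, common slope.

    Points are returned sorted by x within each participant; every line
    shares the common slope exactly by construction.
    """
    if result.n_obs != data.L or not np.array_equal(
        result.participant_levels, data.participant_levels
    ):
        raise ConsistencyError("result was not fitted on this dataset")
    out = []
    intercepts = result.intercepts.to_numpy()
    for j, label in enumerate(data.participant_levels):
        rows = np.flatnonzero(data.codes == j)
        xs = np.sort(data.measure2[rows])
        out.append(ParticipantLine(str(label), xs, intercepts[j] + result.slope * xs))
    return out


@dataclass(frozen=True)
class PearsonCorr:
    r: float
    p_value: float
    df: int
    n: int


@dataclass(frozen=True)
class PearsonBaselines:
    """Inter-individual (Pearson) analyses for side-by-side reporting.

    ``averaged`` correlates participant means (one point per participant,
    df N - 2); ``pooled`` treats every row as independent (df L - 2),
    which violates independence and is reported for comparison only;
    ``per_occasion`` holds one Pearson correlation per trial/occasion
    when a trial label per row is supplied.
    """

    averaged: PearsonCorr
    pooled: PearsonCorr
    per_occasion: list[tuple[str, PearsonCorr]] | None = None


def _pearson(x: np.ndarray, y: np.ndarray) -> PearsonCorr:
    n = x.shape[0]
    if n < 3:
        raise DataInsufficiencyError(f"Pearson correlation needs at least 3 points, got {n}")
    r, p = stats.pearsonr(x, y)
    return PearsonCorr(r=float(r), p_value=float(p), df=n - 2, n=n)


def pearson_baselines(data: PairedRepeatedData, trial=None) -> PearsonBaselines:
    """Pearson correlations of the averaged and pooled data.

    These answer the *inter-individual* question (across people), in
    contrast to the intra-individual association measured by rmcorr; the
    two can differ in sign (Simpson's paradox).
    """
    if data.N < 3:
        raise DataInsufficiencyError(
            f"averaged-data Pearson correlation needs at least 3 participants, got {data.N}"
        )
    counts = data.counts.astype(float)
    xm = np.bincount(data.codes, weights=data.measure2, minlength=data.N) / counts
    ym = np.bincount(data.codes, weights=data.measure1, minlength=data.N) / counts
    averaged = _pearson(xm, ym)
    pooled = _pearson(data.measure2, data.measure1)

    per_occasion = None
    if trial is not None:
        trial = np.asarray(trial, dtype=object)
        if trial.shape[0] != data.L:
            raise ConfigurationError("trial labels must have one entry per row")
        per_occasion = []
        for lev in pd.unique(trial):
            rows = np.flatnonzero(trial == lev)
            if rows.size >= 3:
                per_occasion.append(
                    (str(lev), _pearson(data.measure2[rows], data.measure1[rows]))
                )
    return PearsonBaselines(averaged=averaged, pooled=pooled, per_occasion=per_occasion)
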