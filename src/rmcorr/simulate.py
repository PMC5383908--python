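"""Synthetic paired repeated-measures data with controlled structure.

The generator follows the varying-intercept, common-slope model: each
participant j receives a covariate center x_bar_j and a response center
y_bar_j (linked by an optional between-participant trend), the covariate
is spread around its center by deterministic equispaced offsets, and the
response is

    y_ij = y_bar_j + slope * (x_ij - x_bar_j) + eps_ij,
    eps_ij ~ Normal(0, noise_sd^2).

The theoretical within-participant correlation implied by a spec is

    rho_w = slope * within_x_sd / sqrt(slope^2 * within_x_sd^2 + noise_sd^2).

Because the within-covariate offsets are deterministic (Gaussian noise
enters only through the response), noise-free specs yield exactly
collinear per-participant points, which makes the didactic grid and
linear-transformation fixtures exact rather than approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .data import PairedRepeatedData
from .errors import ConfigurationError

__all__ = [
    "SimulationSpec",
    "generate",
    "spec_for_correlation",
    "figure2_grid",
    "figure3_fixtures",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Generative parameters for one synthetic dataset.

    Parameters
    ----------
    N : int
        Number of participants (>= 2).
    k : int
        Paired observations per participant (>= 2).
    slope : float
        Common within-participant slope beta.
    within_x_sd : float
        Spread of the covariate around each participant's center (> 0).
    noise_sd : float
        Residual standard deviation on the response (>= 0).
    intercept_sd : float
        Spread of participant response centers around the between-trend
        line.
    between_trend : float
        Slope of participant response centers against covariate centers;
        controls the inter-individual pattern independently of the
        within-participant association.
    between_x_sd : float
        Spread of participant covariate centers.
    x_jitter_sd : float
        Optional Gaussian jitter added to the deterministic covariate
        offsets (0 keeps noise-free specs exactly collinear).
    seed : int or None
        Seed for the generator; identical spec + seed reproduce the
        dataset bit for bit.

    Defaults describe a moderate design — 20 participants with 5 paired
    observations each and a true within-participant correlation of 0.5 —
    typical of the repeated-measures studies this estimator targets.
    """

    N: int = 20
    k: int = 5
    slope: float = 0.5
    within_x_sd: float = 1.0
    noise_sd: float = math.sqrt(0.75)
    intercept_sd: float = 1.0
    between_trend: float = 0.0
    between_x_sd: float = 1.0
    x_jitter_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.N < 2:
            raise ConfigurationError(f"N must be >= 2, got {self.N}")
        if self.k < 2:
            raise ConfigurationError(f"k must be >= 2, got {self.k}")
        if self.within_x_sd <= 0:
            raise ConfigurationError(f"within_x_sd must be > 0, got {self.within_x_sd}")
        if self.noise_sd < 0 or self.intercept_sd < 0 or self.between_x_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        if self.x_jitter_sd < 0:
            raise ConfigurationError("x_jitter_sd must be non-negative")

    @property
    def rho_within(self) -> float:
        """Theoretical within-participant correlation implied by the spec."""
        s = self.slope * self.within_x_sd
        denom = math.hypot(s, self.noise_sd)
        return 0.0 if denom == 0.0 else s / denom

    def to_dict(self) -> dict:
        return asdict(self)


def spec_for_correlation(rho: float, N: int = 20, k: int = 5, seed: int | None = None, **overrides) -> SimulationSpec:
    """Spec whose theoretical within-correlation equals ``rho``.

    Uses unit within-covariate spread, slope = rho and noise_sd =
    sqrt(1 - rho^2); any other field may be overridden by keyword.
    """
    if not -1.0 <= rho <= 1.0:
        raise ConfigurationError(f"rho must be in [-1, 1], got {rho}")
    return SimulationSpec(
        N=N,
        k=k,
        slope=rho,
        within_x_sd=1.0,
        noise_sd=math.sqrt(max(0.0, 1.0 - rho * rho)),
        seed=seed,
        **overrides,
    )


def _symmetric_offsets(k: int) -> np.ndarray:
    """Integer-valued, exactly symmetric offsets with zero sum.

    Odd k includes 0; even k skips it.  Symmetry is exact in floating
    point, so group means and centered values carry no rounding error.
    """
    half = np.arange(1, k // 2 + 1, dtype=float)
    if k % 2:
        return np.concatenate([-half[::-1], [0.0], half])
    return np.concatenate([-half[::-1], half])


def _unit_sd_offsets(k: int) -> np.ndarray:
    u = _symmetric_offsets(k)
    return u / u.std()


def _generate_arrays(spec: SimulationSpec, rng: np.random.Generator | None = None):
    """Raw (codes, N, x, y) arrays; fast path shared with the power module."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    N, k = spec.N, spec.k
    # Deterministic offsets are scaled to sd * sqrt((k-1)/k): the expected
    # within-group *centered* spread of a random covariate sample.  This
    # keeps the ANCOVA estimand equal to rho_within (centering shrinks the
    # residual spread by the same factor), so the fitted r_rm is a
    # consistent estimator of the spec's theoretical within-correlation.
    offsets = _unit_sd_offsets(k) * spec.within_x_sd * math.sqrt((k - 1) / k)
    xbar = rng.normal(0.0, spec.between_x_sd, N) if spec.between_x_sd > 0 else np.zeros(N)
    ybar = spec.between_trend * xbar
    if spec.intercept_sd > 0:
        ybar = ybar + rng.normal(0.0, spec.intercept_sd, N)
    x = xbar[:, None] + offsets[None, :]
    if spec.x_jitter_sd > 0:
        x = x + rng.normal(0.0, spec.x_jitter_sd, (N, k))
    y = ybar[:, None] + spec.slope * (x - xbar[:, None])
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, (N, k))
    else:
        y = y + 0.0
    codes = np.repeat(np.arange(N, dtype=np.intp), k)
    return codes, N, x.ravel(), y.ravel()


def _labels_from_codes(codes: np.ndarray, N: int) -> np.ndarray:
    width = len(str(N))
    levels = np.array([f"p{j + 1:0{width}d}" for j in range(N)], dtype=object)
    return levels[codes]


def generate(spec: SimulationSpec, rng: np.random.Generator | None = None) -> PairedRepeatedData:
    """Draw one dataset from the spec's generative model."""
    codes, N, x, y = _generate_arrays(spec, rng)
    return PairedRepeatedData(_labels_from_codes(codes, N), y, x)


# Between-participant geometry of the didactic grid: covariate centers
# spaced 4 apart and trend slopes +/-2 make the between-participant
# variation dominate the pooled OLS slope, which is what produces the
# Simpson's-paradox panels.
_GRID_TRENDS = {"negative": -2.0, "none": 0.0, "positive": 2.0}
_GRID_SPACING = 4.0


def figure2_grid(
    points_per_participant: int = 5, N: int = 5, seed: int | None = None
) -> dict[tuple[int, str], PairedRepeatedData]:
    """Nine datasets crossing within-correlation with between-trend.

    Columns fix the within-participant correlation at exactly -1, 0 or
    +1 (noise-free integer constructions, exact in floating point); rows
    vary the trend of the participant means (negative / none /
    positive).  Keys are ``(within_corr, trend_label)`` with
    ``within_corr`` in {-1, 0, 1} and ``trend_label`` in {"negative",
    "none", "positive"}.

    The (within = +1, trend = "negative") panel is an exact instance of
    Simpson's paradox: every participant's points rise while the pooled
    OLS line falls.
    """
    k = points_per_participant
    if N < 3:
        raise ConfigurationError(f"grid requires N >= 3, got {N}")
    if k < 3:
        raise ConfigurationError(f"grid requires >= 3 points per participant, got {k}")
    u = _symmetric_offsets(k)  # integers: exact arithmetic throughout
    a = np.abs(u)
    # Even-symmetric integer pattern orthogonal to u with zero sum: gives
    # within-variance in y but a within-covariance of exactly zero.
    w = k * a - a.sum()
    xbar = (np.arange(N, dtype=float) - (N - 1) / 2.0) * _GRID_SPACING
    column_offsets = {-1: -u, 0: w, 1: u}
    codes = np.repeat(np.arange(N, dtype=np.intp), k)
    grid: dict[tuple[int, str], PairedRepeatedData] = {}
    for within, yoff in column_offsets.items():
        for label, trend in _GRID_TRENDS.items():
            x = (xbar[:, None] + u[None, :]).ravel()
            y = (trend * xbar[:, None] + yoff[None, :]).ravel()
            grid[(within, label)] = PairedRepeatedData(
                _labels_from_codes(codes, N), y, x
            )
    return grid


def figure3_fixtures(base: PairedRepeatedData) -> dict[str, PairedRepeatedData]:
    """Linear-transformation fixtures sharing one r_rm and p exactly.

    Returns the original dataset, a copy with the covariate globally
    transformed to x/2 + 1, and a copy with the response of the first
    participant shifted down by 2.  All three fits agree to machine
    precision.
    """
    x_transformed = base.with_measures(measure2=base.measure2 / 2.0 + 1.0)
    y = base.measure1.copy()
    first = np.flatnonzero(base.codes == 0)
    y[first] = y[first] - 2.0
    y_shifted = base.with_measures(measure1=y)
    return {
        "original": base,
        "x_half_plus_one": x_transformed,
        "y_minus_two_first_participant": y_shifted,
    }
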