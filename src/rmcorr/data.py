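"""Long-format paired repeated-measures data: validation, loading, saving.

The canonical layout is one row per observation with three columns: a
participant identifier and the two paired measures.  Each participant
contributes two or more rows (repeated occasions).  Following the usual
notation, ``L`` is the total number of rows, ``N`` the number of unique
participants, and ``k = L / N`` the mean number of paired repeated
measures per participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DataInsufficiencyError

__all__ = [
    "PairedRepeatedData",
    "ValidationReport",
    "Summary",
    "load_long_table",
    "from_dataframe",
    "summarize",
]


def _normalize_label(value) -> str:
    """Normalize a participant identifier to a comparable string.

    Numeric labels are compared by value (3, 3.0 and "3" collapse to the
    same label); string labels are stripped of surrounding whitespace.
    """
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        f = float(value)
        return str(int(f)) if f.is_integer() else repr(f)
    s = str(value).strip()
    try:
        f = float(s)
    except ValueError:
        return s
    return str(int(f)) if f.is_integer() else repr(f)


@dataclass
class ValidationReport:
    """Bookkeeping for rows and participants dropped while cleaning.

    The counts always reconcile:
    ``n_input_rows = n_retained_rows + n_dropped_incomplete_rows +
    n_dropped_participant_rows``.
    """

    n_input_rows: int
    n_dropped_incomplete_rows: int = 0
    n_dropped_participant_rows: int = 0
    dropped_participants: dict[str, str] = field(default_factory=dict)
    n_retained_rows: int = 0
    n_retained_participants: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def reconciles(self) -> bool:
        return self.n_input_rows == (
            self.n_retained_rows
            + self.n_dropped_incomplete_rows
            + self.n_dropped_participant_rows
        )

    def to_dict(self) -> dict:
        return {
            "n_input_rows": self.n_input_rows,
            "n_dropped_incomplete_rows": self.n_dropped_incomplete_rows,
            "n_dropped_participant_rows": self.n_dropped_participant_rows,
            "dropped_participants": dict(self.dropped_participants),
            "n_retained_rows": self.n_retained_rows,
            "n_retained_participants": self.n_retained_participants,
            "warnings": list(self.warnings),
        }


class Summary(NamedTuple):
    L: int
    N: int
    k: float


class PairedRepeatedData:
    """A validated long-format paired repeated-measures dataset.

    Parameters
    ----------
    participants : array-like
        Participant identifier per row (opaque labels; order of first
        appearance fixes the factor-level order).
    measure1, measure2 : array-like of float
        The two paired measures.  In the ANCOVA parameterization
        ``measure1`` plays the response and ``measure2`` the covariate,
        but the correlation is symmetric in the two.

    Raises
    ------
    DataInsufficiencyError
        If N < 2, L < 4, or any participant has fewer than 2 rows.
    DataError
        If any measure value is non-finite.  Use :func:`load_long_table`
        or :func:`from_dataframe` to filter messy input instead.
    """

    def __init__(
        self,
        participants,
        measure1,
        measure2,
        participant_name: str = "participant",
        measure1_name: str = "measure1",
        measure2_name: str = "measure2",
    ):
        labels = np.array(
            [_normalize_label(p) for p in np.asarray(participants, dtype=object)],
            dtype=object,
        )
        y = np.ascontiguousarray(measure1, dtype=float)
        x = np.ascontiguousarray(measure2, dtype=float)
        if not (labels.shape[0] == y.shape[0] == x.shape[0]):
            raise ConfigurationError(
                "participants, measure1 and measure2 must have equal length"
            )
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise DataError(
                "non-finite measure values present; load via load_long_table/"
                "from_dataframe to drop incomplete rows"
            )
        codes, levels = pd.factorize(labels)
        counts = np.bincount(codes)
        L = int(y.shape[0])
        N = int(levels.shape[0])
        if N < 2:
            raise DataInsufficiencyError(f"need at least 2 participants, got {N}")
        if L < 4:
            raise DataInsufficiencyError(f"need at least 4 rows in total, got {L}")
        if counts.min() < 2:
            bad = levels[np.flatnonzero(counts < 2)[0]]
            raise DataInsufficiencyError(
                f"participant {bad!r} has fewer than 2 complete pairs; "
                "use load_long_table/from_dataframe to filter such participants"
            )
        self._labels = labels
        self._y = y
        self._x = x
        self._codes = np.ascontiguousarray(codes, dtype=np.intp)
        self._levels = np.asarray(levels, dtype=object)
        self._counts = counts
        self.participant_name = participant_name
        self.measure1_name = measure1_name
        self.measure2_name = measure2_name

    # -- basic accessors -------------------------------------------------
    @property
    def participants(self) -> np.ndarray:
        """Normalized participant label per row."""
        return self._labels

    @property
    def measure1(self) -> np.ndarray:
        return self._y

    @property
    def measure2(self) -> np.ndarray:
        return self._x

    @property
    def codes(self) -> np.ndarray:
        """Integer participant code per row (first-appearance order)."""
        return self._codes

    @property
    def participant_levels(self) -> np.ndarray:
        return self._levels

    @property
    def counts(self) -> np.ndarray:
        """Rows per participant, indexed by participant code."""
        return self._counts

    @property
    def L(self) -> int:
        """Total number of paired repeated measures (rows)."""
        return int(self._y.shape[0])

    @property
    def N(self) -> int:
        """Number of unique participants."""
        return int(self._levels.shape[0])

    @property
    def k(self) -> float:
        """Mean number of paired repeated measures per participant, L/N."""
        return self.L / self.N

    def participant_rows(self, label) -> np.ndarray:
        """Row indices belonging to one participant."""
        key = _normalize_label(label)
        matches = np.flatnonzero(self._levels == key)
        if matches.size == 0:
            raise KeyError(f"unknown participant {label!r}")
        return np.flatnonzero(self._codes == matches[0])

    # -- conversion ------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.participant_name: self._labels,
                self.measure1_name: self._y,
                self.measure2_name: self._x,
            }
        )

    def write(self, path, delimiter: str = ",") -> None:
        """Write as delimited text (header row, '.' decimal, UTF-8)."""
        self.to_dataframe().to_csv(path, sep=delimiter, index=False, encoding="utf-8")

    def with_measures(self, measure1=None, measure2=None) -> "PairedRepeatedData":
        """Copy with one or both measures replaced (e.g. linear transforms)."""
        return PairedRepeatedData(
            self._labels,
            self._y if measure1 is None else measure1,
            self._x if measure2 is None else measure2,
            participant_name=self.participant_name,
            measure1_name=self.measure1_name,
            measure2_name=self.measure2_name,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, PairedRepeatedData):
            return NotImplemented
        return (
            np.array_equal(self._labels, other._labels)
            and np.array_equal(self._y, other._y)
            and np.array_equal(self._x, other._x)
        )

    def __len__(self) -> int:
        return self.L

    def __repr__(self) -> str:
        return (
            f"PairedRepeatedData(L={self.L}, N={self.N}, k={self.k:g}, "
            f"measures=({self.measure1_name!r}, {self.measure2_name!r}))"
        )


def from_dataframe(
    df: pd.DataFrame,
    participant_col: str = "participant",
    measure1_col: str = "measure1",
    measure2_col: str = "measure2",
) -> tuple[PairedRepeatedData, ValidationReport]:
    """Clean a long-format frame into a :class:`PairedRepeatedData`.

    Rows with a missing/non-numeric value in either measure (or a missing
    participant id) are dropped whole; participants left with fewer than
    two complete pairs are then dropped with a warning.  Ordering of the
    retained rows is preserved.  Cleaning is idempotent.
    """
    missing = [c for c in (participant_col, measure1_col, measure2_col) if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"column(s) not found in input: {', '.join(repr(c) for c in missing)}; "
            f"available columns: {', '.join(repr(c) for c in df.columns)}"
        )
    n_input = len(df)
    part_raw = df[participant_col]
    y = pd.to_numeric(df[measure1_col], errors="coerce").to_numpy(dtype=float)
    x = pd.to_numeric(df[measure2_col], errors="coerce").to_numpy(dtype=float)
    complete = np.isfinite(y) & np.isfinite(x) & part_raw.notna().to_numpy()
    n_incomplete = int((~complete).sum())

    labels = np.array(
        [_normalize_label(v) for v in part_raw.to_numpy(dtype=object)[complete]],
        dtype=object,
    )
    y, x = y[complete], x[complete]

    report = ValidationReport(n_input_rows=n_input, n_dropped_incomplete_rows=n_incomplete)
    if n_incomplete:
        report.warnings.append(f"dropped {n_incomplete} incomplete row(s)")

    if labels.size:
        codes, levels = pd.factorize(labels)
        counts = np.bincount(codes)
        too_few = counts < 2
        if too_few.any():
            for lev in levels[too_few]:
                report.dropped_participants[str(lev)] = "fewer than 2 complete pairs"
            keep = ~too_few[codes]
            report.n_dropped_participant_rows = int((~keep).sum())
            report.warnings.append(
                "dropped participant(s) with fewer than 2 complete pairs: "
                + ", ".join(map(str, levels[too_few]))
            )
            labels, y, x = labels[keep], y[keep], x[keep]

    report.n_retained_rows = int(labels.size)
    report.n_retained_participants = int(pd.unique(labels).size)

    if report.n_retained_participants < 2:
        raise DataInsufficiencyError(
            "fewer than 2 participants remain after filtering "
            f"({report.n_retained_participants})"
        )
    df_error = report.n_retained_rows - report.n_retained_participants - 1
    if df_error < 1:
        raise DataInsufficiencyError(
            f"error degrees of freedom L - N - 1 = {df_error} < 1 after filtering"
        )

    dup = pd.DataFrame({"p": labels, "y": y, "x": x}).duplicated().sum()
    if dup:
        report.warnings.append(
            f"{int(dup)} duplicated identical row(s) retained (treated as "
            "legitimate repeated observations)"
        )

    data = PairedRepeatedData(
        labels,
        y,
        x,
        participant_name=participant_col,
        measure1_name=measure1_col,
        measure2_name=measure2_col,
    )
    return data, report


def load_long_table(
    path,
    participant_col: str = "participant",
    measure1_col: str = "measure1",
    measure2_col: str = "measure2",
    delimiter: str = ",",
) -> tuple[PairedRepeatedData, ValidationReport]:
    """Load a delimited long-format text file (CSV by default, TSV via delimiter)."""
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"input file not found: {p}")
    df = pd.read_csv(p, sep=delimiter, encoding="utf-8", float_precision="round_trip")
    return from_dataframe(df, participant_col, measure1_col, measure2_col)


def summarize(data: PairedRepeatedData) -> Summary:
    """Return (L, N, k) with k = L/N exactly."""
    return Summary(L=data.L, N=data.N, k=data.L / data.N)
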