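"""Mitotic-progression analysis with movie-end censoring.

Cells are followed from nuclear envelope breakdown (NEB) through metaphase
to anaphase onset in overnight movies (one frame every 3 min for 12 h by
default).  A transition not observed before the movie ends — or never, for
arrested cells — is *censored*: the cell still counts in denominators
(cumulative histograms, exit fractions) but contributes no observed
interval.  Medians are computed over cells with observed transitions only
and flagged unreliable when more than half the cohort is censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ValidationError

__all__ = [
    "MitoticEvents",
    "Intervals",
    "TimingSummary",
    "intervals",
    "cohort_intervals",
    "cumulative_histogram",
    "summarize",
    "load_events",
    "DEFAULT_FRAME_INTERVAL",
]

#: Acquisition granularity of the overnight movies (minutes).
DEFAULT_FRAME_INTERVAL = 3.0

_COLUMNS = [
    "cell_id", "neb_min", "metaphase_min", "anaphase_min",
    "censored_metaphase", "censored_anaphase",
]


@dataclass
class MitoticEvents:
    """Event times of one cell (minutes).  Censored events carry the movie
    length as their time."""

    cell_id: str
    t_neb: float
    t_metaphase: float
    t_anaphase: float
    censored_metaphase: bool = False
    censored_anaphase: bool = False
    movie_length: float = 720.0

    def __post_init__(self):
        if self.t_neb > self.t_metaphase or self.t_metaphase > self.t_anaphase:
            raise ValidationError(
                f"{self.cell_id}: event times must be ordered NEB <= metaphase <= anaphase"
            )
        if self.censored_metaphase and not self.censored_anaphase:
            raise ValidationError(
                f"{self.cell_id}: metaphase censored but anaphase observed"
            )
        for censored, t in (
            (self.censored_metaphase, self.t_metaphase),
            (self.censored_anaphase, self.t_anaphase),
        ):
            if censored and t != self.movie_length:
                raise ValidationError(
                    f"{self.cell_id}: censored events must carry the movie length"
                )


@dataclass
class Intervals:
    """NEB-anchored intervals of one cell with censor flags."""

    neb_to_meta: float
    neb_to_ana: float
    censored_metaphase: bool
    censored_anaphase: bool


def intervals(ev: MitoticEvents) -> Intervals:
    """Differences of event times from NEB; censor flags propagate."""
    return Intervals(
        neb_to_meta=ev.t_metaphase - ev.t_neb,
        neb_to_ana=ev.t_anaphase - ev.t_neb,
        censored_metaphase=ev.censored_metaphase,
        censored_anaphase=ev.censored_anaphase,
    )


def load_events(path_or_frame, movie_length: float = 720.0) -> pd.DataFrame:
    """Load and validate a cohort events table (CSV path or DataFrame)."""
    df = (
        path_or_frame.copy()
        if isinstance(path_or_frame, pd.DataFrame)
        else pd.read_csv(path_or_frame)
    )
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"events table missing columns {missing}")
    for c in ("censored_metaphase", "censored_anaphase"):
        df[c] = df[c].astype(bool)
    bad = (df["neb_min"] > df["metaphase_min"]) | (
        df["metaphase_min"] > df["anaphase_min"]
    )
    if bad.any():
        raise ValidationError(
            f"unordered event times for cells {df.loc[bad, 'cell_id'].tolist()}"
        )
    return df


def cohort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Per-cell intervals for a cohort table."""
    return pd.DataFrame(
        {
            "cell_id": df["cell_id"],
            "neb_to_meta": df["metaphase_min"] - df["neb_min"],
            "neb_to_ana": df["anaphase_min"] - df["neb_min"],
            "censored_metaphase": df["censored_metaphase"],
            "censored_anaphase": df["censored_anaphase"],
        }
    )


def cumulative_histogram(interval_values, censored, grid) -> np.ndarray:
    """Fraction of *all* cells with an observed interval <= each grid time.

    Censored cells stay in the denominator forever, so the curve plateaus at
    the fraction of cells that completed the transition.
    """
    interval_values = np.asarray(interval_values, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    grid = np.asarray(grid, dtype=float)
    if interval_values.size == 0:
        raise ParameterError("empty interval set")
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ParameterError("grid must be non-empty and strictly increasing")
    observed = interval_values[~censored]
    n = len(interval_values)
    return np.array([(observed <= t).sum() / n for t in grid])


@dataclass
class TimingSummary:
    """Cohort summary: observed-transition medians, exit fraction, and the
    cumulative NEB→anaphase curve.  ``median_unreliable`` flags medians
    computed with more than 50% of the cohort censored."""

    n: int
    median_neb_meta: float
    median_neb_ana: float
    frac_exiting: float
    grid: np.ndarray
    cumulative_neb_ana: np.ndarray
    median_unreliable: dict = field(default_factory=dict)
    fold_delay: float | None = None


def _median_observed(values, censored, label, flags):
    observed = values[~censored]
    frac_cens = censored.mean()
    flags[label] = bool(frac_cens > 0.5)
    if len(observed) == 0:
        raise DegenerateMedian(f"no observed {label} transitions; median undefined")
    return float(np.median(observed))


class DegenerateMedian(ParameterError):
    """No observed transitions: the requested median does not exist."""


def summarize(
    cohort,
    control=None,
    grid=None,
    movie_length: float = 720.0,
) -> TimingSummary:
    """Summarize a cohort (and optionally a control cohort).

    Medians are over observed transitions only; ``frac_exiting`` is the
    fraction of cells reaching anaphase before the movie ends; the fold
    delay is the treated/control ratio of median NEB→anaphase times.
    """
    df = load_events(cohort, movie_length)
    iv = cohort_intervals(df)
    if grid is None:
        grid = np.arange(0.0, movie_length + DEFAULT_FRAME_INTERVAL,
                         DEFAULT_FRAME_INTERVAL)
    flags: dict = {}
    median_meta = _median_observed(
        iv["neb_to_meta"].to_numpy(), iv["censored_metaphase"].to_numpy(),
        "neb_to_meta", flags,
    )
    median_ana = _median_observed(
        iv["neb_to_ana"].to_numpy(), iv["censored_anaphase"].to_numpy(),
        "neb_to_ana", flags,
    )
    curve = cumulative_histogram(
        iv["neb_to_ana"], iv["censored_anaphase"], grid
    )
    frac_exiting = float((~iv["censored_anaphase"]).mean())
    fold = None
    if control is not None:
        fold = median_ana / summarize(control, grid=grid,
                                      movie_length=movie_length).median_neb_ana
    return TimingSummary(
        n=len(df),
        median_neb_meta=median_meta,
        median_neb_ana=median_ana,
        frac_exiting=frac_exiting,
        grid=np.asarray(grid, dtype=float),
        cumulative_neb_ana=curve,
        median_unreliable=flags,
        fold_delay=fold,
    )
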