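"""Relocalization statistics: spindle fractions, ternary compositions,
arrow-plot summaries with paired tests, and relocalization-efficiency calls.

Ternary diagrams of spindle/mitochondria/cytoplasm fluorescence show that
induced rerouting moves signal almost exclusively between spindle and
mitochondria, so the headline statistic is the *spindle fraction*:
spindle / (spindle + mitochondria) fluorescence, 1 = fully spindle-localized,
0 = fully mitochondrial.  Per-cell arrows from the pre- to the
post-rapamycin fraction — target channel on x, partner channel on y — make
co-rerouting of a partner protein visible as a diagonal arrow.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, ParameterError, ValidationError
from .quantify import CompartmentMeasurement

__all__ = [
    "ArrowRecord",
    "TernaryComposition",
    "PairedTTest",
    "ArrowSummary",
    "spindle_fraction",
    "ternary_composition",
    "paired_t_test",
    "arrow_summary",
    "classify_relocalized",
    "efficiency",
    "arrow_records_from_measurements",
    "arrows_to_csv",
    "arrows_from_csv",
]


@dataclass
class ArrowRecord:
    """Per-cell spindle fraction before and after rapamycin for one channel
    role (``target`` = directly rerouted FKBP fusion, ``partner`` = candidate
    co-rerouting protein)."""

    cell_id: str
    role: str  # "target" | "partner"
    f_pre: float
    f_post: float

    def __post_init__(self):
        for f in (self.f_pre, self.f_post):
            if not 0.0 <= f <= 1.0:
                raise ParameterError(f"spindle fraction {f} outside [0, 1]")
        if self.role not in ("target", "partner"):
            raise ParameterError(f"unknown channel role {self.role!r}")


@dataclass
class TernaryComposition:
    """Point on the spindle/mito/cytoplasm simplex for one measurement."""

    cell_id: str
    channel: str
    phase: str
    p_spindle: float
    p_mito: float
    p_cyto: float

    def __post_init__(self):
        total = self.p_spindle + self.p_mito + self.p_cyto
        if abs(total - 1.0) > 1e-12:
            raise ParameterError(f"composition sums to {total}, not 1")
        if min(self.p_spindle, self.p_mito, self.p_cyto) < 0:
            raise ParameterError("composition components must be non-negative")


def spindle_fraction(m) -> float:
    """Fraction of combined spindle + mitochondria fluorescence at the
    spindle.  Accepts a :class:`~knockscope.quantify.CompartmentMeasurement`
    or an (spindle, mito) pair."""
    if isinstance(m, CompartmentMeasurement):
        spindle, mito = m.spindle, m.mito
    else:
        spindle, mito = m
    if not np.isfinite(spindle) or not np.isfinite(mito):
        raise ParameterError("spindle and mito values must be finite")
    if spindle < 0 or mito < 0:
        raise ParameterError("compartment values must be >= 0")
    total = spindle + mito
    if total <= 0:
        raise DegenerateInputError(
            "spindle + mito fluorescence is zero; fraction undefined"
        )
    return spindle / total


def ternary_composition(m: CompartmentMeasurement, phase: str = "") -> TernaryComposition:
    """Normalize the three compartments onto the 2-simplex."""
    total = m.spindle + m.mito + m.cytoplasm
    if not np.isfinite(total) or total <= 0:
        raise DegenerateInputError("total compartment fluorescence is zero or undefined")
    return TernaryComposition(
        cell_id=m.cell_id,
        channel=m.channel,
        phase=phase or str(m.time),
        p_spindle=m.spindle / total,
        p_mito=m.mito / total,
        p_cyto=m.cytoplasm / total,
    )


@dataclass
class PairedTTest:
    """Classical paired Student t-test result.  ``degenerate`` is set (with
    ``p`` = NaN) when all paired differences are identical, where the
    statistic is undefined."""

    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_t_test(x, y) -> PairedTTest:
    """Two-sided paired t-test on differences ``d_i = x_i - y_i``:
    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``n - 1`` degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("paired samples must be 1-D and equal length")
    n = len(x)
    if n < 2:
        raise ParameterError("paired t-test needs n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedTTest(t=float("nan"), df=n - 1, p=float("nan"), degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedTTest(t=float(t), df=n - 1, p=float(p))


@dataclass
class ArrowSummary:
    """Cohort summary per channel role: mean pre/post fractions (the mean
    arrow) and the paired test of pre vs post."""

    n: int
    mean_f_pre: dict[str, float]
    mean_f_post: dict[str, float]
    tests: dict[str, PairedTTest]


def _by_role(records) -> dict[str, dict[str, ArrowRecord]]:
    roles: dict[str, dict[str, ArrowRecord]] = {}
    for rec in records:
        roles.setdefault(rec.role, {})[rec.cell_id] = rec
    return roles


def arrow_summary(records) -> ArrowSummary:
    """Summarize a cohort of arrow records.

    Every channel role present must cover the same set of cells (a movie
    yields one target and one partner record per cell); at least two cells
    are required for the paired test.
    """
    roles = _by_role(records)
    if not roles:
        raise ParameterError("no arrow records")
    cell_sets = [set(cells) for cells in roles.values()]
    if any(s != cell_sets[0] for s in cell_sets[1:]):
        raise ValidationError("channel roles cover different cell sets")
    n = len(cell_sets[0])
    if n < 2:
        raise ParameterError("arrow summary needs >= 2 cells")
    mean_pre, mean_post, tests = {}, {}, {}
    for role, cells in roles.items():
        pre = np.array([r.f_pre for r in cells.values()])
        post = np.array([r.f_post for r in cells.values()])
        mean_pre[role] = float(pre.mean())
        mean_post[role] = float(post.mean())
        tests[role] = paired_t_test(pre, post)
    return ArrowSummary(n=n, mean_f_pre=mean_pre, mean_f_post=mean_post, tests=tests)


def classify_relocalized(rec: ArrowRecord, drop_threshold: float = 0.3) -> bool:
    """A cell counts as relocalized when its spindle fraction dropped by at
    least ``drop_threshold`` (absolute).  The threshold is an analysis
    choice calibrated so that complete-transfer simulations score 100%."""
    return (rec.f_pre - rec.f_post) >= drop_threshold


def efficiency(records, drop_threshold: float = 0.3) -> float:
    """Percentage of cells classified as relocalized."""
    records = list(records)
    if not records:
        raise ParameterError("efficiency of an empty cohort is undefined")
    hits = sum(classify_relocalized(r, drop_threshold) for r in records)
    return 100.0 * hits / len(records)


def arrow_records_from_measurements(
    measured: dict, roles: dict[str, str] | None = None
) -> list[ArrowRecord]:
    """Build arrow records from :func:`~knockscope.quantify.measure_cell`
    output.  ``roles`` maps channel name to role; by default channel names
    that are already roles are used as-is."""
    roles = roles or {}
    out = []
    for channel, (pre, post) in measured.items():
        role = roles.get(channel, channel)
        out.append(
            ArrowRecord(
                cell_id=pre.cell_id,
                role=role,
                f_pre=spindle_fraction(pre),
                f_post=spindle_fraction(post),
            )
        )
    return out


def arrows_to_csv(records, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_id", "role", "f_pre", "f_post"])
        for r in records:
            writer.writerow([r.cell_id, r.role, repr(r.f_pre), repr(r.f_post)])
    return path


def arrows_from_csv(path) -> list[ArrowRecord]:
    with open(path, newline="") as fh:
        return [
            ArrowRecord(
                cell_id=row["cell_id"],
                role=row["role"],
                f_pre=float(row["f_pre"]),
                f_post=float(row["f_post"]),
            )
            for row in csv.DictReader(fh)
        ]
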