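"""Fixed-cell spindle-localization scoring, line-scan microtubule enrichment
and group comparisons.

The spindle-localization score is the log2 of the background-subtracted
spindle-to-cytoplasm mean fluorescence ratio: 0 means no enrichment, +1
twice, -1 half the cytoplasmic signal.  Line-scan enrichment ratios the mean
intensity along three 1-3 µm lines on microtubules to three adjacent
control lines.  Construct groups are compared by one-way ANOVA with Tukey's
honest-significant-difference post-hoc test against a reference group (WT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import draw as _skdraw
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exceptions import DegenerateInputError, ParameterError, ValidationError
from .imaging_io import ChannelFrame
from .quantify import background_subtract

__all__ = [
    "SpindleEnrichment",
    "LineScanResult",
    "GroupComparison",
    "spindle_localization_score",
    "linescan_enrichment",
    "compare_groups",
    "significance_tier",
]


@dataclass
class SpindleEnrichment:
    """Spindle/cytoplasm enrichment of one fixed cell; ``score`` is
    ``log2(ratio)`` so 0 marks no enrichment."""

    cell_id: str
    channel: str
    ratio: float
    score: float


@dataclass
class LineScanResult:
    """Microtubule enrichment ratio from paired on/adjacent line scans."""

    cell_id: str
    on_line_mean: float
    adjacent_mean: float
    enrichment: float


def spindle_localization_score(
    spindle_mean: float,
    cyto_mean: float,
    background: float = 0.0,
    *,
    cell_id: str = "cell",
    channel: str = "",
) -> SpindleEnrichment:
    """Background-subtract both means, ratio spindle/cytoplasm, log2.

    A score of 1 means twice the cytoplasmic fluorescence on the spindle,
    -1 half, 0 no enrichment.
    """
    s = background_subtract(spindle_mean, background)
    c = background_subtract(cyto_mean, background)
    if c <= 0:
        raise DegenerateInputError("cytoplasm fluorescence <= 0 after background subtraction")
    if s <= 0:
        raise DegenerateInputError("spindle fluorescence <= 0 after background subtraction")
    ratio = s / c
    return SpindleEnrichment(
        cell_id=cell_id, channel=channel, ratio=ratio, score=float(np.log2(ratio))
    )


def _line_mean(pixels: np.ndarray, segment, pixel_size: float) -> float:
    (r0, c0), (r1, c1) = segment
    length = np.hypot(r1 - r0, c1 - c0) * pixel_size
    if not 1.0 - 1e-9 <= length <= 3.0 + 1e-9:
        raise ParameterError(f"line length {length:.3g} um outside the 1-3 um range")
    rr, cc = _skdraw.line(int(r0), int(c0), int(r1), int(c1))
    if (rr.min() < 0 or cc.min() < 0
            or rr.max() >= pixels.shape[0] or cc.max() >= pixels.shape[1]):
        raise ParameterError("line segment outside image bounds")
    return float(pixels[rr, cc].mean())


def linescan_enrichment(
    frame,
    on_lines,
    adjacent_lines,
    background: float = 0.0,
    *,
    pixel_size: float = 1.0,
    cell_id: str = "cell",
) -> LineScanResult:
    """Mean of three 1-px line profiles on microtubules over the mean of
    three adjacent control profiles, both background-subtracted.

    Lines are rasterized with a standard integer line walk at 1-pixel
    width; lengths must fall in the 1-3 µm range given ``pixel_size``.
    """
    pixels = frame.pixels if isinstance(frame, ChannelFrame) else np.asarray(frame, dtype=float)
    if len(on_lines) != 3 or len(adjacent_lines) != 3:
        raise ParameterError("exactly three on-microtubule and three adjacent lines required")
    on = float(np.mean([_line_mean(pixels, seg, pixel_size) for seg in on_lines]))
    adj = float(np.mean([_line_mean(pixels, seg, pixel_size) for seg in adjacent_lines]))
    on_bs = background_subtract(on, background)
    adj_bs = background_subtract(adj, background)
    if adj_bs <= 0:
        raise DegenerateInputError("adjacent line signal <= 0 after background subtraction")
    return LineScanResult(
        cell_id=cell_id,
        on_line_mean=on_bs,
        adjacent_mean=adj_bs,
        enrichment=on_bs / adj_bs,
    )


def significance_tier(p: float) -> str:
    """Figure-legend star coding: *** p<0.001, ** p<0.01, * p<=0.05, NS."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "NS"


@dataclass
class GroupComparison:
    """One-way ANOVA omnibus p plus Tukey HSD pairwise table.  ``pairwise``
    has columns group1, group2, meandiff, p_adj, tier; ``vs_reference``
    restricts it to comparisons against the reference group."""

    p_omnibus: float
    pairwise: pd.DataFrame
    reference: str

    @property
    def vs_reference(self) -> pd.DataFrame:
        mask = (self.pairwise["group1"] == self.reference) | (
            self.pairwise["group2"] == self.reference
        )
        return self.pairwise[mask].reset_index(drop=True)


def compare_groups(scores, reference: str = "WT") -> GroupComparison:
    """Compare per-cell scores between constructs.

    ``scores`` is a mapping of group label to 1-D score array, or a tidy
    DataFrame with columns ``group`` and ``score``.  Requires at least two
    groups with n >= 2 each.  ANOVA and Tukey HSD are delegated to scipy
    and statsmodels.
    """
    if isinstance(scores, pd.DataFrame):
        groups = {g: np.asarray(sub["score"], dtype=float)
                  for g, sub in scores.groupby("group", sort=False)}
    else:
        groups = {g: np.asarray(v, dtype=float) for g, v in dict(scores).items()}
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValidationError(f"group {g!r} has n < 2")
    f_stat, p_omnibus = stats.f_oneway(*groups.values())
    if f_stat <= 0:  # rounding can push a zero between-group variance negative
        p_omnibus = 1.0
    labels = np.concatenate([[g] * len(v) for g, v in groups.items()])
    values = np.concatenate(list(groups.values()))
    tukey = pairwise_tukeyhsd(values, labels)
    table = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    ).rename(columns={"p-adj": "p_adj"})
    table = table[["group1", "group2", "meandiff", "p_adj"]].copy()
    table["p_adj"] = tukey.pvalues  # full precision, not table rounding
    table["tier"] = [significance_tier(p) for p in table["p_adj"]]
    return GroupComparison(
        p_omnibus=float(p_omnibus), pairwise=table, reference=reference
    )
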