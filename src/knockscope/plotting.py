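"""Figure-style plots: arrow plots, ternary diagrams, cumulative timing
histograms and per-cell enrichment dot plots.

All functions draw on a provided axes or create one, and optionally save to
a path; they return the axes for further styling.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .exceptions import ParameterError  # noqa: E402
from .relocalization import ArrowSummary, _by_role  # noqa: E402

__all__ = [
    "arrow_plot",
    "ternary_plot",
    "cumulative_timing_plot",
    "enrichment_dot_plot",
]


def _finish(fig, ax, path):
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax


def arrow_plot(records, summary: ArrowSummary | None = None, ax=None, path=None):
    """Per-cell pre→post arrows in the unit square: target spindle fraction
    on x, partner on y; the mean arrow is overlaid in orange."""
    roles = _by_role(records)
    if set(roles) != {"target", "partner"}:
        raise ParameterError("arrow plot needs target and partner records")
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(4, 4))
    for cell_id, t_rec in roles["target"].items():
        p_rec = roles["partner"].get(cell_id)
        if p_rec is None:
            continue
        ax.annotate(
            "",
            xy=(t_rec.f_post, p_rec.f_post),
            xytext=(t_rec.f_pre, p_rec.f_pre),
            arrowprops=dict(arrowstyle="->", color="0.6", lw=0.8),
        )
    if summary is not None:
        ax.annotate(
            "",
            xy=(summary.mean_f_post["target"], summary.mean_f_post["partner"]),
            xytext=(summary.mean_f_pre["target"], summary.mean_f_pre["partner"]),
            arrowprops=dict(arrowstyle="->", color="tab:orange", lw=2.0),
        )
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("target spindle fraction")
    ax.set_ylabel("partner spindle fraction")
    ax.set_aspect("equal")
    return _finish(fig, ax, path)


def _simplex_xy(p_spindle, p_mito, p_cyto):
    # corners: spindle (0,0), mito (1,0), cytoplasm (0.5, sqrt(3)/2)
    x = p_mito + 0.5 * p_cyto
    y = (np.sqrt(3) / 2.0) * p_cyto
    return x, y


def ternary_plot(compositions, ax=None, path=None, **scatter_kw):
    """Spindle/mito/cytoplasm compositions on a triangular diagram."""
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(4, 3.6))
    tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0, 0]])
    ax.plot(tri[:, 0], tri[:, 1], color="k", lw=1)
    xs, ys = [], []
    for comp in compositions:
        x, y = _simplex_xy(comp.p_spindle, comp.p_mito, comp.p_cyto)
        xs.append(x)
        ys.append(y)
    scatter_kw.setdefault("s", 12)
    ax.scatter(xs, ys, **scatter_kw)
    for label, (x, y, va, ha) in {
        "spindle": (0, -0.03, "top", "center"),
        "mito": (1, -0.03, "top", "center"),
        "cytoplasm": (0.5, np.sqrt(3) / 2 + 0.03, "bottom", "center"),
    }.items():
        ax.text(x, y, label, va=va, ha=ha, fontsize=8)
    ax.set_aspect("equal")
    ax.axis("off")
    return _finish(fig, ax, path)


def cumulative_timing_plot(summaries: dict, ax=None, path=None):
    """Cumulative NEB→anaphase histograms, one curve per labelled cohort."""
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(4.5, 3))
    for label, summary in summaries.items():
        ax.step(summary.grid, summary.cumulative_neb_ana, where="post", label=label)
    ax.set_xlabel("time after NEB (min)")
    ax.set_ylabel("cumulative fraction of cells")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    return _finish(fig, ax, path)


def enrichment_dot_plot(scores_by_group: dict, ax=None, path=None):
    """Per-cell scores as dots with mean ± s.d. overlay and a dashed line at
    zero (no enrichment)."""
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(4.5, 3))
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for i, (label, values) in enumerate(scores_by_group.items()):
        values = np.asarray(values, dtype=float)
        x = i + rng.uniform(-0.15, 0.15, len(values))
        ax.scatter(x, values, s=10, color="0.6", zorder=1)
        ax.errorbar(
            i, values.mean(), yerr=values.std(ddof=1), fmt="o",
            color="tab:blue", capsize=3, zorder=2, markersize=7,
        )
    ax.axhline(0.0, ls="--", color="k", lw=0.8)
    ax.set_xticks(range(len(scores_by_group)), list(scores_by_group), rotation=45)
    ax.set_ylabel("spindle localization (log2)")
    return _finish(fig, ax, path)
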