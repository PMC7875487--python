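"""Background-subtracted, bleach-corrected compartment measurements.

The measurement chain for one cell in a knocksideways movie is:

1. register the post-rapamycin frame to the pre-rapamycin frame (target
   channel, applied to all channels);
2. take the mean of three square ROIs per compartment (spindle, cytoplasm,
   mitochondria), one background ROI outside the cell and one whole-cell
   measurement, per channel and frame;
3. subtract the background mean from every compartment and whole-cell value
   (negative results are floored at zero — intensities are physical);
4. divide each compartment value by the bleach factor
   ``wholecell_t / wholecell_0`` of its own channel, i.e. normalize to the
   pre-rapamycin frame.

Order matters: background is subtracted before bleach correction, and the
whole-cell reference itself is background-subtracted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ParameterError
from .imaging_io import ChannelFrame, RoiSet, register_translation
from .synthetic_data import Timelapse

__all__ = [
    "CompartmentMeasurement",
    "roi_mean",
    "background_subtract",
    "bleach_correct",
    "measure_cell",
    "measurements_to_frame",
]


@dataclass
class CompartmentMeasurement:
    """Mean compartment intensities of one cell/channel/timepoint (a.u.),
    background-subtracted and bleach-corrected.  ``mito`` is NaN when no
    mitochondrial ROIs were measured (fixed-cell analysis)."""

    cell_id: str
    channel: str
    time: float | str
    spindle: float
    cytoplasm: float
    mito: float
    wholecell: float  # background-subtracted whole-cell mean, uncorrected
    background: float  # raw background mean

    def __post_init__(self):
        if self.wholecell is not None and self.wholecell <= 0:
            raise DegenerateInputError(
                f"non-positive whole-cell fluorescence for {self.cell_id}"
            )


def roi_mean(frame, box) -> float:
    """Arithmetic mean over a half-open ``(r0, c0, h, w)`` box."""
    pixels = frame.pixels if isinstance(frame, ChannelFrame) else np.asarray(frame)
    r0, c0, h, w = box
    if h <= 0 or w <= 0:
        raise ParameterError(f"empty ROI box {box}")
    if r0 < 0 or c0 < 0 or r0 + h > pixels.shape[0] or c0 + w > pixels.shape[1]:
        raise ParameterError(f"ROI box {box} outside image bounds {pixels.shape}")
    return float(pixels[r0 : r0 + h, c0 : c0 + w].mean())


def background_subtract(value: float, background: float) -> float:
    """``value - background``, floored at zero.

    A negative difference can only arise from noise; it is clamped with a
    warning because compartment intensities are physical quantities.
    """
    if not (math.isfinite(value) and math.isfinite(background)):
        raise ParameterError("value and background must be finite")
    diff = value - background
    if diff < 0:
        warnings.warn(
            f"background ({background:g}) exceeds measured value ({value:g}); "
            "flooring at 0",
            stacklevel=2,
        )
        return 0.0
    return diff


def bleach_correct(value_t: float, wholecell_t: float, wholecell_0: float) -> float:
    """Correct a compartment value for photobleaching.

    Divides by the whole-cell decay factor ``wholecell_t / wholecell_0``
    (both background-subtracted, same channel), normalizing every frame to
    the first, pre-rapamycin frame.
    """
    if wholecell_0 <= 0 or wholecell_t <= 0:
        raise DegenerateInputError(
            "whole-cell fluorescence must be > 0 for bleach correction"
        )
    return value_t / (wholecell_t / wholecell_0)


def _foreground(pixels: np.ndarray) -> np.ndarray:
    """Cell footprint as float, for registration.

    Frames are roughly trimodal (extracellular background, cytoplasm,
    bright spindle or mitochondria); the lower of the two 3-class Otsu
    thresholds separates background from cell.  Falls back to plain Otsu
    for images without three separable modes.
    """
    from skimage.filters import threshold_multiotsu, threshold_otsu

    try:
        thr = threshold_multiotsu(pixels, classes=3)[0]
    except ValueError:
        thr = threshold_otsu(pixels)
    return (pixels > thr).astype(float)


def _measure_frame(pixels: np.ndarray, rois: RoiSet) -> dict:
    """Raw ROI means for one channel frame: compartment mean-of-means,
    whole-cell mean and background mean, with background subtraction."""
    background = roi_mean(pixels, rois.background)
    values = {}
    for comp, boxes in (
        ("spindle", rois.spindle),
        ("cytoplasm", rois.cytoplasm),
        ("mito", rois.mito),
    ):
        if not boxes:
            values[comp] = float("nan")
            continue
        mean_of_means = float(np.mean([roi_mean(pixels, b) for b in boxes]))
        values[comp] = background_subtract(mean_of_means, background)
    wholecell = background_subtract(roi_mean(pixels, rois.wholecell), background)
    return {"background": background, "wholecell": wholecell, **values}


def measure_cell(
    movie: Timelapse,
    rois: RoiSet,
    pre_index: int = 0,
    post_index: int = -1,
    *,
    cell_id: str = "cell",
    register: bool = True,
    radius: int = 10,
) -> dict[str, tuple[CompartmentMeasurement, CompartmentMeasurement]]:
    """Measure one cell pre and post rapamycin.

    Registration is computed on the first (target) channel and the resulting
    offset is applied to the ROI coordinates for the post frame in every
    channel.  Because rerouting redistributes intensity between compartments
    (the spindle dims while mitochondria brighten), the correlation is
    evaluated on the thresholded cell footprint rather than raw intensities:
    the footprint does not change when signal moves within the cell.
    Returns ``{channel: (pre, post)}`` with post values bleach-corrected
    against the pre frame.
    """
    n = movie.n_frames
    pre_index, post_index = pre_index % n, post_index % n
    if pre_index == post_index:
        raise ParameterError("pre and post indices must differ")

    if register:
        pre_fg = _foreground(movie.data[pre_index, 0])
        post_fg = _foreground(movie.data[post_index, 0])
        dr, dc = register_translation(pre_fg, post_fg, radius=radius)
    else:
        dr, dc = 0, 0
    post_rois = rois.shifted(dr, dc)
    shape = movie.data.shape[2:]
    rois.validate(shape, n_per_compartment=len(rois.spindle))
    post_rois.validate(shape, n_per_compartment=len(rois.spindle))

    out = {}
    for ci, channel in enumerate(movie.channel_names):
        raw_pre = _measure_frame(movie.data[pre_index, ci], rois)
        raw_post = _measure_frame(movie.data[post_index, ci], post_rois)
        pre = CompartmentMeasurement(
            cell_id=cell_id,
            channel=channel,
            time=float(movie.times[pre_index]),
            spindle=raw_pre["spindle"],
            cytoplasm=raw_pre["cytoplasm"],
            mito=raw_pre["mito"],
            wholecell=raw_pre["wholecell"],
            background=raw_pre["background"],
        )
        post = CompartmentMeasurement(
            cell_id=cell_id,
            channel=channel,
            time=float(movie.times[post_index]),
            spindle=bleach_correct(
                raw_post["spindle"], raw_post["wholecell"], raw_pre["wholecell"]
            ),
            cytoplasm=bleach_correct(
                raw_post["cytoplasm"], raw_post["wholecell"], raw_pre["wholecell"]
            ),
            mito=bleach_correct(
                raw_post["mito"], raw_post["wholecell"], raw_pre["wholecell"]
            )
            if not math.isnan(raw_post["mito"])
            else float("nan"),
            wholecell=raw_post["wholecell"],
            background=raw_post["background"],
        )
        out[channel] = (pre, post)
    return out


def measurements_to_frame(measured: dict, phases=("pre", "post")) -> pd.DataFrame:
    """Tidy long-format table: cell_id, channel, phase, compartment, value."""
    rows = []
    for channel, pair in measured.items():
        for phase, m in zip(phases, pair):
            d = asdict(m)
            for comp in ("spindle", "cytoplasm", "mito"):
                rows.append(
                    {
                        "cell_id": d["cell_id"],
                        "channel": channel,
                        "phase": phase,
                        "compartment": comp,
                        "value": d[comp],
                    }
                )
    return pd.DataFrame(rows)
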