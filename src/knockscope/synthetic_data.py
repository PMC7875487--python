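"""Ground-truthed synthetic knocksideways data.

This module fabricates the three kinds of raw data the analysis pipeline
consumes, each with full ground truth attached:

* **Knocksideways movies** — two-channel (GFP-tagged target, red-tagged
  partner) time-lapses of a synthetic metaphase cell with a central spindle,
  a peripheral mitochondrial network and diffuse cytoplasm.  Adding rapamycin
  at t=0 transfers spindle signal to the mitochondria with single-exponential
  kinetics; the partner channel co-reroutes with a tunable coupling
  coefficient.  Photobleaching is multiplicative and noise is added last, so
  every intermediate quantity has a closed form.
* **Line-scan scenes** — an interphase-like tubulin channel with straight
  filaments plus a probe channel with a known on-filament enrichment ratio.
* **Mitotic-timing cohorts** — per-cell NEB/metaphase/anaphase event times
  drawn from log-normal interval distributions, with metaphase arrest and
  movie-end censoring.

Every generator takes an explicit integer seed and uses a single local
``numpy.random.Generator``; identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as _skdraw

from .exceptions import ParameterError

__all__ = [
    "CHANNELS",
    "COMPARTMENTS",
    "Scene",
    "Timelapse",
    "TimingCohortSpec",
    "LinescanScene",
    "transferred_fraction",
    "generate_scene",
    "render_timelapse",
    "generate_timing_cohort",
    "generate_linescan_scene",
    "SCENE_PRESETS",
]

CHANNELS = ("target", "partner")
COMPARTMENTS = ("spindle", "cytoplasm", "mito")

#: Geometry presets.  "movie" mimics widefield live imaging of a metaphase
#: HeLa cell; "fixed" mimics confocal fixed-cell imaging at the pixel size
#: implied by a 31x31 px = 1.4 um^2 region of interest (0.0382 um/px).
SCENE_PRESETS = {
    "movie": dict(image_shape=(256, 256), pixel_size=0.1, cell_radius=10.0),
    "fixed": dict(image_shape=(512, 512), pixel_size=0.0382, cell_radius=8.0),
}

_DEFAULT_AMP = {
    "target": {"spindle": 150.0, "cytoplasm": 30.0, "mito": 10.0},
    "partner": {"spindle": 100.0, "cytoplasm": 40.0, "mito": 20.0},
}
_DEFAULT_BACKGROUND = {"target": 5.0, "partner": 8.0}


def transferred_fraction(t, phi_max: float, tau: float):
    """Fraction of spindle signal transferred to mitochondria by time ``t``.

    Single-exponential approach ``phi_max * (1 - exp(-t / tau))``: zero at
    t=0 (rapamycin addition), asymptotically ``phi_max``.  With the default
    tau of 2 min transfer is >99% complete by 10 min, matching the observed
    timecourse of knocksideways rerouting.

    Parameters
    ----------
    t : float or array
        Minutes since rapamycin addition; must be >= 0.
    phi_max : float
        Asymptotic transferred fraction, in [0, 1].
    tau : float
        Transfer time constant in minutes; must be > 0.
    """
    if tau <= 0:
        raise ParameterError(f"tau must be > 0, got {tau}")
    if not 0.0 <= phi_max <= 1.0:
        raise ParameterError(f"phi_max must be in [0, 1], got {phi_max}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be >= 0 (rapamycin added at t=0)")
    phi = phi_max * (1.0 - np.exp(-t / tau))
    return float(phi) if phi.ndim == 0 else phi


@dataclass
class Scene:
    """Ground-truth description of one synthetic metaphase cell.

    Masks are boolean rasters with ``mito`` and ``spindle`` inside ``cell``
    and disjoint from each other; cytoplasm is ``cell`` minus both.
    Amplitudes are mean intensities (a.u.) per channel per compartment at
    t=0, before transfer, bleaching and noise.
    """

    image_shape: tuple[int, int]
    pixel_size: float  # um / pixel
    cell_mask: np.ndarray
    spindle_mask: np.ndarray
    mito_mask: np.ndarray
    amp: dict[str, dict[str, float]]
    background: dict[str, float]
    phi_max: float = 0.95
    tau: float = 2.0  # min
    coupling: float = 1.0
    bleach_rate: dict[str, float] = field(
        default_factory=lambda: {"target": 0.02, "partner": 0.02}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"target": 3.0, "partner": 3.0}
    )
    noise_model: str = "gaussian"  # or "poisson" (variance proportional to mean)
    puncta: np.ndarray | None = None  # (n, 2) decoy coated-pit centres, target channel
    puncta_amp: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for m in (self.cell_mask, self.spindle_mask, self.mito_mask):
            if m.shape != tuple(self.image_shape):
                raise ParameterError("mask shape does not match image_shape")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        if np.any(self.spindle_mask & ~self.cell_mask) or np.any(
            self.mito_mask & ~self.cell_mask
        ):
            raise ParameterError("spindle and mito masks must lie inside the cell")
        if np.any(self.spindle_mask & self.mito_mask):
            raise ParameterError("spindle and mito masks must be disjoint")
        if not 0.0 <= self.phi_max <= 1.0:
            raise ParameterError("phi_max must be in [0, 1]")
        if not 0.0 <= self.coupling <= 1.0:
            raise ParameterError("coupling must be in [0, 1]")
        if self.tau <= 0:
            raise ParameterError("tau must be > 0")
        for ch in CHANNELS:
            if self.background[ch] < 0 or not math.isfinite(self.background[ch]):
                raise ParameterError("background must be finite and >= 0")
            if self.bleach_rate[ch] < 0:
                raise ParameterError("bleach_rate must be >= 0")
            if self.noise_sd[ch] < 0:
                raise ParameterError("noise_sd must be >= 0")
            for comp in COMPARTMENTS:
                a = self.amp[ch][comp]
                if a < 0 or not math.isfinite(a):
                    raise ParameterError("amplitudes must be finite and >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ParameterError(f"unknown noise model {self.noise_model!r}")

    @property
    def cytoplasm_mask(self) -> np.ndarray:
        return self.cell_mask & ~self.spindle_mask & ~self.mito_mask

    def masks(self) -> dict[str, np.ndarray]:
        return {
            "cell": self.cell_mask,
            "spindle": self.spindle_mask,
            "cytoplasm": self.cytoplasm_mask,
            "mito": self.mito_mask,
        }

    def area(self, compartment: str) -> int:
        """Compartment area in pixels."""
        return int(self.masks()[compartment].sum())

    def amplitude(self, channel: str, compartment: str, t: float) -> float:
        """Noiseless, unbleached mean intensity of a compartment at time t.

        Transfer conserves integrated fluorescence: the spindle loses
        ``phi(t)`` of its initial amplitude and the mitochondria gain the
        same integrated amount spread over their area.  The partner channel
        transfers ``coupling * phi(t)``.
        """
        phi = transferred_fraction(t, self.phi_max, self.tau)
        if channel == "partner":
            phi *= self.coupling
        sp0 = self.amp[channel]["spindle"]
        if compartment == "spindle":
            return sp0 * (1.0 - phi)
        if compartment == "mito":
            gain = sp0 * phi * self.area("spindle") / self.area("mito")
            return self.amp[channel]["mito"] + gain
        if compartment == "cytoplasm":
            return self.amp[channel]["cytoplasm"]
        raise ParameterError(f"unknown compartment {compartment!r}")

    def true_spindle_fraction(self, channel: str, t: float) -> float:
        """Ground-truth spindle fraction at time t.

        Defined on mean compartment intensities — spindle mean over
        (spindle mean + mito mean) — because that is what ROI measurement
        estimates; it is the noiseless limit of the measured arrow-plot
        statistic.
        """
        s = self.amplitude(channel, "spindle", t)
        m = self.amplitude(channel, "mito", t)
        return s / (s + m)


@dataclass
class Timelapse:
    """Multi-channel time-lapse: ``data`` has shape (T, C, rows, cols)."""

    data: np.ndarray
    times: np.ndarray  # minutes since first frame; times[0] == 0
    channel_names: tuple[str, ...]
    pixel_size: float
    ground_truth: dict | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 4:
            raise ParameterError("data must be 4-D (T, C, rows, cols)")
        if self.data.shape[0] != len(self.times):
            raise ParameterError("number of frames must match number of times")
        if self.data.shape[1] != len(self.channel_names):
            raise ParameterError("channel axis must match channel_names")
        if len(self.times) == 0:
            raise ParameterError("empty time-lapse")
        if self.times[0] != 0:
            raise ParameterError("times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame(self, time_index: int, channel: str) -> np.ndarray:
        return self.data[time_index, self.channel_names.index(channel)]


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse_mask(shape, center, semi_r, semi_c):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semi_r) ** 2 + ((cc - center[1]) / semi_c) ** 2 <= 1.0


def _mito_network(
    rng, shape, cell_mask, spindle_mask, n_segments, width_px, pixel_size
):
    """Random curvilinear ribbons in the cytoplasm, clear of the spindle.

    Paths are persistent random walks restricted to a safe region (cell
    eroded, spindle dilated, by the ribbon half-width plus margin), then
    dilated with a square footprint so that a width x width box fits fully
    inside the ribbon at every path pixel — this is what lets small
    mitochondrial ROIs be placed strictly inside the mask.
    """
    margin = width_px + 2
    dist_in = ndimage.distance_transform_edt(cell_mask)
    dist_sp = ndimage.distance_transform_edt(~spindle_mask)
    allowed = (dist_in > margin) & (dist_sp > margin)
    allowed_idx = np.argwhere(allowed)
    if len(allowed_idx) == 0:
        raise ParameterError("no room for mitochondria between spindle and cell edge")
    path = np.zeros(shape, dtype=bool)
    seg_len_px = (4.0 / pixel_size, 10.0 / pixel_size)  # 4-10 um segments
    for _ in range(n_segments):
        r, c = allowed_idx[rng.integers(len(allowed_idx))].astype(float)
        theta = rng.uniform(0, 2 * np.pi)
        n_steps = int(rng.uniform(*seg_len_px))
        for _ in range(n_steps):
            theta += rng.normal(0.0, 0.15)
            r2, c2 = r + np.sin(theta), c + np.cos(theta)
            ir, ic = int(round(r2)), int(round(c2))
            if not (0 <= ir < shape[0] and 0 <= ic < shape[1]) or not allowed[ir, ic]:
                break
            r, c = r2, c2
            path[ir, ic] = True
    if not path.any():
        raise ParameterError("mitochondrial network generation produced no pixels")
    footprint = np.ones((width_px, width_px), dtype=bool)
    return ndimage.binary_dilation(path, structure=footprint)


def generate_scene(
    *,
    preset: str = "movie",
    image_shape: tuple[int, int] | None = None,
    pixel_size: float | None = None,
    cell_radius: float | None = None,  # um
    spindle_semiaxes: tuple[float, float] = (2.2, 5.5),  # um (rows, cols)
    n_mito: tuple[int, int] | int = (8, 15),
    mito_width: int = 5,  # px
    amp: dict | None = None,
    background: dict | None = None,
    phi_max: float = 0.95,
    tau: float = 2.0,
    coupling: float = 1.0,
    bleach_rate: float | dict = 0.02,
    noise_sd: float | dict = 3.0,
    noise_model: str = "gaussian",
    n_puncta: int = 0,
    puncta_amp: float = 80.0,
    seed: int = 0,
) -> Scene:
    """Build a reproducible synthetic metaphase cell.

    Geometry is specified in micrometres and rasterized at ``pixel_size``:
    a circular cell, an elliptical spindle at the cell centre and a
    mitochondrial network of ``n_mito`` curvilinear ribbons (count drawn
    uniformly when a range is given).  Optional coated-pit-like puncta act
    as decoy structures in the target channel and are off by default.
    """
    defaults = SCENE_PRESETS.get(preset)
    if defaults is None:
        raise ParameterError(f"unknown preset {preset!r}")
    image_shape = tuple(image_shape or defaults["image_shape"])
    pixel_size = pixel_size or defaults["pixel_size"]
    cell_radius = cell_radius or defaults["cell_radius"]
    if len(image_shape) != 2 or min(image_shape) < 64:
        raise ParameterError("image_shape must be at least 64x64")
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be > 0")
    if cell_radius <= 0:
        raise ParameterError("cell_radius must be > 0")
    if min(spindle_semiaxes) <= 0:
        raise ParameterError("spindle semi-axes must be > 0 (zero-area spindle)")
    if mito_width < 1:
        raise ParameterError("mito_width must be >= 1 px")
    if n_puncta < 0:
        raise ParameterError("n_puncta must be >= 0")

    rng = np.random.default_rng(seed)
    center = (image_shape[0] / 2.0, image_shape[1] / 2.0)
    cell_mask = _disk_mask(image_shape, center, cell_radius / pixel_size)
    if cell_mask.all():
        raise ParameterError("cell does not fit in the image (no extracellular room)")
    spindle_mask = _ellipse_mask(
        image_shape,
        center,
        spindle_semiaxes[0] / pixel_size,
        spindle_semiaxes[1] / pixel_size,
    )
    if not spindle_mask.any():
        raise ParameterError("spindle rasterized to zero area")
    spindle_mask &= cell_mask

    if isinstance(n_mito, int):
        n_segments = n_mito
    else:
        n_segments = int(rng.integers(n_mito[0], n_mito[1] + 1))
    if n_segments <= 0:
        raise ParameterError("n_mito must be positive")
    mito_mask = _mito_network(
        rng, image_shape, cell_mask, spindle_mask, n_segments, mito_width, pixel_size
    )

    if isinstance(bleach_rate, (int, float)):
        bleach_rate = {ch: float(bleach_rate) for ch in CHANNELS}
    if isinstance(noise_sd, (int, float)):
        noise_sd = {ch: float(noise_sd) for ch in CHANNELS}
    amp = {ch: dict((amp or _DEFAULT_AMP)[ch]) for ch in CHANNELS}
    background = dict(background or _DEFAULT_BACKGROUND)

    puncta = None
    if n_puncta:
        cyto_idx = np.argwhere(cell_mask & ~spindle_mask & ~mito_mask)
        puncta = cyto_idx[rng.integers(len(cyto_idx), size=n_puncta)]

    return Scene(
        image_shape=image_shape,
        pixel_size=pixel_size,
        cell_mask=cell_mask,
        spindle_mask=spindle_mask,
        mito_mask=mito_mask,
        amp=amp,
        background=background,
        phi_max=phi_max,
        tau=tau,
        coupling=coupling,
        bleach_rate=dict(bleach_rate),
        noise_sd=dict(noise_sd),
        noise_model=noise_model,
        puncta=puncta,
        puncta_amp=float(puncta_amp) if n_puncta else 0.0,
        seed=seed,
    )


def _puncta_image(scene: Scene) -> np.ndarray:
    img = np.zeros(scene.image_shape)
    if scene.puncta is None or scene.puncta_amp == 0:
        return img
    for r, c in scene.puncta:
        rr, cc = _skdraw.disk((r, c), 2, shape=scene.image_shape)
        img[rr, cc] += scene.puncta_amp
    return img


def render_timelapse(scene: Scene, times) -> Timelapse:
    """Render a movie from a scene; rapamycin is added at t=0.

    Per channel and frame the noiseless image is ``background`` everywhere
    plus the per-compartment amplitude from :meth:`Scene.amplitude`; the
    whole frame is then multiplied by ``exp(-bleach_rate * t)`` and noise is
    added last.  Integrated fluorescence is conserved across frames before
    bleaching and noise.

    Returns a :class:`Timelapse` whose ``ground_truth`` dict records, per
    channel and compartment, the noiseless unbleached mean amplitudes, the
    bleach factors and the transferred fraction at every frame.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ParameterError("times must be non-empty")
    if times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ParameterError("times must be strictly increasing from 0")
    rng = np.random.default_rng(np.random.SeedSequence([scene.seed, 0x5EED]))
    masks = scene.masks()
    puncta_img = _puncta_image(scene)
    T = len(times)
    data = np.empty((T, len(CHANNELS), *scene.image_shape))
    gt: dict = {
        "times": times.tolist(),
        "phi": [transferred_fraction(t, scene.phi_max, scene.tau) for t in times],
        "coupling": scene.coupling,
        "channels": {},
    }
    for ci, ch in enumerate(CHANNELS):
        amps = {
            comp: [scene.amplitude(ch, comp, t) for t in times]
            for comp in COMPARTMENTS
        }
        bleach = np.exp(-scene.bleach_rate[ch] * times)
        gt["channels"][ch] = {
            "amplitude": amps,
            "bleach_factor": bleach.tolist(),
            "background": scene.background[ch],
            "area": {comp: scene.area(comp) for comp in COMPARTMENTS},
        }
        for ti, t in enumerate(times):
            img = np.full(scene.image_shape, scene.background[ch])
            for comp in COMPARTMENTS:
                img[masks[comp]] += amps[comp][ti]
            if ch == "target":
                img += puncta_img
            img *= bleach[ti]
            sd = scene.noise_sd[ch]
            if sd > 0:
                if scene.noise_model == "gaussian":
                    img = img + rng.normal(0.0, sd, scene.image_shape)
                else:  # shot-like: variance proportional to the mean, sd is gain
                    img = img + rng.normal(0.0, 1.0, scene.image_shape) * np.sqrt(
                        sd * np.clip(img, 0, None)
                    )
            data[ti, ci] = img
    return Timelapse(
        data=data,
        times=times,
        channel_names=CHANNELS,
        pixel_size=scene.pixel_size,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# Mitotic timing cohorts
# ---------------------------------------------------------------------------

@dataclass
class TimingCohortSpec:
    """Parameters of a synthetic mitotic-progression cohort.

    Interval distributions are log-normal, parameterized by their median (in
    minutes) and log-scale shape sigma.  Defaults reproduce untreated HeLa
    behaviour: NEB→metaphase median 13.2 min, metaphase→anaphase median 20.8
    min, no arrest, 12 h movies.  ``delay_factor`` multiplies the
    metaphase→anaphase interval (a treatment effect); ``arrest_prob`` is the
    probability a cell never exits metaphase.
    """

    n_cells: int = 100
    neb_to_meta: tuple[float, float] = (13.2, 0.35)  # (median min, shape)
    meta_to_ana: tuple[float, float] = (20.8, 0.35)
    delay_factor: float = 1.0
    arrest_prob: float = 0.0
    movie_length: float = 720.0  # min (every 3 min for 12 h)
    seed: int = 0

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ParameterError("n_cells must be positive")
        if self.neb_to_meta[0] <= 0 or self.meta_to_ana[0] <= 0:
            raise ParameterError("interval medians must be > 0")
        if not 0.0 <= self.arrest_prob <= 1.0:
            raise ParameterError("arrest_prob must be in [0, 1]")
        if self.delay_factor < 0:
            raise ParameterError("delay_factor must be >= 0")
        if self.movie_length <= 0:
            raise ParameterError("movie_length must be > 0")


def generate_timing_cohort(spec: TimingCohortSpec) -> pd.DataFrame:
    """Draw one cohort of per-cell mitotic event times.

    NEB is at 0 for every cell.  Events later than ``movie_length`` — and
    anaphase in arrested cells — are censored: the flag is set and the
    recorded time is the movie end.  Columns match the on-disk CSV layout:
    cell_id, neb_min, metaphase_min, anaphase_min, censored_metaphase,
    censored_anaphase.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    med_m, s_m = spec.neb_to_meta
    med_a, s_a = spec.meta_to_ana
    meta = med_m * np.exp(s_m * rng.standard_normal(n))
    ana_interval = spec.delay_factor * med_a * np.exp(s_a * rng.standard_normal(n))
    arrested = rng.random(n) < spec.arrest_prob
    ana = meta + ana_interval
    cens_meta = meta > spec.movie_length
    cens_ana = arrested | cens_meta | (ana > spec.movie_length)
    return pd.DataFrame(
        {
            "cell_id": [f"cell{i:04d}" for i in range(n)],
            "neb_min": 0.0,
            "metaphase_min": np.where(cens_meta, spec.movie_length, meta),
            "anaphase_min": np.where(cens_ana, spec.movie_length, ana),
            "censored_metaphase": cens_meta,
            "censored_anaphase": cens_ana,
        }
    )


# ---------------------------------------------------------------------------
# Line-scan scenes
# ---------------------------------------------------------------------------

@dataclass
class LinescanScene:
    """A tubulin/probe image pair with ground-truth line-scan coordinates.

    ``on_lines`` run along filament centres; ``adjacent_lines`` are parallel
    controls offset into filament-free background.  ``r_true`` is the
    ground-truth on-filament enrichment of the probe channel after
    background subtraction.
    """

    tubulin: np.ndarray
    probe: np.ndarray
    pixel_size: float
    on_lines: list[tuple[tuple[int, int], tuple[int, int]]]
    adjacent_lines: list[tuple[tuple[int, int], tuple[int, int]]]
    filament_mask: np.ndarray
    r_true: float
    background: dict[str, float]


def _segment_pixels(p0, p1):
    rr, cc = _skdraw.line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
    return rr, cc


def generate_linescan_scene(
    *,
    image_shape: tuple[int, int] = (256, 256),
    pixel_size: float = 0.1,  # um/px
    n_filaments: int = 6,
    filament_width: int = 3,  # px
    filament_length: float = 4.0,  # um
    line_length: float = 2.0,  # um, measured sub-segment
    adjacent_offset: int = 6,  # px, perpendicular offset of control lines
    tubulin_amp: float = 120.0,
    probe_base: float = 50.0,
    r_true: float = 1.5,
    background: dict | None = None,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> LinescanScene:
    """Render straight microtubule-like filaments plus a probe channel.

    The probe is ``background + probe_base`` off filaments and
    ``background + r_true * probe_base`` on them, so the background-
    subtracted on/adjacent line-scan ratio is exactly ``r_true`` in the
    noiseless limit.  Three filaments carry a measured line (a central
    sub-segment of ``line_length``) and a parallel adjacent control line
    that is kept clear of every filament.
    """
    if n_filaments < 3:
        raise ParameterError("need at least 3 filament segments")
    if r_true <= 0 or probe_base <= 0:
        raise ParameterError("r_true and probe_base must be > 0")
    if not 1.0 <= line_length <= 3.0:
        raise ParameterError("measured line length must be 1-3 um")
    background = dict(background or {"tubulin": 5.0, "probe": 5.0})
    rng = np.random.default_rng(seed)
    shape = tuple(image_shape)
    half_len = filament_length / 2.0 / pixel_size
    margin = int(half_len + adjacent_offset + filament_width + 2)
    if 2 * margin >= min(shape):
        raise ParameterError("filaments and control lines do not fit in the frame")

    for _attempt in range(200):
        centers, angles = [], []
        min_sep = 2 * (adjacent_offset + filament_width)
        tries = 0
        while len(centers) < n_filaments and tries < 5000:
            tries += 1
            r = rng.uniform(margin, shape[0] - margin)
            c = rng.uniform(margin, shape[1] - margin)
            if all((r - r2) ** 2 + (c - c2) ** 2 > min_sep**2 + 4 * half_len**2
                   for r2, c2 in centers):
                centers.append((r, c))
                angles.append(rng.uniform(0, np.pi))
        if len(centers) < n_filaments:
            continue

        fil_mask = np.zeros(shape, dtype=bool)
        ends = []
        for (r, c), th in zip(centers, angles):
            dr, dc = np.sin(th), np.cos(th)
            p0 = (int(round(r - dr * half_len)), int(round(c - dc * half_len)))
            p1 = (int(round(r + dr * half_len)), int(round(c + dc * half_len)))
            rr, cc = _segment_pixels(p0, p1)
            fil_mask[rr, cc] = True
            ends.append((p0, p1, (r, c), (dr, dc)))
        fil_mask = ndimage.binary_dilation(
            fil_mask, structure=np.ones((filament_width, filament_width), dtype=bool)
        )
        clear = ~ndimage.binary_dilation(fil_mask, iterations=2)

        half_meas = line_length / 2.0 / pixel_size
        on_lines, adj_lines = [], []
        ok = True
        for p0, p1, (r, c), (dr, dc) in ends[:3]:
            # measured line endpoints taken from the rasterized centre line so
            # every re-rasterized pixel stays on the filament
            rr, cc = _segment_pixels(p0, p1)
            mid = len(rr) // 2
            k = max(1, int(round(half_meas * max(abs(dr), abs(dc)))))
            i0, i1 = max(0, mid - k), min(len(rr) - 1, mid + k)
            q0 = (int(rr[i0]), int(cc[i0]))
            q1 = (int(rr[i1]), int(cc[i1]))
            # perpendicular offset for the control line
            pr, pc = -dc, dr
            a0 = (int(round(q0[0] + pr * adjacent_offset)),
                  int(round(q0[1] + pc * adjacent_offset)))
            a1 = (int(round(q1[0] + pr * adjacent_offset)),
                  int(round(q1[1] + pc * adjacent_offset)))
            coords = _segment_pixels(*[a0, a1])
            if not (
                0 <= min(a0[0], a1[0])
                and max(a0[0], a1[0]) < shape[0]
                and 0 <= min(a0[1], a1[1])
                and max(a0[1], a1[1]) < shape[1]
                and clear[coords].all()
            ):
                ok = False
                break
            on_lines.append((q0, q1))
            adj_lines.append((a0, a1))
        if ok:
            break
    else:
        raise ParameterError("could not place filaments with clear control lines")

    tubulin = np.full(shape, background["tubulin"], dtype=float)
    tubulin[fil_mask] += tubulin_amp
    probe = np.full(shape, background["probe"] + probe_base, dtype=float)
    probe[fil_mask] += (r_true - 1.0) * probe_base
    if noise_sd > 0:
        tubulin = tubulin + rng.normal(0.0, noise_sd, shape)
        probe = probe + rng.normal(0.0, noise_sd, shape)
    return LinescanScene(
        tubulin=tubulin,
        probe=probe,
        pixel_size=pixel_size,
        on_lines=on_lines,
        adjacent_lines=adj_lines,
        filament_mask=fil_mask,
        r_true=r_true,
        background=background,
    )
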