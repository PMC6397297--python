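"""Synthetic fluorescence-microscopy data with known ground truth.

Emulates the statistical structure of a heterogeneously transduced cell
population imaged by epifluorescence: cell-to-cell expression of a
GFP-tagged probe follows a lognormal law spanning several decades, and
each morphometric parameter responds to expression through a piecewise
(flat / log-linear / flat) transfer function — a no-effect regime below a
lower breakpoint, a dose-response regime between the breakpoints, and a
saturation plateau above the upper one.

Per cell, a three-channel field of view is rendered: a uniform GFP signal
whose in-mask total equals the drawn expression (proportionality constant
1 count per expression unit), stress fibres in the stain channel as
anti-aliased capsules with Gaussian cross-section, and an elliptical DAPI
nucleus.  Optional noise adds a planar background gradient, Poisson shot
noise and Gaussian read noise.  Every generator is a pure function of its
configuration and seed.

The module also generates persistent-random-walk migration tracks and
exponential F-actin decay series for the time-lapse analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import i0, i1
from skimage.draw import polygon as draw_polygon

from .morphometrics import CellImageSet

# Rendering constants (camera counts)
FIBRE_PEAK = 300.0       # peak brightness of one fibre capsule
CYTOPLASM_LEVEL = 30.0   # diffuse non-fibrous stain inside the cell
DAPI_LEVEL = 1200.0      # nucleus fill intensity
FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = FWHM_SIGMA * sigma


# ---------------------------------------------------------------------------
# Transfer functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransferFunction:
    """Piecewise flat / log-linear / flat map from expression to a parameter.

    ``t1`` and ``t2`` are breakpoints on the log10-expression axis
    (t1 < t2).  Below t1 the value is ``baseline``; above t2 it is
    ``plateau``; in between it interpolates log-linearly (linear in
    log-value vs log-expression), so the curve is continuous at both
    breakpoints.  ``noise_cv`` is the coefficient of variation of the
    multiplicative lognormal cell-to-cell scatter applied on sampling.
    """

    baseline: float
    t1: float
    t2: float
    plateau: float
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if not self.t1 < self.t2:
            raise ValueError("require t1 < t2")
        if self.baseline <= 0 or self.plateau <= 0:
            raise ValueError("baseline and plateau must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def value(self, expression: float) -> float:
        """Deterministic transfer value at a positive expression level."""
        if np.any(np.asarray(expression) <= 0):
            raise ValueError("expression must be positive")
        x = np.log10(expression)
        f = np.clip((x - self.t1) / (self.t2 - self.t1), 0.0, 1.0)
        logv = (1 - f) * math.log10(self.baseline) + f * math.log10(self.plateau)
        return 10.0 ** logv

    @property
    def is_flat(self) -> bool:
        return self.baseline == self.plateau


def sample_parameter(tf: TransferFunction, expression: float,
                     rng: np.random.Generator) -> float:
    """Draw one parameter value: tf(expression) x lognormal scatter.

    The scatter is median-one lognormal with the configured CV, so the
    geometric mean of many draws recovers the deterministic transfer value.
    With ``noise_cv = 0`` the deterministic value is returned.
    """
    base = tf.value(expression)
    if tf.noise_cv == 0:
        return float(base)
    sigma = math.sqrt(math.log(1.0 + tf.noise_cv ** 2))
    return float(base * math.exp(rng.normal(0.0, sigma)))


def default_transfer_functions(t1: float, t2: float
                               ) -> Dict[str, TransferFunction]:
    """Transfer-function set emulating the reported dose-response trends.

    Area grows ~10-fold, fibre count and thickness grow (jointly driving a
    large fibre-amount increase), orientation coherence rises, aspect
    ratio falls and the perimeter gets less stellate with expression.
    """
    return {
        "area": TransferFunction(800.0, t1, t2, 8000.0, noise_cv=0.15),
        "fibre_count": TransferFunction(4.0, t1, t2, 24.0, noise_cv=0.20),
        "fibre_thickness": TransferFunction(1.5, t1, t2, 4.5, noise_cv=0.10),
        "orientation_coherence": TransferFunction(0.30, t1, t2, 0.90,
                                                  noise_cv=0.05),
        "aspect_ratio": TransferFunction(3.0, t1, t2, 1.5, noise_cv=0.10),
        "stellate_amp": TransferFunction(0.15, t1, t2, 0.05, noise_cv=0.20),
    }


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class NoiseConfig:
    background_level: float = 0.0   # flat additive offset, counts
    background_gradient: float = 0.0  # peak-to-peak planar ramp, counts
    gaussian_sd: float = 0.0        # read noise, counts
    use_poisson: bool = False       # shot noise on the signal

    def __post_init__(self) -> None:
        if min(self.background_level, self.background_gradient,
               self.gaussian_sd) < 0:
            raise ValueError("noise levels must be >= 0")

    @property
    def is_zero(self) -> bool:
        return (self.background_level == 0 and self.background_gradient == 0
                and self.gaussian_sd == 0 and not self.use_poisson)

    @classmethod
    def realistic(cls) -> "NoiseConfig":
        """Typical CCD epifluorescence noise: camera offset, uneven
        illumination, shot noise and read noise."""
        return cls(background_level=100.0, background_gradient=50.0,
                   gaussian_sd=5.0, use_poisson=True)


@dataclass
class PopulationConfig:
    """Study conditions for one synthetic population.

    Expression is drawn as ``10**Normal(gfp_log_mean, gfp_log_sd)`` (log10
    units), spanning several decades as observed for viral transduction.
    Default breakpoints sit 1 and 2 decades above the median expression.
    """

    n_cells: int = 100
    gfp_log_mean: float = 3.0
    gfp_log_sd: float = 1.5
    transfer: Optional[Dict[str, TransferFunction]] = None
    image_size: int = 256
    pixel_size: float = 0.65   # um/px, 20x objective with binning
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.gfp_log_sd < 0:
            raise ValueError("gfp_log_sd must be >= 0")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64 px")
        if self.transfer is None:
            t1 = self.gfp_log_mean + 1.0
            t2 = self.gfp_log_mean + 2.0
            self.transfer = default_transfer_functions(t1, t2)
        else:
            # fill unspecified parameters with defaults sharing the
            # breakpoints of the first provided transfer function
            first = next(iter(self.transfer.values()))
            full = default_transfer_functions(first.t1, first.t2)
            full.update(self.transfer)
            self.transfer = full

    @property
    def t1(self) -> float:
        return next(iter(self.transfer.values())).t1

    @property
    def t2(self) -> float:
        return next(iter(self.transfer.values())).t2


@dataclass
class GroundTruth:
    """Per-cell generative truth and the population-level breakpoints.

    ``cells`` has one row per generated cell; ``masks`` holds the rendered
    boolean truth masks (cell, nucleus, fibres) in cell order; ``t1``/``t2``
    are the shared breakpoints in log10-expression units.
    """

    cells: pd.DataFrame
    masks: List[Dict[str, np.ndarray]]
    t1: float
    t2: float


def regime_label(expression: float, t1: float, t2: float) -> str:
    """Half-open regime convention: [0,t1) no-effect, [t1,t2) dose-response,
    [t2,inf) saturation (breakpoints in log10-expression units)."""
    x = math.log10(expression)
    if x < t1:
        return "no_effect"
    if x < t2:
        return "dose_response"
    return "saturation"


# ---------------------------------------------------------------------------
# Rendering primitives
# ---------------------------------------------------------------------------


def star_polygon(center: Tuple[float, float], area_px: float,
                 aspect_ratio: float, protrusion_amp: float,
                 n_lobes: int, phase: float, tilt: float,
                 n_vertices: int = 360) -> np.ndarray:
    """Vertices (row, col) of a star-convex cell outline.

    A circle of matching area is modulated radially by
    ``1 + protrusion_amp * cos(n_lobes * phi + phase)`` (the stellate
    protrusions), stretched into an ellipse of the requested aspect ratio
    and rotated by ``tilt``.
    """
    base_r = math.sqrt(area_px / (math.pi * (1 + protrusion_amp ** 2 / 2)))
    phi = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = base_r * (1 + protrusion_amp * np.cos(n_lobes * phi + phase))
    a = math.sqrt(aspect_ratio)
    x = r * np.cos(phi) * a
    y = r * np.sin(phi) / a
    ct, st = math.cos(tilt), math.sin(tilt)
    col = center[1] + x * ct - y * st
    row = center[0] + x * st + y * ct
    return np.stack([row, col], axis=1)


def rasterize_polygon(vertices: np.ndarray, shape: Tuple[int, int]
                      ) -> np.ndarray:
    rr, cc = draw_polygon(vertices[:, 0], vertices[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def rasterize_ellipse(center: Tuple[float, float], semi_major: float,
                      semi_minor: float, tilt: float,
                      shape: Tuple[int, int]) -> np.ndarray:
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    dr = rows - center[0]
    dc = cols - center[1]
    ct, st = math.cos(tilt), math.sin(tilt)
    u = dc * ct + dr * st
    v = -dc * st + dr * ct
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0


def render_fibre(shape: Tuple[int, int], center: Tuple[float, float],
                 theta: float, length: float, width: float,
                 amplitude: float = FIBRE_PEAK
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Render one capsule fibre with Gaussian cross-section.

    ``width`` is the full width at half maximum; the truth mask is the
    half-maximum footprint (distance to the axis segment <= width/2).
    Returns ``(intensity, mask)`` rasters of the full shape.
    """
    sigma = width / FWHM_SIGMA
    half = length / 2.0
    ur, uc = math.sin(theta), math.cos(theta)
    r0, c0 = center
    pad = 3.0 * sigma + 2.0
    rmin = max(int(r0 - half * abs(ur) - pad), 0)
    rmax = min(int(r0 + half * abs(ur) + pad) + 1, shape[0])
    cmin = max(int(c0 - half * abs(uc) - pad), 0)
    cmax = min(int(c0 + half * abs(uc) + pad) + 1, shape[1])
    img = np.zeros(shape, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    if rmax <= rmin or cmax <= cmin:
        return img, mask
    rows, cols = np.mgrid[rmin:rmax, cmin:cmax]
    vr = rows - r0
    vc = cols - c0
    t = np.clip(vr * ur + vc * uc, -half, half)
    d2 = (vr - t * ur) ** 2 + (vc - t * uc) ** 2
    img[rmin:rmax, cmin:cmax] = amplitude * np.exp(-d2 / (2 * sigma ** 2))
    mask[rmin:rmax, cmin:cmax] = d2 <= (width / 2.0) ** 2
    return img, mask


def kappa_from_mrl(r: float) -> float:
    """Invert the von-Mises mean resultant length A(kappa)=I1/I0 ~ r.

    Uses Fisher's piecewise approximation; r=1 maps to infinity.
    """
    if not 0 <= r <= 1:
        raise ValueError("mean resultant length must be in [0, 1]")
    if r >= 1.0:
        return math.inf
    if r < 0.53:
        return 2 * r + r ** 3 + 5 * r ** 5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r ** 3 - 4 * r ** 2 + 3 * r)


def mrl_from_kappa(kappa: float) -> float:
    if math.isinf(kappa):
        return 1.0
    if kappa == 0:
        return 0.0
    return float(i1(kappa) / i0(kappa))


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------


class GeometryError(RuntimeError):
    """Raised when a cell cannot be placed inside the image bounds."""


def _draw_cell_geometry(cfg: PopulationConfig, expression: float,
                        rng: np.random.Generator, max_retries: int = 25
                        ) -> dict:
    """Sample one cell's geometric ground truth, retrying until it fits."""
    size = cfg.image_size
    for _ in range(max_retries):
        params = {name: sample_parameter(tf, expression, rng)
                  for name, tf in cfg.transfer.items()}
        area_px = params["area"] / cfg.pixel_size ** 2
        ar = max(params["aspect_ratio"], 1.0)
        amp = min(params["stellate_amp"], 0.6)
        coherence = min(max(params["orientation_coherence"], 0.0), 0.999)
        center = (size / 2 + rng.uniform(-5, 5),
                  size / 2 + rng.uniform(-5, 5))
        verts = star_polygon(center, area_px, ar, amp,
                             n_lobes=int(rng.integers(5, 9)),
                             phase=rng.uniform(0, 2 * np.pi),
                             tilt=rng.uniform(0, np.pi))
        if (verts[:, 0].min() < 1 or verts[:, 1].min() < 1
                or verts[:, 0].max() > size - 2
                or verts[:, 1].max() > size - 2):
            continue
        return {
            "params": params, "center": center, "vertices": verts,
            "aspect_ratio": ar, "stellate_amp": amp, "coherence": coherence,
            "n_fibres": max(int(round(params["fibre_count"])), 1),
            "thickness_um": params["fibre_thickness"],
        }
    raise GeometryError(
        f"cell geometry exceeds a {size}x{size} image after "
        f"{max_retries} retries (area {params['area']:.0f} um^2)")


def _apply_noise(img: np.ndarray, noise: NoiseConfig,
                 rng: np.random.Generator) -> np.ndarray:
    out = img.astype(float)
    if noise.use_poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if noise.background_level or noise.background_gradient:
        h, w = img.shape
        phi = rng.uniform(0, 2 * np.pi)
        rows, cols = np.mgrid[0:h, 0:w]
        ramp = (math.cos(phi) * cols / w + math.sin(phi) * rows / h)
        ramp = (ramp - ramp.min()) / max(np.ptp(ramp), 1e-12)
        out = out + noise.background_level + noise.background_gradient * ramp
    if noise.gaussian_sd:
        out = out + rng.normal(0, noise.gaussian_sd, size=img.shape)
    return np.clip(out, 0, None)


def generate_cell(cfg: PopulationConfig, expression: float,
                  rng: np.random.Generator, identifier: str = ""
                  ) -> Tuple[CellImageSet, dict, Dict[str, np.ndarray]]:
    """Render one cell: returns (image set, truth record, truth masks)."""
    size = cfg.image_size
    shape = (size, size)
    geom = _draw_cell_geometry(cfg, expression, rng)
    cell_mask = rasterize_polygon(geom["vertices"], shape)
    n_px = int(cell_mask.sum())
    if n_px == 0:
        raise GeometryError("degenerate cell mask")

    # nucleus: ellipse at the cell centre, bounded by the cell core
    area_px = n_px
    nuc_area_px = 0.12 * area_px
    nuc_ar = 1.3
    semi_minor = math.sqrt(nuc_area_px / (math.pi * nuc_ar))
    semi_major = semi_minor * nuc_ar
    min_half_extent = math.sqrt(area_px / math.pi) * (1 - geom["stellate_amp"]) \
        / math.sqrt(geom["aspect_ratio"])
    scale = min(1.0, 0.8 * min_half_extent / semi_major)
    semi_major *= scale
    semi_minor *= scale
    nuc_tilt = rng.uniform(0, np.pi)
    crow, ccol = np.argwhere(cell_mask).mean(axis=0)
    nucleus_mask = rasterize_ellipse((crow, ccol), semi_major, semi_minor,
                                     nuc_tilt, shape) & cell_mask

    # fibres in the stain channel
    width_px = geom["thickness_um"] / cfg.pixel_size
    kappa = kappa_from_mrl(geom["coherence"])
    mu = rng.uniform(0, np.pi)
    interior = np.argwhere(cell_mask)
    diameter_px = 2 * math.sqrt(area_px / math.pi)
    stain = np.zeros(shape, dtype=float)
    fibre_mask = np.zeros(shape, dtype=bool)
    thetas, lengths, widths = [], [], []
    for _ in range(geom["n_fibres"]):
        if math.isinf(kappa):
            theta = mu
        else:
            theta = (mu + 0.5 * rng.vonmises(0.0, kappa)) % np.pi
        r0, c0 = interior[rng.integers(len(interior))]
        length = diameter_px * rng.uniform(0.4, 0.8)
        width = width_px * rng.uniform(0.9, 1.1)
        img, m = render_fibre(shape, (float(r0), float(c0)), theta,
                              length, width)
        stain += img
        fibre_mask |= m
        thetas.append(theta)
        lengths.append(length)
        widths.append(width)
    stain *= cell_mask
    fibre_mask &= cell_mask
    fibre_render_total = float(stain.sum())
    # the fibre "amount" proper is the signal inside the half-maximum
    # footprint; the Gaussian skirt outside it counts as diffuse signal
    fibre_amount = float(stain[fibre_mask].sum())
    stain = stain + CYTOPLASM_LEVEL * cell_mask

    gfp = np.zeros(shape, dtype=float)
    gfp[cell_mask] = expression / n_px
    dapi = np.where(nucleus_mask, DAPI_LEVEL, 0.0)

    images = CellImageSet(
        gfp=_apply_noise(gfp, cfg.noise, rng),
        stain=_apply_noise(stain, cfg.noise, rng),
        dapi=_apply_noise(dapi, cfg.noise, rng),
        pixel_size=cfg.pixel_size,
        identifier=identifier,
    )
    doubled = np.exp(2j * np.array(thetas))
    truth = {
        "identifier": identifier,
        "expression": expression,
        "area_um2": n_px * cfg.pixel_size ** 2,
        "area_target_um2": geom["params"]["area"],
        "aspect_ratio": geom["aspect_ratio"],
        "stellate_amp": geom["stellate_amp"],
        "n_fibres": geom["n_fibres"],
        "fibre_thickness_um": float(np.mean(widths)) * cfg.pixel_size,
        "fibre_length_um": float(np.mean(lengths)) * cfg.pixel_size,
        "orientation_coherence": geom["coherence"],
        "mean_orientation": float(np.angle(doubled.mean()) / 2 % np.pi),
        "fibre_amount": fibre_amount,
        "fibre_render_total": fibre_render_total,
        "cytoplasm_level": CYTOPLASM_LEVEL,
        "nucleus_area_um2": float(nucleus_mask.sum()) * cfg.pixel_size ** 2,
        "regime": regime_label(expression, cfg.t1, cfg.t2),
    }
    masks = {"cell": cell_mask, "nucleus": nucleus_mask, "fibre": fibre_mask}
    return images, truth, masks


def generate_population(cfg: PopulationConfig
                        ) -> Tuple[List[CellImageSet], GroundTruth]:
    """Generate one annotated field of view per cell.

    Deterministic under a fixed ``cfg.seed``; the GFP-channel total inside
    the cell mask equals the drawn expression before noise.
    """
    rng = np.random.default_rng(cfg.seed)
    expressions = 10.0 ** rng.normal(cfg.gfp_log_mean, cfg.gfp_log_sd,
                                     size=cfg.n_cells)
    image_sets: List[CellImageSet] = []
    records: List[dict] = []
    mask_list: List[Dict[str, np.ndarray]] = []
    for i, expr in enumerate(expressions):
        images, truth, masks = generate_cell(cfg, float(expr), rng,
                                             identifier=f"cell_{i:04d}")
        image_sets.append(images)
        records.append(truth)
        mask_list.append(masks)
    gt = GroundTruth(cells=pd.DataFrame(records), masks=mask_list,
                     t1=cfg.t1, t2=cfg.t2)
    return image_sets, gt


def render_protein_stain(masks: Dict[str, np.ndarray],
                         cyto_level: float, fibre_level: float = 0.0,
                         nuclear_enrichment: float = 1.0,
                         background: float = 0.0) -> np.ndarray:
    """Flat-painted stain for an arbitrary protein (e.g. YAP or cofilin).

    Pixels outside the cell take ``background``; cytoplasm takes
    ``cyto_level``; nucleus takes ``nuclear_enrichment * cyto_level``;
    fibre pixels are overwritten with ``fibre_level`` when non-zero,
    emulating a protein decorating the stress fibres.
    """
    img = np.full(masks["cell"].shape, float(background))
    img[masks["cell"]] = cyto_level
    img[masks["nucleus"]] = nuclear_enrichment * cyto_level
    if fibre_level:
        img[masks["fibre"]] = fibre_level
    return img


# ---------------------------------------------------------------------------
# Migration tracks
# ---------------------------------------------------------------------------


def default_speed_law(expression: float) -> float:
    """Mean step speed (um/min), declining with expression towards
    quasi-static behaviour at very high probe levels."""
    return 1.0 * 1e4 / (1e4 + expression)


def default_persistence_law(expression: float) -> float:
    """Directional persistence in [0,1]: low at low expression, peaking at
    intermediate levels, erratic again at very high expression."""
    x = math.log10(max(expression, 1e-12))
    return 0.25 + 0.6 * math.exp(-((x - 4.5) ** 2) / (2 * 0.6 ** 2))


@dataclass
class TrackConfig:
    """Persistent-random-walk configuration (default: 18 h at 10-min
    sampling, as in overnight live-cell migration assays)."""

    n_steps: int = 108
    dt: float = 10.0  # minutes
    speed_law: Callable[[float], float] = default_speed_law
    persistence_law: Callable[[float], float] = default_persistence_law
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def generate_tracks(tc: TrackConfig, expressions: Sequence[float]):
    """One persistent-random-walk centroid track per expression value.

    The walk takes steps of length speed*dt with wrapped-normal turning
    angles whose mean resultant length equals the persistence parameter
    (sigma = sqrt(-2 ln p)); persistence 1 gives a straight line, 0 an
    uncorrelated walk.  Returns a list of
    :class:`cytodose.dynamics.Track`.
    """
    from .dynamics import Track

    rng = np.random.default_rng(tc.seed)
    tracks = []
    for expr in expressions:
        if expr <= 0:
            raise ValueError("expressions must be positive")
        speed = tc.speed_law(expr)
        p = tc.persistence_law(expr)
        if not 0 <= p <= 1:
            raise ValueError("persistence must lie in [0, 1]")
        # wrapped-normal turning: mean resultant length exp(-sigma^2/2) = p
        sigma = 0.0 if p >= 1 else math.sqrt(-2.0 * math.log(max(p, 1e-300)))
        sigma = min(sigma, 50.0)  # indistinguishable from uniform beyond
        n_pos = tc.n_steps
        theta = rng.uniform(0, 2 * np.pi)
        turns = sigma * rng.standard_normal(max(n_pos - 2, 0))
        pos = np.zeros((n_pos, 2))
        for i in range(1, n_pos):
            if i > 1:
                theta += turns[i - 2]
            pos[i] = pos[i - 1] + speed * tc.dt * np.array(
                [math.cos(theta), math.sin(theta)])
        times = np.arange(n_pos) * tc.dt
        tracks.append(Track(times=times, positions=pos))
    return tracks


# ---------------------------------------------------------------------------
# F-actin decay series
# ---------------------------------------------------------------------------


def generate_decay_series(fa0: float, rate: float, t_end: float = 30.0,
                          dt: float = 2.0, noise_cv: float = 0.0,
                          rng: Optional[np.random.Generator] = None):
    """Exponential F-actin decay FA(t) = fa0 * exp(-rate * t).

    Emulates depolymerising-drug time lapses (default 30 min at 2-min
    intervals, t = 0..t_end inclusive).  ``rate`` is per minute; optional
    multiplicative lognormal noise with the given CV.
    """
    from .dynamics import FASeries

    if fa0 <= 0:
        raise ValueError("fa0 must be positive")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    times = np.arange(0.0, t_end + dt / 2, dt)
    fa = fa0 * np.exp(-rate * times)
    if noise_cv > 0:
        if rng is None:
            rng = np.random.default_rng()
        sigma = math.sqrt(math.log(1 + noise_cv ** 2))
        fa = fa * np.exp(rng.normal(0.0, sigma, size=fa.shape))
    return FASeries(times=times, fa=fa)
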