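"""Binocular energy model: Gabor monocular fields, LN elements, quadrature
complex cells, jittered populations and aperture-sweep simulations.

A binocular complex cell is built from four pairs of vertically oriented
monocular Gabor filters in phase quadrature.  Each monocular simple
response is the inner product of a Gabor with that eye's image; left and
right responses are summed and squared (an LN element), and the four LN
elements (phases 0, pi/2, pi, 3pi/2) are summed into the complex response

    Cx = sum_theta (SxL(theta) + SxR(theta))^2 .

Disparity tuning comes from a horizontal position offset between the
left- and right-eye filters (left centre - delta/2, right centre
+ delta/2).  The vertical envelope SD is fixed at 1.5x the horizontal SD,
matching macaque V1 aspect ratios; all filters are vertically oriented.

Populations of such cells (default 1000, desk profile 100) are centred at
one visual-field location with small Gaussian positional jitter (SD 0.1
deg) so that averaging washes out the response to the particular dot
placements of each random-dot stereogram.  Sweeping a bar (or wedge)
aperture across the population while averaging complex responses over
many RDS draws yields a neural response series that is then fitted with
the Gaussian-overlap pRF model (location fixed, size free) to read out
the apparent population receptive field size for each stimulus condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .apertures import ApertureSequence, bar_aperture, wedge_aperture
from .grid import VisualFieldGrid, make_grid
from .prf import GaussianPRF, _drive_series, _ols_scale
from .stimuli import DOT_DENSITY, DOT_RADIUS, StereoFrame, _n_dots

__all__ = [
    "BinocularUnit",
    "PopulationSpec",
    "ModelResponseSeries",
    "ModelPRFFit",
    "gabor_filter",
    "simple_response",
    "ln_element",
    "complex_response",
    "build_population",
    "sweep_response",
    "fit_model_prf",
    "size_curve",
    "disparity_contrast_ratio",
    "model_grid",
    "model_bar",
    "model_wedge",
    "DESK_PROFILE",
    "PAPER_PROFILE",
]

PHASES = (0.0, 0.5 * np.pi, np.pi, 1.5 * np.pi)
VERTICAL_ASPECT = 1.5  # sigma_v / sigma_h
STIMULUS_DISPARITY = 0.2  # degrees, the experiment's single magnitude
ENVELOPE_TRUNCATE = 3.0  # SDs kept when windowing a cohort
SCENE_JITTER = 0.25  # deg, half-range of per-frame fixational scene jitter
N_PATTERN_PHASES = 8  # stratified jitter phases for deterministic stimuli

CONDITIONS = (
    "chequerboard",
    "correlated_disparity",
    "luminance",
    "anticorrelated",
    "zero_disparity_correlated",
)
ZERO_DISPARITY_CONDITIONS = ("chequerboard", "luminance", "zero_disparity_correlated")

DESK_PROFILE = {"n_units": 100, "n_frames": 100}
PAPER_PROFILE = {"n_units": 1000, "n_frames": 1000}


@dataclass(frozen=True)
class BinocularUnit:
    """One quadrature-pair complex cell (cyclopean parameterisation)."""

    centre: tuple[float, float]
    sigma_h: float
    spatial_frequency: float  # cycles/degree of the carrier
    disparity_offset: float = 0.0  # right-eye centre minus left-eye centre

    def __post_init__(self) -> None:
        if self.sigma_h <= 0 or self.spatial_frequency <= 0:
            raise ValueError("sigma_h and spatial_frequency must be positive")

    @property
    def sigma_v(self) -> float:
        return VERTICAL_ASPECT * self.sigma_h

    @property
    def left_centre(self) -> tuple[float, float]:
        return (self.centre[0] - self.disparity_offset / 2.0, self.centre[1])

    @property
    def right_centre(self) -> tuple[float, float]:
        return (self.centre[0] + self.disparity_offset / 2.0, self.centre[1])


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for a simulated population.

    ``sizes`` is the horizontal-envelope sweep (default 15 values, SD 0.2
    to 3 deg).  ``sf_rule`` is "fixed" (carrier at ``sf_multiplier``
    cycles per sigma_h, i.e. f = m / sigma_h) or "variable" (multiplier
    drawn uniformly from ``sf_range``, the 0.5-3.5x spread of macaque V1
    tuning).  ``sf_reading`` selects the dimensional reading of the
    multiplier: "cycles_per_sigma" (f = m / sigma_h, the physiological
    reading, default) or "scaled_by_sigma" (f = m * sigma_h).
    ``disparity_rule`` is "fixed" (every unit tuned exactly to the
    nominal disparity) or "jittered" (Gaussian jitter, SD 0.25 deg).
    """

    n_units: int = 1000
    sizes: tuple = tuple(np.linspace(0.2, 3.0, 15))
    position_jitter_sd: float = 0.1
    sf_rule: str = "fixed"
    sf_multiplier: float = 0.5
    sf_range: tuple[float, float] = (0.5, 3.5)
    sf_reading: str = "cycles_per_sigma"
    disparity_rule: str = "fixed"
    disparity_jitter_sd: float = 0.25
    centre: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units <= 0:
            raise ValueError("n_units must be positive")
        if not np.all(np.diff(self.sizes) > 0):
            raise ValueError("sizes must be strictly increasing")
        if self.sf_rule not in ("fixed", "variable"):
            raise ValueError("sf_rule must be 'fixed' or 'variable'")
        if self.sf_reading not in ("cycles_per_sigma", "scaled_by_sigma"):
            raise ValueError("unknown sf_reading")
        if self.disparity_rule not in ("fixed", "jittered"):
            raise ValueError("disparity_rule must be 'fixed' or 'jittered'")


@dataclass
class ModelResponseSeries:
    """Population-mean complex response at each aperture step (>= 0)."""

    responses: np.ndarray
    sigma_h: float
    condition: str
    n_frames: int

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if np.any(self.responses < -1e-9):
            raise ValueError("complex responses must be non-negative")


MIN_FIT_R2 = 0.2  # read-out validity floor (cf. the CCnorm > 0.5 thresholding
# of the empirical fits): below it the overlap model explains nothing and the
# returned sigma is numerical noise


@dataclass
class ModelPRFFit:
    sigma: float
    r2: float
    amplitude: float
    baseline: float
    ok: bool


# ---------------------------------------------------------------------------
# single-unit reference operations


def gabor_filter(
    grid: VisualFieldGrid,
    centre: tuple[float, float],
    sigma_h: float,
    sigma_v: float,
    f: float,
    theta: float,
) -> np.ndarray:
    """Vertically oriented Gabor: horizontal sinusoid (phase referenced to
    the filter centre) under an anisotropic Gaussian envelope normalised to
    unit volume."""
    if min(sigma_h, sigma_v) < grid.pixel_size:
        raise ValueError("envelope smaller than one pixel")
    x, y = grid.mesh()
    cx, cy = centre
    carrier = np.sin(2 * np.pi * f * (x - cx) + theta)
    envelope = np.exp(-0.5 * (((x - cx) / sigma_h) ** 2 + ((y - cy) / sigma_v) ** 2))
    return carrier * envelope / (2 * np.pi * sigma_h * sigma_v)


def simple_response(filt: np.ndarray, image: np.ndarray, pixel_area: float = 1.0) -> float:
    """Monocular simple-cell response: pixelwise product summed x pixel area."""
    if filt.shape != image.shape:
        raise ValueError("filter and image shapes differ")
    return float(np.einsum("hw,hw->", filt, image, optimize=False) * pixel_area)


def ln_element(s_left: float, s_right: float) -> float:
    """Squared binocular sum; symmetric in its arguments."""
    return (s_left + s_right) ** 2


def complex_response(unit: BinocularUnit, frame: StereoFrame) -> float:
    """Sum of the four phase-quadrature LN elements for one stereo frame."""
    grid = frame.grid
    out = 0.0
    for theta in PHASES:
        fl = gabor_filter(grid, unit.left_centre, unit.sigma_h, unit.sigma_v, unit.spatial_frequency, theta)
        fr = gabor_filter(grid, unit.right_centre, unit.sigma_h, unit.sigma_v, unit.spatial_frequency, theta)
        out += ln_element(
            simple_response(fl, frame.left, grid.pixel_area),
            simple_response(fr, frame.right, grid.pixel_area),
        )
    return out


# ---------------------------------------------------------------------------
# population construction


def build_population(
    spec: PopulationSpec,
    tuned_disparity: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[BinocularUnit]:
    """Units for every size cohort of the sweep.

    Centres are jittered around ``spec.centre`` (seeded); the carrier SF
    and the interocular position offset follow the recipe's rules around
    ``tuned_disparity``.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    units = []
    for sigma_h in spec.sizes:
        jit = rng.normal(0.0, spec.position_jitter_sd, size=(spec.n_units, 2))
        if spec.sf_rule == "fixed":
            mult = np.full(spec.n_units, spec.sf_multiplier)
        else:
            mult = rng.uniform(*spec.sf_range, size=spec.n_units)
        if spec.sf_reading == "cycles_per_sigma":
            sf = mult / sigma_h
        else:
            sf = mult * sigma_h
        if spec.disparity_rule == "fixed":
            delta = np.full(spec.n_units, tuned_disparity)
        else:
            delta = rng.normal(tuned_disparity, spec.disparity_jitter_sd, size=spec.n_units)
        for u in range(spec.n_units):
            units.append(
                BinocularUnit(
                    centre=(spec.centre[0] + jit[u, 0], spec.centre[1] + jit[u, 1]),
                    sigma_h=float(sigma_h),
                    spatial_frequency=float(sf[u]),
                    disparity_offset=float(delta[u]),
                )
            )
    return units


# ---------------------------------------------------------------------------
# vectorised cohort engine


class _Window:
    """Rectangular sub-raster of a grid around the population centre."""

    def __init__(self, grid: VisualFieldGrid, centre: tuple[float, float], half_x: float, half_y: float):
        xs, ys = grid.x_coords, grid.y_coords
        c0 = int(np.searchsorted(xs, centre[0] - half_x, side="left"))
        c1 = int(np.searchsorted(xs, centre[0] + half_x, side="right"))
        ys_asc = ys[::-1]
        r0a = int(np.searchsorted(ys_asc, centre[1] - half_y, side="left"))
        r1a = int(np.searchsorted(ys_asc, centre[1] + half_y, side="right"))
        self.r0, self.r1 = len(ys) - r1a, len(ys) - r0a
        self.c0, self.c1 = c0, c1
        self.x = xs[self.c0 : self.c1]
        self.y = ys[self.r0 : self.r1]
        self.ppd = grid.pixels_per_degree
        self.pixel_area = grid.pixel_area

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.y), len(self.x))

    def crop(self, image: np.ndarray) -> np.ndarray:
        return image[..., self.r0 : self.r1, self.c0 : self.c1]

    def lookup(self, mask: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Nearest-pixel mask membership for window-coordinate positions."""
        h, w = self.shape
        col = np.rint((positions[:, 0] - self.x[0]) * self.ppd).astype(np.int64)
        row = np.rint((self.y[0] - positions[:, 1]) * self.ppd).astype(np.int64)
        ok = (row >= 0) & (row < h) & (col >= 0) & (col < w)
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = mask[row[ok], col[ok]] > 0
        return out


class _CohortEngine:
    """Precomputed separable filter bank for the units of one size cohort.

    Exploits the exact phase antisymmetry LN(0) = LN(pi) and
    LN(pi/2) = LN(3pi/2): the complex response is computed as twice the
    sum of the two distinct quadrature LN elements.
    """

    def __init__(self, units: list[BinocularUnit], win: _Window):
        self.win = win
        U = len(units)
        y = win.y
        x = win.x
        self.V = np.empty((U, len(y)), dtype=np.float32)
        self.H = np.empty((U, 2, 2, len(x)), dtype=np.float32)  # (unit, eye, phase, x)
        for u, unit in enumerate(units):
            sh, sv, f = unit.sigma_h, unit.sigma_v, unit.spatial_frequency
            norm = 1.0 / (2 * np.pi * sh * sv)
            self.V[u] = np.exp(-0.5 * ((y - unit.centre[1]) / sv) ** 2)
            for e, (cx, _) in enumerate((unit.left_centre, unit.right_centre)):
                env = np.exp(-0.5 * ((x - cx) / sh) ** 2) * norm
                for p, theta in enumerate(PHASES[:2]):
                    self.H[u, e, p] = np.sin(2 * np.pi * f * (x - cx) + theta) * env

    def responses(self, left: np.ndarray, right: np.ndarray) -> np.ndarray:
        """Complex responses, shape (n_frames, n_units)."""
        BL = np.matmul(self.V, left)  # (F, U, W)
        BR = np.matmul(self.V, right)
        SL = np.einsum("fuw,upw->fup", BL, self.H[:, 0], optimize=True)
        SR = np.einsum("fuw,upw->fup", BR, self.H[:, 1], optimize=True)
        s = (SL + SR) * self.win.pixel_area
        return 2.0 * (s.astype(np.float64) ** 2).sum(axis=2)

    def responses_identical(self, image: np.ndarray) -> np.ndarray:
        """Fast path for binocularly identical frames of delta = 0 units
        (left filter = right filter, so SL = SR and Cx = 8 sum SL^2)."""
        B = np.matmul(self.V, image)
        S = np.einsum("fuw,upw->fup", B, self.H[:, 0], optimize=True)
        s = S * self.win.pixel_area
        return 8.0 * (s.astype(np.float64) ** 2).sum(axis=2)


def _render_batch(
    shape: tuple[int, int],
    ppd: float,
    x0: float,
    y0: float,
    frame_idx: np.ndarray,
    positions: np.ndarray,
    polarity: np.ndarray,
    dot_radius: float,
    n_frames: int,
    tie_signs: np.ndarray,
    rsign: float = 1.0,
) -> np.ndarray:
    """Render dots for a whole batch of frames with one bincount.

    ``x0``/``y0`` are the degree coordinates of pixel (0, 0) of the
    window; positions are cyclopean/eye coordinates in degrees.  Overlap
    follows the same rule as the single-frame renderer: signed sum
    clipped, cancelled covered pixels take ``rsign * tie_signs``.
    """
    h, w = shape
    npx = h * w
    cx = (positions[:, 0] - x0) * ppd
    cy = (y0 - positions[:, 1]) * ppd
    r_px = dot_radius * ppd
    reach = int(np.ceil(r_px + 0.5))
    c0 = np.floor(cx).astype(np.int64)
    r0 = np.floor(cy).astype(np.int64)
    fx = cx - c0
    fy = cy - r0
    base = frame_idx.astype(np.int64) * npx
    idx_parts, w_parts = [], []
    r2 = r_px**2
    for dr in range(-reach, reach + 2):
        dy2 = (dr - fy) ** 2
        for dc in range(-reach, reach + 2):
            hit = (dc - fx) ** 2 + dy2 <= r2
            if not hit.any():
                continue
            rr = r0[hit] + dr
            cc = c0[hit] + dc
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            if not ok.any():
                continue
            idx_parts.append(base[hit][ok] + rr[ok] * w + cc[ok])
            w_parts.append(polarity[hit][ok])
    total = np.zeros(n_frames * npx)
    cnt = np.zeros(n_frames * npx)
    if idx_parts:
        idx = np.concatenate(idx_parts)
        total = np.bincount(idx, weights=np.concatenate(w_parts), minlength=n_frames * npx)
        cnt = np.bincount(idx, minlength=n_frames * npx)
    img = np.clip(total, -1.0, 1.0)
    ties = (cnt > 0) & (total == 0)
    img[ties] = rsign * tie_signs[ties]
    return img.astype(np.float32).reshape(n_frames, h, w)


def _balanced_batch(n_total: int, per_frame: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced +/-1 polarities, shuffled independently per frame."""
    n_frames = n_total // per_frame
    pol = np.ones((n_frames, per_frame))
    pol[:, : per_frame // 2] = -1.0
    return rng.permuted(pol, axis=1).ravel()


class _RDSSampler:
    """Full-field dot sample shared by every cohort of a sweep.

    One sample of dot positions, polarities and overlap tie-break signs is
    drawn for the whole field and reused (a) at every aperture step — only
    the aperture membership of each dot changes as the bar/wedge moves —
    and (b) by every size cohort, which sees the dots falling inside its
    own analysis window.  Conditions seeded identically draw the same
    sample.  These common random numbers leave every mean response
    unbiased while making the sampling error vary smoothly along the
    aperture-transit profile, across the size sweep and between
    conditions, which is what stabilises the fitted size curves at
    moderate frame counts.
    """

    def __init__(
        self,
        grid: VisualFieldGrid,
        condition: str,
        stimulus_disparity: float,
        n_frames: int,
        density: float,
        dot_radius: float,
        rng: np.random.Generator,
    ):
        self.condition = condition
        self.off = stimulus_disparity / 2.0
        self.rsign = -1.0 if condition == "anticorrelated" else 1.0
        self.n_frames = n_frames
        self.dot_radius = dot_radius
        self.luminance_style = "opposed"
        he, r = grid.half_extent, dot_radius
        n = _n_dots(density, (2 * (he + r)) ** 2, dot_radius)
        binocular = condition != "luminance"
        # binocular-background conditions expand each base dot sample into
        # 8 antithetic variants: 4 background-polarity flip combinations
        # times 2 eye-role assignments (see _CohortSample.frames)
        group = 8 if binocular else 1
        n_base = -(-n_frames // group)
        f = np.arange(n_frames)
        base = f // group
        v = f % group
        self.role_b = (v // 4) == 1  # frames where set B leads (fg + left bg)
        self.flip_l = np.where(np.isin(v % 4, (2, 3)), -1.0, 1.0)  # left-bg flip
        self.flip_r = np.where(np.isin(v % 4, (1, 3)), -1.0, 1.0)  # right-bg flip
        self.fidx = np.repeat(f, n)

        def expand(x: np.ndarray) -> np.ndarray:
            shaped = x.reshape(n_base, n, *x.shape[1:])
            return shaped[base].reshape(n_frames * n, *x.shape[1:])

        ties_base = rng.integers(0, 2, size=(n_base, *grid.shape), dtype=np.int8) * 2 - 1
        self.ties = ties_base[base]
        # per-frame fixational scene jitter: the whole retinal image (dots
        # and aperture edges together) shifts by a small random offset,
        # phase-averaging carrier-locked response components; shared within
        # an antithetic group so the flip cancellations stay exact
        jit_base = rng.uniform(-SCENE_JITTER, SCENE_JITTER, size=(n_base, 2))
        self.jitter = jit_base[base]
        m = n * n_base
        self.pos_a = expand(rng.uniform(-he - r, he + r, size=(m, 2)))
        self.pol_a = expand(_balanced_batch(m, n, rng))
        if binocular:
            self.pos_b = expand(rng.uniform(-he - r, he + r, size=(m, 2)))
            self.pol_b = expand(_balanced_batch(m, n, rng))
        else:
            self.pos_b = self.pol_b = None

    def cohort_view(self, win: _Window) -> "_CohortSample":
        return _CohortSample(self, win)


class _CohortSample:
    """The shared dot sample restricted to one cohort's window."""

    def __init__(self, sampler: _RDSSampler, win: _Window):
        self.s = sampler
        self.win = win
        r = sampler.dot_radius + abs(sampler.off) + SCENE_JITTER
        x0, x1 = win.x[0] - r, win.x[-1] + r
        y0, y1 = win.y[-1] - r, win.y[0] + r

        def select(pos):
            return (pos[:, 0] >= x0) & (pos[:, 0] <= x1) & (pos[:, 1] >= y0) & (pos[:, 1] <= y1)

        sa = select(sampler.pos_a)
        self.pos_a = sampler.pos_a[sa]
        self.pol_a = sampler.pol_a[sa]
        self.fidx_a = sampler.fidx[sa]
        if sampler.pos_b is not None:
            sb = select(sampler.pos_b)
            self.pos_b = sampler.pos_b[sb]
            self.pol_b = sampler.pol_b[sb]
            self.fidx_b = sampler.fidx[sb]
        self.ties = (
            np.ascontiguousarray(sampler.ties[:, win.r0 : win.r1, win.c0 : win.c1])
            .astype(np.float64)
            .ravel()
        )

    def frames(self, submask: np.ndarray, luminance_sign: float = 1.0):
        """Render the left/right frame stacks for one aperture position.

        For the binocular-background conditions the two dot sets swap
        roles between the first and second half of the frames (set A
        supplies foreground and left background in half the frames, set B
        in the other half).  The frozen difference between the two sets
        inside the aperture strip then cancels in the frame average,
        which would otherwise ride on the transit profile as a slowly
        varying sample artefact under common random numbers.
        """
        s, win = self.s, self.win
        r, F = s.dot_radius, s.n_frames
        jit = s.jitter
        in_a = win.lookup(submask, self.pos_a)
        if s.condition == "luminance":
            if s.luminance_style == "opposed":
                # the model reading: aperture dots carry one uniform
                # polarity and background dots the opposite one, so the
                # aperture is defined purely by a mean-luminance step
                # (variance-matched inside and out)
                pol = np.where(in_a, -luminance_sign, luminance_sign)
            else:
                # participants'-display reading: uniform aperture polarity
                # (reversing over time) on a balanced background
                pol = np.where(in_a, luminance_sign, self.pol_a)
            left = _render_batch(win.shape, win.ppd, win.x[0], win.y[0],
                                 self.fidx_a, self.pos_a + jit[self.fidx_a], pol,
                                 r, F, self.ties)
            return left, left.copy()
        in_b = win.lookup(submask, self.pos_b)
        off, rsign = s.off, s.rsign
        role_b_a = s.role_b[self.fidx_a]  # per A-dot: does set B lead this frame?
        role_b_b = s.role_b[self.fidx_b]
        fl = s.flip_l
        fr = s.flip_r
        # leading set supplies the foreground and the left background (its
        # complement supplies the right background); background polarities
        # carry the antithetic flip signs, the foreground never flips
        lparts = (
            (self.pos_a[~in_a & ~role_b_a], (self.pol_a * fl[self.fidx_a])[~in_a & ~role_b_a],
             self.fidx_a[~in_a & ~role_b_a], 0.0),
            (self.pos_a[in_a & ~role_b_a], self.pol_a[in_a & ~role_b_a],
             self.fidx_a[in_a & ~role_b_a], -off),
            (self.pos_b[~in_b & role_b_b], (self.pol_b * fl[self.fidx_b])[~in_b & role_b_b],
             self.fidx_b[~in_b & role_b_b], 0.0),
            (self.pos_b[in_b & role_b_b], self.pol_b[in_b & role_b_b],
             self.fidx_b[in_b & role_b_b], -off),
        )
        rparts = (
            (self.pos_b[~in_b & ~role_b_b], (self.pol_b * fr[self.fidx_b])[~in_b & ~role_b_b],
             self.fidx_b[~in_b & ~role_b_b], 0.0, 1.0),
            (self.pos_a[in_a & ~role_b_a], self.pol_a[in_a & ~role_b_a],
             self.fidx_a[in_a & ~role_b_a], off, rsign),
            (self.pos_a[~in_a & role_b_a], (self.pol_a * fr[self.fidx_a])[~in_a & role_b_a],
             self.fidx_a[~in_a & role_b_a], 0.0, 1.0),
            (self.pos_b[in_b & role_b_b], self.pol_b[in_b & role_b_b],
             self.fidx_b[in_b & role_b_b], off, rsign),
        )
        lpos = np.concatenate([p + [dx, 0.0] for p, _, _, dx in lparts])
        lpol = np.concatenate([q for _, q, _, _ in lparts])
        lidx = np.concatenate([i for _, _, i, _ in lparts])
        rpos = np.concatenate([p + [dx, 0.0] for p, _, _, dx, _ in rparts])
        rpol = np.concatenate([q * sg for _, q, _, _, sg in rparts])
        ridx = np.concatenate([i for _, _, i, _, _ in rparts])
        left = _render_batch(win.shape, win.ppd, win.x[0], win.y[0],
                             lidx, lpos + jit[lidx], lpol, r, F, self.ties)
        right = _render_batch(win.shape, win.ppd, win.x[0], win.y[0],
                              ridx, rpos + jit[ridx], rpol, r, F, self.ties, rsign=rsign)
        return left, right


class _FineWindow:
    """Stand-alone fine raster for the deterministic chequerboard sweep.

    The display chequerboard's log-scaled rings are self-similar, so a
    cohort of envelope SD sigma_h responds to ring/sector edges at every
    radius inside its envelope — provided the raster resolves them.  The
    shared 10 px/deg grid aliases rings below 0.1 deg, which silently
    turns the pattern's centre into broadband texture; the chequerboard
    response is therefore evaluated on a cohort-specific raster whose
    density resolves the rings carrying that cohort's response, with the
    aperture masks nearest-neighbour sampled from the shared grid.
    """

    def __init__(self, grid: VisualFieldGrid, centre: tuple[float, float],
                 half_x: float, half_y: float, ppd: float):
        self.ppd = float(ppd)
        step = 1.0 / self.ppd
        he = grid.half_extent
        x0, x1 = max(centre[0] - half_x, -he), min(centre[0] + half_x, he)
        y0, y1 = max(centre[1] - half_y, -he), min(centre[1] + half_y, he)
        self.x = np.arange(x0, x1 + step / 2, step)
        self.y = np.arange(y1, y0 - step / 2, -step)  # row 0 at top
        self.pixel_area = step**2
        # nearest parent-grid pixel for aperture lookup
        self._parent_ppd = grid.pixels_per_degree
        self._parent_half = (grid.width - 1) // 2
        self._parent_width = grid.width
        self._cols = np.clip(
            np.rint(self.x * self._parent_ppd).astype(int) + self._parent_half, 0, grid.width - 1
        )
        self._rows = np.clip(
            self._parent_half - np.rint(self.y * self._parent_ppd).astype(int), 0, grid.height - 1
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.y), len(self.x))

    def resample_mask(self, mask: np.ndarray, x_offset: float = 0.0) -> np.ndarray:
        """Nearest-neighbour aperture sample, optionally scene-shifted in x."""
        if x_offset == 0.0:
            return mask[np.ix_(self._rows, self._cols)]
        cols = np.clip(
            np.rint((self.x - x_offset) * self._parent_ppd).astype(int) + self._parent_half,
            0, self._parent_width - 1,
        )
        return mask[np.ix_(self._rows, cols)]




def _group_cohorts(population: list[BinocularUnit]) -> list[tuple[float, list[BinocularUnit]]]:
    groups: dict[float, list[BinocularUnit]] = {}
    for u in population:
        groups.setdefault(u.sigma_h, []).append(u)
    return sorted(groups.items())


def sweep_response(
    population: list[BinocularUnit],
    condition: str,
    aperture: ApertureSequence,
    stimulus_disparity: float | None = None,
    n_frames: int = 1000,
    rng: np.random.Generator | None = None,
    density: float = DOT_DENSITY,
    dot_radius: float = DOT_RADIUS,
    luminance_style: str = "opposed",
) -> list[ModelResponseSeries]:
    """Population responses to an aperture sweep, one series per size cohort.

    For RDS conditions, ``n_frames`` fresh stereograms are generated at
    each aperture step and the complex responses averaged over frames and
    over the units of each cohort.  The chequerboard is deterministic
    (contrast phase alternates across steps; the squared complex response
    is identical for the two phases, so a single frame per step suffices).

    ``stimulus_disparity`` applies to the correlated/anticorrelated
    conditions (default 0.2 deg); passing a nonzero value for a
    zero-disparity condition is rejected.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition in ZERO_DISPARITY_CONDITIONS:
        if stimulus_disparity not in (None, 0, 0.0):
            raise ValueError(f"{condition} is a zero-disparity stimulus")
        stimulus_disparity = 0.0
    elif stimulus_disparity is None:
        stimulus_disparity = STIMULUS_DISPARITY
    rng = np.random.default_rng() if rng is None else rng
    grid = aperture.grid
    n_steps = len(aperture)
    out = []
    sampler = None
    if condition != "chequerboard":
        sampler = _RDSSampler(grid, condition, stimulus_disparity, n_frames,
                              density, dot_radius, rng)
        sampler.luminance_style = luminance_style
    for sigma_h, units in _group_cohorts(population):
        sigma_v = VERTICAL_ASPECT * sigma_h
        cx = float(np.mean([u.centre[0] for u in units]))
        cy = float(np.mean([u.centre[1] for u in units]))
        pad = 3 * 0.1 + abs(stimulus_disparity) + dot_radius + SCENE_JITTER + 0.2
        win = _Window(
            grid,
            (cx, cy),
            ENVELOPE_TRUNCATE * sigma_h + pad,
            ENVELOPE_TRUNCATE * sigma_v + pad,
        )
        series = np.empty(n_steps)
        if condition == "chequerboard":
            # contrast probe: a contrast-reversing square-wave carrier at the
            # cohort's (median) spatial frequency — the component of the
            # display's scale-matched radial checks that the vertically
            # oriented filters see at their represented eccentricity.  The
            # response is deterministic; the fixational scene jitter becomes
            # stratified offsets of the whole scene (pattern and aperture).
            f_p = float(np.median([u.spatial_frequency for u in units]))
            ppd_c = float(np.clip(8.0 * f_p, 10.0, 160.0))
            fwin = _FineWindow(grid, (cx, cy),
                               ENVELOPE_TRUNCATE * sigma_h + pad,
                               ENVELOPE_TRUNCATE * sigma_v + pad, ppd_c)
            feng = _CohortEngine(units, fwin)
            offsets = (np.arange(N_PATTERN_PHASES) + 0.5) / N_PATTERN_PHASES
            offsets = (2 * offsets - 1) * SCENE_JITTER
            patterns = [
                np.sign(np.sin(2 * np.pi * f_p * (fwin.x - ex))).astype(np.float32)[None, :]
                for ex in offsets
            ]
            identical_eyes = all(abs(u.disparity_offset) < 1e-12 for u in units)
            for t in range(n_steps):
                phase = 1.0 if t % 2 == 0 else -1.0
                imgs = np.stack(
                    [
                        phase * p * fwin.resample_mask(aperture.masks[t], ex)
                        for p, ex in zip(patterns, offsets)
                    ]
                ).astype(np.float32)
                if identical_eyes:
                    series[t] = feng.responses_identical(imgs).mean()
                else:
                    series[t] = feng.responses(imgs, imgs).mean()
        else:
            eng = _CohortEngine(units, win)
            view = sampler.cohort_view(win)
            for t in range(n_steps):
                lum_sign = 1.0 if t % 2 == 0 else -1.0
                left, right = view.frames(win.crop(aperture.masks[t]), lum_sign)
                series[t] = eng.responses(left, right).mean()
        out.append(ModelResponseSeries(series, sigma_h, condition, n_frames))
    return out


# ---------------------------------------------------------------------------
# read-out


def fit_model_prf(
    series: ModelResponseSeries | np.ndarray,
    aperture: ApertureSequence,
    fixed_centre: tuple[float, float],
    sigma_bounds: tuple[float, float] = (0.05, 8.0),
) -> ModelPRFFit:
    """Fit the Gaussian-overlap prediction to a neural response series.

    Responses are neural, not haemodynamic, so no HRF is applied.  The pRF
    centre is fixed a priori; only sigma is estimated, with amplitude and
    baseline solved per candidate by least squares (so a constant offset
    leaves sigma unchanged).  A coarse log-spaced scan brackets the best
    sigma before bounded scalar refinement.
    """
    y = series.responses if isinstance(series, ModelResponseSeries) else np.asarray(series, float)
    if len(y) != len(aperture):
        raise ValueError("series length must match the aperture steps")
    if y.std() < 1e-12 * max(1.0, abs(y.mean())):
        return ModelPRFFit(np.nan, 0.0, 0.0, float(y.mean()), ok=False)

    def r2_of(sig: float) -> float:
        pred = _drive_series(GaussianPRF(fixed_centre[0], fixed_centre[1], sig), aperture)
        return _ols_scale(pred, y)[2]

    scan = np.geomspace(sigma_bounds[0], sigma_bounds[1], 24)
    r2s = [r2_of(s) for s in scan]
    k = int(np.argmax(r2s))
    lo = scan[max(k - 1, 0)]
    hi = scan[min(k + 1, len(scan) - 1)]
    sol = optimize.minimize_scalar(
        lambda ls: 1.0 - r2_of(float(np.exp(ls))),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-5},
    )
    sigma = float(np.exp(sol.x))
    pred = _drive_series(GaussianPRF(fixed_centre[0], fixed_centre[1], sigma), aperture)
    a, b, r2 = _ols_scale(pred, y)
    return ModelPRFFit(sigma=sigma, r2=r2, amplitude=a, baseline=b, ok=bool(r2 >= MIN_FIT_R2))


def model_grid(half_extent: float = 12.0, pixels_per_degree: float = 10.0) -> VisualFieldGrid:
    """Simulation field: 12 deg half-extent keeps the 3-SD envelope of the
    largest (3 deg) cohort untruncated, and the bar traverses it fully."""
    return make_grid(half_extent, pixels_per_degree)


def model_bar(grid: VisualFieldGrid, n_steps: int = 100, bar_width: float = 1.0) -> ApertureSequence:
    """The sweeping-bar aperture of the simulations (100 steps, full field)."""
    return bar_aperture(grid, n_steps=n_steps, bar_width=bar_width)


def model_wedge(grid: VisualFieldGrid, n_steps: int = 36, wedge_width: float = 20.0) -> ApertureSequence:
    """One full rotation of the 20-deg wedge in ``n_steps`` positions."""
    return wedge_aperture(grid, n_steps, "ccw", cycle_volumes=n_steps,
                          wedge_width=wedge_width, frame_interval=1.0)


MANIPULATIONS = {
    "size_only": {"sf_rule": "fixed", "disparity_rule": "fixed"},
    "size_sf": {"sf_rule": "variable", "disparity_rule": "fixed"},
    "size_sf_disparity": {"sf_rule": "variable", "disparity_rule": "jittered"},
}


def _tuning_for(condition: str, stimulus_disparity: float, zero_disparity_tuning: str) -> float:
    """Tuned interocular offset handed to build_population per condition.

    Units are tuned to the stimulus disparity: 0 for the chequerboard and
    luminance stimuli, the programmed disparity for the correlated and
    anti-correlated stimuli.  The interocular-correlation control
    (zero-disparity correlated wedge) asks whether correlation alone can
    drive the disparity-tuned population, so by default it is probed with
    the same population as the disparity condition
    (``zero_disparity_tuning="disparity"``); set it to "zero" for a
    population tuned to the control stimulus itself.
    """
    if condition in ("correlated_disparity", "anticorrelated"):
        return stimulus_disparity
    if condition == "zero_disparity_correlated" and zero_disparity_tuning == "disparity":
        return stimulus_disparity
    return 0.0


def size_curve(
    conditions: list[str],
    manipulation: str = "size_only",
    aperture: ApertureSequence | None = None,
    population_centre: tuple[float, float] = (0.0, 0.0),
    n_units: int = DESK_PROFILE["n_units"],
    n_frames: int = DESK_PROFILE["n_frames"],
    sizes: tuple | None = None,
    stimulus_disparity: float = STIMULUS_DISPARITY,
    zero_disparity_tuning: str = "disparity",
    seed: int = 0,
    grid: VisualFieldGrid | None = None,
) -> pd.DataFrame:
    """Fitted pRF size versus monocular RF size for each condition.

    Runs ``sweep_response`` + ``fit_model_prf`` over the size sweep and
    tabulates sigma_hat per (size, condition).  ``manipulation`` selects
    which receptive-field properties vary across the population:
    "size_only", "size_sf" (adds variable spatial frequency) or
    "size_sf_disparity" (adds disparity-tuning jitter).
    """
    if manipulation not in MANIPULATIONS:
        raise ValueError(f"unknown manipulation {manipulation!r}")
    grid = grid or model_grid()
    aperture = aperture if aperture is not None else model_bar(grid)
    rows = []
    for ci, condition in enumerate(conditions):
        spec = PopulationSpec(
            n_units=n_units,
            sizes=tuple(sizes) if sizes is not None else PopulationSpec.sizes,
            centre=population_centre,
            seed=seed,
            **MANIPULATIONS[manipulation],
        )
        tuned = _tuning_for(condition, stimulus_disparity, zero_disparity_tuning)
        pop = build_population(spec, tuned_disparity=tuned)
        # every condition re-seeds the same stream, so conditions sharing a
        # draw structure see the same dot sample (paired comparisons)
        rng = np.random.default_rng([seed, 1])
        for s in sweep_response(
            pop, condition, aperture,
            stimulus_disparity=None if condition in ZERO_DISPARITY_CONDITIONS else stimulus_disparity,
            n_frames=n_frames, rng=rng,
        ):
            fit = fit_model_prf(s, aperture, population_centre)
            rows.append((s.sigma_h, condition, fit.sigma, fit.r2, fit.amplitude, fit.ok))
    return pd.DataFrame(rows, columns=["rf_size", "condition", "sigma_hat", "r2", "amplitude", "ok"])


def disparity_contrast_ratio(curve: pd.DataFrame, disparity: str = "correlated_disparity",
                             contrast: str = "chequerboard") -> pd.DataFrame:
    """Per-size ratio of fitted pRF size, disparity over contrast."""
    a = curve[curve.condition == disparity].set_index("rf_size")["sigma_hat"]
    b = curve[curve.condition == contrast].set_index("rf_size")["sigma_hat"]
    common = a.index.intersection(b.index)
    return pd.DataFrame({"rf_size": common, "ratio": (a[common] / b[common]).values})
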