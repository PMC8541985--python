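"""Per-eye stimulus frames: radial chequerboards and random-dot stereograms.

Luminance values live in [-1, +1] with mid-grey = 0.  Dot fields are drawn
at 40% coverage with 0.12-deg-radius dots, half white and half black.  The
interocular arrangement of the dots inside the aperture defines the
condition:

``correlated``
    matched dot patterns, horizontally offset by +/- disparity/2 per eye
    (right minus left = +disparity); background dots drawn independently
    per eye (binocularly uncorrelated).
``anticorrelated``
    matched positions, right-eye polarity negated; uncorrelated background.
``zero_disparity_correlated``
    matched patterns at zero offset; uncorrelated background.
``luminance``
    binocularly identical everywhere; aperture dots all share one polarity
    (carrying a net luminance difference, like the participants' stimulus,
    whose foreground reversed between fully black and fully white) while
    background dots are balanced.  ``polarity_style="flip"`` selects the
    alternative, variance-matched reading in which aperture dots negate
    the polarity they would have carried in the shared background pattern.
``motion``
    binocularly identical balanced dots; aperture dots carry velocity tags
    (half clockwise, half counter-clockwise at 7 deg/s) used by
    :func:`advance_dots` for frame-to-frame displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VisualFieldGrid

__all__ = [
    "StereoFrame",
    "DotField",
    "chequerboard_frame",
    "rds_frame",
    "advance_dots",
    "chequerboard_pattern",
]

DOT_DENSITY = 0.40
DOT_RADIUS = 0.12  # degrees
MOTION_SPEED = 7.0  # deg/s, tangential

RDS_MODES = (
    "correlated",
    "anticorrelated",
    "luminance",
    "motion",
    "zero_disparity_correlated",
)


@dataclass
class DotField:
    """Record of the dots composing one frame (cyclopean coordinates)."""

    positions: np.ndarray  # (N, 2) x, y in degrees
    polarity: np.ndarray  # (N,) +1 / -1 as drawn in the LEFT eye
    radius: float
    eye_offset: np.ndarray  # (N,) horizontal half-shift: left -off, right +off
    right_polarity_sign: np.ndarray  # (N,) +1 matched, -1 negated in right eye
    in_aperture: np.ndarray  # (N,) bool
    velocity: np.ndarray | None = None  # (N, 2) deg/s, aperture dots only


@dataclass
class StereoFrame:
    left: np.ndarray  # (H, W) float32 in [-1, 1]
    right: np.ndarray
    grid: VisualFieldGrid
    mode: str
    dots: DotField | None = None


def _balanced_polarities(n: int, rng: np.random.Generator, offset: int = 0) -> np.ndarray:
    """Random +/-1 polarities with (#white - #black) as close to ``-offset``
    as parity allows, so a companion set with imbalance ``offset`` keeps the
    whole frame balanced within one dot."""
    n_plus = int(np.clip(round((n - offset) / 2), 0, n))
    pol = np.full(n, -1.0)
    pol[:n_plus] = 1.0
    rng.shuffle(pol)
    return pol


def _n_dots(density: float, area: float, dot_radius: float) -> int:
    """Dot count giving the requested expected pixel coverage.

    Dots may overlap, so coverage follows 1 - (1 - a)^n for single-dot
    area fraction a; invert for n.
    """
    a = np.pi * dot_radius**2 / area
    return max(1, int(round(np.log1p(-density) / np.log1p(-a))))


def render_dots(
    grid: VisualFieldGrid,
    positions: np.ndarray,
    polarity: np.ndarray,
    dot_radius: float,
    out_sum: np.ndarray | None = None,
    out_cnt: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate dot polarities and coverage counts onto the pixel raster.

    A pixel belongs to a dot when its centre lies within ``dot_radius`` of
    the dot centre (sub-pixel positions respected).  Returns flat
    ``(sum, count)`` accumulators; see :func:`finalize_dots` for the
    overlap-resolution rule.
    """
    h, w = grid.shape
    img = np.zeros(h * w, dtype=np.float64) if out_sum is None else out_sum
    cnt = np.zeros(h * w, dtype=np.float64) if out_cnt is None else out_cnt
    if len(positions) == 0:
        return img, cnt
    ppd = grid.pixels_per_degree
    half = (w - 1) // 2
    cx = positions[:, 0] * ppd + half  # fractional column
    cy = half - positions[:, 1] * ppd  # fractional row
    r_px = dot_radius * ppd
    reach = int(np.ceil(r_px + 0.5))
    c0 = np.floor(cx).astype(np.int64)
    r0 = np.floor(cy).astype(np.int64)
    fx = cx - c0
    fy = cy - r0
    pol = polarity.astype(np.float64)
    idx_parts, w_parts = [], []
    for dr in range(-reach, reach + 2):
        for dc in range(-reach, reach + 2):
            d2 = (dc - fx) ** 2 + (dr - fy) ** 2
            hit = d2 <= r_px**2
            if not hit.any():
                continue
            rr = r0[hit] + dr
            cc = c0[hit] + dc
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            if not ok.any():
                continue
            idx_parts.append(rr[ok] * w + cc[ok])
            w_parts.append(pol[hit][ok])
    if idx_parts:
        idx = np.concatenate(idx_parts)
        img += np.bincount(idx, weights=np.concatenate(w_parts), minlength=h * w)
        cnt += np.bincount(idx, minlength=h * w)
    return img, cnt


def finalize_dots(
    sum_img: np.ndarray, cnt_img: np.ndarray, tie_signs: np.ndarray, rsign: float = 1.0
) -> np.ndarray:
    """Resolve dot overlap: the signed sum clipped to [-1, +1]; covered
    pixels whose polarities cancel exactly take a balanced random sign
    (``tie_signs``, shared between eyes up to the anticorrelation sign)."""
    img = np.clip(sum_img, -1.0, 1.0)
    ties = (cnt_img > 0) & (sum_img == 0)
    img[ties] = rsign * tie_signs[ties]
    return img.astype(np.float32)


def _mask_lookup(grid: VisualFieldGrid, mask: np.ndarray, positions: np.ndarray) -> np.ndarray:
    row, col = grid.degrees_to_pixel(positions[:, 0], positions[:, 1])
    ok = (row >= 0) & (row < grid.shape[0]) & (col >= 0) & (col < grid.shape[1])
    inside = np.zeros(len(positions), dtype=bool)
    inside[ok] = mask[row[ok], col[ok]] > 0
    return inside


def rds_frame(
    grid: VisualFieldGrid,
    aperture_mask: np.ndarray,
    mode: str,
    disparity: float = 0.0,
    density: float = DOT_DENSITY,
    dot_radius: float = DOT_RADIUS,
    rng: np.random.Generator | None = None,
    luminance_polarity: float = 1.0,
    polarity_style: str = "uniform",
) -> StereoFrame:
    """Generate one random-dot stereogram frame for the given aperture."""
    if mode not in RDS_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if not 0 < density < 1:
        raise ValueError("density must lie in (0, 1)")
    if mode in ("luminance", "motion", "zero_disparity_correlated") and disparity != 0:
        raise ValueError(f"mode {mode!r} is a zero-disparity stimulus")
    if disparity != 0 and abs(disparity) * grid.pixels_per_degree < 1:
        raise ValueError("disparity finer than one pixel; increase pixels_per_degree")
    rng = np.random.default_rng() if rng is None else rng
    aperture_mask = np.asarray(aperture_mask)
    if aperture_mask.shape != grid.shape:
        raise ValueError("aperture mask does not match grid")

    he, r = grid.half_extent, dot_radius
    # dots are drawn with a one-radius margin beyond the field so edge
    # pixels see full density; the count uses the expanded draw area
    area = (2 * (he + r)) ** 2
    n = _n_dots(density, area, dot_radius)

    def draw(n_dots: int) -> np.ndarray:
        return rng.uniform(-he - r, he + r, size=(n_dots, 2))

    uncorrelated_bg = mode in ("correlated", "anticorrelated", "zero_disparity_correlated")
    h, w = grid.shape
    tie_signs = rng.choice([-1.0, 1.0], size=h * w)

    pos_a = draw(n)
    in_a = _mask_lookup(grid, aperture_mask, pos_a)
    if uncorrelated_bg:
        # set A supplies the left-eye background and the shared foreground;
        # set B supplies the independent right-eye background.  Each eye's
        # background offsets the foreground imbalance so drawn polarities
        # stay balanced within one dot per frame.
        pos_b = draw(n)
        in_b = _mask_lookup(grid, aperture_mask, pos_b)
        fg_pos = pos_a[in_a]
        fg_pol = _balanced_polarities(len(fg_pos), rng)
        off = disparity / 2.0 if mode in ("correlated", "anticorrelated") else 0.0
        rsign = -1.0 if mode == "anticorrelated" else 1.0
        bgl_pol = _balanced_polarities(int((~in_a).sum()), rng, offset=int(fg_pol.sum()))
        bgr_pol = _balanced_polarities(int((~in_b).sum()), rng, offset=int(rsign * fg_pol.sum()))
        lsum, lcnt = render_dots(grid, pos_a[~in_a], bgl_pol, r)
        render_dots(grid, fg_pos - [off, 0.0], fg_pol, r, out_sum=lsum, out_cnt=lcnt)
        rsum, rcnt = render_dots(grid, pos_b[~in_b], bgr_pol, r)
        render_dots(grid, fg_pos + [off, 0.0], rsign * fg_pol, r, out_sum=rsum, out_cnt=rcnt)
        left = finalize_dots(lsum, lcnt, tie_signs).reshape(h, w)
        right = finalize_dots(rsum, rcnt, tie_signs, rsign=rsign).reshape(h, w)
        dots = DotField(
            positions=np.concatenate([pos_a[~in_a], fg_pos, pos_b[~in_b]]),
            polarity=np.concatenate([bgl_pol, fg_pol, bgr_pol]),
            radius=r,
            eye_offset=np.concatenate(
                [np.zeros((~in_a).sum()), np.full(in_a.sum(), off), np.zeros((~in_b).sum())]
            ),
            right_polarity_sign=np.concatenate(
                [np.ones((~in_a).sum()), np.full(in_a.sum(), rsign), np.ones((~in_b).sum())]
            ),
            in_aperture=np.concatenate(
                [np.zeros((~in_a).sum(), bool), np.ones(in_a.sum(), bool), np.zeros((~in_b).sum(), bool)]
            ),
        )
    else:
        # binocularly identical field
        pol = _balanced_polarities(n, rng)
        vel = None
        if mode == "luminance":
            sign = float(np.sign(luminance_polarity) or 1.0)
            if polarity_style == "uniform":
                # participants' display: uniform-polarity foreground on a
                # balanced background
                pol[in_a] = sign
            elif polarity_style == "opposed":
                # model reading: aperture and background dots carry uniform,
                # mutually opposed polarities (variance-matched, opposed
                # mean luminance)
                pol = np.where(in_a, -sign, sign)
            elif polarity_style == "flip":
                pol[in_a] = -pol[in_a]
            else:
                raise ValueError("polarity_style must be 'uniform', 'opposed' or 'flip'")
        elif mode == "motion":
            vel = np.zeros((n, 2))
            idx = np.flatnonzero(in_a)
            cw = rng.permutation(len(idx)) < len(idx) // 2
            ecc = np.hypot(pos_a[idx, 0], pos_a[idx, 1])
            ang = np.arctan2(pos_a[idx, 1], pos_a[idx, 0])
            omega = np.where(ecc > 1e-9, MOTION_SPEED / np.maximum(ecc, 1e-9), 0.0)
            omega = np.where(cw, -omega, omega)
            vel[idx, 0] = -omega * ecc * np.sin(ang)
            vel[idx, 1] = omega * ecc * np.cos(ang)
        lsum, lcnt = render_dots(grid, pos_a, pol, r)
        left = finalize_dots(lsum, lcnt, tie_signs).reshape(h, w)
        right = left.copy()
        dots = DotField(
            positions=pos_a,
            polarity=pol,
            radius=r,
            eye_offset=np.zeros(n),
            right_polarity_sign=np.ones(n),
            in_aperture=in_a,
            velocity=vel,
        )
    return StereoFrame(left=left, right=right, grid=grid, mode=mode, dots=dots)


def advance_dots(frame: StereoFrame, dt: float, rng: np.random.Generator | None = None) -> StereoFrame:
    """Displace motion-tagged dots by ``velocity * dt`` and re-render."""
    if frame.dots is None or frame.dots.velocity is None:
        raise ValueError("frame carries no velocity tags")
    d = frame.dots
    pos = d.positions + d.velocity * dt
    h, w = frame.grid.shape
    ties = np.ones(h * w) if rng is None else rng.choice([-1.0, 1.0], size=h * w)
    lsum, lcnt = render_dots(frame.grid, pos, d.polarity, d.radius)
    left = finalize_dots(lsum, lcnt, ties).reshape(h, w)
    dots = DotField(pos, d.polarity, d.radius, d.eye_offset, d.right_polarity_sign, d.in_aperture, d.velocity)
    return StereoFrame(left=left, right=left.copy(), grid=frame.grid, mode=frame.mode, dots=dots)


def _ring_edges(half_extent: float, ring_min: float, ring_max: float) -> np.ndarray:
    """Radial segment boundaries with log-scaled (geometric) widths."""
    if ring_min >= ring_max:
        raise ValueError("ring_min must be smaller than ring_max")
    # smallest n whose geometric widths ring_min..ring_max sum past the field
    # edge, then rescale so the boundaries end exactly at half_extent.
    for n in range(2, 10000):
        q = (ring_max / ring_min) ** (1.0 / (n - 1))
        total = ring_min * (q**n - 1) / (q - 1)
        if total >= half_extent:
            break
    widths = ring_min * q ** np.arange(n)
    widths *= half_extent / widths.sum()
    return np.concatenate([[0.0], np.cumsum(widths)])


def chequerboard_pattern(
    grid: VisualFieldGrid,
    angular_segment: float = 5.0,
    ring_min: float = 0.016,
    ring_max: float = 0.49,
) -> np.ndarray:
    """Radial chequerboard: alternating sign across 5-deg angular sectors and
    log-scaled radial segments (geometric widths between ring_min and
    ring_max, rescaled to tile the field exactly)."""
    edges = _ring_edges(grid.half_extent, ring_min, ring_max)
    ecc = grid.eccentricity()
    ring_idx = np.searchsorted(edges, ecc, side="right") - 1
    ang = (np.degrees(grid.polar_angle()) + 360.0) % 360.0
    sector_idx = np.floor(ang / angular_segment).astype(int)
    pattern = np.where((ring_idx + sector_idx) % 2 == 0, 1.0, -1.0)
    pattern[ecc > grid.half_extent] = 0.0
    return pattern.astype(np.float32)


def chequerboard_frame(
    grid: VisualFieldGrid,
    contrast_phase: int = 1,
    angular_segment: float = 5.0,
    ring_min: float = 0.016,
    ring_max: float = 0.49,
) -> StereoFrame:
    """Binocularly identical contrast-reversing radial chequerboard."""
    if contrast_phase not in (1, -1):
        raise ValueError("contrast_phase must be +1 or -1")
    img = contrast_phase * chequerboard_pattern(grid, angular_segment, ring_min, ring_max)
    return StereoFrame(left=img, right=img.copy(), grid=grid, mode="chequerboard")
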