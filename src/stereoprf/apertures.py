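"""Aperture sequences: rotating wedge, expanding/contracting ring, sweeping bar.

An aperture sequence is a time-ordered stack of binary masks on a shared
:class:`~stereoprf.grid.VisualFieldGrid`.  The masks drive both the pRF
forward model (via Gaussian-mask overlap) and the energy-model stimulation
(by gating where stimulus content is drawn).  Scan designs insert blank
(all-zero) volumes used to estimate the baseline response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VisualFieldGrid

__all__ = [
    "ApertureSequence",
    "wedge_aperture",
    "ring_aperture",
    "bar_aperture",
    "scan_design",
]

DEFAULT_TR = 2.488  # seconds per volume
DEFAULT_N_VOLUMES = 168
DEFAULT_N_BLANKS = 24
# 18 volumes/cycle = 44.8 s, i.e. a stimulus fundamental of 0.022 Hz, so the
# 0.02 Hz preprocessing high-pass leaves the retinotopic signal intact
DEFAULT_CYCLE_VOLUMES = 18
FIXATION_CUTOUT = 0.5  # degrees; radial cut-out around fixation


@dataclass
class ApertureSequence:
    """Ordered binary aperture masks with per-frame blank flags."""

    masks: np.ndarray  # (T, H, W) uint8, strictly binary
    grid: VisualFieldGrid
    frame_interval: float  # seconds per mask
    condition_label: str = ""
    blank_flags: np.ndarray = field(default=None)  # (T,) bool

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError("masks must be (T, H, W)")
        if self.masks.shape[1:] != self.grid.shape:
            raise ValueError("masks do not match the grid shape")
        vals = np.unique(self.masks)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("masks must be strictly binary")
        self.masks = self.masks.astype(np.uint8)
        if self.blank_flags is None:
            self.blank_flags = ~self.masks.any(axis=(1, 2))
        self.blank_flags = np.asarray(self.blank_flags, dtype=bool)
        if self.blank_flags.shape != (len(self.masks),):
            raise ValueError("blank_flags length mismatch")
        if np.any(self.masks[self.blank_flags]):
            raise ValueError("blank frames must be all-zero masks")

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def n_blank(self) -> int:
        return int(self.blank_flags.sum())

    @property
    def duration(self) -> float:
        return len(self) * self.frame_interval

    def concatenate(self, other: "ApertureSequence") -> "ApertureSequence":
        if other.grid.shape != self.grid.shape:
            raise ValueError("grids differ")
        return ApertureSequence(
            np.concatenate([self.masks, other.masks]),
            self.grid,
            self.frame_interval,
            condition_label=f"{self.condition_label}+{other.condition_label}",
            blank_flags=np.concatenate([self.blank_flags, other.blank_flags]),
        )


def _annulus(grid: VisualFieldGrid, inner: float, outer: float) -> np.ndarray:
    ecc = grid.eccentricity()
    return (ecc >= inner) & (ecc <= outer)


def wedge_aperture(
    grid: VisualFieldGrid,
    n_volumes: int,
    direction: str = "ccw",
    cycle_volumes: int = DEFAULT_CYCLE_VOLUMES,
    wedge_width: float = 20.0,
    inner_cutout: float = FIXATION_CUTOUT,
    frame_interval: float = DEFAULT_TR,
    start_angle: float = 90.0,
) -> ApertureSequence:
    """Rotating wedge: a ``wedge_width``-degree angular sector of the annulus
    between ``inner_cutout`` and the field edge, advancing 360/cycle_volumes
    degrees per volume.

    ``direction`` is "ccw" (counter-clockwise, increasing polar angle) or
    "cw".  ``start_angle`` is the sector-centre polar angle of the first
    frame, in degrees counter-clockwise from the +x axis.
    """
    if not 0 < wedge_width < 360:
        raise ValueError("wedge_width must lie in (0, 360) degrees")
    if direction not in ("cw", "ccw"):
        raise ValueError("direction must be 'cw' or 'ccw'")
    if n_volumes % cycle_volumes:
        raise ValueError("cycle_volumes must divide n_volumes")
    annulus = _annulus(grid, inner_cutout, grid.half_extent)
    angle = np.degrees(grid.polar_angle())  # (-180, 180]
    step = 360.0 / cycle_volumes
    sign = 1.0 if direction == "ccw" else -1.0
    masks = np.empty((n_volumes, *grid.shape), dtype=np.uint8)
    for t in range(n_volumes):
        centre = start_angle + sign * step * t
        delta = np.abs((angle - centre + 180.0) % 360.0 - 180.0)
        masks[t] = (annulus & (delta <= wedge_width / 2.0)).astype(np.uint8)
    return ApertureSequence(masks, grid, frame_interval, condition_label=f"wedge-{direction}")


def ring_aperture(
    grid: VisualFieldGrid,
    n_volumes: int,
    direction: str = "expand",
    cycle_volumes: int = DEFAULT_CYCLE_VOLUMES,
    duty: float = 0.25,
    inner_cutout: float = FIXATION_CUTOUT,
    frame_interval: float = DEFAULT_TR,
) -> ApertureSequence:
    """Expanding/contracting ring sweeping log-spaced eccentricities.

    Each pixel's eccentricity is mapped to a phase in [0, 1) on a log scale
    between ``inner_cutout`` and the field edge; frame t stimulates the
    phase window [t/cycle, t/cycle + duty) with wrap-around, so the ring
    thickness is a fixed ``duty`` fraction of the log-eccentricity cycle.
    """
    if not 0 < duty < 1:
        raise ValueError("duty must lie in (0, 1)")
    if grid.half_extent <= inner_cutout:
        raise ValueError("grid half_extent must exceed inner_cutout")
    if direction not in ("expand", "contract"):
        raise ValueError("direction must be 'expand' or 'contract'")
    if n_volumes % cycle_volumes:
        raise ValueError("cycle_volumes must divide n_volumes")
    ecc = grid.eccentricity()
    annulus = _annulus(grid, inner_cutout, grid.half_extent)
    span = np.log(grid.half_extent) - np.log(inner_cutout)
    phase = np.zeros_like(ecc)
    phase[annulus] = (np.log(ecc[annulus]) - np.log(inner_cutout)) / span
    masks = np.empty((n_volumes, *grid.shape), dtype=np.uint8)
    for t in range(n_volumes):
        k = t if direction == "expand" else cycle_volumes - 1 - (t % cycle_volumes)
        start = (k % cycle_volumes) / cycle_volumes
        inside = ((phase - start) % 1.0) < duty
        masks[t] = (annulus & inside).astype(np.uint8)
    return ApertureSequence(masks, grid, frame_interval, condition_label=f"ring-{direction}")


def bar_aperture(
    grid: VisualFieldGrid,
    n_steps: int = 100,
    bar_width: float = 1.0,
    orientation: str = "vertical",
    frame_interval: float = 1.0,
    sweep_half_extent: float | None = None,
) -> ApertureSequence:
    """Straight bar translating across the field in equal increments.

    ``orientation`` is the orientation of the bar itself: a "vertical" bar
    sweeps horizontally (left to right), a "horizontal" bar sweeps upward.
    ``sweep_half_extent`` optionally restricts the sweep to a sub-range of
    the field (bar centres in [-s, +s]); the default traverses the full
    field edge to edge.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if bar_width > 2 * grid.half_extent:
        raise ValueError("bar wider than the field")
    if orientation not in ("vertical", "horizontal"):
        raise ValueError("orientation must be 'vertical' or 'horizontal'")
    s = grid.half_extent if sweep_half_extent is None else float(sweep_half_extent)
    centres = np.linspace(-s, s, n_steps)
    coord = grid.x_coords if orientation == "vertical" else grid.y_coords[::-1]
    masks = np.zeros((n_steps, *grid.shape), dtype=np.uint8)
    for t, c in enumerate(centres):
        line = (np.abs(coord - c) <= bar_width / 2.0).astype(np.uint8)
        if orientation == "vertical":
            masks[t, :, :] = line[None, :]
        else:
            masks[t, :, :] = line[::-1, None]
    seq = ApertureSequence(masks, grid, frame_interval, condition_label=f"bar-{orientation}")
    seq.bar_centres = centres
    return seq


def scan_design(
    condition: str,
    aperture_type: str,
    grid: VisualFieldGrid,
    n_volumes: int = DEFAULT_N_VOLUMES,
    n_blanks: int = DEFAULT_N_BLANKS,
    tr: float = DEFAULT_TR,
    cycle_volumes: int = DEFAULT_CYCLE_VOLUMES,
    n_blank_blocks: int = 4,
    **kwargs,
) -> ApertureSequence:
    """Full-run aperture sequence with blank volumes in contiguous blocks.

    Only aperture geometry is encoded: the dot/chequerboard content of a
    condition does not alter the design matrix used for pRF fitting.  The
    default run is 168 volumes at TR 2.488 s with 24 blanks split into four
    6-volume blocks, one after each 36-volume aperture cycle.
    """
    if n_blanks >= n_volumes:
        raise ValueError("n_blanks must be smaller than n_volumes")
    if n_blanks % n_blank_blocks:
        raise ValueError("n_blanks must divide evenly into blocks")
    n_stim = n_volumes - n_blanks
    makers = {
        "wedge-cw": lambda n: wedge_aperture(grid, n, "cw", cycle_volumes, frame_interval=tr, **kwargs),
        "wedge-ccw": lambda n: wedge_aperture(grid, n, "ccw", cycle_volumes, frame_interval=tr, **kwargs),
        "ring-exp": lambda n: ring_aperture(grid, n, "expand", cycle_volumes, frame_interval=tr, **kwargs),
        "ring-con": lambda n: ring_aperture(grid, n, "contract", cycle_volumes, frame_interval=tr, **kwargs),
        "bar": lambda n: bar_aperture(grid, n, frame_interval=tr, **kwargs),
    }
    if aperture_type not in makers:
        raise ValueError(f"unknown aperture_type {aperture_type!r}")
    stim = makers[aperture_type](n_stim)
    block = n_blanks // n_blank_blocks
    seg = n_stim // n_blank_blocks
    masks, flags = [], []
    zero = np.zeros((block, *grid.shape), dtype=np.uint8)
    for b in range(n_blank_blocks):
        masks.append(stim.masks[b * seg : (b + 1) * seg])
        flags.append(np.zeros(seg, dtype=bool))
        masks.append(zero)
        flags.append(np.ones(block, dtype=bool))
    # any remainder of stimulated volumes goes at the end
    if n_blank_blocks * seg < n_stim:
        masks.append(stim.masks[n_blank_blocks * seg :])
        flags.append(np.zeros(n_stim - n_blank_blocks * seg, dtype=bool))
    return ApertureSequence(
        np.concatenate(masks),
        grid,
        tr,
        condition_label=f"{condition}:{aperture_type}",
        blank_flags=np.concatenate(flags),
    )
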