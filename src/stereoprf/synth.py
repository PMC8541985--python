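"""Synthetic cortices, meshes and BOLD runs with known ground truth.

The generator emulates the statistical structure the pRF analysis assumes:
per-vertex Gaussian receptive fields whose size grows linearly with
eccentricity (with condition-specific intercept/slope), scan runs of 168
volumes at TR 2.488 s including blank periods, several repeats per
condition, and additive noise with temporal autocorrelation and slow
drift.  Ground truth is kept strictly separate from the generated BOLD
tables so that recovery tests cannot leak it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .apertures import ApertureSequence
from .hrf import HRFParams, hrf_kernel
from .prf import GaussianPRF, PredictionBank, _convolve_kernel, _drive_series

__all__ = [
    "SigmaRule",
    "NoiseSpec",
    "SyntheticCortex",
    "Mesh",
    "synth_cortex",
    "synth_bold",
    "synth_mesh",
]


@dataclass(frozen=True)
class SigmaRule:
    """Linear eccentricity scaling of pRF size: sigma = intercept + slope*ecc."""

    intercept: float
    slope: float

    def __call__(self, ecc: np.ndarray) -> np.ndarray:
        s = self.intercept + self.slope * np.asarray(ecc)
        if np.any(s <= 0):
            raise ValueError("sigma rule produced non-positive sizes")
        return s


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise: white + AR(1) + slow drift (below the 0.02 Hz
    high-pass cut-off, so preprocessing emulation can remove it).

    ``relative=True`` expresses the white/AR SDs as multiples of each
    vertex's noiseless prediction SD.
    """

    white_sd: float = 1.0
    ar1_coef: float = 0.3
    ar1_sd: float = 0.0
    drift_amplitude: float = 0.0
    drift_freq: float = 0.01  # Hz, below the 0.02 Hz cut-off
    relative: bool = True


@dataclass
class SyntheticCortex:
    """Ground-truth pRF maps for one or more stimulus conditions."""

    truth: dict[str, pd.DataFrame]  # condition -> vertex table (x, y, sigma, ...)
    seed: int

    @property
    def n_vertices(self) -> int:
        return len(next(iter(self.truth.values())))

    def prfs(self, condition: str) -> list[GaussianPRF]:
        t = self.truth[condition]
        return [GaussianPRF(r.x, r.y, r.sigma) for r in t.itertuples()]


@dataclass
class Mesh:
    coords: np.ndarray  # (N, d) millimetres
    edges: np.ndarray  # (E, 2) vertex index pairs

    @property
    def n_vertices(self) -> int:
        return len(self.coords)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg


def synth_cortex(
    n_vertices: int,
    ecc_range: tuple[float, float] = (0.5, 8.0),
    sigma_rules: dict[str, SigmaRule] | None = None,
    seed: int = 0,
) -> SyntheticCortex:
    """Vertices with eccentricities uniform in visual-field area, polar
    angles uniform, and ground-truth pRFs per condition from the linear
    size-eccentricity rules.

    The default rules mirror the qualitative V1 pattern (disparity sizes
    above chequerboard/luminance) purely as a synthetic demonstration.
    """
    if sigma_rules is None:
        sigma_rules = {
            "chequerboard": SigmaRule(0.7, 0.25),
            "luminance": SigmaRule(0.9, 0.25),
            "correlated_disparity": SigmaRule(1.3, 0.25),
        }
    rng = np.random.default_rng(seed)
    r0, r1 = ecc_range
    ecc = np.sqrt(rng.uniform(r0**2, r1**2, size=n_vertices))
    ang = rng.uniform(0, 2 * np.pi, size=n_vertices)
    x = ecc * np.cos(ang)
    y = ecc * np.sin(ang)
    truth = {}
    for cond, rule in sigma_rules.items():
        truth[cond] = pd.DataFrame(
            {
                "vertex_id": np.arange(n_vertices),
                "x": x,
                "y": y,
                "eccentricity": ecc,
                "polar_angle": ang,
                "sigma": rule(ecc),
            }
        )
    return SyntheticCortex(truth=truth, seed=seed)


def _ar1(rng: np.random.Generator, n: int, coef: float, sd: float, size: int) -> np.ndarray:
    """Stationary AR(1) rows with marginal SD ``sd``."""
    innov_sd = sd * np.sqrt(1 - coef**2)
    out = np.empty((size, n))
    out[:, 0] = rng.normal(0, sd, size)
    eps = rng.normal(0, innov_sd, (size, n - 1))
    for t in range(1, n):
        out[:, t] = coef * out[:, t - 1] + eps[:, t - 1]
    return out


def synth_bold(
    cortex: SyntheticCortex,
    condition: str,
    design: ApertureSequence,
    hrf: HRFParams = HRFParams(),
    n_runs: int = 4,
    noise: NoiseSpec = NoiseSpec(),
    amplitude: float = 1.0,
    seed: int | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-run vertex-by-time BOLD with shared signal and independent noise.

    Returns ``(runs, clean)`` where ``clean`` is the noiseless prediction
    matrix (the signal shared by all runs).
    """
    rng = np.random.default_rng(cortex.seed + 1 if seed is None else seed)
    kernel = hrf_kernel(hrf, design.frame_interval)
    prfs = cortex.prfs(condition)
    T = len(design)
    clean = np.empty((len(prfs), T))
    for v, prf in enumerate(prfs):
        clean[v] = amplitude * _convolve_kernel(_drive_series(prf, design, exact=True), kernel)
    sd_ref = clean.std(axis=1, keepdims=True) if noise.relative else np.ones((len(prfs), 1))
    runs = []
    t = np.arange(T) * design.frame_interval
    for _ in range(n_runs):
        eps = rng.normal(0.0, 1.0, clean.shape) * (noise.white_sd * sd_ref)
        if noise.ar1_sd > 0:
            eps += _ar1(rng, T, noise.ar1_coef, 1.0, len(prfs)) * (noise.ar1_sd * sd_ref)
        if noise.drift_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi, (len(prfs), 1))
            eps += noise.drift_amplitude * np.cos(2 * np.pi * noise.drift_freq * t[None, :] + phase)
        runs.append(clean + eps)
    return runs, clean


def synth_mesh(n_vertices: int, spacing_mm: float = 2.0, kind: str = "planar") -> Mesh:
    """Regular test mesh in millimetre coordinates.

    "planar" builds a square lattice (4-connected interior) holding exactly
    ``n_vertices`` vertices; "spherical" distributes vertices on a sphere
    by a Fibonacci lattice with convex-hull adjacency, scaled so the median
    nearest-neighbour spacing equals ``spacing_mm``.
    """
    if n_vertices < 9:
        raise ValueError("need at least 9 vertices")
    if kind == "planar":
        side = int(np.ceil(np.sqrt(n_vertices)))
        ii, jj = np.divmod(np.arange(n_vertices), side)
        coords = np.column_stack([jj * spacing_mm, ii * spacing_mm]).astype(float)
        edges = []
        for v in range(n_vertices):
            if jj[v] + 1 < side and v + 1 < n_vertices and ii[v] == ii[v + 1]:
                edges.append((v, v + 1))
            if v + side < n_vertices:
                edges.append((v, v + side))
        return Mesh(coords=coords, edges=np.asarray(edges))
    if kind == "spherical":
        from scipy.spatial import ConvexHull

        k = np.arange(n_vertices)
        golden = (1 + np.sqrt(5)) / 2
        z = 1 - 2 * (k + 0.5) / n_vertices
        theta = 2 * np.pi * k / golden
        r = np.sqrt(1 - z**2)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        hull = ConvexHull(pts)
        e = set()
        for simplex in hull.simplices:
            for a, b in ((0, 1), (1, 2), (0, 2)):
                e.add((min(simplex[a], simplex[b]), max(simplex[a], simplex[b])))
        edges = np.asarray(sorted(e))
        d = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
        pts *= spacing_mm / np.median(d)
        return Mesh(coords=pts, edges=edges)
    raise ValueError("kind must be 'planar' or 'spherical'")
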