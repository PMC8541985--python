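"""Gaussian pRF forward model and two-stage estimation.

The population receptive field at one vertex is a radially symmetric 2-D
Gaussian (x, y, sigma) in degrees of visual angle.  The forward model is
the overlap of the unit-volume Gaussian with the binary stimulus aperture
at each volume, convolved with the HRF; amplitude and baseline are solved
per candidate by ordinary least squares, which makes the stage-1
correlation objective and the stage-2 variance-explained objective
consistent.  Stage 1 is an exhaustive grid search (on spatially smoothed
series when a mesh is available); stage 2 refines the winning grid point
with Nelder-Mead on the unsmoothed series.  Model validation uses the
split-half normalised correlation coefficient (CCnorm), which divides the
prediction-to-mean-response correlation by the maximum correlation
achievable given the across-repeat reliability of the signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .apertures import ApertureSequence
from .grid import VisualFieldGrid
from .hrf import HRFParams, Timeseries, hrf_kernel

__all__ = [
    "GaussianPRF",
    "FitResult",
    "GridSpec",
    "PredictionBank",
    "gaussian_image",
    "gaussian_overlap",
    "predict_timeseries",
    "grid_search",
    "refine_fit",
    "fit_vertex",
    "fit_many",
    "ccnorm",
    "filter_results",
    "results_table",
    "highpass_filter",
]

SIGMA_BOUNDS = (0.05, 10.0)  # degrees, refinement search range
NM_XATOL = 1e-5
NM_FATOL = 1e-9  # objective is 1 - R^2; parameter-level precision requires
# far finer function tolerance than the R^2 scale suggests
NM_MAXITER = 600


@dataclass(frozen=True)
class GaussianPRF:
    """Radially symmetric 2-D Gaussian receptive field."""

    x: float
    y: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x, self.y))

    @property
    def polar_angle(self) -> float:
        """Radians, counter-clockwise from the +x axis."""
        return float(np.arctan2(self.y, self.x))


@dataclass
class FitResult:
    prf: GaussianPRF | None
    variance_explained: float
    ccnorm: float = np.nan
    amplitude: float = np.nan
    baseline: float = np.nan
    converged: bool = False
    n_iterations: int = 0
    ccnorm_reliable: bool = True


@dataclass(frozen=True)
class GridSpec:
    """Stage-1 search grid.  Defaults bracket the sizes seen empirically:
    21 x/y steps across the field and 16 log-spaced sigmas 0.1-5 deg."""

    x: np.ndarray
    y: np.ndarray
    sigma: np.ndarray

    @classmethod
    def default(cls, half_extent: float, n_xy: int = 21, n_sigma: int = 16,
                sigma_range: tuple[float, float] = (0.1, 5.0)) -> "GridSpec":
        pts = np.linspace(-half_extent, half_extent, n_xy)
        sig = np.geomspace(*sigma_range, n_sigma)
        return cls(x=pts, y=pts, sigma=sig)


def gaussian_image(prf: GaussianPRF, grid: VisualFieldGrid, truncate: float | None = None) -> np.ndarray:
    """Unit-volume Gaussian sampled on the grid (pixel-sum x pixel area = 1
    up to truncation at the field edge)."""
    gx = np.exp(-0.5 * ((grid.x_coords - prf.x) / prf.sigma) ** 2)
    gy = np.exp(-0.5 * ((grid.y_coords - prf.y) / prf.sigma) ** 2)
    img = np.outer(gy, gx) / (2 * np.pi * prf.sigma**2)
    if truncate is not None:
        img[np.add.outer((grid.y_coords - prf.y) ** 2, (grid.x_coords - prf.x) ** 2)
            > (truncate * prf.sigma) ** 2] = 0.0
    return img


def gaussian_overlap(prf: GaussianPRF, mask: np.ndarray, grid: VisualFieldGrid) -> float:
    """Integral of the unit-volume Gaussian over the masked region."""
    if mask.shape != grid.shape:
        raise ValueError("mask does not match grid")
    if prf.sigma < grid.pixel_size:
        warnings.warn("sigma below one pixel; overlap is resolution-limited", RuntimeWarning)
    return float(np.einsum("hw,hw->", mask.astype(np.float64), gaussian_image(prf, grid)) * grid.pixel_area)


FIT_PPD = 5.0  # raster density used when evaluating drive integrals


def _fit_raster(design: ApertureSequence, exact: bool = False):
    """Cached float32 (possibly pooled) mask raster for drive integrals.

    The Gaussian-mask overlap is smooth, so the integral is evaluated on a
    block-averaged raster of about FIT_PPD pixels/degree: masks become
    fractional coverage values, the integral is unchanged to O(px^2) and
    the inner products shrink by the pooling factor squared.
    """
    cache = getattr(design, "_fit_raster_cache", None)
    if cache is None:
        cache = design._fit_raster_cache = {}
    grid = design.grid
    factor = 1 if exact else max(1, int(round(grid.pixels_per_degree / FIT_PPD)))
    if factor in cache:
        return cache[factor]
    masks = design.masks.astype(np.float32)
    xs, ys = grid.x_coords, grid.y_coords
    if factor > 1:
        T, H, W = masks.shape
        Hp, Wp = H // factor, W // factor
        masks = (
            masks[:, : Hp * factor, : Wp * factor]
            .reshape(T, Hp, factor, Wp, factor)
            .mean(axis=(2, 4))
        )
        xs = xs[: Wp * factor].reshape(Wp, factor).mean(axis=1)
        ys = ys[: Hp * factor].reshape(Hp, factor).mean(axis=1)
    raster = (masks, xs.astype(np.float64), ys.astype(np.float64), grid.pixel_area * factor**2)
    cache[factor] = raster
    return raster


def _drive_series(prf: GaussianPRF, design: ApertureSequence, exact: bool = False) -> np.ndarray:
    """Per-volume Gaussian-mask overlap (neural drive); blanks give zero."""
    masks, xs, ys, px_area = _fit_raster(design, exact=exact)
    # evaluate the Gaussian only inside a 5-sigma bounding box for speed
    r = 5.0 * prf.sigma
    c0, c1 = np.searchsorted(xs, [prf.x - r, prf.x + r])
    ys_asc = ys[::-1]
    r0r, r1r = np.searchsorted(ys_asc, [prf.y - r, prf.y + r])
    r0, r1 = len(ys) - r1r, len(ys) - r0r
    r0, r1 = max(r0, 0), min(r1, len(ys))
    c0, c1 = max(c0, 0), min(c1, len(xs))
    if r0 >= r1 or c0 >= c1:
        return np.zeros(len(design))
    gx = np.exp(-0.5 * ((xs[c0:c1] - prf.x) / prf.sigma) ** 2)
    gy = np.exp(-0.5 * ((ys[r0:r1] - prf.y) / prf.sigma) ** 2)
    g = (np.outer(gy, gx) / (2 * np.pi * prf.sigma**2)).astype(np.float32)
    sub = masks[:, r0:r1, c0:c1]
    return np.einsum("thw,hw->t", sub, g, optimize=False).astype(np.float64) * px_area


def _convolve_kernel(drive: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(drive, kernel)[: len(drive)]


def predict_timeseries(prf: GaussianPRF, design: ApertureSequence, hrf: HRFParams) -> Timeseries:
    """BOLD prediction: aperture overlap per volume convolved with the HRF."""
    kernel = hrf_kernel(hrf, design.frame_interval)
    return Timeseries(_convolve_kernel(_drive_series(prf, design), kernel), design.frame_interval)


class PredictionBank:
    """Standardised predictions for every grid-spec candidate.

    Grid predictions are computed with separable Gaussian projections of
    the mask stack (one pass per sigma), which makes the exhaustive stage-1
    search cheap enough to run per design rather than per vertex.
    """

    def __init__(self, design: ApertureSequence, hrf: HRFParams, spec: GridSpec):
        self.design = design
        self.spec = spec
        kernel = hrf_kernel(hrf, design.frame_interval)
        masks, xs, ys, px_area = _fit_raster(design)
        T = len(design)
        nx, ny, ns = len(spec.x), len(spec.y), len(spec.sigma)
        params = np.empty((ns * ny * nx, 3))
        preds = np.empty((ns * ny * nx, T), dtype=np.float32)
        i = 0
        for s in spec.sigma:
            ky = np.exp(-0.5 * ((spec.y[:, None] - ys[None, :]) / s) ** 2).astype(np.float32)
            kx = np.exp(-0.5 * ((spec.x[:, None] - xs[None, :]) / s) ** 2).astype(np.float32)
            b = np.einsum("gh,thw->tgw", ky, masks)  # project rows
            d = np.einsum("tgw,xw->tgx", b, kx)  # then columns
            d *= px_area / (2 * np.pi * s**2)
            for gy in range(ny):
                for gx in range(nx):
                    drive = d[:, gy, gx]
                    params[i] = (spec.x[gx], spec.y[gy], s)
                    preds[i] = _convolve_kernel(drive, kernel)
                    i += 1
        self.params = params
        mu = preds.mean(axis=1, keepdims=True)
        sd = preds.std(axis=1, keepdims=True)
        self.valid = sd[:, 0] > 1e-12
        sd[~self.valid] = 1.0
        self.zpreds = (preds - mu) / sd


def grid_search(series: np.ndarray | Timeseries, bank: PredictionBank) -> GaussianPRF | None:
    """Best-correlating grid candidate; deterministic lowest-index tie-break.

    Returns ``None`` (flagged, no fit) for all-NaN or zero-variance input.
    """
    y = series.values if isinstance(series, Timeseries) else np.asarray(series, float)
    if np.any(~np.isfinite(y)) or y.std() == 0:
        return None
    z = (y - y.mean()) / y.std()
    r = bank.zpreds @ z.astype(np.float32) / len(z)
    r = np.where(bank.valid, r, -np.inf)
    best = int(np.argmax(r))  # argmax takes the first (lowest-index) maximum
    x, yy, s = bank.params[best]
    return GaussianPRF(x, yy, s)


def _ols_scale(pred: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares amplitude/baseline and resulting R^2 (free-signed)."""
    p = pred - pred.mean()
    ssp = float(p @ p)
    if ssp <= 1e-30:
        return 0.0, float(y.mean()), 0.0
    a = float(p @ (y - y.mean())) / ssp
    b = float(y.mean() - a * pred.mean())
    resid = y - (a * pred + b)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 0:
        return a, b, 0.0
    return a, b, 1.0 - float(resid @ resid) / sst


def refine_fit(
    series: np.ndarray | Timeseries,
    seed: GaussianPRF,
    design: ApertureSequence,
    hrf: HRFParams,
    maxiter: int = NM_MAXITER,
) -> FitResult:
    """Nelder-Mead refinement of (x, y, sigma) maximising variance explained.

    Sigma is optimised on a log scale (so it can never be driven
    non-positive); amplitude and baseline are solved in closed form per
    candidate.  The refinement never returns a fit worse than the seed.
    """
    y = series.values if isinstance(series, Timeseries) else np.asarray(series, float)
    kernel = hrf_kernel(hrf, design.frame_interval)

    def predict(theta: np.ndarray) -> np.ndarray:
        prf = GaussianPRF(theta[0], theta[1], float(np.exp(theta[2])))
        return _convolve_kernel(_drive_series(prf, design), kernel)

    def objective(theta: np.ndarray) -> float:
        if not SIGMA_BOUNDS[0] <= np.exp(theta[2]) <= SIGMA_BOUNDS[1]:
            return 1.0
        _, _, r2 = _ols_scale(predict(theta), y)
        return 1.0 - r2

    theta0 = np.array([seed.x, seed.y, np.log(seed.sigma)])
    # explicit initial simplex at physical scales (half a grid step in
    # position, ~15% in size): scipy's default perturbs zero coordinates
    # by 2.5e-4, which strands the search when a seed coordinate is 0
    steps = np.array([0.5, 0.5, 0.15])
    simplex = np.vstack([theta0, theta0 + np.diag(steps)])
    sol = optimize.minimize(
        objective,
        theta0,
        method="Nelder-Mead",
        options={
            "xatol": NM_XATOL,
            "fatol": NM_FATOL,
            "maxiter": maxiter,
            "initial_simplex": simplex,
        },
    )
    theta = sol.x if sol.fun <= objective(theta0) else theta0
    prf = GaussianPRF(theta[0], theta[1], float(np.exp(theta[2])))
    a, b, r2 = _ols_scale(predict(theta), y)
    return FitResult(
        prf=prf,
        variance_explained=r2,
        amplitude=a,
        baseline=b,
        converged=bool(sol.success),
        n_iterations=int(sol.nit),
    )


def fit_vertex(
    series: np.ndarray | Timeseries,
    design: ApertureSequence,
    hrf: HRFParams,
    bank: PredictionBank,
    smoothed_series: np.ndarray | None = None,
    repeats: list[np.ndarray] | None = None,
) -> FitResult:
    """Two-stage fit of one vertex; optional CCnorm from split-half repeats."""
    y = series.values if isinstance(series, Timeseries) else np.asarray(series, float)
    stage1 = y if smoothed_series is None else np.asarray(smoothed_series, float)
    seed = grid_search(stage1, bank)
    if seed is None:
        return FitResult(prf=None, variance_explained=np.nan, converged=False)
    res = refine_fit(y, seed, design, hrf)
    if repeats is not None:
        pred = predict_timeseries(res.prf, design, hrf).values
        res.ccnorm, res.ccnorm_reliable = _ccnorm_impl(pred, repeats)
    return res


def fit_many(
    series_matrix: np.ndarray,
    design: ApertureSequence,
    hrf: HRFParams,
    grid_spec: GridSpec | None = None,
    smoothed_matrix: np.ndarray | None = None,
    repeats_matrix: list[np.ndarray] | None = None,
) -> list[FitResult]:
    """Fit every row of a vertex-by-time matrix.

    ``smoothed_matrix`` supplies the stage-1 (spatially smoothed) series;
    ``repeats_matrix`` is a list of per-repeat vertex-by-time matrices used
    for CCnorm.
    """
    spec = grid_spec or GridSpec.default(design.grid.half_extent)
    bank = PredictionBank(design, hrf, spec)
    out = []
    for v in range(series_matrix.shape[0]):
        reps = [m[v] for m in repeats_matrix] if repeats_matrix is not None else None
        sm = smoothed_matrix[v] if smoothed_matrix is not None else None
        out.append(fit_vertex(series_matrix[v], design, hrf, bank, smoothed_series=sm, repeats=reps))
    return out


def _ccnorm_impl(pred: np.ndarray, repeats: list[np.ndarray]) -> tuple[float, bool]:
    reps = np.asarray(repeats, dtype=float)
    if reps.ndim != 2 or reps.shape[0] < 2:
        raise ValueError("need at least 2 repeats")
    if reps.shape[1] != len(pred):
        raise ValueError("repeats must align with the prediction")
    n = reps.shape[0]
    ybar = reps.mean(axis=0)
    # signal power: variance of the summed response minus summed variances,
    # over N(N-1) (split-half signal-power estimator)
    sp = (reps.sum(axis=0).var(ddof=1) - reps.var(axis=1, ddof=1).sum()) / (n * (n - 1))
    vp = pred.var(ddof=1)
    if sp <= 0 or vp == 0:
        return np.nan, False
    cov = float(np.cov(pred, ybar, ddof=1)[0, 1])
    return cov / np.sqrt(vp * sp), True


def ccnorm(prediction: np.ndarray | Timeseries, repeats: list[np.ndarray]) -> float:
    """Normalised correlation coefficient between a prediction and >= 2
    observed repeats.  Returns NaN (flagged unreliable) when the estimated
    signal power is non-positive."""
    pred = prediction.values if isinstance(prediction, Timeseries) else np.asarray(prediction, float)
    value, reliable = _ccnorm_impl(pred, repeats)
    if not reliable:
        warnings.warn("non-positive estimated signal power; CCnorm unreliable", RuntimeWarning)
    return value


def results_table(results: list[FitResult], vertex_ids: np.ndarray | None = None) -> pd.DataFrame:
    """Tabulate fits: vertex_id, x, y, sigma, eccentricity, polar_angle,
    variance_explained, ccnorm, converged."""
    rows = []
    ids = vertex_ids if vertex_ids is not None else np.arange(len(results))
    for vid, r in zip(ids, results):
        if r.prf is None:
            rows.append((vid, *[np.nan] * 5, r.variance_explained, r.ccnorm, False))
        else:
            rows.append(
                (vid, r.prf.x, r.prf.y, r.prf.sigma, r.prf.eccentricity, r.prf.polar_angle,
                 r.variance_explained, r.ccnorm, r.converged)
            )
    return pd.DataFrame(
        rows,
        columns=["vertex_id", "x", "y", "sigma", "eccentricity", "polar_angle",
                 "variance_explained", "ccnorm", "converged"],
    )


def filter_results(
    results: pd.DataFrame,
    ccnorm_min: float = 0.5,
    min_ecc: float = 0.5,
    max_ecc: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply the strict inclusion rules: keep CCnorm > ccnorm_min (a value
    exactly at the threshold is removed) and discard eccentricities below
    min_ecc or above max_ecc.  Returns (survivors, removal counts)."""
    cc_bad = ~(results["ccnorm"] > ccnorm_min)  # NaN counts as failing
    ecc_low = results["eccentricity"] < min_ecc
    ecc_high = (results["eccentricity"] > max_ecc) if max_ecc is not None else pd.Series(False, index=results.index)
    keep = ~(cc_bad | ecc_low | ecc_high.fillna(False))
    counts = {
        "removed_ccnorm": int(cc_bad.sum()),
        "removed_ecc_low": int(ecc_low.sum()),
        "removed_ecc_high": int(ecc_high.sum()) if max_ecc is not None else 0,
        "n_input": int(len(results)),
        "n_survivors": int(keep.sum()),
    }
    return results[keep].copy(), counts


def highpass_filter(values: np.ndarray, dt: float, cutoff: float = 0.02) -> np.ndarray:
    """Remove fluctuations below ``cutoff`` Hz (DC retained), emulating the
    scanner preprocessing drift removal."""
    v = np.asarray(values, dtype=float)
    f = np.fft.rfftfreq(len(v), dt)
    spec = np.fft.rfft(v)
    spec[(f > 0) & (f < cutoff)] = 0.0
    return np.fft.irfft(spec, n=len(v))
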