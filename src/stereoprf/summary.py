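"""Eccentricity-binned summaries, size regressions, ratio curves and reports.

Fitted pRF sizes are summarised in 0.75-deg eccentricity bins (half-open,
lower edge inclusive) with the across-replicate SEM, regressed linearly on
eccentricity (over bin means, as in the figures), and compared across
conditions through per-bin size ratios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EccBinSummary",
    "bin_by_eccentricity",
    "size_ecc_regression",
    "size_ratio_curve",
    "report",
    "save_report",
]

BIN_WIDTH = 0.75  # degrees


@dataclass
class EccBinSummary:
    table: pd.DataFrame  # bin_lo, bin_hi, mean_sigma, sem_sigma, count
    bin_width: float
    condition: str = ""

    def __post_init__(self) -> None:
        t = self.table
        if len(t) > 1 and not np.allclose(t.bin_lo.values[1:], t.bin_hi.values[:-1]):
            raise ValueError("bins must be contiguous and non-overlapping")


def bin_by_eccentricity(
    results: pd.DataFrame, bin_width: float = BIN_WIDTH, condition: str = ""
) -> EccBinSummary:
    """Per-bin mean and SEM of sigma over [k*w, (k+1)*w) eccentricity bins.

    Empty bins are reported as missing rows, not zeros; SEM is NaN for
    single-vertex bins.
    """
    ecc = results["eccentricity"].to_numpy()
    sig = results["sigma"].to_numpy()
    idx = np.floor(ecc / bin_width).astype(int)
    rows = []
    for k in sorted(set(idx)):
        vals = sig[idx == k]
        rows.append(
            (
                k * bin_width,
                (k + 1) * bin_width,
                float(vals.mean()),
                float(stats.sem(vals)) if len(vals) > 1 else np.nan,
                len(vals),
            )
        )
    table = pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "mean_sigma", "sem_sigma", "count"])
    # contiguity: insert missing bins as NaN rows so edges line up
    if len(table):
        ks = (table.bin_lo / bin_width).round().astype(int)
        full = pd.DataFrame(
            {
                "bin_lo": np.arange(ks.min(), ks.max() + 1) * bin_width,
                "bin_hi": (np.arange(ks.min(), ks.max() + 1) + 1) * bin_width,
            }
        )
        table = full.merge(table, on=["bin_lo", "bin_hi"], how="left")
        table["count"] = table["count"].fillna(0).astype(int)
    return EccBinSummary(table=table, bin_width=bin_width, condition=condition)


def size_ecc_regression(summary: EccBinSummary | pd.DataFrame, raw: bool = False):
    """OLS of sigma on eccentricity.

    By default the fit is to bin means (as in the figure captions).  With
    ``raw=True`` a raw fit-result table (columns eccentricity, sigma) is
    regressed vertex-wise instead; that option is a convenience, not the
    figure convention.

    Returns ``(slope, intercept, r_squared)``.
    """
    if raw:
        x = np.asarray(summary["eccentricity"], float)
        y = np.asarray(summary["sigma"], float)
    else:
        t = summary.table.dropna(subset=["mean_sigma"])
        x = (t.bin_lo + t.bin_hi).to_numpy() / 2.0
        y = t.mean_sigma.to_numpy()
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("need >= 2 distinct eccentricities to regress")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def size_ratio_curve(
    results_a: pd.DataFrame, results_b: pd.DataFrame, bin_width: float = BIN_WIDTH
) -> pd.DataFrame:
    """Per-bin ratio of mean sigma, condition a over condition b.

    Bins lacking either condition (or with a zero denominator) are
    omitted, the latter with a warning.
    """
    a = bin_by_eccentricity(results_a, bin_width).table.set_index("bin_lo")
    b = bin_by_eccentricity(results_b, bin_width).table.set_index("bin_lo")
    common = a.index.intersection(b.index)
    rows = []
    for k in common:
        ma, mb = a.loc[k, "mean_sigma"], b.loc[k, "mean_sigma"]
        if np.isnan(ma) or np.isnan(mb):
            continue
        if mb == 0:
            import warnings

            warnings.warn(f"zero denominator in bin {k}; bin omitted", RuntimeWarning)
            continue
        rows.append((k, k + bin_width, ma / mb))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "ratio"])


def report(
    fits: dict[str, pd.DataFrame] | None = None,
    filter_counts: dict[str, dict] | None = None,
    regressions: dict[str, tuple] | None = None,
    size_curves: pd.DataFrame | None = None,
) -> dict:
    """Consolidated machine-readable summary of a pipeline run.

    Missing artefacts are listed, not fatal; content is deterministic
    given the inputs.
    """
    out: dict = {"missing": []}
    if fits is None:
        out["missing"].append("fits")
        out["conditions"] = {}
    else:
        out["conditions"] = {
            c: {
                "n_vertices": int(len(t)),
                "mean_sigma": float(t["sigma"].mean()) if len(t) else None,
                "mean_ccnorm": float(t["ccnorm"].mean()) if len(t) and t["ccnorm"].notna().any() else None,
            }
            for c, t in fits.items()
        }
    if filter_counts is None:
        out["missing"].append("filter_counts")
    else:
        out["filter_attrition"] = filter_counts
    if regressions is None:
        out["missing"].append("regressions")
    else:
        out["size_ecc_regression"] = {
            c: {"slope": v[0], "intercept": v[1], "r_squared": v[2]} for c, v in regressions.items()
        }
    if size_curves is None:
        out["missing"].append("size_curves")
    else:
        out["energy_size_curves"] = size_curves.to_dict(orient="list")
    return out


def save_report(rep: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(rep, fh, indent=2, sort_keys=True)
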