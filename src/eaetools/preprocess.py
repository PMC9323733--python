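"""Two-channel array preprocessing.

Pipeline per array: Q-spline quantile normalization of the sample channel
against the reference channel, per-spot log2 ratios computed *without*
background subtraction (robust gene selection at the cost of attenuated
fold-change magnitudes near the detection limit), control-probe calibration
of the technical-noise model (detection limit from negative controls,
sigma_tech from replicated spike-in families), replicate outlier
elimination, and summarization to one record per gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate

from .simulate import EXPERIMENTAL, NEGATIVE_CONTROL, SPIKE_IN

__all__ = [
    "NormalizationCurve",
    "TechnicalNoiseModel",
    "PreprocessResult",
    "qspline_normalize",
    "compute_log_ratios",
    "estimate_detection_limit",
    "estimate_technical_variability",
    "calibrate_controls",
    "eliminate_replicate_outliers",
    "summarize_genes",
    "preprocess_scan",
]

FLOOR_INTENSITY = 1.0  # nonpositive intensities are floored here and flagged


class ConfigurationError(ValueError):
    """Raised when an array lacks the control spots an operation needs."""


def _log2_floored(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    floored = x < FLOOR_INTENSITY
    return np.log2(np.where(floored, FLOOR_INTENSITY, x)), floored


@dataclass
class NormalizationCurve:
    """Monotone mapping of sample-channel log2 intensity onto the reference
    channel's quantiles.

    The curve interpolates ``n_quantiles`` evenly spaced quantile pairs of
    the two channels (experimental spots only) with a cubic spline; if the
    spline is not monotone on the data range it falls back to monotone
    (PCHIP) interpolation.  Beyond the 2nd / (n-1)th knot the curve is
    extended linearly — the module's "modified" tail treatment, avoiding
    cubic extrapolation blow-up.
    """

    quantile_grid: np.ndarray
    sample_knots: np.ndarray
    reference_knots: np.ndarray
    monotone_fallback: bool
    _interior: object
    _lo_anchor: tuple[float, float, float]  # x, y, slope
    _hi_anchor: tuple[float, float, float]

    def __call__(self, log2_x: np.ndarray) -> np.ndarray:
        x = np.asarray(log2_x, dtype=float)
        y = np.asarray(self._interior(x), dtype=float)
        x_lo, y_lo, s_lo = self._lo_anchor
        x_hi, y_hi, s_hi = self._hi_anchor
        y = np.where(x < x_lo, y_lo + s_lo * (x - x_lo), y)
        y = np.where(x > x_hi, y_hi + s_hi * (x - x_hi), y)
        return y


def _fit_curve(x_knots: np.ndarray, y_knots: np.ndarray,
               grid: np.ndarray) -> NormalizationCurve:
    # strictly increasing x required; keep first occurrence, keep y monotone
    x_knots, idx = np.unique(x_knots, return_index=True)
    y_knots = np.maximum.accumulate(y_knots[idx])
    if x_knots.size < 4:
        raise ValueError("too few distinct quantile knots to fit a curve")
    fallback = False
    spline = interpolate.CubicSpline(x_knots, y_knots)
    dense = np.linspace(x_knots[0], x_knots[-1], 20 * x_knots.size)
    if np.any(spline(dense, 1) < -1e-12):
        spline = interpolate.PchipInterpolator(x_knots, y_knots)
        fallback = True
    s_lo = (y_knots[1] - y_knots[0]) / (x_knots[1] - x_knots[0])
    s_hi = (y_knots[-1] - y_knots[-2]) / (x_knots[-1] - x_knots[-2])
    return NormalizationCurve(
        quantile_grid=grid,
        sample_knots=x_knots,
        reference_knots=y_knots,
        monotone_fallback=fallback,
        _interior=spline,
        _lo_anchor=(float(x_knots[1]), float(y_knots[1]), float(s_lo)),
        _hi_anchor=(float(x_knots[-2]), float(y_knots[-2]), float(s_hi)),
    )


def qspline_normalize(
    scan: pd.DataFrame, n_quantiles: int = 100,
) -> tuple[pd.DataFrame, NormalizationCurve]:
    """Quantile-spline normalize the sample channel against the reference.

    The curve is fitted on experimental spots only (controls are excluded
    from the fit but transformed); the reference channel is left untouched.
    Order statistics (``inverted_cdf`` quantiles) are used as knots so the
    transform is exactly idempotent up to floating point.
    """
    exp = scan["probe_class"] == EXPERIMENTAL
    n_exp = int(exp.sum())
    if n_exp < 2 * n_quantiles:
        raise ValueError(
            f"need >= {2 * n_quantiles} experimental spots to fit "
            f"{n_quantiles} quantiles, got {n_exp}")
    s_log2, _ = _log2_floored(scan["intensity_sample"].to_numpy())
    r_log2, _ = _log2_floored(scan["intensity_reference"].to_numpy())
    grid = (np.arange(n_quantiles) + 0.5) / n_quantiles
    x_knots = np.quantile(s_log2[exp.to_numpy()], grid, method="inverted_cdf")
    y_knots = np.quantile(r_log2[exp.to_numpy()], grid, method="inverted_cdf")
    curve = _fit_curve(x_knots, y_knots, grid)
    out = scan.copy()
    out["intensity_sample"] = 2.0 ** curve(s_log2)
    return out, curve


def compute_log_ratios(scan: pd.DataFrame) -> pd.DataFrame:
    """Per-spot log2(sample/reference) and mean log2 intensity.

    No background subtraction anywhere.  Nonpositive intensities are floored
    at 1 linear unit and the spot flagged ``floored``.
    """
    s_log2, s_fl = _log2_floored(scan["intensity_sample"].to_numpy())
    r_log2, r_fl = _log2_floored(scan["intensity_reference"].to_numpy())
    return pd.DataFrame({
        "probe_id": scan["probe_id"].to_numpy(),
        "gene_id": scan["gene_id"].to_numpy(),
        "replicate_index": scan["replicate_index"].to_numpy(),
        "probe_class": scan["probe_class"].to_numpy(),
        "log2_ratio": s_log2 - r_log2,
        "mean_log2_intensity": (s_log2 + r_log2) / 2.0,
        "floored": s_fl | r_fl,
        "outlier_flag": False,
    })


@dataclass(frozen=True)
class TechnicalNoiseModel:
    """Control-probe calibration of one array.

    sigma_tech : robust SD (scaled MAD) of replicate log2 ratios within
        spike-in control families — the intra-array technical variability.
    detection_limit : mean + 2 SD of the negative controls' log2 intensity;
        genes averaging below it are "not expressed".
    dynamic_range : high quantile of experimental log2 intensity minus the
        detection limit.
    """

    sigma_tech: float
    detection_limit: float
    dynamic_range: float


def estimate_detection_limit(scan: pd.DataFrame) -> tuple[float, float]:
    """(detection_limit, dynamic_range) from negative-control spots."""
    neg = scan[scan["probe_class"] == NEGATIVE_CONTROL]
    if len(neg) < 10:
        raise ConfigurationError(
            f"need >= 10 negative-control spots, got {len(neg)}")
    s_log2, _ = _log2_floored(neg["intensity_sample"].to_numpy())
    r_log2, _ = _log2_floored(neg["intensity_reference"].to_numpy())
    mli = (s_log2 + r_log2) / 2.0
    limit = float(np.mean(mli) + 2.0 * np.std(mli, ddof=1))
    exp = scan[scan["probe_class"] == EXPERIMENTAL]
    if exp.empty:
        return limit, float("nan")
    es, _ = _log2_floored(exp["intensity_sample"].to_numpy())
    er, _ = _log2_floored(exp["intensity_reference"].to_numpy())
    high = float(np.quantile((es + er) / 2.0, 0.99))
    return limit, high - limit


def estimate_technical_variability(scan: pd.DataFrame) -> float:
    """sigma_tech: pooled scaled-MAD of within-family deviations of the
    spike-in control log2 ratios.

    Families (replicated control probes) need >= 10 spots to contribute.
    MAD-based so that a single gross artifact among the controls barely
    moves the estimate.
    """
    spikes = scan[scan["probe_class"] == SPIKE_IN]
    if spikes.empty:
        raise ConfigurationError("no spike-in control spots on the array")
    s_log2, _ = _log2_floored(spikes["intensity_sample"].to_numpy())
    r_log2, _ = _log2_floored(spikes["intensity_reference"].to_numpy())
    ratios = pd.Series(s_log2 - r_log2, index=spikes["probe_id"].to_numpy())
    deviations = []
    for _, fam in ratios.groupby(level=0):
        if len(fam) >= 10:
            deviations.append(fam.to_numpy() - np.median(fam.to_numpy()))
    if not deviations:
        raise ConfigurationError(
            "no replicated control family with >= 10 spots")
    pooled = np.concatenate(deviations)
    return float(1.4826 * np.median(np.abs(pooled)))


def calibrate_controls(scan: pd.DataFrame) -> TechnicalNoiseModel:
    limit, dyn = estimate_detection_limit(scan)
    sigma = estimate_technical_variability(scan)
    return TechnicalNoiseModel(sigma_tech=sigma, detection_limit=limit,
                               dynamic_range=dyn)


def eliminate_replicate_outliers(
    table: pd.DataFrame,
    noise: TechnicalNoiseModel,
    k: float = 4.0,
) -> pd.DataFrame:
    """Flag replicate spots whose log2 ratio sits more than ``k * sigma_tech``
    from their gene's replicate median.

    At most one replicate per gene is flagged (the largest deviation wins;
    on an exact tie the spot with the lowest replicate index is retained).
    Returns a copy with ``outlier_flag`` set; only experimental spots are
    eligible.  If sigma_tech is not positive the step is skipped with a
    warning.
    """
    out = table.copy()
    out["outlier_flag"] = False
    if noise.sigma_tech <= 0:
        warnings.warn("sigma_tech <= 0; replicate outlier elimination skipped")
        return out
    exp = out[out["probe_class"] == EXPERIMENTAL]
    med = exp.groupby("gene_id")["log2_ratio"].transform("median")
    dev = (exp["log2_ratio"] - med).abs()
    candidates = exp.loc[dev > k * noise.sigma_tech].assign(_dev=dev)
    if candidates.empty:
        return out
    # one flag per gene: max deviation, ties resolved toward keeping the
    # lowest replicate index
    pick = (candidates
            .sort_values(["_dev", "replicate_index"],
                         ascending=[False, False], kind="stable")
            .groupby("gene_id", sort=False)
            .head(1))
    out.loc[pick.index, "outlier_flag"] = True
    return out


def summarize_genes(
    table: pd.DataFrame, noise: TechnicalNoiseModel,
) -> pd.DataFrame:
    """One record per gene over surviving (unflagged) replicates.

    ``expressed`` is decided solely by comparing the gene's mean log2
    intensity (surviving spots) with the detection limit.  Genes with fewer
    than two surviving replicates are excluded with a warning.
    """
    exp = table[(table["probe_class"] == EXPERIMENTAL)
                & ~table["outlier_flag"]]
    grouped = exp.groupby("gene_id")
    genes = grouped.agg(
        mean_log2_ratio=("log2_ratio", "mean"),
        sd_log2_ratio=("log2_ratio", lambda v: v.std(ddof=1)),
        n_surviving=("log2_ratio", "size"),
        mean_log2_intensity=("mean_log2_intensity", "mean"),
    ).reset_index()
    thin = genes["n_surviving"] < 2
    if thin.any():
        warnings.warn(
            f"{int(thin.sum())} gene(s) with < 2 surviving replicates excluded")
        genes = genes[~thin]
    genes["expressed"] = genes["mean_log2_intensity"] > noise.detection_limit
    return genes.reset_index(drop=True)


@dataclass
class PreprocessResult:
    genes: pd.DataFrame
    noise: TechnicalNoiseModel
    curve: NormalizationCurve
    ratios: pd.DataFrame
    n_flagged: int


def preprocess_scan(
    scan: pd.DataFrame, *, n_quantiles: int = 100, k: float = 4.0,
) -> PreprocessResult:
    """Full per-array pipeline: normalize, ratio, calibrate, de-outlier,
    summarize."""
    normalized, curve = qspline_normalize(scan, n_quantiles)
    noise = calibrate_controls(normalized)
    ratios = compute_log_ratios(normalized)
    ratios = eliminate_replicate_outliers(ratios, noise, k)
    genes = summarize_genes(ratios, noise)
    return PreprocessResult(
        genes=genes, noise=noise, curve=curve, ratios=ratios,
        n_flagged=int(ratios["outlier_flag"].sum()))
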