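"""Spectral preprocessing: AWLS baseline correction and ROI variable filtering.

AWLS (automatic weighted least squares) estimates a smooth polynomial
baseline by iteratively reweighted least squares: points sitting above
the current fit — peak candidates — are given a near-zero weight, points
at or below keep full weight, and the polynomial is refit until the
baseline stabilizes.  ROI (region-of-interest) filtering then discards
m/z variables whose intensity never reaches a set fraction (default 3%)
of the dataset's base peak.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import SpectralMatrix, average_replicates

logger = logging.getLogger(__name__)

__all__ = ["PreprocessConfig", "awls_baseline", "roi_filter", "preprocess_matrix"]

# weight assigned to points above the running baseline fit
_ABOVE_WEIGHT = 1e-6


@dataclass
class PreprocessConfig:
    awls_poly_order: int = 2
    awls_max_iter: int = 100
    awls_tol: float = 1e-6
    roi_fraction: float = 0.03
    roi_mode: str = "above"
    tic_normalize: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.roi_fraction <= 1.0:
            raise ValueError("roi_fraction must lie in [0, 1]")
        if self.awls_poly_order < 0:
            raise ValueError("awls_poly_order must be >= 0")
        if self.roi_mode not in ("above", "below"):
            raise ValueError("roi_mode must be 'above' or 'below'")


def awls_baseline(
    intensities: np.ndarray, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and subtract an AWLS polynomial baseline from one spectrum.

    Returns ``(baseline, corrected)`` where ``corrected =
    max(intensities - max(baseline, 0), 0)`` — the baseline estimate is
    floored at zero before subtraction so that corrected intensities
    never exceed the (physical, non-negative) input.  On non-convergence
    the last iterate is returned with a logged warning.
    """
    config = config or PreprocessConfig()
    y = np.asarray(intensities, dtype=float)
    if y.ndim != 1:
        raise ValueError("awls_baseline expects a 1-D intensity vector")
    if y.size <= config.awls_poly_order + 1:
        raise ValueError(
            f"vector length {y.size} too short for polynomial order "
            f"{config.awls_poly_order}"
        )
    # centred/scaled abscissa for conditioning
    x = np.linspace(-1.0, 1.0, y.size)
    w = np.ones_like(y)
    scale = np.abs(y).max()
    if scale == 0.0:
        return np.zeros_like(y), np.zeros_like(y)
    baseline = np.zeros_like(y)
    converged = False
    seen_masks: set[bytes] = set()
    for _ in range(config.awls_max_iter):
        coeffs = np.polynomial.polynomial.polyfit(x, y, config.awls_poly_order, w=w)
        new_baseline = np.polynomial.polynomial.polyval(x, coeffs)
        delta = np.abs(new_baseline - baseline).max()
        baseline = new_baseline
        if delta <= config.awls_tol * scale:
            converged = True
            break
        # peak points are those significantly above the fit; the noise
        # scale is estimated from the negative residuals so the baseline
        # stays centred in the noise band instead of hugging its floor
        resid = y - baseline
        neg = resid[resid <= 0]
        sigma = float(np.sqrt(np.mean(neg**2))) if neg.size else 0.0
        above = resid > 2.0 * sigma
        mask = above.tobytes()
        if mask in seen_masks:
            # the reweighting map reached a fixed point or a limit cycle;
            # with binary weights no further refinement is possible
            converged = True
            break
        seen_masks.add(mask)
        w = np.where(above, _ABOVE_WEIGHT, 1.0)
    if not converged:
        logger.warning(
            "AWLS did not converge in %d iterations (last change %.3g); "
            "returning last iterate",
            config.awls_max_iter,
            delta,
        )
    corrected = np.clip(y - np.clip(baseline, 0.0, None), 0.0, None)
    return baseline, corrected


def roi_filter(
    matrix: SpectralMatrix, config: PreprocessConfig | None = None
) -> tuple[SpectralMatrix, np.ndarray]:
    """Keep m/z variables by relative intensity against the base peak.

    With ``roi_mode='above'`` (the default) variable *j* is kept iff the
    per-column maximum ``max_i X[i, j]`` reaches ``roi_fraction`` times
    the single global maximum of the matrix; ``'below'`` keeps the
    complement.  Column order is preserved.
    """
    config = config or PreprocessConfig()
    if matrix.n_samples == 0 or matrix.n_variables == 0:
        raise ValueError("roi_filter requires a non-empty matrix")
    col_max = matrix.X.max(axis=0)
    threshold = config.roi_fraction * matrix.X.max()
    if config.roi_mode == "above":
        keep = col_max >= threshold
    else:
        keep = col_max < threshold
    if not keep.any():
        raise ValueError(
            f"ROI filter at fraction {config.roi_fraction} removed every "
            "variable; lower the threshold"
        )
    idx = np.flatnonzero(keep)
    out = matrix.select_columns(
        idx.tolist(),
        note=(
            f"ROI filter mode={config.roi_mode} fraction={config.roi_fraction}: "
            f"kept {idx.size}/{matrix.n_variables} variables"
        ),
    )
    return out, matrix.mz_axis[idx]


def preprocess_matrix(
    matrix: SpectralMatrix,
    config: PreprocessConfig | None = None,
    apply_roi: bool = True,
) -> SpectralMatrix:
    """Full preprocessing: per-spectrum AWLS, replicate averaging, then ROI.

    Baseline correction runs on each replicate spectrum before averaging;
    replicate rows (if present) are then collapsed to one row per sample;
    ROI filtering runs last, on the averaged matrix.
    """
    config = config or PreprocessConfig()
    corrected = np.empty_like(matrix.X)
    for i in range(matrix.n_samples):
        _, corrected[i] = awls_baseline(matrix.X[i], config)
    work = SpectralMatrix(
        X=corrected,
        mz_axis=matrix.mz_axis,
        sample_ids=list(matrix.sample_ids),
        labels=matrix.labels.copy(),
        replicate_ids=list(matrix.replicate_ids) if matrix.replicate_ids else None,
        provenance=list(matrix.provenance),
    )
    work.log(
        f"AWLS baseline correction (order={config.awls_poly_order}, "
        f"tol={config.awls_tol}) applied per spectrum"
    )
    if work.replicate_ids is not None:
        work = average_replicates(work)
    if config.tic_normalize:
        tic = work.X.sum(axis=1, keepdims=True)
        tic[tic == 0] = 1.0
        work = SpectralMatrix(
            X=work.X / tic,
            mz_axis=work.mz_axis,
            sample_ids=work.sample_ids,
            labels=work.labels,
            provenance=list(work.provenance),
        )
        work.log("total-ion-current normalization applied")
    if apply_roi:
        work, _ = roi_filter(work, config)
    return work
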