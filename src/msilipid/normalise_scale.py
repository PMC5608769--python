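"""Per-pixel intensity normalisation and centering + Pareto scaling.

Normalisation divides each pixel column by a per-pixel factor: the median
of its nonzero intensities, its total ion count, or the mean intensity of
a set of standard features.  Pareto scaling then centers each feature row
and divides by the square root of its sample standard deviation, damping
the dominance of intense lipids before PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from msilipid.preprocess import FeatureMatrix

__all__ = ["NormalisationSpec", "normalise", "center_pareto"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalisationSpec:
    """Which per-pixel factor to divide by.

    method: "median" | "TIC" | "standards" | "none".  For "standards",
    standard_mzs lists feature m/z values located within ppm_tolerance.
    """

    method: str = "TIC"
    standard_mzs: tuple[float, ...] = ()
    ppm_tolerance: float = 5.0

    def __post_init__(self) -> None:
        if self.method not in ("median", "TIC", "standards", "none"):
            raise ValueError(f"unknown normalisation method {self.method!r}")
        if self.method == "standards" and not self.standard_mzs:
            raise ValueError("method='standards' requires standard_mzs")


def _standard_rows(matrix: FeatureMatrix, spec: NormalisationSpec) -> np.ndarray:
    mzs = matrix.mzs
    rows = []
    for target in spec.standard_mzs:
        ppm = 1e6 * np.abs(mzs - target) / target
        hits = np.flatnonzero(ppm <= spec.ppm_tolerance)
        if len(hits) == 0:
            raise ValueError(
                f"standard ion m/z {target} not resolvable to any feature "
                f"within {spec.ppm_tolerance} ppm"
            )
        rows.append(hits[np.argmin(ppm[hits])])
    return np.array(sorted(set(rows)))


def normalise(matrix: FeatureMatrix, spec: NormalisationSpec) -> FeatureMatrix:
    """Scale each pixel column by its normalisation factor.

    Columns whose factor is zero (empty pixels) are left all-zero and
    logged rather than producing NaNs.
    """
    if matrix.n_features == 0 or matrix.n_pixels == 0:
        raise ValueError("matrix must be non-empty")
    x = matrix.intensities
    if spec.method == "none":
        factors = np.ones(matrix.n_pixels)
    elif spec.method == "TIC":
        factors = x.sum(axis=0)
    elif spec.method == "median":
        factors = np.zeros(matrix.n_pixels)
        for j in range(matrix.n_pixels):
            nz = x[:, j][x[:, j] > 0]
            if len(nz):
                factors[j] = np.median(nz)
    else:  # standards
        rows = _standard_rows(matrix, spec)
        factors = x[rows, :].mean(axis=0)

    zero = factors == 0
    if zero.any():
        logger.warning(
            "%d pixel(s) have zero %s factor; left as all-zero columns",
            int(zero.sum()), spec.method,
        )
    safe = np.where(zero, 1.0, factors)
    return FeatureMatrix(
        features=list(matrix.features),
        intensities=x / safe,
        pixel_index=list(matrix.pixel_index),
    )


def center_pareto(matrix: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Center each feature row and divide by sqrt of its sample sd.

    Rows with zero variance are zeroed (and logged) instead of dropped so
    feature indexing stays stable.  Requires at least two pixels.
    """
    x = matrix.intensities if isinstance(matrix, FeatureMatrix) else np.asarray(matrix)
    if x.shape[1] < 2:
        raise ValueError("Pareto scaling needs at least 2 pixels (sd undefined)")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd[:, 0] == 0
    if degenerate.any():
        logger.warning("%d constant feature row(s) zeroed", int(degenerate.sum()))
    safe_sd = np.where(sd == 0, 1.0, sd)
    scaled = (x - mean) / np.sqrt(safe_sd)
    scaled[degenerate, :] = 0.0
    return scaled
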