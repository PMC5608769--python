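"""Removal of 13C isotope features (M+1, M+2) from the feature matrix.

Expected isotope proportions come from the carbon count estimated linearly
from m/z (glycerophospholipids carry roughly 0.055 carbons per Da):
r1 = nC * 0.0111 and r2 = C(nC, 2) * 0.0111^2, the binomial means for one
and two 13C substitutions.  A candidate at M + k*1.003355 whose
subset-mean intensity ratio to M falls within +/- tolerance of r_k is
flagged and its row removed.  Parents are claimed greedily in ascending
m/z; a feature removed as an isotope never becomes a parent itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from msilipid.preprocess import FeatureMatrix

__all__ = [
    "C13_C12_SPACING",
    "C13_ABUNDANCE",
    "CARBONS_PER_DALTON",
    "IsotopeReport",
    "estimate_carbons",
    "expected_isotope_ratios",
    "deisotope",
    "report_to_frame",
]

C13_C12_SPACING = 1.003355  # Da
C13_ABUNDANCE = 0.0111
CARBONS_PER_DALTON = 0.055


@dataclass(frozen=True)
class IsotopeReport:
    """One tested (parent, candidate) pair."""

    parent_mz: float
    isotope_mz: float
    order: int  # 1 or 2
    observed_ratio: float
    expected_ratio: float
    accepted: bool


def estimate_carbons(mz: float, c_per_da: float = CARBONS_PER_DALTON) -> int:
    """Approximate carbon count of a lipid ion from its m/z, floored at 1."""
    if mz <= 0:
        raise ValueError(f"mz must be positive, got {mz}")
    return max(1, round(c_per_da * mz))


def expected_isotope_ratios(n_carbons: int) -> tuple[float, float]:
    """Predicted M+1/M and M+2/M intensity proportions for nC carbons."""
    if n_carbons < 1:
        raise ValueError(f"carbon count must be >= 1, got {n_carbons}")
    r1 = n_carbons * C13_ABUNDANCE
    r2 = comb(n_carbons, 2) * C13_ABUNDANCE**2
    return r1, r2


def deisotope(
    matrix: FeatureMatrix,
    mean_spectrum: np.ndarray,
    ppm_window: float = 10.0,
    tolerance: float = 0.5,
) -> tuple[FeatureMatrix, list[IsotopeReport]]:
    """Drop features identified as M+1/M+2 isotopes of a lighter parent.

    *mean_spectrum* must be aligned to the matrix rows (one mean intensity
    per feature, typically from
    :func:`msilipid.preprocess.mean_subset_spectrum`).  Returns the reduced
    matrix and a report of every tested candidate.
    """
    if ppm_window <= 0:
        raise ValueError(f"ppm_window must be > 0, got {ppm_window}")
    if not 0 < tolerance <= 1:
        raise ValueError(f"tolerance must be in (0, 1], got {tolerance}")
    mean_spectrum = np.asarray(mean_spectrum, dtype=float)
    if mean_spectrum.shape != (matrix.n_features,):
        raise ValueError("mean_spectrum is not aligned to the matrix features")

    mzs = matrix.mzs
    if np.any(np.diff(mzs) < 0):
        raise ValueError("features must be sorted by m/z")
    n = len(mzs)
    is_isotope = np.zeros(n, dtype=bool)
    reports: list[IsotopeReport] = []

    for i in range(n):
        if is_isotope[i]:
            continue
        parent_mz = mzs[i]
        parent_mean = mean_spectrum[i]
        if parent_mean <= 0:
            continue
        n_c = estimate_carbons(parent_mz)
        expected = expected_isotope_ratios(n_c)
        for order in (1, 2):
            target = parent_mz + order * C13_C12_SPACING
            half = ppm_window * 1e-6 * parent_mz
            lo = np.searchsorted(mzs, target - half, side="left")
            hi = np.searchsorted(mzs, target + half, side="right")
            r_k = expected[order - 1]
            if r_k <= 0:
                continue
            for j in range(lo, hi):
                if j == i or is_isotope[j]:
                    continue
                observed = mean_spectrum[j] / parent_mean
                accepted = r_k * (1 - tolerance) <= observed <= r_k * (1 + tolerance)
                reports.append(
                    IsotopeReport(
                        parent_mz=float(parent_mz),
                        isotope_mz=float(mzs[j]),
                        order=order,
                        observed_ratio=float(observed),
                        expected_ratio=float(r_k),
                        accepted=accepted,
                    )
                )
                if accepted:
                    is_isotope[j] = True

    keep = np.flatnonzero(~is_isotope)
    return matrix.take_features(keep), reports


def report_to_frame(reports: list[IsotopeReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parent_mz": [r.parent_mz for r in reports],
            "isotope_mz": [r.isotope_mz for r in reports],
            "order": [r.order for r in reports],
            "observed_ratio": [r.observed_ratio for r in reports],
            "expected_ratio": [r.expected_ratio for r in reports],
            "accepted": [r.accepted for r in reports],
        }
    )
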