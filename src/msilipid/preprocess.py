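"""Peak thresholding, ppm binning, feature definition and matrix building.

Above-threshold ions from all pixels are pooled and partitioned into a
deterministic ladder of mass bins anchored at the dataset's minimum m/z:
bin k spans [m0*(1 + k*w), m0*(1 + (k+1)*w)) with w = bin_ppm * 1e-6.
Each bin becomes a Feature at the median member m/z; features seen in too
small a fraction of spectra are dropped, and the survivors are laid out as
a features x pixels intensity matrix in raster pixel order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from msilipid.imzml_io import MSIDataset, Spectrum

__all__ = [
    "IonTable",
    "Feature",
    "FeatureMatrix",
    "extract_peaks",
    "extract_all",
    "bin_ions",
    "define_features",
    "filter_features",
    "build_matrix",
    "mean_subset_spectrum",
    "features_to_frame",
    "matrix_to_frame",
    "frame_to_matrix",
]


@dataclass
class IonTable:
    """Flat arrays of pooled ions: (mz, intensity, pixel id)."""

    mz: np.ndarray
    intensity: np.ndarray
    pixel: np.ndarray  # index into the dataset's pixel list

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class Feature:
    """One mass bin: median m/z, bin bounds and detection fraction."""

    mz: float
    bin_lo: float
    bin_hi: float
    detection_fraction: float


@dataclass
class FeatureMatrix:
    """Features x pixels intensity matrix.

    Columns follow ``pixel_index``, a fixed raster ordering (y-major) of
    the acquired pixels; rows follow ``features`` sorted by m/z.
    """

    features: list[Feature]
    intensities: np.ndarray
    pixel_index: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.shape != (len(self.features), len(self.pixel_index)):
            raise ValueError(
                f"matrix shape {self.intensities.shape} does not match "
                f"{len(self.features)} features x {len(self.pixel_index)} pixels"
            )

    @property
    def mzs(self) -> np.ndarray:
        return np.array([f.mz for f in self.features])

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_index)

    def take_features(self, row_indices: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            features=[self.features[i] for i in row_indices],
            intensities=self.intensities[row_indices],
            pixel_index=list(self.pixel_index),
        )


def extract_peaks(spectrum: Spectrum, intensity_threshold: float = 0.0) -> Spectrum:
    """Keep exactly the peaks with intensity strictly above the threshold."""
    if intensity_threshold < 0:
        raise ValueError(f"intensity_threshold must be >= 0, got {intensity_threshold}")
    keep = spectrum.intensity > intensity_threshold
    return Spectrum(
        mz=spectrum.mz[keep], intensity=spectrum.intensity[keep], pixel=spectrum.pixel
    )


def raster_pixel_order(dataset: MSIDataset) -> list[tuple[int, int]]:
    """Acquired pixels sorted row-major: by y, then x."""
    return sorted((s.pixel for s in dataset.spectra), key=lambda p: (p[1], p[0]))


def extract_all(dataset: MSIDataset, intensity_threshold: float = 0.0) -> IonTable:
    """Pool above-threshold ions from every spectrum, sorted by m/z."""
    if intensity_threshold < 0:
        raise ValueError(f"intensity_threshold must be >= 0, got {intensity_threshold}")
    order = {p: i for i, p in enumerate(raster_pixel_order(dataset))}
    mzs, intens, pix = [], [], []
    for s in dataset.spectra:
        keep = s.intensity > intensity_threshold
        mzs.append(s.mz[keep])
        intens.append(s.intensity[keep])
        pix.append(np.full(int(keep.sum()), order[s.pixel], dtype=np.intp))
    if not mzs:
        return IonTable(np.empty(0), np.empty(0), np.empty(0, dtype=np.intp))
    mz = np.concatenate(mzs)
    intensity = np.concatenate(intens)
    pixel = np.concatenate(pix)
    sort = np.argsort(mz, kind="stable")
    return IonTable(mz[sort], intensity[sort], pixel[sort])


def _bin_edges(mz: np.ndarray, bin_ppm: float, anchor: float | None = None):
    """Ladder bin index per ion plus a bounds lookup.

    Returns (indices, lo_of, hi_of) where lo_of/hi_of map a bin index k to
    [m0*(1+k*w), m0*(1+(k+1)*w)).
    """
    if bin_ppm <= 0:
        raise ValueError(f"bin_ppm must be > 0, got {bin_ppm}")
    m0 = float(mz.min()) if anchor is None else float(anchor)
    w = bin_ppm * 1e-6
    step = m0 * w
    k = np.floor((mz - m0) / step).astype(np.int64)
    # guard against float round-down placing an edge ion in the wrong bin
    k = np.where(mz >= m0 * (1 + (k + 1) * w), k + 1, k)
    k = np.where(mz < m0 * (1 + k * w), k - 1, k)
    lo_of = lambda kk: m0 * (1 + kk * w)
    hi_of = lambda kk: m0 * (1 + (kk + 1) * w)
    return k, lo_of, hi_of


def bin_ions(
    ions: IonTable, bin_ppm: float = 10.0, anchor: float | None = None
) -> list[IonTable]:
    """Partition pooled ions into ppm-ladder mass bins.

    Every ion lands in exactly one bin; bins are returned in ascending
    mass order as IonTable slices.
    """
    if len(ions) == 0:
        return []
    sort = np.argsort(ions.mz, kind="stable")
    mz = ions.mz[sort]
    intensity = ions.intensity[sort]
    pixel = ions.pixel[sort]
    k, _, _ = _bin_edges(mz, bin_ppm, anchor)
    bins = []
    boundaries = np.flatnonzero(np.diff(k)) + 1
    for start, stop in zip(
        np.concatenate(([0], boundaries)), np.concatenate((boundaries, [len(mz)]))
    ):
        bins.append(IonTable(mz[start:stop], intensity[start:stop], pixel[start:stop]))
    return bins


def define_features(
    bins: list[IonTable], n_spectra: int, bin_ppm: float = 10.0,
    anchor: float | None = None,
) -> list[Feature]:
    """One feature per bin: median member m/z and detection fraction.

    The detection fraction's denominator is the number of acquired
    spectra, so sparse off-tissue grids do not dilute detection.
    """
    if n_spectra <= 0:
        raise ValueError("n_spectra must be positive")
    features = []
    if not bins:
        return features
    m0 = anchor if anchor is not None else min(float(b.mz.min()) for b in bins)
    for b in bins:
        if len(b) == 0:
            raise RuntimeError("empty bin passed to define_features")
        k, lo_of, hi_of = _bin_edges(b.mz, bin_ppm, m0)
        features.append(
            Feature(
                mz=float(np.median(b.mz)),
                bin_lo=float(lo_of(int(k[0]))),
                bin_hi=float(hi_of(int(k[0]))),
                detection_fraction=len(np.unique(b.pixel)) / n_spectra,
            )
        )
    return sorted(features, key=lambda f: f.mz)


def filter_features(features: list[Feature], min_fraction: float = 0.01) -> list[Feature]:
    """Keep features detected in strictly more than *min_fraction* of spectra."""
    if not 0 <= min_fraction <= 1:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    return [f for f in features if f.detection_fraction > min_fraction]


def build_matrix(
    dataset: MSIDataset,
    features: list[Feature],
    intensity_threshold: float = 0.0,
) -> FeatureMatrix:
    """Accumulate above-threshold ion intensities into features x pixels.

    An ion contributes to the single feature whose [bin_lo, bin_hi) bracket
    contains it (none, after filtering, for dropped bins); multiple ions
    from one pixel in one bin are summed.
    """
    pixel_index = raster_pixel_order(dataset)
    ions = extract_all(dataset, intensity_threshold)
    n_f, n_p = len(features), len(pixel_index)
    mat = np.zeros((n_f, n_p))
    if n_f and len(ions):
        lows = np.array([f.bin_lo for f in features])
        highs = np.array([f.bin_hi for f in features])
        idx = np.searchsorted(lows, ions.mz, side="right") - 1
        valid = (idx >= 0) & (ions.mz < highs[np.clip(idx, 0, n_f - 1)])
        np.add.at(mat, (idx[valid], ions.pixel[valid]), ions.intensity[valid])
    return FeatureMatrix(features=list(features), intensities=mat, pixel_index=pixel_index)


def mean_subset_spectrum(
    matrix: FeatureMatrix, n_pixels: int, seed: int = 0
) -> np.ndarray:
    """Per-feature mean intensity over a seeded random subset of pixels.

    Sampling is uniform without replacement; the same seed always selects
    the same pixels.
    """
    if not 1 <= n_pixels <= matrix.n_pixels:
        raise ValueError(
            f"n_pixels must be in [1, {matrix.n_pixels}], got {n_pixels}"
        )
    rng = np.random.default_rng(seed)
    cols = rng.choice(matrix.n_pixels, size=n_pixels, replace=False)
    return matrix.intensities[:, cols].mean(axis=1)


def features_to_frame(features: list[Feature]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mz": [f.mz for f in features],
            "bin_lo": [f.bin_lo for f in features],
            "bin_hi": [f.bin_hi for f in features],
            "detection_fraction": [f.detection_fraction for f in features],
        }
    )


def matrix_to_frame(matrix: FeatureMatrix) -> pd.DataFrame:
    """Flat-file form: feature columns then one ``x:y`` column per pixel."""
    frame = features_to_frame(matrix.features)
    cols = {f"{x}:{y}": matrix.intensities[:, j]
            for j, (x, y) in enumerate(matrix.pixel_index)}
    return pd.concat([frame, pd.DataFrame(cols)], axis=1)


def frame_to_matrix(frame: pd.DataFrame) -> FeatureMatrix:
    meta = ["mz", "bin_lo", "bin_hi", "detection_fraction"]
    pixel_cols = [c for c in frame.columns if c not in meta]
    features = [
        Feature(
            mz=row.mz, bin_lo=row.bin_lo, bin_hi=row.bin_hi,
            detection_fraction=row.detection_fraction,
        )
        for row in frame[meta].itertuples()
    ]
    pixel_index = [tuple(int(v) for v in c.split(":")) for c in pixel_cols]
    return FeatureMatrix(
        features=features,
        intensities=frame[pixel_cols].to_numpy(dtype=np.float64),
        pixel_index=pixel_index,
    )
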