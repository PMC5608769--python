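"""Synthetic MSI phantom generator with known ground truth.

Builds a rectangular pixel grid carrying a few tissue-like regions, each
with its own panel of lipid ions (drawn from the annotation library), adds
natural-abundance M+1/M+2 isotope peaks at exact binomial proportions,
multiplicative lognormal intensity noise and off-tissue dropout, and emits
the result as a standard imzML/ibd pair plus a ground-truth record.  Every
draw comes from one seeded generator, so output is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, log, sqrt

import numpy as np
import pandas as pd

from msilipid.annotate import (
    LibraryConfig,
    adduct_mz,
    build_species,
    formula_mass,
)
from msilipid.deisotope import C13_ABUNDANCE, C13_C12_SPACING
from msilipid.imzml_io import MSIDataset, Spectrum

__all__ = [
    "SpeciesSpec",
    "RegionSpec",
    "PhantomSpec",
    "GroundTruth",
    "generate",
    "three_region_spec",
    "DEFAULT_PANELS",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """One injected ion: Class(C:D) + adduct at a base intensity."""

    lipid_class: str
    carbons: int
    double_bonds: int
    adduct: str
    base_intensity: float

    @property
    def name(self) -> str:
        return f"{self.lipid_class}({self.carbons}:{self.double_bonds}){self.adduct}"


@dataclass
class RegionSpec:
    """A boolean mask over the grid plus the lipid panel expressed there."""

    mask: np.ndarray  # n_y x n_x boolean
    panel: list[SpeciesSpec]


@dataclass
class PhantomSpec:
    grid: tuple[int, int]  # (n_x, n_y)
    regions: list[RegionSpec]
    isotope_orders: tuple[int, ...] = (0, 1, 2)
    noise_cv: float = 0.2
    dropout_fraction: float = 0.0
    mz_jitter_ppm: float = 1.0
    polarity: str = "positive"
    seed: int = 0

    def __post_init__(self) -> None:
        n_x, n_y = self.grid
        covered = np.zeros((n_y, n_x), dtype=bool)
        for r in self.regions:
            if r.mask.shape != (n_y, n_x):
                raise ValueError(
                    f"region mask shape {r.mask.shape} != grid (n_y, n_x) "
                    f"{(n_y, n_x)}"
                )
            if (covered & r.mask).any():
                raise ValueError("region masks must be disjoint")
            covered |= r.mask
            for sp in r.panel:
                if sp.base_intensity <= 0:
                    raise ValueError(f"base intensity must be > 0 for {sp.name}")
        if not 0 <= self.dropout_fraction < 1:
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if any(o not in (0, 1, 2) for o in self.isotope_orders):
            raise ValueError("isotope orders must be within {0, 1, 2}")


@dataclass
class GroundTruth:
    """What was injected where: per-pixel region labels and the ion list."""

    labels: np.ndarray  # n_y x n_x int; 0 = off-tissue
    species: pd.DataFrame  # region, name, class, C, D, adduct, mz, n_carbons
    pixel_frame: pd.DataFrame  # x, y, region for acquired pixels


def _binomial_isotope_ratio(n_carbons: int, order: int) -> float:
    """P(k 13C) / P(0 13C) for a molecule with n_carbons carbons."""
    p = C13_ABUNDANCE
    return comb(n_carbons, order) * (p / (1 - p)) ** order


def generate(
    spec: PhantomSpec, library_config: LibraryConfig | None = None
) -> tuple[MSIDataset, GroundTruth]:
    """Build the phantom dataset and its ground truth.

    Each in-tissue pixel receives, per panel species, a peak at the
    species' adduct m/z (with one fixed sub-ppm jitter drawn per species
    and isotope order) scaled by a lognormal factor with unit mean and the
    configured CV; isotope peaks share the pixel's noise factor so the
    envelope stays exactly binomial within each spectrum.
    """
    library_config = library_config or LibraryConfig()
    rng = np.random.default_rng(spec.seed)
    n_x, n_y = spec.grid

    # resolve species to exact m/z and carbon counts (fails on infeasible specs)
    species_rows = []
    peak_table: list[list[tuple[float, float]]] = []  # per region: (mz, base) peaks
    jitters: dict[tuple[str, int], float] = {}
    for ridx, region in enumerate(spec.regions):
        peaks = []
        for sp in region.panel:
            formula = build_species(
                sp.lipid_class, sp.carbons, sp.double_bonds, library_config
            )
            n_c = formula.to_dict().get("C", 0)
            mz0 = adduct_mz(formula_mass(formula), sp.adduct)
            for order in sorted(spec.isotope_orders):
                key = (sp.name, order)
                if key not in jitters:
                    jitters[key] = rng.uniform(
                        -spec.mz_jitter_ppm, spec.mz_jitter_ppm
                    )
                mz_k = (mz0 + order * C13_C12_SPACING) * (1 + jitters[key] * 1e-6)
                base_k = sp.base_intensity * _binomial_isotope_ratio(n_c, order)
                peaks.append((mz_k, base_k, sp.name, order))
            species_rows.append(
                {
                    "region": ridx + 1,
                    "name": sp.name,
                    "class": sp.lipid_class,
                    "carbons": sp.carbons,
                    "double_bonds": sp.double_bonds,
                    "adduct": sp.adduct,
                    "mz": mz0,
                    "n_carbons": n_c,
                    "base_intensity": sp.base_intensity,
                }
            )
        peak_table.append(peaks)

    labels = np.zeros((n_y, n_x), dtype=int)
    for ridx, region in enumerate(spec.regions):
        labels[region.mask] = ridx + 1

    if spec.noise_cv > 0:
        sigma = sqrt(log(1 + spec.noise_cv**2))
        mu = -(sigma**2) / 2  # unit-mean lognormal
    else:
        sigma = mu = 0.0

    spectra: list[Spectrum] = []
    pixel_rows = []
    for y in range(1, n_y + 1):
        for x in range(1, n_x + 1):
            region = labels[y - 1, x - 1]
            if region == 0:
                continue
            dropped = spec.dropout_fraction > 0 and rng.random() < spec.dropout_fraction
            if dropped:
                labels[y - 1, x - 1] = 0
                continue
            peaks = peak_table[region - 1]
            mzs, intens = [], []
            # one noise factor per species per pixel, shared by its isotopes
            factors: dict[str, float] = {}
            for mz_k, base_k, name, _order in peaks:
                if name not in factors:
                    factors[name] = (
                        float(rng.lognormal(mu, sigma)) if sigma > 0 else 1.0
                    )
                mzs.append(mz_k)
                intens.append(base_k * factors[name])
            order_idx = np.argsort(mzs)
            spectra.append(
                Spectrum(
                    mz=np.array(mzs)[order_idx],
                    intensity=np.array(intens)[order_idx],
                    pixel=(x, y),
                )
            )
            pixel_rows.append({"x": x, "y": y, "region": region})

    dataset = MSIDataset(
        spectra=spectra, grid=spec.grid, polarity=spec.polarity,
        source_path="<phantom>",
    )
    truth = GroundTruth(
        labels=labels,
        species=pd.DataFrame(species_rows),
        pixel_frame=pd.DataFrame(pixel_rows, columns=["x", "y", "region"]),
    )
    return dataset, truth


# A positive-mode panel of 12 species spread over 3 regions, chosen so no
# two ions (or their isotopes) fall within one 10 ppm bin of each other.
DEFAULT_PANELS: tuple[tuple[SpeciesSpec, ...], ...] = (
    (
        SpeciesSpec("PC", 32, 0, "[M+H]+", 900.0),
        SpeciesSpec("PC", 36, 1, "[M+K]+", 1000.0),
        SpeciesSpec("DAG", 34, 1, "[M+Na]+", 400.0),
        SpeciesSpec("SM", 34, 1, "[M+H]+", 600.0),
    ),
    (
        SpeciesSpec("PC", 34, 1, "[M+H]+", 1000.0),
        SpeciesSpec("PC", 38, 6, "[M+K]+", 800.0),
        SpeciesSpec("TAG", 52, 2, "[M+NH4]+", 500.0),
        SpeciesSpec("Cer", 34, 1, "[M+H]+", 300.0),
    ),
    (
        SpeciesSpec("PC", 40, 6, "[M+K]+", 900.0),
        SpeciesSpec("LysoPC", 16, 0, "[M+H]+", 700.0),
        SpeciesSpec("PE", 36, 2, "[M+H]+", 650.0),
        SpeciesSpec("CE", 18, 1, "[M+Na]+", 450.0),
    ),
)


def three_region_spec(
    n_x: int = 50,
    n_y: int = 50,
    noise_cv: float = 0.2,
    dropout_fraction: float = 0.0,
    seed: int = 0,
    border: int = 2,
) -> PhantomSpec:
    """Three vertical tissue bands inside an off-tissue border."""
    if n_x < 3 * (border + 1) or n_y < 2 * border + 1:
        raise ValueError("grid too small for three bands with this border")
    masks = []
    inner_w = n_x - 2 * border
    edges = [border + round(inner_w * i / 3) for i in range(4)]
    for i in range(3):
        m = np.zeros((n_y, n_x), dtype=bool)
        m[border:n_y - border, edges[i]:edges[i + 1]] = True
        masks.append(m)
    regions = [
        RegionSpec(mask=m, panel=list(panel))
        for m, panel in zip(masks, DEFAULT_PANELS)
    ]
    return PhantomSpec(
        grid=(n_x, n_y),
        regions=regions,
        noise_cv=noise_cv,
        dropout_fraction=dropout_fraction,
        seed=seed,
    )
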