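"""Combinatorial lipid library generation and accurate-mass annotation.

Lipid species are built at sum-composition level — Class(C:D), total acyl
carbons and double bonds — by combining a head-group/backbone formula with
acyl chains drawn from a configurable fatty-acid grid, losing one water per
ester or amide bond formed.  Library m/z values are neutral monoisotopic
masses plus electron-corrected adduct deltas.  Deisotoped features are then
matched to the library within a signed ppm window, and feature pairs are
searched for configured mass differences (oxidation, water loss,
inter-adduct spacings, ...).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ATOMIC_MASS",
    "ELECTRON_MASS",
    "ADDUCTS",
    "DEFAULT_CLASSES",
    "DEFAULT_DIFFERENCES",
    "ElementalFormula",
    "LibraryEntry",
    "LibraryConfig",
    "formula_mass",
    "build_species",
    "build_library",
    "adduct_mz",
    "annotate",
    "difference_match",
    "library_to_frame",
]

# Monoisotopic atomic masses (Da); carbon-12 defines the scale.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 5.48579909e-4


def _hill_order(elements) -> list[str]:
    # Hill convention: C first, H second, remainder alphabetical
    rest = sorted(e for e in elements if e not in ("C", "H"))
    ordered = []
    if "C" in elements:
        ordered.append("C")
    if "H" in elements:
        ordered.append("H")
    return ordered + rest


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element -> count map with formula arithmetic."""

    counts: tuple[tuple[str, int], ...]

    @staticmethod
    def from_dict(d: dict[str, int]) -> "ElementalFormula":
        for el in d:
            if el not in ATOMIC_MASS:
                raise ValueError(f"unknown element {el!r}")
        clean = {el: int(n) for el, n in d.items() if n != 0}
        if any(n < 0 for n in clean.values()):
            raise ValueError(f"negative element count in {d}")
        if not clean:
            raise ValueError("empty formula")
        return ElementalFormula(tuple(sorted(clean.items())))

    def to_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        d = self.to_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return ElementalFormula.from_dict(d)

    def subtract(self, other: dict[str, int]) -> "ElementalFormula":
        d = self.to_dict()
        for el, n in other.items():
            d[el] = d.get(el, 0) - n
            if d[el] < 0:
                raise ValueError(f"cannot remove {n} {el} from {self}")
        return ElementalFormula.from_dict(d)

    def __str__(self) -> str:
        d = self.to_dict()
        parts = []
        for el in _hill_order(d):
            n = d[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)


def formula_mass(formula: ElementalFormula | dict[str, int]) -> float:
    """Neutral monoisotopic mass (Da) of an elemental formula."""
    counts = formula.to_dict() if isinstance(formula, ElementalFormula) else formula
    mass = 0.0
    for el, n in counts.items():
        try:
            mass += n * ATOMIC_MASS[el]
        except KeyError:
            raise ValueError(f"unknown element {el!r}") from None
    if mass <= 0:
        raise ValueError("formula has non-positive mass")
    return mass


# Adduct name -> (mass delta incl. electron correction, polarity)
ADDUCTS: dict[str, tuple[float, str]] = {
    "[M+H]+": (ATOMIC_MASS["H"] - ELECTRON_MASS, "positive"),
    "[M+Na]+": (ATOMIC_MASS["Na"] - ELECTRON_MASS, "positive"),
    "[M+K]+": (ATOMIC_MASS["K"] - ELECTRON_MASS, "positive"),
    "[M+NH4]+": (
        ATOMIC_MASS["N"] + 4 * ATOMIC_MASS["H"] - ELECTRON_MASS,
        "positive",
    ),
    "[M-H]-": (-(ATOMIC_MASS["H"] - ELECTRON_MASS), "negative"),
    "[M+Cl]-": (ATOMIC_MASS["Cl"] + ELECTRON_MASS, "negative"),
    "[M+OAc]-": (
        2 * ATOMIC_MASS["C"] + 3 * ATOMIC_MASS["H"] + 2 * ATOMIC_MASS["O"]
        + ELECTRON_MASS,
        "negative",
    ),
}


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of the singly charged *adduct* ion of a neutral species."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    try:
        delta, _ = ADDUCTS[adduct]
    except KeyError:
        raise ValueError(
            f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}"
        ) from None
    return neutral_mass + delta


# Class construction tables.  Each entry: backbone formula, number of acyl
# chains taken from the FA grid, number of waters lost on assembly, and
# extra atoms bolted on after assembly (SM's phosphocholine).  Sphingoid
# classes ride on a d18:1 base; their (C, D) totals include it.
_GLYCEROL = {"C": 3, "H": 8, "O": 3}
_GPC = {"C": 8, "H": 20, "N": 1, "O": 6, "P": 1}
_GPE = {"C": 5, "H": 14, "N": 1, "O": 6, "P": 1}
_GPS = {"C": 6, "H": 14, "N": 1, "O": 8, "P": 1}
_GPA = {"C": 3, "H": 9, "O": 6, "P": 1}
_GPG = {"C": 6, "H": 15, "O": 8, "P": 1}
_GPI = {"C": 9, "H": 19, "O": 11, "P": 1}
_CHOLESTEROL = {"C": 27, "H": 46, "O": 1}
_SPHINGOSINE = {"C": 18, "H": 37, "N": 1, "O": 2}  # d18:1
_PHOSPHOCHOLINE_LESS_H = {"C": 5, "H": 12, "N": 1, "O": 3, "P": 1}


@dataclass(frozen=True)
class ClassSpec:
    backbone: dict[str, int]
    n_chains: int
    waters_lost: int
    extra: dict[str, int] | None = None
    sphingoid: bool = False  # chains are N-acyls on the d18:1 base


CLASS_TABLE: dict[str, ClassSpec] = {
    "FFA": ClassSpec(backbone={}, n_chains=1, waters_lost=0),
    "DAG": ClassSpec(backbone=_GLYCEROL, n_chains=2, waters_lost=2),
    "TAG": ClassSpec(backbone=_GLYCEROL, n_chains=3, waters_lost=3),
    "PC": ClassSpec(backbone=_GPC, n_chains=2, waters_lost=2),
    "LysoPC": ClassSpec(backbone=_GPC, n_chains=1, waters_lost=1),
    "PE": ClassSpec(backbone=_GPE, n_chains=2, waters_lost=2),
    "PS": ClassSpec(backbone=_GPS, n_chains=2, waters_lost=2),
    "PA": ClassSpec(backbone=_GPA, n_chains=2, waters_lost=2),
    "PG": ClassSpec(backbone=_GPG, n_chains=2, waters_lost=2),
    "PI": ClassSpec(backbone=_GPI, n_chains=2, waters_lost=2),
    "CE": ClassSpec(backbone=_CHOLESTEROL, n_chains=1, waters_lost=1),
    "Cer": ClassSpec(backbone=_SPHINGOSINE, n_chains=1, waters_lost=1,
                     sphingoid=True),
    "SM": ClassSpec(backbone=_SPHINGOSINE, n_chains=1, waters_lost=1,
                    extra=_PHOSPHOCHOLINE_LESS_H, sphingoid=True),
}

DEFAULT_CLASSES: dict[str, tuple[str, ...]] = {
    "positive": ("DAG", "TAG", "PC", "PE", "PS", "LysoPC", "CE", "SM", "Cer"),
    "negative": ("PC", "PA", "PE", "PS", "PG", "PI", "FFA"),
}

DEFAULT_ADDUCTS: dict[str, tuple[str, ...]] = {
    "positive": ("[M+K]+", "[M+H]+", "[M+Na]+", "[M+NH4]+"),
    "negative": ("[M-H]-", "[M+Cl]-", "[M+OAc]-"),
}

_O = ATOMIC_MASS["O"]
_H2O = 2 * ATOMIC_MASS["H"] + _O
DEFAULT_DIFFERENCES: tuple[tuple[str, float], ...] = (
    ("oxidation (+O)", _O),
    ("dioxidation (+2O)", 2 * _O),
    # stored as the positive spacing: the dehydrated fragment is mz_low
    ("water loss (-H2O)", _H2O),
    ("K/H adduct spacing", ATOMIC_MASS["K"] - ATOMIC_MASS["H"]),
    ("Na/H adduct spacing", ATOMIC_MASS["Na"] - ATOMIC_MASS["H"]),
)


@dataclass(frozen=True)
class LibraryConfig:
    """Fatty-acid grid, class list and adduct list for library generation.

    The default grid covers even-carbon chains C12–C24 with 0–6 double
    bonds, capped at (c − 2) / 2 per chain.
    """

    fa_carbons: tuple[int, ...] = tuple(range(12, 25, 2))
    fa_max_double_bonds: int = 6
    classes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES)
    )
    adducts: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ADDUCTS)
    )

    def chains(self) -> list[tuple[int, int]]:
        out = []
        for c in self.fa_carbons:
            for d in range(0, self.fa_max_double_bonds + 1):
                if d <= (c - 2) // 2:
                    out.append((c, d))
        return out

    def compositions(self, lipid_class: str) -> set[tuple[int, int]]:
        """Feasible (total C, total D) sums for a class under this grid."""
        spec = _class_spec(lipid_class)
        chains = self.chains()
        totals: set[tuple[int, int]] = set()
        for combo in itertools.combinations_with_replacement(chains, spec.n_chains):
            c = sum(ch[0] for ch in combo)
            d = sum(ch[1] for ch in combo)
            if spec.sphingoid:
                c += 18
                d += 1
            totals.add((c, d))
        return totals


def _class_spec(lipid_class: str) -> ClassSpec:
    try:
        return CLASS_TABLE[lipid_class]
    except KeyError:
        raise ValueError(
            f"unsupported lipid class {lipid_class!r}; known: {sorted(CLASS_TABLE)}"
        ) from None


def build_species(
    lipid_class: str,
    total_carbons: int,
    total_double_bonds: int,
    config: LibraryConfig | None = None,
) -> ElementalFormula:
    """Neutral elemental formula of Class(C:D) at sum-composition level.

    Acyl chains contribute as free fatty acids CcH(2c-2d)O2; assembly loses
    one water per ester/amide bond.  (C, D) must be reachable as a sum of
    chains from the configured grid (for sphingoid classes the d18:1 base
    contributes 18:1 of the total).
    """
    config = config or LibraryConfig()
    spec = _class_spec(lipid_class)
    if (total_carbons, total_double_bonds) not in config.compositions(lipid_class):
        raise ValueError(
            f"{lipid_class}({total_carbons}:{total_double_bonds}) is not reachable "
            f"from the configured fatty-acid grid"
        )
    acyl_c = total_carbons
    acyl_d = total_double_bonds
    if spec.sphingoid:
        acyl_c -= 18
        acyl_d -= 1
    counts = dict(spec.backbone)
    # n free fatty acids with the summed composition
    counts["C"] = counts.get("C", 0) + acyl_c
    counts["H"] = counts.get("H", 0) + 2 * acyl_c - 2 * acyl_d
    counts["O"] = counts.get("O", 0) + 2 * spec.n_chains
    counts["H"] -= 2 * spec.waters_lost
    counts["O"] -= spec.waters_lost
    if spec.extra:
        for el, n in spec.extra.items():
            counts[el] = counts.get(el, 0) + n
    return ElementalFormula.from_dict(counts)


@dataclass(frozen=True)
class LibraryEntry:
    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    adduct: str
    formula: ElementalFormula
    neutral_mass: float
    mz: float
    mode: str

    @property
    def name(self) -> str:
        return (
            f"{self.lipid_class}({self.total_carbons}:{self.total_double_bonds})"
            f"{self.adduct}"
        )


def build_library(mode: str, config: LibraryConfig | None = None) -> list[LibraryEntry]:
    """Cartesian product of classes × feasible sum compositions × adducts.

    Entries are deduplicated on (class, C, D, adduct) and sorted by m/z;
    generation is deterministic and independent of config listing order.
    """
    if mode not in ("positive", "negative"):
        raise ValueError(f"mode must be 'positive' or 'negative', got {mode!r}")
    config = config or LibraryConfig()
    classes = config.classes.get(mode, ())
    adducts = config.adducts.get(mode, ())
    if not classes:
        raise ValueError(f"no lipid classes configured for mode {mode!r}")
    if not adducts:
        raise ValueError(f"no adducts configured for mode {mode!r}")
    for adduct in adducts:
        if ADDUCTS[adduct][1] != mode:
            raise ValueError(f"adduct {adduct} is not a {mode}-mode adduct")

    entries: dict[tuple, LibraryEntry] = {}
    for lipid_class in sorted(set(classes)):
        for c, d in sorted(config.compositions(lipid_class)):
            formula = build_species(lipid_class, c, d, config)
            neutral = formula_mass(formula)
            for adduct in sorted(set(adducts)):
                key = (lipid_class, c, d, adduct)
                entries[key] = LibraryEntry(
                    lipid_class=lipid_class,
                    total_carbons=c,
                    total_double_bonds=d,
                    adduct=adduct,
                    formula=formula,
                    neutral_mass=neutral,
                    mz=adduct_mz(neutral, adduct),
                    mode=mode,
                )
    return sorted(entries.values(), key=lambda e: (e.mz, e.name))


def library_to_frame(library: list[LibraryEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [e.name for e in library],
            "class": [e.lipid_class for e in library],
            "carbons": [e.total_carbons for e in library],
            "double_bonds": [e.total_double_bonds for e in library],
            "adduct": [e.adduct for e in library],
            "formula": [str(e.formula) for e in library],
            "neutral_mass": [e.neutral_mass for e in library],
            "mz": [e.mz for e in library],
            "mode": [e.mode for e in library],
        }
    )


def annotate(
    feature_mzs: "np.ndarray | list[float]",
    library: list[LibraryEntry],
    ppm_tolerance: float = 5.0,
) -> pd.DataFrame:
    """Match feature m/z values against a library within a ppm window.

    Every (feature, entry) pair with |ppm error| <= tolerance is reported;
    features may carry several isobaric annotations.  The table is sorted
    by feature m/z then |ppm error|.
    """
    if ppm_tolerance <= 0:
        raise ValueError(f"ppm_tolerance must be > 0, got {ppm_tolerance}")
    feature_mzs = np.asarray(feature_mzs, dtype=float)
    lib_mz = np.array([e.mz for e in library])
    order = np.argsort(lib_mz, kind="stable")
    lib_mz = lib_mz[order]
    lib = [library[i] for i in order]

    rows = []
    for fmz in feature_mzs:
        # window half-width in Th at this mass; |Δ|/entry.mz <= tol implies
        # the entry lies within fmz/(1 ± tol*1e-6), a hair wider than ±tol*fmz
        half = ppm_tolerance * 1e-6 * fmz * 1.000001 + 1e-12
        lo = np.searchsorted(lib_mz, fmz - half, side="left")
        hi = np.searchsorted(lib_mz, fmz + half, side="right")
        for e in lib[lo:hi]:
            ppm = 1e6 * (fmz - e.mz) / e.mz
            if abs(ppm) <= ppm_tolerance:
                rows.append(
                    {
                        "feature_mz": fmz,
                        "name": e.name,
                        "class": e.lipid_class,
                        "carbons": e.total_carbons,
                        "double_bonds": e.total_double_bonds,
                        "adduct": e.adduct,
                        "formula": str(e.formula),
                        "library_mz": e.mz,
                        "ppm_error": ppm,
                    }
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "feature_mz", "name", "class", "carbons", "double_bonds",
            "adduct", "formula", "library_mz", "ppm_error",
        ],
    )
    if len(frame):
        frame = frame.assign(_abs=frame.ppm_error.abs())
        frame = frame.sort_values(["feature_mz", "_abs"], kind="stable")
        frame = frame.drop(columns="_abs").reset_index(drop=True)
    return frame


def difference_match(
    feature_mzs: "np.ndarray | list[float]",
    deltas: list[tuple[str, float]] | None = None,
    ppm_tolerance: float = 5.0,
) -> pd.DataFrame:
    """Find feature pairs separated by a configured mass difference.

    Reports every ordered pair (a, b) with mz(b) > mz(a) whose spacing
    matches a named delta within ppm_tolerance of mz(b).
    """
    if deltas is None:
        deltas = list(DEFAULT_DIFFERENCES)
    if not deltas:
        raise ValueError("delta list must be non-empty")
    if ppm_tolerance <= 0:
        raise ValueError(f"ppm_tolerance must be > 0, got {ppm_tolerance}")
    mz = np.sort(np.asarray(feature_mzs, dtype=float))
    rows = []
    for name, delta in deltas:
        for b in mz:
            tol = ppm_tolerance * 1e-6 * b
            target = b - delta
            lo = np.searchsorted(mz, target - tol, side="left")
            hi = np.searchsorted(mz, target + tol, side="right")
            for a in mz[lo:hi]:
                if b > a and abs(b - a - delta) <= tol:
                    rows.append(
                        {
                            "mz_low": a,
                            "mz_high": b,
                            "delta_name": name,
                            "delta_mass": delta,
                            "error_mda": (b - a - delta) * 1e3,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["mz_low", "mz_high", "delta_name", "delta_mass", "error_mda"]
    )
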