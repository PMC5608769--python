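"""Elemental masses, species construction, library generation, matching."""

import re

import numpy as np
import pandas as pd
import pytest

from msilipid.annotate import (
    ADDUCTS,
    DEFAULT_ADDUCTS,
    DEFAULT_CLASSES,
    ElementalFormula,
    LibraryConfig,
    adduct_mz,
    annotate,
    build_library,
    build_species,
    difference_match,
    formula_mass,
    library_to_frame,
)

# Independent mass oracle: separately typed table + string-parsing summation.
ORACLE_MASSES = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}


def oracle_mass(formula_string: str) -> float:
    total = 0.0
    for element, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula_string):
        if element:
            total += ORACLE_MASSES[element] * (int(count) if count else 1)
    return total


class TestFormulaMass:
    def test_water(self):
        f = ElementalFormula.from_dict({"H": 2, "O": 1})
        assert formula_mass(f) == pytest.approx(18.0105646, abs=1e-6)

    def test_carbon_defines_scale(self):
        assert formula_mass({"C": 1}) == 12.0

    def test_pc_34_1(self):
        f = ElementalFormula.from_dict({"C": 42, "H": 82, "N": 1, "O": 8, "P": 1})
        assert formula_mass(f) == pytest.approx(759.57785, abs=1e-4)
        assert formula_mass(f) == pytest.approx(oracle_mass("C42H82NO8P"), abs=1e-9)

    def test_unknown_element(self):
        with pytest.raises(ValueError, match="unknown element"):
            formula_mass({"Xe": 1})


class TestBuildSpecies:
    def test_pc_34_1_formula(self):
        assert str(build_species("PC", 34, 1)) == "C42H82NO8P"

    def test_ffa_16_0(self):
        assert str(build_species("FFA", 16, 0)) == "C16H32O2"

    def test_pc_36_1(self):
        assert str(build_species("PC", 36, 1)) == "C44H86NO8P"

    @pytest.mark.parametrize(
        "lipid_class, c, d, expected",
        [
            ("DAG", 34, 1, "C37H70O5"),
            ("PE", 34, 1, "C39H76NO8P"),
            ("PS", 34, 1, "C40H76NO10P"),
            ("PA", 34, 1, "C37H71O8P"),
            ("PG", 34, 1, "C40H77O10P"),
            ("PI", 34, 1, "C43H81O13P"),
            ("CE", 18, 1, "C45H78O2"),
            ("Cer", 34, 1, "C34H67NO3"),
            ("SM", 34, 1, "C39H79N2O6P"),
            ("LysoPC", 16, 0, "C24H50NO7P"),
            ("TAG", 52, 2, "C55H102O6"),
        ],
    )
    def test_published_sum_compositions(self, lipid_class, c, d, expected):
        assert str(build_species(lipid_class, c, d)) == expected

    def test_unsupported_class(self):
        with pytest.raises(ValueError, match="unsupported lipid class"):
            build_species("PIP2", 34, 1)

    def test_infeasible_composition(self):
        with pytest.raises(ValueError, match="not reachable"):
            build_species("PC", 34, 17)  # too many double bonds

    def test_odd_carbon_count_infeasible_on_even_grid(self):
        with pytest.raises(ValueError, match="not reachable"):
            build_species("PC", 35, 1)


class TestAdductMz:
    def test_protonated_pc(self):
        assert adduct_mz(759.57785, "[M+H]+") == pytest.approx(760.58513, abs=1e-4)

    def test_potassiated_pc_36_1(self):
        # the paper's white-matter marker ion [PC(36:1)+K]+
        neutral = formula_mass(build_species("PC", 36, 1))
        assert neutral == pytest.approx(787.60911, abs=1e-4)
        assert adduct_mz(neutral, "[M+K]+") == pytest.approx(826.57227, abs=1e-4)

    def test_deprotonation_then_protonation_inverts(self):
        m = 700.0
        assert adduct_mz(adduct_mz(m, "[M-H]-"), "[M+H]+") == pytest.approx(m, abs=1e-9)

    def test_unknown_adduct(self):
        with pytest.raises(ValueError, match="unknown adduct"):
            adduct_mz(700.0, "[M+Li]+")

    def test_nonpositive_mass(self):
        with pytest.raises(ValueError):
            adduct_mz(0.0, "[M+H]+")


class TestBuildLibrary:
    def test_single_entry_library(self):
        config = LibraryConfig(
            fa_carbons=(16, 18), fa_max_double_bonds=1,
            classes={"positive": ("PC",)}, adducts={"positive": ("[M+H]+",)},
        )
        entries = [e for e in build_library("positive", config)
                   if (e.total_carbons, e.total_double_bonds) == (34, 1)]
        assert len(entries) == 1
        assert entries[0].mz == pytest.approx(760.58513, abs=1e-4)

    def test_negative_mode_class_exclusions(self, neg_library):
        classes = {e.lipid_class for e in neg_library}
        assert classes == set(DEFAULT_CLASSES["negative"])
        assert not classes & {"TAG", "DAG", "CE", "SM", "Cer"}
        assert all(e.adduct in DEFAULT_ADDUCTS["negative"] for e in neg_library)

    def test_positive_mode_classes(self, pos_library):
        assert {e.lipid_class for e in pos_library} == set(DEFAULT_CLASSES["positive"])

    def test_product_cardinality(self):
        config = LibraryConfig(
            fa_carbons=(16,), fa_max_double_bonds=0,
            classes={"positive": ("PC", "CE")},
            adducts={"positive": ("[M+H]+", "[M+Na]+")},
        )
        lib = build_library("positive", config)
        # PC has one composition (32:0), CE one (16:0); 2 classes x 1 x 2 adducts
        assert len(lib) == 4

    def test_sorted_and_deduplicated(self, pos_library):
        mzs = [e.mz for e in pos_library]
        assert mzs == sorted(mzs)
        keys = [(e.lipid_class, e.total_carbons, e.total_double_bonds, e.adduct)
                for e in pos_library]
        assert len(keys) == len(set(keys))

    def test_order_independence(self):
        a = LibraryConfig(classes={"positive": ("PC", "CE", "SM")},
                          adducts={"positive": ("[M+H]+", "[M+K]+")})
        b = LibraryConfig(classes={"positive": ("SM", "PC", "CE")},
                          adducts={"positive": ("[M+K]+", "[M+H]+")})
        assert build_library("positive", a) == build_library("positive", b)

    def test_wrong_mode_adduct_rejected(self):
        config = LibraryConfig(adducts={"positive": ("[M-H]-",)})
        with pytest.raises(ValueError, match="not a positive-mode adduct"):
            build_library("positive", config)

    def test_empty_class_list_rejected(self):
        with pytest.raises(ValueError, match="no lipid classes"):
            build_library("positive", LibraryConfig(classes={"positive": ()}))

    def test_library_agrees_with_oracle(self, pos_library, neg_library):
        for entry in pos_library + neg_library:
            expected = oracle_mass(str(entry.formula)) + ADDUCTS[entry.adduct][0]
            assert abs(entry.mz - expected) <= 1e-4

    def test_frame_columns(self, pos_library):
        frame = library_to_frame(pos_library)
        assert list(frame.columns) == [
            "name", "class", "carbons", "double_bonds", "adduct", "formula",
            "neutral_mass", "mz", "mode",
        ]


class TestAnnotate:
    def test_match_within_tolerance(self, pos_library):
        hits = annotate([760.5851], pos_library, 5.0)
        pc = hits[(hits["class"] == "PC") & (hits.adduct == "[M+H]+")]
        assert len(pc) == 1
        assert abs(pc.ppm_error.iloc[0]) < 0.2

    def test_no_match_outside_tolerance(self, pos_library):
        hits = annotate([760.5900], pos_library, 5.0)
        assert len(hits[(hits["class"] == "PC") & (hits.adduct == "[M+H]+")
                        & (hits.carbons == 34)]) == 0

    def test_monotone_in_tolerance(self, pos_library):
        rng = np.random.default_rng(8)
        mzs = rng.uniform(400, 900, 50)
        keys = {}
        for ppm in (3.0, 10.0, 50.0):
            hits = annotate(mzs, pos_library, ppm)
            keys[ppm] = set(zip(hits.feature_mz, hits.name))
        assert keys[3.0] <= keys[10.0] <= keys[50.0]

    def test_completeness_vs_brute_force(self, pos_library):
        rng = np.random.default_rng(9)
        mzs = rng.uniform(400, 900, 100)
        hits = annotate(mzs, pos_library, 20.0)
        got = set(zip(hits.feature_mz, hits.name))
        expected = {
            (fmz, e.name)
            for fmz in mzs
            for e in pos_library
            if abs(1e6 * (fmz - e.mz) / e.mz) <= 20.0
        }
        assert got == expected

    def test_soundness(self, pos_library):
        hits = annotate(np.random.default_rng(10).uniform(400, 900, 50),
                        pos_library, 15.0)
        assert (hits.ppm_error.abs() <= 15.0).all()

    def test_invalid_tolerance(self, pos_library):
        with pytest.raises(ValueError):
            annotate([500.0], pos_library, 0.0)


class TestDifferenceMatch:
    def test_oxidation_pair(self):
        pairs = difference_match(
            [700.5000, 716.4949], deltas=[("oxidation", 15.994915)], ppm_tolerance=5.0
        )
        assert len(pairs) == 1
        assert pairs.mz_low.iloc[0] == 700.5000

    def test_empty_delta_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            difference_match([700.0], deltas=[])

    def test_count_matches_double_loop(self):
        rng = np.random.default_rng(11)
        mzs = rng.uniform(400, 900, 200)
        deltas = [("ox", 15.994915), ("K/H", 37.955882)]
        pairs = difference_match(mzs, deltas, 50.0)
        brute = sum(
            1
            for _, delta in deltas
            for a in mzs
            for b in mzs
            if b > a and abs(b - a - delta) <= 50.0 * 1e-6 * b
        )
        assert len(pairs) == brute
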