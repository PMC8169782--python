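"""Theoretical lipid database: masses, names, enumeration, queries."""

import re

import numpy as np
import pytest

from lipidscreen.lipids import (
    ADDUCTS,
    CompositionRangeError,
    ElementComposition,
    LipidSpecies,
    TheoreticalIon,
    UnknownClassError,
    build_database,
    composition_for,
    monoisotopic_mass,
    parse_name,
    ppm_error,
)

# Independent elemental-mass oracle: formula string -> mass, computed
# from IUPAC atomic masses without touching the class backbone rules.
_ORACLE_MASSES = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048,
                  "O": 15.9949146196, "P": 30.97376163}


def oracle_mass(formula: str) -> float:
    return sum(
        _ORACLE_MASSES[el] * int(n or 1)
        for el, n in re.findall(r"([A-Z][a-z]?)(\d*)", formula)
    )


# Golden panel: one formula per class, expected values frozen from the
# oracle above (names in field shorthand; SM/Cer at total composition).
GOLDEN_PANEL = [
    ("PC 34:1", "C42H82NO8P", 759.577805),
    ("PC 36:2", "C44H84NO8P", 785.593455),
    ("LPC 18:2", "C26H50NO7P", 519.332490),
    ("LPC 16:0", "C24H50NO7P", 495.332490),
    ("PE 34:1", "C39H76NO8P", 717.530855),
    ("PE 36:4", "C41H74NO8P", 739.515205),
    ("PS 38:3", "C44H80NO10P", 813.551984),
    ("PS 40:3", "C46H84NO10P", 841.583285),
    ("PA 34:1", "C37H71O8P", 674.488656),
    ("PA 44:5", "C47H83O8P", 806.582556),
    ("PC-O 34:1", "C42H84NO7P", 745.598541),
    ("PE-O 36:2", "C41H80NO7P", 729.567241),
    ("SM d34:1", "C39H79N2O6P", 702.567575),
    ("SM d42:2", "C47H93N2O6P", 812.677125),
    ("Cer d34:1", "C34H67NO3", 537.512095),
    ("Cer d42:1", "C42H83NO3", 649.637296),
    ("TG 52:2", "C55H102O6", 858.767641),
    ("TG 54:3", "C57H104O6", 884.783291),
    ("CE 18:2", "C45H76O2", 648.584532),
    ("FA 18:2", "C18H32O2", 280.240230),
]


@pytest.mark.parametrize("name,formula,mass", GOLDEN_PANEL,
                         ids=[g[0] for g in GOLDEN_PANEL])
def test_golden_panel_formula_and_mass(name, formula, mass):
    """Backbone rules reproduce literature formulas and oracle masses."""
    sp = LipidSpecies.from_name(name)
    assert sp.composition.formula == formula
    assert sp.mass == pytest.approx(mass, abs=1e-3)
    assert sp.mass == pytest.approx(oracle_mass(formula), abs=1e-6)


def test_monoisotopic_mass_examples():
    assert monoisotopic_mass(ElementComposition(h=2, o=1)) == pytest.approx(
        18.010565, abs=1e-6)
    assert monoisotopic_mass(ElementComposition()) == 0.0
    sm = composition_for("SM", 34, 1)
    assert monoisotopic_mass(sm) == pytest.approx(702.5676, abs=1e-3)


def test_composition_arithmetic_closed():
    a = ElementComposition(2, 4, 0, 2, 0)
    b = ElementComposition(1, 2, 0, 1, 0)
    assert (a + b).formula == "C3H6O3"
    assert (a - b).formula == "CH2O"
    with pytest.raises(ValueError):
        _ = b - a  # negative counts are rejected


def test_composition_errors():
    with pytest.raises(UnknownClassError):
        composition_for("XX", 34, 1)
    with pytest.raises(CompositionRangeError):
        composition_for("PC", 300, 1)
    with pytest.raises(CompositionRangeError):
        composition_for("PC", 34, 20)  # D > C/2


@pytest.mark.parametrize(
    "name,expected",
    [
        ("PC 16:0_20:3", ("PC", 36, 3)),
        ("TG 18:0_18:1_18:1", ("TG", 54, 2)),
        ("SM d18:1/22:0", ("SM", 40, 1)),
        ("Cer d18:1/16:0", ("Cer", 34, 1)),
        ("PC-O 34:1", ("PC-O", 34, 1)),
        ("CE 18:2", ("CE", 18, 2)),
    ],
)
def test_parse_chain_annotated_names(name, expected):
    assert parse_name(name) == expected


def test_canonical_name_round_trips():
    for name, _, _ in GOLDEN_PANEL:
        sp = LipidSpecies.from_name(name)
        assert parse_name(sp.name) == (sp.class_code, sp.c, sp.d)


def test_parse_rejects_garbage():
    for bad in ("PC", "34:1", "PC 34", "QQ 34:1", ""):
        with pytest.raises(ValueError):
            parse_name(bad)


def test_ppm_error():
    assert ppm_error(760.5851, 760.5851) == 0.0
    assert ppm_error(760.5927, 760.5851) == pytest.approx(10.0, abs=0.1)
    assert ppm_error(0.0, 760.5851) == pytest.approx(-1e6)
    with pytest.raises(ValueError):
        ppm_error(500.0, 0.0)


def test_build_database_enumeration_and_adduct_mz():
    db = build_database(classes=["PC"], c_range=(34, 34), d_range=(0, 1),
                        adducts=["[M+H]+"], polarity="pos")
    assert len(db) == 2
    pc341 = [i for i in db.ions if i.species.d == 1][0]
    assert pc341.mz == pytest.approx(760.5851, abs=1e-3)
    # determinism: identical params -> identical content
    db2 = build_database(classes=["PC"], c_range=(34, 34), d_range=(0, 1),
                         adducts=["[M+H]+"], polarity="pos")
    assert db.to_dataframe().equals(db2.to_dataframe())


def test_database_invariant_under_class_permutation():
    a = build_database(classes=["PC", "SM", "TG"], polarity="pos")
    b = build_database(classes=["TG", "PC", "SM"], polarity="pos")
    assert a.to_dataframe().equals(b.to_dataframe())


def test_database_sorted_and_unique(pos_db):
    mz = np.array([i.mz for i in pos_db.ions])
    assert (np.diff(mz) >= 0).all()
    keys = {(i.species.name, i.adduct.name) for i in pos_db.ions}
    assert len(keys) == len(pos_db)


def test_species_mass_consistency(pos_db):
    for ion in pos_db.ions[::37]:
        comp_mass = monoisotopic_mass(ion.species.composition)
        assert abs(comp_mass - ion.species.mass) < 1e-6
        expected_mz = (ion.species.mass + ion.adduct.delta) / ion.adduct.charge
        assert ion.mz == pytest.approx(expected_mz, abs=1e-9)


def test_query_against_linear_scan_oracle():
    """searchsorted window query is exactly a linear scan over all ions."""
    db = build_database(classes=["PC", "SM", "PE"], polarity="pos")
    rng = np.random.default_rng(11)
    all_mz = np.array([i.mz for i in db.ions])
    for _ in range(1000):
        target = float(rng.uniform(all_mz.min() - 1, all_mz.max() + 1))
        tol = float(rng.choice([5.0, 10.0, 25.0]))
        got = {(i.ion_name, round(e, 9)) for i, e in db.query(target, tol)}
        want = {
            (i.ion_name, round(ppm_error(target, i.mz), 9))
            for i in db.ions
            if abs(ppm_error(target, i.mz)) <= tol
        }
        assert got == want


def test_query_window_edges(pos_db):
    ion = pos_db.ions[100]
    hits = pos_db.query(ion.mz, tol_ppm=10)
    assert hits[0][0].ion_name == ion.ion_name and hits[0][1] == 0.0
    # 10.5 ppm away from an isolated ion -> outside the window
    db = build_database(classes=["PC"], c_range=(34, 34), d_range=(1, 1),
                        adducts=["[M+H]+"], polarity="pos")
    off = db.ions[0].mz * (1 + 10.5e-6)
    assert db.query(off, tol_ppm=10) == []


def test_adduct_polarity_consistency():
    for a in ADDUCTS.values():
        assert (a.polarity == "pos") == a.name.endswith("+")
        assert abs(a.delta) < 100 and a.charge >= 1
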