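"""Glycan nomenclature, library enumeration, and peak annotation."""

import numpy as np
import pytest

from mabquant.chem import FormulaError, load_mod_registry, mass, parse_formula
from mabquant.proteoforms import (
    annotate_peaks,
    build_library,
    glycan_from_name,
    ppm_error,
    rituximab_chains,
)

LYS_AVG = mass(parse_formula("C6H12N2O")).avg
HEX_MONO = mass(parse_formula("C6H10O5")).mono

MAIN_PAIRS = [
    "A2G0F/A2G0F",
    "A2G0F/A2G1F",
    "A2G1F/A2G1F",
    "A2G1F/A2G2F",
    "A2G2F/A2G2F",
]


@pytest.fixture(scope="module")
def chains():
    return rituximab_chains()


@pytest.mark.parametrize(
    "name, counts",
    [
        ("A2G0F", (4, 3, 1, 0)),  # (HexNAc, Hex, Fuc, NeuAc)
        ("A2G0", (4, 3, 0, 0)),
        ("A2G2F", (4, 5, 1, 0)),
        ("M5", (2, 5, 0, 0)),
        ("M9", (2, 9, 0, 0)),
        ("A2S1G0F", (4, 4, 1, 1)),
        ("A2S2G0F", (4, 5, 1, 2)),
        ("A1G0F", (3, 3, 1, 0)),
    ],
)
def test_glycan_nomenclature(name, counts):
    assert glycan_from_name(name).counts() == counts


def test_glycan_unknown_name():
    with pytest.raises(FormulaError):
        glycan_from_name("B2G0F")


def test_galactose_ladder_spacing():
    """A2G0F..A2G2F masses form an arithmetic ladder of one hexose."""
    masses = [glycan_from_name(f"A2G{k}F").mass().mono for k in range(3)]
    for lighter, heavier in zip(masses, masses[1:]):
        assert heavier - lighter == pytest.approx(HEX_MONO, abs=1e-6)


def test_custom_glycan_registry():
    from mabquant.proteoforms import GlycanComposition

    registry = {"X": GlycanComposition(hexnac=4, hex=3)}
    assert glycan_from_name("X", registry).counts() == (4, 3, 0, 0)


class TestBuildLibrary:
    def test_cardinality(self, chains):
        library = build_library(chains, MAIN_PAIRS, lysine_variants=(0, 1, 2))
        assert len(library) == 15

    def test_lysine_ladder(self, chains):
        library = build_library(chains, MAIN_PAIRS, lysine_variants=(0, 1, 2))
        by_label = {p.label: p for p in library}
        for pair in MAIN_PAIRS:
            m0 = by_label[f"0K {pair}"].mass
            m1 = by_label[f"1K {pair}"].mass
            assert m1.avg - m0.avg == pytest.approx(LYS_AVG, abs=1e-6)

    def test_truncation_delta_shifts_all(self, chains):
        registry = load_mod_registry()
        plain = build_library(chains, MAIN_PAIRS, lysine_variants=(0,))
        truncated = build_library(
            chains, MAIN_PAIRS, lysine_variants=(0,),
            extra_mods=[registry["lc_truncation_qivls"]],
        )
        for p, q in zip(plain, truncated):
            assert q.mass.mono - p.mass.mono == pytest.approx(-540.3271, abs=5e-4)

    def test_isobaric_pairs_merge(self, chains):
        library = build_library(
            chains, ["A2G1F/A2G1F", "A2G0F/A2G2F"], lysine_variants=(0,)
        )
        assert len(library) == 1
        assert library[0].label == "0K A2G1F/A2G1F (or A2G0F/A2G2F)"

    def test_sorted_by_mass(self, chains):
        library = build_library(chains, MAIN_PAIRS + ["M5/M5"], lysine_variants=(0, 1))
        masses = [p.mass.mono for p in library]
        assert masses == sorted(masses)

    def test_empty_pairs_rejected(self, chains):
        with pytest.raises(ValueError):
            build_library(chains, [])

    def test_intact_mab_mass_scale(self, chains):
        """The glycosylated assembly sits near the expected ~147 kDa."""
        library = build_library(chains, ["A2G0F/A2G0F"], lysine_variants=(0,))
        assert 145_000 < library[0].mass.avg < 150_000


def test_ppm_error_examples():
    assert ppm_error(147000.0, 147000.0) == 0.0
    assert ppm_error(147002.94, 147000.0) == pytest.approx(20.0, abs=1e-6)
    assert ppm_error(146997.06, 147000.0) == pytest.approx(-20.0, abs=1e-6)
    with pytest.raises(ValueError):
        ppm_error(1.0, 0.0)


@pytest.fixture(scope="module")
def annotate_library():
    return build_library(
        rituximab_chains(), MAIN_PAIRS + ["M5/M5"], lysine_variants=(0, 1)
    )


class TestAnnotate:
    @pytest.fixture()
    def library(self, annotate_library):
        return annotate_library

    def test_exact_match(self, library):
        target = library[3]
        [ann] = annotate_peaks([(target.mass.avg, 1.0)], library)
        assert ann.label == target.label
        assert ann.ppm == pytest.approx(0.0, abs=1e-9)

    def test_outside_tolerance_unassigned(self, library):
        observed = library[0].mass.avg * (1 + 25e-6)
        [ann] = annotate_peaks([(observed, 1.0)], library[:1], tolerance_ppm=20.0)
        assert ann.label is None and ann.ppm is None

    def test_jittered_peaks_all_recovered(self, library):
        """5 ppm mass jitter never flips assignments in a 12-member library."""
        rng = np.random.default_rng(123)
        peaks = [
            (p.mass.avg * (1 + 5e-6 * rng.standard_normal()), 1.0) for p in library
        ]
        annotations = annotate_peaks(sorted(peaks), library, tolerance_ppm=20.0)
        expected = {p.label for p in library}
        assert {a.label for a in annotations} == expected
        assert all(abs(a.ppm) <= 20.0 for a in annotations)

    def test_order_independent(self, library):
        rng = np.random.default_rng(5)
        peaks = [(p.mass.avg * (1 + 3e-6), 1.0) for p in library]
        shuffled = list(peaks)
        rng.shuffle(shuffled)
        ann_a = {a.observed: a.label for a in annotate_peaks(peaks, library)}
        ann_b = {a.observed: a.label for a in annotate_peaks(shuffled, library)}
        assert ann_a == ann_b


def test_rituximab_fixture_chains():
    chains = rituximab_chains()
    assert len(chains) == 2
    heavy = next(c for c in chains if "heavy" in c.name)
    light = next(c for c in chains if "light" in c.name)
    assert heavy.copies == light.copies == 2
    assert not heavy.sequence.endswith("K")  # lysine-clipped 0K backbone
    assert light.sequence.startswith("QIVLS")  # the truncation-prone N-terminus
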