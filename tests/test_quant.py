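"""EICC extraction, integration, fractions, class metrics, and CIs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mabquant as mq
from mabquant.msio import MsRun, Scan
from mabquant.quant import (
    Chromatogram,
    QuantConfig,
    auto_rt_window,
    class_fraction,
    extract_eicc,
    fractional_abundances,
    galactosylation_level,
    integrate,
    is_afucosylated,
    is_oligomannose,
    is_sialylated,
    theoretical_mz,
    triplicate_ci,
)


class TestTheoreticalMz:
    def test_proton_adduct_arithmetic(self):
        assert theoretical_mz(147000.0, 25) == pytest.approx(5881.00728, abs=1e-4)

    def test_single_charge(self):
        assert theoretical_mz(1000.0, 1) == pytest.approx(1001.007276, abs=1e-6)

    def test_monotone_in_charge(self):
        mzs = [theoretical_mz(147000.0, z) for z in range(20, 40)]
        assert all(b < a for a, b in zip(mzs, mzs[1:]))

    def test_invalid_charge(self):
        with pytest.raises(ValueError):
            theoretical_mz(1000.0, 0)


class TestExtractEicc:
    def test_zero_run_gives_zero_trace(self, panel_run):
        run, _, library = panel_run
        empty = MsRun(
            scans=[Scan(rt=s.rt, mz=s.mz, intensity=np.zeros_like(s.intensity))
                   for s in run.scans]
        )
        chrom = extract_eicc(empty, library[0])
        assert np.all(chrom.intensity == 0)

    def test_linear_in_intensity(self, panel_run):
        run, _, library = panel_run
        doubled = MsRun(
            scans=[Scan(rt=s.rt, mz=s.mz, intensity=2 * s.intensity)
                   for s in run.scans]
        )
        base = extract_eicc(run, library[0])
        twice = extract_eicc(doubled, library[0])
        np.testing.assert_allclose(twice.intensity, 2 * base.intensity)

    def test_apex_at_simulated_rt(self, panel_run):
        run, truth, library = panel_run
        scan_interval = run.scans[1].rt - run.scans[0].rt
        for component in truth.components:
            prot = next(p for p in library if p.label == component["label"])
            chrom = extract_eicc(run, prot)
            apex = chrom.rt[np.argmax(chrom.intensity)]
            assert abs(apex - component["rt_center"]) <= scan_interval

    def test_all_charges_out_of_range_rejected(self):
        run = MsRun(scans=[Scan(rt=1.0, mz=[2600.0], intensity=[1.0])])
        config = QuantConfig(z_min=1, z_max=2)  # 147 kDa at z<=2 is way above m/z 8000
        with pytest.raises(ValueError, match="no usable charge"):
            extract_eicc(run, 147000.0, config)


class TestIntegrate:
    def test_constant_trace_closed_form(self):
        rt = np.linspace(0.0, 2.0, 41)
        chrom = Chromatogram(rt, np.ones_like(rt))
        assert integrate(chrom, (0.0, 2.1)) == pytest.approx(2.0)

    def test_matches_riemann_oracle(self):
        """Trapezoid equals a fine-subdivision Riemann sum on random traces."""
        rng = np.random.default_rng(99)
        for _ in range(5):
            rt = np.linspace(0.0, 10.0, 301)
            intensity = rng.uniform(0.0, 5.0, rt.size)
            chrom = Chromatogram(rt, intensity)
            area = integrate(chrom, (0.0, 10.1))
            # Riemann midpoint sum on a 100x finer linear interpolation
            fine = np.linspace(rt[0], rt[-1], rt.size * 100)
            mid = 0.5 * (fine[1:] + fine[:-1])
            riemann = np.sum(np.interp(mid, rt, intensity) * np.diff(fine))
            assert area == pytest.approx(riemann, rel=1e-3)

    def test_window_outside_peak_is_tiny(self, panel_run):
        run, _, library = panel_run
        chrom = extract_eicc(run, library[0])
        tail = integrate(chrom, (0.0, 2.0))
        peak = integrate(chrom, (7.0, 13.0))
        assert tail < 1e-6 * peak

    def test_empty_overlap_rejected(self):
        chrom = Chromatogram(np.linspace(0, 1, 10), np.ones(10))
        with pytest.raises(ValueError):
            integrate(chrom, (5.0, 6.0))


class TestFractions:
    def test_simple_normalization(self):
        table = fractional_abundances({"a": 10.0, "b": 30.0, "c": 60.0})
        assert table.fraction("a") == pytest.approx(0.10)
        assert table.fraction("b") == pytest.approx(0.30)
        assert table.fraction("c") == pytest.approx(0.60)

    def test_single_species(self):
        assert fractional_abundances({"only": 5.0}).fraction("only") == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fractional_abundances({"a": 0.0, "b": 0.0})

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1, max_size=20),
        st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_sum_to_one_and_scale_invariant(self, areas, scale):
        labels = [f"p{i}" for i in range(len(areas))]
        base = fractional_abundances(dict(zip(labels, areas)))
        scaled = fractional_abundances(
            dict(zip(labels, [a * scale for a in areas]))
        )
        assert abs(base.table["fraction"].sum() - 1.0) < 1e-12
        for label in labels:
            assert abs(base.fraction(label) - scaled.fraction(label)) < 1e-12


@pytest.fixture(scope="module")
def class_library():
    return mq.panel_library(lysine_variants=(0,))


class TestClassMetrics:
    @pytest.fixture()
    def library(self, class_library):
        return class_library

    def _table(self, fractions):
        return fractional_abundances(fractions)

    def test_galactosylation_extremes(self, library):
        zero = self._table({"0K A2G0F/A2G0F": 1.0})
        full = self._table({"0K A2G2F/A2G2F": 1.0})
        assert galactosylation_level(zero, library) == 0.0
        assert galactosylation_level(full, library) == 100.0

    def test_galactosylation_equal_mix(self, library):
        mix = self._table({"0K A2G0F/A2G0F": 1.0, "0K A2G1F/A2G1F": 1.0})
        assert galactosylation_level(mix, library) == pytest.approx(25.0)

    def test_class_fraction_extremes(self, library):
        sial = self._table({"0K A2S1G0F/A2G0F": 1.0})
        assert class_fraction(sial, library, is_sialylated) == pytest.approx(100.0)
        main = self._table({"0K A2G0F/A2G0F": 1.0})
        assert class_fraction(main, library, is_sialylated) == 0.0

    def test_class_predicates(self, library):
        by_label = {p.label: p for p in library}
        assert is_oligomannose(by_label["0K M5/M5"])
        assert not is_afucosylated(by_label["0K M5/M5"])  # not complex-type
        assert is_afucosylated(by_label["0K A2G0F/A2G0"])
        assert is_sialylated(by_label["0K A2S2G0F/A2G0F"])
        assert not is_sialylated(by_label["0K A2G1F/A2G1F"])


class TestTriplicateCi:
    def test_identical_replicates(self):
        assert triplicate_ci([10.0, 10.0, 10.0]) == (10.0, 0.0)

    def test_textbook_example(self):
        mean, halfwidth = triplicate_ci([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert halfwidth == pytest.approx(2.484, abs=5e-4)  # t(0.975, 2) = 4.3027

    def test_halfwidth_scales_with_sd(self):
        _, hw1 = triplicate_ci([1.0, 2.0, 3.0])
        _, hw5 = triplicate_ci([5.0, 10.0, 15.0])
        assert hw5 == pytest.approx(5 * hw1)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            triplicate_ci([1.0])


class TestRecovery:
    def test_zero_noise_fraction_recovery(self, panel_run):
        """Noise-free synthetic run: fractions recovered within 0.002."""
        run, truth, library = panel_run
        table = mq.quantify_run(run, library, rt_window=(7.0, 13.0))
        for label, expected in truth.true_fractions().items():
            assert table.fraction(label) == pytest.approx(expected, abs=0.002)

    def test_auto_window_covers_simulated_peak(self, panel_run):
        run, truth, library = panel_run
        chrom = extract_eicc(run, library[0])
        lo, hi = auto_rt_window(chrom)
        center = next(
            c["rt_center"] for c in truth.components if c["label"] == library[0].label
        )
        assert lo < center < hi
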