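import pytest

from vdist.cells import (
    AssayReadout,
    cell_volume,
    intracellular_kp,
    plasma_referenced_kp,
    strategy_vdss,
)
from vdist.errors import AnalyticalFailureError, DomainError, InputError
from vdist.ionization import CompoundProperties
from vdist.kp import KpVector, kp_all_tissues
from vdist.vdss import erythrocyte_plasma_ratio, vdss_from_kp


def readout(ar_cells=1.3, ar_medium=0.03, protein=10.0, rep=1):
    return AssayReadout(
        compound_id="A", cell_type="adipocyte",
        area_ratio_cells=ar_cells, area_ratio_medium=ar_medium,
        protein_mg=protein, replicate=rep,
    )


COMPOUND = CompoundProperties("C1", logP=2.0, fup=0.5, BPR=1.5, pKa_basic=9.0)


class TestCellVolume:
    def test_printed_conversion_factor(self):
        assert cell_volume(1.0) == pytest.approx(6.5)

    def test_ten_mg_protein(self):
        assert cell_volume(10.0) == pytest.approx(65.0)

    def test_nonpositive_protein_rejected(self):
        with pytest.raises(DomainError):
            cell_volume(0.0)


class TestIntracellularKp:
    def test_worked_example_kp_100(self):
        # (1.3 * 150 µl) / (65 µl) / 0.03 = 100
        assert intracellular_kp(readout()) == pytest.approx(100.0)

    def test_no_accumulation_gives_zero(self):
        assert intracellular_kp(readout(ar_cells=0.0)) == 0.0

    def test_common_scaling_of_both_ratios_cancels(self):
        a = intracellular_kp(readout(ar_cells=1.3, ar_medium=0.03))
        b = intracellular_kp(readout(ar_cells=2.6, ar_medium=0.06))
        assert a == pytest.approx(b)

    def test_replicates_averaged_after_per_well_kp(self):
        reps = [readout(ar_cells=1.3, rep=1), readout(ar_cells=2.6, rep=2)]
        assert intracellular_kp(reps) == pytest.approx(150.0)

    def test_zero_medium_signal_flags_analytical_failure(self):
        with pytest.raises(AnalyticalFailureError, match="A"):
            intracellular_kp(readout(ar_medium=0.0))


class TestPlasmaReferencing:
    def test_unbound_plasma_is_identity(self):
        assert plasma_referenced_kp(100.0, 1.0) == 100.0

    def test_multiply_convention(self):
        assert plasma_referenced_kp(100.0, 0.1) == pytest.approx(10.0)

    def test_divide_convention_is_switchable(self):
        assert plasma_referenced_kp(100.0, 0.1, convention="divide") == pytest.approx(1000.0)

    def test_missing_fup_rejected(self):
        with pytest.raises(InputError):
            plasma_referenced_kp(100.0, 0.0)


class TestStrategies:
    def test_combined_with_unit_kp_collapses_to_all_ones_baseline(self, phys):
        pred = strategy_vdss("combined", COMPOUND, phys, Kp_fat=1.0, Kp_muscle=1.0)
        ones = KpVector("C1", {t: 1.0 for t in phys.tissues}, 0.0, 0.0)
        ep = erythrocyte_plasma_ratio(COMPOUND.BPR, phys.Hct)
        assert pred.vdss == vdss_from_kp(ones, phys, ep).vdss

    def test_adipocyte_and_myocyte_baselines_agree_at_unit_kp(self, phys):
        a = strategy_vdss("adipocyte_only", COMPOUND, phys, Kp_fat=1.0)
        m = strategy_vdss("myocyte_only", COMPOUND, phys, Kp_muscle=1.0)
        assert a.vdss == m.vdss

    def test_adipocyte_only_direct_sum(self, phys):
        comp = CompoundProperties("C2", logP=1.0, fup=0.5, BPR=1.0)
        pred = strategy_vdss("adipocyte_only", comp, phys, Kp_fat=10.0)
        expected = (
            phys.V_P + phys.V_E * 1.0
            + 10.0 * phys.volumes["adipose"]
            + sum(v for t, v in phys.volumes.items() if t != "adipose")
        )
        assert pred.vdss == pytest.approx(expected, rel=1e-12)

    def test_separate_fed_mechanistic_values_reproduces_mechanistic_vdss(self, phys):
        vec = kp_all_tissues(COMPOUND, phys)
        pred = strategy_vdss(
            "separate", COMPOUND, phys,
            Kp_fat=vec["adipose"], Kp_muscle=vec["muscle"], mechanistic_kp=vec,
        )
        ep = erythrocyte_plasma_ratio(COMPOUND.BPR, phys.Hct)
        assert pred.vdss == vdss_from_kp(vec, phys, ep).vdss

    def test_average_fills_other_tissues_with_mean(self, phys):
        pred = strategy_vdss("average", COMPOUND, phys, Kp_fat=4.0, Kp_muscle=2.0)
        expected = (
            phys.V_P
            + phys.V_E * erythrocyte_plasma_ratio(COMPOUND.BPR, phys.Hct)
            + 4.0 * phys.volumes["adipose"]
            + 2.0 * phys.volumes["muscle"]
            + 3.0 * sum(
                v for t, v in phys.volumes.items()
                if t not in ("adipose", "muscle")
            )
        )
        assert pred.vdss == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("strategy", ["adipocyte_only", "combined", "average"])
    def test_monotone_in_supplied_kp(self, phys, strategy):
        kwargs_lo = {"Kp_fat": 1.0, "Kp_muscle": 1.0}
        kwargs_hi = {"Kp_fat": 2.0, "Kp_muscle": 1.0}
        lo = strategy_vdss(strategy, COMPOUND, phys, **kwargs_lo)
        hi = strategy_vdss(strategy, COMPOUND, phys, **kwargs_hi)
        assert hi.vdss > lo.vdss

    def test_missing_required_kp_names_strategy(self, phys):
        with pytest.raises(InputError, match="myocyte_only"):
            strategy_vdss("myocyte_only", COMPOUND, phys, Kp_fat=1.0)

    def test_separate_requires_mechanistic_vector(self, phys):
        with pytest.raises(InputError, match="separate"):
            strategy_vdss("separate", COMPOUND, phys, Kp_fat=1.0, Kp_muscle=1.0)
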