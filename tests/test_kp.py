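import numpy as np
import pytest

from _naive import naive_kpu, naive_vdss, ratios
from vdist.errors import DomainError, FloorWarning
from vdist.ionization import CompoundProperties
from vdist.kp import (
    calibrate_ka_ap,
    calibrate_ka_pr,
    kp_all_tissues,
    kpu_tissue,
)
from vdist.physiology import PlasmaComposition


def make_compound(
    cid="C", logP=2.0, fup=0.5, BPR=1.5, pKa_acidic=None, pKa_basic=None
):
    return CompoundProperties(
        compound_id=cid, logP=logP, fup=fup, BPR=BPR,
        pKa_acidic=pKa_acidic, pKa_basic=pKa_basic,
    )


class TestCalibrateKaPr:
    def test_fully_unbound_drug_has_no_protein_affinity(self, phys):
        assert calibrate_ka_pr(1.0, -30.0, PlasmaComposition(0.0, 0.0)) == 0.0

    def test_lipid_free_plasma_hand_value(self):
        # fup 0.5, P -> 0: Ka_PR = 1/0.5 - 1 = 1 exactly
        assert calibrate_ka_pr(0.5, -300.0, PlasmaComposition(0.0, 0.0)) == 1.0

    def test_hand_arithmetic_with_plasma_lipid(self):
        # fup 0.1, P = 1: 10 - 1 - (0.0023 + 1.0*0.0013) = 8.9964
        plasma = PlasmaComposition(f_NL=0.0023, f_NP=0.0013)
        assert calibrate_ka_pr(0.1, 0.0, plasma) == pytest.approx(8.9964)

    @pytest.mark.parametrize("fup", [0.0, -0.1, 1.5])
    def test_fup_outside_unit_interval_rejected(self, fup):
        with pytest.raises(DomainError):
            calibrate_ka_pr(fup, 2.0, PlasmaComposition(0.0, 0.0))

    def test_negative_bracket_floors_at_zero_with_warning(self, phys):
        with pytest.warns(FloorWarning):
            assert calibrate_ka_pr(1.0, 5.0, phys.plasma) == 0.0


class TestCalibrateKaAp:
    def test_neutral_compound_carries_no_information(self, phys):
        assert calibrate_ka_ap(make_compound(BPR=5.0), phys) == 0.0

    def test_acid_has_no_cationic_species(self, phys):
        comp = make_compound(pKa_acidic=4.0, BPR=2.0)
        assert calibrate_ka_ap(comp, phys) == 0.0

    def test_bpr_at_physical_floor_warns_and_returns_zero(self, phys):
        comp = make_compound(pKa_basic=9.0, BPR=1 - phys.Hct)
        with pytest.warns(FloorWarning, match="floor"):
            assert calibrate_ka_ap(comp, phys) == 0.0

    def test_base_matches_spreadsheet_evaluation(self, phys):
        comp = make_compound(logP=2.0, fup=0.5, BPR=1.5, pKa_basic=9.0)
        bc = phys.blood_cell
        x_bc, z_bc = ratios(None, 9.0, bc.pH)
        x_p, z_p = ratios(None, 9.0, phys.pH_P)
        d_p = 1 + x_p + z_p
        p = 10.0 ** 2.0
        kpu_bc = (1.5 - (1 - phys.Hct)) / (phys.Hct * 0.5)
        expected = (
            kpu_bc
            - ((1 + x_bc + z_bc) / d_p) * bc.f_IW
            - (p * bc.f_NL + (0.3 * p + 0.7) * bc.f_NP) / d_p
        ) * d_p / (bc.AP * x_bc)
        assert calibrate_ka_ap(comp, phys) == pytest.approx(expected, rel=1e-12)


class TestKpuTissue:
    def test_water_only_limit_is_exact(self, phys):
        # P -> 0, no ionization, no protein affinity: only the water terms
        # and the water-like 0.7*f_NP phospholipid residue survive
        comp = make_compound(logP=-300.0, fup=1.0, BPR=1.0)
        for name, t in phys.tissues.items():
            kpu = kpu_tissue(comp, t, Ka_AP=0.0, Ka_PR=0.0)
            assert kpu == pytest.approx(
                t.f_EW + t.f_IW + 0.7 * t.f_NP, abs=1e-12
            ), name

    def test_no_equation_switch_at_pka_seven(self, phys):
        t = phys.tissues["muscle"]
        lo, mid, hi = (
            kpu_tissue(make_compound(pKa_basic=pk), t, 1.0, 1.0)
            for pk in (6.999, 7.000, 7.001)
        )
        # smooth in pKa: the two half-steps agree (a switch would show as a
        # jump in one of them) and the total change is a fraction of a %
        assert abs((hi - mid) - (mid - lo)) < 1e-5 * mid
        assert abs(hi - lo) / mid < 5e-3

    def test_muscle_base_matches_term_by_term_evaluation(self, phys):
        comp = make_compound(logP=2.0, fup=0.5, BPR=1.5, pKa_basic=9.0)
        expected = naive_kpu(comp, "muscle", phys, ka_ap=2.0, ka_pr=1.5)
        assert kpu_tissue(comp, phys.tissues["muscle"], 2.0, 1.5) == pytest.approx(
            expected, rel=1e-12
        )

    def test_monotone_in_logp(self, phys):
        t = phys.tissues["liver"]
        values = [
            kpu_tissue(make_compound(logP=lp), t, 0.5, 0.5)
            for lp in np.linspace(-2, 6, 30)
        ]
        assert np.all(np.diff(values) >= 0)


class TestKpAllTissues:
    def test_covers_every_tissue_positively(self, phys):
        vec = kp_all_tissues(
            make_compound(pKa_acidic=4.0, pKa_basic=9.0, BPR=1.2), phys
        )
        assert set(vec.kp) == set(phys.tissues)
        assert all(v > 0 for v in vec.kp.values())

    def test_doubling_bpr_raises_kp_of_ap_tissues_for_a_base(self, phys):
        lo = kp_all_tissues(make_compound(pKa_basic=9.5, BPR=1.5), phys)
        hi = kp_all_tissues(make_compound(pKa_basic=9.5, BPR=3.0), phys)
        for name, t in phys.tissues.items():
            if t.AP > 0:
                assert hi[name] > lo[name], name

    def test_missing_bpr_defaults_to_unity(self, phys):
        explicit = kp_all_tissues(make_compound(pKa_basic=9.0, BPR=1.0), phys)
        defaulted = kp_all_tissues(make_compound(pKa_basic=9.0, BPR=None), phys)
        assert defaulted.kp == explicit.kp

    def test_continuity_across_pka_sweep(self, phys):
        """Kpu is continuous in pKa_basic over [4, 11]: each grid step change
        is bounded by three times its neighbours (a jump would spike)."""
        grid = np.arange(4.0, 11.0 + 1e-9, 1e-2)
        kpu = np.array([
            kp_all_tissues(
                CompoundProperties(
                    "C", logP=2.0, fup=0.5, BPR=1.5,
                    pKa_basic=float(pk), ionization_class="base",
                ),
                phys,
            )["muscle"]
            for pk in grid
        ])
        diffs = np.abs(np.diff(kpu))
        for i in range(1, len(diffs) - 1):
            neighbour = max(diffs[i - 1], diffs[i + 1])
            assert diffs[i] <= 3 * neighbour + 1e-12

    def test_matches_naive_oracle_on_random_compounds(self, phys):
        rng = np.random.default_rng(42)
        for _ in range(100):
            kind = rng.integers(4)
            comp = make_compound(
                cid=f"R{_}",
                logP=float(rng.uniform(-2, 6)),
                fup=float(rng.uniform(0.01, 1.0)),
                BPR=float(rng.uniform(0.6, 5.0)),
                pKa_acidic=float(rng.uniform(2, 7.4)) if kind in (0, 3) else None,
                pKa_basic=float(rng.uniform(6.1, 11)) if kind in (1, 3) else None,
            )
            mine = naive_vdss(comp, phys)
            vec = kp_all_tissues(comp, phys)
            total = (
                phys.V_P
                + phys.V_E * max((comp.BPR - 1 + phys.Hct) / phys.Hct, 0.0)
                + sum(vec[t] * phys.volumes[t] for t in phys.tissues)
            )
            assert total == pytest.approx(mine, rel=1e-10)
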