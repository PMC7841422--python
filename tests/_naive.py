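"""Independent straight-line re-evaluation of the partition equations.

Deliberately written as unvectorised term-by-term arithmetic with no reuse
of the package's helper functions, so it can serve as an oracle for the
library implementation.
"""

import math


def ratios(pka_a, pka_b, ph):
    x = 10.0 ** (pka_b - ph) if pka_b is not None else 0.0
    z = 10.0 ** (ph - pka_a) if pka_a is not None else 0.0
    return x, z


def naive_vdss(comp, phys):
    """Full mechanistic V_D,ss for one compound, term by term."""
    fup = comp.fup
    bpr = comp.BPR if comp.BPR is not None else 1.0
    p = 10.0 ** comp.logP
    x_p, z_p = ratios(comp.pKa_acidic, comp.pKa_basic, phys.pH_P)
    d_p = 1.0 + x_p + z_p

    # protein affinity from the plasma mass balance
    ka_pr = 1.0 / fup - 1.0 - (p * phys.plasma.f_NL + (0.3 * p + 0.7) * phys.plasma.f_NP)
    if ka_pr < 0:
        ka_pr = 0.0

    # acidic-phospholipid affinity from erythrocyte partitioning
    bc = phys.blood_cell
    x_bc, z_bc = ratios(comp.pKa_acidic, comp.pKa_basic, bc.pH)
    if x_bc == 0.0:
        ka_ap = 0.0
    else:
        kpu_bc = (bpr - (1.0 - phys.Hct)) / (phys.Hct * fup)
        if kpu_bc <= 0:
            ka_ap = 0.0
        else:
            resid = (
                kpu_bc
                - ((1.0 + x_bc + z_bc) / d_p) * bc.f_IW
                - (p * bc.f_NL + (0.3 * p + 0.7) * bc.f_NP) / d_p
            )
            ka_ap = resid * d_p / (bc.AP * x_bc)
            if ka_ap < 0:
                ka_ap = 0.0

    total = 0.0
    for name, t in phys.tissues.items():
        x_t, z_t = ratios(comp.pKa_acidic, comp.pKa_basic, t.pH_IW)
        p_nl = 10.0 ** comp.logD74 if name == "adipose" else p
        ra = t.RA_lip if comp.ionization_class == "base" else t.RA_alb
        kpu = (
            t.f_EW
            + ((1.0 + x_t + z_t) / d_p) * t.f_IW
            + (p_nl * t.f_NL + (0.3 * p + 0.7) * t.f_NP) / d_p
            + ka_ap * t.AP * x_t / d_p
            + ka_pr * ra
        )
        total += fup * kpu * phys.volumes[name]

    ep = (bpr - 1.0 + phys.Hct) / phys.Hct
    if ep < 0:
        ep = 0.0
    return phys.V_P + phys.V_E * ep + total


def naive_kpu(comp, tissue_name, phys, ka_ap, ka_pr):
    """Single-tissue Kpu with externally supplied affinity constants."""
    t = phys.tissues[tissue_name]
    p = 10.0 ** comp.logP
    x_p, z_p = ratios(comp.pKa_acidic, comp.pKa_basic, phys.pH_P)
    d_p = 1.0 + x_p + z_p
    x_t, z_t = ratios(comp.pKa_acidic, comp.pKa_basic, t.pH_IW)
    p_nl = 10.0 ** comp.logD74 if tissue_name == "adipose" else p
    ra = t.RA_lip if comp.ionization_class == "base" else t.RA_alb
    return (
        t.f_EW
        + ((1.0 + x_t + z_t) / d_p) * t.f_IW
        + (p_nl * t.f_NL + (0.3 * p + 0.7) * t.f_NP) / d_p
        + ka_ap * t.AP * x_t / d_p
        + ka_pr * ra
    )
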