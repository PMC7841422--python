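# Methods

## Model

V<sub>D,ss</sub> is assembled plasma-referenced from per-tissue partition
coefficients:

    V_D,ss = V_P + V_E·(E/P) + Σ_T Kp_T·V_T            [L/kg]
    E/P    = (BPR + Hct − 1)/Hct

Tissue partitioning uses a unified continuous equation of the
Rodgers–Rowland family. Tissue-to-plasma-water partitioning sums five
mechanisms — extracellular water, pH-partitioned intracellular water,
neutral lipid + neutral phospholipid, acidic-phospholipid binding of the
cationic species, and extracellular protein binding — and every term is
present for every compound; terms vanish smoothly when their driver
(cation ratio, lipophilicity, binding affinity) is zero. This removes the
discontinuity of formulations that switch equation sets at pKa 7, which is
the property the continuity tests exercise.

Assumptions worth stating explicitly:

- Partitioning is passive and at equilibrium; transporter-mediated uptake
  is not modelled, so tissues with strong active uptake (e.g. liver via
  OATPs) can be under-predicted.
- One acidic and one basic pKa per compound; multiprotic behaviour beyond
  that is out of scope.
- Binding to extracellular protein is attributed to lipoprotein for bases
  and albumin for other classes, with the tissue:plasma concentration
  ratios of the packaged table.
- `Ka_AP` is calibrated from erythrocyte partitioning, which presumes the
  acidic-phospholipid affinity measured in blood cells transfers to tissue
  acidic phospholipids.

## Calibration details

`Ka_PR` comes from the plasma mass balance `1/fup = 1 + lipid + Ka_PR`
(plasma protein ratio ≡ 1). `Ka_AP` comes from
`Kpu_BC = (BPR − (1 − Hct))/(Hct·fup)` after subtracting the erythrocyte's
water and neutral-lipid contributions. Both brackets can turn negative for
extreme inputs (very lipophilic neutral with fup ≈ 1; BPR at or below the
physical floor `1 − Hct`); they are floored at 0 with a counted warning
rather than raised, so batch runs complete. Compounds with no cationic
species at erythrocyte pH return `Ka_AP = 0` — their BPR carries no
information about acidic-phospholipid binding.

Numerical choices: E/P is evaluated as `((BPR − 1) + Hct)/Hct`, which is
algebraically identical to the definition but keeps the BPR = 1 reference
point at exactly 1.0 in floating point. All logarithms are base 10.
Missing BPR defaults to 1 (the fallback that performs best when no
measurement exists); missing fup is a hard error because both calibrations
need it. The adipose neutral-lipid term uses 10^logD7.4 (derived from logP
and pKa when not supplied) instead of 10^logP, the usual convention for the
mostly-neutral-lipid adipose compartment.

One discrete convention deserves a note: the protein-ratio choice
(lipoprotein for bases, albumin otherwise) switches at the ionization-class
boundary (basic pKa 6.0), producing a small, deliberate jump there. The
partition *equation* is continuous in pKa; continuity tests therefore hold
the class fixed while sweeping pKa.

## Packaged physiology

`human_70kg` ships as a versioned CSV (13 tissues: adipose, bone, brain,
gut, heart, kidney, liver, lung, muscle, pancreas, skin, spleen, thymus)
plus a blood-side YAML. Composition values follow the widely reproduced
Rodgers–Rowland tissue-composition tables; per-kg volumes are reference-man
style (adipose 0.20, muscle 0.40 L/kg — together ~62% of body volume —
with plasma 0.0436 and erythrocytes 0.0357 L/kg, Hct 0.45). Vendor PBPK
tools use proprietary tables that differ slightly; absolute Kp values are
therefore table-dependent, while the structural properties (limits,
continuity, monotonicity) are not. Defaults: plasma pH 7.4, intracellular
pH 7.0, erythrocyte pH 7.22, erythrocyte acidic phospholipid 0.5 mg/g.
Validation enforces non-negative fractions summing to ≤ 1 per tissue,
`V_E = Hct/(1 − Hct)·V_P`, and total body volume within 10% of 1 L/kg.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `bpr_default` | 1.0 | BPR used when none is supplied |
| `fup_correction` | on | fup-ratio correction in single-species allometry |
| `two_species.{a0,a_r,a_d}` | 0, 0.5, 0.5 | log-space rat/dog weights (geometric mean); published regression coefficients can be substituted |
| `cell_kp_convention` | multiply | plasma referencing of cell Kp: `Kp_tissue = Kp_cell·fup` (protein-free medium); `divide` selects the inverse convention |
| assay limits | fup 0.001–1, BPR 0–200, logP/logD −3–10 | clipping range for *predicted* inputs; measured values are validated, never clipped |
| `r2_scale` | log | r² on log10 values (V_D,ss spans orders of magnitude); `linear` available |

Fold-boundary rule: fold error exactly equal to k counts as "within
k-fold". The reported r² is the squared Pearson correlation.

## Synthetic-data generator

The generator emulates the statistical structure of clinical evaluation
sets without reproducing any proprietary compound list:

- ionization classes drawn with probabilities (acid 0.25, base 0.40,
  neutral 0.25, zwitterion 0.10), bases most common as in drug space;
- logP ~ Normal(2.5, 1.5) truncated to [−3, 7.5]; acidic pKa uniform on
  [2, 7.4); basic pKa uniform on (6, 11] (the basic range truncated above
  the classification threshold so the intended class always holds);
- logit(fup) ~ Normal(0.5 − (logP − 1), 1), floored at 0.001 — unbound
  fraction falls with lipophilicity;
- each cationic compound receives a true acidic-phospholipid affinity
  (log10 Ka_AP ~ Normal(0.3 + 0.2·logP, 0.6)) and its BPR is *derived*
  from the blood-cell partition at that affinity, so BPR is self-consistent
  with the model, ≥ 1 − Hct by construction and capped at 200;
- observed V_D,ss = mechanistic V_D,ss × 10^ε, ε ~ Normal(0, σ), σ = 0.3
  by default (≈ 2-fold typical scatter, a realistic inter-study spread);
- rat/dog V_D,ss and fup are the human truth transformed through the
  fup-ratio relation with log-normal species noise (log10 sd 0.2/0.15);
  adipocyte/myocyte cell partitions equal the mechanistic tissue Kpu;
  assay readouts are back-computed by inverting the Kp formula and
  perturbed per replicate with log-normal noise at a given CV.

Because ground truth is generated **by the mechanistic model itself**,
recovery statistics (with σ = 0.3: AAFE → 10^(σ√(2/π)) ≈ 1.74, % within
3-fold → 2Φ(log10 3/σ) − 1 ≈ 88.8%) verify noise propagation and
implementation correctness. They say nothing about accuracy on real
compounds, where model misspecification (transporters, unusual binding)
dominates. The generator also does not emulate real chemical-space
structure (scaffold clustering, assay censoring patterns).

Problem sizes used by the test suite and the acceptance script — 300
compounds for exact noise-free recovery, 2000 for the σ = 0.3 closed-form
comparison, 1000 for the BPR sensitivity ordering, 10000 once for class
frequencies — are large enough that the sampling error of each statistic is
an order of magnitude below the asserted tolerance.

## Sensitivity analysis

`bpr_sensitivity_analysis` compares mechanistic AAFE under three BPR input
qualities on the same population: the generating value, the BPR = 1
fallback, and the generating value perturbed by 10^N(0, 0.5) (a poorly
calibrated upstream predictor). The expected and observed ordering is
exact < default < noisy: errors in BPR feed directly into the
acidic-phospholipid calibration for bases, while the neutral fallback is
merely uninformative.

## Known limitations

- Absolute Kp values depend on the packaged composition table; swap in a
  lab-specific table via `load_physiology(path, blood=...)` for vendor
  comparisons.
- The two-species default is the geometric mean, not a fitted regression.
- The "corrected medium concentration" of cell assays is accepted as
  already corrected; no recovery/adsorption correction is applied.
- No lysosomal ion trapping; strongly basic lysosomotropic compounds may
  be under-predicted.
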