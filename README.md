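# vdist

Mechanistic prediction of the human volume of distribution at steady state
(V<sub>D,ss</sub>, L/kg) for small-molecule drug candidates, from routinely
measured physicochemical inputs: log P / log D, pKa, the fraction unbound in
plasma (f<sub>up</sub>) and the blood-to-plasma concentration ratio (BPR).
Written for DMPK scientists and modellers who want early human
V<sub>D,ss</sub> estimates without in vivo data, and a common harness to
compare prediction strategies.

## What it computes

**Tissue partitioning.** For each tissue the tissue-to-plasma-water
partition coefficient is a single continuous five-term sum valid for acids,
bases, neutrals and zwitterions alike:

```
Kpu_T = f_EW
      + ((1 + X_T + Z_T)/(1 + X_P + Z_P)) · f_IW
      + (P·f_NL + (0.3P + 0.7)·f_NP)/(1 + X_P + Z_P)
      + Ka_AP · AP · X_T/(1 + X_P + Z_P)
      + Ka_PR · RA
```

with `P = 10^logP` (adipose neutral lipid uses `10^logD7.4`), `X`/`Z` the
Henderson–Hasselbalch cation/anion ratios at the tissue and plasma pH, and
tissue composition (`f_EW`, `f_IW`, `f_NL`, `f_NP`, acidic phospholipid
`AP`, protein ratios `RA`) from a packaged 70-kg human reference table.
The two affinity constants are calibrated per compound: `Ka_PR` from
f<sub>up</sub> via the plasma mass balance, `Ka_AP` from BPR via the
erythrocyte partition `Kpu_BC = (BPR − (1 − Hct))/(Hct·f_up)`. There is no
pKa-dependent switch between equation sets, so partitioning is continuous
in every input.

**Assembly.** `Kp_T = f_up · Kpu_T` and

```
V_D,ss = V_P + V_E·(E/P) + Σ_T Kp_T·V_T ,     E/P = (BPR + Hct − 1)/Hct
```

**Alternative strategies**, all sharing the same assembly: single-species
allometry from rat or dog (`V_human = V_animal · f_up,human/f_up,animal`,
correction optional), two-species log-linear rat+dog scaling, and five
strategies that plug measured adipocyte/myocyte cell partitioning into fat
and muscle (the tissues holding ~60% of body volume).

**Evaluation.** Percentage of compounds within 2-, 3- and 10-fold of
observed, squared Pearson correlation of log10 values, and the absolute
average fold error `AAFE = 10^(mean |log10(pred/obs)|)`.

**Synthetic data.** Clinical V<sub>D,ss</sub> evaluation sets are
proprietary, so `vdist.simulate` generates compound populations with
drug-like property distributions whose BPR is derived from the same
blood-cell partition the predictor inverts, and whose "observed"
V<sub>D,ss</sub> is the mechanistic value perturbed by log-normal noise.
Recovery statistics on these populations measure noise propagation and
pipeline correctness — not real-world accuracy (see `docs/methods.md`).

## Worked example

```python
import vdist

phys = vdist.load_physiology("human_70kg")
drug = vdist.CompoundProperties(
    "example-base", logP=2.0, fup=0.5, BPR=1.5, pKa_basic=9.0
)
vec = vdist.kp_all_tissues(drug, phys)
print(f"Ka_AP={vec.Ka_AP:.3f}  Ka_PR={vec.Ka_PR:.3f}")
print(f"Kp adipose={vec['adipose']:.3f}  muscle={vec['muscle']:.3f}")
pred = vdist.predict_mechanistic(drug, phys)
print(f"VDss = {pred.vdss:.2f} L/kg  (E/P = {pred.EP_ratio:.2f})")
```

prints

```
Ka_AP=4.485  Ka_PR=0.730
Kp adipose=2.337  muscle=9.282
VDss = 6.69 L/kg  (E/P = 2.11)
```

The strong base partitions mostly via acidic phospholipids (`Ka_AP` is
calibrated > 0 because its BPR of 1.5 exceeds the 1 − Hct = 0.55 floor);
muscle Kp exceeds adipose because muscle carries ~4× the acidic
phospholipid and the cation gains little from adipose neutral lipid at its
log D ≈ 0.4. The result, 6.7 L/kg, is far above total body water (~0.6
L/kg), typical of a basic lipophilic amine.

Command line, end to end on synthetic data:

```
vdist simulate --n 500 --seed 7 --out synth/
vdist predict --input synth/compounds.csv --out results/ \
      --methods mechanistic,allometry_two_species,combined
vdist evaluate --pred results/predictions.csv --obs synth/compounds.csv
```

## Layout

- `src/vdist/physiology.py` — reference human body composition (versioned CSV/YAML data files)
- `src/vdist/ionization.py` — Henderson–Hasselbalch ratios, ionization classes, log D
- `src/vdist/kp.py` — the unified partition equation and its calibrations
- `src/vdist/vdss.py` — whole-body assembly and the E/P ratio
- `src/vdist/allometry.py` — single- and two-species interspecies scaling
- `src/vdist/cells.py` — adipocyte/myocyte assay arithmetic and the five tissue-level strategies
- `src/vdist/tables.py` — compound-table I/O, assay-limit clipping, CHI transform
- `src/vdist/metrics.py` — fold-error statistics and method-comparison reports
- `src/vdist/simulate.py` — synthetic populations, observations, assay readouts
- `src/vdist/pipeline.py`, `src/vdist/cli.py` — orchestration and the `vdist` command
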