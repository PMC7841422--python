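# File formats

All inputs are UTF-8 delimited text (comma by default; tab accepted for
`.tsv`/`.tab`), with a header row, decimal points, and empty cells for
missing values.

## Compound table (`vdist predict --input`, `read_compound_table`)

Column names are case-insensitive.

| column | required | unit / range | notes |
|---|---|---|---|
| `compound_id` | yes | unique label | duplicates are rejected per row |
| `logp` | yes | −3 to 10 | log octanol–water partition of the neutral species |
| `fup` | yes | (0, 1] | values > 1 are read as percent and divided by 100 |
| `bpr` | no | ≥ 0 | blood-to-plasma ratio; defaults to 1 when absent |
| `logd74` | no | −3 to 10 | derived from `logp` + pKa when absent |
| `pka_acidic` | no | −2 to 16 | strongest acidic pKa |
| `pka_basic` | no | −2 to 16 | strongest basic pKa |
| `observed_vdss` | no | L/kg, > 0 | enables evaluation |
| `chi_ph74` | no | — | chromatographic hydrophobicity index at pH 7.4 |
| `kp_cell_adipocyte` | no | ≥ 0 | cell-to-medium partition from adipocyte assay |
| `kp_cell_myocyte` | no | ≥ 0 | cell-to-medium partition from myocyte assay |
| `v_rat`, `v_dog` | no | L/kg, > 0 | animal V_D,ss for allometry |
| `fup_rat`, `fup_dog` | no | (0, 1] | animal unbound fractions |
| `smiles` | no | — | carried through, never interpreted |

Rows failing validation are collected into `rejects.csv` with a reason;
the batch continues.

## Assay readout table (`vdist assay-kp --input`)

One row per replicate well:
`compound_id, cell_type (adipocyte|myocyte), area_ratio_cells,
area_ratio_medium, protein_mg, v_lysate (µl, default 150), replicate`.

## Physiology

Two files (see `src/vdist/data/` for the packaged reference):

- tissue CSV with columns `tissue_name, V_T, f_EW, f_IW, f_NL, f_NP, AP,
  RA_alb, RA_lip, pH_IW` — one row per tissue, volumes in L per kg body
  weight, `AP` in mg/g;
- blood YAML with `V_P, V_E, Hct, pH_P`, `plasma: {f_NL, f_NP}` and
  `blood_cell: {f_IW, f_NL, f_NP, AP, pH}`.

`write_physiology` emits this format; `load_physiology` round-trips it.

## Outputs

`predictions.csv` (`compound_id, method_label, vdss_L_per_kg`),
`report.csv`/`report.json` (`method_label, n, pct_within_2fold,
pct_within_3fold, pct_within_10fold, r2, aafe`), `rejects.csv`, and
`manifest.json` (config, seed, package version, warning counts).
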