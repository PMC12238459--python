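# voxdose

Voxel-phantom Monte Carlo dosimetry for Lu-177 preclinical studies:
synthetic mouse-like voxel phantoms with shoulder tumour xenografts, a
simplified voxel transport engine (straight-line CSDA electrons, analog
photoelectric/Compton photons), and MIRD S-value pipelines with
batch-statistics uncertainties, mass-corrected reference comparisons, and
tumour-size sensitivity reports.

## Layout

| module | role |
|---|---|
| `voxdose.phantom` | analytic-solid voxel phantoms (LR 74×74×184 @ 0.625 mm, HR 128×128×400 @ 0.29 mm), marrow-bearing skeleton, tumour insertion into expanded matrices, activity/attenuation images, HU conversion |
| `voxdose.lu177` | Lu-177 emission model (beta spectrum + discrete lines), samplers, CSDA range utilities |
| `voxdose.engine` | voxel transport, batch execution, merging, history-by-history-style uncertainty grids |
| `voxdose.svalues` | S = D̄/N, δS propagation, S-value tables, mass correction, percent differences, tumour relative change |
| `voxdose.pipeline` | end-to-end runs, manifests, reference comparisons, tumour sweeps |
| `voxdose.reference` | bundled transcriptions of published reference tables |
| `voxdose.cli` | `voxdose` command-line interface |

Bundled data (`src/voxdose/data/`): Lu-177 decay lines, water electron
stopping powers, water photoelectric coefficients, a default HU↔µ curve,
and reference CSVs (organ masses, sphere self-dose S-values, BM S-value
comparisons).

## CLI

```sh
voxdose phantom build --resolution lr --out phantom/
voxdose phantom tumour --resolution hr --mass 0.54 --out phantom_tumour/
voxdose simulate --source spleen --source liver --primaries 100000 --batches 10 \
    --seed 1 --out run/
voxdose sweep --mass 0.13 --mass 0.26 --mass 0.54 --target tumour --target BM \
    --primaries 50000 --batches 4 --out sweep/
voxdose compare --table run/svalues_long.csv --reference ref.csv --out cmp.csv
```

All randomness derives from the master `--seed`; per-batch seeds are
spawned deterministically and recorded in `manifest.json`, so reruns are
bit-identical and merge results are batch-order independent.

## Physics notes

- Electrons: straight-line condensed-history stepping on the water
  range-energy relation, scaled by local density and stopping-power ratio;
  step ≤ min(half voxel, 0.05 mm); termination below 10 keV deposits
  locally. No multiple-scattering deflection, no bremsstrahlung (sub-percent
  at Lu-177 energies).
- Photons: delta-tracking with photoelectric absorption and Klein-Nishina
  incoherent scattering (Kahn sampling); recoil electrons deposit locally;
  cut 10 keV; coherent scattering neglected.
- Uncertainties follow the printed batch-statistics formulas over batch
  dose realizations; S-values use the per-realization primaries count.
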