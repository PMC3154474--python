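# ptgg

Conformational-ensemble analysis of platinum 1,2-intrastrand GG cross-link
(Pt-GG) DNA adducts — the lesions formed by cisplatin and oxaliplatin on
adjacent guanines. Damage-recognition proteins bind the distorted duplex,
not the drug, so the questions this package serves are structural: how
much roll and bend the cross-link imposes, which minor conformations the
Pt-amine hydrogen bonds (to the 3′ guanine O6 and the 3′-flanking thymine
O4) stabilize, and how parameter distributions differ between ensembles
(adduct vs. undamaged, NMR family vs. MD trajectory, one hydrogen-bond
class vs. another).

It is written for structural bioinformaticians working with multi-model
PDB ensembles of platinated duplexes: NMR families of a dozen conformers,
or MD trajectories exported as MODEL blocks.

## What it computes

- **Helical parameters** from coordinates, via standard-reference-frame
  base fitting and the exactly invertible mid-frame (CEHS-style)
  decomposition: shear/stretch/stagger + buckle/propeller/opening per
  pair, shift/slide/rise + tilt/roll/twist per step, plus the inter-guanine
  plane angle and a global bend estimate.
- **Hydrogen-bond classification** of every frame by the geometric
  criterion d(D···A) ≤ 3.5 Å and ∠(D–H···A) ≥ 135°, into the classes
  {None, G7-O6, T8-O4, T8-O4+G7-O6}, with frequency tables and per-bond
  occupancies.
- **Ensemble comparison**: Welch Z-scores of parameter means (small NMR
  families), exact two-sample Kolmogorov–Smirnov statistics and
  critical-value-normalized KS ratios (large ensembles), heat-map
  matrices, and class-conditional histograms jointly normalized over all
  frames.
- **Superposition machinery**: Kabsch alignment, iterative mean
  structures, per-model family RMSD, centroid extraction, running-average
  RMSD series.
- **A synthetic duplex generator** that builds ensembles with known
  helical-parameter distributions, an optional Pt moiety, and planted
  hydrogen-bond class fractions — exact ground truth for every recovery
  test (the builder is the machine-precision inverse of the analyzer).

See `docs/methods.md` for conventions, assumptions and limitations.

## Worked example

```python
from ptgg import (GeneratorSpec, plant_hbond_classes, classify_frames,
                  frequency_table, aggregate_bond_occupancy,
                  compute_param_table, sample_ensemble, comparison_matrix,
                  family_rmsd)
from ptgg.structure_io import heavy_atom_selector

# a 5000-frame platinated ensemble with planted class fractions
spec = GeneratorSpec(pt=True, preset="pt_gg", n_frames=5000, seed=0,
                     class_fractions=(0.20, 0.59, 0.06, 0.15))
built = plant_hbond_classes(spec)
freq = frequency_table(classify_frames(built.ensemble))
for name, pct in freq.percentages.items():
    print(f"{name:>14s}  {pct:3.0f}%")
print("G7-O6 occupancy:", aggregate_bond_occupancy(freq, "G7-O6"), "%")

# compare a free duplex family against a platinated one
free = sample_ensemble(GeneratorSpec(n_frames=14, seed=1))
adduct = sample_ensemble(GeneratorSpec(n_frames=14, seed=2,
                                       pt=True, preset="pt_gg"))
m = comparison_matrix({"free": compute_param_table(free.ensemble),
                       "pt": compute_param_table(adduct.ensemble)},
                      [("free", "pt")], "z")
param, comp = m.max_cell()
print(f"largest |Z|: {param} ({m.data.loc[param, comp]:.1f})")

rep = family_rmsd(free.ensemble, heavy_atom_selector, "non-H atoms")
print(f"family RMSD ({rep.selection_tag}): {rep.mean:.2f} +/- {rep.sd:.2f} A")
```

prints

```
         G7-O6   59%
         T8-O4    6%
   T8-O4+G7-O6   14%
          None   21%
G7-O6 occupancy: 73 %
largest |Z|: step_6_7_roll (-23.1)
family RMSD (non-H atoms): 1.18 +/- 0.33 A
```

The classifier recovers the planted class fractions to sampling accuracy;
the bond occupancy sums every class containing the bond (59 + 14). The
largest Z-score between the free and platinated families lands on the
central-step roll — the hallmark Pt-GG distortion that the `pt_gg` preset
plants — and the family RMSD line is the usual NMR-family precision
statistic (each model against the iteratively converged mean structure).

## Command line

The `ptgg` entry point wraps the same library:

```sh
ptgg simulate --n-frames 200 --pt --preset pt_gg \
     --fractions 0.2,0.59,0.06,0.15 --seed 7 --out sim   # multi-model PDB
ptgg hbonds sim.pdb                                      # class frequencies
ptgg superpose sim.pdb --selection heavy                 # family RMSD
ptgg analyze --config run.yaml                           # full pipeline
ptgg compare --config run.yaml --statistic ks_ratio      # heat-map matrix
```

`analyze`/`compare` take a declarative YAML config (inputs, cutoffs,
designation, burn-in, statistic, seed, output directory); every emitted
file is tab-separated text, listed with its SHA-256 checksum in
`run_report.yaml`, and reruns of one config are byte-identical.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a planted ensemble from scratch, runs the full analysis
pipeline on it (classification, frequency table, histograms), computes a
free-vs-platinated family heat map and a family-RMSD/centroid report, and
writes the results JSON. All randomness derives from `--seed`.
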