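# dapsol

Solubility modeling for dapsone (4,4'-diaminodiphenylsulfone), an
antibacterial drug whose poor aqueous solubility and unmeasurable fusion
thermodynamics (its stable polymorph converts below the melting point) make
it a hard case for first-principles solubility prediction.  The package is
aimed at physical/pharmaceutical chemists who need to (i) standardize
multi-source solubility–temperature data, (ii) screen thermodynamic-backend
predictions without fusion properties, and (iii) train descriptor-based
regression models of solubility.

Four library stages, also exposed as CLI subcommands:

* **curation** — fits the three-parameter van't Hoff model
  `ln x = A + B/T + C/T²` per (solute, solvent, composition) system by exact
  least squares and emits consensus `log10 x` values back-calculated at the
  experimental temperatures.  Ships the newly measured dapsone dataset
  (five neat solvents × four temperatures).
* **consonance** — the reference-solvent workaround for missing fusion data:
  `ΔG_fus(T) = μ_gap(ref, T, x_exp) − RT·ln x_exp` anchored to an
  experimental point, then the solid–liquid equilibrium solved for every
  other solvent.  Builds the target×reference MAPE heat-map matrix, discovers
  solvent classes from signed-error profiles, and exhaustively selects the
  minimal reference set ("consonance solvents"), excluding singletons that
  match no class.  The thermodynamic engine is a pluggable backend (CSV of
  chemical-potential gaps).
* **descriptors** — conformer-resolved pair energetics → affinity
  descriptors: 2.5 kcal/mol energy-window filtering, Kabsch-RMSD
  deduplication, Boltzmann-weighted corrections, reaction Gibbs energies
  ΔG_r of X + Y → XY, and the descriptor↔solubility R² diagnostic.
* **ensemble** — hyperparameter tuning of ten regressor families under a
  custom loss `val_MAE + α·mean(max(0, val − train))` built from
  cross-validated learning curves, selection of the nine joint-low-AUC
  members, and sign-constrained (negative-only) prediction averaging.

A seeded **synthetic** module generates solubility profiles, class-structured
mock backends, and descriptor tables with planted ground truth, so the whole
pipeline is validated by parameter recovery (see `docs/methods.md` for what
that does and does not demonstrate).

## Worked example

```python
import dapsol

records = dapsol.load_dapsone_table1()
print(dapsol.solubility_ratio(records, "NMP", 313.15, 298.15))   # 10.6
print(dapsol.solubility_ratio(records, "DMSO", 313.15, 298.15))  # 2.4

fit = dapsol.fit_vanthoff([r for r in records if r.solvent_id == "NMP"])
print(f"A={fit.A:.3f}  B={fit.B:.1f} K  C={fit.C:.4g} K^2  rmsd={fit.rmsd_lnx:.4f}")
# A=38.432  B=-10828.7 K  C=-5.928e+05 K^2  rmsd=0.0035
print(f"{dapsol.backcalc(fit, 308.15):.4f}")                     # -1.2821
```

Dapsone's solubility in NMP rises 10.6-fold between 298.15 K and 313.15 K
(only 2.4-fold in DMSO), and the fitted curve reproduces the measured NMP
profile to 0.0035 in ln x; the back-calculated `log10 x = −1.2821` at
308.15 K is the consensus value a model would train on.

The consonance screen on a synthetic 12-solvent, 3-class study:

```python
from dapsol import build_consensus, consonance_screen
from dapsol.synthetic import (gen_solvent_space, gen_truth,
                              gen_solubility_profiles, gen_mock_backend)

solvents = gen_solvent_space(4, (-1.0, 0.0, 1.0), seed=1, within_class_sd=0.05)
truth = gen_truth(solvents, seed=1)
recs = gen_solubility_profiles(solvents, [288.15 + 5*i for i in range(8)], truth, seed=2)
consensus = build_consensus({"synthetic": recs})
backend = gen_mock_backend(solvents, truth, seed=3)

matrix, classes, result = consonance_screen(backend, consensus, k=3)
print(result.reference_set)            # ('acc02', 'don00', 'pol03')
print(f"{result.overall_mape:.2f}%")   # 1.19%
```

One reference per planted chemistry class is recovered, and the mean
decadal-log MAPE of predicting every solvent from its class reference is
1.19% — the within-class backend scatter is all that survives.

From the shell:

```sh
dapsol run --seed 1 --out run1        # simulate → curate → screen → train → predict
dapsol screen --seed 1 --out run2     # just the consonance screen on synthetic data
```

`run1/manifest.json` records the config, seeds, and per-stage metrics;
re-running the same config reproduces the deterministic outputs bit-for-bit.

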