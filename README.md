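# praakit

Kinetic analysis toolkit for the **peroxyl-radical averting assay (PRAA)**:
a competitive AAPH/ABTS microplate assay in which a thermal azo initiator
(AAPH) generates peroxyl radicals (ROO•) at a steady, temperature-controlled
rate and the radicals oxidise an indicator (ABTS) to the green radical
cation ABTS•+, read at 414 nm in kinetic mode over 0–70 min. An antioxidant
in the well competes with the indicator for the radical flux, so its
potency shows up as a depressed or delayed colour curve.

The package is for assay developers and screening groups who need the whole
numeric chain behind such an assay in one tested place:

- **`praakit.simulate`** — a mechanistic simulator of 96-well plate reads.
  Radical flux Rg(t) = 2·e·k_d·[AAPH]₀·e^(−k_d·t) is partitioned between
  indicator and antioxidant in proportion to their scavenging fluxes
  k_ABTS[ABTS] and k_AH[AH]; a stoichiometric scavenger (n radicals trapped
  per molecule) produces an induction time ≈ n[AH]₀/Rg(0). The noise-free
  control curve is calibrated to rise linearly 0.06 → 0.60 OD over 70 min
  and plateau at 0.85 OD by 24 h (indicator depletion).
- **`praakit.plate_io`** — long/wide CSV plate reads, layout files, blank
  correction, reduction limits.
- **`praakit.reductions`** — the six microplate kinetic reductions
  (Vmax by creeping iteration, slope, trapezoid AUC, peak, mean, time to
  half-max) plus a tangent-intersection lag-time estimator. "Not detected"
  (ND) is a first-class result.
- **`praakit.inhibition`** — percent inhibition
  `(Control − Unknown)/Control × 100` of any reduction, dose–response
  assembly, 4-parameter log-logistic IC50 fitting with residual
  bootstrap-t confidence intervals, and a seeded IC50 parameter-recovery
  study.
- **`praakit.stats_corr`** — cross-parameter Pearson/RSQ matrices over
  compounds at one dose, and an audit that flags printed (r, r²) report
  pairs that cannot be reconciled by two-decimal rounding.

## Worked example

```python
import praakit as pk

layout = pk.example_layout(
    compounds=("trolox_like", "quercetin_like", "gallate_like", "nicotinate_like"),
    n_controls=3, n_blanks=2,
)
p = pk.SimulationParams(seed=7)                       # 0.005 OD read noise
curves = pk.simulate_plate(p, layout)
corrected = pk.blank_correct(curves, layout)
results = pk.reduce_plate(corrected, layout)

r = results["A1"]                                     # a control well
print(f"vmax={r.vmax_mOD_per_min:.2f} mOD/min  auc={r.auc_OD_min:.2f} OD*min "
      f"peak={r.peak_OD:.3f}  t1/2={r.t_half_max_min:.1f} min")

drs = pk.build_dose_response(results, layout, "auc")
for name, dr in sorted(drs.items()):
    top = [pi for c, pi, _ in dr.points if abs(c - 1e-5) < 1e-11][0]
    print(f"{name:18s} inhibition at 10 uM: {top:5.1f} %")
```

prints (exactly, at seed 7):

```
vmax=11.90 mOD/min  auc=18.84 OD*min peak=0.540  t1/2=35.4 min
gallate_like       inhibition at 10 uM:  30.2 %
nicotinate_like    inhibition at 10 uM:  -0.1 %
quercetin_like     inhibition at 10 uM:  48.7 %
trolox_like        inhibition at 10 uM:  34.3 %
```

The control's Vmax (11.9 mOD/min) exceeds the true underlying rate
(7.7 mOD/min) because the steepest 5-point window rides the read noise —
the classic reason to compare several reductions instead of one. The AUC
inhibition column ranks the compounds by scavenging capacity and is near
zero for the almost-inert nicotinate-like compound; a fast scavenger at
10 µM instead shows a clean induction lag
(`pk.lag_time(corrected[well])` ≈ 41 min for the quercetin-like compound).
Note that under purely competitive kinetics a scavenger is consumed by the
radical flux (~1.5 µM/min here), so sub-10 µM doses rarely hold any
reduction below 50 % of control for the full 70 min window — IC50 fits then
honestly return ND rather than an extrapolated number.

The same pipeline is available from the shell:

```sh
praa simulate  --layout layout.csv --seed 7 --out plate.csv
praa reduce    --in plate.csv --layout layout.csv --out reductions.csv
praa inhibit   --reductions reductions.csv --layout layout.csv --out inhibition.csv
praa ic50      --reductions reductions.csv --layout layout.csv --parameter auc --out ic50.csv
praa correlate --inhibition inhibition.csv --conc 1e-5 --out pearson.csv,rsq.csv
```

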