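# aucbind

Quantitative analysis of the interaction between NADPH–cytochrome P450
oxidoreductase (CPR) and heme-bound heme oxygenase-1 (heme–HO-1):
sedimentation-equilibrium hetero-association fitting with dissociation
constants, spectrophotometric heme-reduction kinetics, HO turnover, and the
percent-of-control summary table — plus a seeded synthetic-data generator
that produces every input with known ground truth.

It is written for protein biophysicists who run analytical
ultracentrifugation (AUC) sedimentation-equilibrium experiments on
hetero-associating protein pairs and follow electron-transfer kinetics by
UV–visible spectroscopy.

## The model

At sedimentation equilibrium an ideal species distributes radially as an
exponential in r² whose steepness is set by its buoyant molar mass. For a
1:1 hetero-associating pair the total absorbance at radius *r* is

```
A(r) = A_HO1(r0)·exp{ M_HO1·H_HO1·(r² − r0²) }
     + A_CPR(r0)·exp{ M_CPR·H_CPR·(r² − r0²) }
     + K·A_HO1(r0)·A_CPR(r0)·exp{ (M_HO1·H_HO1 + M_CPR·H_CPR)(r² − r0²) }
     + δ
```

with `H = (1 − v̄ρ)ω²/2RT` the per-mass buoyancy coefficient and *K* the
association constant on the absorbance scale,
`K = A_complex(r0)/(A_HO1(r0)·A_CPR(r0))`. Dropping the complex term
(`K = 0`) gives the non-complexed model of two independent monomers. *K*
converts to a molar dissociation constant through the extinction
coefficients and optical path length:

```
Kd = (ε_HO1 + ε_CPR)/(ε_HO1·ε_CPR·l) · 1/K
```

The scan is fitted by multi-start nonlinear least squares with the
amplitudes and *K* log-parameterised (positivity without constraints), the
two models are compared by a nested F-test plus a runs test on residual
signs, and the Kd standard error comes from the delta method or a residual
bootstrap.

Reduction kinetics: the ferric→CO-ferrous Soret shift of heme–HO-1 (406 nm
falls, 420 nm rises; Δε 82.2 and 131 mM⁻¹cm⁻¹) gives per-trace initial
reduction rates, and the slope of initial rate versus reductase
concentration is the apparent reduction rate constant (min⁻¹). HO activity
is the bilirubin-formation rate at 468 nm per enzyme.

## Worked example

The repository ships a demo pipeline config
([examples/demo.yaml](examples/demo.yaml)) that simulates a tight-binding
equilibrium experiment (Kd 0.178 μM, 5 μM equimolar loadings), a
reduction-kinetics series (generating slope 122 min⁻¹ at 10–30 nM
reductase) and a bilirubin assay (turnover 1.96 min⁻¹), then refits them:

```bash
aucbind run --config examples/demo.yaml --out demo_out
python -c "import json; print(json.dumps(json.load(open('demo_out/summary.json'))['sedeq'], indent=1))"
```

prints (abridged):

```
"dtgee_5uM": {
  "complex":       { "kd_uM": 0.1559, "kd_se_uM": 0.0685, "rmsd": 0.00523, "converged": true, ... },
  "non_complexed": { "rmsd": 0.11340, ... },
  "comparison":    { "f_statistic": 139165.5, "f_pvalue": 0.0, "preferred": "complex", ... }
}
```

The complex model recovers the generating Kd (0.156 vs 0.178 μM, within
the fit's own standard error), while the monomer-only model fits ~22×
worse in RMSD and is rejected by the F-test; `summary.json` also reports
the recovered rate constant (114.5 min⁻¹) and turnover (1.941 min⁻¹), and
`summary.md` renders the percent-of-control table (e.g. a variant with
0.229 min⁻¹ activity against a 1.96 min⁻¹ control renders as 11.7%).

Python API sketch:

```python
import aucbind as ab

sp, cond = ab.reference_species(), ab.default_conditions()
truth = ab.EquilibriumTruth(ho1=sp["heme_rHO1"], cpr=sp["dTGEE"], conditions=cond,
                            kd_M=0.178e-6, total_ho1_uM=5, total_cpr_uM=5)
scan = ab.simulate_equilibrium_scan(truth, seed=1)
fit = ab.fit_equilibrium(scan.profile, truth.ho1, truth.cpr, cond, "complex")
print(fit.kd * 1e6, "uM +/-", fit.kd_se * 1e6)
```

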