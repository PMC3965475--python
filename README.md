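# lipomet

Lipoprotein metabolism indicators from particle-size profiles, and their
incremental value in 10-year cardiovascular risk prediction.

## The problem

ApoB-containing lipoproteins (VLDL → IDL → LDL) are produced by the
liver, shrink through lipolysis (lipoprotein lipase, LPL, in peripheral
tissue; hepatic lipase, HL, in the liver), attach to the liver, and are
taken up. The measured particle-size distribution — an NMR-style table of
subclass concentrations — is the steady-state fingerprint of those
processes. `lipomet` inverts a steady-state population-balance model of
this cascade to recover, per subject, dimensionless **lipoprotein
metabolism indicators**: ratios of process fluxes that are comparable
between subjects even though the absolute kinetics are identifiable only
up to a common scale.

Two named indicators are the focus:

* **VLDL_E** (extrahepatic lipolysis) = F_LPL(VLDL) / influx(VLDL) —
  LPL lipolysis flux in the VLDL range per particle entering it (liver
  production plus lipolysis of larger particles). Lower VLDL_E: incoming
  VLDL is lipolysed more slowly in peripheral tissue.
* **VLDL_H** (hepatic turnover) = ½ · (mean HL rate constant over VLDL /
  F_prod(VLDL) + F_att(VLDL) / F_prod(VLDL)) — hepatic VLDL processing
  per produced particle. Lower VLDL_H: less hepatic VLDL turnover.

The package then asks the epidemiological question: do these indicators
improve cardiovascular risk prediction beyond conventional risk factors?
It implements the full evaluation machinery — a Gaussian-kernel
L2-regularized SVM risk score with Platt-calibrated probabilities, a
grouped forward variable-selection protocol (six classical variables with
age and sex forced, two cholesterol markers, then indicators gated by an
AUC gain ≥ δ and an r² < 0.25 collinearity screen), and nested-model
comparison by DeLong ΔAUC tests, Net Reclassification Improvement (6% /
20% risk cutoffs), and Integrated Discrimination Improvement.

The real study cohort behind this design is access-restricted, so the
package ships a first-class **synthetic cohort generator**: kinetic
parameters from a log-normal population, profiles with multiplicative
measurement noise, sex-specific risk-factor marginals matching published
baseline characteristics, and a configurable logistic outcome model
(default 10-year event rate 7.32%; lower VLDL_E and VLDL_H raise risk).

## Worked example

```python
from lipomet import SizeGrid, fit_kinetic_parameters, indicator_matrix
from lipomet.cohort import CohortConfig, generate_cohort
from lipomet.evaluation import delong_compare, nri, idi
from lipomet.risk_model import SelectionConfig, fit_fixed_model

grid = SizeGrid.default()                       # 60 bins, 19-80 nm
cohort = generate_cohort(CohortConfig(n_subjects=2000, seed=1))

# invert one subject's noisy subclass profile
obs = {s: cohort.profiles.loc[0, s] for s in grid.subclass_names}
params, diag = fit_kinetic_parameters(obs, grid)
ind = indicator_matrix(params, grid=grid)
print(f"VLDL_E = {ind.vldl_e:.2f}, VLDL_H = {ind.vldl_h:.4f}")

# does adding the indicators to conventional markers + LDLc/HDLc help?
base = ["age", "sex", "cigarettes_per_day", "bp_medication", "sbp_nurse",
        "glucose", "ldl_cholesterol_nmr", "hdl_cholesterol"]
m1 = fit_fixed_model(cohort.data, base, SelectionConfig(seed=1))
m2 = fit_fixed_model(cohort.data, base + ["vldl_e", "vldl_h"],
                     SelectionConfig(seed=1))
y = cohort.data.cvd10y.to_numpy(int)
print(delong_compare(m1.cv_probabilities, m2.cv_probabilities, y))
```

Output:

```
subject S00000: VLDL_E = 17.92, VLDL_H = 0.0174 (objective 9.31e-03)
AUC without indicators: 0.779, with: 0.799
DeLong dAUC = +0.0201, p = 0.0065
NRI = 0.0925 (p = 0.0081)
IDI = 0.0186 (p = 0.0028)
```

Reading this: the cross-validated AUC rises from 0.779 to 0.799 when the
two indicators are added; the DeLong test says that gain is unlikely
under the null (p ≈ 0.007); the NRI says a net 9% of subjects move into
a more appropriate risk class; the IDI says the discrimination slope
(mean predicted risk in events minus non-events) improves by 0.019.
These numbers are for the synthetic cohort — the generator plants the
indicator signal, so they demonstrate that the pipeline can detect it,
not that it exists in any particular population.

## Command line

```bash
lipomet run-all --seed 7                 # simulate -> fit -> select -> report
lipomet simulate-cohort --seed 7 --n 2000
lipomet fit-profiles / compute-indicators / select-markers / evaluate / report
```

Every subcommand accepts `--config config.yaml` (schema in
`lipomet.io.PipelineConfig`) and `--seed`. `run-all` writes the cohort,
fitted parameters, indicator matrix, per-subject predictions with
low/medium/high risk classes, and four report tables
(`table4_roc.csv` … `table7_intermediate.csv`).

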