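# nrtmodel

Modelling of electrically evoked compound action potential thresholds (NRT
thresholds, in device current-level units) in cochlear-implant recipients.

## The problem

When a cochlear implant stimulates the auditory nerve, the smallest current
that elicits a detectable compound action potential — the NRT threshold —
reflects the quality of the electrode–neuron interface. That threshold is
confounded by where each electrode actually sits: insertion depth and
cochlear size vary so much between patients that the same electrode number
can face neurons more than an octave apart. This package implements an
analysis that puts electrodes on a common physiological axis and separates
the biophysical contributions to the threshold:

1. **Tonotopic geometry.** From CT measurements (large cochlear diameter
   *A*, insertion angle of the apical contact) the cochlear duct length is
   estimated by Escudé's formula `CDL = 2.62·A·ln(1 + θ/235)` (`= 4.3259·A`
   at a full 990° coil), each contact is placed as a fraction of duct
   length, and Greenwood's function `F = 165.4·(10^{2.1 z} − 0.88)` converts
   position (fraction of length from the apex) into the characteristic
   neuron frequency (CNF) of the stimulated spiral-ganglion neurons.
2. **Spline mixed model.** Thresholds are modelled as

   `y_ij = x_ij'β + s(CNF_ij) + b_i + ε_ij,  b_i ~ N(0, σ_b²),  ε_ij ~ N(0, σ_ε²)`

   with a subject random intercept, a truncated-power cubic spline
   `s(f) = β₁f + β₂f² + β₃f³ + β₄(f−5000)³₊ + β₅(f−10000)³₊` in frequency,
   and covariates: squared impedance, squared electrode–modiolus distance,
   scalar placement (scala tympani vs vestibuli), array type, etiology and
   age terms. Estimation is REML with the restricted likelihood profiled
   over the variance ratio σ_b²/σ_ε²; inference is by large-sample Wald
   tests; functional forms are compared by BIC.
3. **Residue profiling.** Conditional residuals (after removing fixed
   effects and the subject's BLUP) binned along the tonotopic axis flag
   frequency regions of abnormal neural activation.

Because the underlying patient data are not public, the package includes a
calibrated synthetic-cohort generator that mirrors the reported cohort
structure (31 subjects × 22 electrodes; impedance 8.71 kOhm with
between/within-subject SDs 2.05/1.60; insertion 346 ± 22° perimodiolar,
312 ± 46° straight, 335 ± 35° slim straight; 35.48% of perimodiolar arrays
translocated to the scala vestibuli; duct length 35.05 ± 4.68 mm) and uses
the published adjusted coefficients as generating truth, so every stage is
validated by parameter recovery.

## Worked example

```python
import nrtmodel as nm

table = nm.generate_cohort(nm.default_config(), seed=1)   # 31 x 22 cohort
mv, res = nm.run_multivariate(table)                      # adjusted model
row = mv.set_index("term")
for t in ["impedance_sq", "scala_tympani", "distance_sq"]:
    r = row.loc[t]
    print(f"{t:>15}: beta={r['beta']:.3f}  SE={r['se']:.3f}  p={r['p']:.3g}")
print("sigma_b^2 =", round(res.sigma2_b, 1),
      " sigma_e^2 =", round(res.sigma2_e, 1), " BIC =", round(res.bic, 1))
```

prints

```
   impedance_sq: beta=-0.107  SE=0.020  p=3.8e-08
  scala_tympani: beta=-7.073  SE=6.323  p=0.263
    distance_sq: beta=0.700  SE=2.129  p=0.742
sigma_b^2 = 160.7  sigma_e^2 = 175.6  BIC = 5664.7
```

The squared-impedance coefficient (−0.107 C.L. per kOhm², truth −0.11) says
each extra kOhm² of impedance *lowers* the threshold slightly; the
scala-tympani contrast (−7.07 C.L., truth −8.50) estimates how much lower
thresholds are when the array lies in the intended compartment — with a
single 31-subject replicate its SE is large because scalar placement varies
only between subjects. `nm.frequency_curve(res, table)` returns the fitted
threshold-vs-frequency curve with its 95% band, and
`nm.residue_profile(res, table)` the binned conditional residues.

A command-line interface mirrors the library:

```sh
nrtmodel generate --seed 7 --out cohort.tsv
nrtmodel map-cf --in table.tsv --out table_cnf.tsv --sg-map identity
nrtmodel run-all --cohort cohort.tsv --out report/
nrtmodel recover --reps 20 --seed 1 --out recovery.json
```

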