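# senodyn

Population dynamics of cellular senescence in growing tumors, under the
cancer-stem-cell (CSC) hypothesis.

Long-term tumor cell cultures show a puzzling transient: the fraction of
senescent cells (SA-β-gal–positive) climbs for weeks, peaks — sometimes
near 90% — and then falls back while growth resumes at its original rate.
`senodyn` implements, tests and fits the branching-process models that
explain this behavior, for quantitative cell biologists who want to
confront growth-curve and senescence-marker data with the CSC hypothesis.

## The models

**Hierarchical CSC model.** CSCs divide indefinitely: into two CSCs with
probability p₂, two ordinary cancer cells (CCs) with probability p₀, or
asymmetrically otherwise. Mean kinetics depend only on δ = p₂ − p₀, the
net CSC increase per duplication. CCs double with unit probability but
senesce after N generations; senescent cells die with probability d per
generation. With S(k) CSCs, C_i(k) CCs of age i and B(k) senescent cells:

    S(k+1)     = (1 + δ) S(k)
    C₁(k+1)    = (1 − δ) S(k)
    C_{i+1}(k+1) = 2 C_i(k),   i = 1..N−1
    B(k+1)     = (1 − d) B(k) + C_N(k)

Closed forms exist for a CSC-only seed and for a uniformly age-distributed
CC seed; a mixed initial condition with CSC fraction f_s(0) is their
linear superposition. Asymptotically the senescent fraction tends to
(1 − δ)/(1 + δ + 2d) — independent of N — and reaches 100% in the
homeostatic limit δ = 0, d → 0. For δ = 0, d = 0 (mesenchymal stem cell
cultures) the cumulative population doublings (CPD = log₂ x(t)/x(0))
reduce to CPD = k for k = R·t ≤ N and N − 1 + log₂(k − N + 2) after.

**Stochastic null model.** No hierarchy: every CC duplicates (p), dies
(q) or senesces by random mutation (α); senescent cells die with
probability d. Its senescent fraction relaxes *monotonically* to
α/(p − q + d) — it cannot produce the observed transient peak, which is
the quantitative argument for the hierarchy.

The package also provides an individual-based Monte-Carlo simulator for
both models, simulated senescence- and death-inducing drug treatments,
a joint multi-curve fitter (two subpopulations sharing δ, N, d, R and
differing only in f_s(0)), synthetic-data generators, and crystal-violet
colony-plate analysis (thresholding + Hoshen–Kopelman cluster labeling).

## Worked example

Generate a synthetic sorted-melanoma experiment (two subpopulations that
differ only in initial CSC fraction, observed twice weekly for 140 days)
and refit the six model parameters:

```python
import senodyn as sd
from senodyn.synthetic import NoiseSpec, generate_growth_experiment

params = sd.HierarchicalParams(delta=0.15, n_senescence=100,
                               death_prob=0.05, division_rate=1.1)
datasets = generate_growth_experiment(
    params, (0.05, 0.002),
    noise=NoiseSpec(cpd_sd=0.2, cells_scored=200, seed=42),
    labels=("ABCG2+", "ABCG2-"))
result = sd.fit_model(datasets, seed=0)
print(result.summary())
```

prints

```
chi2 = 133.997, reduced chi2 = 0.8481 (164 points, 6 free parameters)
                   delta = 0.148616 +/- 0.00168  (t = 88.5)
            n_senescence = 100.05 +/- 0.0956  (t = 1.05e+03)  (rounded: 100)
              death_prob = 0.0534887 +/- 0.00533  (t = 10)
           division_rate = 1.0998 +/- 0.00052  (t = 2.11e+03)
               f[ABCG2+] = 0.0521377 +/- 0.0038  (t = 13.7)
               f[ABCG2-] = 0.0020164 +/- 0.000153  (t = 13.2)
```

All six generating parameters are recovered within their reported
standard errors. The CSC-poor population peaks at 82% senescence on day
91 (N/R ≈ 91 days) before relaxing toward the asymptote
(1 − δ)/(1 + δ + 2d) = 0.68, while the CSC-rich one shows no interior
peak — the structure seen in ABCG2-sorted melanoma cultures.

A command-line interface mirrors the library:

```sh
senodyn simulate --model csc --delta 0.15 -n 100 -d 0.05 --rate 1.1 \
    --f0 0.002 --kmax 160 --out trajectory.csv
senodyn fit --datasets a.csv b.csv --out fit.json
senodyn colonies --image plate.png --threshold otsu --out stats.json,sizes.csv
```

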