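# rheumqc

Integrated quality assessment of medicinal rhubarb (*Rheum* spp.), combining
four complementary views of the same material in one tested Python pipeline:

1. **Delayed-luminescence (DL) kinetics** — after white-light excitation,
   herbal powders re-emit ultraweak photon counts whose 30-s decay follows a
   hyperbolic law

   I(t) = I0 / (1 + t/τ)^β,  T = (e^{1/β} − 1)·τ

   with initial intensity *I0* (counts/bin), time scale *τ* (s), decay index
   *β* and derived decay time *T*. Curves are photon counts in 600
   consecutive 0.05-s bins, measured in triplicate; parameters are fitted by
   Poisson maximum likelihood and replicate-averaged per sample.
2. **HPLC fingerprint similarity** — 28 common chromatographic peaks,
   ratioed against reference peak No. 13 (relative retention time and
   relative peak area); the cosine similarity of each sample to the cohort
   mean fingerprint is its reference similarity index (RSI). Samples with
   RSI ≥ 0.885 form group A, RSI ≤ 0.84 group B.
3. **Chemometrics** — PCA, OPLS-DA with stratified cross-validated R²/Q²,
   Ward/Euclidean hierarchical clustering, two-group Student t tests and a
   Spearman correlation network linking the 15 identified compounds (free
   anthraquinones, anthraquinone glucosides + sennoside A, polyphenols) to
   the four DL properties, with edges classed weak/moderate/strong at
   |ρ| > 0.30 / ≥ 0.50 / ≥ 0.70.
4. **Cathartic bioassay statistics** — diarrhea incidence
   (100·n_loose/n_total), charcoal propelling ratio
   (100·distance/intestine length), one-way ANOVA with a
   homogeneity-of-variance-gated post hoc (LSD or Tamhane T2), and
   chi-square plus pairwise Fisher exact tests on diarrhea counts.

Because no public dataset accompanies the analysis, a first-class synthetic
cohort generator (`rheumqc.synthetic_data`) emulates the study designs: a
28-sample commercial cohort whose glycoside-rich minority sub-group carries
idiosyncratically spiked glucoside profiles and DL properties negatively
linked to glycoside content, a 118-sample wild cohort, and a seven-group
mouse bioassay. The package is aimed at analysts in herbal quality control
and chemometrics who want the full chain reproducible from raw inputs.

## Worked example

```python
import numpy as np
from rheumqc.dl_kinetics import simulate_curve, fit_hyperbolic

rng = np.random.default_rng(1)
curve = simulate_curve(I0=1500, Tau=0.2, Beta=1.0, rng=rng)
fit = fit_hyperbolic(curve)
print(f"I0={fit.I0:.0f}  tau={fit.Tau:.3f}  beta={fit.Beta:.3f}  T={fit.T:.3f}")
```

prints

```
I0=1507  tau=0.198  beta=0.999  T=0.341
```

i.e. the fitter recovers the simulated truth (1500, 0.2, 1.0) to well under
a percent on τ and β; `T = (e^{1/β} − 1)·τ ≈ 0.341 s` is the derived decay
time. The full workflows run from the shell:

```bash
rheumqc run-commercial --seed 1 -o out_commercial
rheumqc run-wild --seed 1 -o out_wild
```

The commercial run writes the pairwise similarity matrix, RSI group table,
two-group t tests, per-replicate DL fits, OPLS-DA R²/Q² for the chemical
and DL blocks, and the compound–DL edge list (`correlation_edges.tsv`); the
wild run writes PCA scores, the two-group Ward clustering of DL properties
(cluster 1 = higher DL values) and the group contrasts. Each run leaves a
`manifest.json` with the seed, config hash and package version.

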