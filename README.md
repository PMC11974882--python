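# mdmri

Tools for asking a blunt question about multidimensional relaxation–diffusion
MRI (MD-MRI): when the goal is to regress voxels onto tissue labels, is it
worth inverting the measured signal into a T1–T2–D spectrum at all, or does
the raw signal carry at least as much label information?

The package is aimed at quantitative-MRI methods researchers. It provides:

- **Forward model** — the discretized Fredholm integral of the first kind
  linking a voxel's non-negative spectrum *f*(T1, T2, D) to its measurement
  vector over acquisition tuples β = (τᵢ, τₑ, b):

  *s* = K₀ *f* + ε,  k(α; β) = (1 − 2e^(−τᵢ/T1)) · e^(−τₑ/T2) · e^(−bD),

  with Gaussian or rician (magnitude) noise at a chosen SNR.
- **Spectral inversion** — Tikhonov-regularized non-negative least squares
  f̂ = argmin_{f≥0} ‖s − K₀f‖₂² + λ‖f‖₂², an L-curve rule for λ, and
  marginalization of 3-D spectra to the standard T1–T2, T1–D and T2–D
  correlation maps.
- **NLCS classifier** — the nearest-local-convex-set rule
  h(x*) = argminᵢ min ‖x* − conv(Z_k^i(x*))‖₂, where Z_k^i(x*) are the k
  training points of class *i* nearest to x*; the inner minimum is a convex
  QP over the probability simplex.
- **Information bounds** — plug-in entropies and mutual information for
  discrete variables, the Fano lower bound (H(X|Y) − 1)/log|χ|, the
  Hellman–Raviv upper bound ½H(X|Y), exact Bayes/MAP error, and exact
  data-processing-inequality audits of chains X → Y → Y′.
- **Synthetic phantom** — two voxel classes ("lesion-like" vs control)
  built from shared multi-compartment T1–T2–D pools whose fractions differ
  by an effect size, observed through the kernel with noise. Spectrum
  features are computed from the signals alone, so X → Y → Y′ is Markov by
  construction.
- **Benchmark** — the paired-bootstrap protocol: repeated seeded 50/50
  train/test splits shared across all (classifier, representation) cells,
  scored by Cohen's κ = (p₀ − pₑ)/(1 − pₑ), for 2-NN, MLP, LDA and NLCS on
  the raw-signal and the three 2-D-spectrum representations.

## Worked example

```bash
python examples/04_phantom_benchmark.py
```

generates the default phantom (2 × 100 voxels, SNR 30 rician, effect size
0.15) and runs a 10-resample benchmark:

```
mean Cohen's kappa (10 paired 50/50 resamples)
             T1-D     T2-D    T1-T2   signal
   2-NN     0.466    0.339    0.351    0.769
    MLP     0.665    0.672    0.652    0.848
    LDA     0.507    0.620    0.516    0.877
   NLCS     0.573    0.540    0.460    0.850
```

Rows are classifiers, columns are data representations. Every row is
maximized in the `signal` column: after the lossy, ill-posed inversion, the
reconstructed 2-D correlation maps support noticeably weaker label
regression than the raw measurements they were computed from — the
behaviour the data processing inequality predicts for this pipeline. The
other examples demonstrate single-voxel inversion, the NLCS rule on a
geometry a linear model cannot separate, and the error-bound sandwich on
closed-form channels.

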