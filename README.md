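# poolcomp

Analysis toolkit for **pooled, barcoded long-term competition experiments**
in yeast (or any microbe): hundreds of genetically barcoded strains are
mixed, propagated through serial 1:250 dilutions (~8 generations per
48-hour transfer), and tracked by amplicon sequencing of their barcodes.
`poolcomp` covers the full desk-side analysis of such an experiment —
barcode counting, fitness inference, trajectory analytics, and the
genomics of the clones that win — together with a synthetic-data generator
that reproduces the statistical structure of every input, so the entire
pipeline runs and is tested without any sequencing data.

It is written for experimental-evolution groups running bulk fitness
assays and long-term competitions, and consumed as a Python library
(`import poolcomp`); the `examples/` directory holds one short runnable
script per capability.

## The model

A barcode `b` with selection coefficient `s_b` (natural-log units per
generation, reference strain ≡ 0) and initial frequency `f_b(0)` follows

    f_b(t_k) = f_b(0) · exp( g · Σ_{j<k} (s_b − x̄_j) · Δt_j )

where `g` is generations per transfer (`round(log2(250)) = 8`) and `x̄_j`
is the population mean fitness over inter-transfer interval `j`, measured
from the decline of neutral reference barcodes spiked into the pool
(wild:reference = 9:1). The observed read count `r_{b,t}` is negative
binomial,

    r_{b,t} ~ NB( mean = f_b(t)·R_t , variance = κ_t·f_b(t)·R_t )

with total depth `R_t` and dispersion `κ_t ≥ 1` calibrated from the
scatter of the reference barcodes (κ = 1 is Poisson). Maximising the
likelihood over `(s_b, f_b(0))` per barcode yields the fitness estimate
with a standard error from the observed information plus the shared
mean-fitness calibration noise. Later-interval fitness is the log fold
change `ln f(t₂)/f(t₁)` (also per generation), conditioned on
non-extinction.

Downstream analytics follow the experiment's decision rules: N99
diversity (minimal number of strains holding 99% of the pool), finalists
(≥ 1% frequency in ≥ 1 replicate at its last timepoint), top-95th-
percentile fitness membership, replicate CV. Evolved-clone genomics
classifies variants into de novo heterozygous/homozygous mutations versus
loss of heterozygosity by allele-fraction thresholds (het band
[0.2, 0.8]), and calls aneuploidies as per-chromosome median depth over
genome median depth rounded to the nearest 0.5.

## Worked example

`python examples/01_fitness_inference.py` simulates a 300-strain pool
with 6 reference barcodes (9:1 mass), five 1:250 transfers, 10⁶
reads/timepoint at dispersion κ = 2, and infers fitness:

```
estimated dispersion kappa = 1.39 (true 2.0)
RMSE of fitness recovery   = 0.0020 per generation (300 strains with f0 >= 1e-4)

five fittest strains (s_hat is per-generation log fitness vs the reference):
            s_hat      se  true_fitness  f0_hat
W0295      0.1482  0.0006        0.1492  0.0041
W0059      0.1479  0.0006        0.1496  0.0035
W0067      0.1478  0.0006        0.1494  0.0026
W0128      0.1470  0.0006        0.1489  0.0043
W0165      0.1468  0.0007        0.1479  0.0018
```

`s_hat = 0.148` means that strain gains ~14.8% in log frequency per
generation relative to the neutral reference; the RMSE of 0.002/gen shows
the trajectory likelihood recovers truth an order of magnitude below the
spread of the pool. The other examples exercise barcode counting
(`02`), replicate analytics and finalist calling (`03`), variant
classification (`04`), karyotype calling (`05`) and cytometry-based
fitness (`06`).

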