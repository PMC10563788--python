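# sweepmix

Genome-wide scans for recent positive selection produce one statistic per
SNP — here the integrated haplotype score, iHS — whose distribution mixes
two very different processes: drift and demography acting everywhere, and
selective sweeps elevating |iHS| in a minority of regions. `sweepmix` asks
*which genomic factors predict belonging to the sweep-enriched part of that
distribution*, using a mixture density regression (MDR): a two-component
Gaussian mixture for the windowed response whose mixing probability is a
logistic function of genomic covariates.

For gene-centered window *i* with standardized covariates
*x<sub>i</sub>* and response *Y<sub>i</sub>* (z-scored log of the window
mean |iHS|),

```
p_i    = σ(a + Σ_j b_j x_ij)                      # gate: enriched-component probability
P(Y_i) = p_i N(Y_i | μ1, σ1) + (1 − p_i) N(Y_i | μ0, σ0),   μ1 > μ0
```

fitted by direct maximum likelihood (multi-start L-BFGS-B, analytic
gradient). Each slope *b<sub>j</sub>* is tested with a likelihood-ratio
test against the nested model without that covariate (χ²₁). The mean of the
fitted *p<sub>i</sub>* — the *component magnitude* — summarizes how much of
the genome the sweep-enriched component claims.

The package is aimed at population geneticists running window-based
selection scans: it covers the full path from per-SNP raw iHS tables
(hapbin-style), genetic maps, gene annotations and interval tracks to the
fitted model and per-covariate tests, plus a synthetic-data module (model-
true datasets and a toy genome with construction-time ground truth) that
makes every stage testable without any external downloads.

## Worked example

Simulate a model-true dataset with four named covariates and recover the
generating parameters:

```python
import sweepmix as sm
from sweepmix.model import FitConfig

params = sm.study_parameters(4)          # a=logit(0.3); b=(0.4,-0.4,0.3,-0.3)
cfg = sm.GeneratorConfig(n_windows=10_000, true_params=params, seed=1,
                         covariate_names=("recomb_rate", "gc_content",
                                          "conserved_density", "vip_distance"))
X, Y, labels = sm.simulate_mdr_dataset(cfg)
fit, lrt = sm.lrt_all_covariates(X, Y, FitConfig(restarts=3, seed=0))
print(f"component magnitude = {sm.component_magnitude(fit):.3f}")
print(lrt.to_string(index=False))
```

which prints:

```
component magnitude = 0.270
        covariate     slope  lr_statistic       pvalue
      recomb_rate  0.437334    133.461948 7.164276e-31
       gc_content -0.322890     75.595418 3.481685e-18
conserved_density  0.248199     44.068243 3.171245e-11
     vip_distance -0.321435     73.054141 1.261417e-17
```

The slopes recover the generating values (0.4, −0.4, 0.3, −0.3) within
sampling error and every covariate is decisively significant; the fitted
component means were μ0 = −0.365, μ1 = 1.071 (truth −0.39 and 0.90), and
the component magnitude 0.270 estimates the generating baseline probability
0.3 (the weight of overlapping components is the least sharply identified
quantity — see `docs/methods.md`).

## Command-line pipeline

The same workflow over files:

```bash
# write a toy genome (genetic map, genes, tracks, FASTA, SNP scores)
sweepmix simulate --out-dir demo --seed 3

# per-gene-window covariate table (100 kb windows)
sweepmix features --genes demo/toy_genome/genes.tsv \
    --genetic-map demo/toy_genome/genetic_map.tsv \
    --snps demo/toy_genome/ihs_scores.tsv --fasta demo/toy_genome/genome.fa \
    --coding-bed demo/toy_genome/coding.bed \
    --conserved-bed demo/toy_genome/conserved.bed \
    --dnase-bed demo/toy_genome/dnase.bed --chip-bed demo/toy_genome/chip.bed \
    --gaps-bed demo/toy_genome/gaps.bed \
    --window-size 100000 --out demo/features.tsv

# fit the MDR and test covariates
sweepmix fit --features demo/features.tsv \
    --covariates recomb_rate,gc_content,n_ihs --seed 0 --out demo/fit.tsv
```

`features` interpolates window-edge genetic positions (50 kb search rule),
computes gap-excluded interval densities (conserved track thresholded to
4.17% of the genome, regulatory tracks to 10%), GC content, gene counts,
expression/PPI transforms, VIP distances and bin-standardized window mean
|iHS|; rows missing any covariate are excluded with logged reasons. `fit`
writes a per-covariate slope / LR / p-value table with a header block
recording μ0, σ0, μ1, σ1, intercept, log-likelihood and component
magnitude.

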