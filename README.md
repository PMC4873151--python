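# duporigin

Classify gene duplicates by mode, date dispersed duplicates by colinearity
against an outgroup ladder, and separate ancient post-polyploidy gene
relocations from recent transpositions.

## The problem

Angiosperm genomes carry duplicated genes made by very different mechanisms:
whole-genome duplications (WGD) leave colinear duplicated blocks; tandem and
proximal duplications leave copies near each other in gene order; dispersed
duplicates are neither colinear with nor near their partners.  In core
eudicots, a large share of *dispersed* duplicates is not recent: they are
survivors of the ancient genome triplication (γ, ~125 Mya) that were moved to
new chromosomal positions by large-scale rearrangements shortly after the
event ("relocated γ duplicates").  Telling these classes apart matters because
they differ in function, essentiality, protein-interaction involvement and
selection pressure.

`duporigin` implements the full classification pipeline for anyone working
with plant comparative genomics:

* **colinearity** — dynamic-programming anchor chaining into synteny blocks
  (an explicit, oracle-tested reimplementation of the MCScanX-style block
  finder; reads/writes the `.collinearity` dialect so real MCScanX output can
  be used instead).
* **modes** — duplicate pairs and genes classified as
  `wgd` (colinear anchor pair) > `tandem` (adjacent) > `proximal` (within 10
  annotated genes) > `dispersed`, with smallest-Ks redundancy reduction.
* **epochs** — each dispersed duplicate is dated by its deepest colinear
  outgroup on a divergence-time ladder (for *Arabidopsis*: Al 5, Br 16, Cp 72,
  Tc 90, Pt 107, Vv 113, St 125, Os 148 Mya).  A gene colinear with
  *P. trichocarpa* but not *V. vinifera* was placed in epoch [107, 113) Mya.
  Per-epoch retention rates (duplicates per My) expose relocation bursts;
  dispersed duplicates dated to [107, 125) are called `relocated_gamma`,
  those younger than the focal–Brassica split `transposed`.  The
  relocated fraction is `100 · n_relocated / (n_gamma + n_relocated)`:
  `relocated_fraction(802, 4763) == 85.6`.
* **divergence** — Ks age distributions with secondary-peak detection
  (the relocated-γ signature is a dispersed-duplicate Ks peak in 1.5–2.2),
  Welch t comparisons of Ks/Ka/Ka-Ks, expression divergence (1 − Pearson r),
  and regulation divergence (Jaccard distance of promoter motif hit sets,
  with a −600/+200 promoter window and a simple log-odds PWM scanner).
* **enrichment** — GO fold-enrichment profiles over the large
  biological-process terms, average-linkage clustering at distance 1 − r,
  and Fisher-exact enrichment for essential genes and PPI participation with
  screened-set backgrounds.
* **simulate** — a forward-in-time gene-order simulator (triplication,
  biased fractionation, relocation burst, ongoing single-gene duplications,
  clock-scaled Ks/Ka, synthetic annotations) that provides full ground truth
  for every gene, so the whole pipeline can be validated against the
  generating process.

## Worked example

```python
from duporigin import SimConfig, simulate, run_pipeline_sim, evaluate_calls

result = simulate(SimConfig(seed=1))          # ~2,000 ancestral genes,
pipe = run_pipeline_sim(result)               # triplication at 126 Mya,
print(pipe.origins["origin"].value_counts())  # relocation burst 107-148 Mya
```

```
wgd                2121
tandem              955
dispersed_other     951
proximal            494
relocated_gamma     354
transposed          202
```

The retention-rate table shows the relocation burst: the two epochs inside
the burst window have by far the highest rates, and the oldest epoch — whose
duplicates may predate the triplication and is therefore excluded from the
relocated-γ call — drops back down:

```
epoch_index  start_mya  end_mya  count  rate_per_my
          0        0.0      5.0     69        13.80
          1        5.0     16.0    133        12.09
          2       16.0     72.0    380         6.79
          3       72.0     90.0    124         6.89
          4       90.0    107.0    120         7.06
          5      107.0    113.0    172        28.67   <- burst
          6      113.0    125.0    182        15.17   <- burst
          7      125.0    148.0     91         3.96
```

Because the simulator knows every gene's true history, the calls can be
scored directly:

```python
metrics = evaluate_calls(result, pipe)
# recall_wgd: 0.963   recall_tandem: 0.945   recall_proximal: 0.909
# relocated_gamma_sensitivity: 0.787   relocated_gamma_precision: 0.825
```

A fixture-based command-line flow is also available:

```bash
duporigin simulate --out fixture/ --seed 1
duporigin pipeline --fixture fixture/ --out run1/   # origins.tsv, retention.tsv, report.json
```

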