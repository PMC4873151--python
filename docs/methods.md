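# Methods

## Scope

`duporigin` classifies duplicated genes by duplication mode, dates dispersed
duplicates by colinearity conservation against an ordered outgroup ladder,
calls relocated post-triplication ("relocated γ") and recently transposed
duplicates, and characterises the classes by coding, expression, regulation
and functional divergence.  Because the real analysis requires many complete
genomes and curated block sets, validation here is against a forward
genome-evolution simulator with full ground truth; the analysis modules are
agnostic about whether their inputs come from the simulator, from MCScanX
output, or from user tables.

## Colinearity detection

Anchors are homolog pairs placed on gene-rank coordinates.  Per chromosome
pair and orientation, blocks are maximal chains with unit anchor weight,
strictly increasing ranks on both axes (decreasing on one axis for inverted
blocks), and a hard rank-gap cap.  Defaults `min_block_size = 5`,
`max_gap = 25` follow the de facto standard defaults of MCScanX-style tools;
both are exposed everywhere.  Design choices that matter:

* **Score and tie-breaks.** Chain score is the anchor count with no gap
  penalty.  Among equal-score chains, the one with lexicographically smallest
  (Σ rank_a, Σ rank_b) wins, making output order-independent.
* **Local-stack handling.** An anchor outscored by another at the same rank
  is dropped.  Anchors that share a gene and sit within the local window
  (10 ranks) on the other axis are alternative placements of one local
  duplicate stack: a chain may use at most one anchor per such component,
  the chaining-time equivalent of MCScanX's collapse of tandem arrays to a
  single representative.  Without this, a tandem array matching a tandem
  array contributes several stacked anchors and inflates blocks.
* **Non-overlap.** Best chains are extracted greedily; a rank used by a
  block cannot re-anchor within the same chromosome pair (local copies of
  chained genes would otherwise form shadow diagonals offset by a few
  ranks).  A gene may still anchor blocks on different chromosome pairs.
* **Self-comparisons** exclude self pairs, treat unordered pairs once, and
  drop same-chromosome pairs within 10 ranks before chaining — such pairs
  are tandem/proximal duplicates by definition, not syntenic anchors.

The chainer is verified against exhaustive search over all valid chains on
hundreds of random ≤20-anchor instances.

## Mode classification

A pair is `wgd` if it is a block anchor; else `tandem` if adjacent in gene
order; else `proximal` if separated by 2–10 annotated genes on the same
chromosome (the "within 10 annotated genes" convention); else `dispersed`.
Gene-level labels use the precedence wgd > tandem > proximal > dispersed.
For local and dispersed modes, each gene keeps only its smallest-Ks pair
(ties to the lexicographically smaller partner, so results are independent
of input order).  When an E-value column is present, pairs are pre-filtered
to E < 1e-10 and the union of per-gene top-5 match lists; simulated input
uses a Ks detectability cap (default 3.0) instead, since the simulator has
no alignment scores.  Attribution of WGD genes to named events is accepted
as an input label column; for simulated data, blocks are attributed by
median anchor Ks against configured per-event Ks ranges.

## Epoch dating and origin calling

Epochs are half-open intervals [t_i, t_{i+1}) between successive outgroup
divergences, plus the youngest interval [0, t_1); the default ladder is the
eight-outgroup core-eudicot ladder (5/16/72/90/107/113/125/148 Mya).  A
dispersed gene's creation epoch is bracketed by its deepest colinear
outgroup ("deepest wins", which also resolves non-nested patterns produced
by lineage-specific block loss).  Genes colinear with the farthest outgroup
predate the ladder; they are excluded from retention rates and origin
windows.  Both members of a dispersed pair are dated independently.

Retention rate = dated dispersed duplicates in an epoch / epoch length (per
My).  Origin windows on the default ladder: `transposed` = [0, 16) (younger
than the second split), `relocated_gamma` = [107, 125) (the two epochs
between the 5th and 7th splits).  The oldest epoch [125, 148) is left as
`dispersed_other` because duplicates dated there may predate the
triplication.  The relocated fraction is 100·b/(a+b) rounded half-up to one
decimal.  For lineages without recent WGDs, the γ set is the intra-genome
colinear genes that also show colinearity with at least one outgroup
(excluding recent segmental duplicates), and the relocated set is the
dispersed genes colinear with designated mid-ladder outgroups but with no
designated distal (monocot) outgroup.

## Divergence measures

* Ks distributions use right-closed bins (default width 0.05) under a
  saturation cap (default 3.0; values above it are excluded and counted),
  plus a Gaussian KDE with Silverman bandwidth.  Secondary peaks are local
  density maxima inside a search range (default 1.5–2.2) whose prominence
  exceeds 5 % of the density maximum; an L-shaped density therefore yields
  none.  Peak location is stable to histogram bin phase within half a
  bandwidth.
* Group comparisons use Welch's unequal-variance t-test (two-sided), checked
  against a permutation oracle.
* Expression divergence is 1 − Pearson r (range [0, 2], affine-invariant);
  regulation divergence is the Jaccard distance of promoter PWM hit sets
  (a metric on sets; both-empty is flagged missing).
* Promoter windows span 600 bp upstream to 200 bp downstream of the TSS,
  strand-aware and clipped at sequence ends.  The bundled PWM scanner
  reports a motif when its best log-odds score (uniform background, both
  strands) reaches 80 % of the motif's maximum achievable score; users
  wanting FIMO parity should import FIMO output as a hit-set table.
  JASPAR and MEME-minimal matrices are parsed via Biopython.

## Enrichment

GO term panels are the biological-process terms annotating strictly more
than `min_genes` genes (default 300), counts pre-propagated.  A class's
functional profile is its per-term fold enrichment against the pooled
duplicates (union of all classified duplicate genes).  Profiles are
clustered by average linkage at distance 1 − r with a deterministic leaf
rotation (lexicographically smaller subtree first) and exported as Newick
plus a heat-map matrix/figure.  Class-versus-trait tests are two-sided
Fisher exact tests; raw p-values are reported by default
(Benjamini–Hochberg available as an explicit post-step by the caller).
Essentiality and PPI tests use the phenotype-screened and
interactome-screened gene sets as backgrounds respectively — comparing
against the whole genome would conflate screen coverage with the trait.

## The simulator

A forward, event-driven simulation on a caterpillar species tree (focal
lineage + ordered outgroups = the epoch ladder).  The ancestral genome
(default 2,000 genes on 10 chromosomes) is cloned at each speciation;
branches evolve under per-gene per-My rates, with Poisson event counts drawn
on ≤5 My slices so rates track the changing gene number.  Events:

* **Triplication** (default at 126 Mya, on the stem above the 7th-outgroup
  split so that all ladder eudicots inherit it; the event must precede that
  split, and 125 Mya would coincide with it).  Two extra copies of every
  gene are appended on new chromosomes preserving ancestral order — later
  relocations, not the event, do the shuffling.
* **Loss** removes a gene and closes the rank gap (fractionation).  Only
  genes with a surviving same-genome family copy can be lost.  Rates:
  baseline 0.002/gene/My; polyploidy-born copies 0.015 within a 40-My
  post-event window; single-gene duplicate copies 0.008 constantly (high
  turnover is what produces the L-shaped local-duplicate age
  distribution).  A 30 % fraction of ancestral lineages is
  dosage-constrained (loss × 0.15, inherited by copies and orthologs), so
  fractionation is correlated across lineages as in real post-polyploid
  genomes; with independent loss, the outgroup ortholog of a surviving
  focal gene would be lost far too often for colinearity dating to work —
  on real genomes this correlation is the gene-balance effect.
* **Relocation** moves a gene to a uniformly chosen position.  Baseline
  0.001/gene/My; 10× that inside the burst window (107–148 Mya) on lineages
  descending from the triplication (the burst models post-event chromosomal
  instability, so a never-triplicated monocot outgroup relocates at
  baseline only).  The paper-scale relocated fraction among surviving γ
  duplicates is not reproduced quantitatively — these rates give ~15–25 %,
  a deliberately mild regime that keeps genome-wide colinearity realistic;
  the qualitative signatures (retention-rate burst, secondary Ks peak) are
  what the pipeline is validated on.
* **Single-gene duplications**: tandem (adjacent insertion, 0.002),
  proximal (2–10 ranks away, 0.001), transposed (uniform position, 0.001).

Ks for a pair is 2 μ T with T the divergence time from the gene genealogy
(duplication or speciation node), μ = 0.0075 /My per lineage — placing γ
pairs near Ks ≈ 1.9 — and multiplicative lognormal noise (σ = 0.15, keeps Ks
positive).  Ka = ω·Ks with ω lognormal around 0.2 (σ = 0.5), i.e. purifying
selection.  Homolog-pair emission keeps, per gene, the top-5 smallest-Ks
same-family partners under the Ks cap — a detectability stand-in for the
BLAST E-value filter.

**Ground truth.** Every gene records its birth mechanism, birth time and
relocation history.  The observable expected mode used for scoring is:
`wgd` if the gene has a partner separated by a polyploidy event with both
members still at event-derived positions (present at or born by the event,
never relocated since); otherwise tandem/proximal by final rank distance
(local modes are positional by definition — a tandem pair interrupted by a
later insertion *is* a proximal pair); otherwise dispersed.  Truth
`relocated_gamma` requires: present at the triplication, last relocation
inside the burst window and after the event (a gene relocated again later is
no longer at its burst-era position).  Truth `transposed` is a
transposed-born, never-relocated copy.

**Synthetic annotations** condition on truth classes: essentiality and PPI
participation are Bernoulli with class multipliers over a base rate
(defaults make relocated-γ essential-enriched and WGD PPI-enriched,
single-gene classes depleted — the pattern the enrichment module is meant
to resolve); GO term draws are Zipf-weighted with class-favored terms;
expression profiles are multivariate normal per family with covariance
exp(−2·t_div/τ) (an Ornstein–Uhlenbeck process on the gene genealogy,
τ = 250 My); motif sets evolve along the genealogy by per-My loss and gain
(τ = 180 My), so age-0 copies share their parent's exact set and overlap
decays monotonically with pair age.

**What the simulator does not emulate:** nucleotide sequences and codon
models, inversions/translocations as block events (relocations are
per-gene), biased subgenome dominance beyond the shared retention factor,
E-value distributions, and expression/regulation measurement noise
structure.  Passing recovery tests therefore demonstrates that the pipeline
reads the positional/colinearity signal correctly under realistic gene-order
evolution, not that real-data error sources (annotation errors, alignment
artefacts, Ks saturation) are handled.

## Validation sizes and known limitations

The recovery experiments use ~2,000 ancestral genes and 20 replicate seeds
(the acceptance script uses 6); secondary-peak detection uses
exponential+Gaussian mixtures of 5,000 pairs; Fisher calibration uses
independent draws over a 2,000-gene background.  Under these conditions the
pipeline recovers WGD/tandem/proximal genes at ≥0.9 pooled recall and
relocated-γ calls at ~0.78 sensitivity / ~0.83 precision (frozen acceptance
floors 0.70 / 0.75).  The residual, structural confusions are informative:
a local copy of a colinear gene can legitimately fill its parent's anchor
slot (history says tandem/proximal, position says WGD), and a relocated-γ
gene whose ortholog in the single bracketing outgroup was fractionated
cannot be dated into the burst window.  Both effects exist on real data and
are ceilings of the method, not of this implementation.
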