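# debrisem

Ambient-RNA debris filtering for droplet-based single-nucleus (and
single-cell) RNA-seq count matrices.

## The problem

Isolating nuclei for snRNA-seq lyses the cell membrane and releases
cytoplasmic and cell-free RNA into suspension. This *ambient RNA* is
encapsulated into droplets — both droplets without a nucleus and droplets
carrying one — so the raw barcode × gene count matrix mixes genuine nuclear
profiles with a background signature. Hard count thresholds (keep every
droplet above some total-UMI cutoff) fail in both directions: contaminated
droplets occur far above any threshold, and real nuclei occur below it, so
downstream clustering produces spurious, background-driven "cell types".

## The model

Let **X** be a g × N matrix of UMI counts. Each droplet's count vector
**x**ᵢ (total uᵢ) is modeled as a multinomial draw whose gene-probability
vector **α**ₖ depends on a latent component zᵢ ∈ {0, …, K}: component 0 is
the ambient-debris pool, components 1…K are cell types, with mixing weights
**π**. The observed-data log-likelihood is

    log P(X) = Σᵢ log Σₖ πₖ · Mult(xᵢ | αₖ, uᵢ)

Parameters are estimated by **semi-supervised EM**: droplets with fewer
than T = 100 total counts are assumed ambient and their labels are held
fixed at the debris component through every iteration, anchoring the debris
profile to the long tail of near-empty droplets. EM is initialized by
k-means on the top 30 principal components of the depth-normalized,
log-transformed expression of the top 2,000 variable genes (droplets with
≥ 200 genes detected). After convergence (max parameter change < 10⁻⁴),
each droplet is assigned to its maximum-posterior component.

Filtering then works on a per-droplet **debris score**: clusters averaging
fewer than d = 200 detected genes join the fixed component in the debris
set; genes enriched in debris (Welch's t-test on log-normalized
proportions, log fold change > 0, Benjamini–Hochberg FDR < 0.05) define a
signature; a droplet's raw score is its summed normalized expression over
that signature, rescaled so the cleanest cluster averages 0 and the debris
clusters average 1. Droplets with a normalized score below t = 0.5 are
kept; fixed low-count droplets are always removed.

For evaluation the package also computes contamination metrics — percent
spliced (ambient RNA is mostly spliced mRNA, nuclear RNA mostly unspliced
pre-mRNA; mitochondrial genes are excluded because they lack introns), MT%
and MALAT1% — and a two-Gaussian midpoint classifier on the bimodal
percent-spliced distribution. A fully seeded simulator generates matrices
with known ambient profiles, per-droplet contamination fractions, and
splice labels.

## Worked example

`examples/filter_simulated_experiment.py` simulates the default scenario —
3 cell types × 300 nuclei, 5,000 empty droplets, per-nucleus contamination
ρ ~ Beta(1, 9) — and filters it:

```text
simulated 1000 genes x 5900 droplets
EM converged in 9 iterations; debris clusters: [0, 4]; 320 debris-enriched genes
kept 897 droplets at score cutoff 0.5
nuclei kept (sensitivity):  0.997
empties removed (specificity): 1.000
quantile baseline (threshold 272 counts): sensitivity 0.871, specificity 0.984
Pearson R, debris score vs true ambient fraction: 0.988
adjusted Rand index, cluster labels vs true cell types: 0.998
```

The mixture filter keeps 99.7% of true nuclei while removing every
ambient-only droplet, whereas the hard-count baseline discards 13% of
nuclei and still keeps dozens of empties; the normalized debris score is
essentially a read-out of each droplet's true ambient fraction (R ≈ 0.99).
See also `examples/contamination_metrics.py` (percent-spliced midpoint
classifier) and `examples/semi_supervised_em_toy.py` (the EM core on a toy
matrix).

## Command line

```bash
debrisem simulate --out-dir sim --seed 7            # MTX triplet + truth + splice table
debrisem run --counts-dir sim --out-dir out --k 4 --seed 7
debrisem quantile --counts-dir sim --out-dir base   # hard-count baseline
debrisem metrics --counts-dir sim --splice-tsv sim/splice.tsv --out-dir met
```

`run` writes the score table, debris-gene table, mixture parameters,
EM trace, kept-barcode list, the filtered MTX triplet, and a
`manifest.json` that reproduces the run bit-for-bit.

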