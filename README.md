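# resphylo

Screen a protein family for residues whose evolutionary divergence tracks
species lifespan, while controlling for shared ancestry.

Comparative studies of longevity proteins (the motivating case is p53 across
hundreds of vertebrates) ask which alignment positions changed in ways that
correlate with how long species live. Two species are not independent data
points — close relatives share both sequence and lifespan by descent — so a
naive per-site correlation is confounded by phylogeny. `resphylo` implements
the full workflow:

1. **Relative Evolutionary Score (RES).** From a multiple sequence alignment
   over the 21-symbol alphabet (20 amino acids + gap), build a position
   weight matrix with additive pseudocount κ and an alignment-wide background:

   p(a, j) = (c(a, j) + κ) / (n + 21κ),  q(a) = (C(a) + κ) / (nL + 21κ)

   and score sequence *i* at column *j* as the log-odds
   **RES(i, j) = log₂ p(aᵢⱼ, j) / q(aᵢⱼ)**. Common residues at a position
   score near zero; lineage-specific substitutions score negative.

2. **Phylogenetic GLS per column.** With a rooted tree (supplied, or built by
   neighbor joining on p-distances with midpoint rooting), the
   Brownian-motion covariance **V** has V(i, j) = shared root-to-MRCA branch
   length. Each column is fit by generalized least squares,
   lifespan ~ β₀ + β₁·RES with error covariance σ²V, solved by Cholesky
   whitening; the slope gets a two-sided t test on n − 2 df. Columns with
   p < 0.05 are **RPLARs** (RES-predicted longevity-associated residues) and
   are mapped to residue numbers of a reference ortholog.

3. **Signal and model fit.** Pagel's λ (off-diagonal multiplier of V) is
   estimated by maximum likelihood to quantify how strongly phylogeny
   structures the lifespan trait, and a joint GLS over all RPLAR columns
   reports AIC and logLik.

4. **Lifespan normalization.** Where only maximum lifespan L_max is recorded,
   a regression L_avg = αL_max + β fit on species with both values imputes
   L_avg_est, and L_norm = L_avg_est + (L_max − L_avg_est)·α gives the
   normalized lifespan used for broad multi-order datasets.

A seeded synthetic-data module (Yule trees, Brownian traits with tunable λ,
alignments with known trait-linked columns) makes every stage testable with
exact ground truth.

## Worked example

```python
import resphylo as rp

cfg = rp.SimConfig(n_taxa=60, L_total=120,
                   linked_columns=(10, 30, 50, 70, 90, 110),
                   effect=0.95, seed=1)
bundle = rp.make_dataset(cfg)

aln, tree, traits = rp.harmonize(bundle.alignment, bundle.tree, bundle.traits)
res = rp.compute_res(aln, pseudocount=1.0, log_base=2.0)

signal = rp.estimate_lambda(tree, traits.lifespan())
print(f"Pagel's lambda = {signal.lambda_hat:.3f} (logLik {signal.loglik:.2f})")

cov = rp.bm_covariance(tree)
fits, rplars = rp.site_screen(res, traits, cov, alpha_screen=0.05)
rplars = rp.map_to_reference(rplars, aln, reference_id=aln.ids[0])
print(f"RPLARs: {sorted(rplars['column'])}")
print(f"truth : {bundle.truth['linked_columns']}")

joint = rp.joint_model_fit(res, traits, cov, rplars["column"].tolist())
print(f"joint model AIC = {joint.aic:.1f}, logLik = {joint.loglik:.1f}, k = {joint.k}")
```

prints

```
Pagel's lambda = 0.992 (logLik -78.28)
RPLARs: [10, 15, 24, 28, 30, 39, 48, 50, 52, 60, 62, 70, 90, 101, 115]
truth : [10, 30, 50, 70, 90, 110]
joint model AIC = 126.2, logLik = -46.1, k = 17
```

The trait was simulated under pure Brownian motion, and λ̂ ≈ 0.99 recovers
that. The screen finds 5 of the 6 planted columns (column 110's signal fell
below the 0.05 cut in this replicate) plus a handful of false positives —
the expected behavior of an uncorrected p < 0.05 screen over 114 neutral
columns.

The same pipeline runs from the shell:

```sh
resphylo simulate --seed 1 --out-prefix sim/
resphylo run --alignment sim/aln.fasta --traits sim/traits.tsv \
             --tree sim/tree.nwk --out-dir results/
```

writing `sitefits.tsv`, `rplars.tsv`, `res_heatmap.tsv` (rows in descending
lifespan order), `summary.json`, and a run manifest. See `resphylo --help`
for `normalize`, `score`, `tree`, `signal`, and `screen` subcommands.

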