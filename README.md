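# rearnet

Two-step Bayesian network analysis linking SNP genotypes to the traits that
determine rearing success in purebred layer hens.

During the rearing phase (hatch to ~17 weeks), pullets are lost to
first-week mortality, culling for rearing abnormalities, and natural death;
the surviving percentage is the rearing success,

    RS = 100 − (FWM + RA + ND).

Given allele-dosage genotypes of dams, per-batch rearing/incubation traits
(clutch size, embryo mortality, the three loss components, rearing success,
flock age, genetic line, season), `rearnet` asks which SNPs are directly
associated with the rearing-success traits:

1. **Naive Bayes pre-selection.** The SNP panel is split into 10 random
   groups; within each group every SNP is scored per trait by repeated
   stratified 10-fold × 3 cross-validation of a Laplace-smoothed
   categorical Naive Bayes classifier (held-out single-SNP ROC AUC), and
   the per-trait top-20 lists are pooled with single-entry deduplication.
2. **Structure learning.** Per group, a Bayesian network over the nine
   phenotypes plus the selected SNPs is learnt by simulated annealing under
   the BDeu score, with a blocklist excluding (a) the edges confounded by
   the RS identity above (both directions) and (b) phenotype pairs whose
   chi-square independence test gives p ≥ 0.25.
3. **Overlap.** Edges incident to the traits of interest (clutch size,
   FWM, RA, ND, RS) are combined across the 10 top networks into one
   overlapped network with per-edge support counts, and trait-linked SNPs
   are mapped to their nearest gene (BED/GFF3) for export to enrichment
   tools.

Because the motivating data are proprietary, the package ships a
first-class synthetic generator (`rearnet.simulate`) that reproduces the
study's structure — Hardy-Weinberg dosages, four lines and seasons,
zero-inflated loss traits, clutch size concentrated near 14 eggs, the RS
identity holding exactly — with a planted, known dependency network, so
every stage is testable against ground truth.

## Worked example

Run the full pipeline on the default synthetic study (500 dams, 200 SNPs,
5 causal SNPs planted with strong effects):

```sh
rearnet run-all --seed 1 --out demo_run
```

or equivalently in Python:

```python
from rearnet.pipeline import PipelineConfig, run_all
run_all(PipelineConfig(output_dir="demo_run", seed=1))
```

`demo_run/` then contains the simulated data, the discretized table with
its category maps, the per-trait SNP rankings, the blocklist, the 10 subset
networks, and the overlapped network. For seed 1 the planted truth is

```
parent      child                   effect
snp00018    clutch_size             0.045
snp00078    first_week_mortality    0.18
snp00081    rearing_abnormalities   0.36
snp00115    natural_death           0.18
snp00174    clutch_size             0.045
```

and `demo_run/overlapped.edges.tsv` comes back with exactly those
associations recovered (plus snp00081 also linking to rearing success,
whose direct RA link is blocked by construction):

```
node_a                 node_b     multiplicity  orientations
clutch_size            snp00018   1             snp00018->clutch_size
clutch_size            snp00174   1             clutch_size->snp00174
first_week_mortality   snp00078   1             first_week_mortality->snp00078
natural_death          snp00115   1             snp00115->natural_death
rearing_abnormalities  snp00081   1             snp00081->rearing_abnormalities
rearing_success        snp00081   1             rearing_success->snp00081
```

`demo_run/associations.json` summarizes: clutch size linked to 2 SNPs, FWM
/ RA / ND to 1 each, 5 distinct SNPs in total. Edge orientations are
reported but should be read as associations, not causal directions: BDeu
cannot distinguish Markov-equivalent orientations.

Each stage is also available as its own subcommand (`simulate`,
`discretize`, `select`, `block`, `learn`, `overlap`, `annotate`) operating
on the serialized intermediates; chained subcommands reproduce `run-all`
bit-for-bit for the same seed, and `demo_run/manifest.json` records config
and per-file checksums.

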