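# Methods

`rearnet` implements a two-step Bayesian analysis that links SNP genotypes
of layer-hen dams to the traits determining rearing success, and validates
the whole chain on synthetic data with a planted dependency network.

## The two-step procedure

**Step 1 — Naive Bayes SNP pre-selection.** The SNP panel is randomly split
into *G* disjoint groups (default 10, sizes differing by at most one).
Within a group, each SNP is scored against each trait of interest with a
categorical Naive Bayes classifier under repeated stratified k-fold
cross-validation (defaults: 10 folds, 3 repeats). The classifier uses
Laplace smoothing: with class counts `N_c` and cell counts `N_{cs}` for
feature state `s`,

    P(s | c) = (N_{cs} + alpha) / (N_c + alpha * r),    alpha = 1 by default,

and class priors are the empirical frequencies. A SNP's importance is the
held-out separation achieved by that SNP alone: the area under the ROC
curve of the ordering of held-out rows by the single-feature posterior
P(class | SNP state). Fold-level AUCs are averaged over all folds x repeats
first, and the mean *m* is then folded into [0.5, 1] as `max(m, 1 - m)`;
averaging before folding matters, because folding each fold's noisy AUC
first would bias a null SNP's importance above 0.5 by roughly the mean
absolute fold noise. For traits with more than two states the score is the
maximum over one-vs-one class-pair AUCs. Per group, the top-k SNPs per
trait (default k = 20) are pooled into a single deduplicated list.

Because each fold's scores take at most three distinct values (one per
dosage state), the AUC is computed in closed form from the grouped held-out
counts with midrank tie handling; this makes ranking hundreds of SNPs over
30 folds a few vectorized array operations per fold.

**Step 2 — network structure learning.** For each group, a Bayesian network
over the nine phenotype variables plus that group's selected SNPs is learnt
by simulated annealing, scored with the BDeu marginal likelihood: for child
`i` with `r_i` states and `q_i` parent configurations,

    score_i = sum_j [ lnG(a_j) - lnG(a_j + N_ij)
                      + sum_k ( lnG(a_ijk + N_ijk) - lnG(a_ijk) ) ],

with `a_ijk = ess / (q_i r_i)`, `a_j = ess / q_i`, and equivalent sample
size `ess = 1` by default. The total score is the sum of local scores
(decomposable) and BDeu is score-equivalent: Markov-equivalent DAGs score
identically, which the tests assert to 1e-9.

The search proposes uniformly over the currently *legal* moves — edge
additions, deletions and reversals that keep the graph acyclic, respect the
per-node parent bound (default 4) and never touch a blocked edge. A move
worsening the score by `d` is accepted with probability `exp(d / T)`; `T`
follows a geometric schedule (`T <- c * T` every `m` proposals). When no
start temperature is given, it is calibrated in a 1,000-proposal random
walk so that the median worsening move seen there would be accepted with
probability 1/2. The schedule must end effectively cold — cooled far enough
that only improving moves are accepted — or the search degenerates into a
random walk whose best visited state is the initial graph; the pipeline
default (20,000 proposals, `c = 0.85` every 50) spends roughly the second
half of its budget cold, which on ~30-node subset problems behaves like a
randomized local search seeded by the annealing phase.

Legality masks are maintained as boolean matrices. Acyclicity of an
addition `u -> v` is read off the transitive closure (no path `v ~> u`);
for a reversal the package uses a DAG identity: reversing `u -> v` creates
a cycle iff some other out-edge `u -> w` has a path `w ~> v` (such a path
can never use the edge `u -> v` itself, since that would close a cycle
through `u`), so the reversal mask is one boolean matrix product. The
closure is patched incrementally for additions and recomputed for
deletions/reversals.

**Blocked edges.** Two sources: (i) the arithmetic identity

    rearing_success = 100 - (first_week_mortality
                             + rearing_abnormalities + natural_death)

makes links among its components and the total confounded by construction;
those four pairs are blocked in both directions. (ii) phenotype pairs whose
Pearson chi-square test of independence (no continuity correction, on the
discretized data) yields p >= 0.25 are blocked as imbalance-artefact
candidates. Lack of dependency is symmetric, so contingency pairs are also
blocked in both directions by default (a config switch restricts to one
direction). Under a uniform null the exclusion fires at rate 0.75, which
the calibration study verifies. SNP-touching edges are never blocked.

**Overlap and annotation.** From each group's top network, every edge
incident to a trait of interest (clutch size, first week mortality, rearing
abnormalities, natural death, rearing success) is kept; "incident" is
direction-agnostic, with observed orientations retained as metadata. The
union across groups forms the overlapped network; an edge's multiplicity
counts the groups containing it in either orientation. Trait-linked SNPs
are then assigned to their nearest feature on the same chromosome (distance
0 inside an interval, otherwise the gap to the nearer edge; all equidistant
features reported, smallest start primary) and exported as a plain gene
list for external enrichment tools. BED input is treated as 0-based
half-open, GFF3 as 1-based closed, SNP map positions as 1-based; everything
is normalized to 0-based half-open internally.

## Discretization

Defaults follow the trait semantics: genetic line and season get fixed
categorical codes (Line1..Line4 -> 0..3; autumn, spring, summer, winter ->
0..3); embryo mortality, first week mortality and natural death are
zero-heavy percentages binarized zero/nonzero; clutch size splits at <= 12
eggs; rearing success, flock age and rearing abnormalities get 3-state
quantile bins. Quantile bins are left-closed at the interior cuts; when a
cut coincides with the data minimum (a zero-heavy column) the binning
switches to right-closed so the tied mass stays below the cut instead of
collapsing the partition, and duplicate cuts shrink the arity with a logged
warning. Category maps are serialized next to the coded table with
repr-precision interval bounds, so re-applying them to the raw data
reproduces the codes bit-exactly. SNPs are 3-state allele dosage;
monomorphic SNPs are dropped, and a missing dosage class is compacted to
consecutive codes.

## The synthetic generator

The generator emulates the structure of the motivating data — four genetic
lines, four seasons, one rearing batch per genotyped dam, and the trait
distributions — without modelling pedigree, linkage disequilibrium or the
14-day egg-collection process:

* dosages are Binomial(2, p) per SNP under Hardy-Weinberg equilibrium, MAF
  drawn uniformly from [0.1, 0.5] unless specified;
* clutch size is Binomial(14, 0.95), concentrated near 14 with ~15% of
  batches at <= 12 eggs;
* embryo mortality, first week mortality and natural death are
  zero-inflated (zero with probability 0.55 / 0.60 / 0.50) with gamma
  positive parts, capped so the rearing-success components can never sum
  past 100; rearing abnormalities and flock age are gamma-distributed
  positives (flock age centred at 45 weeks);
* rearing success is computed exactly from its three components.

Planted effects act per parent on a trait-specific channel: the zero
probability (shifted down by `effect * dosage`), the gamma mean (scaled by
`1 + effect * dosage`), or clutch size's per-egg probability (shifted down
by `effect * dosage`). Probability shifts that leave [0, 1] raise a
validation error rather than being clipped. The default planted network
spreads 5 causal SNPs round-robin over clutch size, first week mortality,
rearing abnormalities and natural death, with a base effect of 0.18 per
dosage unit (scaled to 0.045 on the clutch channel, whose binarized signal
is far more sensitive, and 0.36 on the mean channel, whose signal is
diluted by 3-state quantile binning). Causal SNPs are drawn from those with
sample allele frequency >= 0.2 so all three dosage classes are populated.

What passing tests show — and do not show. Recovery results on this
generator demonstrate that the pipeline finds dependencies it is pointed
at, at realistic sample sizes, and never fabricates blocked structure. They
do not demonstrate performance under linkage disequilibrium (where many
correlated SNPs tag one signal), under population structure across the four
lines, or at the original study's scale of 62,575 SNPs, and draws whose
causal SNP lands near the MAF floor carry genuinely marginal signal at 500
dams — the validation studies report exactly how often such draws are
recovered rather than hiding them.

## Validation studies and problem sizes

`rearnet.validation` re-runs the machinery end to end at sizes chosen to
finish in minutes on one CPU; `scripts/acceptance.py` executes all of them
and writes the measured numbers:

* annealing vs exhaustive enumeration on 20 planted 4-variable problems
  (n = 1000, noisy chain / v-structure, all 543 labelled DAGs enumerated);
* BDeu local scores vs a plain-loop log-gamma reference on 50 random
  tables, plus the closed-form no-parent example ln(3/128);
* Markov-equivalence gap across the three equivalent 3-node DAGs, and the
  collider's advantage on v-structure data;
* selection recovery: 2,000 dams x 500 SNPs, 5 causal SNPs planted on
  clutch size (effect 0.05 on the per-egg channel), causal SNPs counted in
  the top 20 of the full panel over 10 seeded studies;
* full-pipeline recovery on the 500-dam / 200-SNP fixture over 10 seeded
  runs, with a blocked-edge audit of every learned and overlapped network;
  both the association-level recovery rate and the per-run full-recovery
  rate are reported;
* contingency calibration: exclusion rate of an independent trait pair
  over 200 replicates (expected 0.75);
* exactness of the rearing-success identity, and the nearest-gene lookup
  against a brute-force scan on 1,000 random fixtures.

## Numerical choices and degenerate inputs

* All marginal-likelihood arithmetic is in log-gamma space; unobserved
  parent configurations contribute zero terms.
* Score ties (|difference| <= 1e-12) are broken toward fewer edges; the
  exhaustive oracle additionally breaks remaining ties lexicographically on
  the sorted edge list.
* Constant columns are rejected from the discrete dataset; monomorphic
  SNPs are dropped with a warning rather than erroring, since a simulated
  or subsetted panel can legitimately contain them.
* An annealing state with no legal move (everything blocked) returns the
  empty graph with a warning.
* Missing genotypes (code -1) fail fast unless impute-to-mode is requested.
* Exhaustive enumeration refuses more than 6 variables; it is routinely
  used at 4 (543 DAGs) and is slow but correct at 6 (~3.8M DAGs).
* Every stage seed is derived from the master seed through named
  `SeedSequence` keys, so the manifest's checksums are reproducible
  bit-for-bit, and chained CLI subcommands reproduce `run-all` exactly
  (both read and write the same plain-text intermediates).

## Known limitations

* The importance metric is a filter, blind to interactions: a SNP
  informative only jointly with another SNP will not be selected.
* BDeu with ess = 1 at a few hundred rows is conservative; weak true edges
  (e.g. an association with chi-square p ~ 1e-4 spread over a 3x3 table)
  can be score-negative and are correctly — but disappointingly — omitted.
* The annealing search guarantees nothing; its oracle agreement is
  demonstrated only at small variable counts, and at pipeline scale its
  budget is a pragmatic choice, not a convergence proof.
* Networks are structures only: no parameter estimation or conditional
  inference is provided, and no significance is attached to overlap
  multiplicities.
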