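"""Synthetic genotype/phenotype generator with a planted dependency network.

The generator emulates the structure of a layer-hen rearing study: dams from
four genetic lines genotyped at biallelic SNPs (allele-dosage coded under
Hardy-Weinberg equilibrium), one rearing batch per dam, and per-batch traits —
clutch size concentrated near 14 eggs with a meaningful mass at <=12,
zero-inflated mortality percentages, continuous positive rearing abnormalities
and flock age, and rearing success defined as

    rearing_success = 100 - (first_week_mortality
                             + rearing_abnormalities + natural_death)

A :class:`GroundTruth` object plants a known dependency network from a small
set of causal SNPs into the traits, so every downstream stage (discretization,
Naive Bayes selection, Bayesian-network learning, overlap extraction) can be
validated against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

LINES = ("Line1", "Line2", "Line3", "Line4")
SEASONS = ("autumn", "spring", "summer", "winter")

#: Traits that may receive planted parent effects, with the parameter the
#: effect acts on: "zero" shifts P(value == 0) down by effect*dosage, "mean"
#: scales the positive part's mean by (1 + effect*dosage), "clutch" shifts
#: the per-egg laying probability down by effect*dosage.
TRAIT_EFFECT_CHANNEL = {
    "clutch_size": "clutch",
    "embryo_mortality": "zero",
    "first_week_mortality": "zero",
    "natural_death": "zero",
    "rearing_abnormalities": "mean",
    "flock_age": "mean",
}

PHENOTYPE_COLUMNS = [
    "batch_id",
    "line",
    "season",
    "clutch_size",
    "embryo_mortality",
    "first_week_mortality",
    "rearing_abnormalities",
    "natural_death",
    "rearing_success",
    "flock_age",
]

#: Base rates of exact zeros for the zero-inflated traits.
DEFAULT_ZERO_INFLATION = {
    "embryo_mortality": 0.55,
    "first_week_mortality": 0.60,
    "natural_death": 0.50,
}

# Gamma (shape, scale) for the positive part of each continuous trait, in
# percent (mortalities/abnormalities) or weeks (flock age).  Values are capped
# so that the Eq-1 components can never sum above 100.
_GAMMA_PARAMS = {
    "embryo_mortality": (2.0, 3.0, 30.0),
    "first_week_mortality": (1.5, 1.2, 20.0),
    "natural_death": (2.0, 1.5, 20.0),
    "rearing_abnormalities": (3.0, 2.0, 30.0),
    "flock_age": (20.0, 2.25, 75.0),
}

_CLUTCH_EGGS = 14
_CLUTCH_P = 0.95


@dataclass(frozen=True)
class GroundTruth:
    """Planted dependency network: which SNPs drive which traits, how hard.

    ``dag`` lists directed (parent, trait) edges; parents are causal SNP ids
    (or the categorical dam attributes ``line``/``season``).  ``effect_sizes``
    gives the per-edge probability shift per unit of the parent value.
    """

    dag: tuple[tuple[str, str], ...]
    effect_sizes: dict[tuple[str, str], float]
    causal_snp_ids: tuple[str, ...]
    zero_inflation: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ZERO_INFLATION)
    )
    maf: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        import networkx as nx

        g = nx.DiGraph(list(self.dag))
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("ground-truth dag contains a cycle")
        parents = {p for p, _ in self.dag}
        for snp in self.causal_snp_ids:
            if snp not in parents:
                raise ValidationError(
                    f"causal SNP {snp!r} is not a parent of any trait"
                )
        for trait, q in self.zero_inflation.items():
            if not 0.0 <= q <= 1.0:
                raise ValidationError(
                    f"zero_inflation[{trait!r}]={q} outside [0, 1]"
                )
        for snp, p in self.maf.items():
            if not 0.0 < p <= 0.5:
                raise ValidationError(f"maf[{snp!r}]={p} outside (0, 0.5]")
        for edge, eff in self.effect_sizes.items():
            if edge not in set(self.dag):
                raise ValidationError(f"effect size for unknown edge {edge}")
            _, trait = edge
            if trait not in TRAIT_EFFECT_CHANNEL:
                raise ValidationError(f"no effect channel for trait {trait!r}")
            if not np.isfinite(eff):
                raise ValidationError(f"non-finite effect size for edge {edge}")

    def trait_parents(self, trait: str) -> list[tuple[str, float]]:
        return [
            (p, self.effect_sizes.get((p, t), 0.0))
            for p, t in self.dag
            if t == trait
        ]


@dataclass
class GenotypeMatrix:
    """Dams x SNPs allele-dosage matrix with a chromosome/position map."""

    dam_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray  # int8, values in {0,1,2}
    snp_map: pd.DataFrame  # columns: snp_id, chromosome, position

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.shape != (len(self.dam_ids), len(self.snp_ids)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.dam_ids)} dams x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("snp_ids are not unique")

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self.snp_ids.index(snp_id)]


def _as_maf_array(maf, n_snps: int) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(maf, dtype=float), (n_snps,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ValidationError("minor-allele frequencies must be finite")
    if np.any(arr <= 0.0) or np.any(arr > 0.5):
        raise ValidationError(
            "minor-allele frequencies must lie in (0, 0.5]"
        )
    return arr


def simulate_genotypes(
    n_dams: int,
    n_snps: int,
    maf,
    seed: int,
    n_chromosomes: int = 5,
) -> GenotypeMatrix:
    """Draw dam genotypes under per-SNP Hardy-Weinberg equilibrium.

    Each SNP's dosage is Binomial(2, p) with p the minor-allele frequency,
    i.e. genotype frequencies (1-p)^2, 2p(1-p), p^2 for dosages 0/1/2.
    SNPs are laid out on ``n_chromosomes`` chromosomes with strictly
    increasing positions.
    """
    if n_dams < 1 or n_snps < 1:
        raise ValidationError("n_dams and n_snps must be >= 1")
    p = _as_maf_array(maf, n_snps)
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, p, size=(n_dams, n_snps)).astype(np.int8)
    chrom = np.repeat(
        np.arange(1, n_chromosomes + 1),
        -(-n_snps // n_chromosomes),
    )[:n_snps]
    # strictly increasing positions within chromosome
    step = rng.integers(500, 5000, size=n_snps)
    pos = np.empty(n_snps, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = np.cumsum(step[idx])
    snp_ids = [f"snp{i:05d}" for i in range(n_snps)]
    snp_map = pd.DataFrame(
        {"snp_id": snp_ids, "chromosome": chrom.astype(str), "position": pos}
    )
    dam_ids = [f"dam{i:05d}" for i in range(n_dams)]
    return GenotypeMatrix(dam_ids, snp_ids, dosage, snp_map)


def _parent_values(
    name: str, genotypes: GenotypeMatrix, table: dict[str, np.ndarray]
) -> np.ndarray:
    if name in table:
        return table[name]
    if name in genotypes.snp_ids:
        return genotypes.column(name).astype(float)
    raise ValidationError(f"ground-truth parent {name!r} not found in inputs")


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: GroundTruth,
    n_batches: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample one rearing batch per dam under the planted dependency network.

    Traits are sampled in ancestral order (all planted parents are exogenous:
    SNP dosages or the dam's line/season).  Zero-inflated traits are exactly
    zero with their configured probability, shifted down by
    ``effect * parent_value`` for each planted parent; positive parts are
    gamma.  Clutch size is Binomial(14, p) with p shifted per planted parent.
    Rearing success is computed exactly from its three components.
    """
    n_dams = len(genotypes.dam_ids)
    if n_batches is None:
        n_batches = n_dams
    if n_batches > n_dams:
        raise ValidationError(
            f"n_batches={n_batches} exceeds the {n_dams} genotyped dams "
            "(one batch per dam)"
        )
    for snp in truth.causal_snp_ids:
        if snp not in genotypes.snp_ids:
            raise ValidationError(f"causal SNP {snp!r} absent from genotypes")
    rng = np.random.default_rng(seed)
    n = n_batches
    cols: dict[str, np.ndarray] = {
        "line": rng.integers(0, 4, size=n).astype(float),
        "season": rng.integers(0, 4, size=n).astype(float),
    }

    def effect_shift(trait: str) -> np.ndarray:
        shift = np.zeros(n)
        for parent, eff in truth.trait_parents(trait):
            shift += eff * _parent_values(parent, genotypes, cols)[:n]
        return shift

    # clutch size: per-egg laying probability shifted by planted parents
    p_egg = np.clip(_CLUTCH_P - effect_shift("clutch_size"), 0.0, 1.0)
    cols["clutch_size"] = rng.binomial(_CLUTCH_EGGS, p_egg).astype(float)

    for trait in (
        "embryo_mortality",
        "first_week_mortality",
        "natural_death",
        "rearing_abnormalities",
        "flock_age",
    ):
        shape, scale, cap = _GAMMA_PARAMS[trait]
        shift = effect_shift(trait)
        if trait in truth.zero_inflation:
            p_zero = truth.zero_inflation[trait] - shift
            if np.any(p_zero < -1e-12) or np.any(p_zero > 1 + 1e-12):
                raise ValidationError(
                    f"planted effects push P({trait}=0) outside [0, 1]"
                )
            p_zero = np.clip(p_zero, 0.0, 1.0)
            zero = rng.random(n) < p_zero
        else:
            mult = 1.0 + shift
            if np.any(mult <= 0):
                raise ValidationError(
                    f"planted effects push the mean of {trait} below 0"
                )
            scale = scale * mult
            zero = np.zeros(n, dtype=bool)
        values = np.minimum(rng.gamma(shape, scale, size=n), cap)
        values[zero] = 0.0
        cols[trait] = values

    success = 100.0 - (
        cols["first_week_mortality"]
        + cols["rearing_abnormalities"]
        + cols["natural_death"]
    )
    table = pd.DataFrame(
        {
            "batch_id": [f"batch{i:05d}" for i in range(n)],
            "line": [LINES[int(v)] for v in cols["line"]],
            "season": [SEASONS[int(v)] for v in cols["season"]],
            "clutch_size": cols["clutch_size"].astype(int),
            "embryo_mortality": cols["embryo_mortality"],
            "first_week_mortality": cols["first_week_mortality"],
            "rearing_abnormalities": cols["rearing_abnormalities"],
            "natural_death": cols["natural_death"],
            "rearing_success": success,
            "flock_age": cols["flock_age"],
        },
        index=pd.Index(genotypes.dam_ids[:n], name="dam_id"),
    )
    return table


def default_ground_truth(
    genotypes: GenotypeMatrix,
    n_causal: int = 5,
    effect: float = 0.18,
    seed: int = 0,
) -> GroundTruth:
    """Plant ``n_causal`` SNPs into the rearing traits with strong effects.

    Causal SNPs are spread round-robin over clutch size, first week
    mortality, rearing abnormalities and natural death (the traits of
    interest downstream).  ``effect`` is the per-dosage-unit probability
    shift; the clutch-size channel is scaled down because the per-egg
    probability is much more sensitive than a zero-inflation probability.
    """
    rng = np.random.default_rng(seed)
    # choose common SNPs so all three dosage classes are populated
    candidates = [
        s
        for s, f in zip(
            genotypes.snp_ids, genotypes.dosage.mean(axis=0) / 2.0
        )
        if f >= 0.2
    ]
    if len(candidates) < n_causal:
        candidates = list(genotypes.snp_ids)
    causal = [candidates[i] for i in
              sorted(rng.choice(len(candidates), n_causal, replace=False))]
    targets = [
        "clutch_size",
        "first_week_mortality",
        "rearing_abnormalities",
        "natural_death",
    ]
    dag, effects = [], {}
    for i, snp in enumerate(causal):
        trait = targets[i % len(targets)]
        dag.append((snp, trait))
        channel = TRAIT_EFFECT_CHANNEL[trait]
        if channel == "clutch":
            effects[(snp, trait)] = effect / 4.0
        elif channel == "mean":
            effects[(snp, trait)] = 2.0 * effect
        else:
            effects[(snp, trait)] = effect
    return GroundTruth(
        dag=tuple(dag),
        effect_sizes=effects,
        causal_snp_ids=tuple(causal),
        maf={},
    )


def single_trait_truth(
    genotypes: GenotypeMatrix,
    trait: str = "clutch_size",
    n_causal: int = 5,
    effect: float | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Plant ``n_causal`` SNPs into a single trait that binarizes downstream.

    The default target is clutch size: its effect channel (the per-egg
    laying probability) tolerates strong shifts from several simultaneous
    parents while keeping every conditional probability valid.
    ``effect=None`` picks a strong per-dosage shift — 0.05 for the clutch
    channel, otherwise the largest shift that keeps the trait's zero
    probability inside [0, 1] at the worst-case dosage sum.
    """
    if trait not in TRAIT_EFFECT_CHANNEL:
        raise ValidationError(f"no effect channel for trait {trait!r}")
    if effect is None:
        if TRAIT_EFFECT_CHANNEL[trait] == "clutch":
            effect = 0.05
        elif trait in DEFAULT_ZERO_INFLATION:
            effect = DEFAULT_ZERO_INFLATION[trait] / (2.0 * n_causal)
        else:
            effect = 0.3
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(genotypes.snp_ids), n_causal, replace=False))
    causal = [genotypes.snp_ids[i] for i in idx]
    dag = tuple((snp, trait) for snp in causal)
    return GroundTruth(
        dag=dag,
        effect_sizes={edge: effect for edge in dag},
        causal_snp_ids=tuple(causal),
        maf={},
    )


def simulate_study(
    n_dams: int = 500,
    n_snps: int = 200,
    n_causal: int = 5,
    effect: float = 0.18,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame, GroundTruth]:
    """One-call study fixture: genotypes, phenotypes and the planted truth."""
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, size=n_snps)
    genotypes = simulate_genotypes(n_dams, n_snps, maf, seed=int(rng.integers(2**31)))
    truth = default_ground_truth(
        genotypes, n_causal=n_causal, effect=effect, seed=int(rng.integers(2**31))
    )
    phenotypes = simulate_phenotypes(
        genotypes, truth, seed=int(rng.integers(2**31))
    )
    return genotypes, phenotypes, truth
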