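"""End-to-end orchestration: simulate/load -> discretize -> select -> block
-> learn -> overlap -> annotate, with a single master seed and a manifest.

Every stage reads and writes plain-text intermediates, so the chained CLI
subcommands and :func:`run_all` produce bit-identical outputs for the same
configuration; ``run_all`` simply runs the stages in sequence.  Defaults
reproduce the study settings: 10 SNP subsets, top-20 selection per trait,
10-fold cross-validation repeated 3 times, contingency exclusion at
P >= 0.25, and the confounded rearing-success links blocked in both
directions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from . import io as rio
from .blocklist import (
    DEFAULT_CONFOUNDED_PAIRS,
    DEFAULT_P_THRESHOLD,
    EdgeBlocklist,
    build_blocklist,
)
from .bn import DAGNetwork, SAConfig, learn_subset_networks
from .discretize import (
    DiscreteDataset,
    PHENOTYPE_VARS,
    discretize_genotypes,
    discretize_phenotypes,
    join_datasets,
)
from .errors import ValidationError
from .nb_select import cv_importance, partition_snps, select_top_k
from .overlap import TRAITS_OF_INTEREST, build_overlapped, summarize_associations
from .simulate import simulate_study

logger = logging.getLogger(__name__)

_STAGE_KEYS = {"simulate": 0, "partition": 1, "cv": 2, "learn": 3}


def derive_seed(master: int, stage: str, *extra: int) -> int:
    """Deterministic per-stage (and per-substage) seed below 2**31."""
    seq = np.random.SeedSequence([int(master), _STAGE_KEYS[stage], *extra])
    return int(seq.generate_state(1)[0] % 2**31)


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults reproduce the study's constants."""

    output_dir: str = "rearnet_output"
    genotypes_path: str | None = None
    map_path: str | None = None
    phenotypes_path: str | None = None
    annotation_path: str | None = None
    annotation_format: str = "bed"
    # synthetic study (used when no input paths are given)
    n_dams: int = 500
    n_snps: int = 200
    n_causal: int = 5
    effect: float = 0.18
    # selection
    n_subsets: int = 10
    top_k: int = 20
    cv_folds: int = 10
    cv_repeats: int = 3
    nb_alpha: float = 1.0
    # blocklist
    p_threshold: float = DEFAULT_P_THRESHOLD
    confounded_pairs: tuple = DEFAULT_CONFOUNDED_PAIRS
    # structure search
    sa: SAConfig = field(
        default_factory=lambda: SAConfig(
            max_iterations=20_000,
            moves_per_temperature=50,
            cooling_factor=0.85,
            restarts=1,
        )
    )
    traits_of_interest: tuple = TRAITS_OF_INTEREST
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sa" in d and isinstance(d["sa"], dict):
            d["sa"] = SAConfig(**d["sa"])
        if "confounded_pairs" in d:
            d["confounded_pairs"] = tuple(
                tuple(p) for p in d["confounded_pairs"]
            )
        if "traits_of_interest" in d:
            d["traits_of_interest"] = tuple(d["traits_of_interest"])
        return cls(**d)


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------- stages


def stage_simulate(config: PipelineConfig) -> dict[str, Path]:
    out = _outdir(config) / "data"
    genotypes, phenotypes, truth = simulate_study(
        n_dams=config.n_dams,
        n_snps=config.n_snps,
        n_causal=config.n_causal,
        effect=config.effect,
        seed=derive_seed(config.seed, "simulate"),
    )
    return rio.write_dataset(genotypes, phenotypes, truth, out)


def _load_inputs(config: PipelineConfig):
    out = _outdir(config)
    if config.genotypes_path is not None:
        if config.phenotypes_path is None:
            raise ValidationError(
                "phenotypes_path required when genotypes_path is given"
            )
        geno = rio.read_genotypes(config.genotypes_path, config.map_path)
        pheno = rio.read_phenotypes(config.phenotypes_path)
    else:
        data_dir = out / "data"
        geno = rio.read_genotypes(data_dir / "dosage.csv", data_dir / "snps.map")
        pheno = rio.read_phenotypes(data_dir / "phenotypes.csv")
    shared = [d for d in geno.dam_ids if d in set(pheno.index.astype(str))]
    if not shared:
        raise ValidationError(
            "no shared dam ids between genotypes and phenotypes"
        )
    missing = [c for c in PHENOTYPE_VARS if c not in pheno.columns]
    if missing:
        raise ValidationError(f"phenotype table misses column(s) {missing}")
    return geno, pheno.loc[shared]


def stage_discretize(config: PipelineConfig) -> Path:
    out = _outdir(config)
    geno, pheno = _load_inputs(config)
    ds = join_datasets(discretize_phenotypes(pheno), discretize_genotypes(geno))
    ds.data.to_csv(out / "discrete.csv")
    rio.write_json(
        {
            col: {str(k): v for k, v in ds.category_maps[col].items()}
            for col in ds.columns
        },
        out / "category_maps.json",
    )
    return out / "discrete.csv"


def load_discrete(config: PipelineConfig) -> DiscreteDataset:
    out = _outdir(config)
    data = pd.read_csv(out / "discrete.csv", index_col=0)
    maps_raw = rio.read_json(out / "category_maps.json")
    maps = {
        col: {int(code): label for code, label in m.items()}
        for col, m in maps_raw.items()
    }
    return DiscreteDataset(data, maps)


def stage_select(config: PipelineConfig, traits=None) -> Path:
    out = _outdir(config)
    ds = load_discrete(config)
    snp_cols = [c for c in ds.columns if c not in PHENOTYPE_VARS]
    groups = partition_snps(
        snp_cols, config.n_subsets, seed=derive_seed(config.seed, "partition")
    )
    traits = list(traits) if traits else list(config.traits_of_interest)
    rankings = {}
    rows = []
    for gi, group in enumerate(groups):
        for ti, trait in enumerate(traits):
            ranking = cv_importance(
                ds,
                trait,
                snp_vars=group,
                folds=config.cv_folds,
                repeats=config.cv_repeats,
                seed=derive_seed(config.seed, "cv", gi, ti),
                alpha=config.nb_alpha,
            )
            ranking.subset_index = gi
            rankings[(trait, gi)] = ranking
            for rank, (snp, score) in enumerate(ranking.entries, 1):
                rows.append((trait, gi, rank, snp, score))
    pd.DataFrame(
        rows, columns=["trait", "subset", "rank", "snp_id", "importance"]
    ).to_csv(out / "rankings.tsv", sep="\t", index=False)
    selection = select_top_k(rankings, k=config.top_k)
    rio.write_json(
        {
            "importance_metric": "held-out single-feature AUC "
            "(fold-mean, folded into [0.5,1]; max one-vs-one pair for "
            "multiclass)",
            "subsets": {str(k): v for k, v in selection.items()},
            "groups": {str(i): g for i, g in enumerate(groups)},
        },
        out / "selection.json",
    )
    return out / "selection.json"


def stage_block(config: PipelineConfig) -> Path:
    out = _outdir(config)
    ds = load_discrete(config)
    pheno_vars = [c for c in ds.columns if c in PHENOTYPE_VARS]
    bl = build_blocklist(
        ds.restrict(pheno_vars),
        pheno_vars,
        confounded_pairs=config.confounded_pairs,
        p_threshold=config.p_threshold,
    )
    edges = sorted(bl.edges)
    rio.write_edge_list(
        edges,
        out / "blocklist.tsv",
        extra_columns={
            "provenance": [bl.provenance[e] for e in edges],
            "p_value": [
                bl.p_values.get(frozenset(e), "") for e in edges
            ],
        },
    )
    return out / "blocklist.tsv"


def load_blocklist(path) -> EdgeBlocklist:
    df = rio.read_edge_list(path)
    bl = EdgeBlocklist()
    for row in df.itertuples(index=False):
        p = getattr(row, "p_value", None)
        p = None if p in ("", None) or pd.isna(p) else float(p)
        bl.add(str(row[0]), str(row[1]), str(row.provenance), p_value=p)
    return bl


def write_network(net: DAGNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# score={net.score!r}\n")
        fh.write("# nodes=" + ",".join(net.nodes) + "\n")
        fh.write(
            "# arity=" + ",".join(str(net.arities[n]) for n in net.nodes) + "\n"
        )
        fh.write("from\tto\n")
        for u, v in net.sorted_edges():
            fh.write(f"{u}\t{v}\n")


def read_network(path) -> DAGNetwork:
    score = None
    nodes: list[str] = []
    arities: list[int] = []
    edges = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# score="):
                score = float(line.split("=", 1)[1])
            elif line.startswith("# nodes="):
                nodes = line.split("=", 1)[1].split(",")
            elif line.startswith("# arity="):
                arities = [int(x) for x in line.split("=", 1)[1].split(",")]
            elif line and not line.startswith("#") and line != "from\tto":
                u, v = line.split("\t")
                edges.add((u, v))
    if score is None or not nodes:
        raise ValidationError(f"{path}: malformed network file")
    return DAGNetwork(
        nodes=nodes,
        arities=dict(zip(nodes, arities)),
        edges=edges,
        score=score,
    )


def stage_learn(config: PipelineConfig) -> list[Path]:
    out = _outdir(config)
    ds = load_discrete(config)
    selection = rio.read_json(out / "selection.json")["subsets"]
    bl = load_blocklist(out / "blocklist.tsv")
    pheno_vars = [c for c in ds.columns if c in PHENOTYPE_VARS]
    datasets = []
    for gi in sorted(selection, key=int):
        cols = pheno_vars + [s for s in selection[gi] if s in ds.columns]
        datasets.append(ds.restrict(cols))
    sa = dataclasses.replace(config.sa, seed=derive_seed(config.seed, "learn"))
    networks = learn_subset_networks(datasets, bl, sa)
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    paths = []
    for gi, net in enumerate(networks):
        path = net_dir / f"subset_{gi:02d}.edges.tsv"
        write_network(net, path)
        (net_dir / f"subset_{gi:02d}.dot").write_text(
            net.to_dot(snp_nodes=set(net.nodes) - set(pheno_vars))
        )
        paths.append(path)
    return paths


def stage_overlap(config: PipelineConfig) -> Path:
    out = _outdir(config)
    net_dir = out / "networks"
    paths = sorted(net_dir.glob("subset_*.edges.tsv"))
    if not paths:
        raise ValidationError(f"no network files under {net_dir}")
    networks = [read_network(p) for p in paths]
    ov = build_overlapped(
        networks,
        traits_of_interest=config.traits_of_interest,
        phenotype_vars=[n for n in networks[0].nodes if n in PHENOTYPE_VARS],
    )
    pairs = ov.edge_pairs()
    rio.write_edge_list(
        pairs,
        out / "overlapped.edges.tsv",
        header=("node_a", "node_b"),
        extra_columns={
            "multiplicity": [
                ov.multiplicity[frozenset(p)] for p in pairs
            ],
            "orientations": [
                ";".join(
                    f"{u}->{v}"
                    for u, v in sorted(ov.orientations[frozenset(p)])
                )
                for p in pairs
            ],
        },
    )
    summary = summarize_associations(ov)
    rio.write_json(summary, out / "associations.json")
    (out / "overlapped.dot").write_text(ov.to_dot())
    return out / "associations.json"


def stage_annotate(config: PipelineConfig) -> Path | None:
    out = _outdir(config)
    if config.annotation_path is None:
        logger.info("no annotation file configured; skipping annotation")
        return None
    if config.annotation_format == "bed":
        features = annotate_mod.read_bed(config.annotation_path)
    elif config.annotation_format == "gff3":
        features = annotate_mod.read_gff3(config.annotation_path)
    else:
        raise ValidationError(
            f"unknown annotation format {config.annotation_format!r}"
        )
    if config.map_path is not None:
        snp_map = rio.read_map(config.map_path)
    else:
        snp_map = rio.read_map(out / "data" / "snps.map")
    summary = rio.read_json(out / "associations.json")
    linked = sorted(
        {s for row in summary["per_trait"] for s in row["snp_ids"]}
    )
    assignments = annotate_mod.annotate_snps(snp_map, features, snp_ids=linked)
    if assignments:
        annotate_mod.export_gene_list(assignments, out / "gene_list.txt")
        rows = [
            {
                "snp_id": a.snp_id,
                "feature_id": a.feature_id,
                "distance": a.distance,
                "tie_ids": ";".join(a.tie_ids),
            }
            for a in assignments
        ]
        pd.DataFrame(rows).to_csv(out / "nearest_genes.tsv", sep="\t", index=False)
    return out / "gene_list.txt" if assignments else None


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in sequence and write a manifest with checksums."""
    out = _outdir(config)
    if config.genotypes_path is None:
        stage_simulate(config)
    stage_discretize(config)
    stage_select(config)
    stage_block(config)
    stage_learn(config)
    stage_overlap(config)
    stage_annotate(config)
    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        "seed": config.seed,
        "checksums": {str(p.relative_to(out)): _checksum(p) for p in files},
    }
    rio.write_json(manifest, out / "manifest.json")
    return manifest
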