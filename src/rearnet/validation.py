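"""Seeded validation studies: recovery, calibration and oracle checks.

These routines re-run the package's own machinery on synthetic data with
planted ground truth and measure how well it is recovered — the package's
substitute for headline numbers that would require the original proprietary
study data.  Problem sizes are module defaults chosen to finish on a single
CPU in minutes; see the methods note for the reasoning behind each study
design.
"""

from __future__ import annotations

import itertools
import math
import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import io as rio
from .annotate import FeatureInterval, nearest_feature
from .blocklist import chi_square_independence
from .bn import SAConfig, bde_local_score, exhaustive_search, sa_search
from .discretize import (
    DiscreteDataset,
    discretize_genotypes,
    discretize_phenotypes,
    join_datasets,
)
from .nb_select import cv_importance
from .pipeline import PipelineConfig, run_all
from .simulate import (
    GroundTruth,
    simulate_genotypes,
    simulate_phenotypes,
    single_trait_truth,
)

#: Generous-budget annealing settings for small oracle-checked problems.
ORACLE_SA = SAConfig(
    max_iterations=4000,
    moves_per_temperature=50,
    cooling_factor=0.85,
    restarts=2,
)


def _binary_dataset(cols: dict[str, np.ndarray]) -> DiscreteDataset:
    df = pd.DataFrame({k: np.asarray(v, dtype=np.int64) for k, v in cols.items()})
    maps = {k: {0: "0", 1: "1"} for k in df.columns}
    return DiscreteDataset(df, maps)


def _four_variable_problem(rng, n: int = 1000, kind: str = "chain"):
    """Planted 4-variable binary dataset: a noisy chain or a v-structure
    with a chain tail (flip noise 0.1)."""
    flip = lambda x: (x ^ (rng.random(n) < 0.1)).astype(np.int64)
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    if kind == "chain":
        bb = flip(a)
        c = flip(bb)
        d = flip(c)
        return _binary_dataset({"A": a, "B": bb, "C": c, "D": d})
    c = flip(a ^ b)
    d = flip(c)
    return _binary_dataset({"A": a, "B": b, "C": c, "D": d})


def sa_oracle_study(
    n_problems: int = 20, n: int = 1000, seed: int = 0,
    sa_config: SAConfig | None = None,
) -> dict:
    """Fraction of planted 4-variable problems where annealing attains the
    exhaustive-search BDeu maximum."""
    sa_config = sa_config or ORACLE_SA
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_problems):
        kind = "chain" if i % 2 == 0 else "vstructure"
        ds = _four_variable_problem(rng, n=n, kind=kind)
        oracle = exhaustive_search(ds)
        net = sa_search(
            ds, None, replace(sa_config, seed=int(rng.integers(2**31)))
        )
        if abs(net.score - oracle.score) < 1e-6:
            hits += 1
    return {"hits": hits, "total": n_problems, "rate": hits / n_problems}


def naive_bde_reference(child, parents, data: DiscreteDataset, ess: float) -> float:
    """Plain-loop BDeu reference (explicit per-configuration products)."""
    arity = data.arity
    df = data.data
    r = arity[child]
    q = int(np.prod([arity[p] for p in parents])) if parents else 1
    a_jk = ess / (q * r)
    a_j = ess / q
    total = 0.0
    configs = (
        itertools.product(*(range(arity[p]) for p in parents))
        if parents
        else [()]
    )
    for cfg in configs:
        rows = df
        for p, s in zip(parents, cfg):
            rows = rows[rows[p] == s]
        total += gammaln(a_j) - gammaln(a_j + len(rows))
        for k in range(r):
            total += gammaln(a_jk + (rows[child] == k).sum()) - gammaln(a_jk)
    return total


def bde_oracle_study(n_tables: int = 50, seed: int = 0) -> dict:
    """Max |implementation - reference| over random count tables, plus the
    closed-form no-parent worked example ln(3/128)."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_tables):
        arities = rng.integers(2, 4, size=3)
        n = int(rng.integers(5, 60))
        df = pd.DataFrame(
            {k: rng.integers(0, a, n) for k, a in zip("ABC", arities)}
        )
        maps = {
            k: {int(s): str(s) for s in range(int(a))}
            for k, a in zip("ABC", arities)
        }
        ds = DiscreteDataset(df, maps)
        ess = float(rng.uniform(0.5, 10))
        diff = abs(
            bde_local_score("A", ["B", "C"], ds, ess)
            - naive_bde_reference("A", ["B", "C"], ds, ess)
        )
        max_diff = max(max_diff, diff)
    example = bde_local_score(
        "A", [], _binary_dataset({"A": np.array([0, 0, 1, 1])}), ess=1.0
    )
    return {
        "max_abs_diff": max_diff,
        "no_parent_example": example,
        "no_parent_expected": math.log(3 / 128),
    }


def markov_equivalence_study(seed: int = 0, n: int = 2000) -> dict:
    """Score gap across the three Markov-equivalent 3-node DAGs, and the
    collider's advantage on v-structure data."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, n)
    b = (a ^ (rng.random(n) < 0.1)).astype(np.int64)
    c = (b ^ (rng.random(n) < 0.1)).astype(np.int64)
    chain_ds = _binary_dataset({"A": a, "B": b, "C": c})
    dags = {
        "chain": [("A", []), ("B", ["A"]), ("C", ["B"])],
        "fork": [("A", ["B"]), ("B", []), ("C", ["B"])],
        "reversed": [("A", ["B"]), ("B", ["C"]), ("C", [])],
    }
    scores = {
        name: sum(bde_local_score(ch, ps, chain_ds) for ch, ps in dag)
        for name, dag in dags.items()
    }
    gap = max(scores.values()) - min(scores.values())
    a2 = rng.integers(0, 2, n)
    b2 = rng.integers(0, 2, n)
    c2 = ((a2 ^ b2) ^ (rng.random(n) < 0.1)).astype(np.int64)
    v_ds = _binary_dataset({"A": a2, "B": b2, "C": c2})
    collider = sum(
        bde_local_score(ch, ps, v_ds)
        for ch, ps in [("A", []), ("B", []), ("C", ["A", "B"])]
    )
    chain_on_v = sum(
        bde_local_score(ch, ps, v_ds)
        for ch, ps in [("A", []), ("B", ["A"]), ("C", ["B"])]
    )
    return {
        "equivalence_gap": gap,
        "collider_advantage": collider - chain_on_v,
    }


def selection_recovery_study(
    n_seeds: int = 10,
    n_dams: int = 2000,
    n_snps: int = 500,
    n_causal: int = 5,
    top_k: int = 20,
    seed: int = 0,
) -> dict:
    """How often the cross-validated importance filter places the planted
    causal SNPs of a binary trait inside the top-k of the full panel."""
    rng = np.random.default_rng(seed)
    per_seed = []
    for _ in range(n_seeds):
        maf = rng.uniform(0.1, 0.5, n_snps)
        g = simulate_genotypes(
            n_dams, n_snps, maf, seed=int(rng.integers(2**31))
        )
        truth = single_trait_truth(
            g, n_causal=n_causal, seed=int(rng.integers(2**31))
        )
        pheno = simulate_phenotypes(g, truth, seed=int(rng.integers(2**31)))
        ds = join_datasets(
            discretize_phenotypes(pheno), discretize_genotypes(g)
        )
        snps = [c for c in ds.columns if c in set(g.snp_ids)]
        ranking = cv_importance(
            ds, "clutch_size", snp_vars=snps, seed=int(rng.integers(2**31))
        )
        top = set(s for s, _ in ranking.entries[:top_k])
        per_seed.append(sum(s in top for s in truth.causal_snp_ids))
    hits = sum(c >= n_causal - 1 for c in per_seed)
    return {
        "per_seed_in_top_k": per_seed,
        "seeds_with_at_least_4": hits,
        "n_seeds": n_seeds,
        "rate": hits / n_seeds,
    }


def pipeline_recovery_study(
    n_runs: int = 10, seed: int = 0, work_dir=None
) -> dict:
    """Full-pipeline recovery of planted trait-SNP associations on the
    500-dam / 200-SNP fixture, plus a blocked-edge audit of every learned
    and overlapped network."""
    results = []
    blocked_violations = 0
    base = Path(work_dir) if work_dir else None
    ctx = tempfile.TemporaryDirectory() if base is None else None
    root = base if base is not None else Path(ctx.name)
    try:
        for run in range(n_runs):
            out = root / f"run_{run:02d}"
            cfg = PipelineConfig(
                output_dir=str(out), seed=int(seed * 1000 + run)
            )
            run_all(cfg)
            truth = rio.read_truth_edges(out / "data" / "truth_edges.tsv")
            planted_snps = {s for s, _, _ in truth}
            summary = rio.read_json(out / "associations.json")
            linked = {
                s for row in summary["per_trait"] for s in row["snp_ids"]
            }
            from .pipeline import load_blocklist, read_network

            bl = load_blocklist(out / "blocklist.tsv")
            for net_path in sorted((out / "networks").glob("*.edges.tsv")):
                net = read_network(net_path)
                blocked_violations += len(net.edges & bl.edges)
            overlapped = rio.read_edge_list(out / "overlapped.edges.tsv")
            for row in overlapped.itertuples(index=False):
                if (row.node_a, row.node_b) in bl.edges or (
                    row.node_b,
                    row.node_a,
                ) in bl.edges:
                    blocked_violations += 1
            results.append(
                {
                    "planted": len(planted_snps),
                    "recovered": len(planted_snps & linked),
                    "total_linked": summary["total_distinct_snps"],
                }
            )
    finally:
        if ctx is not None:
            ctx.cleanup()
    full = sum(r["recovered"] == r["planted"] for r in results)
    n_assoc = sum(r["planted"] for r in results)
    n_recovered = sum(r["recovered"] for r in results)
    return {
        "runs": results,
        "runs_fully_recovered": full,
        "n_runs": n_runs,
        "association_rate": n_recovered / n_assoc,
        "full_recovery_rate": full / n_runs,
        "blocked_edge_violations": blocked_violations,
    }


def null_blocking_study(
    n_replicates: int = 200,
    n: int = 500,
    p_threshold: float = 0.25,
    seed: int = 0,
) -> dict:
    """Rate at which an independent trait pair is excluded (p >= threshold);
    under a uniform p-value null this is 1 - threshold."""
    rng = np.random.default_rng(seed)
    g = simulate_genotypes(n, 2, 0.4, seed=int(rng.integers(2**31)))
    truth = GroundTruth(
        dag=(("snp00000", "natural_death"),),
        effect_sizes={("snp00000", "natural_death"): 0.0},
        causal_snp_ids=("snp00000",),
    )
    blocked = 0
    for _ in range(n_replicates):
        pheno = simulate_phenotypes(g, truth, seed=int(rng.integers(2**31)))
        em = (pheno["embryo_mortality"] > 0).astype(int)
        cs = (pheno["clutch_size"] > 12).astype(int)
        _, _, p = chi_square_independence(em.to_numpy(), cs.to_numpy())
        blocked += p >= p_threshold
    return {
        "blocked": blocked,
        "n_replicates": n_replicates,
        "rate": blocked / n_replicates,
        "expected": 1 - p_threshold,
    }


def eq1_conservation_study(seed: int = 0, n_dams: int = 500) -> dict:
    """Exactness of the rearing-success identity on generated rows."""
    from .discretize import compute_rearing_success
    from .simulate import simulate_study

    _, pheno, _ = simulate_study(n_dams=n_dams, n_snps=10, seed=seed)
    total = (
        pheno["first_week_mortality"]
        + pheno["rearing_abnormalities"]
        + pheno["natural_death"]
        + pheno["rearing_success"]
    )
    worked = compute_rearing_success(1.0, 2.0, 1.0)
    return {
        "max_abs_error": float(np.abs(total - 100.0).max()),
        "worked_example": float(worked),
    }


def nearest_gene_study(n_fixtures: int = 1000, seed: int = 0) -> dict:
    """Exact agreement (including ties) between the nearest-feature lookup
    and a brute-force all-intervals scan on random fixtures."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_fixtures):
        features = [
            FeatureInterval(
                "1", int(s), int(s + rng.integers(1, 50)), f"g{i}"
            )
            for i, s in enumerate(rng.integers(0, 1000, 12))
        ]
        pos1 = int(rng.integers(1, 1100))
        hit = nearest_feature(("1", pos1), features)
        # brute force
        pos = pos1 - 1
        dists = [
            max(f.start - pos, 0) + max(pos - (f.end - 1), 0)
            for f in features
        ]
        dmin = min(dists)
        ids = [
            f.feature_id
            for f in sorted(
                (f for f, d in zip(features, dists) if d == dmin),
                key=lambda f: (f.start, f.feature_id),
            )
        ]
        if hit.distance != dmin or [hit.feature_id, *hit.tie_ids] != ids:
            mismatches += 1
    return {"mismatches": mismatches, "n_fixtures": n_fixtures}
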