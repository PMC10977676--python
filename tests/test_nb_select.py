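"""SNP partitioning, Laplace-smoothed Naive Bayes, cross-validated AUC
importance and top-k pooling."""

import numpy as np
import pytest
from scipy.stats import chisquare

from rearnet.discretize import discretize_genotypes, discretize_phenotypes, join_datasets
from rearnet.errors import ValidationError
from rearnet.nb_select import (
    ImportanceRanking,
    _grouped_auc,
    cv_importance,
    fit_naive_bayes,
    partition_snps,
    select_top_k,
)

from conftest import binary_dataset


class TestPartition:
    def test_balanced_split_arithmetic(self):
        ids = [f"s{i}" for i in range(25)]
        groups = partition_snps(ids, n_groups=10, seed=0)
        sizes = sorted(len(g) for g in groups)
        assert sizes == [2] * 5 + [3] * 5
        assert sorted(x for g in groups for x in g) == sorted(ids)

    def test_single_group_identity(self):
        ids = [f"s{i}" for i in range(10)]
        (group,) = partition_snps(ids, n_groups=1, seed=3)
        assert sorted(group) == sorted(ids)

    def test_deterministic(self):
        ids = [f"s{i}" for i in range(40)]
        assert partition_snps(ids, 10, seed=5) == partition_snps(ids, 10, seed=5)

    def test_too_many_groups_rejected(self):
        with pytest.raises(ValidationError):
            partition_snps(["a", "b"], n_groups=3)


class TestNaiveBayes:
    def test_hand_counted_laplace_conditional(self):
        # class0 rows have SNP states (0,0); class1 rows have (1,1); alpha=1
        ds = binary_dataset({"snp": [0, 0, 1, 1], "y": [0, 0, 1, 1]})
        model = fit_naive_bayes(ds, "y", alpha=1.0)
        cond = model.conditionals["snp"]
        assert cond[0, 0] == pytest.approx((2 + 1) / (2 + 2))  # P(snp=0|y=0)
        assert cond[1, 0] == pytest.approx(0.25)
        assert np.allclose(cond.sum(axis=0), 1.0)

    def test_large_alpha_approaches_uniform(self):
        ds = binary_dataset({"snp": [0, 0, 1, 1], "y": [0, 0, 1, 1]})
        model = fit_naive_bayes(ds, "y", alpha=1e9)
        assert np.allclose(model.conditionals["snp"], 0.5, atol=1e-6)

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        ds = binary_dataset(
            {
                "a": rng.integers(0, 3, 50),
                "b": rng.integers(0, 2, 50),
                "y": rng.integers(0, 2, 50),
            }
        )
        model = fit_naive_bayes(ds, "y")
        post = model.predict_proba(ds)
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_constant_class_rejected(self):
        ds = binary_dataset({"snp": [0, 1, 0, 1], "y": [1, 1, 1, 1]})
        with pytest.raises(ValidationError):
            fit_naive_bayes(ds, "y")

    def test_matches_sklearn_categorical_nb(self):
        sklearn = pytest.importorskip("sklearn.naive_bayes")
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, size=(200, 4))
        y = rng.integers(0, 2, 200)
        ds = binary_dataset(
            {**{f"f{j}": X[:, j] for j in range(4)}, "y": y}
        )
        model = fit_naive_bayes(ds, "y", alpha=1.0)
        ref = sklearn.CategoricalNB(alpha=1.0, min_categories=3).fit(X, y)
        ours = model.predict_proba(ds)
        theirs = ref.predict_proba(X)
        assert np.allclose(ours, theirs, atol=1e-9)


class TestGroupedAUC:
    def test_matches_sklearn_roc_auc(self):
        roc_auc_score = pytest.importorskip("sklearn.metrics").roc_auc_score
        rng = np.random.default_rng(2)
        for _ in range(20):
            states = rng.integers(0, 3, 300)
            y = rng.integers(0, 2, 300)
            scores = rng.random(3)
            neg = np.stack(
                [((states == s) & (y == 0)).sum() for s in range(3)]
            ).reshape(3, 1)
            pos = np.stack(
                [((states == s) & (y == 1)).sum() for s in range(3)]
            ).reshape(3, 1)
            ours = _grouped_auc(scores.reshape(3, 1), neg, pos)[0]
            theirs = roc_auc_score(y, scores[states])
            assert ours == pytest.approx(theirs, abs=1e-12)


class TestImportance:
    def test_perfect_separator_scores_one(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 400)
        noise = rng.integers(0, 3, 400)
        ds = binary_dataset({"copy": y, "noise": noise, "y": y})
        ranking = cv_importance(ds, "y", snp_vars=["copy", "noise"], seed=0)
        scores = dict(ranking.entries)
        assert scores["copy"] == pytest.approx(1.0)
        assert ranking.entries[0][0] == "copy"

    def test_independent_snp_near_half(self):
        """Permutation oracle: mean importance of a label-shuffled SNP
        concentrates at 0.5."""
        rng = np.random.default_rng(4)
        snp = rng.integers(0, 3, 2000)
        y = rng.integers(0, 2, 2000)
        scores = []
        for shuffle in range(100):
            ds = binary_dataset({"snp": snp, "y": rng.permutation(y)})
            ranking = cv_importance(ds, "y", snp_vars=["snp"], seed=shuffle)
            scores.append(ranking.entries[0][1])
        assert abs(np.mean(scores) - 0.5) < 0.02

    def test_importance_invariant_to_state_relabeling(self):
        rng = np.random.default_rng(5)
        snp = rng.integers(0, 3, 500)
        y = (snp + (rng.random(500) < 0.3)).astype(int) % 2
        relabeled = np.array([2, 0, 1])[snp]
        ds = binary_dataset({"snp": snp, "perm": relabeled, "y": y})
        r1 = cv_importance(ds, "y", snp_vars=["snp"], seed=7)
        r2 = cv_importance(ds, "y", snp_vars=["perm"], seed=7)
        assert r1.entries[0][1] == pytest.approx(r2.entries[0][1], abs=1e-12)

    def test_planted_causal_ranks_first(self, small_study):
        geno, pheno, truth = small_study
        ds = join_datasets(
            discretize_phenotypes(pheno), discretize_genotypes(geno)
        )
        snp, trait = truth.dag[0]
        snps = [c for c in ds.columns if c.startswith("snp")]
        wins = 0
        for seed in range(5):
            ranking = cv_importance(ds, trait, snp_vars=snps, seed=seed)
            wins += ranking.entries[0][0] == snp
        assert wins >= 4

    def test_multiclass_trait_accepted(self, small_study):
        geno, pheno, _ = small_study
        ds = join_datasets(
            discretize_phenotypes(pheno), discretize_genotypes(geno)
        )
        snps = [c for c in ds.columns if c.startswith("snp")][:5]
        ranking = cv_importance(ds, "flock_age", snp_vars=snps, seed=0)
        assert all(0.5 <= s <= 1.0 for _, s in ranking.entries)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        ds = binary_dataset(
            {
                **{f"s{j}": rng.integers(0, 3, 300) for j in range(5)},
                "y": rng.integers(0, 2, 300),
            }
        )
        r1 = cv_importance(ds, "y", seed=9)
        r2 = cv_importance(ds, "y", seed=9)
        assert r1.entries == r2.entries

    def test_constant_trait_rejected(self):
        import pandas as pd

        from rearnet.discretize import DiscreteDataset

        # declared binary but observed constant: rejected at ranking time
        ds = DiscreteDataset(
            pd.DataFrame({"snp": [0, 1, 0, 1], "y": [0, 0, 0, 0]}),
            {"snp": {0: "0", 1: "1"}, "y": {0: "0", 1: "1"}},
        )
        with pytest.raises(ValidationError):
            cv_importance(ds, "y", snp_vars=["snp"])

    def test_null_rank_uniformity(self):
        """On null data the rank of a fixed SNP is uniform over positions
        (chi-square goodness of fit over 200 replicates)."""
        rng = np.random.default_rng(10)
        n_snps = 5
        ranks = []
        for _ in range(200):
            ds = binary_dataset(
                {
                    **{
                        f"s{j}": rng.integers(0, 3, 120)
                        for j in range(n_snps)
                    },
                    "y": rng.integers(0, 2, 120),
                }
            )
            ranking = cv_importance(ds, "y", folds=5, repeats=1, seed=0)
            ranks.append([s for s, _ in ranking.entries].index("s0"))
        counts = np.bincount(ranks, minlength=n_snps)
        assert chisquare(counts).pvalue > 0.01


class TestSelectTopK:
    def _ranking(self, trait, subset, ids):
        return ImportanceRanking(
            trait=trait,
            subset_index=subset,
            entries=[(s, 1.0 - i * 0.01) for i, s in enumerate(ids)],
        )

    def test_full_overlap_collapses(self):
        ids = [f"s{i}" for i in range(20)]
        rankings = {
            (t, 0): self._ranking(t, 0, ids) for t in ("t1", "t2", "t3")
        }
        assert select_top_k(rankings, k=20) == {0: ids}

    def test_disjoint_lists_concatenate(self):
        rankings = {
            ("t1", 0): self._ranking("t1", 0, [f"a{i}" for i in range(20)]),
            ("t2", 0): self._ranking("t2", 0, [f"b{i}" for i in range(20)]),
        }
        assert len(select_top_k(rankings, k=20)[0]) == 40

    def test_k_larger_than_subset_saturates(self):
        rankings = {("t1", 0): self._ranking("t1", 0, ["x", "y"])}
        assert select_top_k(rankings, k=20) == {0: ["x", "y"]}

    def test_empty_ranking_rejected(self):
        rankings = {("t1", 0): ImportanceRanking("t1", 0, [])}
        with pytest.raises(ValidationError):
            select_top_k(rankings, k=5)
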