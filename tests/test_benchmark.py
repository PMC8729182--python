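"""Synthetic multi-omics generator, Ward pathways, effect injection,
benchmark orchestration, and the evaluation metrics."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import minimaxomics as mx
from minimaxomics.benchmark import assign_groups, _round_half_away


class TestGenerator:
    def test_rho_zero_uncorrelated(self):
        data = mx.generate_multiomics(
            pathway_sizes=[2] * 5, samples_per_omics=(2000,), rho=0.0, seed=1
        )
        x = data.layers[0].data.to_numpy()
        for k in range(5):
            r = np.corrcoef(x[2 * k], x[2 * k + 1])[0, 1]
            assert abs(r) < 0.05

    def test_rho_half_within_block_correlation(self):
        data = mx.generate_multiomics(
            pathway_sizes=[2] * 10, samples_per_omics=(500,), rho=0.5, seed=2
        )
        x = data.layers[0].data.to_numpy()
        rs = [np.corrcoef(x[2 * k], x[2 * k + 1])[0, 1] for k in range(10)]
        assert np.mean(rs) == pytest.approx(0.5, abs=0.07)

    def test_seed_reproducible(self):
        a = mx.generate_multiomics(n_genes=60, samples_per_omics=(30, 20), seed=7)
        b = mx.generate_multiomics(n_genes=60, samples_per_omics=(30, 20), seed=7)
        for la, lb in zip(a.layers, b.layers):
            pd.testing.assert_frame_equal(la.data, lb.data)

    def test_matched_subjects_share_latent_factor(self):
        data = mx.generate_multiomics(
            pathway_sizes=[4] * 10, samples_per_omics=(400, 400), rho=0.8,
            overlap=1.0, seed=4,
        )
        a, b = (layer.data.to_numpy() for layer in data.layers)
        # same gene, same subjects, different layers: correlation ~ rho
        rs = [np.corrcoef(a[i], b[i])[0, 1] for i in range(0, 40, 4)]
        assert np.mean(rs) == pytest.approx(0.8, abs=0.07)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mx.generate_multiomics(
                n_genes=10, pathway_sizes=[3, 3], samples_per_omics=(20,)
            )


def ward_d_objective(partition, dmat):
    """ward.D merge cost for a 2-cluster partition of 4 points: total
    within-cluster Lance-Williams cost accumulated over merges. For tight
    pairs it is enough to compare total within-pair distances."""
    return sum(
        dmat[i, j] for cluster in partition for i, j in itertools.combinations(cluster, 2)
    )


class TestSyntheticPathways:
    def test_k1_single_cluster(self, rng):
        X = pd.DataFrame(rng.standard_normal((6, 4)))
        labels = mx.build_synthetic_pathways(X, 1)
        assert labels.nunique() == 1

    def test_two_tight_pairs(self):
        """Two well-separated pairs: the cut must recover the pairs, the
        unique 2-partition minimising within-cluster distance (checked
        against all 2-partitions of 4 points)."""
        pts = np.array(
            [[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]]
        )
        dmat = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        best = min(
            (
                ({0, i}, {0, 1, 2, 3} - {0, i})
                for i in (1, 2, 3)
            ),
            key=lambda part: ward_d_objective(part, dmat),
        )
        labels = mx.build_synthetic_pathways(pd.DataFrame(pts), 2)
        got = ({i for i in range(4) if labels.iloc[i] == labels.iloc[0]},)
        got = (got[0], {0, 1, 2, 3} - got[0])
        assert {frozenset(c) for c in got} == {frozenset(c) for c in best}

    def test_partition_contract(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 12)))
        labels = mx.build_synthetic_pathways(X, 50)
        assert labels.nunique() == 50
        assert len(labels) == 200

    def test_invalid_k_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((5, 3)))
        for k in (0, 6):
            with pytest.raises(ValueError):
                mx.build_synthetic_pathways(X, k)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_r_hclust_ward_d(self, rng, tmp_path):
        """Independent oracle: R's hclust(method='ward.D') on the same
        Euclidean distances yields the same 5-cluster partition."""
        X = rng.standard_normal((30, 8))
        xfile = tmp_path / "X.tsv"
        np.savetxt(xfile, X, delimiter="\t")
        script = (
            f'X <- as.matrix(read.table("{xfile}", sep="\t"));'
            'cat(cutree(hclust(dist(X), method="ward.D"), k=5))'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_labels = np.array(out.stdout.split(), dtype=int)
        ours = mx.build_synthetic_pathways(pd.DataFrame(X), 5).to_numpy()
        # partitions equal up to label renaming
        mapping = {}
        for a, b in zip(ours, r_labels):
            assert mapping.setdefault(a, b) == b


class TestInjectEffect:
    def _prepared(self, seed=3):
        data = mx.generate_multiomics(
            pathway_sizes=[10] * 6, samples_per_omics=(40, 40), seed=seed
        )
        rng = np.random.default_rng(seed)
        data.groups = assign_groups(data, rng)
        data.truth = {"BLOCK000", "BLOCK003"}
        return data, rng

    def test_mu_zero_identity(self):
        data, rng = self._prepared()
        out = mx.inject_effect(data, mx.BenchmarkScenario(mu=0.0, prop=0.4), rng)
        for before, after in zip(data.layers, out.layers):
            pd.testing.assert_frame_equal(before.data, after.data)

    def test_exact_gene_count_modified(self):
        data, rng = self._prepared()
        scenario = mx.BenchmarkScenario(mu=1.0, prop=0.2)
        out = mx.inject_effect(data, scenario, rng)
        for before, after in zip(data.layers, out.layers):
            changed = (before.data != after.data).any(axis=1)
            # 2 true pathways x round(0.2 * 10) = 2 genes each
            assert int(changed.sum()) == 4

    def test_group_mean_shift(self):
        data = mx.generate_multiomics(
            pathway_sizes=[10] * 4, samples_per_omics=(1000,), seed=8
        )
        rng = np.random.default_rng(8)
        data.groups = assign_groups(data, rng)
        data.truth = {"BLOCK001"}
        scenario = mx.BenchmarkScenario(mu=0.5, prop=1.0)
        out = mx.inject_effect(data, scenario, rng)
        layer = out.layers[0]
        a = layer.data.loc[:, data.groups.loc[layer.sample_ids] == "A"]
        b = layer.data.loc[:, data.groups.loc[layer.sample_ids] == "B"]
        diff = (a.mean(axis=1) - b.mean(axis=1)).loc[list(data.pathways["BLOCK001"])]
        assert diff.mean() == pytest.approx(0.5, abs=0.1)

    def test_rounding_half_away_from_zero(self):
        assert _round_half_away(0.5) == 1
        assert _round_half_away(2.5) == 3
        assert _round_half_away(2.4) == 2
        assert _round_half_away(0.0) == 0

    def test_requires_groups(self):
        data = mx.generate_multiomics(
            pathway_sizes=[5] * 4, samples_per_omics=(30,), seed=1
        )
        with pytest.raises(ValueError, match="group labels"):
            mx.inject_effect(data, mx.BenchmarkScenario(mu=0.2))


class TestRunBenchmark:
    def test_record_count_and_determinism(self):
        scenario = mx.BenchmarkScenario(
            mu=0.3, prop=0.4, n_pathways=10, n_true=2, n_reps=2,
            n_genes=60, samples_per_omics=(40, 40), seed=5,
        )
        a = mx.run_benchmark(scenario)
        b = mx.run_benchmark(scenario)
        assert len(a) == 2 * 10
        pd.testing.assert_frame_equal(a, b)
        assert a.groupby("replicate")["truth"].sum().eq(2).all()

    def test_effect_separates_truth(self):
        scenario = mx.BenchmarkScenario(
            mu=1.0, prop=1.0, n_pathways=10, n_true=2, n_reps=3,
            n_genes=60, samples_per_omics=(60, 60), seed=5,
        )
        summary = mx.summarize_benchmark(mx.run_benchmark(scenario))
        assert summary["mean_auc"] > 0.9


class TestMetrics:
    @pytest.mark.parametrize(
        "pvals, level, expected",
        [((0.01, 0.04, 0.06, 0.5), 0.05, 0.5)],
    )
    def test_type1_examples(self, pvals, level, expected):
        assert mx.type1_rate(pvals, level) == expected

    def test_type1_uniform_draws(self, rng):
        rate = mx.type1_rate(rng.random(5000), 0.05)
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_type1_empty_rejected(self):
        with pytest.raises(ValueError):
            mx.type1_rate([])

    @pytest.mark.parametrize(
        "scores, truth, expected",
        [
            ((0.01, 0.02, 0.5, 0.6), (1, 1, 0, 0), 1.0),
            ((0.01, 0.5, 0.02, 0.6), (1, 1, 0, 0), 0.75),
            ((0.3, 0.3), (1, 0), 0.5),
        ],
    )
    def test_auc_examples(self, scores, truth, expected):
        assert mx.roc_auc(scores, truth) == pytest.approx(expected)

    def test_auc_single_class_rejected(self):
        with pytest.raises(ValueError):
            mx.roc_auc((0.1, 0.2), (1, 1))

    def test_auc_matches_pair_counting(self, rng):
        """Exhaustive pair-counting oracle for all input sizes <= 8."""

        def oracle(scores, truth):
            pos = [s for s, t in zip(scores, truth) if t]
            neg = [s for s, t in zip(scores, truth) if not t]
            total = 0.0
            for p in pos:
                for q in neg:
                    total += 1.0 if p < q else (0.5 if p == q else 0.0)
            return total / (len(pos) * len(neg))

        for n in range(2, 9):
            for _ in range(20):
                truth = rng.integers(0, 2, n)
                if truth.min() == truth.max():
                    continue
                scores = rng.choice([0.1, 0.2, 0.3, 0.9], size=n)  # force ties
                assert mx.roc_auc(scores, truth) == pytest.approx(
                    oracle(scores, truth)
                )
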