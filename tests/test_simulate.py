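"""Synthetic-data generators: determinism, planted signal, permutation validity."""

import math

import numpy as np
import pytest
from scipy import stats

from ctpscreen import (
    CTPLibrary,
    ExpressionSimConfig,
    GeneSet,
    GroundTruth,
    LibrarySimConfig,
    SignaturePair,
    compute_deg,
    rank_library,
    recovery_rate,
    simulate_ctp_library,
    simulate_expression,
)
from ctpscreen.errors import (
    ConfigurationError,
    UndefinedMetricError,
    UniverseError,
)

from conftest import brute_force_es


class TestExpressionSimulation:
    def test_same_seed_bit_identical(self):
        cfg = ExpressionSimConfig(n_genes=200, seed=5)
        m1, t1 = simulate_expression(cfg)
        m2, t2 = simulate_expression(cfg)
        assert m1.values.equals(m2.values)
        assert t1 == t2

    def test_different_seed_differs(self):
        m1, _ = simulate_expression(ExpressionSimConfig(n_genes=200, seed=5))
        m2, _ = simulate_expression(ExpressionSimConfig(n_genes=200, seed=6))
        assert not m1.values.equals(m2.values)

    def test_zero_noise_planted_fold_change_exact(self):
        cfg = ExpressionSimConfig(
            n_genes=20, n_deg_up=1, n_deg_down=0, noise_sd=0.0, effect_fc=4.0, seed=1
        )
        expr, truth = simulate_expression(cfg)
        (gene,) = truth.deg_up_ids
        mean_a = expr.group_values("A")[expr.values.index.get_loc(gene)].mean()
        mean_b = expr.group_values("B")[expr.values.index.get_loc(gene)].mean()
        assert mean_b / mean_a == pytest.approx(4.0, rel=1e-12)

    def test_null_design_has_empty_truth(self):
        _, truth = simulate_expression(
            ExpressionSimConfig(n_genes=50, n_deg_up=0, n_deg_down=0, seed=2)
        )
        assert truth.deg_up_ids == () and truth.deg_down_ids == ()

    def test_shape_and_labels(self):
        cfg = ExpressionSimConfig(
            n_genes=30, n_deg_up=5, n_deg_down=5, n_per_group=4, seed=0
        )
        expr, _ = simulate_expression(cfg)
        assert expr.values.shape == (30, 8)
        assert sorted(expr.condition.unique()) == ["A", "B"]
        assert expr.reference == "A"

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(n_deg_up=60, n_deg_down=60, n_genes=100), "exceeds n_genes"),
            (dict(n_per_group=1), "n_per_group"),
            (dict(effect_fc=1.0), "effect_fc"),
            (dict(noise_sd=-0.1), "noise_sd"),
        ],
    )
    def test_invalid_config_names_bound(self, kwargs, msg):
        with pytest.raises(ConfigurationError, match=msg):
            ExpressionSimConfig(**kwargs)

    def test_deg_calls_match_oracle_gene_for_gene(self, planted_expression):
        """Pipeline DEG calls equal a direct per-gene pooled-t + fold-change
        re-implementation over all genes, and recover most planted genes."""
        _, expr, truth = planted_expression
        deg = compute_deg(expr)
        a = expr.group_values("A")
        b = expr.group_values("B")
        for i, gene in enumerate(expr.values.index):
            tstat, p = stats.ttest_ind(b[i], a[i], equal_var=True)
            fc = b[i].mean() / a[i].mean()
            expected = (
                "up" if (fc > 2 and p < 0.05)
                else "down" if (fc < 0.5 and p < 0.05)
                else "none"
            )
            assert deg.loc[gene, "direction"] == expected, gene
            assert deg.loc[gene, "p_value"] == pytest.approx(p, rel=1e-10)
        called_up = set(deg.index[deg["direction"] == "up"])
        sensitivity = len(called_up & set(truth.deg_up_ids)) / len(truth.deg_up_ids)
        assert sensitivity > 0.8


class TestLibrarySimulation:
    def test_every_column_is_a_permutation(self, small_signature):
        cfg = LibrarySimConfig(
            n_genes=30, n_compounds=12, n_reversers=2, n_mimickers=2,
            strength=0.7, seed=3,
        )
        library, _ = simulate_ctp_library(cfg, small_signature)
        arr = library.ranks.to_numpy()
        for j in range(arr.shape[1]):
            assert sorted(arr[:, j]) == list(range(1, 31))

    def test_same_seed_bit_identical(self, small_signature):
        cfg = LibrarySimConfig(n_genes=50, n_compounds=10, n_reversers=2, seed=8)
        l1, t1 = simulate_ctp_library(cfg, small_signature)
        l2, t2 = simulate_ctp_library(cfg, small_signature)
        assert l1.ranks.equals(l2.ranks)
        assert t1 == t2

    def test_strength_one_forces_extreme_ranks(self):
        up = GeneSet("up", tuple(f"g{i:06d}" for i in range(1, 11)))
        down = GeneSet("down", tuple(f"g{i:06d}" for i in range(11, 16)))
        sig = SignaturePair(up=up, down=down)
        cfg = LibrarySimConfig(
            n_genes=100, n_compounds=3, n_reversers=1, strength=1.0, seed=4
        )
        library, truth = simulate_ctp_library(cfg, sig)
        (rev,) = truth.reverser_ids
        col = library.ranks[rev]
        assert sorted(col.loc[list(up.members)]) == list(range(1, 11))
        assert sorted(col.loc[list(down.members)]) == list(range(96, 101))

    def test_mimicker_is_mirror_image(self):
        up = GeneSet("up", tuple(f"g{i:06d}" for i in range(1, 11)))
        down = GeneSet("down", tuple(f"g{i:06d}" for i in range(11, 21)))
        sig = SignaturePair(up=up, down=down)
        cfg = LibrarySimConfig(
            n_genes=100, n_compounds=3, n_mimickers=1, strength=1.0, seed=4
        )
        library, truth = simulate_ctp_library(cfg, sig)
        (mim,) = truth.mimicker_ids
        col = library.ranks[mim]
        assert sorted(col.loc[list(down.members)]) == list(range(1, 11))
        assert sorted(col.loc[list(up.members)]) == list(range(91, 101))

    def test_strength_zero_still_labels_nominal_reversers(self, small_signature):
        cfg = LibrarySimConfig(
            n_genes=40, n_compounds=8, n_reversers=3, strength=0.0, seed=1
        )
        library, truth = simulate_ctp_library(cfg, small_signature)
        assert len(truth.reverser_ids) == 3
        assert set(truth.reverser_ids) <= set(library.compound_ids)

    def test_signature_gene_missing_from_universe_is_listed(self):
        sig = SignaturePair(
            up=GeneSet("up", ("g000001", "not-a-gene")),
            down=GeneSet("down", ("g000002",)),
        )
        with pytest.raises(UniverseError, match="not-a-gene"):
            simulate_ctp_library(LibrarySimConfig(n_genes=10, n_compounds=2), sig)

    def test_planted_reversers_beat_all_nulls(self, planted_library):
        """Every planted reverser's up-set ES, recomputed with the
        brute-force scan oracle, exceeds the best null compound's."""
        cfg, sig, library, truth = planted_library
        up_idx = [library.ranks.index.get_loc(g) for g in sig.up.members]
        arr = library.ranks.to_numpy()
        es_by_compound = {}
        for j, comp in enumerate(library.compound_ids):
            _, _, es = brute_force_es(arr[up_idx, j], cfg.n_genes)
            es_by_compound[comp] = es
        null_max = max(
            es for c, es in es_by_compound.items() if c not in truth.reverser_ids
        )
        for rev in truth.reverser_ids:
            assert es_by_compound[rev] > null_max

    def test_strength_monotonicity_of_mean_reverser_es(self):
        """Mean up-set ES of planted reversers is non-decreasing in strength,
        averaged over 50 seeds on a small universe."""
        up = GeneSet("up", tuple(f"g{i:06d}" for i in range(1, 11)))
        down = GeneSet("down", tuple(f"g{i:06d}" for i in range(11, 21)))
        sig = SignaturePair(up=up, down=down)
        means = []
        for strength in (0.0, 0.25, 0.5, 0.75, 1.0):
            vals = []
            for seed in range(50):
                cfg = LibrarySimConfig(
                    n_genes=100, n_compounds=5, n_reversers=2,
                    strength=strength, seed=seed,
                )
                library, truth = simulate_ctp_library(cfg, sig)
                up_idx = [library.ranks.index.get_loc(g) for g in up.members]
                for rev in truth.reverser_ids:
                    ranks = library.ranks[rev].to_numpy()[up_idx]
                    _, _, es = brute_force_es(ranks, 100)
                    vals.append(es)
            means.append(np.mean(vals))
        assert all(m2 >= m1 - 1e-9 for m1, m2 in zip(means, means[1:])), means

    def test_null_calibration_at_strength_zero(self, small_signature):
        """With strength 0 the bone scores of nominal 'reversers' and nulls
        come from the same distribution (Mann-Whitney, alpha = 0.01)."""
        rev_scores, null_scores = [], []
        for seed in range(30):
            cfg = LibrarySimConfig(
                n_genes=120, n_compounds=10, n_reversers=3,
                strength=0.0, seed=seed,
            )
            library, truth = simulate_ctp_library(cfg, small_signature)
            report = rank_library(small_signature, library, mode="signed", k=1)
            for s in report.scores:
                (rev_scores if s.compound_id in truth.reverser_ids
                 else null_scores).append(s.bone_score)
        _, p = stats.mannwhitneyu(rev_scores, null_scores)
        assert p > 0.01


class TestRecoveryRate:
    def test_perfect_recovery(self):
        truth = GroundTruth(reverser_ids=("c1", "c2"))
        assert recovery_rate(["c1", "c2", "c3"], truth, k=2) == 1.0

    def test_zero_recovery(self):
        truth = GroundTruth(reverser_ids=("c9",))
        assert recovery_rate(["c1", "c2", "c9"], truth, k=2) == 0.0

    def test_partial_recovery(self):
        truth = GroundTruth(reverser_ids=tuple(f"r{i}" for i in range(5)))
        ranking = ["r0", "r1", "r2"] + [f"x{i}" for i in range(7)] + ["r3", "r4"]
        assert recovery_rate(ranking, truth, k=10) == pytest.approx(0.6)

    def test_no_reversers_is_an_error(self):
        with pytest.raises(UndefinedMetricError):
            recovery_rate(["c1"], GroundTruth(), k=1)

    def test_k_beyond_ranking_rejected(self):
        truth = GroundTruth(reverser_ids=("c1",))
        with pytest.raises(ConfigurationError):
            recovery_rate(["c1"], truth, k=2)
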