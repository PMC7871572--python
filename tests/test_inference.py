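import math

import numpy as np
import pytest

from comhub.errors import ValidationError
from comhub.inference import (
    InferenceConfig,
    aracne,
    clr,
    clr_from_mi,
    elasticnet_bootstrap,
    genie3,
    mutual_information_matrix,
    pcc_network,
    run_engine,
    tigress,
)
from comhub.io import ExpressionMatrix, RegulatorSet

from _utils import (
    brute_equal_frequency_levels,
    brute_pearson,
    brute_plugin_mi,
    random_expression,
)


def expr_of(values, n_regs):
    values = np.asarray(values, dtype=float)
    gene_ids = tuple(f"g{i}" for i in range(values.shape[0]))
    expr = ExpressionMatrix(
        gene_ids, tuple(f"s{j}" for j in range(values.shape[1])), values
    )
    return expr, RegulatorSet.from_iterable(gene_ids[:n_regs])


def conf_map(edges):
    return {(r, t): c for r, t, c in edges.edges}


class TestPcc:
    def test_identical_profiles_share_top_rank_with_confidence_one(self, rng):
        base = rng.standard_normal(30)
        values = np.vstack([base, rng.standard_normal(30), base])
        expr, regs = expr_of(values, 1)
        edges = pcc_network(expr, regs)
        assert conf_map(edges)[("g0", "g2")] == pytest.approx(1.0, abs=1e-12)
        assert edges.edges[0][:2] == ("g0", "g2")

    def test_constant_regulator_scores_zero(self, rng):
        values = np.vstack([np.full(20, 3.0), rng.standard_normal((3, 20))])
        expr, regs = expr_of(values, 2)
        edges = pcc_network(expr, regs)
        cm = conf_map(edges)
        assert all(cm[("g0", t)] == 0.0 for t in ("g1", "g2", "g3"))

    def test_matches_sum_of_products_oracle(self, rng):
        expr, regs = random_expression(rng, 6, 30, 3)
        cm = conf_map(pcc_network(expr, regs))
        for (r, t), conf in cm.items():
            expected = abs(
                brute_pearson(list(expr.profile(r)), list(expr.profile(t)))
            )
            assert conf == pytest.approx(expected, abs=1e-12)


class TestMutualInformation:
    def test_independent_profiles_have_small_mi(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(size=(2, 1000))
        expr, regs = expr_of(values, 1)
        mi, _, _ = mutual_information_matrix(expr, regs, mi_bins=10)
        assert 0.0 <= mi[0, 1] < 0.1

    def test_identity_profile_gives_binned_entropy(self):
        x = np.arange(100, dtype=float)
        expr, regs = expr_of(np.vstack([x, x * 2.0 + 1.0]), 1)
        mi, _, _ = mutual_information_matrix(expr, regs, mi_bins=10)
        # equal-frequency bins with n divisible by bins: MI(x, y) = H = ln(10)
        assert mi[0, 1] == pytest.approx(math.log(10), abs=1e-12)
        assert mi[0, 0] == pytest.approx(math.log(10), abs=1e-12)

    def test_matches_hand_computed_plugin_estimator(self, rng):
        expr, regs = random_expression(rng, 3, 12, 2)
        bins = 4
        mi, reg_ids, gene_ids = mutual_information_matrix(expr, regs, mi_bins=bins)
        for i, r in enumerate(reg_ids):
            for j, g in enumerate(gene_ids):
                lx = brute_equal_frequency_levels(list(expr.profile(r)), bins)
                ly = brute_equal_frequency_levels(list(expr.profile(g)), bins)
                assert mi[i, j] == pytest.approx(
                    brute_plugin_mi(lx, ly, bins), abs=1e-12
                )

    def test_symmetric_on_regulator_block_and_nonnegative(self, rng):
        expr, regs = random_expression(rng, 5, 40, 3)
        mi, reg_ids, gene_ids = mutual_information_matrix(expr, regs, mi_bins=5)
        assert (mi >= -1e-15).all()
        block = mi[:, : len(reg_ids)]
        np.testing.assert_allclose(block, block.T, atol=1e-12)

    def test_fewer_samples_than_bins_rejected(self, rng):
        expr, regs = random_expression(rng, 3, 5, 1)
        with pytest.raises(ValidationError, match="samples"):
            mutual_information_matrix(expr, regs, mi_bins=10)


class TestClr:
    def test_flat_mi_gives_zero_confidences(self):
        mi = np.full((2, 4), 0.3)
        edges = clr_from_mi(mi, ["g0", "g1"], ["g0", "g1", "g2", "g3"])
        assert all(c == 0.0 for _, _, c in edges.edges)

    def test_single_elevated_entry_is_top_edge(self):
        mi = np.full((3, 6), 0.2)
        mi[1, 4] = 2.0
        edges = clr_from_mi(
            mi, ["g0", "g1", "g2"], [f"g{i}" for i in range(6)]
        )
        assert edges.edges[0][:2] == ("g1", "g4")
        assert edges.edges[0][2] > edges.edges[1][2]

    def test_matches_background_z_formula(self, rng):
        expr, regs = random_expression(rng, 5, 40, 3)
        mi, reg_ids, gene_ids = mutual_information_matrix(expr, regs, mi_bins=5)
        cm = conf_map(clr(expr, regs, mi_bins=5))
        for i, r in enumerate(reg_ids):
            for j, g in enumerate(gene_ids):
                if r == g:
                    continue
                row = mi[i, :]
                col = mi[:, j]
                zi = max(0.0, (mi[i, j] - row.mean()) / row.std()) if row.std() else 0.0
                zj = max(0.0, (mi[i, j] - col.mean()) / col.std()) if col.std() else 0.0
                assert cm[(r, g)] == pytest.approx(
                    math.sqrt(zi**2 + zj**2), abs=1e-12
                )


class TestAracne:
    def test_chain_indirect_edge_removed(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(300)
        y = x + 0.3 * rng.standard_normal(300)
        z = y + 0.3 * rng.standard_normal(300)
        expr, regs = expr_of(np.vstack([x, y, z]), 2)
        pairs = {(r, t) for r, t, _ in aracne(expr, regs, mi_bins=5).edges}
        assert ("g0", "g2") not in pairs  # x -> z is the weakest in its triangle
        assert ("g0", "g1") in pairs and ("g1", "g2") in pairs

    def test_full_tolerance_disables_pruning(self, rng):
        expr, regs = random_expression(rng, 6, 40, 3)
        pruned = aracne(expr, regs, mi_bins=5, dpi_tolerance=1.0)
        mi, reg_ids, gene_ids = mutual_information_matrix(expr, regs, mi_bins=5)
        expected = {
            (r, g): mi[i, j]
            for i, r in enumerate(reg_ids)
            for j, g in enumerate(gene_ids)
            if r != g
        }
        cm = conf_map(pruned)
        assert set(cm) == set(expected)
        for key, value in expected.items():
            assert cm[key] == pytest.approx(value, abs=1e-12)

    def test_matches_exhaustive_triangle_oracle(self, rng):
        expr, regs = random_expression(rng, 8, 50, 4)
        mi, reg_ids, gene_ids = mutual_information_matrix(expr, regs, mi_bins=5)
        pos_r = {r: i for i, r in enumerate(reg_ids)}
        pos_g = {g: j for j, g in enumerate(gene_ids)}

        def pair_mi(a, b):
            if a in pos_r:
                return mi[pos_r[a], pos_g[b]]
            return mi[pos_r[b], pos_g[a]]

        # brute force: every unordered triple with >= 2 regulators
        import itertools

        nodes = list(gene_ids)
        removed = set()
        for trio in itertools.combinations(nodes, 3):
            n_regs_in = sum(1 for n in trio if n in pos_r)
            if n_regs_in < 2:
                continue
            es = [tuple(sorted(p)) for p in itertools.combinations(trio, 2)]
            vals = sorted((pair_mi(*e), e) for e in es)
            if vals[0][0] < min(vals[1][0], vals[2][0]):
                removed.add(vals[0][1])
        surviving_pairs = {
            tuple(sorted((r, t))) for r, t, _ in aracne(expr, regs, mi_bins=5).edges
        }
        expected = {
            tuple(sorted((r, g)))
            for r in reg_ids
            for g in gene_ids
            if r != g
        } - removed
        assert surviving_pairs == expected


class TestGenie3:
    def test_true_regulator_ranks_first_for_its_target(self, rng):
        base = rng.standard_normal(60)
        decoys = rng.standard_normal((5, 60))
        target = base.copy()
        expr, regs = expr_of(np.vstack([base, decoys, target]), 6)
        edges = genie3(expr, regs, n_trees=50, random_seed=1)
        target_edges = [e for e in edges.edges if e[1] == "g6"]
        assert target_edges[0][0] == "g0"

    def test_importances_sum_to_one_or_zero_per_target(self, rng):
        expr, regs = random_expression(rng, 6, 30, 3)
        values = expr.values.copy()
        values[5] = 2.5  # constant target
        expr2 = ExpressionMatrix(expr.gene_ids, expr.sample_ids, values)
        edges = genie3(expr2, regs, n_trees=30, random_seed=0)
        per_target = {}
        for r, t, c in edges.edges:
            per_target.setdefault(t, 0.0)
            per_target[t] += c
        for t, total in per_target.items():
            assert total == pytest.approx(1.0, abs=1e-9) or total == 0.0
        assert per_target["g5"] == 0.0

    def test_noise_target_has_no_dominant_regulator(self, rng):
        expr, regs = random_expression(rng, 6, 80, 5)
        edges = genie3(expr, regs, n_trees=100, random_seed=2)
        noise_edges = [c for r, t, c in edges.edges if t == "g5"]
        assert max(noise_edges) < 0.5


class TestElasticNet:
    def test_confidences_are_frequencies(self, rng):
        expr, regs = random_expression(rng, 5, 30, 3)
        edges = elasticnet_bootstrap(expr, regs, n_bootstrap=10, random_seed=0)
        assert all(0.0 <= c <= 1.0 for _, _, c in edges.edges)

    def test_noiseless_proportional_target_always_selected(self, rng):
        reg = rng.standard_normal(40)
        decoys = rng.standard_normal((2, 40))
        target = 2.0 * reg
        expr, regs = expr_of(np.vstack([reg, decoys, target]), 3)
        edges = elasticnet_bootstrap(expr, regs, n_bootstrap=25, random_seed=3)
        assert conf_map(edges)[("g0", "g3")] == 1.0

    def test_single_bootstrap_gives_binary_confidences(self, rng):
        expr, regs = random_expression(rng, 4, 25, 2)
        edges = elasticnet_bootstrap(expr, regs, n_bootstrap=1, random_seed=0)
        assert set(c for _, _, c in edges.edges) <= {0.0, 1.0}


class TestTigress:
    def test_area_scores_bounded(self, rng):
        expr, regs = random_expression(rng, 8, 30, 6)
        edges = tigress(expr, regs, n_resample=10, lars_steps=3, random_seed=0)
        assert all(0.0 <= c <= 1.0 for _, _, c in edges.edges)

    def test_dominant_regulator_scores_highest_for_its_target(self, rng):
        reg = rng.standard_normal(50)
        others = rng.standard_normal((4, 50))
        target = reg + 0.05 * rng.standard_normal(50)
        expr, regs = expr_of(np.vstack([reg, others, target]), 5)
        edges = tigress(expr, regs, n_resample=20, lars_steps=2, random_seed=1)
        target_edges = sorted(
            (e for e in edges.edges if e[1] == "g5"), key=lambda e: -e[2]
        )
        assert target_edges[0][0] == "g0"

    def test_hand_traceable_single_step_path(self, rng):
        r1 = rng.standard_normal(24)
        r2 = rng.standard_normal(24)
        target = r1.copy()
        expr, regs = expr_of(np.vstack([r1, r2, target]), 2)
        edges = tigress(expr, regs, n_resample=2, lars_steps=1, random_seed=0)
        cm = conf_map(edges)
        # positive weights never change |correlation|; r1 enters at step 1
        # in both resamples, r2 never does
        assert cm[("g0", "g2")] == 1.0
        assert cm[("g1", "g2")] == 0.0

    def test_rejects_odd_resample_counts_and_too_many_steps(self, rng):
        expr, regs = random_expression(rng, 5, 30, 3)
        with pytest.raises(ValidationError, match="even"):
            tigress(expr, regs, n_resample=3, lars_steps=1)
        with pytest.raises(ValidationError, match="lars_steps"):
            tigress(expr, regs, n_resample=4, lars_steps=3)


@pytest.mark.parametrize(
    "name,cfg",
    [
        ("pcc", InferenceConfig()),
        ("clr", InferenceConfig(mi_bins=5)),
        ("aracne", InferenceConfig(mi_bins=5)),
        ("genie3", InferenceConfig(n_trees=20)),
        ("elasticnet", InferenceConfig(n_bootstrap=5)),
        ("tigress", InferenceConfig(n_resample=4, lars_steps=2)),
    ],
)
def test_engine_contract_and_determinism(name, cfg, rng):
    """Every engine emits a valid ranked list (sorted, deduplicated,
    regulators only as sources) and is bitwise reproducible under a seed."""
    expr, regs = random_expression(rng, 7, 30, 4)
    first = run_engine(name, expr, regs, cfg)
    second = run_engine(name, expr, regs, cfg)
    assert first.edges == second.edges
    assert set(e[0] for e in first.edges) <= regs.ids
    confs = [c for _, _, c in first.edges]
    assert confs == sorted(confs, reverse=True)
    assert len({(r, t) for r, t, _ in first.edges}) == len(first.edges)
    assert all(r != t for r, t, _ in first.edges)


def test_engines_require_known_regulators(rng):
    expr, _ = random_expression(rng, 4, 20, 2)
    foreign = RegulatorSet.from_iterable(["nope"])
    with pytest.raises(ValidationError, match="nope"):
        pcc_network(expr, foreign)


def test_config_validation():
    with pytest.raises(ValidationError):
        InferenceConfig(mi_bins=1)
    with pytest.raises(ValidationError):
        InferenceConfig(dpi_tolerance=1.5)
    with pytest.raises(ValidationError):
        InferenceConfig(l1_ratio=0.0)
    with pytest.raises(ValidationError):
        InferenceConfig(tree_feature_fraction="half")
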