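"""Colocation-quotient statistics: hand-computed cases, brute-force
equivalence, neutrality, permutation-test mechanics and the immune
phenotype classifier."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_local_clq
from spexkit.synthetic_data import PatternSpec, gen_labeled_pattern
from spexkit.spatial_stats import (
    build_neighbor_graph,
    classify_immune_phenotype,
    clq_significance,
    cooccurrence_permutation,
    global_clq,
    local_clq,
)
from spexkit.types import ValidationError, make_cell_table


def _table(coords, types):
    return make_cell_table(
        X=np.zeros((len(types), 0)),
        coords=np.asarray(coords, dtype=float),
        feature_names=[],
        cell_type=pd.Categorical(types),
    )


class TestNeighborGraph:
    def test_collinear_cells_radius_cut(self):
        # cells at x = 0, 1, 3: only the 0-1 pair is within radius 1.5
        t = _table([[0, 0], [1, 0], [3, 0]], ["A", "A", "A"])
        g = build_neighbor_graph(t, 1.5)
        got = {tuple(p) for p in g.pairs}
        assert got == {(0, 1), (1, 0)}
        assert np.allclose(g.distances, 1.0)

    def test_radius_beyond_field_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        n = 15
        t = _table(rng.uniform(0, 10, (n, 2)), ["A"] * n)
        g = build_neighbor_graph(t, 1000.0)
        assert g.n_pairs == n * (n - 1)

    def test_graph_is_symmetric_and_distances_exact(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 50, (30, 2))
        t = _table(coords, ["A"] * 30)
        g = build_neighbor_graph(t, 20.0)
        pairs = {tuple(p) for p in g.pairs}
        assert all((j, i) in pairs for i, j in pairs)
        assert not any(i == j for i, j in pairs)
        recomputed = np.linalg.norm(
            coords[g.pairs[:, 0]] - coords[g.pairs[:, 1]], axis=1
        )
        np.testing.assert_allclose(g.distances, recomputed, rtol=1e-9)

    def test_gaussian_kernel_monotone_decreasing(self):
        t = _table([[0, 0], [1, 0], [2, 0], [3, 0]], ["A"] * 4)
        g = build_neighbor_graph(t, 10.0, kernel="gaussian", sigma_um=2.0)
        order = np.argsort(g.distances)
        w = g.weights[order]
        assert np.all(np.diff(w) <= 1e-12)
        assert w[0] < 1.0 and w[0] > np.exp(-0.5 * (g.distances.min() / 2.0) ** 2) - 1e-9

    def test_pairs_never_cross_images(self):
        t = make_cell_table(
            X=np.zeros((4, 0)),
            coords=np.array([[0, 0], [1, 0], [0, 0], [1, 0]], dtype=float),
            feature_names=[],
            image_id=np.array(["im1", "im1", "im2", "im2"]),
            cell_type=pd.Categorical(["A", "B", "A", "B"]),
        )
        g = build_neighbor_graph(t, 5.0)
        assert {tuple(p) for p in g.pairs} == {(0, 1), (1, 0), (2, 3), (3, 2)}

    def test_nonpositive_radius_rejected(self):
        t = _table([[0, 0]], ["A"])
        with pytest.raises(ValidationError):
            build_neighbor_graph(t, 0.0)


class TestLocalGlobalCLQ:
    def test_six_cell_hand_computation(self, six_cell_table):
        g = build_neighbor_graph(six_cell_table, 1.5)
        lclq = local_clq(g, six_cell_table, "A", "B")
        # A(0,0): both neighbors are B -> 1 / (3/5) = 5/3; A(5,5) isolated;
        # A(10,0): single neighbor is B -> 5/3
        np.testing.assert_allclose(lclq[0], 5 / 3)
        assert np.isnan(lclq[1])
        np.testing.assert_allclose(lclq[2], 5 / 3)
        assert np.all(np.isnan(lclq[3:]))  # B cells carry no A->B value
        np.testing.assert_allclose(global_clq(g, six_cell_table, "A", "B"), 5 / 3)

    def test_complete_graph_distinct_types_is_exactly_one(self):
        rng = np.random.default_rng(7)
        t = _table(rng.uniform(0, 10, (20, 2)), ["A"] * 10 + ["B"] * 10)
        g = build_neighbor_graph(t, 1e4)
        assert global_clq(g, t, "A", "B") == 1.0

    def test_self_pair_complete_graph_is_one_with_correction(self):
        # (N_A - 1)/(N - 1) expected proportion keeps the neutral value at 1
        rng = np.random.default_rng(8)
        t = _table(rng.uniform(0, 10, (20, 2)), ["A"] * 12 + ["B"] * 8)
        g = build_neighbor_graph(t, 1e4)
        np.testing.assert_allclose(global_clq(g, t, "A", "A"), 1.0, rtol=1e-12)

    def test_single_cell_self_pair_rejected(self):
        t = _table([[0, 0], [1, 0], [2, 0]], ["A", "A", "B"])
        g = build_neighbor_graph(t, 10.0)
        with pytest.raises(ValidationError):
            local_clq(g, t, "B", "B")

    @pytest.mark.parametrize("kernel,sigma", [("uniform", None), ("gaussian", 5.0)])
    def test_matches_brute_force_double_loop(self, kernel, sigma):
        rng = np.random.default_rng(42)
        n = 50
        coords = rng.uniform(0, 60, (n, 2))
        types = rng.choice(["A", "B", "C"], size=n).tolist()
        t = _table(coords, types)
        g = build_neighbor_graph(t, 15.0, kernel=kernel, sigma_um=sigma)
        for a in "ABC":
            for b in "ABC":
                got = local_clq(g, t, a, b)
                want = brute_force_local_clq(
                    coords, types, a, b, 15.0, kernel, sigma
                )
                np.testing.assert_allclose(got, want, rtol=1e-9, equal_nan=True)

    def test_moving_b_into_neighborhood_never_decreases_lclq(self):
        # uniform kernel: adding a B neighbor raises the neighborhood proportion
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 100, (30, 2))
        types = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        t = _table(coords, types)
        g = build_neighbor_graph(t, 20.0)
        base = local_clq(g, t, "A", "B")[0]
        moved = coords.copy()
        moved[15] = coords[0] + [1.0, 0.0]  # drop a B next to A cell 0
        t2 = _table(moved, types)
        g2 = build_neighbor_graph(t2, 20.0)
        new = local_clq(g2, t2, "A", "B")[0]
        assert np.isnan(base) or new >= base - 1e-12

    def test_csr_global_clq_near_one(self):
        # Monte-Carlo null: mean over seeds within 1 +/- 0.05
        vals = []
        for seed in range(50):
            t = gen_labeled_pattern(
                PatternSpec("csr", {"A": 200, "B": 200}, (500, 500), seed=seed)
            )
            g = build_neighbor_graph(t, 15.0)
            vals.append(global_clq(g, t, "A", "B"))
        assert abs(np.mean(vals) - 1.0) < 0.05


class TestCLQSignificance:
    def test_global_equals_mean_of_local(self):
        rng = np.random.default_rng(5)
        t = _table(rng.uniform(0, 80, (40, 2)), ["A"] * 20 + ["B"] * 20)
        g = build_neighbor_graph(t, 25.0)
        res = clq_significance(g, t, pairs=[("A", "B")], n_perm=19, seed=0)
        lclq = res.local_clq[("A", "B")]
        defined = lclq[~np.isnan(lclq)]
        np.testing.assert_allclose(
            res.global_clq.loc["A", "B"], defined.mean(), rtol=1e-9
        )

    def test_pvalues_on_permutation_grid(self):
        rng = np.random.default_rng(6)
        t = _table(rng.uniform(0, 80, (50, 2)), ["A"] * 25 + ["B"] * 25)
        g = build_neighbor_graph(t, 25.0)
        n_perm = 37
        res = clq_significance(g, t, pairs=[("A", "B")], n_perm=n_perm, seed=0)
        for p in (res.p_attractive.loc["A", "B"], res.p_avoidant.loc["A", "B"]):
            k = p * (n_perm + 1)
            assert abs(k - round(k)) < 1e-9
            assert 1 <= round(k) <= n_perm + 1

    def test_attraction_pattern_detected(self):
        t = gen_labeled_pattern(
            PatternSpec(
                "attraction", {"A": 60, "B": 60}, (400, 400),
                interaction_radius_um=20, strength=8, seed=11,
            )
        )
        g = build_neighbor_graph(t, 25.0)
        res = clq_significance(g, t, pairs=[("A", "B")], n_perm=99, seed=0)
        assert res.call.loc["A", "B"] == "attractive"
        assert res.p_attractive.loc["A", "B"] == 1 / 100

    def test_degenerate_permutation_invariant_pattern(self):
        # all non-A cells are B and every neighborhood is complete: permuting
        # labels cannot change the statistic, so both p-values are 1
        rng = np.random.default_rng(9)
        t = _table(rng.uniform(0, 5, (12, 2)), ["A"] * 6 + ["B"] * 6)
        g = build_neighbor_graph(t, 1e3)
        res = clq_significance(g, t, pairs=[("A", "B")], n_perm=49, seed=0)
        assert res.p_attractive.loc["A", "B"] == 1.0
        assert res.p_avoidant.loc["A", "B"] == 1.0
        assert res.call.loc["A", "B"] == "ns"

    def test_determinism(self):
        t = gen_labeled_pattern(
            PatternSpec("csr", {"A": 40, "B": 40}, (200, 200), seed=2)
        )
        g = build_neighbor_graph(t, 30.0)
        r1 = clq_significance(g, t, n_perm=29, seed=123)
        r2 = clq_significance(g, t, n_perm=29, seed=123)
        pd.testing.assert_frame_equal(r1.p_attractive, r2.p_attractive)
        pd.testing.assert_frame_equal(r1.global_clq, r2.global_clq)

    def test_invalid_n_perm_rejected(self, six_cell_table):
        g = build_neighbor_graph(six_cell_table, 1.5)
        with pytest.raises(ValidationError):
            clq_significance(g, six_cell_table, n_perm=0)


class TestCooccurrence:
    def test_blocks_pattern_zero_interactions_minimal_avoidant_p(self):
        t = gen_labeled_pattern(
            PatternSpec(
                "blocks", {"A": 60, "B": 60}, (400, 400),
                interaction_radius_um=60, seed=4,
            )
        )
        df = cooccurrence_permutation(t, radius_um=20.0, n_perm=99, seed=0)
        row = df[(df.type_a == "A") & (df.type_b == "B")].iloc[0]
        assert row.mean_neighbors == 0.0
        assert row.p_avoidant == 1 / 100

    def test_attraction_power_over_seeds(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            t = gen_labeled_pattern(
                PatternSpec(
                    "attraction", {"A": 50, "B": 50}, (400, 400),
                    interaction_radius_um=15, strength=5, seed=seed,
                )
            )
            df = cooccurrence_permutation(t, radius_um=20.0, n_perm=99, seed=seed)
            row = df[(df.type_a == "A") & (df.type_b == "B")].iloc[0]
            hits += row.p_attractive <= 0.05
        assert hits >= 0.9 * n_seeds

    def test_tiny_radius_all_statistics_zero(self):
        t = gen_labeled_pattern(
            PatternSpec("csr", {"A": 20, "B": 20}, (500, 500), seed=1)
        )
        df = cooccurrence_permutation(t, radius_um=1e-6, n_perm=9, seed=0)
        assert (df.mean_neighbors == 0).all()


class TestImmunePhenotype:
    @staticmethod
    def _samples(seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(6):  # inflamed: high CLQ both ways
            rows.append(("inf%d" % i, 0.4, 2.0, 2.0))
        for i in range(6):  # excluded: low CLQ
            rows.append(("exc%d" % i, 0.3, 0.2, 0.2))
        for i in range(3):  # desert by immune fraction
            rows.append(("des%d" % i, 0.05, 2.0, 2.0))
        df = pd.DataFrame(
            rows, columns=["sample", "immune_fraction",
                           "clq_immune_tumor", "clq_tumor_immune"]
        ).set_index("sample")
        noisy = df.copy()
        noisy[["clq_immune_tumor", "clq_tumor_immune"]] *= np.exp(
            rng.normal(0, 0.05, size=(len(df), 2))
        )
        return noisy

    def test_desert_gate_precedes_mixture(self):
        res = classify_immune_phenotype(self._samples(), desert_threshold=0.10)
        # 5% immune fraction -> desert regardless of CLQ
        assert (res.table.loc[res.table.index.str.startswith("des"),
                              "phenotype"] == "desert").all()

    def test_well_separated_mixture_recovered(self):
        res = classify_immune_phenotype(self._samples(), seed=0)
        tab = res.table
        assert (tab.loc[tab.index.str.startswith("inf"), "phenotype"]
                == "inflamed").all()
        assert (tab.loc[tab.index.str.startswith("exc"), "phenotype"]
                == "excluded").all()

    def test_too_few_nondesert_samples_rejected(self):
        df = self._samples().iloc[[0, 1, 2, -1]]  # 3 non-desert + 1 desert
        with pytest.raises(ValidationError):
            classify_immune_phenotype(df)

    def test_identical_nondesert_samples_rejected(self):
        df = self._samples()
        df[["clq_immune_tumor", "clq_tumor_immune"]] = 1.0
        with pytest.raises(ValidationError):
            classify_immune_phenotype(df)
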