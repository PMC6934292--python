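import numpy as np
import pandas as pd
import pytest

import spathet as sp
from spathet.states import MolecularStateAssignment

from conftest import make_table, pool_tables


def circle_table(xs, areas=None, state_marker=None, sample_id="s1"):
    """Cells on a line (y=0) with given x positions and areas."""
    n = len(xs)
    areas = areas if areas is not None else [np.pi] * n  # radius 1
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "sample_id": sample_id,
            "x": xs,
            "y": 0.0,
            "area": areas,
            "quality_score": 1.0,
            "M": state_marker if state_marker is not None else 1.0,
        }
    )
    return sp.CellTable(df=df, markers=("M",))


def assignment_from_codes(codes, n_markers=3, cell_ids=None):
    codes = np.asarray(codes)
    n = len(codes)
    return MolecularStateAssignment(
        hallmark="h",
        markers=tuple("m" * 1 for _ in range(n_markers)),
        cell_ids=cell_ids if cell_ids is not None else np.array([f"c{i}" for i in range(n)]),
        sample_ids=np.array(["s1"] * n),
        levels=np.zeros((n, n_markers), dtype=int),
        codes=codes,
    )


def brute_force_edges(xy, radii, factor):
    edges = []
    for i in range(len(xy)):
        for j in range(i + 1, len(xy)):
            if np.hypot(*(xy[i] - xy[j])) < factor * (radii[i] + radii[j]):
                edges.append((i, j))
    return sorted(edges)


class TestNeighborGraph:
    def test_contact_rule_strict_inequality(self):
        near = sp.build_neighbor_graph(circle_table([0.0, 2.5]))
        assert len(near.edges) == 1  # 2.5 < 1.3 * 2
        far = sp.build_neighbor_graph(circle_table([0.0, 2.7]))
        assert len(far.edges) == 0  # 2.7 > 2.6

    def test_single_cell_graph(self):
        g = sp.build_neighbor_graph(circle_table([0.0]))
        assert g.n_cells == 1 and len(g.edges) == 0 and g.z_max == 0

    @pytest.mark.parametrize("n", [50, 200])
    def test_matches_all_pairs_brute_force(self, n):
        t = make_table(n=n, seed=n)
        g = sp.build_neighbor_graph(t)
        xy = t.df[["x", "y"]].to_numpy()
        radii = np.sqrt(t.df["area"].to_numpy() / np.pi)
        expected = brute_force_edges(xy, radii, 1.3)
        got = sorted(map(tuple, np.sort(g.edges, axis=1)))
        assert got == expected

    def test_symmetry_and_no_self_neighbors(self):
        t = make_table(n=100, seed=42)
        g = sp.build_neighbor_graph(t)
        for i in range(0, 100, 17):
            for j in g.neighbors(i):
                assert i != j
                assert i in g.neighbors(j)

    def test_radius_from_area(self):
        t = make_table(n=5, seed=1)
        g = sp.build_neighbor_graph(t)
        np.testing.assert_allclose(g.radii, np.sqrt(t.df["area"] / np.pi))

    def test_multi_sample_table_rejected(self):
        t1, t2 = make_table(sample_id="a"), make_table(sample_id="b")
        with pytest.raises(ValueError, match="per sample"):
            sp.build_neighbor_graph(pool_tables([t1, t2]))


class TestMolecularHeterogeneity:
    def test_single_state_is_zero(self):
        assert sp.molecular_heterogeneity(assignment_from_codes([5] * 40)) == 0.0

    def test_uniform_over_all_states_is_one(self):
        codes = np.repeat(np.arange(27), 10)
        assert sp.molecular_heterogeneity(assignment_from_codes(codes)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_two_equal_states_closed_form(self):
        codes = np.array([0] * 50 + [26] * 50)
        expected = np.log(2) / np.log(27)  # ~0.21037
        assert sp.molecular_heterogeneity(assignment_from_codes(codes)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            sp.molecular_heterogeneity(assignment_from_codes([]))


class TestSpatialStates:
    def test_isolated_cells_all_zero(self):
        t = circle_table([0.0, 100.0, 200.0])
        g = sp.build_neighbor_graph(t)
        a = assignment_from_codes([1, 1, 1], cell_ids=t.df["cell_id"].to_numpy())
        assert sp.spatial_states(g, a).tolist() == [0, 0, 0]

    def test_chain_same_state(self):
        t = circle_table([0.0, 2.0, 4.0])  # consecutive pairs adjacent only
        g = sp.build_neighbor_graph(t)
        a = assignment_from_codes([3, 3, 3], cell_ids=t.df["cell_id"].to_numpy())
        assert sp.spatial_states(g, a).tolist() == [1, 2, 1]

    def test_chain_middle_cell_differs(self):
        t = circle_table([0.0, 2.0, 4.0])
        g = sp.build_neighbor_graph(t)
        a = assignment_from_codes([3, 5, 3], cell_ids=t.df["cell_id"].to_numpy())
        assert sp.spatial_states(g, a).tolist() == [0, 0, 0]

    def test_cell_set_mismatch_errors(self):
        t = circle_table([0.0, 2.0])
        g = sp.build_neighbor_graph(t)
        with pytest.raises(ValueError, match="different cells"):
            sp.spatial_states(g, assignment_from_codes([1, 1, 1]))


class TestSpatialHeterogeneity:
    def test_constant_state_is_zero(self):
        assert sp.spatial_heterogeneity(np.array([2] * 30), z_max=2) == 0.0

    def test_uniform_states_is_one(self):
        counts = np.repeat(np.arange(5), 8)
        assert sp.spatial_heterogeneity(counts, z_max=4) == pytest.approx(1.0, abs=1e-12)

    def test_chain_closed_form(self):
        # states (1,2,1): Ps = (0, 2/3, 1/3)
        expected = -(2 / 3 * np.log(2 / 3) + 1 / 3 * np.log(1 / 3)) / np.log(3)
        assert sp.spatial_heterogeneity(np.array([1, 2, 1]), z_max=2) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.57938, abs=1e-5)

    def test_all_isolated_defined_as_zero(self):
        assert sp.spatial_heterogeneity(np.zeros(10, dtype=int), z_max=0) == 0.0

    def test_count_above_z_max_errors(self):
        with pytest.raises(ValueError, match="z_max"):
            sp.spatial_heterogeneity(np.array([3]), z_max=2)


class TestHeterogeneityReport:
    def test_row_count_and_bounds(self, small_cohort, hallmarks):
        _, tables, _ = small_cohort
        pooled = pool_tables(tables)
        model = sp.fit_quantization(pooled)
        two = list(tables.values())[:2]
        rep = sp.heterogeneity_report(two, hallmarks, model)
        assert len(rep) == 2 * len(hallmarks)
        assert rep["molecular_heterogeneity"].between(0, 1).all()
        assert rep["spatial_heterogeneity"].between(0, 1).all()

    def test_cell_order_invariance(self, small_cohort, hallmarks):
        _, tables, _ = small_cohort
        t = list(tables.values())[0]
        model = sp.fit_quantization(t)
        shuffled = t.with_df(t.df.sample(frac=1, random_state=0))
        r1 = sp.heterogeneity_report(t, hallmarks, model)
        r2 = sp.heterogeneity_report(shuffled, hallmarks, model)
        pd.testing.assert_frame_equal(r1, r2)

    def test_one_phenotype_less_heterogeneous_than_six(self, markers, hallmarks):
        from spathet.synthetic import (
            GroupSpec, SyntheticConfig, make_level_profile_means, DEFAULT_HALLMARKS,
        )

        six = tuple(f"p{i}" for i in range(6))
        means = make_level_profile_means(
            {"g": six}, markers, seed=3,
            hallmark_subsets=list(DEFAULT_HALLMARKS.values()),
        )
        base = dict(
            phenotype_marker_means=means, cells_per_sample=800,
            n_subjects_per_group=1, rng_seed=3,
        )
        cfg1 = SyntheticConfig(groups={"g": GroupSpec(six[:1], 1.0)}, **base)
        cfg6 = SyntheticConfig(groups={"g": GroupSpec(six, 1.0)}, **base)
        t1 = sp.generate_sample(cfg1, "g", "s1", 3)
        t6 = sp.generate_sample(cfg6, "g", "s6", 3)
        # common state definition fit on the diverse reference sample: with a
        # shared quantization, fewer phenotypes occupy fewer states
        model = sp.fit_quantization(t6)
        r1 = sp.heterogeneity_report(t1, hallmarks, model)
        r6 = sp.heterogeneity_report(t6, hallmarks, model)
        for hm in (h.name for h in hallmarks):
            assert (
                r1.set_index("hallmark").at[hm, "molecular_heterogeneity"]
                < r6.set_index("hallmark").at[hm, "molecular_heterogeneity"]
            )

    def test_label_shuffle_breaks_spatial_structure_only(self, markers, hallmarks):
        # aggregated sample: shuffling state labels across cells preserves the
        # state frequencies (molecular entropy) but destroys spatial clumping
        cfg = sp.default_config(n_subjects_per_group=1, cells_per_sample=1500, seed=5)
        t = sp.generate_sample(cfg, "mt-like", "s1", 5)
        model = sp.fit_quantization(t)
        hm = hallmarks[0]
        graph = sp.build_neighbor_graph(t)
        a = sp.encode_states(t, model, hm)
        rng = np.random.default_rng(0)
        shuffled = MolecularStateAssignment(
            hallmark=a.hallmark, markers=a.markers, cell_ids=a.cell_ids,
            sample_ids=a.sample_ids, levels=a.levels,
            codes=rng.permutation(a.codes),
        )
        assert sp.molecular_heterogeneity(a) == pytest.approx(
            sp.molecular_heterogeneity(shuffled), abs=1e-12
        )
        assert sp.spatial_states(graph, shuffled).mean() < sp.spatial_states(graph, a).mean()

    def test_pool_by_patient_means(self):
        rep = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1"],
                "hallmark": ["h", "h", "h"],
                "molecular_heterogeneity": [0.2, 0.4, 0.6],
                "spatial_heterogeneity": [0.1, 0.3, 0.5],
            }
        )
        pooled = sp.pool_by_patient(rep, {"a1": "A", "a2": "A", "b1": "B"})
        assert pooled.set_index("patient_id").at["A", "molecular_heterogeneity"] == pytest.approx(0.3)
        assert len(pooled) == 2
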