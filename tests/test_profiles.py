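"""Editing matrix, pattern classification, and co-editing network."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screditome.profiles import (
    EditingMatrix,
    LineageConfig,
    adjacency_from_profiles,
    build_matrix,
    classify_patterns,
    detect_modules,
    pick_soft_power,
    scale_free_r2,
    tom_similarity,
)
from screditome.model import EditingSite
from screditome.synthetic import simulate_block_profiles, simulate_scalefree_profiles

from helpers import tom_triple_loop

TYPES = ["HSC", "MPP", "LMPP", "MLP", "MEMP", "CMP", "GMP", "MEP"]


def site(pos0, ct, p_edit=0.9):
    return EditingSite("chr1", pos0, "+", "A", "G", 40, 8, 0.2, p_edit, True, cell_type=ct)


class TestBuildMatrix:
    def test_called_in_one_type_kept_when_covered_everywhere(self):
        tables = {ct: [] for ct in TYPES}
        tables["HSC"] = [site(100, "HSC", 0.9)]
        m = build_matrix(tables, lambda key, ct: 40, TYPES)
        assert m.site_keys == [("chr1", 100, "+")]
        assert m.p_edit[0, 0] == 0.9 and m.p_edit[0, 1:].sum() == 0

    def test_row_dropped_when_uncovered_in_one_type(self):
        tables = {ct: [] for ct in TYPES}
        tables["HSC"] = [site(100, "HSC")]
        m = build_matrix(tables, lambda key, ct: 10 if ct == "GMP" else 40, TYPES)
        assert m.site_keys == []

    def test_missing_cell_type_rejected(self):
        with pytest.raises(KeyError):
            build_matrix({"HSC": []}, lambda k, c: 40, TYPES)

    def test_rows_are_exactly_fully_covered_called_sites(self, clean_sim, clean_called, clean_depths):
        by_type, sites_by_type = clean_called
        cts = list(clean_sim.config.cell_types)

        def depth_fn(key, ct):
            d = clean_depths[ct].get((key[0], key[1]))
            if d is None:
                from screditome.editcall import site_depth

                d = site_depth(by_type[ct], key[0], key[1])
            return d

        m = build_matrix(sites_by_type, depth_fn, cts)
        union = {s.key for ss in sites_by_type.values() for s in ss}
        expected = {k for k in union if all(depth_fn(k, ct) >= 30 for ct in cts)}
        assert set(m.site_keys) == expected


class TestClassifyPatterns:
    def matrix(self, edited_sets):
        keys = [("chr1", i, "+") for i in range(len(edited_sets))]
        p = np.zeros((len(edited_sets), len(TYPES)))
        for i, edited in enumerate(edited_sets):
            for j, ct in enumerate(TYPES):
                if ct in edited:
                    p[i, j] = 0.8
        return EditingMatrix(keys, TYPES, p, np.ones_like(p, dtype=bool))

    def test_taxonomy(self):
        m = self.matrix(
            [
                set(TYPES),  # shared
                {"LMPP", "MLP"},  # lymphoid group
                {"MEMP", "CMP", "GMP", "MEP"},  # myeloid group
                {"HSC", "MPP"},  # stem group
                {"GMP"},  # type specific
                {"HSC", "GMP"},  # neither
            ]
        )
        labels = [str(v) for v in classify_patterns(m).values()]
        assert labels == [
            "shared",
            "group_specific:lymphoid",
            "group_specific:myeloid",
            "group_specific:HSC/MPP",
            "type_specific:GMP",
            "other",
        ]

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(5)
        sets = [set(np.array(TYPES)[rng.random(8) < 0.5]) or {"HSC"} for _ in range(50)]
        labels = classify_patterns(self.matrix(sets))
        assert len(labels) == 50
        assert all(v.kind in {"shared", "group_specific", "type_specific", "other"} for v in labels.values())

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            LineageConfig(groups={"a": {"HSC"}, "b": {"HSC", "MPP"}})


class TestSoftPower:
    def test_matches_brute_force_scan(self):
        x = simulate_scalefree_profiles(seed=21)
        beta, table = pick_soft_power(x)
        # independent scan: recompute R^2 per power from scratch
        chosen = None
        for p in range(1, 21):
            cor = np.corrcoef(x)
            a = np.abs(cor) ** p
            np.fill_diagonal(a, 0)
            r2 = scale_free_r2(a.sum(1))
            if r2 >= 0.8:
                chosen = p
                break
        assert chosen is not None and beta == chosen

    def test_degenerate_identical_rows_warns(self):
        # identical rows: all correlations 1, adjacency all 1 at any power,
        # connectivity constant -> no scale-free fit, warning path
        x = np.tile(np.array([0.1, 0.5, 0.9, 0.2, 0.8]), (40, 1))
        with pytest.warns(UserWarning, match="no power reached"):
            beta, table = pick_soft_power(x)
        assert (table["r2"] == 0).all()
        assert np.allclose(adjacency_from_profiles(x, beta) + np.eye(40), 1.0)

    def test_cutoff_zero_returns_first_power(self):
        x = simulate_scalefree_profiles(seed=3)
        beta, _ = pick_soft_power(x, r2_cutoff=0.0)
        assert beta == 1

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            pick_soft_power(np.ones((10, 1)))


class TestTom:
    def test_all_zero_adjacency(self):
        tom = tom_similarity(np.zeros((3, 3)))
        assert np.allclose(tom, np.eye(3))

    def test_single_edge_two_nodes(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_matches_triple_loop_formula(self):
        rng = np.random.default_rng(42)
        for _ in range(3):
            a = rng.random((20, 20))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            assert np.max(np.abs(tom_similarity(a) - tom_triple_loop(a))) < 1e-12

    def test_asymmetric_rejected(self):
        a = np.array([[0.0, 0.5], [0.1, 0.0]])
        with pytest.raises(ValueError):
            tom_similarity(a)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 15))
    def test_bounds_and_symmetry(self, seed, n):
        rng = np.random.default_rng(seed)
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        tom = tom_similarity(a)
        assert np.allclose(tom, tom.T)
        assert tom.max() <= 1.0 + 1e-12 and tom.min() >= 0.0


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        x, labels = simulate_block_profiles(within_cor=0.95, seed=0)
        tom = tom_similarity(adjacency_from_profiles(x, 6))
        mods = detect_modules(1 - tom, min_module_size=30, cut_height=0.995)
        assert mods.max() == 2
        assert adjusted_rand_score(labels, mods) == 1.0

    def test_fewer_sites_than_min_module_size(self):
        d = 1 - np.eye(10)
        assert (detect_modules(d, min_module_size=30) == 0).all()

    def test_min_size_one_with_distinct_distances_gives_singletons(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0.5, 1.0, (8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        mods = detect_modules(d, min_module_size=1, cut_height=0.1)
        assert sorted(mods) == list(range(1, 9))

    def test_labels_ordered_by_size(self):
        x, labels = simulate_block_profiles(n_sites_per_block=30, n_blocks=2, seed=2)
        # enlarge block 0 by duplicating profiles with fresh noise
        x = np.vstack([x, x[:15] + 0.01])
        truth = np.concatenate([labels, labels[:15]])
        tom = tom_similarity(adjacency_from_profiles(x, 6))
        mods = detect_modules(1 - tom, min_module_size=20, cut_height=0.995)
        sizes = {m: (mods == m).sum() for m in set(mods) - {0}}
        assert sizes[1] >= sizes.get(2, 0)
        assert (mods[truth == 0] == 1).mean() > 0.9
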