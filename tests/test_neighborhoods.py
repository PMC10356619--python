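import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from histoarch import ConfigError
from histoarch.core import LabelAssignment
from histoarch.neighborhoods import (
    cluster_windows, composition_windows, concentric_enrichment,
    conservation_delta, enrichment_matrix, merge_clusters, suggest_merges,
)
from histoarch.synthetic import ZoneSpec, generate_tissue

import oracles
from conftest import make_cellmap, random_cellmap


class TestCompositionWindows:
    def test_homogeneous_map_is_one_hot(self):
        cm = random_cellmap(n=50, n_types=1, seed=0)
        w = composition_windows(cm, k=10)
        assert list(w.values.columns) == ["t0"]
        assert np.allclose(w.values.to_numpy(), 1.0)

    def test_toy_matches_bruteforce(self, toy_map):
        w = composition_windows(toy_map, k=4)
        expect = oracles.window_fractions_bruteforce(
            toy_map.coords, toy_map.cell_types, 4)
        for i, row in enumerate(expect):
            for label, frac in row.items():
                assert w.values.iloc[i][label] == pytest.approx(frac)
        assert np.allclose(w.values.sum(axis=1), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_to_one(self, seed):
        cm = random_cellmap(n=100, n_types=4, seed=seed)
        w = composition_windows(cm, k=7)
        assert np.allclose(w.values.sum(axis=1), 1.0, atol=1e-9)

    def test_exclude_self_variant(self, toy_map):
        w = composition_windows(toy_map, k=4, include_self=False)
        expect = oracles.window_fractions_bruteforce(
            toy_map.coords, toy_map.cell_types, 4, include_self=False)
        for i, row in enumerate(expect):
            for label, frac in row.items():
                assert w.values.iloc[i][label] == pytest.approx(frac)

    def test_permutation_invariance_to_cell_order(self):
        cm = random_cellmap(n=60, n_types=3, seed=9)
        w1 = composition_windows(cm, k=6).values
        perm = np.random.default_rng(1).permutation(cm.n)
        shuffled = make_cellmap(cm.coords[perm], cm.cell_types[perm],
                                area=cm.area)
        # same cell ids in the same geometric placement, new row order
        shuffled.cells["cell_id"] = cm.cells["cell_id"].to_numpy()[perm]
        w2 = composition_windows(shuffled, k=6).values
        pd.testing.assert_frame_equal(w1.loc[w2.index], w2)

    def test_k_larger_than_n_rejected(self, toy_map):
        with pytest.raises(ConfigError):
            composition_windows(toy_map, k=100)


class TestClusterWindows:
    def test_separable_compositions_ari_one(self):
        coords = np.vstack([np.random.default_rng(0).uniform(0, 10, (100, 2)),
                            np.random.default_rng(1).uniform(100, 110, (100, 2))])
        types = np.array(["A"] * 100 + ["B"] * 100, dtype=object)
        cm = make_cellmap(coords, types, area=1e4)
        w = composition_windows(cm, k=10)
        labels = cluster_windows(w, 2, seed=0)
        planted = np.array([0] * 100 + [1] * 100)
        assert adjusted_rand_score(planted, labels.labels) == 1.0

    def test_deterministic_given_seed(self):
        cm = random_cellmap(n=200, n_types=4, seed=3)
        w = composition_windows(cm, k=10)
        a = cluster_windows(w, 5, seed=11)
        b = cluster_windows(w, 5, seed=11)
        assert np.array_equal(a.labels, b.labels)

    def test_per_group_prefixing(self):
        cm = random_cellmap(n=100, n_types=3, seed=4)
        w = composition_windows(cm, k=5)
        groups = np.array(["g1"] * 50 + ["g2"] * 50, dtype=object)
        labels = cluster_windows(w, 2, seed=0, group_by=groups)
        assert all(l.startswith("g1:") for l in labels.labels[:50])
        assert all(l.startswith("g2:") for l in labels.labels[50:])

    def test_too_many_clusters_rejected(self):
        cm = random_cellmap(n=30, n_types=1, seed=5)
        w = composition_windows(cm, k=5)  # all rows identical
        with pytest.raises(ConfigError):
            cluster_windows(w, 2, seed=0)


class TestMergeClusters:
    def test_identity_and_surjective(self):
        la = LabelAssignment("neighbourhood",
                            np.array(["a", "b", "c", "a"], dtype=object))
        same = merge_clusters(la, {"a": "a", "b": "b", "c": "c"})
        assert np.array_equal(same.labels, la.labels)
        merged = merge_clusters(la, {"a": "x", "b": "x", "c": "y"})
        assert sorted(set(merged.labels)) == ["x", "y"]

    def test_unmapped_label_rejected(self):
        la = LabelAssignment("neighbourhood", np.array(["a", "b"], dtype=object))
        with pytest.raises(Exception, match="b"):
            merge_clusters(la, {"a": "x"})

    def test_merged_enrichment_is_weighted_average(self):
        cm = random_cellmap(n=300, n_types=4, seed=6)
        w = composition_windows(cm, k=8)
        la = cluster_windows(w, 6, seed=0)
        lower = cm.type_labels()
        e_before = enrichment_matrix(la, lower)
        mapping = {l: ("m0" if i % 2 == 0 else "m1")
                   for i, l in enumerate(sorted(set(la.labels)))}
        merged = merge_clusters(la, mapping)
        e_after = enrichment_matrix(merged, lower)
        for m in ("m0", "m1"):
            parts = [l for l, t in mapping.items() if t == m]
            wts = e_before.weights[parts]
            expect = (e_before.matrix.loc[parts].mul(wts, axis=0).sum()
                      / wts.sum())
            assert np.allclose(e_after.matrix.loc[m], expect, atol=1e-9)


class TestEnrichmentMatrix:
    def test_single_upper_label_all_ones(self):
        cm = random_cellmap(n=80, n_types=3, seed=7)
        upper = LabelAssignment("u", np.array(["only"] * 80, dtype=object))
        e = enrichment_matrix(upper, cm.type_labels())
        assert np.allclose(e.matrix.to_numpy(), 1.0)

    def test_forced_arithmetic(self):
        # cluster 50% A where overall A is 25% -> enrichment 2
        types = np.array(["A"] * 2 + ["B"] * 2 + ["B"] * 4, dtype=object)
        upper = np.array(["u1"] * 4 + ["u2"] * 4, dtype=object)
        e = enrichment_matrix(LabelAssignment("u", upper),
                              LabelAssignment("t", types))
        assert e.matrix.at["u1", "A"] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_identity_and_oracle(self, seed):
        cm = random_cellmap(n=200, n_types=5, seed=seed)
        w = composition_windows(cm, k=10)
        upper = cluster_windows(w, 4, seed=0)
        e = enrichment_matrix(upper, cm.type_labels())
        weighted = e.matrix.mul(e.weights, axis=0).sum(axis=0)
        assert np.allclose(weighted, 1.0, atol=1e-6)
        expect = oracles.enrichment_bruteforce(upper.labels, cm.cell_types)
        for (u, c), v in expect.items():
            assert e.matrix.at[u, c] == pytest.approx(v, abs=1e-9)

    def test_shuffled_labels_enrichment_shrinks_with_n(self):
        def max_dev(n, seed):
            rng = np.random.default_rng(seed)
            cm = random_cellmap(n=n, n_types=4, seed=seed)
            upper = LabelAssignment(
                "u", rng.choice(["u0", "u1", "u2"], size=n).astype(object))
            e = enrichment_matrix(upper, cm.type_labels())
            return np.abs(e.matrix.to_numpy() - 1.0).max()
        assert max_dev(10000, 1) < max_dev(1000, 1)


class TestConservationDelta:
    def _enr(self, seed, n=300):
        cm = random_cellmap(n=n, n_types=4, seed=seed)
        w = composition_windows(cm, k=8)
        upper = cluster_windows(w, 3, seed=0)
        return enrichment_matrix(upper, cm.type_labels())

    def test_equal_matrices_give_zero(self):
        e = self._enr(1)
        d = conservation_delta(e, e)
        assert np.allclose(d.delta.to_numpy(), 0.0)

    def test_single_difference_ranks_first(self):
        e = self._enr(2)
        import copy
        e2 = copy.deepcopy(e)
        label = e2.matrix.index[1]
        ctype = e2.matrix.columns[2]
        e2.matrix.at[label, ctype] += 5.0
        d = conservation_delta(e, e2)
        assert d.row_order[0] == label
        assert d.col_order[0] == ctype


class TestConcentricEnrichment:
    def test_ring_toy_enrichment(self):
        # 1 anchor at origin, ring of 6 B at r=5, 6 A far away -> B overall
        # fraction 0.5, all cells within r=6 are B -> enrichment 2.0
        coords = [(0.0, 0.0)]
        for i in range(6):
            a = 2 * np.pi * i / 6
            coords.append((5 * np.cos(a) + 50, 5 * np.sin(a) + 50))
        coords = [(0.0, 0.0)] + \
            [(5 * np.cos(2 * np.pi * i / 6), 5 * np.sin(2 * np.pi * i / 6))
             for i in range(6)] + \
            [(100.0 + i, 100.0) for i in range(6)]
        types = ["anchor"] + ["B"] * 6 + ["A"] * 6
        cm = make_cellmap(coords, types, area=1e4)
        prof = concentric_enrichment(cm, "anchor", [6.0, 200.0])
        assert prof.enrichment.loc[6.0, "B"] == pytest.approx(2.0)
        assert prof.enrichment.loc[200.0, "B"] == pytest.approx(1.0)

    def test_empty_radii_are_missing(self):
        cm = make_cellmap([(0, 0), (100, 100)], ["anchor", "A"], area=1e4)
        prof = concentric_enrichment(cm, "anchor", [1.0, 2.0])
        assert prof.composition.isna().all().all()

    def test_cumulative_counts_monotone(self):
        cm = random_cellmap(n=200, n_types=3, seed=8)
        prof = concentric_enrichment(cm, "t0", [5.0, 10.0, 20.0, 40.0])
        totals = prof.counts.sum(axis=1).to_numpy()
        assert np.all(np.diff(totals) >= 0)

    def test_no_anchor_rejected(self):
        cm = random_cellmap(n=20, n_types=2, seed=9)
        with pytest.raises(ConfigError):
            concentric_enrichment(cm, "missing", [5.0])

    def test_crypt_anchor_profile_peaks_at_small_radius(self):
        from histoarch.synthetic import Crypt
        zones = (ZoneSpec("z", (0.0, 1.0), 0.01,
                          {"enterocyte": 0.7, "TA": 0.3}),)
        crypts = Crypt(centers=tuple((100.0 * i + 50.0, 500.0) for i in range(9)),
                       radius=30.0, composition={"TA": 0.9, "enterocyte": 0.1},
                       anchor_type="paneth", anchor_count=2)
        cm = generate_tissue(zones, (crypts,), seed=12)
        prof = concentric_enrichment(cm, "paneth", [15.0, 30.0, 120.0, 400.0])
        ta = prof.enrichment["TA"]
        assert ta.iloc[0] > ta.iloc[2] > ta.iloc[3] * 0.9
        assert ta.iloc[0] > 1.5


def test_suggest_merges_reports_correlated_profiles():
    cm = random_cellmap(n=400, n_types=4, seed=10)
    w = composition_windows(cm, k=8)
    la = cluster_windows(w, 8, seed=0)
    e = enrichment_matrix(la, cm.type_labels())
    for a, b, r in suggest_merges(e, min_corr=0.9):
        va = e.matrix.loc[a].to_numpy()
        vb = e.matrix.loc[b].to_numpy()
        assert np.corrcoef(va, vb)[0, 1] >= 0.9
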