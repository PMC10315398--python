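"""Silhouette analysis, DSC%, and modality significance testing."""

import numpy as np
import pytest
from scipy import stats

from dcesom.cluster_stats import (
    compare_modalities,
    dsc_percent,
    holm_adjust,
    levene_test,
    omnibus_test,
    silhouette,
    threshold_labels,
    threshold_sweep,
)
from dcesom.som import NodeProbabilityMaps, SOMConfig, probability_maps, train_ksom


def naive_silhouette(points, labels):
    """Brute-force pairwise-distance silhouette, the independent oracle."""
    points = np.asarray(points, float)
    labels = np.asarray(labels)
    n = len(points)
    out = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            out[i] = 0.0
            continue
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(points[i] - points[j]) for j in range(n) if labels[j] == c])
            for c in set(labels) - {labels[i]}
        )
        out[i] = (b - a) / max(a, b)
    return out


class TestSilhouette:
    def test_hand_computed_1d_example(self):
        # {0,1} vs {10,11}: s(0) = 9.5/10.5, overall mean ~ 0.89975
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        lab = np.array([1, 1, 2, 2])
        sc = silhouette(pts, lab)
        assert sc[0] == pytest.approx(9.5 / 10.5, abs=1e-9)
        assert sc.mean() == pytest.approx(0.89975, abs=1e-4)

    def test_matches_naive_pairwise_oracle_on_random_data(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(40, 3))
        lab = rng.integers(1, 4, 40)
        np.testing.assert_allclose(silhouette(pts, lab), naive_silhouette(pts, lab), atol=1e-12)

    def test_singleton_cluster_scores_zero(self):
        pts = np.array([[0.0], [1.0], [5.0]])
        lab = np.array([1, 1, 2])
        assert silhouette(pts, lab)[2] == 0.0

    def test_values_bounded_in_unit_interval(self):
        rng = np.random.default_rng(1)
        sc = silhouette(rng.normal(size=(60, 4)), rng.integers(1, 3, 60))
        assert (sc >= -1).all() and (sc <= 1).all()

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((5, 2)), np.ones(5))


@pytest.fixture(scope="module")
def trained(two_cluster_profiles):
    profiles, labels = two_cluster_profiles
    model = train_ksom(profiles, SOMConfig(max_epochs=30, cover_steps=15, seed=0))
    pmap = probability_maps(model, profiles, labels)
    return model, pmap


class TestThresholdSweep:
    def test_sweep_has_100_probability_states(self, trained):
        model, pmap = trained
        sweep = threshold_sweep(model, pmap)
        assert sweep.thresholds.size == 100
        assert sweep.thresholds[0] == pytest.approx(0.01)
        assert sweep.thresholds[-1] == pytest.approx(1.00)

    def test_minimal_threshold_includes_every_hit_node(self, trained):
        _model, pmap = trained
        include, _labels = threshold_labels(pmap, 0.01)
        assert include.sum() == pmap.hit_nodes.sum()

    def test_included_node_count_nonincreasing_in_threshold(self, trained):
        model, pmap = trained
        sweep = threshold_sweep(model, pmap)
        assert (np.diff(sweep.n_nodes) <= 0).all()

    def test_sweep_silhouettes_match_naive_oracle(self, trained):
        model, pmap = trained
        sweep = threshold_sweep(model, pmap)
        for tau in (0.01, 0.5, 0.9):
            i = int(round(tau * 100)) - 1
            include, labels = threshold_labels(pmap, tau)
            if np.unique(labels[include]).size < 2:
                assert np.isnan(sweep.mean_sc[i])
                continue
            sc = naive_silhouette(model.weights[include], labels[include])
            assert sweep.mean_sc[i] == pytest.approx(sc.mean(), abs=1e-10)


class TestDSC:
    def test_second_echo_dissimilarity_worked_example(self):
        # mean SCs 0.472 (feature) vs 0.332 (raw) -> 42.2%, printed as 42
        val = dsc_percent(0.472, 0.332)
        assert val == pytest.approx(42.168674698, abs=1e-6)
        assert round(val) == 42

    def test_equal_means_give_zero_and_double_gives_hundred(self):
        assert dsc_percent(0.4, 0.4) == 0.0
        assert dsc_percent(0.8, 0.4) == pytest.approx(100.0)

    def test_zero_raw_mean_rejected(self):
        with pytest.raises(ValueError):
            dsc_percent(0.5, 0.0)


class TestStatisticalTests:
    def test_identical_samples_degenerate_levene_and_omnibus(self):
        a = np.full(10, 0.5)
        w, p = levene_test(a, a.copy())
        assert w == 0.0 and p == 1.0
        p_omni, which = omnibus_test(a, a.copy(), homogeneous=True)
        assert p_omni == 1.0 and which == "anova"

    def test_holm_adjustment_by_hand_sequence(self):
        adj = holm_adjust([0.01, 0.04])
        np.testing.assert_allclose(adj, [0.02, 0.04])

    def test_holm_adjusted_pvalues_monotone_in_sorted_order(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 9)
        adj = holm_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()

    def test_welch_statistic_matches_textbook_formula(self):
        a = np.array([1.1, 2.3, 1.9, 2.8, 1.5])
        b = np.array([3.4, 2.9, 4.1, 3.3, 3.8])
        t_sp, p_sp = stats.ttest_ind(a, b, equal_var=False)
        ma, mb = a.mean(), b.mean()
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t_hand = (ma - mb) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 4)
        p_hand = 2 * stats.t.sf(abs(t_hand), df)
        assert t_sp == pytest.approx(t_hand, abs=1e-10)
        assert p_sp == pytest.approx(p_hand, abs=1e-10)
        p_ours, which = omnibus_test(a, b, homogeneous=False)
        assert which == "welch" and p_ours == pytest.approx(p_hand, abs=1e-10)


class TestCompareModalities:
    def _make_sweeps(self, seed=0):
        """A feature whose SOM separates classes better by construction."""
        rng = np.random.default_rng(seed)
        cfg = SOMConfig(max_epochs=25, cover_steps=12, seed=1)
        n = 150

        def build(sep):
            prof = np.vstack([
                rng.normal(-sep, 1.0, (n, 16)),
                rng.normal(sep, 1.0, (n, 16)),
                rng.normal(3 * sep, 1.0, (n, 16)),
            ])
            lab = np.repeat([1, 2, 3], n)
            model = train_ksom(prof, cfg)
            pmap = probability_maps(model, prof, lab)
            return threshold_sweep(model, pmap, modality_id=f"sep{sep}")

        return build(1.0), build(4.0)  # raw-like, feature-like

    def test_better_separated_feature_gets_positive_significant_dsc(self):
        raw, feature = self._make_sweeps()
        comps = compare_modalities(raw, [feature])
        assert len(comps) == 1
        assert comps[0].dsc_percent > 0
        assert comps[0].significant
        assert comps[0].adjusted_p >= comps[0].omnibus_p - 1e-15

    def test_identical_modality_is_not_significant(self):
        raw, _ = self._make_sweeps()
        twin = self._make_sweeps()[0]
        twin.modality_id = "twin"
        comps = compare_modalities(raw, [twin])
        assert not comps[0].significant
        assert comps[0].dsc_percent == pytest.approx(0.0, abs=1e-9)
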