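"""Per-iteration appearance rules, stability retention, and LR contribution modes."""

import numpy as np
import pandas as pd
import pytest

from panselect import (
    IterationRecord,
    SelectorConfig,
    generate_pangenome,
    lr_select,
    per_iteration_select,
    planted_truth,
    run_external_iterations,
    run_selector,
    stability_retain,
)
from panselect import SyntheticSpec


def _series(values, prefix="f"):
    return pd.Series(values, index=[f"{prefix}{i + 1}" for i in range(len(values))])


class TestPerIterationSelect:
    def test_rf_positive_importance_mode(self):
        config = SelectorConfig(method="rf", rf_appearance_rule="positive_importance")
        selected = per_iteration_select(_series([0.0, 0.7, 0.3, 0.0]), config)
        assert selected == {"f2", "f3"}

    def test_rf_zscore_mode_picks_outliers(self):
        config = SelectorConfig(method="rf")
        values = [0.001] * 99 + [0.9]
        selected = per_iteration_select(_series(values), config)
        assert selected == {"f100"}

    def test_svm_equal_weights_select_nothing(self):
        config = SelectorConfig(method="svm")
        assert per_iteration_select(_series([0.5] * 10), config) == set()

    def test_svm_single_outlier_weight(self):
        # 999 weights near zero plus one at 10: only the outlier's z-score
        # against the iteration's weight distribution can exceed 3.
        rng = np.random.default_rng(0)
        weights = np.abs(rng.normal(0, 1e-3, 999)).tolist() + [10.0]
        arr = np.array(weights)
        z = (arr - arr.mean()) / arr.std()
        assert (z > 3).sum() == 1  # oracle arithmetic
        config = SelectorConfig(method="svm")
        assert per_iteration_select(_series(weights), config) == {"f1000"}

    def test_all_zero_importances_select_nothing(self):
        for method in ("rf", "svm"):
            config = SelectorConfig(method=method)
            assert per_iteration_select(_series([0.0] * 5), config) == set()


def _records(selection_lists, universe):
    base = pd.Series(0.0, index=universe)
    return [
        IterationRecord(
            iteration_index=i,
            selected_families=set(sel),
            importance_summary=base,
            subsample_seed=i,
        )
        for i, sel in enumerate(selection_lists)
    ]


class TestStabilityRetain:
    universe = [f"f{i}" for i in range(5)]

    def test_matches_brute_force_frequency_counting(self):
        rng = np.random.default_rng(1)
        lists = [
            [f for f in self.universe if rng.random() < 0.5] for _ in range(40)
        ]
        selection = stability_retain(_records(lists, self.universe), 0.40)
        for fam in self.universe:
            brute = sum(fam in chosen for chosen in lists) / len(lists)
            assert selection.appearance_frequency[fam] == pytest.approx(brute)
            assert (fam in selection.retained) == (brute >= 0.40)

    @pytest.mark.parametrize("n_hits,expected", [(45, True), (40, True), (39, False)])
    def test_forty_percent_threshold_is_inclusive(self, n_hits, expected):
        lists = [["f0"] if i < n_hits else [] for i in range(100)]
        selection = stability_retain(_records(lists, self.universe), 0.40)
        assert ("f0" in selection.retained) is expected

    def test_threshold_one_requires_every_iteration(self):
        lists = [["f0"]] * 10
        selection = stability_retain(_records(lists, self.universe), 1.0)
        assert selection.retained == {"f0"}

    def test_retained_size_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        lists = [
            [f for f in self.universe if rng.random() < 0.6] for _ in range(50)
        ]
        records = _records(lists, self.universe)
        sizes = [
            len(stability_retain(records, t).retained)
            for t in (0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_retained_subset_of_union_of_selections(self):
        rng = np.random.default_rng(3)
        lists = [
            [f for f in self.universe if rng.random() < 0.3] for _ in range(30)
        ]
        selection = stability_retain(_records(lists, self.universe), 0.2)
        union = set().union(*map(set, lists)) if lists else set()
        assert selection.retained <= union

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValueError):
            stability_retain([], 0.4)


class TestExternalIterations:
    def test_single_rf_iteration_finds_a_marker(self, small_separable):
        spec, pg = small_separable
        config = SelectorConfig(method="rf", rf_external_iterations=1, seed=0)
        (record,) = run_external_iterations(pg, config)
        assert record.selected_families & planted_truth(spec)

    def test_same_seed_reproduces_records(self, small_separable):
        _, pg = small_separable
        config = SelectorConfig(method="svm", svm_external_iterations=3, seed=11)
        a = run_external_iterations(pg, config)
        b = run_external_iterations(pg, config)
        for ra, rb in zip(a, b):
            assert ra.selected_families == rb.selected_families
            pd.testing.assert_series_equal(ra.importance_summary, rb.importance_summary)

    def test_lr_method_rejected(self, small_separable):
        _, pg = small_separable
        with pytest.raises(ValueError):
            run_external_iterations(pg, SelectorConfig(method="lr"))

    def test_tiny_input_single_class_subsample_errors(self):
        spec = SyntheticSpec(
            n_genomes_group_a=1, n_genomes_group_b=10,
            n_core=5, n_cloud=5, n_markers=2, seed=0,
        )
        pg = generate_pangenome(spec)
        config = SelectorConfig(method="rf", rf_external_iterations=1, seed=0)
        with pytest.raises(ValueError, match="single class"):
            run_external_iterations(pg, config)


class TestLrSelect:
    def test_individual_share_threshold(self, small_separable):
        _, pg = small_separable
        config = SelectorConfig(method="lr", seed=0)
        selection = lr_select(pg, config)
        shares = selection.appearance_frequency
        assert shares.sum() == pytest.approx(1.0)
        expected = set(shares.index[shares > config.lr_contribution_threshold])
        assert selection.retained == expected

    def test_individual_share_capacity_bound(self, small_separable):
        # shares sum to 1, so at most floor(1/threshold) families can pass
        _, pg = small_separable
        config = SelectorConfig(method="lr", seed=0)
        selection = lr_select(pg, config)
        assert len(selection.retained) <= int(1 / config.lr_contribution_threshold)

    def test_cumulative_prefix_matches_prefix_sum_oracle(self, small_separable):
        _, pg = small_separable
        config = SelectorConfig(
            method="lr", lr_contribution_mode="cumulative_prefix",
            lr_contribution_threshold=0.3, seed=0,
        )
        selection = lr_select(pg, config)
        order = selection.appearance_frequency.sort_values(
            ascending=False, kind="stable"
        )
        running, expected = 0.0, []
        for fam, share in order.items():
            expected.append(fam)
            running += share
            if running > 0.3:
                break
        assert selection.retained == set(expected)

    def test_share_monotone_in_threshold(self, small_separable):
        _, pg = small_separable
        sizes = [
            len(lr_select(pg, SelectorConfig(
                method="lr", lr_contribution_threshold=t, seed=0
            )).retained)
            for t in (0.001, 0.01, 0.1)
        ]
        assert sizes == sorted(sizes, reverse=True)


def test_run_selector_is_deterministic(small_separable):
    _, pg = small_separable
    for method in ("lr", "svm", "rf"):
        config = SelectorConfig(
            method=method, svm_external_iterations=4, rf_external_iterations=4, seed=2
        )
        a = run_selector(pg, config)
        b = run_selector(pg, config)
        assert a.retained == b.retained
        pd.testing.assert_series_equal(a.appearance_frequency, b.appearance_frequency)


def test_selectors_recover_planted_markers():
    # Markers must be a small fraction of the families for the z-score
    # appearance rules to flag them as outliers, as in a real pangenome.
    spec = SyntheticSpec(
        n_genomes_group_a=30, n_genomes_group_b=30,
        n_core=30, n_cloud=300, n_markers=8,
        p_marker_a=0.95, p_marker_b=0.05, flip_noise=0.01, seed=17,
    )
    pg = generate_pangenome(spec)
    truth = planted_truth(spec)
    for method in ("lr", "svm", "rf"):
        config = SelectorConfig(
            method=method, svm_external_iterations=15, rf_external_iterations=15, seed=4
        )
        selection = run_selector(pg, config)
        assert truth <= selection.retained, method


@pytest.mark.parametrize(
    "kwargs",
    [
        {"method": "knn"},
        {"appearance_threshold": 0.0},
        {"rf_external_iterations": 0},
        {"lr_contribution_mode": "argmax"},
        {"rf_appearance_rule": "topk"},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        SelectorConfig(**kwargs)
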