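"""Venn algebra over the three retained sets and sequence-identity dedup."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panselect import SelectorConfig, build_consensus, deduplicate
from panselect.selectors import MethodSelection


def _selection(method, retained, universe):
    freq = pd.Series(0.5, index=list(universe))
    return MethodSelection(
        method=method,
        appearance_frequency=freq,
        retained=set(retained),
        config_echo=SelectorConfig(method=method),
    )


def _triple(a, b, c, universe):
    return [
        _selection("lr", a, universe),
        _selection("svm", b, universe),
        _selection("rf", c, universe),
    ]


UNIVERSE = [f"g{i}" for i in range(1, 6)]


def test_small_set_algebra():
    result = build_consensus(_triple({"g1", "g2"}, {"g2", "g3"}, {"g2"}, UNIVERSE))
    assert result.intersection == {"g2"}
    assert result.union_nonredundant == {"g1", "g2", "g3"}
    assert result.venn_regions["lr_only"] == {"g1"}
    assert result.venn_regions["svm_only"] == {"g3"}
    assert result.venn_regions["rf_only"] == set()
    assert result.per_method_counts == {"lr": 2, "svm": 2, "rf": 1}


def test_three_empty_sets():
    result = build_consensus(_triple(set(), set(), set(), UNIVERSE))
    assert all(not region for region in result.venn_regions.values())
    assert result.union_nonredundant == set()


def test_region_sizes_match_per_family_enumeration():
    # Oracle: classify every family by its membership pattern, one at a time.
    rng = np.random.default_rng(0)
    universe = [f"fam{i}" for i in range(3000)]
    a = set(rng.choice(universe, 1047, replace=False))
    b = set(rng.choice(universe, 85, replace=False))
    c = set(rng.choice(universe, 113, replace=False))
    result = build_consensus(_triple(a, b, c, universe))

    oracle = {key: 0 for key in result.venn_regions}
    for fam in universe:
        pattern = (fam in a, fam in b, fam in c)
        key = {
            (True, False, False): "lr_only",
            (False, True, False): "svm_only",
            (False, False, True): "rf_only",
            (True, True, False): "lr_svm",
            (True, False, True): "lr_rf",
            (False, True, True): "svm_rf",
            (True, True, True): "lr_svm_rf",
        }.get(pattern)
        if key:
            oracle[key] += 1
    assert {k: len(v) for k, v in result.venn_regions.items()} == oracle


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    a=st.sets(st.integers(0, 30)),
    b=st.sets(st.integers(0, 30)),
    c=st.sets(st.integers(0, 30)),
)
def test_venn_regions_partition_the_union(a, b, c):
    universe = [str(i) for i in range(31)]
    sets = [{str(x) for x in s} for s in (a, b, c)]
    result = build_consensus(_triple(*sets, universe))
    regions = list(result.venn_regions.values())
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            assert not (regions[i] & regions[j])
    assert set().union(*regions) == sets[0] | sets[1] | sets[2]


def test_mismatched_universes_rejected():
    selections = _triple({"g1"}, {"g1"}, {"g1"}, UNIVERSE)
    selections[2] = _selection("rf", {"g1"}, UNIVERSE + ["extra"])
    with pytest.raises(ValueError, match="universe"):
        build_consensus(selections)


def test_wrong_method_combination_rejected():
    selections = _triple({"g1"}, set(), set(), UNIVERSE)
    selections[1] = _selection("lr", set(), UNIVERSE)
    with pytest.raises(ValueError):
        build_consensus(selections)


class TestDeduplicate:
    def test_identity_without_sequences(self):
        families = {"f1", "f2", "f3"}
        survivors, mapping = deduplicate(families)
        assert survivors == families and mapping == {}

    def test_identical_sequences_collapse_to_smallest_id(self):
        survivors, mapping = deduplicate(
            {"f1", "f2", "f3"}, {"f1": "MKV", "f2": "MKV", "f3": "MA"}
        )
        assert survivors == {"f1", "f3"}
        assert mapping == {"f2": "f1"}

    def test_pairwise_duplicates_match_hash_bucket_oracle(self):
        # 100 families where 40 share sequences pairwise: 80 survivors... no:
        # 40 duplicated pairs (80 families) + 20 unique = 60 distinct sequences.
        sequences = {}
        for i in range(40):
            sequences[f"dup{i}_a"] = f"SEQ{i}"
            sequences[f"dup{i}_b"] = f"SEQ{i}"
        for i in range(20):
            sequences[f"uniq{i}"] = f"UNIQUE{i}"
        families = set(sequences)
        survivors, mapping = deduplicate(families, sequences)
        oracle = {}
        for fam in sorted(families):
            oracle.setdefault(sequences[fam], fam)
        assert survivors == set(oracle.values())
        assert len(survivors) == 60
        assert all(sequences[k] == sequences[v] for k, v in mapping.items())

    def test_dedup_is_idempotent(self):
        sequences = {"f1": "AA", "f2": "AA", "f3": "BB"}
        once, _ = deduplicate({"f1", "f2", "f3"}, sequences)
        twice, mapping2 = deduplicate(once, sequences)
        assert once == twice and mapping2 == {}

    def test_missing_sequence_named(self):
        with pytest.raises(KeyError, match="f2"):
            deduplicate({"f1", "f2"}, {"f1": "AA"})
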