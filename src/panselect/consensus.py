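"""Combine the three per-method retained sets into a consensus.

The three selectors emphasize different aspects of the data, so their
retained sets overlap only partially.  This module computes all seven
Venn regions of the three sets, the deduplicated union (the final
non-redundant feature set), and the three-way intersection (the
highest-confidence subset).

Deduplication is exact protein-sequence identity: the input families are
already representatives of homology clusters, so a similarity pass would
be redundant.  Without sequences, family IDs are taken as already unique
and dedup is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .selectors import MethodSelection

__all__ = ["ConsensusResult", "build_consensus", "deduplicate", "write_venn_tsv"]

#: Region keys of a three-set Venn diagram, in a fixed report order.
VENN_REGIONS = (
    "lr_only",
    "svm_only",
    "rf_only",
    "lr_svm",
    "lr_rf",
    "svm_rf",
    "lr_svm_rf",
)


@dataclass
class ConsensusResult:
    per_method_counts: dict[str, int]
    venn_regions: dict[str, set[str]]
    union_nonredundant: set[str]
    dedup_map: dict[str, str]

    @property
    def intersection(self) -> set[str]:
        return self.venn_regions["lr_svm_rf"]

    @property
    def union_raw(self) -> set[str]:
        out: set[str] = set()
        for region in self.venn_regions.values():
            out |= region
        return out


def deduplicate(
    families: set[str], sequences: dict[str, str] | None = None
) -> tuple[set[str], dict[str, str]]:
    """Collapse families with byte-identical protein sequences.

    Among identical sequences, the lexicographically smallest family ID
    is the representative.  Without a sequence map the operation is the
    identity (IDs are already unique cluster representatives).
    """
    if sequences is None:
        return set(families), {}
    missing = sorted(f for f in families if f not in sequences)
    if missing:
        raise KeyError(f"sequence map missing families: {missing}")
    by_seq: dict[str, list[str]] = {}
    for fam in families:
        by_seq.setdefault(sequences[fam], []).append(fam)
    survivors: set[str] = set()
    dedup_map: dict[str, str] = {}
    for members in by_seq.values():
        members.sort()
        representative = members[0]
        survivors.add(representative)
        for other in members[1:]:
            dedup_map[other] = representative
    return survivors, dedup_map


def build_consensus(
    selections: list[MethodSelection],
    sequences: dict[str, str] | None = None,
) -> ConsensusResult:
    """Set algebra over exactly three selections (lr, svm, rf order-free)."""
    if len(selections) != 3:
        raise ValueError(f"exactly three selections required, got {len(selections)}")
    by_method = {sel.method: sel for sel in selections}
    if set(by_method) != {"lr", "svm", "rf"}:
        raise ValueError(f"need one selection per method lr/svm/rf, got {sorted(by_method)}")
    universes = {
        method: frozenset(sel.appearance_frequency.index)
        for method, sel in by_method.items()
    }
    if len(set(universes.values())) != 1:
        raise ValueError("selections cover different family universes")

    a = by_method["lr"].retained
    b = by_method["svm"].retained
    c = by_method["rf"].retained
    venn = {
        "lr_only": a - b - c,
        "svm_only": b - a - c,
        "rf_only": c - a - b,
        "lr_svm": (a & b) - c,
        "lr_rf": (a & c) - b,
        "svm_rf": (b & c) - a,
        "lr_svm_rf": a & b & c,
    }
    union = a | b | c
    nonredundant, dedup_map = deduplicate(union, sequences)
    return ConsensusResult(
        per_method_counts={m: len(by_method[m].retained) for m in ("lr", "svm", "rf")},
        venn_regions=venn,
        union_nonredundant=nonredundant,
        dedup_map=dedup_map,
    )


def write_venn_tsv(result: ConsensusResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tcount\n")
        for region in VENN_REGIONS:
            fh.write(f"{region}\t{len(result.venn_regions[region])}\n")
        fh.write(f"union_nonredundant\t{len(result.union_nonredundant)}\n")
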