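"""Functional summary of selected families via COG categories.

Annotations come from an eggNOG-mapper run parsed by
:func:`panselect.io.read_emapper`.  A protein annotated with several
COG letters (e.g. "JL") contributes fractionally — 1/len to each letter
— so that percentages over the annotated total sum to 100.  A
whole-count mode (each letter counts 1) is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import AnnotationRecord

logger = logging.getLogger(__name__)

__all__ = ["CogDistribution", "cog_distribution", "hypothetical_count", "write_cog_tsv"]


@dataclass
class CogDistribution:
    counts: dict[str, float]  # category -> (fractional) count
    percentages: dict[str, float]  # category -> share of annotated total, in %
    total_annotated: int
    unannotated: int


def cog_distribution(
    records: list[AnnotationRecord],
    subset: set[str] | None = None,
    fractional: bool = True,
) -> CogDistribution:
    """Category counts and percentages over annotated records.

    ``subset`` restricts to the given query IDs; subset members with no
    annotation record are counted as unannotated (with a log note).
    A record with empty ``cog_letters`` is unannotated.
    """
    by_query = {rec.query_id: rec for rec in records}
    if subset is not None:
        absent = subset - set(by_query)
        if absent:
            logger.info("%d subset IDs have no annotation record", len(absent))
        chosen = [by_query[q] for q in sorted(subset & set(by_query))]
        n_missing = len(absent)
    else:
        chosen = records
        n_missing = 0

    counts: dict[str, float] = {}
    annotated = 0
    unannotated = n_missing
    for rec in chosen:
        letters = rec.cog_letters
        if not letters:
            unannotated += 1
            continue
        annotated += 1
        weight = 1.0 / len(letters) if fractional else 1.0
        for letter in letters:
            counts[letter] = counts.get(letter, 0.0) + weight

    total_mass = sum(counts.values())
    percentages = {
        cat: 100.0 * mass / total_mass for cat, mass in counts.items()
    } if total_mass else {}
    return CogDistribution(
        counts=counts,
        percentages=percentages,
        total_annotated=annotated,
        unannotated=unannotated,
    )


def hypothetical_count(descriptions: dict[str, str]) -> int:
    """How many descriptions name a hypothetical protein (case-insensitive)."""
    return sum(
        1 for text in descriptions.values() if "hypothetical protein" in text.lower()
    )


def write_cog_tsv(distributions: dict[str, CogDistribution], path) -> None:
    """Category x subset table of percentages (columns e.g. lr, rf, svm, union)."""
    categories = sorted({c for d in distributions.values() for c in d.counts})
    with open(path, "w") as fh:
        fh.write("category\t" + "\t".join(distributions) + "\n")
        for cat in categories:
            row = "\t".join(
                f"{d.percentages.get(cat, 0.0):.2f}" for d in distributions.values()
            )
            fh.write(f"{cat}\t{row}\n")
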