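"""Core container for a labeled gene presence/absence matrix.

A pangenome here is a binary matrix of genomes (rows) by gene families
(columns), where a 1 means the family has at least one member in that
genome.  For supervised feature extraction every genome additionally
carries a group label drawn from exactly two levels (e.g. "probiotic"
vs. "reference").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PangenomeMatrix", "LabeledPangenome"]


class PangenomeError(ValueError):
    """Raised when a matrix or label table violates the container contract."""


def _check_binary(matrix: pd.DataFrame) -> None:
    values = matrix.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise PangenomeError(
            f"non-binary cell at genome '{matrix.index[i]}', "
            f"family '{matrix.columns[j]}': {values[i, j]!r}"
        )


def _check_unique(ids, kind: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise PangenomeError(f"duplicate {kind} ID(s): {dup}")


@dataclass
class PangenomeMatrix:
    """Unlabeled genomes x families presence/absence matrix."""

    matrix: pd.DataFrame  # genomes x families, int values in {0, 1}

    def __post_init__(self) -> None:
        self.matrix = self.matrix.astype(np.int8, copy=False)
        _check_unique(self.matrix.index, "genome")
        _check_unique(self.matrix.columns, "family")
        _check_binary(self.matrix)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_genomes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_families(self) -> int:
        return self.matrix.shape[1]


@dataclass
class LabeledPangenome(PangenomeMatrix):
    """Presence/absence matrix with a two-level group label per genome.

    ``labels`` is aligned to ``matrix.index``; exactly two distinct label
    levels must be present.  ``group_levels`` preserves the order in which
    the levels were supplied (the second level is treated as the positive
    class in evaluation).
    """

    labels: pd.Series = field(default=None)  # type: ignore[assignment]
    group_levels: tuple[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.labels is None:
            raise PangenomeError("labels are required for a LabeledPangenome")
        self.labels = self.labels.reindex(self.matrix.index)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()
            raise PangenomeError(f"genomes without a label: {missing}")
        levels = pd.unique(self.labels)
        if len(levels) != 2:
            raise PangenomeError(
                f"exactly two label levels required, found {len(levels)}: "
                f"{sorted(map(str, levels))}"
            )
        if self.group_levels is None:
            self.group_levels = (str(levels[0]), str(levels[1]))

    def binary_labels(self) -> np.ndarray:
        """0/1 vector with the second group level coded as 1."""
        return (self.labels.to_numpy() == self.group_levels[1]).astype(np.int8)

    def group_counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    def subset_genomes(self, genome_ids) -> "LabeledPangenome":
        sub = self.matrix.loc[genome_ids]
        return LabeledPangenome(
            matrix=sub,
            labels=self.labels.loc[genome_ids],
            group_levels=self.group_levels,
        )
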