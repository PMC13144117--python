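"""Synthetic two-group pangenome generator with planted discriminative families.

The simulator emulates the structure of a partitioned bacterial pangenome
as a binary genomes x families matrix:

* **core** families are present with high probability (default 0.99) in
  both genome groups;
* **cloud** families are sparse (default presence probability 0.10) and
  group-independent;
* **marker** families are planted discriminative features whose presence
  probability differs between the two groups (``p_marker_a`` vs.
  ``p_marker_b``).

After Bernoulli sampling, every cell is independently inverted with
probability ``flip_noise`` — a single symmetric-error knob that degrades
group separability.  Genomes are exchangeable within a group; no gene
order, sequence content, or phylogenetic correlation is simulated.

Family IDs encode their role ("core_0001", "marker_0003", "cloud_0042")
so recovery can be asserted without a side channel.  When exporting to
disk, :func:`export_pangenome` substitutes opaque aliases and writes the
planted truth to a sidecar file, so a pipeline reading the files cannot
see the roles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pangenome import LabeledPangenome

__all__ = ["SyntheticSpec", "generate_pangenome", "planted_truth", "export_pangenome"]

GROUP_A = "group_A"
GROUP_B = "group_B"


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a simulated labeled pangenome."""

    n_genomes_group_a: int = 100
    n_genomes_group_b: int = 100
    n_core: int = 500
    n_cloud: int = 2000
    n_markers: int = 50
    p_marker_a: float = 0.95
    p_marker_b: float = 0.05
    p_core: float = 0.99
    p_cloud: float = 0.10
    flip_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genomes_group_a", "n_genomes_group_b", "n_core", "n_cloud", "n_markers"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
        for name in ("p_marker_a", "p_marker_b", "p_core", "p_cloud", "flip_noise"):
            value = getattr(self, name)
            if not 0.0 <= float(value) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value!r}")
        if self.n_core + self.n_cloud + self.n_markers < 1:
            raise ValueError("at least one family (core, cloud, or marker) is required")

    @property
    def n_genomes(self) -> int:
        return self.n_genomes_group_a + self.n_genomes_group_b

    @property
    def n_families(self) -> int:
        return self.n_core + self.n_markers + self.n_cloud

    def family_ids(self) -> list[str]:
        """Column order: core, then markers, then cloud."""
        width = max(4, len(str(max(self.n_core, self.n_markers, self.n_cloud, 1))))
        return (
            [f"core_{i:0{width}d}" for i in range(self.n_core)]
            + [f"marker_{i:0{width}d}" for i in range(self.n_markers)]
            + [f"cloud_{i:0{width}d}" for i in range(self.n_cloud)]
        )

    def genome_ids(self) -> list[str]:
        width = max(4, len(str(max(self.n_genomes, 1))))
        return [f"genome_{i:0{width}d}" for i in range(self.n_genomes)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def planted_truth(spec: SyntheticSpec) -> set[str]:
    """IDs of the planted marker families (ground truth for recovery tests)."""
    ids = spec.family_ids()
    return set(ids[spec.n_core : spec.n_core + spec.n_markers])


def generate_pangenome(spec: SyntheticSpec) -> LabeledPangenome:
    """Draw one labeled pangenome from the parameterized generative model.

    A single RNG stream seeded from ``spec.seed`` drives all sampling, so
    an identical spec reproduces a bit-identical matrix.  The first
    ``n_genomes_group_a`` genomes carry the group-A label.
    """
    rng = np.random.default_rng(spec.seed)
    n_a, n_b = spec.n_genomes_group_a, spec.n_genomes_group_b
    n = n_a + n_b

    # Per-cell presence probability, built column-block-wise.
    probs = np.empty((n, spec.n_families), dtype=float)
    probs[:, : spec.n_core] = spec.p_core
    marker_slice = slice(spec.n_core, spec.n_core + spec.n_markers)
    probs[:n_a, marker_slice] = spec.p_marker_a
    probs[n_a:, marker_slice] = spec.p_marker_b
    probs[:, spec.n_core + spec.n_markers :] = spec.p_cloud

    cells = (rng.random(probs.shape) < probs).astype(np.int8)
    if spec.flip_noise > 0:
        flips = rng.random(cells.shape) < spec.flip_noise
        cells = np.where(flips, 1 - cells, cells)

    matrix = pd.DataFrame(cells, index=spec.genome_ids(), columns=spec.family_ids())
    labels = pd.Series(
        [GROUP_A] * n_a + [GROUP_B] * n_b, index=matrix.index, name="group"
    )
    return LabeledPangenome(matrix=matrix, labels=labels, group_levels=(GROUP_A, GROUP_B))


def export_pangenome(
    pangenome: LabeledPangenome,
    spec: SyntheticSpec,
    outdir: str | Path,
    prefix: str = "synthetic",
) -> dict[str, Path]:
    """Write matrix, labels and truth to disk with opaque family aliases.

    The exported Rtab uses aliases ("fam_000001", ...) in place of the
    role-encoding family IDs so that a pipeline consuming the files gets
    no hint of which families are planted markers.  The truth sidecar
    (one alias per line) and the alias map allow tests to score recovery.
    """
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    width = max(6, len(str(pangenome.n_families)))
    alias = {
        fam: f"fam_{i:0{width}d}" for i, fam in enumerate(pangenome.family_ids)
    }
    aliased = LabeledPangenome(
        matrix=pangenome.matrix.rename(columns=alias),
        labels=pangenome.labels,
        group_levels=pangenome.group_levels,
    )
    paths = {
        "rtab": outdir / f"{prefix}.Rtab",
        "labels": outdir / f"{prefix}.labels.tsv",
        "truth": outdir / f"{prefix}.truth.txt",
        "alias_map": outdir / f"{prefix}.alias_map.tsv",
    }
    pio.write_rtab(aliased, paths["rtab"])
    pio.write_labels(aliased.labels, paths["labels"])
    truth = sorted(alias[f] for f in planted_truth(spec))
    paths["truth"].write_text("".join(t + "\n" for t in truth))
    with open(paths["alias_map"], "w") as fh:
        fh.write("family_id\talias\n")
        for fam, al in alias.items():
            fh.write(f"{fam}\t{al}\n")
    return paths
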