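"""Readers and writers for the pipeline's text formats.

Supported dialects:

* **Rtab** — tab-separated presence/absence matrix as exported by
  PPanGGOLiN and friends: first column is the gene-family ID, the header
  row lists genome IDs, cells are 0/1.  Families are rows on disk; the
  in-memory orientation is genomes x families (one transpose).
* **presence CSV** — the comma-separated 0/1 matrix variant; copy
  numbers > 1 are coerced to 1 with a warning, since the downstream
  models are strictly binary.
* **label TSV** — two columns (genome_id, group), no header required.
* **emapper annotations** — the ``.emapper.annotations`` tab-separated
  layout with ``#``-prefixed comment lines; only the query, e-value, COG
  category and description fields are consumed.
* **protein FASTA** — read-only, used for sequence-identity
  deduplication of the consensus set.

All text I/O is UTF-8 and tolerant of trailing newlines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .pangenome import LabeledPangenome, PangenomeError, PangenomeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_rtab",
    "write_rtab",
    "read_presence_csv",
    "read_labels",
    "write_labels",
    "attach_labels",
    "AnnotationRecord",
    "read_emapper",
    "read_protein_fasta",
]

#: Single-letter functional categories of the COG scheme.
COG_ALPHABET = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

#: Default e-value cutoff applied when parsing emapper annotations.
DEFAULT_MAX_EVALUE = 6e-5


def _binary_frame(frame: pd.DataFrame, what: str) -> pd.DataFrame:
    """Validate a families-as-rows frame read from disk and report offenders."""
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        raise PangenomeError(f"duplicate family ID(s) in {what}: {dup}")
    values = frame.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() | ~values.isin((0, 1)).to_numpy()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise PangenomeError(
            f"non-binary cell in {what}: family '{frame.index[i]}', "
            f"genome '{frame.columns[j]}' has value {frame.iloc[i, j]!r}"
        )
    return values.astype(np.int8)


def read_rtab(path: str | Path) -> PangenomeMatrix:
    """Read a PPanGGOLiN-style Rtab file into a genomes x families matrix."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame = _binary_frame(frame, f"Rtab file {path}")
    return PangenomeMatrix(matrix=frame.T)


def write_rtab(pangenome: PangenomeMatrix, path: str | Path) -> None:
    """Write the matrix as Rtab (families as rows, genome columns)."""
    out = pangenome.matrix.T
    out.index.name = "Gene"
    out.to_csv(path, sep="\t")


def read_presence_csv(path: str | Path) -> PangenomeMatrix:
    """Read a comma-separated presence/absence matrix (families as rows).

    Copy-number cells (> 1) are coerced to presence with a warning; the
    downstream models operate on a strictly binary matrix.
    """
    frame = pd.read_csv(path, sep=",", index_col=0)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        raise PangenomeError(f"duplicate family ID(s) in {path}: {dup}")
    values = frame.apply(pd.to_numeric, errors="coerce")
    if values.isna().to_numpy().any():
        i, j = np.argwhere(values.isna().to_numpy())[0]
        raise PangenomeError(
            f"non-numeric cell in {path}: family '{frame.index[i]}', "
            f"genome '{frame.columns[j]}'"
        )
    n_coerced = int((values.to_numpy() > 1).sum())
    if n_coerced:
        logger.warning(
            "%s: coerced %d copy-number cells (>1) to presence", path, n_coerced
        )
        values = values.clip(upper=1)
    if (values.to_numpy() < 0).any():
        raise PangenomeError(f"negative cell value in {path}")
    return PangenomeMatrix(matrix=values.astype(np.int8).T)


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (genome_id, group) TSV into a Series."""
    table = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if table.shape[1] < 2:
        raise PangenomeError(f"label table {path} needs two columns")
    # Tolerate an optional header row.
    if str(table.iloc[0, 0]).lower() in {"genome", "genome_id", "id", "sample"}:
        table = table.iloc[1:]
    labels = pd.Series(
        table.iloc[:, 1].to_numpy(), index=table.iloc[:, 0].to_numpy(), name="group"
    )
    if labels.index.has_duplicates:
        dup = labels.index[labels.index.duplicated()].unique().tolist()
        raise PangenomeError(f"duplicate genome ID(s) in label table: {dup}")
    return labels


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", header=False)


def attach_labels(matrix: PangenomeMatrix, labels: pd.Series) -> LabeledPangenome:
    """Join a label table onto an unlabeled matrix.

    Every genome in the matrix must be labeled; label-table entries for
    genomes absent from the matrix are ignored with a warning.  Exactly
    two label levels must remain among the matched genomes.
    """
    genome_ids = pd.Index(matrix.genome_ids)
    missing = genome_ids.difference(labels.index).tolist()
    if missing:
        raise PangenomeError(f"genomes missing from label table: {missing}")
    extra = labels.index.difference(genome_ids).tolist()
    if extra:
        logger.warning(
            "label table has %d genomes absent from the matrix (ignored): %s",
            len(extra),
            extra[:10],
        )
    matched = labels.loc[genome_ids]
    levels = pd.unique(matched)
    if len(levels) != 2:
        raise PangenomeError(
            f"exactly two label levels required among matched genomes, "
            f"found {len(levels)}: {sorted(map(str, levels))}"
        )
    return LabeledPangenome(
        matrix=matrix.matrix,
        labels=matched,
        group_levels=(str(levels[0]), str(levels[1])),
    )


@dataclass(frozen=True)
class AnnotationRecord:
    """One functional annotation hit for a query protein."""

    query_id: str
    evalue: float
    cog_letters: str  # zero or more single-letter COG categories
    description: str

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.query_id}")
        bad = set(self.cog_letters) - COG_ALPHABET
        if bad:
            raise ValueError(
                f"invalid COG letter(s) {sorted(bad)} for {self.query_id}"
            )


# Column positions in the standard emapper .annotations layout.
_EMAPPER_QUERY = 0
_EMAPPER_EVALUE = 2
_EMAPPER_COG = 6
_EMAPPER_DESC = 7


def read_emapper(
    path: str | Path, max_evalue: float = DEFAULT_MAX_EVALUE
) -> list[AnnotationRecord]:
    """Parse an eggNOG-mapper ``.emapper.annotations`` file.

    Records with e-value strictly greater than ``max_evalue`` are
    dropped (ties at the threshold are retained).  Comment lines start
    with ``#``.  A missing or placeholder ("-") COG field yields empty
    ``cog_letters``.
    """
    records: list[AnnotationRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) <= _EMAPPER_EVALUE:
                raise PangenomeError(
                    f"{path}:{lineno}: malformed row with {len(fields)} fields"
                )
            try:
                evalue = float(fields[_EMAPPER_EVALUE])
            except ValueError as exc:
                raise PangenomeError(
                    f"{path}:{lineno}: unparseable e-value {fields[_EMAPPER_EVALUE]!r}"
                ) from exc
            if evalue > max_evalue:
                continue
            cog = fields[_EMAPPER_COG] if len(fields) > _EMAPPER_COG else ""
            if cog in {"-", ""}:
                cog = ""
            desc = fields[_EMAPPER_DESC] if len(fields) > _EMAPPER_DESC else ""
            records.append(
                AnnotationRecord(
                    query_id=fields[_EMAPPER_QUERY],
                    evalue=evalue,
                    cog_letters=cog,
                    description=desc,
                )
            )
    return records


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record ID."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
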