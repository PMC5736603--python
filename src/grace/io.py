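"""Tabular I/O for gene-level omics matrices, gene annotation and gene sets.

All matrices are tab-separated text with genes as rows and samples as
columns: the first column holds gene identifiers and the header row holds
sample identifiers (the layout of GDAC-style gene-level tables, including
GISTIC2 gene-level copy-number output).  Missing values are written and
read as ``NA`` (an empty cell is also accepted on input).  Genomic
coordinates in the annotation table are 0-based, half-open — the BED
convention.

Orientation is fixed to genes x samples; values are stored as float64 with
``NaN`` for missing.  NA cells are preserved at I/O time — deciding which
genes or samples to exclude is the job of :mod:`grace.preprocess`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: allowed values for :attr:`OmicsMatrix.kind`
MATRIX_KINDS = ("expression", "copy_number", "residual")

#: tokens interpreted as missing on input
NA_TOKENS = ("NA", "")

ANNOTATION_COLUMNS = ("gene_id", "chromosome", "start", "end", "arm", "cytoband")


def _find_duplicates(labels) -> list:
    seen, dups = set(), []
    for x in labels:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class OmicsMatrix:
    """A named gene-by-sample numeric matrix.

    Parameters
    ----------
    kind : str
        One of ``"expression"``, ``"copy_number"`` or ``"residual"``.
    data : pandas.DataFrame
        Float matrix indexed by gene id with sample ids as columns.
    provenance : dict, optional
        For ``residual`` matrices: identifiers of the expression and
        copy-number inputs the residuals were derived from.
    """

    kind: str
    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in MATRIX_KINDS:
            raise ValidationError(
                f"unknown matrix kind {self.kind!r}; expected one of {MATRIX_KINDS}"
            )
        dup_g = _find_duplicates(self.data.index)
        if dup_g:
            raise ValidationError(f"duplicate gene id(s): {dup_g[:5]}")
        dup_s = _find_duplicates(self.data.columns)
        if dup_s:
            raise ValidationError(f"duplicate sample id(s): {dup_s[:5]}")
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            raise ValidationError("matrix values must be numeric")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def has_missing(self) -> bool:
        return bool(self.data.isna().to_numpy().any())

    def subset_genes(self, gene_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.kind, self.data.loc[list(gene_ids)], dict(self.provenance))

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.kind, self.data[list(sample_ids)], dict(self.provenance))


def read_matrix(path, kind: str) -> OmicsMatrix:
    """Read a tab-separated gene x sample matrix.

    The first column carries gene ids, the header row sample ids.  ``NA``
    or empty cells become missing values; any other non-numeric cell is a
    hard error reported with its (gene, sample) coordinates.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str,
        na_values=list(NA_TOKENS), keep_default_na=False,
    )
    raw.index = raw.index.astype(str)
    dup = _find_duplicates(raw.index)
    if dup:
        raise ValidationError(f"{path}: duplicate gene id(s): {dup[:5]}")
    dup = _find_duplicates(raw.columns)
    if dup:
        raise ValidationError(f"{path}: duplicate sample id(s): {dup[:5]}")
    coerced = raw.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & raw.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {raw.iat[g, s]!r} at "
            f"gene {raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    # convert via float() cell-wise: correctly-rounded, so written values
    # survive the round trip bit for bit
    numeric = raw.map(lambda v: float(v) if isinstance(v, str) else np.nan)
    return OmicsMatrix(kind, numeric)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    """Write a matrix as TSV; missing values are written as ``NA``.

    Floats are written with 17 significant digits so that values survive a
    write/read round trip bit for bit.
    """
    matrix.data.to_csv(path, sep="\t", na_rep="NA", index_label="gene_id",
                       float_format="%.17g")


def _chromosome_sort_key(label: str):
    """Natural order for chromosome labels: 1..22 before X, Y, others."""
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


@dataclass
class GeneAnnotation:
    """Genomic location (chromosome, start, end, arm, cytoband) per gene.

    Coordinates are 0-based half-open.  Genes are sortable genomically by
    (chromosome, start) with a deterministic tie-break on gene id.
    """

    data: pd.DataFrame  # indexed by gene_id

    def __post_init__(self):
        required = set(ANNOTATION_COLUMNS) - {"gene_id"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"annotation missing column(s): {sorted(missing)}")
        dup = _find_duplicates(self.data.index)
        if dup:
            raise ValidationError(f"duplicate gene id(s) in annotation: {dup[:5]}")
        starts = self.data["start"].to_numpy()
        ends = self.data["end"].to_numpy()
        bad = np.flatnonzero(~(starts < ends))
        if bad.size:
            g = self.data.index[bad[0]]
            raise ValidationError(
                f"annotation: start >= end for gene {g!r} "
                f"({starts[bad[0]]} >= {ends[bad[0]]})"
            )
        bad_arm = set(self.data["arm"]) - {"p", "q"}
        if bad_arm:
            raise ValidationError(f"annotation: arm must be 'p' or 'q', got {sorted(bad_arm)}")

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    def chromosome_of(self) -> pd.Series:
        return self.data["chromosome"]

    def sorted_gene_ids(self) -> list:
        """Gene ids in genomic order: chromosome, start, then gene id."""
        keys = sorted(
            self.data.index,
            key=lambda g: (
                _chromosome_sort_key(self.data.at[g, "chromosome"]),
                self.data.at[g, "start"],
                str(g),
            ),
        )
        return keys

    def subset(self, gene_ids) -> "GeneAnnotation":
        return GeneAnnotation(self.data.loc[list(gene_ids)])


def read_annotation(path) -> GeneAnnotation:
    """Read a gene annotation TSV with the documented six-column dialect."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str,
                                            "arm": str, "cytoband": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: annotation missing column(s): {sorted(missing)}")
    df = df.set_index("gene_id")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return GeneAnnotation(df)


def write_annotation(annotation: GeneAnnotation, path) -> None:
    annotation.data.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (the GMT payload)."""

    name: str
    sets: Mapping[str, frozenset]

    def __post_init__(self):
        for set_name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {set_name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_name: str) -> frozenset:
        return self.sets[set_name]

    def items(self):
        return self.sets.items()


def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: set name, description, then member genes, tab-separated.

    Duplicate members within a line are collapsed; lines with no members
    are dropped with a warning.  A line with fewer than two fields is an
    error reported with its line number.
    """
    path = Path(path)
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"{path}:{lineno}: malformed GMT line (need name and description)")
            set_name = fields[0]
            if set_name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {set_name!r}")
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                logger.warning("%s:%d: gene set %r has no members; dropped", path, lineno, set_name)
                continue
            sets[set_name] = members
    return GeneSetCollection(name or path.stem, sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for set_name, members in collection.items():
            fh.write("\t".join([set_name, collection.name, *sorted(members)]) + "\n")
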