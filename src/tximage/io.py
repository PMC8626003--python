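"""Reading, validation and filtering of expression matrices, annotations and labels.

The on-disk dialects are deliberately plain:

* expression matrix — TSV/CSV, header row of sample ids, first column gene ids;
* gene annotation — TSV with columns ``gene_id``, ``chromosome``, ``biotype``
  and an optional ``excluded`` (0/1) flag for curated exclusions such as
  multi-haplotype loci;
* labels — TSV with columns ``sample_id``, ``label`` (1 = case, 0 = control).

A one-line recipe to derive the annotation TSV from a GTF lives in the docs;
GTF parsing itself is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "LabeledDataset",
    "ValidationError",
    "read_expression_matrix",
    "read_annotation",
    "read_labels",
    "filter_autosomal",
    "filter_high_expression",
    "filter_protein_coding",
]

AUTOSOMES = {str(i) for i in range(1, 23)}


class ValidationError(ValueError):
    """Raised when an input table violates a documented contract."""


@dataclass
class ExpressionMatrix:
    """Non-negative genes x samples matrix with ordered, unique identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float64

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2 or self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dup):
                raise ValidationError(f"duplicate {kind} ids: {sorted(set(dup))[:5]}")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value {self.values[r, c]} at gene {self.gene_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """New matrix keeping genes where the boolean mask is True (order preserved)."""
        keep = np.asarray(keep, dtype=bool)
        genes = [g for g, k in zip(self.gene_ids, keep) if k]
        return ExpressionMatrix(genes, list(self.sample_ids), self.values[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())


@dataclass
class LabeledDataset:
    """Expression matrix with a binary per-sample label (1 = case, 0 = control)."""

    matrix: ExpressionMatrix
    labels: pd.Series  # index = sample ids, values in {0, 1}

    def __post_init__(self):
        self.labels = self.labels.astype(int)
        missing = [s for s in self.matrix.sample_ids if s not in self.labels.index]
        if missing:
            raise ValidationError(f"samples without label: {missing[:5]}")
        self.labels = self.labels.loc[self.matrix.sample_ids]
        bad = set(self.labels.unique()) - {0, 1}
        if bad:
            raise ValidationError(f"labels must be 0/1, found {sorted(bad)}")

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy()


def _read_table(path, **kw) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, **kw)


def read_expression_matrix(
    path,
    orientation: Literal["genes_in_rows", "samples_in_rows"] = "genes_in_rows",
) -> ExpressionMatrix:
    """Read a delimited expression table and validate it.

    The header row and the first column carry identifiers; the body must be
    numeric and non-negative. ``orientation`` states what the file's *rows*
    are; the returned matrix is always genes x samples.
    """
    df = _read_table(path, index_col=0)
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().to_numpy().any() and not df.isna().to_numpy().any():
        r, c = np.argwhere(body.isna().to_numpy())[0]
        raise ValidationError(
            f"non-numeric cell {df.iat[r, c]!r} at row {df.index[r]!r}, column {df.columns[c]!r} in {path}"
        )
    if body.isna().to_numpy().any():
        r, c = np.argwhere(body.isna().to_numpy())[0]
        raise ValidationError(f"missing value at row {df.index[r]!r}, column {df.columns[c]!r} in {path}")
    if orientation == "samples_in_rows":
        body = body.T
    elif orientation != "genes_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix.from_frame(body)


def read_annotation(path) -> pd.DataFrame:
    """Read the gene annotation TSV (gene_id, chromosome, biotype[, excluded])."""
    ann = _read_table(path, dtype={"gene_id": str, "chromosome": str, "biotype": str})
    required = {"gene_id", "chromosome", "biotype"}
    missing = required - set(ann.columns)
    if missing:
        raise ValidationError(f"annotation missing columns {sorted(missing)}")
    if "excluded" not in ann.columns:
        ann["excluded"] = 0
    ann["excluded"] = ann["excluded"].astype(int).astype(bool)
    if ann["gene_id"].duplicated().any():
        dup = ann.loc[ann["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"duplicate gene ids in annotation: {dup[:5]}")
    if (ann["chromosome"].str.len() == 0).any():
        raise ValidationError("empty chromosome token in annotation")
    return ann.set_index("gene_id")


def read_labels(path) -> pd.Series:
    df = _read_table(path, dtype={"sample_id": str})
    if not {"sample_id", "label"} <= set(df.columns):
        raise ValidationError("labels file needs columns sample_id, label")
    return df.set_index("sample_id")["label"].astype(int)


def normalize_chromosome(token: str) -> str:
    """Strip an optional 'chr' prefix so both annotation dialects compare equal."""
    t = str(token).strip()
    return t[3:] if t.lower().startswith("chr") else t


def _align_annotation(
    m: ExpressionMatrix, ann: pd.DataFrame, missing: str
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    absent = [g for g in m.gene_ids if g not in ann.index]
    if absent:
        if missing == "error":
            raise ValidationError(
                f"{len(absent)} genes missing from annotation (e.g. {absent[:5]}); "
                "pass missing='drop' to discard them"
            )
        if missing != "drop":
            raise ValueError(f"missing policy must be 'error' or 'drop', got {missing!r}")
        keep = np.array([g in ann.index for g in m.gene_ids])
        m = m.subset_genes(keep)
    return m, ann.loc[m.gene_ids]


def filter_autosomal(m: ExpressionMatrix, ann: pd.DataFrame, missing: str = "error") -> ExpressionMatrix:
    """Keep genes on chromosomes 1-22 that are not on the curated exclusion list.

    Sex chromosomes have different ploidy between donors and multi-haplotype
    loci quantify unreliably, so both are removed before training.
    """
    m, ann = _align_annotation(m, ann, missing)
    chrom = ann["chromosome"].map(normalize_chromosome)
    keep = chrom.isin(AUTOSOMES).to_numpy() & ~ann["excluded"].to_numpy()
    out = m.subset_genes(keep)
    if out.n_genes == 0:
        raise ValidationError("no autosomal genes left after filtering")
    return out


def filter_high_expression(
    m: ExpressionMatrix, min_count: float = 10, min_samples: int = 10
) -> ExpressionMatrix:
    """Keep genes with value >= min_count in >= min_samples samples.

    Thresholds are applied to the stored real values, so abundance estimates
    (non-integer) are treated the same way as integer read counts.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    n_high = (m.values >= min_count).sum(axis=1)
    out = m.subset_genes(n_high >= min_samples)
    if out.n_genes == 0:
        raise ValidationError(
            f"no genes with >={min_count} in >={min_samples} samples; lower the thresholds"
        )
    return out


def filter_protein_coding(
    m: ExpressionMatrix, ann: pd.DataFrame, missing: str = "error"
) -> ExpressionMatrix:
    """Keep genes annotated with biotype 'protein_coding'."""
    m, ann = _align_annotation(m, ann, missing)
    keep = (ann["biotype"] == "protein_coding").to_numpy()
    out = m.subset_genes(keep)
    if out.n_genes == 0:
        raise ValidationError("no protein-coding genes left after filtering")
    return out


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("label").to_frame().to_csv(path, sep="\t", index_label="sample_id")
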