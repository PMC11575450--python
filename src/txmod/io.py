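"""Shared data types and readers/writers for count matrices, metadata, and gene sets.

The on-disk formats are deliberately plain: tab-separated count matrices with a
header row of sample identifiers, MatrixMarket triplets with gene/sample sidecar
files, TSV sample metadata, and Broad-dialect GMT gene-set files. Gene
identifiers are treated as opaque strings throughout; no symbol-to-ID mapping is
attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import ParseError, SchemaError, ValidationError

COMPARTMENTS = ("blood", "BAL")
CONDITIONS = ("HIVneg", "HIVpos")
CELL_TYPES = (
    "CD4",
    "CD8",
    "MAIT",
    "NK",
    "B",
    "monocyte",
    "macrophage",
    "CD8_CM",
    "CD8_EM",
    "bulk",
)

REQUIRED_METADATA_COLUMNS = ("sample_id", "compartment", "condition")


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample matrix with identifiers.

    ``counts`` has shape ``(len(genes), len(samples))``. All entries must be
    integral and >= 0; gene and sample identifiers must be unique.
    """

    genes: list[str]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"counts shape {arr.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        _check_unique(self.genes, "gene")
        _check_unique(self.samples, "sample")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere(~np.isfinite(arr) | (arr != np.floor(arr)))[0]
                raise ValidationError(
                    f"non-integer count for gene {self.genes[bad[0]]!r}, "
                    f"sample {self.samples[bad[1]]!r}"
                )
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count for gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}"
            )
        self.counts = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def subset_samples(self, keep: Sequence[str]) -> "CountMatrix":
        idx = [self.samples.index(s) for s in keep]
        return CountMatrix(list(self.genes), list(keep), self.counts[:, idx])

    def subset_genes(self, keep: Sequence[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        idx = [pos[g] for g in keep]
        return CountMatrix(list(keep), list(self.samples), self.counts[idx, :])


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample matrix on log2 scale, with normalization provenance."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"values shape {arr.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        _check_unique(self.genes, "gene")
        _check_unique(self.samples, "sample")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        self.values = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def subset_samples(self, keep: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.samples.index(s) for s in keep]
        return ExpressionMatrix(
            list(self.genes), list(keep), self.values[:, idx], dict(self.normalization)
        )


@dataclass
class GeneModule:
    """Named ordered set of constituent genes with derivation provenance."""

    name: str
    genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"module {self.name!r} has no genes")
        deduped: list[str] = []
        seen: set[str] = set()
        for g in self.genes:
            if g in seen:
                warnings.warn(
                    f"module {self.name!r}: duplicate gene {g!r} removed", stacklevel=2
                )
                continue
            seen.add(g)
            deduped.append(str(g))
        self.genes = deduped


# ---------------------------------------------------------------------------
# Count-matrix I/O
# ---------------------------------------------------------------------------


def _mtx_sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return (
        stem.with_name(stem.name + "_genes.tsv"),
        stem.with_name(stem.name + "_samples.tsv"),
    )


def read_count_matrix(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a gene x sample count matrix from TSV or MatrixMarket.

    TSV: header row of sample ids, first column of gene ids.
    MTX: ``<stem>.mtx`` with sidecar ``<stem>_genes.tsv`` / ``<stem>_samples.tsv``
    holding one identifier per line (row/column order).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"could not parse count TSV {path}: {exc}") from exc
        if frame.columns.size == 0:
            raise ParseError(f"{path}: header row has no sample identifiers")
        for col in frame.columns:
            if not pd.api.types.is_numeric_dtype(frame[col]):
                bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()].index
                raise ParseError(
                    f"{path}: non-numeric count in sample {col!r}"
                    f" (e.g. gene {bad[0]!r})"
                )
        return CountMatrix.from_frame(frame)
    if format == "mtx":
        genes_path, samples_path = _mtx_sidecars(path)
        for side in (genes_path, samples_path):
            if not side.exists():
                raise ParseError(f"missing MatrixMarket sidecar file: {side}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = genes_path.read_text().splitlines()
        samples = samples_path.read_text().splitlines()
        return CountMatrix(genes, samples, np.asarray(mat))
    raise ValueError(f"unknown count-matrix format: {format!r}")


def write_count_matrix(matrix: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        matrix.to_frame().to_csv(path, sep="\t", index_label="gene")
        return
    if format == "mtx":
        genes_path, samples_path = _mtx_sidecars(path)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(matrix.counts))
        genes_path.write_text("\n".join(matrix.genes) + "\n")
        samples_path.write_text("\n".join(matrix.samples) + "\n")
        return
    raise ValueError(f"unknown count-matrix format: {format!r}")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and return a normalized copy.

    Required columns: sample_id, compartment (blood|BAL), condition
    (HIVneg|HIVpos). Optional: cell_type (defaults to "bulk"), total_reads,
    detected_genes (nonnegative integers, may be missing).
    """
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"metadata missing required column {col!r}")
    out = table.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    _check_unique(list(out["sample_id"]), "sample")
    for col, allowed in (("compartment", COMPARTMENTS), ("condition", CONDITIONS)):
        bad = set(out[col].astype(str)) - set(allowed)
        if bad:
            raise ValidationError(f"unknown {col} value(s): {sorted(bad)!r}")
    if "cell_type" not in out.columns:
        out["cell_type"] = "bulk"
    else:
        out["cell_type"] = out["cell_type"].fillna("bulk").astype(str)
        bad = set(out["cell_type"]) - set(CELL_TYPES)
        if bad:
            raise ValidationError(f"unknown cell_type value(s): {sorted(bad)!r}")
    for col in ("total_reads", "detected_genes"):
        if col in out.columns:
            vals = pd.to_numeric(out[col], errors="coerce")
            if ((vals.dropna() < 0) | (vals.dropna() % 1 != 0)).any():
                raise ValidationError(f"{col} must be nonnegative integers")
            out[col] = vals.astype("Int64")
    return out.reset_index(drop=True)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return validate_sample_table(pd.read_csv(path, sep="\t"))


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneModule]:
    """Read a Broad-dialect GMT file: name TAB description TAB gene1 ... geneN."""
    path = Path(path)
    modules: list[GeneModule] = []
    names: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, description = fields[0], fields[1]
        if name in names:
            raise ValidationError(f"{path}:{lineno}: duplicate module name {name!r}")
        names.add(name)
        genes = [g for g in fields[2:] if g]
        modules.append(GeneModule(name, genes, {"description": description}))
    return modules


def write_gmt(modules: Iterable[GeneModule], path: str | Path) -> None:
    lines = []
    for m in modules:
        description = str(m.provenance.get("description", ""))
        lines.append("\t".join([m.name, description, *m.genes]))
    Path(path).write_text("\n".join(lines) + "\n")
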