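"""Core data containers and plain-text readers/writers.

The package works with two expression tables — a single-cell (SC) reference
annotated with cell types, and a spatial-transcriptomics (ST) dataset whose
columns are capture spots with x/y coordinates — plus the mapping result that
places individual cells at jittered coordinates inside spots.

On-disk formats are deliberately plain text: matrix-market triplets with
companion gene/column id files, or delimited tables with a header row and a
leading gene-id column.  Matrix-market indices are 1-based on disk and
0-based in memory; the conversion happens only here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "SCReference",
    "STDataset",
    "MappingResult",
    "read_expression",
    "write_expression",
    "read_coordinates",
    "read_labels",
    "load_sc_reference",
    "load_st_dataset",
    "write_mapping",
    "read_mapping",
]

# matrices smaller than this many entries may be densified freely
DENSE_THRESHOLD = 5_000_000


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})[:5]
        raise ValueError(f"duplicate {what} ids: {dupes}")
    return ids


@dataclass
class ExpressionMatrix:
    """A gene x column matrix (columns are cells or spots) with ids attached.

    ``layer_tag`` distinguishes raw counts from normalized values; counts must
    be non-negative and every value finite.
    """

    values: sp.spmatrix | np.ndarray
    gene_ids: list[str]
    column_ids: list[str]
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        if self.layer_tag not in ("counts", "normalized"):
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.column_ids = _check_unique(self.column_ids, "column")
        if self.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValueError(
                f"id lengths {len(self.gene_ids)}x{len(self.column_ids)} do not "
                f"match matrix shape {self.shape}"
            )
        data = self.values.data if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(data)):
            raise ValueError("expression values must be finite")
        if self.layer_tag == "counts" and data.size and data.min() < 0:
            raise ValueError("counts layer must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.shape[0]

    @property
    def n_columns(self) -> int:
        return self.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        vals = self.values.tocsr()[idx, :] if sp.issparse(self.values) else self.values[idx, :]
        return ExpressionMatrix(vals, [self.gene_ids[i] for i in idx], list(self.column_ids), self.layer_tag)

    def subset_columns(self, cols: Sequence[int]) -> "ExpressionMatrix":
        cols = np.asarray(cols, dtype=int)
        vals = self.values.tocsc()[:, cols] if sp.issparse(self.values) else self.values[:, cols]
        return ExpressionMatrix(
            vals, list(self.gene_ids), [self.column_ids[i] for i in cols], self.layer_tag
        )


@dataclass
class SCReference:
    """Single-cell reference: expression plus per-cell type labels."""

    matrix: ExpressionMatrix
    labels: list[str]
    type_index: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != self.matrix.n_columns:
            raise ValueError("one label per cell required")
        known = set(self.type_index)
        bad = sorted({l for l in self.labels if l not in known})
        if bad:
            raise ValueError(f"labels outside type_index: {bad[:5]}")

    @property
    def n_types(self) -> int:
        return len(self.type_index)

    @property
    def cell_ids(self) -> list[str]:
        return self.matrix.column_ids

    def type_columns(self, type_name: str) -> np.ndarray:
        lab = np.asarray(self.labels)
        return np.flatnonzero(lab == type_name)

    def with_matrix(self, matrix: ExpressionMatrix) -> "SCReference":
        return SCReference(matrix, list(self.labels), list(self.type_index))


@dataclass
class STDataset:
    """Spatial dataset: expression plus one (x, y) coordinate per spot."""

    matrix: ExpressionMatrix
    coords: np.ndarray  # (S, 2)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.matrix.n_columns, 2):
            raise ValueError("need one (x, y) pair per spot")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("spot coordinates must be finite")
        if self.matrix.n_columns < 2:
            raise ValueError("a spatial dataset needs at least 2 spots")

    @property
    def spot_ids(self) -> list[str]:
        return self.matrix.column_ids

    @property
    def n_spots(self) -> int:
        return self.matrix.n_columns


@dataclass
class MappingResult:
    """Final output: one record per mapped cell plus per-spot summaries.

    ``records`` rows are (cell_id, cell_type, spot_id, x, y); ``per_spot_counts``
    holds the estimated cell count of every retained spot; ``compositions`` is
    the per-spot type-proportion table (rows on the simplex) and
    ``global_composition`` the slice-level proportion vector.
    """

    records: pd.DataFrame
    per_spot_counts: dict[str, int]
    compositions: pd.DataFrame | None = None
    global_composition: pd.Series | None = None

    COLUMNS = ("cell_id", "cell_type", "spot_id", "x", "y")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns {missing}")
        if self.records["cell_id"].duplicated().any():
            raise ValueError("each cell_id may appear only once")

    @property
    def n_cells(self) -> int:
        return len(self.records)

    def cells_per_spot(self) -> pd.Series:
        return self.records.groupby("spot_id").size()

    def type_sets_per_spot(self) -> dict[str, set]:
        return {
            s: set(g["cell_type"]) for s, g in self.records.groupby("spot_id")
        }


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, format: str = "mtx_triplet",
                    layer_tag: str = "counts") -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``mtx_triplet`` expects ``<path>`` to be a matrix-market file with
    companion id files ``<stem>.genes.txt`` and ``<stem>.columns.txt`` (one id
    per line).  ``delimited`` expects a TSV/CSV with a header row of column
    ids and a first column of gene ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty expression file: {path}")
    if format == "mtx_triplet":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # noqa: BLE001 - surface as parse error
            raise ValueError(f"malformed matrix-market file {path}: {exc}") from exc
        genes = _read_id_file(path.with_suffix("").with_suffix(".genes.txt"))
        cols = _read_id_file(path.with_suffix("").with_suffix(".columns.txt"))
        return ExpressionMatrix(sp.csr_matrix(mat), genes, cols, layer_tag)
    if format == "delimited":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return ExpressionMatrix(
            df.to_numpy(dtype=float), list(df.index.astype(str)),
            list(df.columns.astype(str)), layer_tag,
        )
    raise ValueError(f"unknown format {format!r}")


def _read_id_file(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"companion id file missing: {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     format: str = "mtx_triplet") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx_triplet":
        vals = matrix.values if sp.issparse(matrix.values) else sp.coo_matrix(matrix.values)
        scipy.io.mmwrite(path, vals)
        base = path.with_suffix("")
        base.with_suffix(".genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
        base.with_suffix(".columns.txt").write_text("\n".join(matrix.column_ids) + "\n")
    elif format == "delimited":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        pd.DataFrame(matrix.dense(), index=matrix.gene_ids,
                     columns=matrix.column_ids).to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: str | Path) -> pd.Series:
    """Two-column delimited file cell_id<TAB>type (no header required)."""
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     names=["cell_id", "cell_type"], dtype=str, comment="#")
    if df["cell_id"].iloc[0] == "cell_id":  # tolerate a header line
        df = df.iloc[1:]
    return pd.Series(df["cell_type"].values, index=df["cell_id"].values)


def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Delimited table spot_id,x,y (header optional)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 3:
        raise ValueError("coordinate table needs spot_id, x, y columns")
    df = df.iloc[:, :3]
    df.columns = ["spot_id", "x", "y"]
    df["spot_id"] = df["spot_id"].astype(str)
    return df.set_index("spot_id").astype(float)


def load_sc_reference(matrix: ExpressionMatrix, labels: pd.Series,
                      min_cells: int = 5) -> SCReference:
    """Attach labels and drop cell types with fewer than ``min_cells`` cells.

    Cells of a removed type are removed with it.  Raises if any column is
    unlabeled or if no type survives.
    """
    missing = [c for c in matrix.column_ids if c not in labels.index]
    if missing:
        raise ValueError(f"unlabeled columns: {missing[:5]}")
    lab = labels.loc[matrix.column_ids].astype(str)
    sizes = lab.value_counts()
    keep_types = sorted(sizes.index[sizes >= min_cells])
    if not keep_types:
        raise ValueError(
            f"all cell types have fewer than min_cells={min_cells} cells"
        )
    dropped = sorted(set(sizes.index) - set(keep_types))
    if dropped:
        warnings.warn(f"dropping under-represented cell types: {dropped}")
    keep_cols = np.flatnonzero(lab.isin(keep_types).to_numpy())
    sub = matrix.subset_columns(keep_cols)
    return SCReference(sub, list(lab.iloc[keep_cols]), keep_types)


def load_st_dataset(matrix: ExpressionMatrix, coords: pd.DataFrame) -> STDataset:
    missing = [s for s in matrix.column_ids if s not in coords.index]
    if missing:
        raise ValueError(f"spots without coordinates: {missing[:5]}")
    xy = coords.loc[matrix.column_ids, ["x", "y"]].to_numpy(dtype=float)
    return STDataset(matrix, xy)


def write_mapping(result: MappingResult, path: str | Path) -> None:
    """Write mapping records plus companion per-spot count/composition files.

    ``<path>`` gets one row per cell (cell_id, cell_type, spot_id, x, y);
    ``<stem>.spot_counts.tsv`` and ``<stem>.compositions.csv`` sit beside it.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.records.loc[:, list(MappingResult.COLUMNS)].to_csv(path, sep="\t", index=False)
    base = path.with_suffix("")
    counts = pd.Series(result.per_spot_counts, name="cell_count")
    counts.rename_axis("spot_id").to_csv(base.with_suffix(".spot_counts.tsv"), sep="\t")
    if result.compositions is not None:
        result.compositions.rename_axis("spot_id").to_csv(base.with_suffix(".compositions.csv"))
    if result.global_composition is not None:
        result.global_composition.rename_axis("cell_type").to_frame("proportion").to_csv(
            base.with_suffix(".global_composition.csv")
        )


def read_mapping(path: str | Path) -> MappingResult:
    path = Path(path)
    records = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "cell_type": str, "spot_id": str})
    base = path.with_suffix("")
    counts_path = base.with_suffix(".spot_counts.tsv")
    per_spot: dict[str, int] = {}
    if counts_path.exists():
        cdf = pd.read_csv(counts_path, sep="\t", dtype={"spot_id": str})
        per_spot = dict(zip(cdf["spot_id"], cdf["cell_count"].astype(int)))
    comp_path = base.with_suffix(".compositions.csv")
    comps = pd.read_csv(comp_path, index_col=0) if comp_path.exists() else None
    glob_path = base.with_suffix(".global_composition.csv")
    glob = (
        pd.read_csv(glob_path, index_col=0)["proportion"] if glob_path.exists() else None
    )
    return MappingResult(records, per_spot, comps, glob)
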