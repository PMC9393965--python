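"""Reading and writing of expression matrices, labels and pipeline artifacts.

The universal input is a cells x genes TPM matrix with unique gene and cell
identifiers plus a per-cell phase label. Two on-disk layouts are supported:

* dense TSV/CSV: header row of gene ids, first column of cell ids;
* MatrixMarket coordinate triplets with one-column gene and cell id sidecars
  (CellRanger-style layout).

All downstream artifacts (ranked lists, IFS curves, rule sets, Boruta
results) round-trip through TSV or JSON via :func:`write_table` and the
matching ``read_*`` functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .phases import normalize_phase

__all__ = [
    "ExpressionMatrix",
    "ExpressionIOError",
    "MalformedHeaderError",
    "DuplicateIdentifierError",
    "NegativeValueError",
    "NonFiniteValueError",
    "DimensionMismatchError",
    "MissingCellError",
    "DuplicateCellError",
    "read_expression",
    "read_labels",
    "write_expression",
    "write_labels",
    "write_table",
    "read_ranked_list",
    "read_ifs_curve",
    "read_ruleset",
    "read_boruta_result",
]


class ExpressionIOError(ValueError):
    """Base class for all expression I/O failures."""


class MalformedHeaderError(ExpressionIOError):
    pass


class DuplicateIdentifierError(ExpressionIOError):
    pass


class NegativeValueError(ExpressionIOError):
    pass


class NonFiniteValueError(ExpressionIOError):
    pass


class DimensionMismatchError(ExpressionIOError):
    pass


class MissingCellError(ExpressionIOError):
    pass


class DuplicateCellError(ExpressionIOError):
    pass


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DuplicateIdentifierError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Cells x genes TPM matrix with identifiers and optional phase labels.

    Invariants enforced at construction: values non-negative and finite,
    identifier lists unique and matching the matrix dimensions, labels (when
    present) one per cell and drawn from the closed phase set.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionMismatchError("expression values must be a 2-D matrix")
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.cell_ids = [str(c).strip() for c in self.cell_ids]
        n_cells, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise DimensionMismatchError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(self.cell_ids) != n_cells:
            raise DimensionMismatchError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if not np.all(np.isfinite(self.values)):
            raise NonFiniteValueError("expression matrix contains NaN or infinite values")
        if np.any(self.values < 0):
            raise NegativeValueError("negative expression value in matrix")
        if self.labels is not None:
            labels = np.asarray([normalize_phase(l) for l in self.labels], dtype=object)
            if len(labels) != n_cells:
                raise DimensionMismatchError(
                    f"{len(labels)} labels for {n_cells} cells"
                )
            self.labels = labels

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def zero_variance_mask(self) -> np.ndarray:
        """Boolean mask over genes that are constant across all cells."""
        return self.values.std(axis=0) == 0.0

    def gene_index(self, genes: list[str]) -> np.ndarray:
        """Column indices for the given gene ids (KeyError on unknown gene)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown gene id: {exc.args[0]!r}") from None

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            self.values[:, idx], [self.gene_ids[i] for i in idx], list(self.cell_ids),
            None if self.labels is None else self.labels.copy(),
        )

    def with_labels(self, labels) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values, list(self.gene_ids), list(self.cell_ids), labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        same_labels = (
            (self.labels is None and other.labels is None)
            or (
                self.labels is not None
                and other.labels is not None
                and list(self.labels) == list(other.labels)
            )
        )
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and same_labels
            and np.allclose(self.values, other.values, rtol=0, atol=1e-12)
        )


@dataclass
class ReadReport:
    """Side information from :func:`read_expression`.

    ``zero_variance_genes`` are flagged (never dropped) so that ranking
    engines can exclude them while the matrix keeps stable column indices.
    """

    zero_variance_genes: list[str] = field(default_factory=list)


def read_expression(
    path: str | Path,
    fmt: str = "dense-tsv",
    cells_as_rows: bool = True,
) -> tuple[ExpressionMatrix, ReadReport]:
    """Read an expression matrix from disk.

    Parameters
    ----------
    path:
        For ``dense-tsv``: the TSV/CSV file. For ``mtx-triplet``: either the
        ``.mtx`` file (sidecars ``<stem>_genes.tsv`` / ``<stem>_cells.tsv``
        beside it) or a directory containing ``matrix.mtx``, ``genes.tsv``
        and ``cells.tsv`` (``barcodes.tsv`` also accepted).
    cells_as_rows:
        Orientation of the on-disk matrix. The in-memory orientation is
        always cells x genes; set this to False to transpose on read.
        Orientation is never auto-detected.
    """
    path = Path(path)
    if fmt == "dense-tsv":
        matrix, row_ids, col_ids = _read_dense(path)
    elif fmt == "mtx-triplet":
        matrix, row_ids, col_ids = _read_mtx(path)
    else:
        raise ValueError(f"unknown expression format: {fmt!r}")
    if not cells_as_rows:
        matrix = matrix.T
        row_ids, col_ids = col_ids, row_ids
    em = ExpressionMatrix(matrix, gene_ids=col_ids, cell_ids=row_ids)
    zv = [g for g, flag in zip(em.gene_ids, em.zero_variance_mask()) if flag]
    return em, ReadReport(zero_variance_genes=zv)


def _read_dense(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(header) < 2:
        raise MalformedHeaderError(f"no data columns in {path}; header row missing?")
    _check_unique([h.strip() for h in header[1:]], "column")
    try:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MalformedHeaderError(f"could not parse dense expression file {path}: {exc}")
    if df.shape[1] == 0:
        raise MalformedHeaderError(f"no data columns in {path}; header row missing?")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MalformedHeaderError(f"non-numeric expression values in {path}: {exc}")
    return values, [str(i) for i in df.index], [str(c) for c in df.columns]


def _read_mtx(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    if path.is_dir():
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        cells_f = path / "cells.tsv"
        if not cells_f.exists():
            cells_f = path / "barcodes.tsv"
    else:
        mtx = path
        genes_f = path.with_name(path.stem + "_genes.tsv")
        cells_f = path.with_name(path.stem + "_cells.tsv")
    for f in (mtx, genes_f, cells_f):
        if not f.exists():
            raise FileNotFoundError(f"mtx-triplet component missing: {f}")
    try:
        sparse = mmread(str(mtx))
    except Exception as exc:
        raise MalformedHeaderError(f"could not parse MatrixMarket file {mtx}: {exc}")
    values = np.asarray(coo_matrix(sparse).todense(), dtype=float)
    row_ids = [l.strip() for l in genes_f.read_text().splitlines() if l.strip()]
    col_ids = [l.strip() for l in cells_f.read_text().splitlines() if l.strip()]
    # MatrixMarket triplet layout stores genes as rows, cells as columns
    # (CellRanger convention); read_expression's orientation flag applies on top.
    if values.shape != (len(row_ids), len(col_ids)):
        raise DimensionMismatchError(
            f"matrix shape {values.shape} does not match sidecars "
            f"({len(row_ids)} genes, {len(col_ids)} cells)"
        )
    return values.T, col_ids, row_ids


def write_expression(em: ExpressionMatrix, path: str | Path, fmt: str = "dense-tsv") -> None:
    """Write a matrix in one of the supported layouts (cells as rows on disk
    for dense TSV; genes x cells triplets for MTX)."""
    path = Path(path)
    if fmt == "dense-tsv":
        df = pd.DataFrame(em.values, index=em.cell_ids, columns=em.gene_ids)
        df.to_csv(path, sep="\t", index_label="cell_id")
    elif fmt == "mtx-triplet":
        path.mkdir(parents=True, exist_ok=True)
        mmwrite(str(path / "matrix.mtx"), coo_matrix(em.values.T))
        (path / "genes.tsv").write_text("\n".join(em.gene_ids) + "\n")
        (path / "cells.tsv").write_text("\n".join(em.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown expression format: {fmt!r}")


def read_labels(path: str | Path, cell_ids: list[str]) -> np.ndarray:
    """Read a two-column (cell_id, phase) TSV and return labels ordered by cell_ids.

    Phase strings map case-insensitively onto {G1, S, G2M}; "G2/M" is accepted.
    Raises a distinct error for a missing cell, an unknown phase string, or a
    duplicated cell.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "phase"], dtype=str)
    if df.shape[1] < 2 or df["phase"].isna().any():
        raise MalformedHeaderError(f"label file {path} is not a two-column TSV")
    # tolerate a header line
    first = str(df.iloc[0, 0]).strip().lower()
    if first in {"cell_id", "cell", "barcode"}:
        df = df.iloc[1:]
    mapping: dict[str, str] = {}
    for cid, phase in zip(df["cell_id"], df["phase"]):
        cid = str(cid).strip()
        if cid in mapping:
            raise DuplicateCellError(f"duplicate cell in label file: {cid!r}")
        mapping[cid] = normalize_phase(phase)
    out = []
    for cid in cell_ids:
        key = str(cid).strip()
        if key not in mapping:
            raise MissingCellError(f"label file is missing cell: {key!r}")
        out.append(mapping[key])
    return np.asarray(out, dtype=object)


def write_labels(cell_ids: list[str], labels, path: str | Path) -> None:
    pd.DataFrame({"cell_id": cell_ids, "phase": list(labels)}).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# Artifact tables


def write_table(obj, path: str | Path) -> None:
    """Write a RankedList / IFSCurve (TSV) or RuleSet / BorutaResult (JSON).

    The matching ``read_*`` function restores an object comparing equal
    (exact identifiers and integers, reals to 1e-12).
    """
    from .boruta import BorutaResult
    from .ifs import IFSCurve
    from .ranking import RankedList
    from .rules import RuleSet

    path = Path(path)
    if isinstance(obj, RankedList):
        obj.to_frame().to_csv(path, sep="\t", index=False)
    elif isinstance(obj, IFSCurve):
        obj.to_frame().to_csv(path, sep="\t", index=False)
    elif isinstance(obj, (RuleSet, BorutaResult)):
        path.write_text(json.dumps(obj.to_json_dict(), indent=1, sort_keys=True))
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def read_ranked_list(path: str | Path):
    from .ranking import RankedList

    return RankedList.from_frame(pd.read_csv(path, sep="\t", dtype={"gene_id": str}))


def read_ifs_curve(path: str | Path):
    from .ifs import IFSCurve

    return IFSCurve.from_frame(pd.read_csv(path, sep="\t"))


def read_ruleset(path: str | Path):
    from .rules import RuleSet

    return RuleSet.from_json_dict(json.loads(Path(path).read_text()))


def read_boruta_result(path: str | Path):
    from .boruta import BorutaResult

    return BorutaResult.from_json_dict(json.loads(Path(path).read_text()))
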