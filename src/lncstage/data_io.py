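"""Input/output and preprocessing of single-cell expression data.

The canonical in-memory container is :class:`ExpressionMatrix`, a thin
wrapper around a genes x cells :class:`pandas.DataFrame` plus an optional
gene-role map (``lncRNA`` / ``mRNA``).  Preprocessing follows the usual
pipeline for log-scale single-cell matrices: collapse duplicate gene
symbols by averaging, drop genes with constant expression, apply a
log2(x+1) transform, then restrict to genes with a known role.

All on-disk formats are plain text: tab-separated tables with a header
row, or MatrixMarket coordinate files with ``genes.txt`` / ``cells.txt``
sidecars for sparse input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

ROLE_LNCRNA = "lncRNA"
ROLE_MRNA = "mRNA"
_VALID_ROLES = frozenset({ROLE_LNCRNA, ROLE_MRNA})


class ParseError(ValueError):
    """Malformed input file (bad header, non-numeric cell, shape mismatch)."""


class EmptyMatrixError(ValueError):
    """All genes removed by a filtering step."""


@dataclass
class ExpressionMatrix:
    """Genes x cells expression matrix with optional gene roles.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with cell identifiers as columns.
        Duplicate gene symbols are permitted before :func:`dedupe_average`;
        cell identifiers must always be unique.
    gene_role
        Mapping gene symbol -> ``"lncRNA"`` or ``"mRNA"``.  ``None`` until
        :func:`split_roles` has been applied.
    """

    values: pd.DataFrame
    gene_role: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ParseError(f"duplicate cell identifier {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("expression matrix contains non-numeric entries")
        if np.isnan(arr).any():
            g, c = np.argwhere(np.isnan(arr))[0]
            raise ParseError(
                "missing value at gene "
                f"{self.values.index[g]!r}, cell {self.values.columns[c]!r}; "
                "missing values are not supported"
            )
        if self.gene_role is not None:
            bad = set(self.gene_role.values()) - _VALID_ROLES
            if bad:
                raise ValueError(f"unknown gene roles: {sorted(bad)}")

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cells(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def lncrnas(self) -> list[str]:
        self._require_roles()
        return [g for g in self.genes if self.gene_role[g] == ROLE_LNCRNA]

    @property
    def mrnas(self) -> list[str]:
        self._require_roles()
        return [g for g in self.genes if self.gene_role[g] == ROLE_MRNA]

    def _require_roles(self) -> None:
        if self.gene_role is None:
            raise ValueError("gene roles not assigned; call split_roles first")

    def gene_values(self, gene: str) -> np.ndarray:
        """Expression vector of one gene across cells (1-D float array)."""
        row = self.values.loc[gene]
        if isinstance(row, pd.DataFrame):
            raise ValueError(f"gene symbol {gene!r} is duplicated")
        return row.to_numpy(dtype=float)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            dict(self.gene_role) if self.gene_role is not None else None,
        )


@dataclass(frozen=True)
class StageAssignment:
    """Assignment of each cell to exactly one developmental stage.

    Stage order follows first appearance in the input, so files listing
    cells stage by stage preserve the intended chronology.
    """

    mapping: Mapping[str, str]

    @property
    def stages(self) -> list[str]:
        seen: dict[str, None] = {}
        for stage in self.mapping.values():
            seen.setdefault(stage, None)
        return list(seen)

    @property
    def cells(self) -> list[str]:
        return list(self.mapping)

    def stage_of(self, cell: str) -> str:
        try:
            return self.mapping[cell]
        except KeyError:
            raise KeyError(f"cell {cell!r} has no stage assignment") from None

    def cells_in(self, stage: str) -> list[str]:
        return [c for c, s in self.mapping.items() if s == stage]

    def validate_against(self, cell_ids: Iterable[str]) -> None:
        """Check the assignment covers exactly the given cells.

        Raises ``ValueError`` naming the first cell missing from the
        assignment, or the first assigned cell absent from the matrix.
        """
        cell_ids = list(cell_ids)
        cell_set = set(cell_ids)
        for c in cell_ids:
            if c not in self.mapping:
                raise ValueError(f"cell {c!r} missing from stage assignment")
        for c in self.mapping:
            if c not in cell_set:
                raise ValueError(f"unknown cell {c!r} in stage assignment")


@dataclass(frozen=True)
class InteractionList:
    """Ordered, de-duplicated list of directed lncRNA -> mRNA pairs."""

    pairs: tuple[tuple[str, str], ...]
    tag: str = "prior"

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], None] = {}
        n_dup = 0
        for p in self.pairs:
            pair = (str(p[0]), str(p[1]))
            if pair in seen:
                n_dup += 1
            seen[pair] = None
        if n_dup:
            logger.warning(
                "%d duplicate pair(s) removed from %s interaction list",
                n_dup,
                self.tag,
            )
        object.__setattr__(self, "pairs", tuple(seen))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.pairs)

    def __contains__(self, pair: object) -> bool:
        return pair in self.pair_set

    @property
    def pair_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.pairs)

    @property
    def lncrnas(self) -> list[str]:
        seen: dict[str, None] = {}
        for u, _ in self.pairs:
            seen.setdefault(u, None)
        return list(seen)

    @property
    def mrnas(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, v in self.pairs:
            seen.setdefault(v, None)
        return list(seen)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def load_expression(
    path: str | Path,
    format: str | None = None,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a raw (untransformed) expression matrix.

    TSV input has gene symbols in the first column and cell identifiers in
    the header.  MTX input is a MatrixMarket coordinate file accompanied by
    one-symbol-per-line ``genes.txt`` and ``cells.txt`` sidecars (override
    with *genes_path* / *cells_path*).  Duplicate (i, j) coordinate entries
    are summed, the standard MatrixMarket convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        return _load_expression_tsv(path)
    if format == "mtx":
        return _load_expression_mtx(path, genes_path, cells_path)
    raise ValueError(f"unknown expression format {format!r}")


def _load_expression_tsv(path: Path) -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no cell columns found (tab-separated?)")
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[i]!r} at "
                f"gene {df.index[i]!r} (row {i + 2}), cell {col!r} (column {j + 2})"
            )
        df[col] = numeric
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float))


def _read_name_file(path: Path) -> list[str]:
    names = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not names:
        raise ParseError(f"{path}: empty name file")
    return names


def _load_expression_mtx(
    path: Path,
    genes_path: str | Path | None,
    cells_path: str | Path | None,
) -> ExpressionMatrix:
    genes_path = Path(genes_path) if genes_path else path.parent / "genes.txt"
    cells_path = Path(cells_path) if cells_path else path.parent / "cells.txt"
    for p in (genes_path, cells_path):
        if not p.exists():
            raise FileNotFoundError(p)
    try:
        mat = scipy.io.mmread(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    dense = np.asarray(
        mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=float
    )
    genes = _read_name_file(genes_path)
    cells = _read_name_file(cells_path)
    if dense.shape != (len(genes), len(cells)):
        raise ParseError(
            f"{path}: matrix shape {dense.shape} does not match "
            f"{len(genes)} genes x {len(cells)} cells in sidecar files"
        )
    return ExpressionMatrix(pd.DataFrame(dense, index=genes, columns=cells))


def load_interactions(path: str | Path, tag: str = "prior") -> InteractionList:
    """Read a two-column (lncRNA, mRNA) TSV; duplicates removed with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns")
    pairs = [
        (str(u), str(v)) for u, v in zip(df.iloc[:, 0], df.iloc[:, 1])
    ]
    return InteractionList(tuple(pairs), tag=tag)


def load_stages(path: str | Path) -> StageAssignment:
    """Read a two-column (cell_id, stage) TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns")
    mapping: dict[str, str] = {}
    for cell, stage in zip(df.iloc[:, 0], df.iloc[:, 1]):
        cell = str(cell)
        if cell in mapping and mapping[cell] != str(stage):
            raise ParseError(
                f"{path}: cell {cell!r} assigned to multiple stages"
            )
        mapping[cell] = str(stage)
    return StageAssignment(mapping)


def load_annotation(path: str | Path) -> dict[str, str]:
    """Read a two-column (gene, role) TSV mapping symbols to lncRNA/mRNA."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns")
    return _annotation_from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _annotation_from_pairs(pairs: Iterable[tuple[str, str]]) -> dict[str, str]:
    ann: dict[str, str] = {}
    for gene, role in pairs:
        gene, role = str(gene), str(role)
        if role not in _VALID_ROLES:
            raise ValueError(
                f"unknown role {role!r} for gene {gene!r}; "
                f"expected one of {sorted(_VALID_ROLES)}"
            )
        if gene in ann and ann[gene] != role:
            raise ValueError(f"conflicting role annotations for gene {gene!r}")
        ann[gene] = role
    return ann


def load_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (set_name, gene) TSV into named gene sets."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns")
    sets: dict[str, set[str]] = {}
    for name, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        sets.setdefault(str(name), set()).add(str(gene))
    return sets


def load_gene_list(path: str | Path) -> list[str]:
    """Read a one-column gene list (header optional lines kept verbatim)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, None] = {}
    for ln in path.read_text().splitlines():
        g = ln.strip().split("\t")[0]
        if g:
            out.setdefault(g, None)
    return list(out)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def dedupe_average(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse duplicated gene symbols to the mean of their rows.

    First-occurrence order of symbols is preserved.
    """
    df = m.values
    if not df.index.duplicated().any():
        return m.copy()
    collapsed = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(collapsed, m.gene_role)


def drop_constant(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes whose expression is identical in every cell."""
    arr = m.values.to_numpy()
    keep = arr.max(axis=1) != arr.min(axis=1)
    if not keep.any():
        raise EmptyMatrixError("empty matrix after filtering constant genes")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d constant gene(s)", n_dropped)
    return ExpressionMatrix(m.values.loc[keep], m.gene_role)


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1); input must be nonnegative."""
    arr = m.values.to_numpy()
    if (arr < 0).any():
        g, c = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative expression value at gene {m.values.index[g]!r}, "
            f"cell {m.values.columns[c]!r}"
        )
    return ExpressionMatrix(np.log2(m.values + 1.0), m.gene_role)


def split_roles(
    m: ExpressionMatrix, annotation: Mapping[str, str] | Iterable[tuple[str, str]]
) -> ExpressionMatrix:
    """Restrict to annotated genes and attach lncRNA/mRNA roles.

    Unannotated genes are dropped (logged).  Raises if the annotation is
    empty, contains conflicting duplicate labels, or if no lncRNA or no
    mRNA remains.
    """
    if not isinstance(annotation, Mapping):
        annotation = _annotation_from_pairs(annotation)
    else:
        annotation = _annotation_from_pairs(annotation.items())
    if not annotation:
        raise ValueError("empty gene-role annotation")
    keep = [g for g in m.genes if g in annotation]
    dropped = m.n_genes - len(keep)
    if dropped:
        logger.info("dropped %d unannotated gene(s)", dropped)
    roles = {g: annotation[g] for g in keep}
    n_lnc = sum(1 for r in roles.values() if r == ROLE_LNCRNA)
    n_mrna = len(roles) - n_lnc
    if n_lnc == 0 or n_mrna == 0:
        raise ValueError(
            f"role split left {n_lnc} lncRNA(s) and {n_mrna} mRNA(s); "
            "need at least one of each"
        )
    return ExpressionMatrix(m.values.loc[keep], roles)


def preprocess(
    m: ExpressionMatrix,
    annotation: Mapping[str, str] | Iterable[tuple[str, str]],
) -> ExpressionMatrix:
    """Full preprocessing: dedupe -> drop constant -> log2(x+1) -> split roles."""
    return split_roles(log_transform(drop_constant(dedupe_average(m))), annotation)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

#: fixed column order of the stage-level edge table
EDGE_COLUMNS = ["stage", "lncRNA", "mRNA", "support", "mean_rho_hat", "min_p"]


def write_edges(stage_networks: Sequence, path: str | Path) -> None:
    """Write stage networks as a TSV with the documented column order.

    Columns: stage, lncRNA, mRNA, support, mean_rho_hat, min_p.
    """
    rows = []
    for net in stage_networks:
        df = net.edges.copy()
        df.insert(0, "stage", net.stage)
        rows.append(df[EDGE_COLUMNS])
    out = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=EDGE_COLUMNS)
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edges(path: str | Path) -> pd.DataFrame:
    """Read back a stage-edge TSV written by :func:`write_edges`."""
    df = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing edge columns {missing}")
    return df[EDGE_COLUMNS]


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a genes x cells TSV readable by :func:`load_expression`."""
    m.values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def write_annotation(roles: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(roles), "role": [roles[g] for g in roles]}
    ).to_csv(path, sep="\t", index=False)


def write_interactions(interactions: InteractionList, path: str | Path) -> None:
    pd.DataFrame(interactions.pairs, columns=["lncRNA", "mRNA"]).to_csv(
        path, sep="\t", index=False
    )


def write_stages(stages: StageAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"cell_id": list(stages.mapping), "stage": list(stages.mapping.values())}
    ).to_csv(path, sep="\t", index=False)
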