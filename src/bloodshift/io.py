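"""Readers and writers for all on-disk formats.

Expression matrices travel as tab-separated text (genes in rows, samples in
columns, UTF-8, ``.`` decimal separator). Single-cell matrices may instead be
MatrixMarket ``.mtx`` with ``genes.tsv``/``barcodes.tsv`` sidecars. Gene sets
use the standard GMT layout. External differential-expression tables are TSV
with columns ``gene, log2fc, p``. All writers emit ``#``-prefixed comment
headers (seed, parameters) which the readers skip.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    ExpressionMatrix,
    ExternalDETable,
    GeneSetCollection,
    MarkerCatalog,
    SampleRecord,
    _find_duplicates,
)

logger = logging.getLogger("bloodshift")

LENGTH_COLUMN = "length"


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_tsv(
    path: str | os.PathLike, has_lengths: bool = False, unit: str = "counts"
) -> ExpressionMatrix:
    """Read a gene x sample expression TSV.

    The first column holds gene IDs, the header row sample IDs. When
    ``has_lengths`` is true a column named ``length`` (case-insensitive)
    carries per-gene transcript lengths in bp and is not treated as a sample.
    Missing or non-numeric cells are rejected with their coordinates; values
    are not imputed. ``unit`` declares what the file holds (``counts``,
    ``tpm`` or ``log_normalized``); validation depends on it.
    """
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, comment="#", dtype=str)
    gene_ids = [str(g) for g in df.index]
    dup = _find_duplicates(gene_ids)
    if dup:
        raise ValueError(f"{path}: duplicate gene ID {dup[0]!r}")
    dup = _find_duplicates(df.columns.tolist())
    if dup:
        raise ValueError(f"{path}: duplicate sample ID {dup[0]!r}")

    lengths = None
    if has_lengths:
        matches = [c for c in df.columns if c.lower() == LENGTH_COLUMN]
        if not matches:
            raise ValueError(f"{path}: has_lengths=True but no '{LENGTH_COLUMN}' column found")
        raw = pd.to_numeric(df[matches[0]], errors="coerce")
        if raw.isna().any():
            g = raw.index[raw.isna()][0]
            raise ValueError(f"{path}: non-numeric length for gene {g!r}")
        lengths = raw.to_numpy()
        df = df.drop(columns=matches)

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: missing or non-numeric value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r} (value {df.iat[r, c]!r})"
        )
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[str(c) for c in df.columns],
        values=numeric.to_numpy(dtype=float),
        unit=unit,
        gene_lengths_bp=lengths,
    )


def write_expression_tsv(
    matrix: ExpressionMatrix,
    path: str | os.PathLike,
    include_lengths: bool = False,
    header_lines: list[str] | None = None,
) -> None:
    df = matrix.to_frame()
    if include_lengths:
        if matrix.gene_lengths_bp is None:
            raise ValueError("matrix has no gene lengths to write")
        df.insert(0, LENGTH_COLUMN, matrix.gene_lengths_bp)
    df.index.name = "gene"
    _write_tsv(df, path, header_lines, index=True)


def _write_tsv(df: pd.DataFrame, path, header_lines: list[str] | None, index: bool) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


# ---------------------------------------------------------------------------
# sample metadata


def read_sample_meta(path: str | os.PathLike) -> list[SampleRecord]:
    """Read sample metadata TSV with columns ``sample_id, donor_id, condition``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "donor_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata is missing columns {sorted(missing)}")
    return [
        SampleRecord(sample_id=r.sample_id, donor_id=r.donor_id, condition=r.condition)
        for r in df.itertuples()
    ]


def write_sample_meta(meta: list[SampleRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "donor_id": [m.donor_id for m in meta],
            "condition": [m.condition for m in meta],
        }
    )
    _write_tsv(df, path, None, index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | os.PathLike, source_tag: str | None = None) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...`` per line.

    The description field is discarded. Duplicate members within a set are
    dropped (first occurrence kept) with a warning.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            members: list[str] = []
            seen: set[str] = set()
            dupes = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dupes += 1
                    continue
                seen.add(g)
                members.append(g)
            if dupes:
                logger.warning(
                    "%s:%d: set %s had %d duplicate members (removed)", path, lineno, name, dupes
                )
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    tag = source_tag if source_tag is not None else Path(path).stem
    return GeneSetCollection(sets=sets, source_tag=tag)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.source_tag or "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# labeled single-cell matrices


def _read_sidecar_ids(path: Path) -> list[str]:
    # one- or two-column TSV; first column is the identifier
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_labeled_sc_matrix(
    matrix_path: str | os.PathLike,
    labels_path: str | os.PathLike,
    genes_path: str | os.PathLike | None = None,
    barcodes_path: str | os.PathLike | None = None,
) -> tuple[ExpressionMatrix, list[str]]:
    """Read a single-cell count matrix plus a barcode -> cell-type label TSV.

    ``matrix_path`` may be MatrixMarket (``.mtx``, genes in rows, with
    ``genes.tsv``/``barcodes.tsv`` sidecars in the same directory unless
    given explicitly) or a dense expression TSV. Cells without a label are
    dropped (count logged). Raises if no barcode overlaps the labels.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        mat = scipy.io.mmread(matrix_path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        gpath = Path(genes_path) if genes_path else matrix_path.parent / "genes.tsv"
        bpath = Path(barcodes_path) if barcodes_path else matrix_path.parent / "barcodes.tsv"
        genes = _read_sidecar_ids(gpath)
        barcodes = _read_sidecar_ids(bpath)
        if mat.shape != (len(genes), len(barcodes)):
            raise ValueError(
                f"{matrix_path}: matrix shape {mat.shape} does not match "
                f"{len(genes)} genes x {len(barcodes)} barcodes"
            )
        em = ExpressionMatrix(gene_ids=genes, sample_ids=barcodes, values=mat, unit="counts")
    else:
        em = read_expression_tsv(matrix_path)

    ldf = pd.read_csv(labels_path, sep="\t", comment="#", dtype=str)
    if ldf.empty:
        raise ValueError(f"{labels_path}: label file has no rows")
    if "barcode" in ldf.columns and "cell_type" in ldf.columns:
        pairs = ldf[["barcode", "cell_type"]]
    elif ldf.shape[1] >= 2:
        # headerless two-column file: the parsed header row is itself data
        first = ldf.columns[:2].tolist()
        pairs = pd.DataFrame(
            [first] + ldf.iloc[:, :2].to_numpy().tolist(), columns=["barcode", "cell_type"]
        )
    else:
        raise ValueError(f"{labels_path}: expected columns barcode, cell_type")
    label_map = dict(zip(pairs["barcode"], pairs["cell_type"]))

    keep = [i for i, bc in enumerate(em.sample_ids) if bc in label_map]
    if not keep:
        raise ValueError(f"{labels_path}: no barcode overlaps the expression matrix")
    dropped = em.n_samples - len(keep)
    if dropped:
        logger.info("dropped %d unlabeled cells of %d", dropped, em.n_samples)
    em = em.subset_samples(np.asarray(keep))
    labels = [label_map[bc] for bc in em.sample_ids]
    logger.info("cell labels: %s", sorted(set(labels)))
    return em, labels


def write_sc_matrix_mtx(
    matrix: ExpressionMatrix, out_dir: str | os.PathLike, name: str = "matrix"
) -> Path:
    """Write counts as MatrixMarket with genes/barcodes sidecars; returns mtx path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mtx = out_dir / f"{name}.mtx"
    scipy.io.mmwrite(mtx, scipy.sparse.coo_matrix(matrix.values))
    (out_dir / "genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n", encoding="utf-8")
    (out_dir / "barcodes.tsv").write_text("\n".join(matrix.sample_ids) + "\n", encoding="utf-8")
    return mtx


def write_cell_labels(barcodes: list[str], labels: list[str], path: str | os.PathLike) -> None:
    df = pd.DataFrame({"barcode": barcodes, "cell_type": labels})
    _write_tsv(df, path, None, index=False)


# ---------------------------------------------------------------------------
# external DE tables


def read_external_de_tables(paths: list[str | os.PathLike]) -> list[ExternalDETable]:
    """Read one TSV per previously published study (columns gene, log2fc, p).

    Dataset IDs are the file-name stems. Duplicate gene rows within a file
    are collapsed to the row with minimum p (a conservative choice for the
    downstream uniqueness filter, which removes genes on significance).
    """
    tables = []
    for path in paths:
        df = pd.read_csv(path, sep="\t", comment="#")
        df.columns = [c.lower() for c in df.columns]
        required = {"gene", "log2fc", "p"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        df = df[["gene", "log2fc", "p"]].copy()
        df["gene"] = df["gene"].astype(str)
        p = pd.to_numeric(df["p"], errors="coerce")
        bad = p.isna() | (p < 0) | (p > 1)
        if bad.any():
            row = df.loc[bad].iloc[0]
            raise ValueError(
                f"{path}: p-value outside [0,1] at gene {row['gene']!r} (p={row['p']!r})"
            )
        df["p"] = p
        n_before = len(df)
        df = df.sort_values(["gene", "p"], kind="mergesort").drop_duplicates("gene", keep="first")
        df = df.sort_index(kind="mergesort").reset_index(drop=True)
        if len(df) != n_before:
            logger.warning(
                "%s: collapsed %d duplicate gene rows (kept min p)", path, n_before - len(df)
            )
        tables.append(ExternalDETable(dataset_id=Path(path).stem, table=df))
    return tables


def write_external_de_table(table: ExternalDETable, path: str | os.PathLike) -> None:
    _write_tsv(table.table, path, None, index=False)


# ---------------------------------------------------------------------------
# marker catalogs


def write_marker_catalog(
    catalog: MarkerCatalog, path: str | os.PathLike, header_lines: list[str] | None = None
) -> None:
    _write_tsv(catalog.scores, path, header_lines, index=False)


def read_marker_catalog(path: str | os.PathLike) -> MarkerCatalog:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str, "cell_type": str})
    cell_types = list(dict.fromkeys(df["cell_type"]))
    markers = {
        ct: df.loc[df["cell_type"] == ct].sort_values("rank")["gene"].tolist()
        for ct in cell_types
    }
    return MarkerCatalog(cell_types=cell_types, markers=markers, scores=df)


def write_table(
    df: pd.DataFrame, path: str | os.PathLike, header_lines: list[str] | None = None
) -> None:
    """Generic TSV writer with optional ``#`` comment header."""
    _write_tsv(df, path, header_lines, index=False)
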