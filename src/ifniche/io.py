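"""Readers, writers, QC filtering and normalization.

File formats: MatrixMarket counts with features/barcodes TSVs, the Visium
``tissue_positions`` CSV (both the headerless 6-column and the headered
dialect), gene sets as TSV (``name<TAB>gene``) or JSON, point tables as
CSV, reports as JSON/TSV.  Readers reject malformed input rather than
coerce it; writers round-trip losslessly at 6 decimal places for
micrometre coordinates.

The variance-stabilizing normalization and cross-sample integration used
by some upstream toolchains are deliberately replaced here by a simple,
fully documented log-normalization (scale each unit to 10,000 molecules,
then natural log); every report header declares this substitution.
"""

from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountsMatrix, GeneSet, PointTable, POINT_REQUIRED
from .errors import EmptyResultError, FormatError, ValidationError
from .lattice import SpotLattice, array_to_um, DEFAULT_DIAMETER_UM, DEFAULT_SPACING_UM

logger = logging.getLogger("ifniche")

NORMALIZATION_NOTE = (
    "normalization: per-unit scaling to 10,000 molecules followed by natural "
    "log (ln(1 + 1e4*c/total)); substituted for variance-stabilizing "
    "normalization and dataset integration"
)


# ---------------------------------------------------------------------------
# counts matrices


def read_counts_mtx(matrix_path, features_path, barcodes_path) -> CountsMatrix:
    """Read a MatrixMarket counts file with matching feature/barcode TSVs."""
    X = scipy.io.mmread(str(matrix_path))
    X = sp.csr_matrix(X)
    genes = pd.read_csv(features_path, sep="\t", header=None).iloc[:, 0].astype(str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str)
    if X.shape[0] != len(genes):
        raise FormatError(
            f"feature count {len(genes)} != matrix rows {X.shape[0]}"
        )
    if X.shape[1] != len(barcodes):
        raise FormatError(
            f"barcode count {len(barcodes)} != matrix columns {X.shape[1]}"
        )
    if barcodes.duplicated().any():
        raise FormatError(f"duplicate barcode {barcodes[barcodes.duplicated()].iloc[0]!r}")
    if X.nnz and not np.allclose(X.data, np.round(X.data)):
        raise FormatError("non-integer entries in raw counts matrix")
    return CountsMatrix(list(genes), list(barcodes), X, layer="raw")


def write_counts_mtx(counts: CountsMatrix, matrix_path, features_path, barcodes_path):
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(counts.X))
    Path(features_path).write_text("".join(f"{g}\n" for g in counts.genes))
    Path(barcodes_path).write_text("".join(f"{u}\n" for u in counts.units))


# ---------------------------------------------------------------------------
# spot positions

_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def read_spot_positions(
    path,
    spacing_um: float = DEFAULT_SPACING_UM,
    diameter_um: float = DEFAULT_DIAMETER_UM,
    um_per_px: float | None = None,
) -> SpotLattice:
    """Read a Visium-dialect tissue_positions CSV into a :class:`SpotLattice`.

    Both dialects are accepted: the headerless 6-column file and the
    headered file whose first column is named ``barcode``.  Micrometre
    coordinates are derived from the array indices via the lattice spacing
    unless a pixel-to-micrometre scale is supplied, in which case the pixel
    coordinates are used.
    """
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = str(first.iloc[0, 0]).strip().lower() == "barcode"
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] != 6:
        raise FormatError(f"expected 6 columns in positions CSV, got {df.shape[1]}")
    df.columns = _POSITION_COLUMNS
    for col in ("in_tissue", "array_row", "array_col"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise FormatError(f"non-numeric value in column {col!r}")
        df[col] = vals.astype(int)
    if df["barcode"].duplicated().any():
        raise FormatError(
            f"duplicate barcode {df.loc[df['barcode'].duplicated(), 'barcode'].iloc[0]!r}"
        )
    if um_per_px is None:
        x, y = array_to_um(df["array_row"], df["array_col"], spacing_um)
    else:
        x = df["pxl_col_in_fullres"].to_numpy(dtype=float) * um_per_px
        y = df["pxl_row_in_fullres"].to_numpy(dtype=float) * um_per_px
    table = pd.DataFrame(
        {
            "spot_id": df["barcode"].astype(str),
            "array_row": df["array_row"],
            "array_col": df["array_col"],
            "x_um": x,
            "y_um": y,
            "in_tissue": df["in_tissue"].astype(bool),
        }
    )
    return SpotLattice(table, spacing_um=spacing_um, diameter_um=diameter_um)


def write_spot_positions(lattice: SpotLattice, path, header: bool = True):
    t = lattice.table
    out = pd.DataFrame(
        {
            "barcode": t["spot_id"],
            "in_tissue": t["in_tissue"].astype(int),
            "array_row": t["array_row"],
            "array_col": t["array_col"],
            "pxl_row_in_fullres": t["y_um"].round(6),
            "pxl_col_in_fullres": t["x_um"].round(6),
        }
    )
    out.to_csv(path, index=False, header=header)


# ---------------------------------------------------------------------------
# QC and normalization


def qc_filter(
    counts: CountsMatrix,
    min_genes: int = 200,
    min_units_per_gene: int = 3,
    max_mito_fraction: float = 0.05,
    mito_prefix: str = "mt-",
) -> CountsMatrix:
    """Remove low-quality units, then low-prevalence genes.

    A unit is kept when it detects at least ``min_genes`` genes and its
    mitochondrial count fraction (genes whose name starts with
    ``mito_prefix``) does not exceed ``max_mito_fraction``; a gene is kept
    when detected in at least ``min_units_per_gene`` retained units.  The
    two filters are iterated to a fixed point, which makes the operation
    idempotent.  Order of retained genes/units is preserved.
    """
    if counts.layer != "raw":
        raise ValidationError("qc_filter expects the raw layer")
    out = counts
    n_pass = 0
    while True:
        X = out.X
        detected = np.asarray((X > 0).sum(axis=0)).ravel()
        totals = out.unit_totals()
        mito = np.array([g.startswith(mito_prefix) for g in out.genes], dtype=bool)
        mito_counts = (
            np.asarray(X[mito].sum(axis=0)).ravel() if mito.any() else np.zeros_like(totals)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
        keep_units = (detected >= min_genes) & (mito_frac <= max_mito_fraction)
        prevalence = np.asarray((X[:, keep_units] > 0).sum(axis=1)).ravel()
        keep_genes = prevalence >= min_units_per_gene
        if keep_units.all() and keep_genes.all():
            break
        n_pass += 1
        logger.info(
            "qc_filter pass %d: removing %d/%d units, %d/%d genes",
            n_pass,
            int((~keep_units).sum()),
            out.n_units,
            int((~keep_genes).sum()),
            out.n_genes,
        )
        out = out.subset(gene_mask=keep_genes, unit_mask=keep_units)
        if out.n_units == 0 or out.n_genes == 0:
            raise EmptyResultError("qc_filter removed every unit or gene")
    return out


def normalize_log10k(counts: CountsMatrix) -> CountsMatrix:
    """Scale each unit to 10,000 molecules and natural-log transform.

    value = ln(1 + 10,000 * c / total_unit).  Zeros stay exactly zero and
    unit ordering is preserved.
    """
    if counts.layer != "raw":
        raise ValidationError("normalize_log10k expects the raw layer")
    totals = counts.unit_totals()
    if (totals <= 0).any():
        bad = counts.units[int(np.argmax(totals <= 0))]
        raise ValidationError(
            f"unit {bad!r} has zero total counts; apply qc_filter first"
        )
    X = sp.csc_matrix(counts.X, dtype=float, copy=True)
    per_entry_total = np.repeat(totals, np.diff(X.indptr))
    X.data = np.log1p(1e4 * X.data / per_entry_total)
    return CountsMatrix(
        list(counts.genes), list(counts.units), sp.csr_matrix(X), layer="lognorm"
    )


# ---------------------------------------------------------------------------
# gene sets, point tables, reports


def read_gene_sets(path) -> list[GeneSet]:
    """Read gene sets from TSV (``name<TAB>gene`` rows) or JSON.

    JSON dialect: ``{"set name": {"genes": [...], "role": "ISG"}}`` or
    ``{"set name": [...]}``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        sets = []
        for name, val in payload.items():
            if isinstance(val, dict):
                sets.append(GeneSet(name, list(val["genes"]), val.get("role", "custom")))
            else:
                sets.append(GeneSet(name, list(val)))
        return sets
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise FormatError("gene-set TSV needs name<TAB>gene columns")
    sets = []
    for name, grp in df.groupby(0, sort=False):
        sets.append(GeneSet(str(name), [str(g) for g in grp[1]]))
    return sets


def write_gene_sets(sets: list[GeneSet], path):
    payload = {s.name: {"genes": s.genes, "role": s.role} for s in sets}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_point_table(path) -> PointTable:
    df = pd.read_csv(path)
    missing = [c for c in POINT_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"point table missing column(s): {missing}")
    return PointTable(df)


def write_point_table(points: PointTable, path):
    points.table.round(6).to_csv(path, index=False)


def write_report(obj, path, substitutions: tuple[str, ...] = (NORMALIZATION_NOTE,)):
    """Write a JSON report with a header declaring method substitutions."""
    payload = {"_meta": {"package": "ifniche", "substitutions": list(substitutions)}}
    payload.update(obj)
    Path(path).write_text(json.dumps(payload, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
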