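"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError

GENE_SET_ROLES = ("ISG", "BZ", "IZ", "matricellular", "custom")


@dataclass
class CountsMatrix:
    """Sparse gene x unit expression matrix.

    ``X`` is genes x units (CSR).  ``layer`` is ``"raw"`` (non-negative
    integers) or ``"lognorm"`` (natural-log normalized values).
    """

    genes: list[str]
    units: list[str]
    X: sp.csr_matrix
    layer: str = "raw"

    def __post_init__(self):
        self.X = sp.csr_matrix(self.X)
        if self.X.shape != (len(self.genes), len(self.units)):
            raise ValidationError(
                f"matrix shape {self.X.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.units)} units"
            )
        if self.layer not in ("raw", "lognorm"):
            raise ValidationError(f"unknown layer {self.layer!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene names")
        if len(set(self.units)) != len(self.units):
            raise ValidationError("duplicate unit identifiers")
        if self.X.nnz:
            data = self.X.data
            if (data < 0).any():
                raise ValidationError("negative entries in counts matrix")
            if self.layer == "raw" and not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer entries in raw counts matrix")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None

    def gene_values(self, gene: str) -> np.ndarray:
        """Dense per-unit vector for one gene."""
        return np.asarray(self.X[self.gene_index(gene)].todense()).ravel()

    def unit_totals(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=0)).ravel()

    def subset(self, gene_mask=None, unit_mask=None) -> "CountsMatrix":
        X = self.X
        genes, units = self.genes, self.units
        if gene_mask is not None:
            gene_mask = np.asarray(gene_mask, dtype=bool)
            X = X[gene_mask]
            genes = [g for g, k in zip(genes, gene_mask) if k]
        if unit_mask is not None:
            unit_mask = np.asarray(unit_mask, dtype=bool)
            X = X[:, unit_mask]
            units = [u for u, k in zip(units, unit_mask) if k]
        return CountsMatrix(genes, units, sp.csr_matrix(X), layer=self.layer)

    def to_anndata(self):
        """Bridge to an :class:`anndata.AnnData` (units as obs, genes as var)."""
        import anndata as ad

        return ad.AnnData(
            X=self.X.T.tocsr(),
            obs=pd.DataFrame(index=self.units),
            var=pd.DataFrame(index=self.genes),
        )


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    role: str = "custom"

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate genes")
        if self.role not in GENE_SET_ROLES:
            raise ValidationError(f"unknown gene-set role {self.role!r}")


POINT_REQUIRED = ("x_um", "y_um", "species")
POINT_OPTIONAL = ("z_um", "cell_id")


@dataclass
class PointTable:
    """Decoded single-molecule records (RNA transcripts or DNA loci).

    Mandatory columns: x_um, y_um, species.  Optional: z_um, cell_id.
    Unknown columns are preserved as opaque metadata.
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in POINT_REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"point table missing column(s): {missing}")
        for c in ("x_um", "y_um", "z_um"):
            if c in self.table.columns:
                vals = pd.to_numeric(self.table[c], errors="coerce")
                if vals.isna().any():
                    bad = self.table.loc[vals.isna(), c].iloc[0]
                    raise ValidationError(f"non-numeric coordinate in {c!r}: {bad!r}")
                self.table[c] = vals.astype(float)
        self.table = self.table.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def has_z(self) -> bool:
        return "z_um" in self.table.columns

    def coords(self, dims: int = 2) -> np.ndarray:
        cols = ["x_um", "y_um"] + (["z_um"] if dims == 3 and self.has_z else [])
        return self.table[cols].to_numpy(dtype=float)

    def filter_species(self, species) -> "PointTable":
        keep = self.table["species"].isin(list(species))
        return PointTable(self.table[keep].reset_index(drop=True).copy())


@dataclass
class CellTable:
    """Segmented cells: cell_id, x_um, y_um, radius_um, cell_type."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"cell_id", "x_um", "y_um", "radius_um", "cell_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"cell table missing column(s): {sorted(missing)}")
        if self.table["cell_id"].duplicated().any():
            raise ValidationError("duplicate cell_id in cell table")
        self.table = self.table.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.table)

    def types(self) -> pd.Series:
        return self.table.set_index("cell_id")["cell_type"]


@dataclass
class NucleusMaskSet:
    """Label image of rasterized nucleus masks.

    ``labels`` is a 2D integer array: 0 = background, k >= 1 = nucleus k.
    ``um_per_px`` converts pixel units to micrometres.
    """

    labels: np.ndarray
    um_per_px: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("label image must be 2D")
        if self.um_per_px <= 0:
            raise ValidationError("um_per_px must be positive")

    @property
    def nucleus_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def mask(self, nucleus_id: int) -> np.ndarray:
        return self.labels == nucleus_id
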