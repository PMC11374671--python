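"""Gene-set scoring, threshold calibration, marker tables and AUROC mapping.

The ISG score of a unit is the sum of its values over an interferon-
stimulated-gene set, on either the raw-count basis (``summed_counts``) or
the log-normalized basis (``summed_lognorm``).  Thresholding the score
against its distribution in a negative-control sample (a genotype unable
to mount a type I interferon response) yields the binary ISG state used by
colony segmentation.  Published default thresholds are also provided:
0.70 for Ifit1 and 0.45 for Rsad2 on the lognorm basis, 3.0 for the ISG
score on spatial lognorm data and 10.0 for the summed-count ISG score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .containers import CountsMatrix, GeneSet
from .errors import (
    BasisMismatchError,
    DegenerateInputError,
    SampleSizeError,
    ValidationError,
)

logger = logging.getLogger("ifniche")

#: published default thresholds, keyed by (quantity, basis)
PUBLISHED_THRESHOLDS = {
    ("Ifit1", "summed_lognorm"): 0.70,
    ("Rsad2", "summed_lognorm"): 0.45,
    ("isg_score", "summed_lognorm"): 3.0,
    ("isg_score", "summed_counts"): 10.0,
}

BASES = ("summed_counts", "summed_lognorm")


@dataclass
class ScoreVector:
    values: np.ndarray
    basis: str
    gene_set: GeneSet
    units: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.basis not in BASES:
            raise ValidationError(f"unknown score basis {self.basis!r}")
        if self.units is not None and len(self.units) != len(self.values):
            raise ValidationError("score vector length != unit count")


@dataclass
class Threshold:
    value: float
    basis: str
    provenance: str = "published_default"
    control_sample_id: str | None = None

    def __post_init__(self):
        if self.value < 0:
            raise ValidationError("threshold must be non-negative")
        if self.basis not in BASES:
            raise ValidationError(f"unknown threshold basis {self.basis!r}")
        if self.provenance not in ("published_default", "calibrated"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")


def published_default_threshold(quantity: str = "isg_score", basis: str = "summed_counts") -> Threshold:
    try:
        value = PUBLISHED_THRESHOLDS[(quantity, basis)]
    except KeyError:
        raise ValidationError(
            f"no published default threshold for ({quantity!r}, {basis!r})"
        ) from None
    return Threshold(value=value, basis=basis, provenance="published_default")


def score_gene_set(counts: CountsMatrix, gene_set: GeneSet, basis: str) -> ScoreVector:
    """Per-unit sum of the gene-set genes on the chosen layer.

    Genes absent from the matrix are warned about and skipped; an empty
    intersection is an error.
    """
    if basis == "summed_counts" and counts.layer != "raw":
        raise BasisMismatchError("summed_counts basis requires the raw layer")
    if basis == "summed_lognorm" and counts.layer != "lognorm":
        raise BasisMismatchError("summed_lognorm basis requires the lognorm layer")
    idx = [i for i, g in enumerate(counts.genes) if g in set(gene_set.genes)]
    n_missing = len(gene_set.genes) - len(idx)
    if n_missing:
        logger.warning(
            "score_gene_set: %d/%d genes of set %r missing from matrix",
            n_missing,
            len(gene_set.genes),
            gene_set.name,
        )
    if not idx:
        raise ValidationError(
            f"no gene of set {gene_set.name!r} is present in the matrix"
        )
    values = np.asarray(counts.X[idx].sum(axis=0)).ravel()
    return ScoreVector(values=values, basis=basis, gene_set=gene_set, units=list(counts.units))


def calibrate_threshold(
    control_scores: ScoreVector,
    quantile: float = 0.99,
    control_sample_id: str | None = None,
) -> Threshold:
    """Threshold at the stated quantile of the negative-control score distribution.

    The empirical quantile is the order statistic at rank ceil(q*n) of the
    sorted control scores.  Requires at least 100 control units.
    """
    n = len(control_scores.values)
    if n < 100:
        raise SampleSizeError(
            f"threshold calibration needs >= 100 control units, got {n}"
        )
    if not (0 < quantile <= 1):
        raise ValidationError("quantile must be in (0, 1]")
    s = np.sort(control_scores.values)
    rank = min(n - 1, max(0, math.ceil(quantile * n) - 1))
    return Threshold(
        value=float(s[rank]),
        basis=control_scores.basis,
        provenance="calibrated",
        control_sample_id=control_sample_id,
    )


def binarize_score(scores: ScoreVector, threshold: Threshold) -> np.ndarray:
    """Binary state per unit: positive iff score >= threshold.

    The boundary is positive: removing spots "with counts of < t" retains
    a spot whose score equals t exactly.
    """
    if scores.basis != threshold.basis:
        raise BasisMismatchError(
            f"score basis {scores.basis!r} != threshold basis {threshold.basis!r}"
        )
    return scores.values >= threshold.value


# ---------------------------------------------------------------------------
# markers


@dataclass
class MarkerTable:
    """Per-gene differential expression summary (one row per marker gene)."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"gene", "ln_fc", "frac_a", "frac_b", "p_value", "p_adj"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"marker table missing column(s): {sorted(missing)}")


def _lognorm_rows(counts: CountsMatrix, unit_idx: np.ndarray) -> np.ndarray:
    return np.asarray(counts.X[:, unit_idx].todense())


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p-value.

    Exact enumeration when both groups have <= 25 observations and the
    pooled data are tie-free; otherwise the normal approximation with tie
    correction.
    """
    method = "asymptotic"
    if len(a) <= 25 and len(b) <= 25:
        pooled = np.concatenate([a, b])
        if len(np.unique(pooled)) == len(pooled):
            method = "exact"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def find_markers(
    counts: CountsMatrix,
    group_a,
    group_b,
    min_lnfc: float = 0.50,
    min_fraction: float = 0.25,
    max_adj_p: float = 1e-4,
    top_n: int = 10,
) -> MarkerTable:
    """Marker genes of group_a vs group_b on the lognorm layer.

    Genes are tested (two-sided Wilcoxon rank-sum) only when
    |lnFC| >= ``min_lnfc`` and the expressed fraction reaches
    ``min_fraction`` in either group; Benjamini-Hochberg adjustment is over
    the tested genes; genes with adjusted p above ``max_adj_p`` are
    dropped; the result is sorted by lnFC (descending, ties broken by gene
    name) and truncated to ``top_n``.  lnFC is the natural-log ratio of
    group means of the de-logged normalized values, with a +1 pseudocount.
    """
    if counts.layer != "lognorm":
        raise ValidationError("find_markers expects the lognorm layer")
    unit_pos = {u: i for i, u in enumerate(counts.units)}
    ia = np.array([unit_pos[u] for u in group_a], dtype=int)
    ib = np.array([unit_pos[u] for u in group_b], dtype=int)
    if len(set(group_a) & set(group_b)):
        raise ValidationError("marker groups overlap")
    if len(ia) < 3 or len(ib) < 3:
        raise ValidationError("each marker group needs >= 3 units")
    Xa = _lognorm_rows(counts, ia)
    Xb = _lognorm_rows(counts, ib)
    frac_a = (Xa > 0).mean(axis=1)
    frac_b = (Xb > 0).mean(axis=1)
    mean_a = np.expm1(Xa).mean(axis=1)
    mean_b = np.expm1(Xb).mean(axis=1)
    ln_fc = np.log(mean_a + 1.0) - np.log(mean_b + 1.0)
    testable = (np.abs(ln_fc) >= min_lnfc) & (
        (frac_a >= min_fraction) | (frac_b >= min_fraction)
    )
    rows = []
    for gi in np.flatnonzero(testable):
        a, b = Xa[gi], Xb[gi]
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = wilcoxon_rank_sum(a, b)
        rows.append(
            {
                "gene": counts.genes[gi],
                "ln_fc": float(ln_fc[gi]),
                "frac_a": float(frac_a[gi]),
                "frac_b": float(frac_b[gi]),
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "ln_fc", "frac_a", "frac_b", "p_value"])
    if len(df):
        df["p_adj"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
        df["p_adj"] = np.maximum(df["p_adj"], df["p_value"])
        df = df[df["p_adj"] <= max_adj_p]
        df = df.sort_values(["ln_fc", "gene"], ascending=[False, True], kind="mergesort")
        df = df.head(top_n).reset_index(drop=True)
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return MarkerTable(df)


# ---------------------------------------------------------------------------
# AUROC mapping


def auroc(score: np.ndarray, positive_mask: np.ndarray) -> float:
    """AUROC of ``score`` discriminating the positive group, via the
    Mann-Whitney identity U/(n1*n2) with mid-ranks for ties."""
    score = np.asarray(score, dtype=float)
    positive_mask = np.asarray(positive_mask, dtype=bool)
    n1 = int(positive_mask.sum())
    n2 = int((~positive_mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValidationError("AUROC needs both positive and negative units")
    r = rankdata(score)
    u = r[positive_mask].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def auroc_map(
    score: ScoreVector, cluster_labels, threshold: float = 0.7
) -> pd.DataFrame:
    """One-vs-rest AUROC per cluster; ``classified`` iff AUROC > threshold.

    This mirrors the mapping of reference-derived gene-set scores onto
    expression clusters, where a cluster is positively classified when its
    score discriminates it from all other units with AUROC > 0.7.
    """
    labels = np.asarray(cluster_labels)
    values = score.values
    if len(labels) != len(values):
        raise ValidationError("cluster labels length != score length")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("auroc_map needs >= 2 clusters")
    if np.ptp(values) == 0:
        raise DegenerateInputError("constant score: AUROC undefined")
    rows = []
    for lab in uniq:
        mask = labels == lab
        if mask.sum() < 2:
            raise ValidationError(f"cluster {lab!r} has fewer than 2 units")
        a = auroc(values, mask)
        rows.append({"cluster": lab, "auroc": a, "classified": bool(a > threshold)})
    return pd.DataFrame(rows)
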