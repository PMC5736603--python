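"""Spearman co-expression ranking and neighbor-bias diagnostics.

Co-expression partners of a query gene are the genes whose expression
profile across samples has the highest positive Spearman rank correlation
with the query's profile.  Run on raw tumor expression this ranking is
biased toward the query's chromosomal neighbors, because somatic copy
number alterations raise and lower whole segments of genes together; run
on copy-number-adjusted residuals the bias largely disappears.  This
module provides the ranking itself plus the three diagnostics that make
the bias visible:

* :func:`autocorrelation_profile` — per-sample correlation between genes
  separated by a fixed number of intervening genes along the chromosome
  (gap 0 = adjacent genes), averaged over samples;
* :func:`neighbor_count_distribution` — for every gene, how many of its
  top-k co-expression partners lie on its own chromosome, aggregated into
  a relative-frequency distribution over 0..k;
* :func:`pool_topk_rho` — the pooled correlation coefficients of all
  top-k partner pairs, split into intra- vs inter-chromosomal.

Partner tables sort by signed rho descending (strength of positive
correlation); ties are broken by gene id so output is reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io import GeneAnnotation, OmicsMatrix

logger = logging.getLogger(__name__)

#: decimal places used when sorting correlations, so that partner order
#: does not depend on float summation order (e.g. block size).
_RHO_DECIMALS = 12


def spearman_rho(u, v) -> float:
    """Spearman rank correlation of two equal-length vectors (ties averaged).

    Returns NaN when either vector is constant.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise DataError("vectors must be one-dimensional and of equal length")
    if u.size < 3:
        raise DataError(f"need at least 3 observations, got {u.size}")
    if np.unique(u).size == 1 or np.unique(v).size == 1:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(u, v).statistic
    return float(rho)


def _rank_standardize(values: np.ndarray) -> np.ndarray:
    """Rank each row (average ranks for ties), then z-score; constant rows -> NaN."""
    ranks = stats.rankdata(values, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks * ranks).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = ranks / norm[:, None]
    z[norm == 0.0] = np.nan
    return z


def correlation_matrix(
    matrix: OmicsMatrix, method: str = "spearman", block_size: int | None = None
) -> np.ndarray:
    """All-pairs gene-gene correlation, computed blockwise over gene rows.

    ``block_size`` bounds the number of rows multiplied at once (a memory
    budget for large gene sets); the result is independent of it.
    Constant genes yield NaN rows/columns.
    """
    if method == "spearman":
        z = _rank_standardize(matrix.values)
    elif method == "pearson":
        v = matrix.values
        vc = v - v.mean(axis=1, keepdims=True)
        norm = np.sqrt((vc * vc).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = vc / norm[:, None]
        z[norm == 0.0] = np.nan
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    n_genes = z.shape[0]
    if block_size is None or block_size >= n_genes:
        return z @ z.T
    out = np.empty((n_genes, n_genes))
    for start in range(0, n_genes, block_size):
        stop = min(start + block_size, n_genes)
        out[start:stop] = z[start:stop] @ z.T
    return out


def _id_tiebreak_order(gene_ids) -> np.ndarray:
    """rank of each gene id in lexicographic order, for deterministic ties."""
    order = np.argsort(np.asarray([str(g) for g in gene_ids]))
    ranks = np.empty(len(gene_ids), dtype=int)
    ranks[order] = np.arange(len(gene_ids))
    return ranks


def topk_partner_indices(
    matrix: OmicsMatrix, k: int, block_size: int | None = None,
    corr: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Top-k partner index matrix for every gene.

    Returns ``(indices, rho)`` of shape (n_genes, k): column j holds each
    gene's rank-(j+1) partner by signed rho descending, gene-id tie-break.
    The query gene itself and constant (NaN) genes are never partners.
    """
    n_genes = len(matrix.gene_ids)
    if k > n_genes - 1:
        logger.warning("k=%d exceeds %d available partners; truncating", k, n_genes - 1)
        k = n_genes - 1
    if corr is None:
        corr = correlation_matrix(matrix, block_size=block_size)
    rho = np.round(corr, _RHO_DECIMALS)
    rho[np.isnan(rho)] = -np.inf
    np.fill_diagonal(rho, -np.inf)
    tie = _id_tiebreak_order(matrix.gene_ids)
    idx = np.empty((n_genes, k), dtype=int)
    out_rho = np.empty((n_genes, k))
    for i in range(n_genes):
        order = np.lexsort((tie, -rho[i]))[:k]
        idx[i] = order
        out_rho[i] = corr[i, order]
    return idx, out_rho


@dataclass
class CoexpressionTable:
    """Ranked co-expression partners of one query gene."""

    query: str
    method: str  # "standard" (raw expression) or "grace" (residuals)
    table: pd.DataFrame  # columns: partner, rho, chromosome, cytoband, rank


def top_coexpressed(
    matrix: OmicsMatrix,
    query: str,
    k: int,
    annotation: GeneAnnotation | None = None,
) -> CoexpressionTable:
    """Top-k co-expression partners of ``query`` by Spearman rho.

    The method tag is ``grace`` iff the matrix holds residuals.  With an
    annotation, partner chromosome and cytoband are included.
    """
    gene_ids = matrix.gene_ids
    if query not in gene_ids:
        raise DataError(f"query gene {query!r} not present in matrix")
    if k > len(gene_ids) - 1:
        logger.warning("k=%d exceeds available partners; truncating", k)
        k = len(gene_ids) - 1
    qi = gene_ids.index(query)
    z = _rank_standardize(matrix.values)
    with np.errstate(invalid="ignore"):
        rho_all = z @ z[qi]
    rho_sort = np.round(rho_all, _RHO_DECIMALS)
    rho_sort[np.isnan(rho_sort)] = -np.inf
    rho_sort[qi] = -np.inf
    order = np.lexsort((_id_tiebreak_order(gene_ids), -rho_sort))[:k]
    partners = [gene_ids[i] for i in order]
    rows = {
        "partner": partners,
        "rho": rho_all[order],
        "rank": np.arange(1, len(order) + 1),
    }
    if annotation is not None:
        ann = annotation.data
        rows["chromosome"] = [ann.at[g, "chromosome"] if g in ann.index else "" for g in partners]
        rows["cytoband"] = [ann.at[g, "cytoband"] if g in ann.index else "" for g in partners]
    else:
        rows["chromosome"] = [""] * len(partners)
        rows["cytoband"] = [""] * len(partners)
    table = pd.DataFrame(rows, columns=["partner", "rho", "chromosome", "cytoband", "rank"])
    method = "grace" if matrix.kind == "residual" else "standard"
    return CoexpressionTable(query, method, table)


@dataclass
class NeighborCountDistribution:
    """Relative frequency of same-chromosome partners among each gene's top k."""

    k: int
    frequencies: np.ndarray  # length k+1, sums to 1
    source: str  # standard | grace | normal | simulated_random

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.size != self.k + 1:
            raise ValueError("need one frequency per count 0..k")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    def total_variation(self, other: "NeighborCountDistribution") -> float:
        """Total-variation distance to another distribution over 0..k."""
        if other.k != self.k:
            raise ValueError("distributions have different support")
        return 0.5 * float(np.abs(self.frequencies - other.frequencies).sum())


def _check_annotated(gene_ids, annotation: GeneAnnotation) -> None:
    missing = [g for g in gene_ids if g not in annotation.data.index]
    if missing:
        raise DataError(f"genes missing from annotation: {missing[:10]}")


def neighbor_count_distribution(
    matrix: OmicsMatrix,
    annotation: GeneAnnotation,
    k: int = 10,
    block_size: int | None = None,
    corr: np.ndarray | None = None,
) -> NeighborCountDistribution:
    """Distribution over genes of same-chromosome counts in their top-k lists."""
    _check_annotated(matrix.gene_ids, annotation)
    idx, _ = topk_partner_indices(matrix, k, block_size=block_size, corr=corr)
    k = idx.shape[1]
    chroms = np.asarray([annotation.data.at[g, "chromosome"] for g in matrix.gene_ids])
    same = chroms[idx] == chroms[:, None]
    counts = same.sum(axis=1)
    freqs = np.bincount(counts, minlength=k + 1) / len(matrix.gene_ids)
    source = "grace" if matrix.kind == "residual" else "standard"
    return NeighborCountDistribution(k, freqs, source)


def random_neighbor_baseline(
    annotation: GeneAnnotation,
    k: int = 10,
    n_draws: int | None = None,
    seed: int = 0,
) -> NeighborCountDistribution:
    """Same-chromosome count distribution if partners were drawn at random.

    For each gene (or each of ``n_draws`` genes sampled with replacement),
    k partners are drawn uniformly without replacement from all other
    genes.  This is the null against which the observed neighbor-count
    distributions are compared.
    """
    gene_ids = annotation.gene_ids
    n_genes = len(gene_ids)
    if n_genes < k + 1:
        raise DataError(f"need at least {k + 1} genes for a top-{k} baseline")
    rng = np.random.default_rng(seed)
    chroms = np.asarray([annotation.data.at[g, "chromosome"] for g in gene_ids])
    if n_draws is None:
        queries = np.arange(n_genes)
    else:
        queries = rng.integers(0, n_genes, size=n_draws)
    counts = np.empty(queries.size, dtype=int)
    for out_i, qi in enumerate(queries):
        partners = rng.choice(n_genes - 1, size=k, replace=False)
        partners[partners >= qi] += 1  # skip the query itself
        counts[out_i] = int((chroms[partners] == chroms[qi]).sum())
    freqs = np.bincount(counts, minlength=k + 1) / counts.size
    return NeighborCountDistribution(k, freqs, "simulated_random")


@dataclass
class AutocorrProfile:
    """Mean per-sample correlation of genes at each genomic gap."""

    gaps: np.ndarray
    mean_r: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gap": self.gaps, "mean_r": self.mean_r, "label": self.label})


def autocorrelation_profile(
    matrix: OmicsMatrix,
    annotation: GeneAnnotation,
    max_gap: int = 40,
    label: str | None = None,
) -> AutocorrProfile:
    """Genomic autocorrelation of a matrix, averaged over samples.

    Genes are sorted genomically.  For each sample and each gap g in
    0..max_gap, the Pearson correlation is taken over all within-
    chromosome gene pairs (i, i+g+1) of that sample's values (gap 0 means
    adjacent genes, i.e. zero genes in between); pairs never cross a
    chromosome boundary.  The profile is the arithmetic mean over samples
    of those per-sample correlations.
    """
    _check_annotated(matrix.gene_ids, annotation)
    order = [g for g in annotation.subset(matrix.gene_ids).sorted_gene_ids()]
    mat = matrix.subset_genes(order)
    chroms = np.asarray([annotation.data.at[g, "chromosome"] for g in order])
    vals = mat.values
    gaps = np.arange(max_gap + 1)
    mean_r = np.full(max_gap + 1, np.nan)
    for g in gaps:
        step = g + 1
        left = np.arange(0, len(order) - step)
        right = left + step
        keep = chroms[left] == chroms[right]
        left, right = left[keep], right[keep]
        if left.size < 3:
            continue
        a = vals[left]
        b = vals[right]
        ac = a - a.mean(axis=0, keepdims=True)
        bc = b - b.mean(axis=0, keepdims=True)
        denom = np.sqrt((ac * ac).sum(axis=0) * (bc * bc).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (ac * bc).sum(axis=0) / denom
        mean_r[g] = float(np.nanmean(r))
    return AutocorrProfile(gaps, mean_r, label or matrix.kind)


def pool_topk_rho(
    matrix: OmicsMatrix,
    annotation: GeneAnnotation,
    k: int = 10,
    block_size: int | None = None,
    corr: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled rho of all top-k partner pairs, split intra/inter-chromosomal.

    Returns raw vectors (density estimation is a plotting concern); their
    combined length is exactly n_genes * k.
    """
    _check_annotated(matrix.gene_ids, annotation)
    idx, rho = topk_partner_indices(matrix, k, block_size=block_size, corr=corr)
    chroms = np.asarray([annotation.data.at[g, "chromosome"] for g in matrix.gene_ids])
    same = chroms[idx] == chroms[:, None]
    return rho[same], rho[~same]
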