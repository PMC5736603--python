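"""Sample intersection and gene filtering for paired expression/CN matrices.

The copy-number adjustment regresses each gene's expression on its own
copy number, so both measurements must exist for the same samples and the
relation must be roughly linear.  Three gene filters enforce that:

* **under-expression** — genes whose expression is exactly zero in more
  than a given fraction of samples (default 10% for RNA-seq; 50% is the
  conventional choice for microarray data where under-detection is more
  prevalent) are dropped;
* **copy-number saturation** — gene-level relative copy number from
  GISTIC-style pipelines is capped for highly amplified genes, which
  destroys linearity; genes whose copy number sits at the saturation
  ceiling in more than 5% of samples (default) are dropped;
* **missing values** — genes with any missing value in either matrix are
  dropped from both.

Both fraction thresholds use a strict inequality ("over X%").  The fixed
filter order is: align samples -> under-expression -> saturation ->
missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .io import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Bookkeeping of which genes each rule removed.

    ``removed`` maps rule name to the ordered list of removed gene ids.
    The invariant ``n_genes_out + |union of removals| == n_genes_in``
    holds for every report produced here.
    """

    n_genes_in: int
    n_genes_out: int
    removed: dict[str, list] = field(default_factory=dict)

    def __post_init__(self):
        union: set = set()
        for ids in self.removed.values():
            union.update(ids)
        if self.n_genes_out + len(union) != self.n_genes_in:
            raise ValueError(
                "inconsistent filter report: "
                f"{self.n_genes_out} kept + {len(union)} removed != {self.n_genes_in} input"
            )

    @property
    def counts(self) -> dict[str, int]:
        return {rule: len(ids) for rule, ids in self.removed.items()}

    def merge(self, other: "FilterReport") -> "FilterReport":
        """Chain two reports applied in sequence (self first)."""
        removed = {rule: list(ids) for rule, ids in self.removed.items()}
        for rule, ids in other.removed.items():
            removed.setdefault(rule, []).extend(ids)
        return FilterReport(self.n_genes_in, other.n_genes_out, removed)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"rule": rule, "gene_id": g}
            for rule, ids in self.removed.items()
            for g in ids
        ]
        return pd.DataFrame(rows, columns=["rule", "gene_id"])


def align_samples(expr: OmicsMatrix, cn: OmicsMatrix) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Restrict both matrices to shared samples and shared genes, same order.

    Sample and gene order follow the expression matrix.  An empty sample
    intersection is an error: the adjustment needs samples with both
    measurements.
    """
    samples = [s for s in expr.sample_ids if s in set(cn.sample_ids)]
    if not samples:
        raise DataError("no samples shared between expression and copy-number matrices")
    genes = [g for g in expr.gene_ids if g in set(cn.gene_ids)]
    if not genes:
        raise DataError("no genes shared between expression and copy-number matrices")
    e = expr.subset_genes(genes).subset_samples(samples)
    c = cn.subset_genes(genes).subset_samples(samples)
    return e, c


def filter_underexpressed(
    expr: OmicsMatrix, max_zero_fraction: float = 0.10
) -> tuple[OmicsMatrix, FilterReport]:
    """Drop genes with zero expression in over ``max_zero_fraction`` of samples.

    Zero detection is exact equality with 0.0 on the stored values;
    callers working on a log scale must filter before transforming.
    The inequality is strict: a gene at exactly the threshold is kept.
    """
    vals = expr.values
    n_samples = vals.shape[1]
    zero_frac = np.nansum(vals == 0.0, axis=1) / n_samples
    drop = zero_frac > max_zero_fraction
    removed = [g for g, d in zip(expr.gene_ids, drop) if d]
    kept = [g for g, d in zip(expr.gene_ids, drop) if not d]
    if not kept:
        logger.warning("under-expression filter removed every gene")
    report = FilterReport(len(expr.gene_ids), len(kept), {"underexpressed": removed})
    return expr.subset_genes(kept), report


def filter_saturated_cn(
    cn: OmicsMatrix,
    max_saturated_fraction: float = 0.05,
    saturation_value: float | None = None,
) -> tuple[OmicsMatrix, FilterReport]:
    """Drop genes whose copy number is saturated in over the given fraction.

    A value is "saturated" iff it equals ``saturation_value``; when that is
    ``None`` the global maximum of the matrix is used, matching the fixed
    amplification ceiling of GISTIC-style gene-level tables.
    """
    vals = cn.values
    if saturation_value is None:
        saturation_value = np.nanmax(vals)
        if saturation_value == np.nanmin(vals):
            # constant matrix: no detection ceiling to infer, nothing saturated
            return cn, FilterReport(len(cn.gene_ids), len(cn.gene_ids), {"saturated_cn": []})
    n_samples = vals.shape[1]
    sat_frac = np.nansum(vals == saturation_value, axis=1) / n_samples
    drop = sat_frac > max_saturated_fraction
    removed = [g for g, d in zip(cn.gene_ids, drop) if d]
    kept = [g for g, d in zip(cn.gene_ids, drop) if not d]
    report = FilterReport(len(cn.gene_ids), len(kept), {"saturated_cn": removed})
    return cn.subset_genes(kept), report


def filter_missing(
    expr: OmicsMatrix, cn: OmicsMatrix
) -> tuple[OmicsMatrix, OmicsMatrix, FilterReport]:
    """Drop genes with any missing value in either matrix, from both."""
    if expr.gene_ids != cn.gene_ids or expr.sample_ids != cn.sample_ids:
        raise DataError("filter_missing expects aligned matrices (run align_samples first)")
    na = np.isnan(expr.values).any(axis=1) | np.isnan(cn.values).any(axis=1)
    removed = [g for g, d in zip(expr.gene_ids, na) if d]
    kept = [g for g, d in zip(expr.gene_ids, na) if not d]
    if not kept:
        logger.warning("missing-value filter removed every gene")
    report = FilterReport(len(expr.gene_ids), len(kept), {"missing": removed})
    return expr.subset_genes(kept), cn.subset_genes(kept), report


def preprocess_pair(
    expr: OmicsMatrix,
    cn: OmicsMatrix,
    max_zero_fraction: float = 0.10,
    max_saturated_fraction: float = 0.05,
    saturation_value: float | None = None,
    drop_missing: bool = True,
) -> tuple[OmicsMatrix, OmicsMatrix, FilterReport]:
    """Run the full fixed-order pipeline on a matrix pair.

    Order: align samples/genes -> under-expression filter on expression ->
    saturation filter on copy number -> (optionally) missing-value filter.
    After each gene filter the partner matrix is subset to keep the pair
    aligned.  Returns the filtered pair and the merged report.
    """
    expr, cn = align_samples(expr, cn)
    expr, rep1 = filter_underexpressed(expr, max_zero_fraction)
    cn = cn.subset_genes(expr.gene_ids)
    cn, rep2 = filter_saturated_cn(cn, max_saturated_fraction, saturation_value)
    expr = expr.subset_genes(cn.gene_ids)
    report = rep1.merge(rep2)
    if drop_missing:
        expr, cn, rep3 = filter_missing(expr, cn)
        report = report.merge(rep3)
    return expr, cn, report
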