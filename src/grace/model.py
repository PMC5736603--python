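"""Model/Results front end tying preprocessing, regression and diagnostics together.

:class:`GraceModel` is constructed from a paired expression / copy-number
dataset (optionally with gene annotation) and holds the filtering
configuration; :meth:`GraceModel.fit` runs the fixed preprocessing
pipeline and the per-gene OLS, returning a :class:`GraceResults` that
carries the fitted coefficients, the residual (copy-number-adjusted)
matrix, the filter report, and the co-expression / diagnostic methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import coexpression as cx
from .errors import DataError
from .io import GeneAnnotation, OmicsMatrix
from .preprocess import FilterReport, preprocess_pair
from .regression import compute_residual_matrix, fit_gene_table


class GraceModel:
    """Copy-number adjustment model for a paired expression/CN dataset.

    Parameters
    ----------
    expr, cn : OmicsMatrix
        Gene x sample expression and relative copy-number matrices.  They
        need not be aligned; alignment is part of fitting.
    annotation : GeneAnnotation, optional
        Required only for the location-aware diagnostics.
    max_zero_fraction, max_saturated_fraction, saturation_value, drop_missing
        Filtering configuration (see :mod:`grace.preprocess`).
    """

    def __init__(
        self,
        expr: OmicsMatrix,
        cn: OmicsMatrix,
        annotation: GeneAnnotation | None = None,
        max_zero_fraction: float = 0.10,
        max_saturated_fraction: float = 0.05,
        saturation_value: float | None = None,
        drop_missing: bool = True,
    ):
        if expr.kind != "expression":
            raise DataError(f"expected an expression matrix, got kind {expr.kind!r}")
        if cn.kind != "copy_number":
            raise DataError(f"expected a copy_number matrix, got kind {cn.kind!r}")
        self.expr = expr
        self.cn = cn
        self.annotation = annotation
        self.max_zero_fraction = max_zero_fraction
        self.max_saturated_fraction = max_saturated_fraction
        self.saturation_value = saturation_value
        self.drop_missing = drop_missing

    @classmethod
    def from_files(cls, expr_path, cn_path, annotation_path=None, **kwargs) -> "GraceModel":
        from .io import read_annotation, read_matrix

        expr = read_matrix(expr_path, "expression")
        cn = read_matrix(cn_path, "copy_number")
        annotation = read_annotation(annotation_path) if annotation_path else None
        return cls(expr, cn, annotation=annotation, **kwargs)

    def fit(self) -> "GraceResults":
        """Align, filter, regress; return the results object."""
        expr, cn, report = preprocess_pair(
            self.expr,
            self.cn,
            max_zero_fraction=self.max_zero_fraction,
            max_saturated_fraction=self.max_saturated_fraction,
            saturation_value=self.saturation_value,
            drop_missing=self.drop_missing,
        )
        params = fit_gene_table(expr, cn)
        residuals = compute_residual_matrix(expr, cn)
        return GraceResults(self, expr, cn, residuals, params, report)


class GraceResults:
    """Fitted copy-number adjustment: coefficients, residuals, diagnostics."""

    def __init__(
        self,
        model: GraceModel,
        expr: OmicsMatrix,
        cn: OmicsMatrix,
        residuals: OmicsMatrix,
        params: pd.DataFrame,
        filter_report: FilterReport,
    ):
        self.model = model
        self.expr = expr
        self.cn = cn
        self.residuals = residuals
        self.params = params
        self.filter_report = filter_report

    # -- basic accessors ---------------------------------------------------

    @property
    def annotation(self) -> GeneAnnotation | None:
        ann = self.model.annotation
        if ann is None:
            return None
        present = [g for g in self.expr.gene_ids if g in ann.data.index]
        return ann.subset(present)

    def _matrix(self, method: str) -> OmicsMatrix:
        if method == "grace":
            return self.residuals
        if method == "standard":
            return self.expr
        raise DataError(f"unknown method {method!r}; use 'grace' or 'standard'")

    def _need_annotation(self) -> GeneAnnotation:
        ann = self.annotation
        if ann is None:
            raise DataError("this diagnostic needs a gene annotation")
        return ann

    # -- co-expression and diagnostics ------------------------------------

    def top_coexpressed(self, query: str, k: int = 10, method: str = "grace"):
        return cx.top_coexpressed(self._matrix(method), query, k, self.annotation)

    def autocorrelation_profile(self, method: str = "grace", max_gap: int = 40):
        return cx.autocorrelation_profile(
            self._matrix(method), self._need_annotation(), max_gap=max_gap,
            label={"grace": "tumor residuals", "standard": "tumor RNA"}[method],
        )

    def neighbor_count_distribution(self, method: str = "grace", k: int = 10):
        return cx.neighbor_count_distribution(self._matrix(method), self._need_annotation(), k=k)

    def pool_topk_rho(self, method: str = "grace", k: int = 10):
        return cx.pool_topk_rho(self._matrix(method), self._need_annotation(), k=k)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary (counts, filters, slope distribution)."""
        from statsmodels.iolib.table import SimpleTable

        n_genes, n_samples = self.expr.shape
        b1 = self.params["b1"]
        lines = [
            ("samples analyzed", f"{n_samples}"),
            ("genes analyzed", f"{n_genes}"),
            ("genes degenerate (constant CN)", f"{int(self.params['degenerate'].sum())}"),
            ("median dosage slope b1", f"{b1.median():.4f}"),
            ("IQR dosage slope b1", f"[{b1.quantile(0.25):.4f}, {b1.quantile(0.75):.4f}]"),
        ]
        for rule, count in self.filter_report.counts.items():
            lines.append((f"genes removed: {rule}", f"{count}"))
        table = SimpleTable(
            [[v] for _, v in lines],
            headers=[""],
            stubs=[k for k, _ in lines],
            title="Copy-number-adjusted co-expression fit",
        )
        return table.as_text()

    def to_files(self, outdir) -> None:
        """Write residual matrix, per-gene fit table and filter report as TSV."""
        from pathlib import Path

        from .io import write_matrix

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_matrix(self.residuals, outdir / "residuals.tsv")
        self.params.to_csv(outdir / "gene_fits.tsv", sep="\t")
        self.filter_report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)

    # -- plotting ----------------------------------------------------------

    def plot_gene(self, gene: str, ax=None):
        """Scatter of copy number vs expression with the fitted line."""
        import matplotlib.pyplot as plt

        if gene not in self.expr.gene_ids:
            raise DataError(f"gene {gene!r} not among the fitted genes")
        if ax is None:
            _, ax = plt.subplots()
        x = self.cn.data.loc[gene].to_numpy()
        y = self.expr.data.loc[gene].to_numpy()
        ax.scatter(x, y, s=8, alpha=0.6)
        b0, b1 = self.params.at[gene, "b0"], self.params.at[gene, "b1"]
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, b0 + b1 * xs, color="crimson")
        ax.set_xlabel("relative copy number")
        ax.set_ylabel("expression")
        ax.set_title(f"{gene}: b1 = {b1:.3f}")
        return ax

    def plot_autocorrelation(self, max_gap: int = 40, ax=None):
        """Raw vs adjusted genomic autocorrelation profiles."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for method in ("standard", "grace"):
            prof = self.autocorrelation_profile(method=method, max_gap=max_gap)
            ax.plot(prof.gaps, prof.mean_r, marker="o", ms=3, label=prof.label)
        ax.set_xlabel("genes in between")
        ax.set_ylabel("mean autocorrelation")
        ax.legend()
        return ax
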