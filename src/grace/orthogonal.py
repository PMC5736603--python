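"""Association of expression (raw RNA or residual RES) with per-sample features.

Orthogonal molecular features — protein abundance, metabolite levels,
drug-response summaries such as Amax — are correlated gene-by-gene with
an expression or residual matrix.  Following field convention, Spearman
rank correlation is used for protein and metabolite levels and Pearson
correlation for drug sensitivity; p-values are two-sided and adjusted
per feature across genes with Benjamini-Hochberg.  Direction filtering
(e.g. "significant negative correlations") is applied after adjustment.

The per-feature significant-gene counts of the two methods (RNA vs RES)
are compared with a one-sided Wilcoxon signed-rank test, exact for up to
25 informative pairs (zero differences are dropped first, the usual
convention) and by normal approximation with tie correction beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .errors import DataError
from .io import OmicsMatrix

FEATURE_KINDS = ("protein", "metabolite", "drug_response")

#: correlation method conventionally used per feature kind
DEFAULT_METHOD = {"protein": "spearman", "metabolite": "spearman", "drug_response": "pearson"}


@dataclass
class FeatureVector:
    """One per-sample feature (protein, metabolite or drug response)."""

    name: str
    kind: str
    values: pd.Series  # indexed by sample id; NA allowed

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise DataError(f"unknown feature kind {self.kind!r}; expected one of {FEATURE_KINDS}")
        self.values = self.values.astype(float)


@dataclass
class AssociationTable:
    """Per-gene correlation of a matrix with one feature."""

    feature: str
    kind: str
    method: str  # spearman | pearson
    label: str  # RNA (raw expression) or RES (residual)
    table: pd.DataFrame  # columns: gene, coef, p, q


def read_feature(path, name: str | None = None, kind: str = "protein") -> FeatureVector:
    """Read a two-column TSV (sample id, value) as a feature vector."""
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""], keep_default_na=False)
    if df.shape[1] < 2:
        raise DataError(f"{path}: feature file needs two columns (sample, value)")
    series = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))
    return FeatureVector(name or str(df.columns[1]), kind, series)


def correlate_feature(
    matrix: OmicsMatrix,
    feature: FeatureVector,
    method: str | None = None,
    min_overlap: int = 3,
) -> AssociationTable:
    """Correlate every gene with a feature, pairwise-complete per gene.

    ``method=None`` picks the conventional method for the feature kind.
    Genes with fewer than ``min_overlap`` complete pairs get NaN
    coefficients; q-values are BH-adjusted across the testable genes.
    """
    if method is None:
        method = DEFAULT_METHOD[feature.kind]
    if method not in ("spearman", "pearson"):
        raise DataError(f"unknown correlation method {method!r}")
    shared = [s for s in matrix.sample_ids if s in feature.values.index]
    fvals = feature.values.reindex(shared).to_numpy()
    valid_f = ~np.isnan(fvals)
    if valid_f.sum() < min_overlap:
        raise DataError(
            f"feature {feature.name!r} overlaps fewer than {min_overlap} matrix samples"
        )
    if np.unique(fvals[valid_f]).size == 1:
        raise DataError(f"feature {feature.name!r} is constant over the shared samples")
    sub = matrix.subset_samples(shared).values
    coef = np.full(sub.shape[0], np.nan)
    pval = np.full(sub.shape[0], np.nan)
    for i in range(sub.shape[0]):
        mask = valid_f & ~np.isnan(sub[i])
        if mask.sum() < min_overlap:
            continue
        x, y = sub[i, mask], fvals[mask]
        if np.unique(x).size == 1 or np.unique(y).size == 1:
            continue
        if method == "spearman":
            res = stats.spearmanr(x, y)
        else:
            res = stats.pearsonr(x, y)
        coef[i], pval[i] = float(res.statistic), float(res.pvalue)
    q = np.full_like(pval, np.nan)
    testable = ~np.isnan(pval)
    if testable.any():
        q[testable] = bh_adjust(pval[testable])
    table = pd.DataFrame(
        {"gene": matrix.gene_ids, "coef": coef, "p": pval, "q": q}
    )
    label = "RES" if matrix.kind == "residual" else "RNA"
    return AssociationTable(feature.name, feature.kind, method, label, table)


def count_significant(assoc: AssociationTable, fdr: float, direction: str = "both") -> int:
    """Number of genes with q < fdr whose coefficient sign matches ``direction``."""
    t = assoc.table
    sig = t["q"] < fdr
    if direction == "negative":
        sig &= t["coef"] < 0
    elif direction == "positive":
        sig &= t["coef"] > 0
    elif direction == "both":
        sig &= t["coef"] != 0
    else:
        raise DataError(f"unknown direction {direction!r}")
    return int(sig.sum())


def wilcoxon_signed_rank(
    differences, alternative: str = "greater", exact_max_n: int = 25
) -> float:
    """One-sided Wilcoxon signed-rank p-value for a vector of differences.

    Zero differences are dropped.  With at most ``exact_max_n``
    informative pairs the exact null distribution of the positive-rank
    sum W+ is enumerated over all 2^n sign assignments (by dynamic
    programming over doubled ranks, so averaged tied ranks stay exact);
    beyond that a normal approximation with tie correction is used.
    ``alternative="greater"`` tests for positive location shift.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DataError("all differences are zero; signed-rank test undefined")
    if alternative not in ("greater", "less"):
        raise DataError(f"unknown alternative {alternative!r}")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if alternative == "less":
        # by symmetry P(W+ <= w) = P(W+ >= n(n+1)/2 - w)
        w_plus = n * (n + 1) / 2 - w_plus
    if n <= exact_max_n:
        r2 = np.rint(2 * ranks).astype(int)  # doubled ranks are integers
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[: total + 1 - r]
        w2 = int(np.rint(2 * w_plus))
        return float(counts[w2:].sum() / 2.0**n)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    return float(stats.norm.sf((w_plus - mu) / sigma))


def compare_methods_paired(counts_rna, counts_res) -> float:
    """One-sided signed-rank p-value that RES counts exceed RNA counts.

    ``counts_rna`` and ``counts_res`` are per-feature significant-gene
    counts for the two methods over the same features (length >= 5).
    """
    a = np.asarray(counts_rna, dtype=float)
    b = np.asarray(counts_res, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("count vectors must be one-dimensional and of equal length")
    if a.size < 5:
        raise DataError(f"need at least 5 paired features, got {a.size}")
    return wilcoxon_signed_rank(b - a, alternative="greater")
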