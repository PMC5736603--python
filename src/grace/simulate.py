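"""Synthetic SCNA + co-regulation data and the partial-correlation oracle.

Two generators are provided.

**Genome-scale generator.**  Genes are laid out on chromosomes with p and
q arms.  Somatic copy-number events are drawn independently per (sample,
arm): with probability ``event_prob`` an arm receives one event covering
a contiguous run of genes (length drawn from a geometric distribution,
clipped to the arm) whose genes all share a single Gaussian amplitude in
log-ratio units around a baseline of 0 — the "relative copy number"
scale of GISTIC-style tables, where co-amplified or co-deleted neighbors
move together.  Expression adds a per-gene dosage effect on that copy
number, module-structured co-regulation through a shared latent factor
per (module, sample), and Gaussian noise:

    expr[g, s] = b0_g + b1_g * cn[g, s] + lambda_g * F[module(g), s] + eps

The latent-factor construction gives within-module pairs an exact
expected correlation lambda^2 / (lambda^2 + sigma^2) on residualized
data, which the tests exploit.

**Pairwise structural model.**  For two genes j, h with copy numbers
Xj, Xh, expression follows the coupled system

    Yj = beta_j Xj + alpha_jh Yh + eps_j
    Yh = beta_h Xh + alpha_hj Yj + eps_h

solvable whenever |alpha_jh * alpha_hj| < 1.  The co-expression signal
of interest is alpha; the copy-number terms confound plain correlation.
:func:`partial_correlation_oracle` computes the correlation of Yj and Yh
conditional on both copy numbers from the precision matrix — the
quantity the residual-correlation shortcut approximates — and
:func:`approximation_study` measures the approximation error over a
parameter grid.

All generators are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import DataError
from .io import GeneAnnotation, OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Full parameterization of the genome-scale generator.

    Defaults are the package's "tumor-like" condition: arm-level events
    in ~30% of (sample, arm) draws with amplitude s.d. 1.0 in log-ratio
    units, a unit dosage effect, and co-regulation strength chosen so
    that within-module correlation on adjusted data is about 0.5 —
    magnitudes comparable to what breast-tumor cohorts show.
    """

    n_genes: int = 1000
    n_samples: int = 200
    n_chromosomes: int = 23
    segment_mean_genes: float = 20.0  # mean genes per segmental event (geometric)
    event_prob: float = 0.3  # per (sample, arm)
    whole_chromosome_prob: float = 0.15  # fraction of events that are whole-chromosome
    amp_sd: float = 1.0  # event amplitude s.d., log-ratio units
    n_modules: int = 30
    module_size_mean: float = 10.0  # Poisson mean, floored at 2
    module_effect: float = 0.7  # latent-factor loading lambda
    b1_mean: float = 1.0  # dosage effect
    b1_sd: float = 0.2
    b0_sd: float = 0.0  # per-gene baseline spread
    noise_sd: float = 0.7
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_samples", "n_chromosomes", "n_modules"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if not 0.0 <= self.event_prob <= 1.0:
            raise DataError("event_prob must lie in [0, 1]")
        for name in ("amp_sd", "noise_sd", "segment_mean_genes", "module_size_mean"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated dataset."""

    annotation: GeneAnnotation
    modules: pd.Series  # gene -> module id, -1 for none
    b1: pd.Series  # gene -> true dosage effect
    b0: pd.Series
    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    # events columns: sample, chromosome, arm, first_gene, n_genes, amplitude

    def module_members(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for g, m in self.modules.items():
            if m >= 0:
                out.setdefault(int(m), []).append(g)
        return out


def _build_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Evenly spread genes over chromosomes; first ~45% of each is the p arm."""
    chrom_sizes = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    chrom_sizes[: config.n_genes % config.n_chromosomes] += 1
    rows = []
    gi = 0
    for ci, size in enumerate(chrom_sizes, start=1):
        p_len = max(1, int(round(size * 0.45))) if size > 1 else 1
        for pos in range(size):
            arm = "p" if pos < p_len else "q"
            band_pos = pos if arm == "p" else pos - p_len
            rows.append(
                {
                    "gene_id": f"G{gi:04d}",
                    "chromosome": f"chr{ci}",
                    "start": pos * 100_000,
                    "end": pos * 100_000 + 50_000,
                    "arm": arm,
                    "cytoband": f"{arm}{band_pos // 5 + 11}.{band_pos % 5 + 1}",
                }
            )
            gi += 1
    df = pd.DataFrame(rows).set_index("gene_id")
    return GeneAnnotation(df)


def _arm_blocks(annotation: GeneAnnotation) -> list[tuple[str, str, np.ndarray]]:
    """(chromosome, arm, row indices) for each arm, in genomic order."""
    ann = annotation.data
    gene_ids = list(ann.index)
    blocks = []
    for (chrom, arm), sub in ann.groupby(["chromosome", "arm"], sort=False):
        idx = np.asarray([gene_ids.index(g) for g in sub.index])
        blocks.append((chrom, arm, idx))
    return blocks


def simulate_scna(config: SimulationConfig) -> tuple[OmicsMatrix, SyntheticTruth]:
    """Draw a relative copy-number matrix with segment-structured events.

    Per (sample, arm): with probability ``event_prob`` a contiguous gene
    segment (geometric length, clipped to the arm) shares one Gaussian
    amplitude added to the 0 baseline.  Also assigns genes to
    co-regulation modules and draws per-gene dosage effects, recorded in
    the returned :class:`SyntheticTruth`.
    """
    rng = np.random.default_rng([config.seed, 1])
    annotation = _build_annotation(config)
    gene_ids = annotation.gene_ids
    n_genes, n_samples = len(gene_ids), config.n_samples
    cn = np.zeros((n_genes, n_samples))
    event_rows = []
    chrom_index: dict[str, np.ndarray] = {}
    for chrom, sub in annotation.data.groupby("chromosome", sort=False):
        order = [g for g in annotation.subset(sub.index).sorted_gene_ids()]
        chrom_index[chrom] = np.asarray([gene_ids.index(g) for g in order])
    warned = False
    for chrom, arm, idx in _arm_blocks(annotation):
        arm_len = idx.size
        chrom_idx = chrom_index[chrom]
        chrom_len = chrom_idx.size
        arm_offset = int(np.flatnonzero(chrom_idx == idx[0])[0])
        hit = rng.random(n_samples) < config.event_prob
        for s in np.flatnonzero(hit):
            if rng.random() < config.whole_chromosome_prob:
                # whole-chromosome gain/loss (aneuploidy)
                start, stop = 0, chrom_len
            else:
                if config.segment_mean_genes >= 1:
                    length = int(rng.geometric(min(1.0, 1.0 / config.segment_mean_genes)))
                else:
                    length = 1
                if length > chrom_len and not warned:
                    logger.warning(
                        "segment of %d genes exceeds chromosome %s (%d genes); clipped",
                        length, chrom, chrom_len,
                    )
                    warned = True
                # a segmental event starts within its arm but, like real
                # broad SCNAs, may run past the arm boundary; it is
                # clipped at the chromosome end
                start = arm_offset + int(rng.integers(0, arm_len))
                stop = min(start + length, chrom_len)
            amp = float(rng.normal(0.0, config.amp_sd))
            cn[chrom_idx[start:stop], s] += amp
            event_rows.append(
                {
                    "sample": f"S{s:03d}",
                    "chromosome": chrom,
                    "arm": arm,
                    "first_gene": gene_ids[chrom_idx[start]],
                    "n_genes": stop - start,
                    "amplitude": amp,
                }
            )
    sample_ids = [f"S{s:03d}" for s in range(n_samples)]
    cn_mat = OmicsMatrix(
        "copy_number", pd.DataFrame(cn, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    )
    # module assignment: sizes ~ Poisson(mean) floored at 2, genes drawn at random
    modules = np.full(n_genes, -1, dtype=int)
    free = rng.permutation(n_genes)
    cursor = 0
    for m in range(config.n_modules):
        size = max(2, int(rng.poisson(config.module_size_mean)))
        take = free[cursor : cursor + size]
        if take.size < 2:
            break
        modules[take] = m
        cursor += size
    b1 = rng.normal(config.b1_mean, config.b1_sd, size=n_genes)
    b0 = rng.normal(0.0, config.b0_sd, size=n_genes) if config.b0_sd > 0 else np.zeros(n_genes)
    truth = SyntheticTruth(
        annotation=annotation,
        modules=pd.Series(modules, index=gene_ids),
        b1=pd.Series(b1, index=gene_ids),
        b0=pd.Series(b0, index=gene_ids),
        events=pd.DataFrame(
            event_rows,
            columns=["sample", "chromosome", "arm", "first_gene", "n_genes", "amplitude"],
        ),
    )
    return cn_mat, truth


def simulate_expression(
    config: SimulationConfig, cn: OmicsMatrix, truth: SyntheticTruth
) -> OmicsMatrix:
    """Layer dosage effect, module co-regulation and noise on a CN matrix."""
    rng = np.random.default_rng([config.seed, 2])
    n_genes, n_samples = cn.shape
    factors = rng.normal(0.0, 1.0, size=(config.n_modules, n_samples))
    noise = rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))
    modules = truth.modules.to_numpy()
    loading = np.where(modules >= 0, config.module_effect, 0.0)
    factor_rows = factors[np.clip(modules, 0, None)]
    expr = (
        truth.b0.to_numpy()[:, None]
        + truth.b1.to_numpy()[:, None] * cn.values
        + loading[:, None] * factor_rows
        + noise
    )
    data = pd.DataFrame(expr, index=cn.data.index, columns=cn.data.columns)
    return OmicsMatrix("expression", data)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, SyntheticTruth]:
    """Convenience: copy number then expression from one config."""
    cn, truth = simulate_scna(config)
    expr = simulate_expression(config, cn, truth)
    return expr, cn, truth


# ---------------------------------------------------------------------------
# pairwise structural model and oracle


@dataclass
class PairwiseModelParams:
    """Parameters of the two-gene structural model."""

    beta_j: float
    beta_h: float
    alpha_jh: float
    alpha_hj: float
    sigma_j: float = 1.0
    sigma_h: float = 1.0

    def __post_init__(self):
        if self.sigma_j <= 0 or self.sigma_h <= 0:
            raise DataError("noise standard deviations must be positive")
        if abs(self.alpha_jh * self.alpha_hj) >= 1:
            raise DataError(
                "model unsolvable: |alpha_jh * alpha_hj| must be < 1, got "
                f"{self.alpha_jh} * {self.alpha_hj}"
            )


def simulate_pairwise(
    params: PairwiseModelParams, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw n samples (Yj, Yh, Xj, Xh) from the coupled two-gene system.

    Copy numbers are independent standard normals; the 2x2 linear system
    is solved exactly per sample.
    """
    rng = np.random.default_rng(seed)
    xj = rng.normal(size=n)
    xh = rng.normal(size=n)
    ej = rng.normal(0.0, params.sigma_j, size=n)
    eh = rng.normal(0.0, params.sigma_h, size=n)
    det = 1.0 - params.alpha_jh * params.alpha_hj
    yj = (params.beta_j * xj + ej + params.alpha_jh * (params.beta_h * xh + eh)) / det
    yh = (params.beta_h * xh + eh + params.alpha_hj * (params.beta_j * xj + ej)) / det
    return yj, yh, xj, xh


def residual_correlation(yj, yh, xj, xh) -> float:
    """GRACE estimate: Pearson correlation of per-gene marginal OLS residuals.

    Each expression vector is regressed on its *own* copy number only —
    the shortcut whose accuracy the oracle below measures.
    """
    from .regression import fit_gene_regression

    rj = fit_gene_regression(yj, xj, "j").residuals
    rh = fit_gene_regression(yh, xh, "h").residuals
    return float(np.corrcoef(rj, rh)[0, 1])


def partial_correlation_oracle(yj, yh, xj, xh) -> float:
    """Correlation of Yj and Yh conditional on (Xj, Xh).

    Computed from the precision matrix: with P the inverse of the 4x4
    sample covariance of (Yj, Yh, Xj, Xh), the partial correlation is
    -P[0,1] / sqrt(P[0,0] * P[1,1]).  Algebraically identical to
    regressing each Y on both X's and correlating the residuals.
    """
    arrs = [np.asarray(v, dtype=float) for v in (yj, yh, xj, xh)]
    n = arrs[0].size
    if any(a.size != n for a in arrs) or n < 10:
        raise DataError("need four equal-length vectors with at least 10 samples")
    cov = np.cov(np.vstack(arrs))
    try:
        prec = np.linalg.inv(cov)
        return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))
    except np.linalg.LinAlgError:
        # exactly collinear input (e.g. Yj == Yh): fall back to the
        # equivalent residual-of-residuals construction, which is still
        # defined as long as the residuals are not degenerate
        X = np.column_stack([np.ones(n), arrs[2], arrs[3]])
        rj = arrs[0] - X @ np.linalg.lstsq(X, arrs[0], rcond=None)[0]
        rh = arrs[1] - X @ np.linalg.lstsq(X, arrs[1], rcond=None)[0]
        if np.allclose(rj, 0.0) or np.allclose(rh, 0.0):
            raise DataError("singular covariance; partial correlation undefined")
        return float(np.corrcoef(rj, rh)[0, 1])


def approximation_study(
    grid: list[PairwiseModelParams] | None = None,
    n: int = 5000,
    seeds: tuple[int, ...] = (0,),
) -> pd.DataFrame:
    """Residual correlation vs partial-correlation oracle over a grid.

    For every parameter set and seed the pairwise model is simulated, the
    residual (marginal-regression) correlation and the conditional-
    correlation oracle are both computed on the same draw, and their
    absolute difference recorded; per-cell results average over seeds.
    ``grid=None`` uses the symmetric default grid beta in {0, 0.5, 1} x
    alpha in {0, 0.2, 0.5} with unit noise.
    """
    if grid is None:
        grid = default_grid()
    rows = []
    for ci, params in enumerate(grid):
        res_vals, oracle_vals = [], []
        for seed in seeds:
            yj, yh, xj, xh = simulate_pairwise(params, n, seed=seed * 10007 + ci)
            res_vals.append(residual_correlation(yj, yh, xj, xh))
            oracle_vals.append(partial_correlation_oracle(yj, yh, xj, xh))
        res_corr = float(np.mean(res_vals))
        partial_corr = float(np.mean(oracle_vals))
        rows.append(
            {
                "beta_j": params.beta_j,
                "beta_h": params.beta_h,
                "alpha_jh": params.alpha_jh,
                "alpha_hj": params.alpha_hj,
                "sigma_j": params.sigma_j,
                "sigma_h": params.sigma_h,
                "residual_corr": res_corr,
                "partial_corr": partial_corr,
                "abs_error": abs(res_corr - partial_corr),
            }
        )
    return pd.DataFrame(rows)


def module_partner_precision(matrix: OmicsMatrix, truth: SyntheticTruth, k: int = 10) -> pd.Series:
    """Per-gene fraction of top-k partners sharing the gene's true module.

    Genes without a module score 0 (no partner can share their module).
    Used to compare functional recovery of the standard and adjusted
    rankings on simulated data.
    """
    from .coexpression import topk_partner_indices

    idx, _ = topk_partner_indices(matrix, k)
    modules = truth.modules.reindex(matrix.gene_ids).to_numpy()
    same = (modules[idx] == modules[:, None]) & (modules[:, None] >= 0)
    return pd.Series(same.mean(axis=1), index=matrix.gene_ids)


def default_grid(
    betas=(0.0, 0.5, 1.0), alphas=(0.0, 0.2, 0.5), sigma: float = 1.0
) -> list[PairwiseModelParams]:
    """Symmetric beta x alpha grid (both genes share beta, both alphas equal)."""
    return [
        PairwiseModelParams(b, b, a, a, sigma, sigma) for b in betas for a in alphas
    ]
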