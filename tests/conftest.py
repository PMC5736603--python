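import numpy as np
import pandas as pd
import pytest

from grace.io import GeneAnnotation, OmicsMatrix


def make_matrix(values, gene_ids=None, sample_ids=None, kind="expression"):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"G{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(values.shape[1])]
    return OmicsMatrix(kind, pd.DataFrame(values, index=gene_ids, columns=sample_ids))


def make_annotation(chromosomes, gene_ids=None, starts=None):
    """Annotation from a list of chromosome labels, one per gene."""
    gene_ids = gene_ids or [f"G{i}" for i in range(len(chromosomes))]
    starts = starts if starts is not None else [100 * i for i in range(len(chromosomes))]
    df = pd.DataFrame(
        {
            "chromosome": chromosomes,
            "start": starts,
            "end": [s + 50 for s in starts],
            "arm": "p",
            "cytoband": "p11.1",
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return GeneAnnotation(df)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_pair(rng):
    """Small aligned expression/CN pair with a known linear relationship."""
    n_genes, n_samples = 12, 30
    cn = rng.normal(0, 0.6, size=(n_genes, n_samples))
    b1 = rng.normal(1.0, 0.2, size=n_genes)
    expr = 2.0 + b1[:, None] * cn + rng.normal(0, 0.5, size=(n_genes, n_samples))
    return (
        make_matrix(expr, kind="expression"),
        make_matrix(cn, kind="copy_number"),
    )
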