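import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scfocal.io_preprocess import GeneExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def qc_counts():
    """Ten cells with constructed feature counts spanning the QC boundaries.

    Detected-feature counts: 100, 200, 201, 300, 1000, 4499, 4500, 5000 (no
    mitochondrial counts), plus two 250-feature cells whose mitochondrial
    percentages are exactly 12.5% and strictly below 12.5%.
    """
    n_plain = 5000
    genes = [f"G{i}" for i in range(n_plain)] + ["MT-1"]
    detected = [100, 200, 201, 300, 1000, 4499, 4500, 5000]
    cells = [f"c{k}" for k in detected] + ["cmA", "cmB"]
    rows, cols, vals = [], [], []
    for j, k in enumerate(detected):
        rows.extend(range(k))
        cols.extend([j] * k)
        vals.extend([1.0] * k)
    # cmA: 249 plain genes totalling 252 counts + 36 mito counts -> 12.5% exactly
    rows.extend(range(249))
    cols.extend([8] * 249)
    vals.extend([4.0] + [1.0] * 248)
    rows.append(n_plain)
    cols.append(8)
    vals.append(36.0)
    # cmB: 249 plain genes @1 + 35 mito counts -> 35/284 = 12.32% < 12.5%
    rows.extend(range(249))
    cols.extend([9] * 249)
    vals.extend([1.0] * 249)
    rows.append(n_plain)
    cols.append(9)
    vals.append(35.0)
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n_plain + 1, 10)).tocsr()
    return GeneExpressionMatrix(genes, cells, mat, layer="counts")


@pytest.fixture
def toy_counts():
    counts = np.array(
        [
            [1.0, 0.0, 2.0],
            [0.0, 3.0, 0.0],
            [1.0, 1.0, 2.0],
        ]
    )
    return GeneExpressionMatrix(["g1", "g2", "g3"], ["c1", "c2", "c3"], counts)


def make_scaled(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return GeneExpressionMatrix(genes, cells, values, layer="scaled")


def make_lognorm(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return GeneExpressionMatrix(genes, cells, values, layer="lognorm")


@pytest.fixture
def small_atlas():
    """A small two-state atlas shared across tests (scaled + lognorm layers)."""
    from scfocal.io_preprocess import lognormalize, scale_genes
    from scfocal.simulate import AtlasSpec, generate_atlas

    spec = AtlasSpec(
        n_states=2,
        genes_per_module=30,
        n_background_genes=150,
        n_cells_per_state=40,
        n_subjects=3,
        n_normal_cells=60,
        seed=11,
    )
    expr, meta, truth = generate_atlas(spec)
    logn = lognormalize(expr)
    scaled = scale_genes(logn)
    return {"counts": expr, "lognorm": logn, "scaled": scaled, "meta": meta, "truth": truth}
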