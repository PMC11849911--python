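import numpy as np
import pandas as pd
import pytest

from dielwl.containers import ZT_GRID, REPLICATES, ExpressionTimeCourse, expression_columns


def make_course(values, accession="Acc", treatment="WW", genes=None):
    """Build an ExpressionTimeCourse from a (genes, 12) array ordered
    ZT-major (ZT1 r1..r3, ZT7 r1..r3, ...)."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=genes, columns=expression_columns())
    df.index.name = "gene_id"
    return ExpressionTimeCourse(accession, treatment, df)


def cosinor_course(phases, amplitude=1.0, baseline=4.0, noise_sd=0.0,
                   accession="Acc", treatment="WW", rng=None):
    """Noiseless-or-noisy cosinor courses, one gene per entry of phases."""
    rng = rng or np.random.default_rng(0)
    zts = np.asarray(ZT_GRID, float)
    rows = []
    for ph in phases:
        prof = baseline + amplitude * np.cos(2 * np.pi * (zts - ph) / 24.0)
        rows.append(np.repeat(prof, len(REPLICATES)))
    arr = np.asarray(rows)
    # columns of make_course are (zt, rep) product in ZT-major order already
    if noise_sd > 0:
        arr = arr + noise_sd * rng.standard_normal(arr.shape)
    return make_course(arr, accession=accession, treatment=treatment)


@pytest.fixture
def small_hmap():
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4", "g5", "g6"],
            "subgenome": ["BnA", "BnC", "BnA", "BnC", "BnC", "BnA"],
            "ortholog_group": ["OG1", "OG1", "OG2", "OG2", "OG2", "OG3"],
            "arabidopsis_ortholog": ["AT1", "AT1", "AT2", "AT2", "AT2", "AT3"],
        }
    )
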