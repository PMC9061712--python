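import numpy as np
import pandas as pd
import pytest

from qtltriad.core_data import (CovariateMatrix, GenotypeMatrix,
                                PhenotypeMatrix, VARIANT_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_genotypes(dosages, positions=None, chrom="1", sample_prefix="S"):
    """Build a GenotypeMatrix from a raw dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    if positions is None:
        positions = 1000 * (np.arange(p) + 1)
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(p)],
        "chrom": chrom,
        "pos": positions,
        "ref": "A",
        "alt": "G",
        "maf": np.nan,
    })[VARIANT_COLUMNS]
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    return GenotypeMatrix(samples, variants, dosages)


def make_phenotypes(values, kind="methylation", anchors=None, chrom="1"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if anchors is None:
        anchors = 1000 * (np.arange(p) + 1) + 100
    features = pd.DataFrame({
        "feature_id": [f"f{j}" for j in range(p)],
        "chrom": chrom,
        "anchor_pos": anchors,
        "strand": "+",
        "kind": kind,
    })
    samples = [f"S{i}" for i in range(n)]
    return PhenotypeMatrix(samples, features, values)
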