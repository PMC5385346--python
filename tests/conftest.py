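import numpy as np
import pandas as pd
import pytest

from xdosage.data_model import validate_dataset
from xdosage.synthetic_data import (default_paper_profile, generate_dataset,
                                    scaled_config)


def make_tiny_tables():
    """Hand-sized dataset: 6 genes x 4 IVF samples with known arithmetic."""
    annotation = pd.DataFrame({
        "gene_id": ["gA1", "gA2", "gX1", "gX2", "gY1", "gU1"],
        "symbol": ["GAPDH", "SYMA2", "XIST", "XG2", "UTY", "SCAF1"],
        "chrom": ["1", "2", "X", "X", "Y", "scaffold_12"],
        "start": [100, 200, 1000, 2_500_000, 300, 50],
        "end": [900, 800, 1900, 2_501_000, 900, 500],
        "strand": ["+", "-", "+", "+", "-", "+"],
    })
    matrix = pd.DataFrame(
        {
            "IVF_m_1": [10.0, 4.0, 0.0, 2.0, 5.0, 1.0],
            "IVF_m_2": [10.0, 6.0, 0.0, 2.0, 5.0, 1.0],
            "IVF_f_1": [10.0, 4.0, 50.0, 4.0, 0.0, 1.0],
            "IVF_f_2": [10.0, 6.0, 50.0, 4.0, 0.0, 1.0],
        },
        index=pd.Index(["gA1", "gA2", "gX1", "gX2", "gY1", "gU1"],
                       name="gene_id"),
    )
    samples = pd.DataFrame({
        "sample_id": ["IVF_m_1", "IVF_m_2", "IVF_f_1", "IVF_f_2"],
        "sex": ["male", "male", "female", "female"],
        "group": ["IVF"] * 4,
        "lineage": ["WHOLE"] * 4,
        "embryo_id": [""] * 4,
    })
    return annotation, matrix, samples


@pytest.fixture
def tiny_tables():
    return make_tiny_tables()


@pytest.fixture
def tiny_dataset():
    from xdosage.data_model import _finalize_annotation
    annotation, matrix, samples = make_tiny_tables()
    ann = _finalize_annotation(annotation,
                               housekeeping_list=["GAPDH", "ACTB"])
    return validate_dataset(ann, matrix, samples.set_index("sample_id"))


@pytest.fixture(scope="session")
def small_profile():
    """Size-reduced calibrated profile (same effect sizes, ~15% of the genes)
    for fast simulation-based tests."""
    return scaled_config(default_paper_profile(seed=11), 0.15)


@pytest.fixture(scope="session")
def small_ivf_dataset(small_profile):
    return generate_dataset(small_profile, groups=("IVF",))


@pytest.fixture(scope="session")
def small_all_groups_dataset():
    cfg = scaled_config(default_paper_profile(seed=5), 0.15)
    return generate_dataset(cfg)
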