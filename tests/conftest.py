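import numpy as np
import pandas as pd
import pytest

from cerna import CountMatrix, SynthParams, generate_study


def make_counts(values, genes=None, samples=None, groups=None) -> CountMatrix:
    """Small CountMatrix helper; defaults to 2 CTRL + 2 CASE samples."""
    arr = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    if groups is None:
        half = arr.shape[1] // 2
        groups = ["CTRL"] * half + ["CASE"] * (arr.shape[1] - half)
    return CountMatrix(
        pd.DataFrame(arr, index=genes, columns=samples),
        pd.Series(groups, index=samples),
    )


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study at generator defaults (fixed seed)."""
    return generate_study(SynthParams(seed=1))


@pytest.fixture(scope="session")
def null_study():
    """Zero-effect cohorts: no modules, no pairs, no group effect."""
    params = SynthParams(
        seed=5, n_genes=2000, n_modules=0, module_size=10, group_effect=0.0,
        n_true_pairs=0, n_decoy_no_mirna=0, n_decoy_low_corr=0,
        n_decoy_no_de=0, n_decoy_no_replication=0,
    )
    return generate_study(params)
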