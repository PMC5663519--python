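"""Shared fixtures: small synthetic atlases generated at test time."""

import numpy as np
import pandas as pd
import pytest

from ectoatlas import preprocessing as prep
from ectoatlas.containers import ExpressionMatrix
from ectoatlas.synthetic_data import (GeneratorConfig, generate_atlas,
                                      inject_homeolog_pairs)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_genes=800, n_homeolog_pairs=60, seed=11,
                           stages=("st12.5",))


@pytest.fixture(scope="session")
def small_atlas(small_config):
    cm, truth = generate_atlas(small_config)
    return inject_homeolog_pairs(cm, truth, small_config)


@pytest.fixture(scope="session")
def small_expr(small_atlas):
    cm, _ = small_atlas
    cm = prep.filter_low_counts(cm)
    return prep.to_log2_cpm(cm, prep.tmm_factors(cm))


def make_expression(values: np.ndarray, regions=None, stages=None,
                    we=None, prefix="s") -> ExpressionMatrix:
    """Wrap a plain array of log2 expression into an ExpressionMatrix."""
    n_genes, n_samples = values.shape
    cols = [f"{prefix}{j}" for j in range(n_samples)]
    idx = [f"g{i}" for i in range(n_genes)]
    meta = pd.DataFrame({
        "stage": stages if stages is not None else ["st1"] * n_samples,
        "region": regions if regions is not None else ["R"] * n_samples,
        "replicate": list(range(n_samples)),
        "is_whole_embryo": we if we is not None else [False] * n_samples,
    }, index=pd.Index(cols, name="sample"))
    return ExpressionMatrix(pd.DataFrame(values, index=idx, columns=cols),
                            pd.Series(1.0, index=cols), 0.5, meta)
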