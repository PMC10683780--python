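import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from grnbench import ExpressionMatrix, RegulonSet, SensitivityMatrix


@pytest.fixture
def small_expr():
    """6 genes x 4 samples, nonnegative, no zeros."""
    rng = np.random.default_rng(42)
    vals = pd.DataFrame(
        rng.uniform(1, 10, size=(6, 4)),
        index=[f"G{i}" for i in range(1, 7)],
        columns=[f"S{i}" for i in range(1, 5)])
    return ExpressionMatrix(vals)


@pytest.fixture
def two_reg_regulon():
    """Two regulators over the genes of small_expr."""
    edges = pd.DataFrame({
        "regulator": ["R1", "R1", "R1", "R2", "R2", "R2"],
        "target": ["G1", "G2", "G3", "G4", "G5", "G6"],
        "weight": [1.0, 0.5, 0.8, 0.9, 0.7, 1.0],
        "mor": [1.0, -1.0, 1.0, 1.0, 1.0, -1.0],
    })
    return RegulonSet(edges, source="synthetic")


@pytest.fixture
def toy_sensitivity():
    """6 genes x 8 cell lines, two cancer types, hand-chosen scores around -0.6."""
    genes = ["ESS_ALL", "NON_ALL", "MIXED_A", "MIXED_B", "RARE_ESS", "BOUNDARY"]
    lines = [f"L{i}" for i in range(1, 9)]
    vals = pd.DataFrame([
        [-1.0, -0.9, -2.0, -0.7, -1.5, -0.8, -1.1, -0.61],   # essential everywhere
        [0.1, -0.2, 0.0, -0.5, 0.3, -0.1, 0.2, -0.59],       # never essential
        [-0.7, -0.8, 0.0, 0.1, -0.9, 0.2, -1.2, 0.3],        # 4 ess / 4 non
        [-0.7, 0.0, 0.1, 0.2, 0.3, 0.4, 0.5, -0.65],         # 2 ess / 6 non
        [-0.7, 0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6],           # 1 ess / 7 non
        [-0.6, -0.6, -0.6, -0.6, 0.0, 0.0, 0.0, 0.0],        # threshold exactly
    ], index=genes, columns=lines)
    types = pd.Series(["A"] * 4 + ["B"] * 4, index=lines)
    return SensitivityMatrix(vals, types)
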