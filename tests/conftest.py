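import numpy as np
import pandas as pd
import pytest

from psem.preprocess import compute_relative_abundances
from psem.simulate import GeneratorSpec, generate, preset


@pytest.fixture(scope="session")
def study_dataset():
    """Study-shaped synthetic dataset (90 samples, 62 genera)."""
    counts, meta, truth = generate(preset("study", seed=7))
    return counts, meta, truth


@pytest.fixture(scope="session")
def small_table():
    """Tiny hand-made abundance table with two replicate groups."""
    counts = pd.DataFrame(
        {
            "s1": [10, 30, 0, 1],
            "s2": [5, 5, 0, 0],
            "s3": [0, 8, 2, 0],
        },
        index=["tA", "tB", "tC", "tD"],
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "weight_g": [100.0, 200.0, 300.0],
            "age_d": [16, 28, 39],
            "sex": ["male", "female", "male"],
            "compartment": ["cloaca", "caecum", "caecum"],
            "bsf_pct": [0, 5, 10],
            "replicate": ["R1", "R1", "R2"],
        }
    )
    return compute_relative_abundances(counts, meta)


def random_categorical_frame(rng, n_rows, arities):
    return pd.DataFrame(
        {f"V{i}": rng.integers(0, a, size=n_rows) for i, a in enumerate(arities)}
    )
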