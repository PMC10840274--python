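import numpy as np
import pandas as pd
import pytest

from cnimpact.containers import CopyNumberProfile, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_expr():
    return ExpressionMatrix(
        pd.DataFrame(
            [[5, 8, 2], [0, 3, 7]],
            index=pd.Index(["G1", "G2"], name="gene_id"),
            columns=pd.Index(["S1", "S2", "S3"], name="sample_id"),
        )
    )


@pytest.fixture
def small_cn():
    idx = pd.Index(["G1", "G2"], name="gene_id")
    cols = pd.Index(["S1", "S2", "S3"], name="sample_id")
    major = pd.DataFrame([[2.0, 3.0, 1.0], [1.0, np.nan, 4.0]], index=idx, columns=cols)
    minor = pd.DataFrame([[1.0, 2.0, 0.0], [1.0, np.nan, 2.0]], index=idx, columns=cols)
    return CopyNumberProfile(major, minor)


def dispersed_cn(rng, n, probs=(0.03, 0.07, 0.25, 0.2, 0.15, 0.12, 0.08, 0.06, 0.04)):
    """Dispersed allele-specific CN states for model-fitting tests."""
    total = rng.choice(np.arange(len(probs)), size=n, p=np.asarray(probs))
    b = np.floor(total / 2.0)
    imb = rng.random(n) < 0.3
    b[imb] = rng.integers(0, np.floor(total[imb] / 2.0).astype(int) + 1)
    return total - b, b
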