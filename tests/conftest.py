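import numpy as np
import pytest

from devswitch.datatypes import ExpressionProfile, Sample


@pytest.fixture
def make_profile():
    """Factory building an ExpressionProfile from values and ages (PCD)."""

    def _make(values, ages, gene="G", region="CBC"):
        values = np.asarray(values, dtype=float)
        ages = np.asarray(ages, dtype=float)
        samples = [
            Sample(f"s{i:03d}", f"s{i:03d}", region, float(a))
            for i, a in enumerate(ages)
        ]
        return ExpressionProfile(gene=gene, values=values, samples=samples)

    return _make


@pytest.fixture
def log_uniform_ages():
    """Ages (PCD) drawn log-uniform over the full developmental range."""

    def _draw(n, seed):
        rng = np.random.default_rng(seed)
        return np.sort(np.exp(rng.uniform(np.log(70.0), np.log(30000.0), n)))

    return _draw
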