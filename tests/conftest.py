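import numpy as np
import pandas as pd
import pytest

from aopke import CompoundSpec, CountMatrix, SampleMeta, generate_dose_response


@pytest.fixture
def make_dataset():
    """Factory for synthetic single-endpoint dose-response datasets."""

    def _make(
        ec50=1e-6,
        h=1.5,
        noise_sd=0.0,
        n_replicates=3,
        seed=0,
        top=1e-4,
        endpoint="V",
        compound_id="cmp",
    ):
        spec = CompoundSpec(
            compound_id, "cI", {endpoint: ec50}, {endpoint: h}, top
        )
        return generate_dose_response(
            spec, endpoint, noise_sd=noise_sd, n_replicates=n_replicates, seed=seed
        )

    return _make


@pytest.fixture
def toy_counts():
    """Factory for small hand-sized count matrices with paired metadata."""

    def _make(counts: np.ndarray, n_control: int, compound="cmp", conc=1e-6):
        counts = np.asarray(counts)
        n = counts.shape[1]
        samples = [f"s{j}" for j in range(n)]
        genes = [f"g{i}" for i in range(counts.shape[0])]
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "compound_id": compound,
                "concentration_M": [0.0] * n_control + [conc] * (n - n_control),
                "replicate": list(range(1, n_control + 1))
                + list(range(1, n - n_control + 1)),
            }
        )
        return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples)), SampleMeta(meta)

    return _make
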