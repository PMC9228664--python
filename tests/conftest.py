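import numpy as np
import pandas as pd
import pytest

from ratiogwas.qc import GenotypeMatrix
from ratiogwas.simulate import demo_config, simulate_cohort


def make_genotypes(dosages, chrom="1", positions=None, ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain array (rows = samples)."""
    d = np.asarray(dosages, dtype=float)
    n_var = d.shape[1]
    if positions is None:
        positions = 1000 * np.arange(1, n_var + 1)
    if ids is None:
        ids = [f"v{j + 1}" for j in range(n_var)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "id": ids,
            "ref": "A",
            "alt": "G",
            "is_indel": False,
        }
    )
    return GenotypeMatrix(
        dosages=d,
        variants=variants,
        sample_ids=[f"S{i + 1:04d}" for i in range(d.shape[0])],
    )


@pytest.fixture(scope="session")
def demo_cohort():
    """The standard demonstration cohort (520 samples, 200 variants,
    branch + conversion effects in LD blocks). Session-scoped: several
    modules exercise different stages on the same cohort."""
    return simulate_cohort(demo_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
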